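"""Traffic covariates from a road network with AADT attributes.

Three covariates drive the exposure models:

* a kernel traffic-density surface — each road segment's AADT×length mass
  spread with a quadratic (Silverman) kernel that is maximal on the road
  and falls to zero at the search radius (300 m and 500 m in the study);
* length-weighted AADT, Σ(AADT·length)/Σ(length) over the roadway clipped
  to a 500 m disc around the query point;
* distance to (and class of) the nearest road.

Coordinates are planar metres (see :mod:`pbpah.projection`). Densities are
reported in vehicles/day·km per km².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

__all__ = [
    "RoadSegment",
    "RoadNetwork",
    "kernel_density_at",
    "density_surface",
    "length_weighted_aadt",
    "nearest_road",
]

ROAD_CLASSES = ("freeway_highway", "other")


@dataclass(frozen=True)
class RoadSegment:
    segment_id: int
    geometry: LineString
    aadt: float
    road_class: str = "other"

    def __post_init__(self):
        if len(self.geometry.coords) < 2 or self.geometry.length <= 0:
            raise ValueError(f"segment {self.segment_id}: degenerate geometry")
        if self.aadt < 0:
            raise ValueError(f"segment {self.segment_id}: negative AADT")
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"segment {self.segment_id}: unknown road_class {self.road_class!r}")


@dataclass
class RoadNetwork:
    """A collection of road segments with a spatial index for range queries."""

    segments: list[RoadSegment]
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment_id in network")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree([s.geometry for s in self.segments])
        return self._tree

    def query_within(self, point: Point, radius: float) -> list[RoadSegment]:
        """Segments whose geometry intersects the disc of ``radius`` around ``point``."""
        idx = self.tree.query(point.buffer(radius))
        hits = [
            self.segments[i]
            for i in idx
            if self.segments[i].geometry.distance(point) <= radius
        ]
        hits.sort(key=lambda s: s.segment_id)
        return hits

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(s.geometry)),
                "properties": {
                    "segment_id": s.segment_id,
                    "aadt": s.aadt,
                    "road_class": s.road_class,
                },
            }
            for s in self.segments
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RoadNetwork":
        with open(path) as fh:
            fc = json.load(fh)
        segs = []
        for i, feat in enumerate(fc["features"]):
            geom = feat["geometry"]
            if geom["type"] != "LineString":
                raise ValueError(f"feature {i}: expected LineString, got {geom['type']}")
            props = feat.get("properties", {})
            segs.append(
                RoadSegment(
                    segment_id=int(props.get("segment_id", i)),
                    geometry=LineString(geom["coordinates"]),
                    aadt=float(props["aadt"]),
                    road_class=props.get("road_class", "other"),
                )
            )
        return cls(segs)


def quadratic_kernel(dist, radius: float):
    """Planar quadratic (Silverman) kernel, unit mass over the plane.

    K(d) = 3/(pi r^2) (1 - (d/r)^2)^2 for d < r, else 0; units 1/m^2.
    """
    d = np.asarray(dist, dtype=float)
    u2 = np.clip((d / radius) ** 2, 0.0, 1.0)
    return 3.0 / (np.pi * radius**2) * (1.0 - u2) ** 2 * (d < radius)


def _discretize(segment: RoadSegment, step: float = 5.0):
    """Quadrature points (midpoints) and sub-lengths (m) along a segment."""
    n = max(1, int(np.ceil(segment.geometry.length / step)))
    edges = np.linspace(0.0, segment.geometry.length, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    pts = shapely.line_interpolate_point(segment.geometry, mids)
    coords = shapely.get_coordinates(pts)
    return coords, np.diff(edges)


def kernel_density_at(point, network: RoadNetwork, radius: float, step: float = 5.0) -> float:
    """Kernel traffic density at a point, vehicles/day·km per km².

    Each segment is discretized at <= ``step`` m; every sub-segment carries
    mass AADT · sublength(km) which is spread by the quadratic kernel.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = point if isinstance(point, Point) else Point(point)
    total = 0.0
    for seg in network.query_within(p, radius):
        coords, sublen = _discretize(seg, step)
        d = np.hypot(coords[:, 0] - p.x, coords[:, 1] - p.y)
        # mass in vehicles/day·km, kernel in 1/m^2 -> x 1e6 for per-km^2
        total += float(np.sum(seg.aadt * (sublen / 1000.0) * quadratic_kernel(d, radius)))
    return total * 1e6


def density_surface(
    network: RoadNetwork,
    radius: float,
    cell_size: float = 20.0,
    extent: tuple[float, float, float, float] = None,
):
    """Raster of kernel density at cell centres.

    ``extent`` is (xmin, ymin, xmax, ymax); origin is the extent minimum
    corner, rows ordered north-up (row 0 = northernmost), row-major.
    Returns (grid, x_centres, y_centres).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if extent is None:
        raise ValueError("extent is required")
    xmin, ymin, xmax, ymax = extent
    nx = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    xc = xmin + cell_size * (np.arange(nx) + 0.5)
    yc = ymin + cell_size * (np.arange(ny) + 0.5)
    grid = np.zeros((ny, nx))
    for i, y in enumerate(yc[::-1]):  # north-up
        for j, x in enumerate(xc):
            grid[i, j] = kernel_density_at((x, y), network, radius)
    return grid, xc, yc


def write_ascii_grid(path, grid, xmin, ymin, cell_size, nodata=-9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (north-up row order preserved)."""
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {xmin}\nyllcorner {ymin}\n"
        f"cellsize {cell_size}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%.6g")


def length_weighted_aadt(
    point, network: RoadNetwork, radius: float = 500.0, clipped: bool = True
) -> float | None:
    """Σ(AADT·length)/Σ(length) over roadway within ``radius`` of the point.

    With ``clipped`` (default) only the portion of each segment inside the
    disc contributes its length; otherwise whole-segment lengths are used
    for every intersecting segment. Returns None when no roadway intersects
    the disc.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = point if isinstance(point, Point) else Point(point)
    disc = p.buffer(radius, quad_segs=64)
    num = den = 0.0
    for seg in network.query_within(p, radius):
        length = seg.geometry.intersection(disc).length if clipped else seg.geometry.length
        num += seg.aadt * length
        den += length
    if den == 0.0:
        return None
    return num / den


def nearest_road(point, network: RoadNetwork) -> tuple[float, str]:
    """Distance (m) to the nearest segment and its road class.

    Ties are broken by the lower segment_id. Raises on an empty network.
    """
    if len(network) == 0:
        raise ValueError("empty road network")
    p = point if isinstance(point, Point) else Point(point)
    best = min(
        network.segments, key=lambda s: (round(s.geometry.distance(p), 9), s.segment_id)
    )
    return best.geometry.distance(p), best.road_class
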