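#!/usr/bin/env python
"""Step 3 — attach traffic covariates to each minute record.

Computes, at every minute's mean position, the quadratic-kernel traffic
density (300 m bandwidth) and the length-weighted AADT within 500 m, and
writes a kernel-density raster of the study area for inspection. Writes
``results/interim/minutes_traffic.csv`` and ``results/figures/density.asc``.
"""

import argparse
from pathlib import Path

import numpy as np

from pbpah import io as pio
from pbpah.aggregation import attach_traffic_metrics
from pbpah.spatial_traffic import RoadNetwork, density_surface, write_ascii_grid

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--raw", type=Path, default=RESULTS / "raw")
    ap.add_argument("--interim", type=Path, default=RESULTS / "interim")
    ap.add_argument("--cell-size", type=float, default=100.0)
    args = ap.parse_args()

    network = RoadNetwork.from_geojson(args.raw / "network.geojson")
    minutes = pio.read_minutes_csv(args.interim / "minutes.csv")

    minutes = attach_traffic_metrics(minutes, network)
    pio.write_minutes_csv(minutes, args.interim / "minutes_traffic.csv")

    lw = minutes["lw_aadt_500"]
    print(f"minutes with a road within 500 m: {lw.notna().sum()}/{len(minutes)}")
    print(f"length-weighted AADT: mean {lw.mean():.0f}, sd {lw.std():.0f}, "
          f"range [{lw.min():.0f}, {lw.max():.0f}]")
    print(f"kernel density_300: mean {minutes['density_300'].mean():.0f}, "
          f"max {minutes['density_300'].max():.0f} veh/day*km per km^2")

    xs = np.array([s.geometry.bounds for s in network.segments])
    extent = (xs[:, 0].min(), xs[:, 1].min(), xs[:, 2].max(), xs[:, 3].max())
    grid, *_ = density_surface(network, radius=300.0, cell_size=args.cell_size,
                               extent=extent)
    figdir = RESULTS / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(figdir / "density.asc", grid, extent[0], extent[1], args.cell_size)
    print(f"wrote {args.interim / 'minutes_traffic.csv'} and {figdir / 'density.asc'} "
          f"({grid.shape[0]}x{grid.shape[1]} cells)")


if __name__ == "__main__":
    main()
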