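"""Synthetic cohorts with the statistical structure of a GPS/PAH field study.

Two generators live here.

The *trajectory* generator builds a planar grid road network with AADT
attributes, template-based daily schedules (home dwell, vehicle trips
along roads, outdoor walks), 15-s GPS fixes with ground-truth activity
labels, minute-level particle-bound PAH concentrations that are lognormal
within each activity category, plus weather and questionnaire tables. Its
defaults reproduce the study-scale structure: subjects spend ~91.3% of
minutes indoors, 4.5% in vehicles and 4.2% in other activities, with
category geometric means 46.8 (in-vehicle), 1.9 (indoor) and 3.2 (other)
ng/m³, a 1 ng/m³ detection floor and a 4000 ng/m³ ceiling.

The *tabular* generator draws analysis-level records directly from a
stated regression model (coefficients, predictor distributions, residual
SD, optional subject random effects on the sqrt-concentration scale) for
parameter-recovery experiments against the published coefficient tables.

All outputs are byte-deterministic for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .spatial_traffic import RoadNetwork, RoadSegment

__all__ = [
    "SimulationConfig",
    "SubjectProfile",
    "TabularModelSpec",
    "generate_road_network",
    "generate_subjects",
    "simulate_subject_day",
    "simulate_pah_minutes",
    "simulate_cohort",
    "simulate_regression_table",
    "simulate_microenvironment_table",
    "daily_model_spec",
    "daily_mixed_model_spec",
    "subject_model_spec",
    "MICROENV_MODEL",
]

# grid origin in UTM 11N metres (southern California) so that inverse
# projection of synthetic x/y yields plausible lat/lon
ORIGIN_X = 430_000.0
ORIGIN_Y = 3_740_000.0

STUDY_TZ = "America/Los_Angeles"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the trajectory generator.

    Geometric means are the published per-category values; per-category
    GSDs are not published and the defaults are package choices kept small
    enough that the 1 ng/m³ detection floor shifts sample GMs by < 2%.
    """

    n_subjects: int = 28
    days_per_subject: tuple[int, int] = (3, 10)  # inclusive range, ~6.5 mean
    seed: int = 0
    indoor_gm: float = 1.9
    invehicle_gm: float = 46.8
    other_gm: float = 3.2
    gsd_by_category: dict = field(
        default_factory=lambda: {"indoor": 1.5, "in_vehicle": 2.0, "other": 2.0}
    )
    fraction_invehicle: float = 0.045
    fraction_other: float = 0.042
    grid_extent: float = 5000.0
    road_spacing: float = 500.0
    aadt_range: tuple[float, float] = (5000.0, 80000.0)
    freeway_fraction: float = 0.15
    gps_noise_sd: float = 5.0
    weekday_prob: float = 0.73
    indoor_spike_prob: float = 0.0  # rare >1000 ng/m³ indoor spikes (QA exercise)
    day_truncation_prob: float = 0.0  # battery-failure style short days
    waking_minutes: int = 900  # 07:00-22:00
    study_start: str = "2009-08-03"
    study_days: int = 450

    def __post_init__(self):
        if not (0 <= self.fraction_invehicle <= 1 and 0 <= self.fraction_other <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.fraction_invehicle + self.fraction_other > 1:
            raise ValueError("fraction_invehicle + fraction_other must be <= 1")
        for gm in (self.indoor_gm, self.invehicle_gm, self.other_gm):
            if gm <= 0:
                raise ValueError("geometric means must be positive")
        if any(g < 1 for g in self.gsd_by_category.values()):
            raise ValueError("GSDs must be >= 1")
        if self.aadt_range[0] < 0 or self.aadt_range[1] <= self.aadt_range[0]:
            raise ValueError("aadt_range must be positive and increasing")
        if self.road_spacing <= 0 or self.grid_extent <= 0:
            raise ValueError("road spacing and extent must be positive")
        if self.grid_extent < 2 * self.road_spacing:
            raise ValueError("grid_extent must be at least 2 * road_spacing")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    home_location: tuple[float, float]
    works: bool
    work_location: tuple[float, float] | None = None
    work_related_exposure: bool = False
    speaks_english_at_home: bool = True
    vehicle_type: str = "asian"
    income_category: str = "middle"

    def __post_init__(self):
        if self.works != (self.work_location is not None):
            raise ValueError("work_location must be present iff works")
        if self.work_related_exposure and not self.works:
            raise ValueError("work_related_exposure implies works")


def generate_road_network(config: SimulationConfig, rng: np.random.Generator | None = None) -> RoadNetwork:
    """Planar grid of road polylines with uniform AADT draws.

    Lines every ``road_spacing`` m across ``grid_extent``; a configurable
    fraction is tagged freeway/highway. Deterministic under the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_lines = int(config.grid_extent // config.road_spacing) + 1
    segs = []
    sid = 0
    lo, hi = config.aadt_range
    for i in range(n_lines):
        off = i * config.road_spacing
        for geom in (
            LineString([(ORIGIN_X + off, ORIGIN_Y), (ORIGIN_X + off, ORIGIN_Y + config.grid_extent)]),
            LineString([(ORIGIN_X, ORIGIN_Y + off), (ORIGIN_X + config.grid_extent, ORIGIN_Y + off)]),
        ):
            aadt = rng.uniform(lo, hi)
            cls = "freeway_highway" if rng.random() < config.freeway_fraction else "other"
            segs.append(RoadSegment(sid, geom, aadt, cls))
            sid += 1
    return RoadNetwork(segs)


def generate_subjects(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[SubjectProfile]:
    """Subject profiles with homes (and workplaces) inside the grid."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    margin = config.road_spacing
    profiles = []
    for i in range(config.n_subjects):
        home = (
            ORIGIN_X + rng.uniform(margin, config.grid_extent - margin),
            ORIGIN_Y + rng.uniform(margin, config.grid_extent - margin),
        )
        works = bool(rng.random() < 0.6)  # ~40% of subjects did not work
        work = (
            (
                ORIGIN_X + rng.uniform(margin, config.grid_extent - margin),
                ORIGIN_Y + rng.uniform(margin, config.grid_extent - margin),
            )
            if works
            else None
        )
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                home_location=home,
                works=works,
                work_location=work,
                work_related_exposure=bool(works and rng.random() < 0.30),
                speaks_english_at_home=bool(rng.random() < 0.6),
                vehicle_type=rng.choice(["asian", "german", "us"]),
                income_category=rng.choice(["low", "middle", "high"]),
            )
        )
    return profiles


def _nearest_grid_line(point: tuple[float, float], network: RoadNetwork) -> LineString:
    from shapely.geometry import Point

    p = Point(point)
    best = min(network.segments, key=lambda s: (s.geometry.distance(p), s.segment_id))
    return best.geometry


def _truncnorm(rng, sd, size):
    """Normal(0, sd) truncated at +-3 sd (keeps construction bounds exact)."""
    return np.clip(rng.normal(0.0, sd, size), -3 * sd, 3 * sd)


def _minute_schedule(config: SimulationConfig, profile: SubjectProfile, rng) -> list[str]:
    """Per-minute truth categories for one waking day (template schedule).

    Day-level variation in travel/walk time uses a mean-one lognormal
    multiplier (CV ~ 1, matching the heavy day-to-day spread of observed
    in-vehicle percentages).
    """
    total = config.waking_minutes
    mult = rng.lognormal(-0.405, 0.9)  # mean 1
    n_iv = int(np.clip(round(total * config.fraction_invehicle * mult), 0, total // 3))
    mult_o = rng.lognormal(-0.405, 0.9)
    n_other = int(np.clip(round(total * config.fraction_other * mult_o), 0, total // 3))
    n_indoor = total - n_iv - n_other

    trip1 = n_iv // 2
    trip2 = n_iv - trip1
    # morning dwell, trip out, midday dwell (work if employed), walk,
    # trip back, evening dwell
    a = n_indoor // 3
    b = n_indoor // 3
    c = n_indoor - a - b
    schedule = (
        ["indoor_home"] * a
        + ["in_vehicle"] * trip1
        + (["indoor_work"] if profile.works else ["indoor_home"]) * b
        + ["other"] * n_other
        + ["in_vehicle"] * trip2
        + ["indoor_home"] * c
    )
    return schedule


def simulate_subject_day(
    profile: SubjectProfile,
    network: RoadNetwork,
    date,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One waking day of 15-s fixes plus the per-minute truth labels.

    Indoor fixes jitter about the home/work anchor at near-zero speed;
    in-vehicle fixes move along the nearest road polyline at driving
    speed; 'other' fixes walk near the anchor. Positions are perturbed by
    ``gps_noise_sd`` (truncated at 3 sd). Raises when ``date`` falls
    outside the configured study window.
    """
    date = pd.Timestamp(date)
    start = pd.Timestamp(config.study_start)
    if not (start <= date < start + pd.Timedelta(days=config.study_days)):
        raise ValueError(f"date {date.date()} outside study window")

    from shapely.geometry import Point

    schedule = _minute_schedule(config, profile, rng)
    road = _nearest_grid_line(profile.home_location, network)
    # the drive starts at the nearest point on that road to home
    s0 = road.project(Point(profile.home_location))

    day_start = date.tz_localize(STUDY_TZ) + pd.Timedelta(hours=7)
    n_min = len(schedule)
    if config.day_truncation_prob > 0 and rng.random() < config.day_truncation_prob:
        n_min = int(rng.integers(30, 360))
        schedule = schedule[:n_min]

    times, xs, ys, speeds, labels15 = [], [], [], [], []
    arc = s0  # position along the road for vehicle motion
    direction = 1.0
    walk_angle = rng.uniform(0, 2 * np.pi)
    for m, slot in enumerate(schedule):
        anchor = (
            profile.work_location if slot == "indoor_work" else profile.home_location
        )
        for k in range(4):
            t = day_start + pd.Timedelta(seconds=15 * (4 * m + k))
            if slot.startswith("indoor"):
                x = anchor[0] + float(_truncnorm(rng, 3.0, 1)[0])
                y = anchor[1] + float(_truncnorm(rng, 3.0, 1)[0])
                v = abs(rng.normal(0.3, 0.4))
                lab = "indoor"
            elif slot == "in_vehicle":
                v = float(np.clip(rng.normal(40.0, 10.0), 15.0, 90.0))
                arc += direction * v / 3.6 * 15.0
                if arc >= road.length or arc <= 0.0:  # ping-pong at road ends
                    direction *= -1.0
                    arc = float(np.clip(arc, 0.0, road.length))
                pt = road.interpolate(arc)
                x, y = pt.x, pt.y
                lab = "in_vehicle"
            else:  # walking / outdoor static
                v = float(np.clip(rng.normal(3.5, 1.0), 2.2, 6.0))
                walk_angle += rng.normal(0, 0.4)
                r = 60.0 + 40.0 * np.sin(m / 7.0)
                x = profile.home_location[0] + r * np.cos(walk_angle)
                y = profile.home_location[1] + r * np.sin(walk_angle)
                lab = "other"
            times.append(t)
            xs.append(x)
            ys.append(y)
            speeds.append(max(v + float(rng.normal(0, 0.2)), 0.0))
            labels15.append(lab)

    noise_x = _truncnorm(rng, config.gps_noise_sd, len(xs))
    noise_y = _truncnorm(rng, config.gps_noise_sd, len(ys))
    fixes = pd.DataFrame(
        {
            "subject_id": profile.subject_id,
            "timestamp": times,
            "x": np.asarray(xs) + noise_x,
            "y": np.asarray(ys) + noise_y,
            "speed_kmh": speeds,
            "altitude_m": 30.0 + 2.0 * _truncnorm(rng, 1.0, len(xs)),
            "truth": labels15,
        }
    )
    truth_minutes = pd.DataFrame(
        {
            "subject_id": profile.subject_id,
            "minute": [day_start + pd.Timedelta(minutes=m) for m in range(len(schedule))],
            "category": ["indoor" if s.startswith("indoor") else s for s in schedule],
        }
    )
    return fixes, truth_minutes


def simulate_pah_minutes(
    truth_minutes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """1-min PAH concentrations, lognormal within each activity category.

    Values are floored at the 1 ng/m³ detection limit and capped at the
    4000 ng/m³ instrument ceiling. With ``indoor_spike_prob`` > 0, rare
    indoor minutes are replaced by >1000 ng/m³ spikes (indoor-source /
    noise events that downstream QA is expected to remove). Unknown
    category labels raise.
    """
    gm = {"indoor": config.indoor_gm, "in_vehicle": config.invehicle_gm, "other": config.other_gm}
    vals = np.empty(len(truth_minutes))
    for i, cat in enumerate(truth_minutes["category"]):
        if cat not in gm:
            raise ValueError(f"unknown category label {cat!r}")
        v = rng.lognormal(np.log(gm[cat]), np.log(config.gsd_by_category[cat]))
        if cat == "indoor" and config.indoor_spike_prob > 0 and rng.random() < config.indoor_spike_prob:
            v = rng.uniform(1001.0, 4000.0)
        vals[i] = v
    out = truth_minutes[["subject_id", "minute"]].copy()
    out["pah_ng_m3"] = np.clip(vals, 1.0, 4000.0)
    return out


def simulate_weather(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hourly weather at two synthetic stations over the study window."""
    hours = pd.date_range(
        pd.Timestamp(config.study_start).tz_localize(STUDY_TZ),
        periods=config.study_days * 24,
        freq="h",
    )
    frames = []
    for sid, (sx, sy) in enumerate(
        [(ORIGIN_X - 2000.0, ORIGIN_Y - 2000.0), (ORIGIN_X + config.grid_extent + 2000.0, ORIGIN_Y + config.grid_extent + 2000.0)]
    ):
        h = np.arange(len(hours))
        temp = 21.1 + 6.0 * np.sin(2 * np.pi * (h % 24 - 9) / 24) + rng.normal(0, 1.5, len(hours))
        wind = np.clip(rng.gamma(6.0, 0.7, len(hours)), 0.1, None)
        hum = np.clip(rng.normal(63.0, 12.0, len(hours)), 5, 100)
        frames.append(
            pd.DataFrame(
                {
                    "station_id": f"W{sid}",
                    "x": sx,
                    "y": sy,
                    "timestamp": hours,
                    "temperature_c": temp,
                    "wind_speed_ms": wind,
                    "humidity_pct": hum,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def questionnaire_table(profiles: list[SubjectProfile]) -> pd.DataFrame:
    """Session-1 questionnaire rows derived from the subject profiles."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "session": 1,
            "work_related_exposure": [int(p.work_related_exposure) for p in profiles],
            "pregnancy": 1,
            "working": [int(p.works) for p in profiles],
            "housing": "owned",
            "vehicle_type": [p.vehicle_type for p in profiles],
            "income": [p.income_category for p in profiles],
            "language": ["english" if p.speaks_english_at_home else "other" for p in profiles],
        }
    )


def simulate_cohort(config: SimulationConfig) -> dict:
    """Full synthetic study: network, subjects, fixes, truth, PAH, weather.

    Returns a dict with keys ``network``, ``profiles``, ``fixes``,
    ``truth_minutes``, ``pah``, ``weather``, ``questionnaire``.
    Deterministic for a fixed config (all randomness spawns from
    ``config.seed``).
    """
    root = np.random.SeedSequence(config.seed)
    ss_net, ss_subj, ss_days, ss_pah, ss_met = root.spawn(5)
    network = generate_road_network(config, np.random.default_rng(ss_net))
    profiles = generate_subjects(config, np.random.default_rng(ss_subj))
    rng_days = np.random.default_rng(ss_days)
    start = pd.Timestamp(config.study_start)

    fixes_all, truth_all = [], []
    for p in profiles:
        n_days = int(rng_days.integers(config.days_per_subject[0], config.days_per_subject[1] + 1))
        offset = int(rng_days.integers(0, config.study_days - 8 * n_days - 1))
        # weekday/weekend mix targets weekday_prob; day cursor only moves
        # forward so per-subject timestamps stay strictly increasing
        day = start + pd.Timedelta(days=offset)
        for _ in range(n_days):
            want_weekday = rng_days.random() < config.weekday_prob
            while (day.dayofweek < 5) != want_weekday:
                day += pd.Timedelta(days=1)
            fixes, truth = simulate_subject_day(p, network, day, config, rng_days)
            day += pd.Timedelta(days=1)
            fixes_all.append(fixes)
            truth_all.append(truth)
    truth_minutes = pd.concat(truth_all, ignore_index=True)
    pah = simulate_pah_minutes(truth_minutes, config, np.random.default_rng(ss_pah))
    return {
        "network": network,
        "profiles": profiles,
        "fixes": pd.concat(fixes_all, ignore_index=True),
        "truth_minutes": truth_minutes,
        "pah": pah,
        "weather": simulate_weather(config, np.random.default_rng(ss_met)),
        "questionnaire": questionnaire_table(profiles),
    }


# ---------------------------------------------------------------------------
# Tabular simulator keyed to published coefficient tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TabularModelSpec:
    """A generative regression model on the sqrt-concentration scale.

    ``predictors`` maps each name to a distribution tuple:
    ("normal", mu, sd), ("bernoulli", p), ("halfnormal", mu, sd) — values
    |N(mu, sd)| — or ("clipnormal", mu, sd, lo, hi). Optional subject
    random effects (independent intercept and slope on
    ``random_slope_term``) turn the table into clustered person-days.
    """

    name: str
    intercept: float
    coefficients: tuple  # ((name, beta), ...)
    residual_sd: float
    predictors: dict
    n_records: int
    random_intercept_sd: float = 0.0
    random_slope_sd: float = 0.0
    random_slope_term: str | None = None
    n_groups: int = 0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        for name, _ in self.coefficients:
            if name not in self.predictors:
                raise ValueError(f"coefficient {name!r} has no predictor distribution")
        if self.random_slope_sd > 0 and self.random_slope_term is None:
            raise ValueError("random_slope_sd set without random_slope_term")


def _draw(dist: tuple, n: int, rng) -> np.ndarray:
    family = dist[0]
    if family == "normal":
        return rng.normal(dist[1], dist[2], n)
    if family == "bernoulli":
        return (rng.random(n) < dist[1]).astype(float)
    if family == "halfnormal":
        return np.abs(rng.normal(dist[1], dist[2], n))
    if family == "clipnormal":
        return np.clip(rng.normal(dist[1], dist[2], n), dist[3], dist[4])
    raise ValueError(f"unknown predictor family {family!r}")


def simulate_regression_table(spec: TabularModelSpec, seed) -> pd.DataFrame:
    """Draw ``n_records`` rows: predictors per their distributions, outcome
    = intercept + Σ beta·x (+ subject effects) + Gaussian residual.

    With random-effect SDs set, rows carry ``subject_id`` and records are
    split as evenly as possible over ``n_groups`` subjects.
    """
    if spec.residual_sd <= 0 and spec.residual_sd != 0.0:
        raise ValueError("residual_sd must be positive")
    rng = np.random.default_rng(seed)
    n = spec.n_records
    table = pd.DataFrame({name: _draw(d, n, rng) for name, d in spec.predictors.items()})
    lp = spec.intercept + sum(beta * table[name] for name, beta in spec.coefficients)

    clustered = spec.random_intercept_sd > 0 or spec.random_slope_sd > 0
    if clustered:
        if spec.n_groups < 2:
            raise ValueError("clustered spec requires n_groups >= 2")
        groups = np.repeat(np.arange(spec.n_groups), int(np.ceil(n / spec.n_groups)))[:n]
        b0 = rng.normal(0.0, spec.random_intercept_sd, spec.n_groups)[groups]
        lp = lp + b0
        if spec.random_slope_sd > 0:
            b1 = rng.normal(0.0, spec.random_slope_sd, spec.n_groups)[groups]
            lp = lp + b1 * table[spec.random_slope_term]
        table["subject_id"] = [f"S{g + 1:02d}" for g in groups]

    table["sqrt_pah"] = lp + rng.normal(0.0, spec.residual_sd, n)
    return table


# published daily-exposure model: outcome sqrt(ng/m^3), fractions in [0, 1]
_DAILY_PREDICTORS = {
    "pct_invehicle": ("normal", 0.046, 0.051),
    "lw_aadt_500": ("normal", 35797.0, 30026.0),
    "work_related_exposure": ("bernoulli", 0.179),
    "weekday": ("bernoulli", 0.73),
}


def daily_model_spec(n_records: int = 180, residual_sd: float = 0.80) -> TabularModelSpec:
    """Generative twin of the published daily (person-day) OLS model."""
    return TabularModelSpec(
        name="daily",
        intercept=1.54,
        coefficients=(
            ("pct_invehicle", 16.90),
            ("lw_aadt_500", 1.02e-5),
            ("work_related_exposure", 0.41),
            ("weekday", 0.33),
        ),
        residual_sd=residual_sd,
        predictors=_DAILY_PREDICTORS,
        n_records=n_records,
    )


def daily_mixed_model_spec(
    n_groups: int = 28,
    records_per_group: int = 6,
    residual_sd: float = 0.70,
    random_intercept_sd: float = 0.4,
    random_slope_sd: float = 3.0,
) -> TabularModelSpec:
    """Generative twin of the published mixed-effect daily model."""
    return TabularModelSpec(
        name="daily_mixed",
        intercept=1.55,
        coefficients=(
            ("pct_invehicle", 17.40),
            ("lw_aadt_500", 0.94e-5),
            ("work_related_exposure", 0.57),
            ("weekday", 0.31),
        ),
        residual_sd=residual_sd,
        predictors=_DAILY_PREDICTORS,
        n_records=n_groups * records_per_group,
        random_intercept_sd=random_intercept_sd,
        random_slope_sd=random_slope_sd,
        random_slope_term="pct_invehicle",
        n_groups=n_groups,
    )


def subject_model_spec(n_records: int = 28, residual_sd: float = 0.55) -> TabularModelSpec:
    """Generative twin of the published subject-level OLS model."""
    return TabularModelSpec(
        name="subject",
        intercept=1.68,
        coefficients=(
            ("pct_invehicle", 12.19),
            ("pct_weekday", 1.14),
            ("work_related_exposure", 0.77),
        ),
        residual_sd=residual_sd,
        predictors={
            "pct_invehicle": ("normal", 0.046, 0.030),
            "pct_weekday": ("normal", 0.73, 0.15),
            "work_related_exposure": ("bernoulli", 0.179),
        },
        n_records=n_records,
    )


#: published subject-by-activity (microenvironment) model coefficients
MICROENV_MODEL = {
    "intercept": 1.29,
    "sqrt_speed": 0.82,
    "indoor_indicator": -1.75,
    "pct_daytime": 3.87,
    "residual_sd": 0.9,
}


def simulate_microenvironment_table(seed, n_records: int = 74) -> pd.DataFrame:
    """Subject-by-activity records from the microenvironment model.

    Categories are near-balanced; speeds are category-specific (driving
    ~30 km/h, indoor ~0.5 km/h, walking ~3 km/h), the indoor indicator
    follows the category, and the outcome uses sqrt of speed.
    """
    rng = np.random.default_rng(seed)
    base = n_records // 3
    counts = [base + (1 if i < n_records - 3 * base else 0) for i in range(3)]
    cats = np.repeat(["indoor", "in_vehicle", "other"], counts)
    speed = np.where(
        cats == "in_vehicle",
        np.clip(rng.normal(30.0, 8.0, n_records), 5.0, None),
        np.where(
            cats == "indoor",
            np.abs(rng.normal(0.5, 0.3, n_records)) + 1e-6,
            np.clip(rng.normal(3.0, 1.0, n_records), 0.5, None),
        ),
    )
    table = pd.DataFrame(
        {
            "category": cats,
            "sqrt_speed": np.sqrt(speed),
            "indoor_indicator": (cats == "indoor").astype(float),
            "pct_daytime": np.clip(rng.normal(0.55, 0.18, n_records), 0.0, 1.0),
        }
    )
    m = MICROENV_MODEL
    table["sqrt_pah"] = (
        m["intercept"]
        + m["sqrt_speed"] * table["sqrt_speed"]
        + m["indoor_indicator"] * table["indoor_indicator"]
        + m["pct_daytime"] * table["pct_daytime"]
        + rng.normal(0.0, m["residual_sd"], n_records)
    )
    return table
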