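"""Synthetic study-region generator.

Emulates a district-level observational dataset for under-five pneumonia
risk analysis: 18 irregular administrative polygons, 13 demographic /
climate / socioeconomic / health-infrastructure covariates whose published
summary statistics (min, max, mean, SD) are reproduced by moment-matched
truncated normal distributions, per-district station measurements of a
climate field, and Poisson case counts drawn from a log-linear model with
the published slope estimates and a calibrated intercept.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import Voronoi
from scipy.special import logsumexp
from shapely.geometry import Polygon, box
from shapely import contains_xy

from .errors import CalibrationError, InvalidArgumentError

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "DEFAULT_BBOX",
    "DEFAULT_COVARIATES",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_TARGET_MEAN_COUNT",
    "make_geometry",
    "generate_covariates",
    "simulate_counts",
    "generate_stations",
    "induce_collinearity",
    "truncnorm_for_spec",
]

# Study-region bounding box (lon_min, lat_min, lon_max, lat_max), WGS84 degrees.
DEFAULT_BBOX = (100.28, 1.23, 101.35, 2.75)

# Overall case burden: 1,954 recorded cases across 18 districts.
DEFAULT_TARGET_MEAN_COUNT = 1954.0 / 18.0


@dataclass(frozen=True)
class CovariateSpec:
    """Published summary statistics of one covariate.

    ``direction`` marks whether larger values raise ("risk") or lower
    ("protective") pneumonia risk; it drives the Likert scoring stage only.
    """

    name: str
    mean: float
    sd: float
    min: float
    max: float
    direction: str = "risk"
    unit: str = ""

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidArgumentError(f"{self.name}: sd must be >= 0, got {self.sd}")
        if not (self.min <= self.mean <= self.max):
            raise InvalidArgumentError(
                f"{self.name}: need min <= mean <= max, got "
                f"{self.min}, {self.mean}, {self.max}"
            )
        if self.sd > 0 and not self.min < self.max:
            raise InvalidArgumentError(f"{self.name}: need min < max with sd > 0")
        if self.direction not in ("risk", "protective"):
            raise InvalidArgumentError(f"{self.name}: bad direction {self.direction!r}")


# The 13 covariates with their published district-level summaries.
# Rainfall is annual precipitation in mm (2917-3470); the under-five service
# coverage is an attainment percentage and may exceed 100.
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("population_density", 69.78, 40.25, 29.0, 168.0, "risk", "people/km2"),
    CovariateSpec("air_temperature", 26.52, 0.71, 25.76, 28.27, "risk", "degC"),
    CovariateSpec("air_humidity", 87.71, 3.92, 78.31, 91.12, "risk", "%"),
    CovariateSpec("rainfall", 3127.44, 156.56, 2917.0, 3470.0, "risk", "mm/year"),
    CovariateSpec("pm25", 11.68, 1.20, 10.31, 13.27, "risk", "ug/m3"),
    CovariateSpec("exclusive_breastfeeding", 41.13, 20.78, 1.66, 79.81, "protective", "%"),
    CovariateSpec("chl", 53.65, 22.90, 17.22, 100.0, "protective", "%"),
    CovariateSpec("malnutrition", 0.056, 0.081, 0.0, 0.31, "risk", "%"),
    CovariateSpec("healthy_home", 71.11, 15.28, 47.0, 93.0, "protective", "%"),
    CovariateSpec("poverty", 46.21, 12.79, 19.68, 70.39, "risk", "%"),
    CovariateSpec("under_five_services", 61.86, 25.34, 23.67, 113.96, "protective", "%"),
    CovariateSpec("health_workers", 104.94, 107.78, 34.0, 468.0, "risk", "persons"),
    CovariateSpec("health_facilities", 10.39, 6.26, 3.0, 23.0, "risk", "units"),
)

# Published log-linear model: name -> (estimate, standard error). Air
# temperature, air humidity and health-worker count were screened out by the
# multicollinearity test and therefore carry no slope.
DEFAULT_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "intercept": (8.306, 1.0630),
    "population_density": (0.004, 0.0007),
    "rainfall": (0.002, 0.0003),
    "pm25": (0.077, 0.0481),
    "exclusive_breastfeeding": (-0.004, 0.0015),
    "malnutrition": (1.786, 0.4834),
    "under_five_services": (-0.003, 0.0015),
    "chl": (-0.001, 0.0016),
    "healthy_home": (-0.021, 0.0022),
    "poverty": (0.001, 0.0033),
    "health_facilities": (0.073, 0.0054),
}

# Which collinear covariate is rebuilt from which surviving sources when
# `collinear_triple` is on. Disjoint source triples keep the survivors' own
# VIFs well under the screening threshold (about 1/(1 - r2/ (r2 + 3(1-r2))))
# while each rebuilt column's VIF is about 1/(1-r2).
_COLLINEAR_SOURCES: dict[str, tuple[str, ...]] = {
    "air_temperature": ("rainfall", "pm25", "poverty"),
    "air_humidity": ("chl", "exclusive_breastfeeding", "under_five_services"),
    "health_workers": ("population_density", "health_facilities", "healthy_home"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic dataset generator."""

    n_districts: int = 18
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    target_mean_count: float = DEFAULT_TARGET_MEAN_COUNT
    seed: int = 0
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    collinear_triple: bool = False
    collinear_r2: float = 0.94

    def __post_init__(self):
        if self.n_districts < 3:
            raise InvalidArgumentError("n_districts must be >= 3")
        if not self.covariates:
            raise InvalidArgumentError("covariate list must not be empty")
        if self.target_mean_count <= 0:
            raise InvalidArgumentError("target_mean_count must be > 0")
        names = {s.name for s in self.covariates}
        extra = set(self.coefficients) - names - {"intercept"}
        if extra:
            raise InvalidArgumentError(f"coefficients without covariates: {sorted(extra)}")
        if "intercept" not in self.coefficients:
            raise InvalidArgumentError("coefficient set must include an intercept")


# ---------------------------------------------------------------------------
# moment-matched truncated normals
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _matched_truncnorm(minv: float, maxv: float, mean: float, sd: float):
    """Solve for (a, b, loc, scale) so the *truncated* normal on [minv, maxv]
    has mean ``mean`` exactly and SD as close to ``sd`` as the family allows.

    The naive choice loc=mean, scale=sd biases the realized mean whenever the
    bounds are asymmetric about it, so the underlying location is solved by
    root finding at every candidate scale, and the scale then minimizes the
    SD mismatch.
    """

    # Location offsets beyond ~12 sigma put both truncation points deep in
    # one tail, where scipy's truncated moments lose accuracy; scales whose
    # mean cannot be matched inside that window get a penalty instead.
    _SPAN = 12.0

    def g(loc, scale):
        a, b = (minv - loc) / scale, (maxv - loc) / scale
        return stats.truncnorm.mean(a, b, loc=loc, scale=scale) - mean

    def loc_for(scale):
        lo, hi = minv - _SPAN * scale, maxv + _SPAN * scale
        if not (g(lo, scale) < 0.0 < g(hi, scale)):
            return None
        return optimize.brentq(
            g, lo, hi, args=(scale,), xtol=1e-12 * max(1.0, abs(mean))
        )

    def sd_gap(log_scale):
        scale = math.exp(log_scale)
        loc = loc_for(scale)
        if loc is None:
            return 1e9 * (1.0 + log_scale**2)
        a, b = (minv - loc) / scale, (maxv - loc) / scale
        return (stats.truncnorm.std(a, b, loc=loc, scale=scale) - sd) ** 2

    res = optimize.minimize_scalar(
        sd_gap, bounds=(math.log(sd / 8.0), math.log(sd * 60.0)), method="bounded"
    )
    scale = math.exp(res.x)
    loc = loc_for(scale)
    if loc is None:  # pragma: no cover - small scales are always feasible
        scale = sd
        loc = optimize.brentq(
            g, minv - _SPAN * scale, maxv + _SPAN * scale, args=(scale,)
        )
    a, b = (minv - loc) / scale, (maxv - loc) / scale
    return a, b, loc, scale


def truncnorm_for_spec(spec: CovariateSpec):
    """Frozen scipy truncated-normal distribution matched to ``spec``.

    Returns ``None`` for the degenerate sd=0 case (point mass at the mean).
    """
    if spec.sd == 0:
        return None
    a, b, loc, scale = _matched_truncnorm(spec.min, spec.max, spec.mean, spec.sd)
    return stats.truncnorm(a, b, loc=loc, scale=scale)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_geometry(n_districts: int, bbox=DEFAULT_BBOX, seed: int = 0) -> dict[str, Polygon]:
    """Tile ``bbox`` with ``n_districts`` Voronoi cells of seeded random points.

    Returns an ordered mapping district_id -> shapely Polygon. The cells are
    interior-disjoint and their areas sum to the bbox area (a stand-in for
    administrative subdistrict boundaries).
    """
    if n_districts < 3:
        raise InvalidArgumentError("n_districts must be >= 3")
    lon0, lat0, lon1, lat1 = bbox
    if not (lon1 > lon0 and lat1 > lat0):
        raise InvalidArgumentError(f"degenerate bbox {bbox}")

    rng = np.random.default_rng(seed)
    pts = rng.uniform((lon0, lat0), (lon1, lat1), size=(n_districts, 2))

    # Mirror the seeds across all four edges so every original cell is
    # bounded and the original cells exactly tile the rectangle.
    mirrored = np.vstack(
        [
            pts,
            np.column_stack([2 * lon0 - pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * lon1 - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * lat0 - pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * lat1 - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    frame = box(lon0, lat0, lon1, lat1)

    polygons: dict[str, Polygon] = {}
    for i in range(n_districts):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # pragma: no cover - mirroring bounds all cells
            raise InvalidArgumentError("unbounded Voronoi cell; bbox too degenerate")
        cell = Polygon(vor.vertices[region]).intersection(frame)
        polygons[f"D{i + 1:02d}"] = cell
    return polygons


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the covariate table: one row per district, one column per covariate.

    Each covariate comes from the moment-matched truncated normal of its spec
    (sd=0 specs collapse to the mean). With ``config.collinear_triple`` the
    air-temperature / air-humidity / health-worker columns are then rebuilt as
    near-linear combinations of surviving covariates (see
    :func:`induce_collinearity`).
    """
    if not config.covariates:
        raise InvalidArgumentError("covariate list must not be empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_districts
    data = {"district_id": [f"D{i + 1:02d}" for i in range(n)]}
    for spec in config.covariates:
        dist = truncnorm_for_spec(spec)
        if dist is None:
            data[spec.name] = np.full(n, spec.mean)
        else:
            data[spec.name] = dist.rvs(size=n, random_state=rng)
    table = pd.DataFrame(data)
    if config.collinear_triple:
        present = {s.name for s in config.covariates}
        targets = {
            t: s for t, s in _COLLINEAR_SOURCES.items()
            if t in present and set(s) <= present
        }
        spec_map = {s.name: s for s in config.covariates}
        table = induce_collinearity(
            table, targets, spec_map, r2=config.collinear_r2,
            seed=rng.integers(0, 2**31 - 1),
        )
    return table


def induce_collinearity(
    table: pd.DataFrame,
    targets: Mapping[str, tuple[str, ...]],
    specs: Mapping[str, CovariateSpec],
    r2: float = 0.94,
    seed: int = 0,
) -> pd.DataFrame:
    """Rebuild each target column as a near-linear combination of its sources.

    Sources are sample-standardized, mixed with equal weights plus Gaussian
    noise so the R^2 of the target against its sources is ``r2``, and
    rescaled to the target spec's mean/SD (exactly, in-sample). The rebuilt
    columns are intentionally not re-truncated: a hard clip would bend the
    linear relationship the VIF screen is meant to detect.
    """
    if not 0 < r2 < 1:
        raise InvalidArgumentError("r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for target, sources in targets.items():
        combo = np.zeros(len(out))
        c = math.sqrt(r2 / len(sources))
        for s in sources:
            combo += c * _standardize(out[s].to_numpy())
        noise = rng.standard_normal(len(out)) * math.sqrt(1.0 - r2)
        spec = specs[target]
        out[target] = spec.mean + spec.sd * _standardize(combo + noise)
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=0)
    if s == 0:
        raise InvalidArgumentError("cannot standardize a constant column")
    return (x - x.mean()) / s


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    table: pd.DataFrame,
    coefficients: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    target_mean_count: float = DEFAULT_TARGET_MEAN_COUNT,
) -> pd.DataFrame:
    """Draw Poisson case counts from the log-linear model.

    mu_i = exp(b0 + sum_j b_j x_ij), where the slopes are taken from
    ``coefficients`` and the intercept is re-calibrated so that the mean of
    mu over districts equals ``target_mean_count`` (the published intercept
    belongs to an unrecoverable covariate scaling and is ignored).
    Returns a copy of ``table`` with a ``case_count`` column.
    """
    if coefficients is None:
        coefficients = DEFAULT_COEFFICIENTS
    if "intercept" not in coefficients:
        raise InvalidArgumentError("coefficient set must include an intercept")
    missing = [k for k in coefficients if k != "intercept" and k not in table.columns]
    if missing:
        raise InvalidArgumentError(f"coefficients without covariate columns: {missing}")
    if target_mean_count <= 0:
        raise InvalidArgumentError("target_mean_count must be > 0")

    eta = np.zeros(len(table))
    for name, (est, _se) in coefficients.items():
        if name == "intercept":
            continue
        eta += est * table[name].to_numpy(dtype=float)

    # beta0 = log(target) - log(mean(exp(eta))), computed in log space.
    beta0 = math.log(target_mean_count) - (logsumexp(eta) - math.log(len(table)))
    lin = beta0 + eta
    if np.any(lin > 700):
        bad = table["district_id"].iloc[int(np.argmax(lin))]
        raise CalibrationError(
            f"linear predictor overflow (eta > 700) for district {bad}; "
            "check covariate scaling"
        )
    mu = np.exp(lin)
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["case_count"] = rng.poisson(mu)
    return out


def calibrated_intercept(
    table: pd.DataFrame,
    coefficients: Mapping[str, tuple[float, float]] | None = None,
    target_mean_count: float = DEFAULT_TARGET_MEAN_COUNT,
) -> float:
    """The intercept that sets mean(mu) over districts to ``target_mean_count``."""
    if coefficients is None:
        coefficients = DEFAULT_COEFFICIENTS
    eta = np.zeros(len(table))
    for name, (est, _se) in coefficients.items():
        if name != "intercept":
            eta += est * table[name].to_numpy(dtype=float)
    return math.log(target_mean_count) - (logsumexp(eta) - math.log(len(table)))


# ---------------------------------------------------------------------------
# stations
# ---------------------------------------------------------------------------

def generate_stations(
    polygons: Mapping[str, Polygon],
    field_spec: CovariateSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """One climate station at a random interior point of each polygon.

    Station values are drawn from the field's moment-matched truncated
    normal, so all values lie inside [spec.min, spec.max]. Returns a
    DataFrame (station_id, lon, lat, value) in polygon order.
    """
    if not polygons:
        raise InvalidArgumentError("need at least one polygon")
    rng = np.random.default_rng(seed)
    dist = truncnorm_for_spec(field_spec)
    rows = []
    for district_id, poly in polygons.items():
        if poly.area <= 0:
            raise InvalidArgumentError(f"polygon {district_id} has zero area")
        lon, lat = _random_interior_point(poly, rng)
        value = field_spec.mean if dist is None else float(dist.rvs(random_state=rng))
        rows.append({"station_id": f"S_{district_id}", "lon": lon, "lat": lat, "value": value})
    return pd.DataFrame(rows)


def _random_interior_point(poly: Polygon, rng: np.random.Generator) -> tuple[float, float]:
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if contains_xy(poly, x, y):
            return float(x), float(y)
    p = poly.representative_point()  # pragma: no cover - rejection virtually always wins
    return float(p.x), float(p.y)
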