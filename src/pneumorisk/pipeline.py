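"""End-to-end pipeline: simulate -> interpolate -> screen -> fit -> classify -> map.

Chains the stages into the full district vulnerability analysis:

1. generate district polygons, covariates and case counts;
2. sample climate stations, IDW-interpolate the rainfall field onto a
   raster and replace the tabular rainfall covariate by its zonal mean;
3. VIF screen with backward elimination, Poisson GLM fit, Wald / deviance /
   runs tests;
4. per-factor Jenks classification, Likert scoring, risk-zone
   classification and the vulnerability map.

All randomness flows from one root seed split deterministically per stage,
so two runs with the same configuration produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .classification import jenks_breaks, classify_with_breaks, goodness_of_variance_fit
from .datagen import (
    GeneratorConfig,
    generate_covariates,
    generate_stations,
    make_geometry,
    simulate_counts,
)
from .errors import PipelineStageError
from .interpolation import IdwConfig, grid_for_bbox, idw_interpolate, zonal_mean
from .regression import PoissonRiskModel, backward_eliminate_vif
from .vulnerability import (
    FactorScoreConfig,
    build_vulnerability_map,
    classify_risk,
    level_counts,
    score_factors,
    total_scores,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of a full pipeline run."""

    generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(collinear_triple=True)
    )
    idw: IdwConfig = field(default_factory=IdwConfig)
    cell_size: float = 0.01
    vif_threshold: float = 10.0
    alpha: float = 0.1
    scoring: FactorScoreConfig = field(default_factory=FactorScoreConfig)
    output_dir: str = "pneumorisk_run"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must be > 1")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        """Build a config from a TOML file; keyword overrides win."""
        raw = pio.load_toml_config(path)
        gen_kwargs = raw.get("generator", {})
        idw_kwargs = raw.get("idw", {})
        scoring_kwargs = raw.get("scoring", {})
        if "factors" in scoring_kwargs:
            scoring_kwargs["factors"] = tuple(
                tuple(f) for f in scoring_kwargs["factors"]
            )
        top = {
            k: v
            for k, v in raw.items()
            if k in ("cell_size", "vif_threshold", "alpha", "output_dir", "seed")
        }
        top.update(overrides)
        seed = int(top.get("seed", 0))
        gen_kwargs.setdefault("seed", seed)
        return cls(
            generator=GeneratorConfig(**gen_kwargs),
            idw=IdwConfig(**idw_kwargs),
            scoring=FactorScoreConfig(**scoring_kwargs),
            **top,
        )


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: PipelineConfig
    polygons: dict
    districts: pd.DataFrame
    stations: pd.DataFrame
    raster: object
    vif_removed: list
    fit: object
    wald: pd.DataFrame
    deviance_test: object
    runs_test: object
    breaks: dict
    classes: pd.DataFrame
    scores: pd.DataFrame
    totals: pd.Series
    levels: pd.Series
    counts: dict
    artifacts: dict


def _stage(log, name, func):
    t0 = time.perf_counter()
    try:
        out = func()
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc
    log["timings"][name] = round(time.perf_counter() - t0, 4)
    return out


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full analysis and write all artifacts to ``output_dir``."""
    config = config or PipelineConfig()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(4)]
    gen = dataclasses.replace(config.generator, seed=seeds[3])

    log = {
        "seed": config.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "timings": {},
    }

    # --- synthetic study region -------------------------------------------
    polygons = _stage(
        log, "geometry", lambda: make_geometry(gen.n_districts, gen.bbox, seed=seeds[0])
    )
    table = _stage(log, "covariates", lambda: generate_covariates(gen))

    # --- climate field: stations -> IDW raster -> zonal means -------------
    spec_map = {s.name: s for s in gen.covariates}
    raster = None
    stations = pd.DataFrame(columns=["station_id", "lon", "lat", "value"])
    if "rainfall" in spec_map:
        stations = _stage(
            log,
            "stations",
            lambda: generate_stations(polygons, spec_map["rainfall"], seed=seeds[1]),
        )
        grid = grid_for_bbox(gen.bbox, cell_size=config.cell_size)
        raster = _stage(
            log, "idw", lambda: idw_interpolate(stations, grid, config.idw)
        )
        zonal = _stage(log, "zonal", lambda: zonal_mean(raster, polygons))
        table = table.drop(columns=["rainfall"]).merge(
            zonal.rename(columns={"value": "rainfall"}), on="district_id"
        )

    # --- counts ------------------------------------------------------------
    districts = _stage(
        log,
        "counts",
        lambda: simulate_counts(
            table,
            gen.coefficients,
            seed=seeds[2],
            target_mean_count=gen.target_mean_count,
        ),
    )

    # --- multicollinearity screen + GLM ------------------------------------
    covariate_cols = [s.name for s in gen.covariates]
    reduced, vif_report = _stage(
        log,
        "vif",
        lambda: backward_eliminate_vif(districts[covariate_cols], config.vif_threshold),
    )
    fit = _stage(
        log,
        "fit",
        lambda: PoissonRiskModel.from_dataframe(
            districts, predictors=list(reduced.columns)
        ).fit(),
    )
    wald = fit.wald_tests(alpha=config.alpha)
    dev_test = fit.deviance_test(alpha=config.alpha)
    run_test = fit.runs_test()

    # --- per-factor classification and scoring ------------------------------
    factor_names = [f for f, _ in config.scoring.factors if f in districts.columns]
    breaks = {}
    class_rows = []
    for name in factor_names:
        values = districts[name].to_numpy()
        bs = jenks_breaks(values, k=3)
        breaks[name] = bs
        labels = classify_with_breaks(values, bs)
        for did, v, lab in zip(districts["district_id"], values, labels):
            class_rows.append(
                {"district_id": did, "factor": name, "value": v, "class": lab}
            )
    classes = pd.DataFrame(class_rows)
    scoring = dataclasses.replace(
        config.scoring,
        factors=tuple((f, d) for f, d in config.scoring.factors if f in factor_names),
    )
    scores = _stage(log, "scores", lambda: score_factors(classes, scoring))
    totals = total_scores(scores)
    levels = _stage(log, "risk", lambda: classify_risk(totals, scoring))
    feature_collection, counts = build_vulnerability_map(polygons, levels, totals)

    # --- artifacts ----------------------------------------------------------
    artifacts = {}

    def _write(name, fn):
        path = out_dir / name
        fn(path)
        artifacts[name] = str(path)

    _write("districts.csv", lambda p: pio.write_district_csv(districts, p))
    _write("polygons.geojson", lambda p: pio.write_geojson(polygons, p))
    if len(stations):
        _write("stations.csv", lambda p: pio.write_stations_csv(stations, p))
    if raster is not None:
        _write("rainfall.asc", lambda p: pio.write_ascii_grid(raster, p))
    _write(
        "vif_report.csv",
        lambda p: pd.DataFrame(
            {"vif": vif_report.vif, "tolerance": vif_report.tolerance}
        )
        .rename_axis("variable")
        .to_csv(p),
    )
    _write("fit_summary.csv", lambda p: fit.to_frame().to_csv(p, index=False))
    _write(
        "fit_footer.csv",
        lambda p: pd.DataFrame(
            [
                {
                    "deviance": fit.deviance,
                    "aic": fit.aic,
                    "z_critical": wald["critical"].iloc[0],
                    "chi2_critical": dev_test.critical,
                    "df": dev_test.df,
                    "runs_p_value": run_test.p_value,
                }
            ]
        ).to_csv(p, index=False),
    )
    _write(
        "breaks.csv",
        lambda p: pd.DataFrame(
            [
                {"factor": name, **{f"b{i}": b for i, b in enumerate(bs.boundaries)},
                 "labels": "|".join(bs.labels),
                 "gvf": goodness_of_variance_fit(districts[name].to_numpy(), bs)}
                for name, bs in breaks.items()
            ]
        ).to_csv(p, index=False),
    )
    _write("classified.csv", lambda p: classes.to_csv(p, index=False))
    _write(
        "scores.csv",
        lambda p: scores.assign(total=totals, level=levels).to_csv(p),
    )
    _write(
        "vulnerability_map.geojson", lambda p: pio.write_geojson(feature_collection, p)
    )

    log["effective_config"] = _config_dict(config)
    log["vif_removed"] = vif_report.removed
    log["level_counts"] = counts
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    artifacts["run_log.json"] = str(out_dir / "run_log.json")

    return PipelineResult(
        config=config,
        polygons=polygons,
        districts=districts,
        stations=stations,
        raster=raster,
        vif_removed=vif_report.removed,
        fit=fit,
        wald=wald,
        deviance_test=dev_test,
        runs_test=run_test,
        breaks=breaks,
        classes=classes,
        scores=scores,
        totals=totals,
        levels=levels,
        counts=counts,
        artifacts=artifacts,
    )


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj

    return convert(config)
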