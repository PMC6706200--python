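"""End-to-end orchestration: ingest -> QC -> filters -> movements -> indices
-> networks -> motifs -> models -> reports, under one YAML-able config.

Every stage is a pure function of the config and its inputs, so a rerun
with the same config and seed reproduces every output file; the manifest
records the config hash, seed and per-stage record counts (including the
exclusion audit trail).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import motifs as motifs_mod
from . import networks as networks_mod
from . import preprocess, stats, telemetry_io

log = logging.getLogger("codnet")


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run."""

    seed: int | None = None
    detections_path: str | None = None
    receivers_path: str | None = None
    fish_path: str | None = None
    environment_path: str | None = None
    outdir: str | None = None
    timezone: str = telemetry_io.DAY_TZ
    study_end: str = "2016-01-18"
    qc_window_hours: float = 1.0
    qc_min_neighbors: int = 1
    postrelease_hours: float = 24.0
    min_transit_minutes: float = 4.0
    weekly_start: str = "2015-08-25"
    n_weeks: int | None = None  # None: as many full 7-day weeks as fit
    vif_threshold: float = 3.0
    #: Fixed-effect covariates per response (the reference model formulas)
    strength_predictors: tuple[str, ...] = ("sst", "log_wind_speed", "wind_direction")
    degree_predictors: tuple[str, ...] = ("sst", "wind_direction")
    seasons: tuple = preprocess.REFERENCE_SEASONS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seasons" in raw:
            raw["seasons"] = tuple(
                preprocess.SeasonWindow(
                    s["label"], date.fromisoformat(str(s["start"])), date.fromisoformat(str(s["end"]))
                )
                for s in raw["seasons"]
            )
        for key in ("strength_predictors", "degree_predictors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["seasons"] = [
            {"label": w.label, "start": w.start.isoformat(), "end": w.end.isoformat()}
            for w in self.seasons
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(repr(dataclasses.asdict(self)).encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig, *, require_paths: bool = False) -> list[str]:
    """Collect configuration errors (empty list = valid)."""
    errors = []
    if config.seed is None:
        errors.append("seed is required for a reproducible run")
    for name in ("qc_window_hours", "postrelease_hours"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    if config.min_transit_minutes < 0:
        errors.append("min_transit_minutes must be non-negative")
    try:
        preprocess.check_season_windows(config.seasons)
    except ValueError as e:
        errors.append(f"seasons: {e}")
    if config.n_weeks is not None and config.n_weeks <= 0:
        errors.append("n_weeks must be positive")
    if require_paths:
        for name in ("detections_path", "receivers_path", "fish_path", "environment_path"):
            p = getattr(config, name)
            if p is None:
                errors.append(f"{name} is required")
            elif not Path(p).exists():
                errors.append(f"{name}: {p} does not exist")
    return errors


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(config: PipelineConfig, bundle: dict | None) -> dict:
    if bundle is not None:
        return {
            "detections": bundle["detections"].copy(),
            "receivers": bundle["receivers"],
            "fish": bundle["fish"],
            "environment": bundle["environment"],
            "read_report": None,
        }
    det, report = telemetry_io.read_detections(config.detections_path)
    return {
        "detections": det,
        "receivers": telemetry_io.read_receivers(config.receivers_path),
        "fish": telemetry_io.read_fish(config.fish_path),
        "environment": telemetry_io.read_environment(config.environment_path),
        "read_report": report,
    }


def run_pipeline(config: PipelineConfig, bundle: dict | None = None) -> dict:
    """Run the full analysis; returns a result dict and (optionally) writes files.

    ``bundle`` supplies in-memory inputs (the synthetic generator's output)
    instead of reading the configured paths.  Any stage failure aborts with
    a :class:`StageError` naming the stage.
    """
    errors = validate_config(config, require_paths=bundle is None)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    tz = config.timezone
    out: dict = {"config": config}
    counts: dict[str, int] = {}

    stage = "ingest"
    try:
        data = _load_inputs(config, bundle)
        detections = data["detections"]
        receivers = data["receivers"]
        fish = data["fish"]
        environment = data["environment"]
        counts["detections_in"] = len(detections)
        log.info("ingest: %d detections, %d receivers, %d fish",
                 len(detections), len(receivers), len(fish))

        stage = "qc"
        detections = telemetry_io.correct_time_drift_all(detections, receivers)
        detections = telemetry_io.flag_false_detections(
            detections,
            window=pd.Timedelta(hours=config.qc_window_hours),
            min_neighbors=config.qc_min_neighbors,
        )
        counts["detections_valid"] = int(detections["valid"].sum())
        out["qc_detections"] = detections
        log.info("qc: %d/%d detections valid", counts["detections_valid"], len(detections))

        stage = "postrelease_filter"
        detections = preprocess.remove_postrelease_window(
            detections, fish, pd.Timedelta(hours=config.postrelease_hours)
        )
        counts["detections_post_release"] = len(detections)

        stage = "movements"
        movements = preprocess.extract_movements(
            detections, pd.Timedelta(minutes=config.min_transit_minutes)
        )
        counts["movements"] = len(movements)
        log.info("movements: %d extracted", len(movements))

        stage = "summaries"
        study_end = pd.Timestamp(config.study_end)
        summary = preprocess.fish_summary(detections, movements, fish, study_end, tz)
        retained, exclusions = preprocess.exclude_fish(fish, detections, movements)
        counts["fish_tagged"] = len(fish)
        counts["fish_retained"] = len(retained)
        movements = movements.loc[movements["transmitter_id"].isin(retained)].reset_index(drop=True)
        detections_retained = detections.loc[
            detections["transmitter_id"].isin(retained)
        ].reset_index(drop=True)
        out.update(fish_summary=summary, exclusions=exclusions, retained=retained,
                   movements=movements)
        log.info("summaries: retained %d of %d fish", len(retained), len(fish))

        stage = "seasonal_networks"
        nodes = list(receivers["receiver_id"])
        seasonal = networks_mod.aggregate_seasonal(movements, config.seasons, nodes=nodes, tz=tz)
        rel = preprocess.relative_movements_per_day(movements, detections_retained, tz)
        rel["season"] = [
            preprocess.assign_season(pd.Timestamp(d), config.seasons, tz="UTC")
            for d in rel["date"]
        ]
        groups = [
            rel.loc[rel["season"] == w.label, "relative_movements"].dropna().to_numpy()
            for w in config.seasons
        ]
        seasonal_tests = None
        if all(len(g) >= 2 and np.var(g, ddof=1) > 0 for g in groups):
            seasonal_tests = {
                "welch": stats.welch_anova(groups),
                "games_howell": stats.games_howell(groups, labels=[w.label for w in config.seasons]),
            }
        out.update(seasonal_networks=seasonal, relative_movements=rel,
                   seasonal_tests=seasonal_tests)

        stage = "weekly_metrics"
        week0 = pd.Timestamp(config.weekly_start, tz="UTC")
        study_end_utc = pd.Timestamp(config.study_end, tz="UTC")
        n_weeks = config.n_weeks or int((study_end_utc - week0).days // 7)
        weekly = networks_mod.weekly_metric_series(movements, week0, n_weeks, retained, nodes=nodes)
        env_t = stats.transform_predictors(environment)
        env_t["week_start_date"] = pd.to_datetime(env_t["week_start"]).dt.date
        weekly["week_start_date"] = weekly["week_start"].dt.date
        weekly = weekly.merge(
            env_t.drop(columns=["week_start"]), on="week_start_date", how="left"
        ).drop(columns=["week_start_date"])
        counts["weekly_rows"] = len(weekly)
        out["weekly_metrics"] = weekly

        stage = "collinearity"
        cov_cols = ["sst", "log_wind_speed", "sqrt_par", "wind_direction", "sea_level"]
        _, vif_table = stats.vif_screen(
            env_t[cov_cols].dropna(), threshold=config.vif_threshold
        )
        out["vif_table"] = vif_table

        stage = "models"
        modeled = weekly.dropna(subset=list(config.strength_predictors))
        strength_fit = stats.fit_nb_glmm(
            modeled["strength"].to_numpy(),
            modeled[list(config.strength_predictors)],
            modeled["subject"].to_numpy(),
        )
        degree_fit = stats.fit_zinb_glmm(
            modeled["degree"].to_numpy(),
            modeled[list(config.degree_predictors)],
            modeled["subject"].to_numpy(),
        )
        out["model_fits"] = {"strength": strength_fit, "degree": degree_fit}
        out["model_table"] = model_summary_table(out["model_fits"])

        stage = "motifs"
        months = sorted(
            pd.PeriodIndex(
                pd.DatetimeIndex(preprocess.local_dates(detections_retained["timestamp"], tz)),
                freq="M",
            ).unique()
        ) if len(detections_retained) else []
        sst_by_month = {
            m: float(s)
            for m, s in environment.assign(
                month=pd.PeriodIndex(pd.to_datetime(environment["week_start"]), freq="M")
            ).groupby("month")["sst"].mean().items()
        }
        months = [m for m in months if m in sst_by_month]
        motif_series = motifs_mod.monthly_motif_series(
            movements, retained, months, sst_by_month, nodes=nodes, tz=tz
        )
        motif_fits = {
            lab: motifs_mod.motif_temperature_model(motif_series, lab)
            for lab in motifs_mod.MAN_LABELS
        }
        out.update(motif_series=motif_series, motif_fits=motif_fits)

        stage = "size_correlations"
        retained_summary = summary.loc[summary["transmitter_id"].isin(retained)]
        out["size_tests"] = _size_tests(retained_summary, config.seed)

        stage = "report"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "counts": counts,
            "versions": _versions(),
        }
        out["manifest"] = manifest
        if config.outdir:
            _write_outputs(out, Path(config.outdir))
    except Exception as e:  # noqa: BLE001 - rethrown with stage context
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e) from e
    return out


def _size_tests(summary: pd.DataFrame, seed) -> dict:
    """Size vs residency/mobility correlations and between-site contrasts."""
    tests: dict = {}
    s = summary.dropna(subset=["residency_index"])
    for size_var in ("weight_g", "total_length_cm"):
        for index_var in ("residency_index", "movement_index"):
            sub = s.dropna(subset=[index_var])
            key = f"{size_var}~{index_var}"
            try:
                tests[key] = stats.spearman_test(
                    sub[size_var], sub[index_var], method="permutation", seed=seed
                )
            except ValueError as e:
                tests[key] = str(e)
    by_site = {site: g for site, g in s.groupby("release_site")}
    if len(by_site) == 2:
        (a, b) = [g for _, g in sorted(by_site.items())]
        try:
            tests["ri_site"] = stats.site_comparison(
                a["residency_index"], b["residency_index"], method="t"
            )
            tests["movements_site"] = stats.site_comparison(
                a["n_movements"], b["n_movements"], method="wilcoxon"
            )
        except ValueError as e:
            tests["site"] = str(e)
    return tests


def model_summary_table(fits: dict) -> pd.DataFrame:
    """Flatten model fits into a response/predictor estimate table."""
    rows = []
    for response, fit in fits.items():
        if fit.terms is None:
            rows.append({"response": response, "predictor": "(non-estimable)",
                         "estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan})
            continue
        for term, r in fit.terms.iterrows():
            rows.append({"response": response, "predictor": term, **r.to_dict()})
    return pd.DataFrame(rows)


def _versions() -> dict:
    import networkx
    import scipy
    import statsmodels

    from . import __version__

    return {
        "codnet": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
    }


def _write_outputs(out: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    out["fish_summary"].to_csv(outdir / "fish_summary.csv", index=False)
    out["exclusions"].to_csv(outdir / "exclusions.csv", index=False)
    mov = out["movements"].copy()
    mov.to_csv(outdir / "movements.csv", index=False)
    out["relative_movements"].to_csv(outdir / "relative_movements.csv", index=False)
    out["weekly_metrics"].to_csv(outdir / "weekly_metrics.csv", index=False)
    out["vif_table"].to_csv(outdir / "vif_table.csv", index=False)
    out["model_table"].to_csv(outdir / "model_summaries.csv", index=False)
    out["motif_series"].to_csv(outdir / "motif_series.csv", index=False)
    for season, net in out["seasonal_networks"].items():
        networks_mod.write_graphml(net, outdir / f"network_{season}.graphml")
        networks_mod.write_edgelist_csv(net, outdir / f"network_{season}_edges.csv")
    motif_rows = []
    for lab, fit in out["motif_fits"].items():
        if fit.terms is not None and "SST" in fit.terms.index:
            r = fit.terms.loc["SST"]
            motif_rows.append({"class": lab, "estimate": r["estimate"], "se": r["se"],
                               "z": r["z"], "p": r["p"], "converged": fit.converged})
        else:
            motif_rows.append({"class": lab, "estimate": np.nan, "se": np.nan,
                               "z": np.nan, "p": np.nan, "converged": False})
    pd.DataFrame(motif_rows).to_csv(outdir / "motif_models.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(out["manifest"], indent=1, default=str))
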