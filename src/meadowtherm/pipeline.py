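"""Configuration, orchestration and report assembly for the full pipeline.

Stages: simulate -> qc -> metrics -> compare -> project.  Each stage consumes
only files written by earlier stages, so later stages can be re-run in
isolation; all machine outputs are deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import (
    aggregate_metric,
    binarize_solar,
    compare_groups_lmm,
    gradient_regression,
    shade_logistic,
    vegetation_type_test,
    willow_heights,
    willow_spacing,
)
from .ingest import apply_qc, load_study, qc_report, read_willows
from .metrics import site_summary, study_metrics
from .projection import (
    DEFAULT_SCENARIOS,
    ScenarioSpec,
    baseline_wavgt,
    fit_max_vs_avg,
    recurrence_table,
    render_recurrence_table,
)
from .synthetic import (
    SimulationParams,
    build_study,
    default_layout,
    simulate_willows,
    write_study,
    write_willows,
)
from .types import VEGETATION_CLASSES

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("meadowtherm")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    data_dir: str | None = None  # None -> simulate into out_dir/data
    seed: int = 0
    years: list[int] = field(default_factory=lambda: [2010, 2011, 2012])
    window: tuple[int, int] = (24, 31)
    week_convention: str = "iso"
    completeness_frac: float = 0.75
    min_days: int = 4
    align: str = "center"
    scales: list[str] = field(default_factory=lambda: ["year", "month", "week"])
    aggregation_mode: str = "per_probe"
    ratio: float = 0.5
    scenarios: list[ScenarioSpec] = field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    sd_mode: str = "total"
    pool_mulkey: bool = True
    skip_simulate: bool = False
    sim_params: dict = field(default_factory=dict)
    layout: dict | None = None  # reach -> (n_probes, length_m); None = study layout

    def errors(self) -> list[str]:
        errs = []
        lo, hi = self.window
        if not (1 <= lo <= 53 and 1 <= hi <= 53):
            errs.append("window weeks must lie in 1..53")
        if lo > hi:
            errs.append("first_week > last_week")
        if self.ratio <= 0:
            errs.append("ratio must be positive")
        if not self.scenarios:
            errs.append("scenarios must be non-empty")
        if self.week_convention not in ("iso", "ordinal"):
            errs.append("week_convention must be iso or ordinal")
        if not 0.0 <= self.completeness_frac <= 1.0:
            errs.append("completeness_frac must be in [0, 1]")
        if self.align not in ("center", "trailing"):
            errs.append("align must be center or trailing")
        bad = [s for s in self.scales if s not in ("week", "month", "year")]
        if bad:
            errs.append(f"unknown aggregation scales {bad}")
        if self.aggregation_mode not in ("per_probe", "per_reach"):
            errs.append("aggregation_mode must be per_probe or per_reach")
        if self.sd_mode not in ("total", "residual_only"):
            errs.append("sd_mode must be total or residual_only")
        if self.skip_simulate and not self.data_dir:
            errs.append("skip_simulate requires data_dir")
        return errs


def validate_config(path) -> PipelineConfig:
    """Parse a YAML config; every violated constraint is reported at once."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"unparseable config {path}: {exc}") from exc
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    errs = [f"unknown config key {k!r}" for k in sorted(unknown)]
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "window" in kwargs:
        kwargs["window"] = tuple(kwargs["window"])
    if "scenarios" in kwargs:
        kwargs["scenarios"] = [
            ScenarioSpec(
                s["label"], float(s["delta_air"]), float(s.get("ratio", 0.5)),
                s.get("delta_water"),
            )
            for s in kwargs["scenarios"]
        ]
    cfg = PipelineConfig(**kwargs)
    errs.extend(cfg.errors())
    if errs:
        raise ValueError("invalid config: " + "; ".join(errs))
    return cfg


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle under ``out_dir``."""
    errs = config.errors()
    if errs:
        raise ValueError("invalid config: " + "; ".join(errs))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    t0 = time.perf_counter()
    summary: list[str] = [f"meadowtherm {__version__} | seed {config.seed}", ""]
    results: dict = {}
    stage = "simulate"
    try:
        # -- simulate ------------------------------------------------------
        if config.skip_simulate:
            data_dir = Path(config.data_dir)
            log.info("simulate: skipped, using %s", data_dir)
        else:
            data_dir = Path(config.data_dir) if config.data_dir else out / "data"
            params = SimulationParams(**{**config.sim_params, "seed": config.seed})
            layout = (
                {k: (int(n), float(length)) for k, (n, length) in config.layout.items()}
                if config.layout
                else None
            )
            probes, series = build_study(
                params, layout, years=config.years,
                weeks=range(config.window[0], config.window[1] + 1),
            )
            write_study(data_dir, probes, series)
            write_willows(data_dir / "willows.csv", simulate_willows(seed=config.seed))
            log.info("simulate: %d probes, %d series -> %s", len(probes), len(series), data_dir)

        # -- qc ------------------------------------------------------------
        stage = "qc"
        dataset = load_study(data_dir, window=config.window, years=config.years)
        dataset, qc_table = apply_qc(dataset, convention=config.week_convention)
        qc_table.to_csv(out / "qc_report.csv", index=False)
        removed = int(qc_table["days_removed"].sum())
        if removed:
            summary.append(f"WARNING: removed {removed} out-of-water probe-days")
        log.info("qc: removed %d probe-days", removed)

        # -- metrics -------------------------------------------------------
        stage = "metrics"
        daily, weekly, season = study_metrics(
            dataset, config.completeness_frac, config.min_days, config.align
        )
        daily.to_csv(out / "daily.csv", index=False)
        weekly.to_csv(out / "weekly.csv", index=False)
        season.to_csv(out / "season_maxima.csv", index=False)
        probes_df = dataset.probes_df
        summ = site_summary(weekly, probes_df.set_index("probe_id")["reach"])
        summ.to_csv(out / "site_summary.csv", index=False)
        summary += ["Temperature summary (mean +- sd per reach):", summ.to_string(index=False), ""]
        log.info("metrics: %d probe-days, %d weekly rows", len(daily), len(weekly))

        # -- compare -------------------------------------------------------
        stage = "compare"
        fits = gradient_regression(season, probes_df)
        grad = pd.DataFrame(
            [
                {
                    "reach": f.reach, "slope_per_100m": f.slope_per_100m,
                    "se_per_100m": f.se_per_100m, "t": f.t, "df": f.df,
                    "p_value": f.p_value, "n_probes": f.n_probes,
                    "moran_i": None if f.residual_moran is None else f.residual_moran.I,
                    "moran_p": None if f.residual_moran is None else f.residual_moran.p_value,
                }
                for f in fits.values()
            ]
        )
        grad.to_csv(out / "gradients.csv", index=False)
        summary += ["Season-maximum gradients (C per 100 m):", grad.to_string(index=False), ""]

        rows = []
        for scale in config.scales:
            agg = aggregate_metric(weekly, probes_df, scale, config.aggregation_mode)
            if agg["unit"].nunique() < 2:
                log.info("compare: skipping %s scale (single time unit)", scale)
                summary.append(f"note: {scale}-scale contrasts skipped (single time unit)")
                continue
            rows += compare_groups_lmm(agg, scale, config.aggregation_mode)
        contrasts = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        contrasts.to_csv(out / "contrasts.csv", index=False)

        mulkey = probes_df[probes_df["meadow"] == "Mulkey"]
        veg = None
        if mulkey["treatment"].nunique() == 2:
            table = (
                mulkey.assign(veg=pd.Categorical(mulkey["vegetation"], VEGETATION_CLASSES))
                .groupby(["treatment", "veg"], observed=False).size().unstack()
            )
            keep = table.columns[(table.sum(axis=0) > 0)]
            chi2, dfree, p = vegetation_type_test(table[keep].to_numpy())
            shade = shade_logistic(
                [binarize_solar(s) for s in mulkey["solar_pct"]], mulkey["treatment"]
            )
            veg = {"chi2": chi2, "df": dfree, "p_value": p, **{f"shade_{k}": v for k, v in shade.items() if k != "proportions"}}
            willows_path = data_dir / "willows.csv"
            if willows_path.exists():
                survey = read_willows(
                    willows_path, {"Mulkey:ungrazed": 1200.0, "Mulkey:grazed": 900.0}
                )
                sp, hh = willow_spacing(survey), willow_heights(survey)
                for reach, d in sp["per_reach"].items():
                    veg[f"willow_count_{reach}"] = d["count"]
                    veg[f"willow_spacing_{reach}"] = d["mean_spacing_m"]
                for reach, d in hh["per_reach"].items():
                    veg[f"willow_height_{reach}"] = d["mean_cm"]
            pd.DataFrame([veg]).to_csv(out / "vegetation.csv", index=False)
            if shade["separation"]:
                summary.append("WARNING: complete separation in shade logistic model")
        log.info("compare: %d contrasts", len(contrasts))

        # -- project -------------------------------------------------------
        stage = "project"
        proj_probes = probes_df
        if not config.pool_mulkey:
            proj_probes = probes_df[
                (probes_df["meadow"] != "Mulkey") | (probes_df["treatment"] == "grazed")
            ]
        model = fit_max_vs_avg(daily, weekly, proj_probes)
        baselines = baseline_wavgt(weekly, proj_probes)
        table = recurrence_table(model, baselines, config.scenarios, config.sd_mode)
        table.to_csv(out / "projections.csv", index=False)
        rendered = render_recurrence_table(table)
        (out / "projections.txt").write_text(rendered + "\n")
        summary += ["Scenario projections:", rendered, ""]
        singular = [m for m, r in model.responses.items() if r.singular]
        if singular:
            summary.append(f"WARNING: singular date random effect in {singular}")
        log.info("project: %d rows", len(table))

        (out / "summary.txt").write_text("\n".join(summary) + "\n")
        log.info("done in %.1f s", time.perf_counter() - t0)
        results.update(
            qc=qc_table, daily=daily, weekly=weekly, season=season,
            site_summary=summ, gradients=grad, contrasts=contrasts,
            vegetation=veg, model=model, baselines=baselines, projections=table,
        )
        return results
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
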