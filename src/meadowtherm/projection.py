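"""Climate-scenario projection of maximum stream temperatures.

A mixed model links the observed daily maximum (DmaxT) at each probe to the
weekly average temperature (WavgT) of the same probe and date, with a random
intercept per calendar date to absorb repeated measures.  Air-temperature
warming scenarios are scaled to water with a fixed conservative ratio
(0.5 C water per 1 C air), shifted through the fitted line, and wrapped in
50 / 95 / 99% normal prediction bands whose upper limits are read as the
2-, 20- and 100-year recurrence temperatures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_lmm
from .types import MeadowResponse, ProjectionModel, ScenarioSpec

__all__ = [
    "DEFAULT_SCENARIOS",
    "air_to_water",
    "fit_max_vs_avg",
    "project_scenario",
    "recurrence_table",
    "baseline_wavgt",
]

#: The four scenarios with their printed water deltas (the pessimistic air
#: rise of 3.7 C is quoted as 1.8 C of water, not the exact product 1.85).
DEFAULT_SCENARIOS = (
    ScenarioSpec("current", 0.0, 0.5, 0.0),
    ScenarioSpec("optimistic", 1.0, 0.5, 0.5),
    ScenarioSpec("pessimistic", 3.7, 0.5, 1.8),
    ScenarioSpec("cataclysmic", 5.6, 0.5, 2.8),
)

#: band level -> (two-sided coverage, recurrence label)
BAND_LEVELS = {"50%": (0.50, "2 yr"), "95%": (0.95, "20 yr"), "99%": (0.99, "100 yr")}


def air_to_water(delta_air: float, ratio: float = 0.5) -> float:
    """Water-temperature increase for a given air-temperature increase."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return delta_air * ratio


def _join_max_avg(daily: pd.DataFrame, weekly: pd.DataFrame, probes: pd.DataFrame) -> pd.DataFrame:
    df = daily[daily["complete"]][["probe_id", "date", "DmaxT"]].merge(
        weekly[["probe_id", "date", "WavgT"]], on=["probe_id", "date"]
    )
    return df.merge(probes[["probe_id", "meadow"]], on="probe_id")


def fit_max_vs_avg(
    daily: pd.DataFrame,
    weekly: pd.DataFrame,
    probes: pd.DataFrame,
    reference: str | None = None,
    min_obs_per_meadow: int = 30,
) -> ProjectionModel:
    """Fit DmaxT ~ WavgT with a date random intercept.

    One fit per meadow (slopes and variance components used for projection)
    plus one all-meadow interaction fit providing the slope contrasts
    against the reference meadow.
    """
    df = _join_max_avg(daily, weekly, probes)
    meadows = sorted(df["meadow"].unique())
    counts = df["meadow"].value_counts()
    thin = [m for m in meadows if counts[m] < min_obs_per_meadow]
    if thin:
        raise ValueError(f"fewer than {min_obs_per_meadow} probe-days in {thin}")
    if reference is None:
        reference = "Mulkey" if "Mulkey" in meadows else meadows[0]

    responses: dict[str, MeadowResponse] = {}
    for m in meadows:
        sub = df[df["meadow"] == m]
        X = np.column_stack([np.ones(len(sub)), sub["WavgT"].to_numpy()])
        fit = fit_lmm(sub["DmaxT"].to_numpy(), X, {"date": sub["date"].astype(str).to_numpy()})
        responses[m] = MeadowResponse(
            meadow=m,
            slope=float(fit.beta[1]),
            slope_se=float(np.sqrt(fit.cov_beta[1, 1])),
            intercept=float(fit.beta[0]),
            date_re_sd=fit.re_sd("date"),
            residual_sd=fit.residual_sd,
            n_obs=len(sub),
            # degenerate (exact-fit) responses are flagged alongside pinned
            # random-effect variances
            singular=bool(fit.singular) or fit.residual_sd < 1e-6,
        )

    slope_differences: dict[str, tuple[float, float, float, float, float]] = {}
    if len(meadows) >= 2:
        cat = pd.Categorical(df["meadow"], categories=[reference] + [m for m in meadows if m != reference])
        w = df["WavgT"].to_numpy()
        cols = [np.ones(len(df)), w]
        for k in range(1, len(meadows)):
            ind = (cat.codes == k).astype(float)
            cols.extend([ind, ind * w])
        X = np.column_stack(cols)
        fit = fit_lmm(df["DmaxT"].to_numpy(), X, {"date": df["date"].astype(str).to_numpy()})
        slope_differences[reference] = (0.0, 0.0, 0.0, float(fit.n - fit.p), 1.0)
        for k, m in enumerate([m for m in meadows if m != reference], start=1):
            c = np.zeros(X.shape[1])
            c[1 + 2 * k] = -1.0  # reference slope minus meadow m's slope offset
            res = fit.contrast(c)
            slope_differences[m] = (res.estimate, res.se, res.t, res.df, res.p_value)
    return ProjectionModel(responses=responses, reference=reference, slope_differences=slope_differences)


def baseline_wavgt(weekly: pd.DataFrame, probes: pd.DataFrame) -> dict[str, float]:
    """Mean WavgT per meadow over all probe-days of the summer window.

    The two areas of the partially grazed meadow are pooled (the grazed-only
    variant is a caller-side filter of ``probes``).
    """
    df = weekly.merge(probes[["probe_id", "meadow"]], on="probe_id")
    return df.groupby("meadow")["WavgT"].mean().to_dict()


def project_scenario(
    model: ProjectionModel,
    scenario: ScenarioSpec,
    baselines: dict[str, float],
    sd_mode: str = "total",
    allow_cooling: bool = False,
) -> pd.DataFrame:
    """Expected DmaxT per meadow under one scenario, with recurrence bands.

    expected = intercept + slope * (baseline WavgT + delta_water); bands are
    normal quantiles at 50/95/99% two-sided coverage around the expectation,
    with sd from the model's variance components (residual plus date
    random-intercept by default).
    """
    if scenario.delta_water < 0 and not allow_cooling:
        raise ValueError("negative water delta; pass allow_cooling=True to permit")
    rows = []
    for meadow in sorted(model.responses):
        r = model.responses[meadow]
        base = baselines[meadow]
        shifted = base + scenario.delta_water
        expected = r.intercept + r.slope * shifted
        sd = r.sd_total(sd_mode)
        row = {
            "scenario": scenario.label,
            "delta_air": scenario.delta_air,
            "delta_water": scenario.delta_water,
            "meadow": meadow,
            "baseline_wavgt": base,
            "shifted_wavgt": shifted,
            "expected_dmaxt": expected,
            "sd_total": sd,
        }
        for name, (cover, recurrence) in BAND_LEVELS.items():
            z = stats.norm.ppf(0.5 + cover / 2.0)
            row[f"lo_{name}"] = expected - z * sd
            row[f"hi_{name}"] = expected + z * sd
            row[f"recurrence_{name}"] = recurrence
        rows.append(row)
    return pd.DataFrame(rows)


def recurrence_table(
    model: ProjectionModel,
    baselines: dict[str, float],
    scenarios=DEFAULT_SCENARIOS,
    sd_mode: str = "total",
) -> pd.DataFrame:
    """Scenario x meadow table of expected maxima and recurrence bands."""
    parts = [
        project_scenario(model, sc, baselines, sd_mode=sd_mode) for sc in scenarios
    ]
    return pd.concat(parts, ignore_index=True)


def render_recurrence_table(table: pd.DataFrame) -> str:
    """Aligned text rendering, values half-up rounded to 1 decimal place."""
    def r1(v: float) -> str:
        import decimal

        return str(
            decimal.Decimal(str(float(v))).quantize(
                decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
            )
        )

    lines = [
        f"{'scenario':<12} {'meadow':<11} {'WavgT':>6} {'shift':>6} {'DmaxT':>6} "
        f"{'50% (2 yr)':>14} {'95% (20 yr)':>14} {'99% (100 yr)':>14}"
    ]
    for _, row in table.iterrows():
        lines.append(
            f"{row['scenario']:<12} {row['meadow']:<11} {r1(row['baseline_wavgt']):>6} "
            f"{r1(row['shifted_wavgt']):>6} {r1(row['expected_dmaxt']):>6} "
            f"{'[' + r1(row['lo_50%']) + ':' + r1(row['hi_50%']) + ']':>14} "
            f"{'[' + r1(row['lo_95%']) + ':' + r1(row['hi_95%']) + ']':>14} "
            f"{'[' + r1(row['lo_99%']) + ':' + r1(row['hi_99%']) + ']':>14}"
        )
    return "\n".join(lines)
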