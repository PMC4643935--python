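"""The grazing analyses.

Vegetation and shading contrasts between the grazed and ungrazed areas of the
partially grazed meadow, per-reach regressions of season-maximum temperature
on downstream distance, and autocorrelation-aware mixed-model temperature
contrasts among meadows at week / month / year aggregation scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import fit_lmm
from .spatial import (
    autoregressive_adjusted_model,
    inverse_distance_weights,
    morans_i,
)
from .types import (
    SOLAR_SUNNY_THRESHOLD,
    GradientFit,
    GroupContrast,
    MoranResult,
    WillowSurvey,
)

__all__ = [
    "vegetation_type_test",
    "willow_spacing",
    "willow_heights",
    "binarize_solar",
    "shade_logistic",
    "gradient_regression",
    "aggregate_metric",
    "compare_groups_lmm",
]

METRICS = ("WminT", "WavgT", "WmaxT")


def vegetation_type_test(counts) -> tuple[float, int, float]:
    """Pearson chi-squared test of a treatment x vegetation-class table.

    No continuity correction; df = (number of classes) - 1 for the two
    treatments.  A zero expected cell is an error (merge sparse classes).
    """
    table = np.asarray(counts, float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("need a 2 x k table with k >= 2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError("zero expected cell; merge vegetation categories")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def willow_spacing(survey: WillowSurvey) -> dict:
    """Consecutive-stem spacing per treatment, with an adjusted comparison.

    Spacing is the difference of sorted positions along the bank transect.
    The treatment comparison regresses spacing on treatment adjusted for a
    quadratic trend in position (midpoint of each gap) and reports the
    F-test plus residual Moran's I.
    """
    per, rows = {}, []
    for reach, grp in survey.records.groupby("reach", sort=True):
        pos = np.sort(grp["position_m"].to_numpy())
        length = survey.reach_lengths[reach]
        if len(pos) < 2:
            per[reach] = {
                "count": len(pos), "mean_spacing_m": np.nan,
                "density_per_m": len(pos) / length,
            }
            continue
        spacing = np.diff(pos)
        per[reach] = {
            "count": len(pos),
            "mean_spacing_m": float(spacing.mean()),
            "density_per_m": len(pos) / length,
        }
        mid = (pos[:-1] + pos[1:]) / 2.0
        treatment = grp["treatment"].iloc[0]
        rows.append(pd.DataFrame({"spacing": spacing, "treatment": treatment, "pos": mid}))
    comparison = None
    if len(rows) >= 2:
        df = pd.concat(rows, ignore_index=True)
        try:
            comparison = autoregressive_adjusted_model(
                df["spacing"], df["treatment"], position=df["pos"]
            )
        except ValueError:
            comparison = None  # too few gaps for the adjusted model
    return {"per_reach": per, "comparison": comparison}


def willow_heights(survey: WillowSurvey) -> dict:
    """Stem height mean +- sd per treatment plus the adjusted F-test."""
    per = {}
    for reach, grp in survey.records.groupby("reach", sort=True):
        h = grp["height_cm"]
        per[reach] = {"count": len(h), "mean_cm": float(h.mean()), "sd_cm": float(h.std())}
    rec = survey.records
    comparison = autoregressive_adjusted_model(
        rec["height_cm"], rec["treatment"], position=rec["position_m"]
    )
    return {"per_reach": per, "comparison": comparison}


def binarize_solar(solar_pct: float) -> int:
    """1 when solar exposure is near-total (>= 98%), else 0 (shade present)."""
    if not 0.0 <= solar_pct <= 100.0:
        raise ValueError(f"solar_pct {solar_pct} outside [0, 100]")
    return int(solar_pct >= SOLAR_SUNNY_THRESHOLD)


def shade_logistic(sunny, treatment) -> dict:
    """Logistic regression of the sunny/shaded binary on treatment.

    Returns the treatment z and p plus per-treatment sunny proportions.
    Complete separation is flagged and the p-value replaced by Fisher's
    exact test on the 2x2 table.
    """
    y = np.asarray(sunny, int)
    tr = pd.Categorical(treatment)
    if len(tr.categories) < 2:
        raise ValueError("need both treatments present")
    props = {
        str(level): float(y[tr.codes == k].mean()) for k, level in enumerate(tr.categories)
    }
    table = np.array(
        [[np.sum((tr.codes == k) & (y == v)) for v in (0, 1)] for k in (0, 1)]
    )
    separated = (table == 0).any()
    if separated:
        _, p = stats.fisher_exact(table)
        return {"z": np.nan, "p_value": float(p), "proportions": props, "separation": True}
    X = sm.add_constant((tr.codes == 1).astype(float))
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return {
        "z": float(fit.tvalues[1]),
        "p_value": float(fit.pvalues[1]),
        "proportions": props,
        "separation": False,
    }


def gradient_regression(
    season: pd.DataFrame,
    probes: pd.DataFrame,
    metric: str = "MWmaxT",
) -> dict[str, GradientFit]:
    """Per-reach OLS of the season maximum on downstream distance.

    Each reach is fitted separately (the slopes differ between treatments,
    so no pooled interaction model).  Slopes are reported per 100 m; Moran's
    I of the residuals against probe coordinates is attached.
    """
    df = season.merge(
        probes[["probe_id", "reach", "distance_m", "lat", "lon"]], on="probe_id"
    )
    out: dict[str, GradientFit] = {}
    for reach, grp in df.groupby("reach", sort=True):
        n = len(grp)
        if n < 3:
            raise ValueError(f"{reach}: need >= 3 probes for a gradient fit")
        if grp["distance_m"].nunique() < 2:
            raise ValueError(f"{reach}: distances all equal")
        X = sm.add_constant(grp["distance_m"].to_numpy() / 100.0)
        fit = sm.OLS(grp[metric].to_numpy(), X).fit()
        resid_moran: MoranResult | None
        try:
            w = inverse_distance_weights(grp[["lat", "lon"]].to_numpy())
            resid_moran = morans_i(fit.resid, w)
        except ValueError:
            resid_moran = None
        out[reach] = GradientFit(
            reach=reach,
            slope_per_100m=float(fit.params[1]),
            se_per_100m=float(fit.bse[1]),
            t=float(fit.tvalues[1]),
            df=int(fit.df_resid),
            p_value=float(fit.pvalues[1]),
            n_probes=n,
            intercept=float(fit.params[0]),
            residual_moran=resid_moran,
        )
    return out


def aggregate_metric(
    weekly: pd.DataFrame,
    probes: pd.DataFrame,
    scale: str = "month",
    mode: str = "per_probe",
) -> pd.DataFrame:
    """Average the weekly metrics within (probe or reach) x time-unit cells.

    ``scale`` is the calendar unit (ISO week, calendar month, calendar year)
    that one averaged value represents; ``mode="per_reach"`` collapses probes
    so each reach contributes one value per unit (the fully collapsed
    analysis), while ``per_probe`` keeps probes as replicates for the mixed
    model.
    """
    if scale not in ("week", "month", "year"):
        raise ValueError("scale must be week, month or year")
    if mode not in ("per_probe", "per_reach"):
        raise ValueError("mode must be per_probe or per_reach")
    if weekly.empty:
        raise ValueError("empty weekly table")
    df = weekly.merge(probes[["probe_id", "reach"]], on="probe_id")
    ts = pd.to_datetime(df["date"])
    if scale == "week":
        iso = ts.dt.isocalendar()
        df["unit"] = iso.year.astype(str) + "-W" + iso.week.astype(str).str.zfill(2)
    elif scale == "month":
        df["unit"] = ts.dt.strftime("%Y-%m")
    else:
        df["unit"] = ts.dt.year.astype(str)
    keys = ["reach", "unit"] if mode == "per_reach" else ["reach", "probe_id", "unit"]
    agg = df.groupby(keys, sort=True)[list(METRICS)].mean().reset_index()
    agg["scale"] = scale
    return agg


def _temporal_moran(residuals: np.ndarray, units: pd.Series) -> MoranResult | None:
    """Moran's I of residuals against time distance between their units."""
    import warnings

    codes = pd.Categorical(units, categories=sorted(units.unique())).codes.astype(float)
    try:
        with warnings.catch_warnings():
            # groups observed in the same unit are structurally coincident
            warnings.filterwarnings("ignore", message="coincident")
            w = inverse_distance_weights(codes)
        return morans_i(residuals, w)
    except ValueError:
        return None


def compare_groups_lmm(
    aggregated: pd.DataFrame,
    scale: str | None = None,
    mode: str = "per_probe",
) -> list[GroupContrast]:
    """All pairwise reach contrasts of each weekly metric via a mixed model.

    Model: metric ~ reach with a random intercept per time unit (and per
    probe in ``per_probe`` mode), Satterthwaite degrees of freedom, residual
    temporal Moran's I attached to every contrast of that metric.
    """
    df = aggregated
    scale = scale or str(df["scale"].iloc[0])
    groups = sorted(df["reach"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if df["unit"].nunique() < 2:
        raise ValueError("need at least 2 time units")

    cat = pd.Categorical(df["reach"], categories=groups)
    X = np.column_stack(
        [np.ones(len(df))] + [(cat.codes == k).astype(float) for k in range(1, len(groups))]
    )
    factors = {"unit": df["unit"].to_numpy()}
    if mode == "per_probe" and "probe_id" in df.columns:
        factors["probe"] = df["probe_id"].to_numpy()

    out: list[GroupContrast] = []
    for metric in METRICS:
        fit = fit_lmm(df[metric].to_numpy(), X, factors)
        rm = _temporal_moran(fit.residuals(df[metric].to_numpy()), df["unit"])
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                c = np.zeros(X.shape[1])
                if a > 0:
                    c[a] = 1.0
                if b > 0:
                    c[b] = -1.0
                res = fit.contrast(c)
                out.append(
                    GroupContrast(
                        metric=metric,
                        scale=scale,
                        group_a=groups[a],
                        group_b=groups[b],
                        difference=res.estimate,
                        se=res.se,
                        t=res.t,
                        df=res.df,
                        p_value=res.p_value,
                        moran_i=None if rm is None else rm.I,
                        moran_p=None if rm is None else rm.p_value,
                    )
                )
    return out
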