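"""Moran's I autocorrelation diagnostics and autoregression adjustments.

Moran's I is computed with inverse-distance weights (great-circle metres for
lat/lon coordinates, absolute differences for 1-D transect positions or time
lags) and tested against its randomization null: E[I] = -1/(n-1), variance
from the Cliff-Ord randomization formula, two-sided normal p-value.  A
seeded permutation test is available for small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import MoranResult

__all__ = [
    "great_circle_m",
    "inverse_distance_weights",
    "morans_i",
    "lag1_autoregression",
    "autoregressive_adjusted_model",
    "AdjustedModelFit",
]

_EARTH_RADIUS_M = 6_371_008.8  # mean sphere radius


def great_circle_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance in metres on the mean-radius sphere."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, float)
    if points.ndim == 1 or points.shape[1] == 1:
        x = points.reshape(-1)
        return np.abs(x[:, None] - x[None, :])
    if points.shape[1] == 2:  # (lat, lon)
        lat, lon = points[:, 0], points[:, 1]
        return great_circle_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    raise ValueError("points must be 1-D positions or (n, 2) lat/lon")


def inverse_distance_weights(points) -> np.ndarray:
    """w_ij = 1 / d_ij with zero diagonal.

    Coincident pairs have their distance floored at half the smallest
    positive pairwise distance (with a warning); all-coincident input is an
    error.
    """
    d = _pairwise_distances(points)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    off = ~np.eye(n, dtype=bool)
    positive = d[off][d[off] > 0]
    if positive.size == 0:
        raise ValueError("all points are coincident")
    floor = positive.min() / 2.0
    if (d[off] == 0).any():
        warnings.warn(f"coincident points: distances floored at {floor:.6g}")
    d = np.where(off & (d < floor), floor, d)
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return w


def _randomization_sd(x: np.ndarray, w: np.ndarray) -> float:
    n = len(x)
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    z = x - x.mean()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - 1.0 / (n - 1) ** 2
    return float(np.sqrt(max(var, 0.0)))


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    z = x - x.mean()
    s0 = w.sum()
    return float(len(x) / s0 * (z @ w @ z) / (z @ z))


def morans_i(
    values,
    weights: np.ndarray,
    method: str = "normal",
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I of ``values`` under inverse-distance (or any) weights.

    ``method="normal"`` uses the randomization-null normal approximation;
    ``method="permutation"`` a seeded two-sided permutation test (the normal
    sd is still reported).
    """
    x = np.asarray(values, float)
    w = np.asarray(weights, float)
    n = len(x)
    if w.shape != (n, n):
        raise ValueError("weights shape does not match values")
    if np.ptp(x) == 0:
        raise ValueError("constant residuals: Moran's I undefined")
    i_obs = _moran_stat(x, w)
    e_i = -1.0 / (n - 1)
    sd = _randomization_sd(x, w)
    if method == "normal":
        z = (i_obs - e_i) / sd if sd > 0 else np.inf
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.array(
            [_moran_stat(rng.permutation(x), w) for _ in range(n_permutations)]
        )
        p = (1.0 + np.sum(np.abs(null - e_i) >= abs(i_obs - e_i))) / (n_permutations + 1.0)
    else:
        raise ValueError("method must be 'normal' or 'permutation'")
    return MoranResult(I=i_obs, expected_I=e_i, sd_I=sd, p_value=float(min(p, 1.0)))


def lag1_autoregression(series) -> tuple[float, float]:
    """Slope and p-value of x_{t+1} regressed on x_t (lag-1 autoregression)."""
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise ValueError("need at least 4 time points")
    res = stats.linregress(x[:-1], x[1:])
    return float(res.slope), float(res.pvalue)


@dataclass(frozen=True)
class AdjustedModelFit:
    """Treatment effect adjusted for polynomial spatial trend."""

    coefficient: float  # treatment effect (second level minus first)
    se: float
    F: float
    df_num: int
    df_den: int
    p_value: float
    residual_moran: MoranResult | None
    params: pd.Series


def autoregressive_adjusted_model(
    response,
    treatment,
    lon=None,
    lat=None,
    position=None,
) -> AdjustedModelFit:
    """OLS of response on treatment plus spatial polynomial covariates.

    With lat/lon the covariates are lon, lat and their squares (coordinates
    are centred and scaled first for conditioning); with a 1-D transect
    ``position`` they are position and position^2.  Reports the treatment
    F-test and Moran's I of the residuals against the spatial coordinates.
    """
    y = np.asarray(response, float)
    tr = pd.Categorical(treatment)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if len(tr.categories) < 2:
        raise ValueError("need both treatments present")
    if np.ptp(y) == 0:  # constant response: every effect is exactly zero
        params = pd.Series(
            {"const": float(y[0]), "treatment": 0.0}
        )
        return AdjustedModelFit(0.0, 0.0, 0.0, 1, len(y) - 2, 1.0, None, params)

    cols = {"treatment": (tr.codes == 1).astype(float)}
    if position is not None:
        s = _standardize(position)
        cols["pos"], cols["pos2"] = s, s**2
        coords = np.asarray(position, float)
    elif lon is not None and lat is not None:
        slon, slat = _standardize(lon), _standardize(lat)
        cols.update(lon=slon, lat=slat, lon2=slon**2, lat2=slat**2)
        coords = np.column_stack([np.asarray(lat, float), np.asarray(lon, float)])
    else:
        raise ValueError("provide either lon+lat or position")

    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.iloc[:, 1:].corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear terms {pair}")

    fit = sm.OLS(y, X).fit()
    contrast = np.zeros(X.shape[1])
    contrast[list(X.columns).index("treatment")] = 1.0
    ftest = fit.f_test(contrast)
    try:
        rm = morans_i(fit.resid, inverse_distance_weights(coords))
    except ValueError:
        rm = None
    return AdjustedModelFit(
        coefficient=float(fit.params["treatment"]),
        se=float(fit.bse["treatment"]),
        F=float(ftest.fvalue),
        df_num=int(ftest.df_num),
        df_den=int(ftest.df_denom),
        p_value=float(ftest.pvalue),
        residual_moran=rm,
        params=fit.params,
    )


def _standardize(x) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)
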