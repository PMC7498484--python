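"""Per-observation goodness-of-fit and complexity metrics, and stat maps.

Metrics computed for each observation (voxel/vertex):

* MSE — the residual sum of squares ``||y - f(X)||^2``.  Where a
  per-sample mean is semantically required (AIC), the sum is divided by
  the sample size L; both conventions are exposed explicitly.
* R^2 = 1 - SS_res / SS_y, with SS_y about the observation mean.
* AIC = 2k - 2 LLR with LLR = -L/2 (log(2 pi MSE_mean) + 1): a
  goodness-of-fit/complexity trade-off, k counting all fitted
  parameters.
* F-test — does the full model (correctors + predictors) explain
  significantly more variance than the restricted, correctors-only
  model?  f = ((SS_res - SS_full)/SS_full) * ((L - df_full)/(df_full -
  df_restricted)); the p-value is the upper tail of
  F(df_full - df_restricted, L - df_full).
* PRSS = MSE + gamma * c_abruptness — complexity measured from the
  fitted curve's shape (integrated squared second derivative) rather
  than its df, so a flexible fitter that happens to produce a straight
  line is penalized no more than a linear model.  VNPRSS divides PRSS
  by the curve's variance about the observation mean, for
  high-variability data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .fitters import CurveSet, FittedModel, eval_curves

__all__ = [
    "StatMap",
    "mse",
    "r2",
    "aic",
    "f_test",
    "f_test_arrays",
    "c_abruptness",
    "prss",
    "vnprss",
    "make_stat_map",
    "cluster_extent_filter",
]

#: sentinel stored where a metric is undefined (e.g. zero-variance voxel)
UNDEFINED = np.nan


@dataclass
class StatMap:
    """One scalar metric per observation, with optional p-values."""

    values: np.ndarray
    name: str
    p_values: np.ndarray | None = None
    mask: np.ndarray | None = None
    df: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        if self.p_values is not None:
            p = np.asarray(self.p_values, dtype=float)
            ok = p[np.isfinite(p)]
            if ok.size and (ok.min() < 0 or ok.max() > 1):
                raise ValueError("p-values outside [0, 1]")
            self.p_values = p

    @property
    def n(self) -> int:
        return self.values.size


def mse(y, yhat, mean: bool = False) -> float:
    """Residual sum of squares ``||y - yhat||^2`` (or its mean over L)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    ss = float(((y - yhat) ** 2).sum())
    return ss / y.shape[0] if mean else ss


def r2(y, yhat) -> float:
    """Coefficient of determination about the observation mean."""
    y = np.asarray(y, dtype=float)
    ss_y = float(((y - y.mean()) ** 2).sum())
    if ss_y == 0:
        return UNDEFINED
    return 1.0 - mse(y, yhat) / ss_y


def aic(mse_value: float, k: float, L: int) -> float:
    """Akaike information criterion from the per-sample mean squared error."""
    if mse_value < 0:
        raise ValueError("mse must be nonnegative")
    if mse_value == 0:
        warnings.warn("zero MSE: AIC is -infinity")
        return -np.inf
    return 2.0 * k + L * (np.log(2.0 * np.pi * mse_value) + 1.0)


def f_test(y, corrector_fit, full_fit, df_full: float,
           df_restricted: float, L: int | None = None):
    """Nested-model F-test of the predictor contribution (scalar case).

    Returns (f_score, p_value) where p is the upper-tail probability of
    F(df_full - df_restricted, L - df_full) at f_score.
    """
    y = np.asarray(y, dtype=float)
    L = y.shape[0] if L is None else L
    if df_full <= df_restricted:
        raise ValueError("df_full must exceed df_restricted")
    if L <= df_full:
        raise ValueError("sample size must exceed df_full")
    ss_res = mse(y, corrector_fit)
    ss_full = mse(y, full_fit)
    if ss_full == 0:
        warnings.warn("zero full-model residual: p-value sentinel 0")
        return np.inf, 0.0
    f = ((ss_res - ss_full) / ss_full) * ((L - df_full) /
                                          (df_full - df_restricted))
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_full - df_restricted, L - df_full))
    return float(f), p


def f_test_arrays(Y, corrector_fitted, full_fitted, df_full,
                  df_restricted, L: int):
    """Vectorized nested-model F-test over N observations.

    df_full may be per-observation (e.g. SVR support-vector counts).
    """
    Y = np.asarray(Y, dtype=float)
    ss_res = ((Y - corrector_fitted) ** 2).sum(axis=0)
    ss_full = ((Y - full_fitted) ** 2).sum(axis=0)
    df_full = np.broadcast_to(np.asarray(df_full, dtype=float), ss_res.shape)
    d1 = df_full - df_restricted
    d2 = L - df_full
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_res - ss_full) / ss_full * (d2 / d1)
    f = np.where(ss_full > 0, np.maximum(f, 0.0), np.inf)
    bad = (d1 <= 0) | (d2 <= 0)
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0.0),
                                            d1, d2), 0.0)
    f = np.where(bad, UNDEFINED, f)
    p = np.where(bad, UNDEFINED, p)
    return f, p


def c_abruptness(curve, grid, squared: bool = True) -> float:
    """Roughness of a curve: trapezoidal integral of its second
    derivative over the grid — squared by default, absolute value as a
    variant."""
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 5:
        raise ValueError("curve grid needs at least 5 points")
    d1 = np.gradient(curve, grid, edge_order=2)
    d2 = np.gradient(d1, grid, edge_order=2)
    integrand = d2 ** 2 if squared else np.abs(d2)
    return float(np.trapezoid(integrand, grid))


def prss(curveset: CurveSet | np.ndarray, mse_value, gamma_penalty: float = 1.0,
         grid=None, squared: bool = True):
    """Penalized residual sum of squares: MSE + gamma * c_abruptness."""
    if gamma_penalty < 0:
        raise ValueError("gamma must be nonnegative")
    if isinstance(curveset, CurveSet):
        grid = curveset.grid
        curves = curveset.curves
    else:
        curves = np.atleast_2d(np.asarray(curveset, dtype=float))
        if grid is None:
            raise ValueError("grid required when passing raw curves")
    ab = np.array([c_abruptness(c, grid, squared=squared) for c in curves])
    out = np.asarray(mse_value, dtype=float) + gamma_penalty * ab
    return float(out[0]) if out.size == 1 and np.isscalar(mse_value) else out


def vnprss(prss_value, curveset: CurveSet | np.ndarray, ybar, grid=None):
    """Variance-normalized PRSS: PRSS / ||f - ybar||^2 over the grid."""
    if isinstance(curveset, CurveSet):
        curves = curveset.curves
    else:
        curves = np.atleast_2d(np.asarray(curveset, dtype=float))
    cvar = ((curves - np.atleast_1d(ybar)[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(prss_value, dtype=float) / cvar
    out = np.where(cvar > 0, out, UNDEFINED)
    return float(out[0]) if out.size == 1 and np.isscalar(prss_value) else out


def make_stat_map(model: FittedModel, Y, metric: str,
                  gamma_penalty: float = 1.0, curve_points: int = 100,
                  mask=None) -> StatMap:
    """Vectorize a metric over all observations of a two-stage fit.

    ``metric`` is one of mse, r2, aic, ftest, prss, vnprss.  For ftest
    the map carries a p-value array and values = 1 - p ("significance")
    is available to display code; the raw f-scores are the values.
    Masked-out observations carry the NaN sentinel.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y.reshape(Y.shape[0], -1)
    L, N = Y.shape
    fitted = model.fitted
    ss_res_full = ((Y - fitted) ** 2).sum(axis=0)
    dfm = {"df_correctors": model.df_correctors,
           "df_predictors": float(np.mean(np.atleast_1d(model.df_predictors)))}
    if mask is None:
        mask = np.ones(N, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    p_values = None
    if metric == "mse":
        values = ss_res_full
    elif metric == "r2":
        ss_y = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = 1.0 - ss_res_full / ss_y
        values = np.where(ss_y > 0, values, UNDEFINED)
    elif metric == "aic":
        k = model.df_correctors + np.atleast_1d(model.df_predictors)
        m = np.maximum(ss_res_full / L, 1e-300)
        values = 2.0 * np.broadcast_to(k, ss_res_full.shape) \
            + L * (np.log(2.0 * np.pi * m) + 1.0)
    elif metric == "ftest":
        df_full = model.df_correctors + np.atleast_1d(model.df_predictors)
        values, p_values = f_test_arrays(
            Y, model.corrector_fitted, fitted, df_full,
            model.df_correctors, L)
    elif metric in {"prss", "vnprss"}:
        curves = eval_curves(model, T=curve_points)
        values = prss(curves, ss_res_full, gamma_penalty)
        if metric == "vnprss":
            # curves explain corrector residuals, whose mean is ~0
            ybar = model.corrected_observations.mean(axis=0)
            values = vnprss(values, curves, ybar)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    values = np.where(mask, values, UNDEFINED)
    if p_values is not None:
        p_values = np.where(mask, p_values, UNDEFINED)
    return StatMap(values=values, name=metric, p_values=p_values,
                   mask=mask, df=dfm)


def cluster_extent_filter(p_values: np.ndarray, shape, mask=None,
                          threshold: float = 0.001,
                          extent: int = 100) -> np.ndarray:
    """Uncorrected p-threshold plus connected-component extent filtering.

    Voxels with p below ``threshold`` are kept only if they belong to a
    6-connected cluster of at least ``extent`` voxels.  Returns a
    boolean array of surviving voxels (flat, same length as p_values).
    """
    p = np.asarray(p_values, dtype=float)
    sig = np.zeros(int(np.prod(shape)), dtype=bool)
    if mask is None:
        sig[:] = np.isfinite(p) & (p < threshold)
    else:
        idx = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        sig[idx] = np.isfinite(p) & (p < threshold)
    vol = sig.reshape(shape)
    structure = ndimage.generate_binary_structure(vol.ndim, 1)
    labels, n = ndimage.label(vol, structure=structure)
    keep = np.zeros_like(vol)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() >= extent:
            keep |= comp
    return keep.ravel()
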