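"""Curve-fitting families behind one stage contract, and two-stage fitting.

Three model families fit each observation (voxel/vertex) independently
against the subject covariates:

* GLM — ordinary least squares on a polynomial basis expansion of each
  design column; df equals the expanded column count.
* GAM — an additive model ``y = a + f_1(x_1) + ... + f_m(x_m) + e``
  whose per-covariate smoothers (linear, polynomial, B-spline, natural
  spline) are estimated by backfitting: each smoother is cyclically
  refitted to the partial residual of the others until the largest
  component change falls below a tolerance.  df is the sum of the
  smoother dfs.
* SVR — epsilon-insensitive support vector regression (polynomial or
  RBF kernel); only deviations beyond the epsilon-tube are penalized,
  with C trading flatness against tube violations.  The effective df is
  the number of marginal support vectors (dual coefficient strictly
  inside (0, C)), with a kernel-trace fallback behind a flag.

The analysis proper is two-stage: the corrector (confound) model is
fitted to the observations first, then the predictor model is fitted to
the corrector residuals.  Any family may serve at either stage.

All fitters process observations strictly one at a time internally, so
fitting in chunks of any size is bit-identical to fitting all at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from patsy import dmatrix, build_design_matrices
from sklearn.svm import SVR as _SkSVR

from .design import DesignSplit

__all__ = [
    "GLMSpec",
    "GAMSpec",
    "SVRSpec",
    "SmootherSpec",
    "FittedModel",
    "CurveSet",
    "fit_glm",
    "fit_gam",
    "fit_svr",
    "fit_stage",
    "fit_two_stage",
    "fit_two_stage_chunked",
    "predict",
    "eval_curves",
    "grid_search_svr",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLMSpec:
    """Polynomial-expansion GLM; ``degrees`` is per-column (int broadcasts)."""

    degrees: int | tuple[int, ...] = 1
    family: str = field(default="glm", init=False)

    def degrees_for(self, m: int) -> tuple[int, ...]:
        d = self.degrees
        degs = (d,) * m if isinstance(d, int) else tuple(d)
        if len(degs) != m:
            raise ValueError(f"{len(degs)} degrees for {m} design columns")
        if any(int(x) < 1 for x in degs):
            raise ValueError("polynomial degrees must be >= 1")
        return tuple(int(x) for x in degs)


@dataclass(frozen=True)
class SmootherSpec:
    """One per-covariate GAM smoother.

    kind: 'linear' (df 1), 'polynomial' (df = degree),
    'bspline' or 'natural_spline' (df supplied by the user, >= 3).
    """

    kind: str = "linear"
    df: int = 1

    def __post_init__(self):
        if self.kind not in {"linear", "polynomial", "bspline", "natural_spline"}:
            raise ValueError(f"unknown smoother kind {self.kind!r}")
        if self.kind == "linear" and self.df != 1:
            raise ValueError("linear smoother has df 1")
        if self.kind == "polynomial" and self.df < 1:
            raise ValueError("polynomial smoother needs degree >= 1")
        if self.kind in {"bspline", "natural_spline"} and self.df < 3:
            raise ValueError("spline smoothers need df >= 3")


@dataclass(frozen=True)
class GAMSpec:
    smoothers: tuple[SmootherSpec, ...] = (SmootherSpec(),)
    max_iter: int = 500
    tol: float = 1e-6
    family: str = field(default="gam", init=False)

    def smoothers_for(self, m: int) -> tuple[SmootherSpec, ...]:
        s = self.smoothers
        if len(s) == 1 and m > 1:
            s = s * m
        if len(s) != m:
            raise ValueError(f"{len(s)} smoothers for {m} design columns")
        return s


@dataclass(frozen=True)
class SVRSpec:
    """epsilon-SVR with a polynomial or RBF kernel."""

    kernel: str = "rbf"
    epsilon: float = 0.1
    C: float = 1.0
    gamma: float = 1.0       # RBF width
    degree: int = 3          # polynomial kernel degree
    df_mode: str = "support_vectors"   # or "kernel_trace"
    family: str = field(default="svr", init=False)

    def __post_init__(self):
        if self.kernel not in {"rbf", "polynomial"}:
            raise ValueError(f"unknown SVR kernel {self.kernel!r}")
        if self.epsilon < 0 or self.C <= 0 or self.gamma <= 0:
            raise ValueError("SVR needs epsilon >= 0, C > 0, gamma > 0")


FitterSpec = GLMSpec | GAMSpec | SVRSpec


# ---------------------------------------------------------------------------
# Stage fits
# ---------------------------------------------------------------------------

def _expand_poly(X: np.ndarray, degrees: tuple[int, ...]) -> np.ndarray:
    """Column-wise polynomial expansion: column j contributes powers 1..d_j."""
    cols = [X[:, j][:, None] ** np.arange(1, d + 1)[None, :]
            for j, d in enumerate(degrees)]
    return np.hstack(cols) if cols else np.empty((X.shape[0], 0))


class GLMStage:
    """Least-squares fit of Y on a polynomial expansion of X."""

    def __init__(self, X, Y, spec: GLMSpec, include_intercept: bool = True):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        Y = Y.reshape(Y.shape[0], -1)
        L = Y.shape[0]
        self.spec = spec
        self.include_intercept = include_intercept
        self.degrees = spec.degrees_for(X.shape[1])
        B = _expand_poly(X, self.degrees)
        if include_intercept:
            B = np.hstack([np.ones((L, 1)), B])
        if B.shape[1] >= L:
            raise ValueError(
                f"expanded design has {B.shape[1]} columns for {L} subjects"
            )
        if B.shape[1] and np.linalg.matrix_rank(B) < B.shape[1]:
            raise np.linalg.LinAlgError("expanded design is rank deficient")
        self._pinv = np.linalg.pinv(B)
        # one observation at a time so chunked fitting is bit-identical
        coefs = np.empty((B.shape[1], Y.shape[1]))
        for i in range(Y.shape[1]):
            coefs[:, i] = self._pinv @ Y[:, i]
        self.coefs = coefs
        self.df = float(sum(self.degrees))
        self.fitted = self._design_predict(B)
        self._squeeze = squeeze

    def _design_predict(self, B):
        out = np.empty((B.shape[0], self.coefs.shape[1]))
        for i in range(self.coefs.shape[1]):
            out[:, i] = B @ self.coefs[:, i]
        return out

    def predict(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        B = _expand_poly(X_new, self.degrees)
        if self.include_intercept:
            B = np.hstack([np.ones((B.shape[0], 1)), B])
        return self._design_predict(B)


class _Smoother:
    """A GAM component: basis construction + least-squares projection."""

    def __init__(self, x: np.ndarray, spec: SmootherSpec):
        self.spec = spec
        self.x = np.asarray(x, dtype=float)
        self._design_info = None
        if spec.kind == "linear":
            B = self.x[:, None]
        elif spec.kind == "polynomial":
            B = self.x[:, None] ** np.arange(1, spec.df + 1)[None, :]
        else:
            if np.unique(self.x).size < spec.df + 1:
                raise ValueError(
                    f"{spec.kind}(df={spec.df}) needs at least {spec.df + 1} "
                    "distinct covariate values"
                )
            term = "bs" if spec.kind == "bspline" else "cr"
            dm = dmatrix(f"{term}(x, df={spec.df}) - 1", {"x": self.x})
            self._design_info = dm.design_info
            B = np.asarray(dm)
        # fit with an own intercept (centered away afterwards) so each
        # smoother projects onto span(1, basis)
        self.B = np.hstack([np.ones((B.shape[0], 1)), B])
        self._pinv = np.linalg.pinv(self.B)
        self.df = float(spec.df)

    def basis(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        if self._design_info is None:
            if self.spec.kind == "linear":
                B = x_new[:, None]
            else:
                B = x_new[:, None] ** np.arange(1, self.spec.df + 1)[None, :]
        else:
            B = np.asarray(
                build_design_matrices([self._design_info], {"x": x_new})[0])
        return np.hstack([np.ones((B.shape[0], 1)), B])

    def fit_coefs(self, r: np.ndarray) -> np.ndarray:
        return self._pinv @ r


class GAMStage:
    """Backfitting fit of an additive model, one observation at a time.

    Components are mean-centered after every refit (the additive model's
    identifiability gauge); the running intercept absorbs the means.
    """

    def __init__(self, X, Y, spec: GAMSpec):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float).reshape(X.shape[0], -1)
        L, m = X.shape
        self.spec = spec
        smoother_specs = spec.smoothers_for(m)
        self.smoothers = [_Smoother(X[:, j], s) for j, s in
                          enumerate(smoother_specs)]
        self.df = float(sum(s.df for s in self.smoothers))
        N = Y.shape[1]
        self.alpha = np.empty(N)
        self.coefs = [np.zeros((s.B.shape[1], N)) for s in self.smoothers]
        self.offsets = [np.zeros(N) for _ in self.smoothers]
        self.converged = np.ones(N, dtype=bool)
        self.fitted = np.empty((L, N))
        for i in range(N):
            self._backfit_one(Y[:, i], i)
        if not self.converged.all():
            warnings.warn(
                f"GAM backfitting did not converge for "
                f"{(~self.converged).sum()} observation(s) "
                f"within {spec.max_iter} iterations"
            )

    def _backfit_one(self, y: np.ndarray, i: int) -> None:
        L = y.shape[0]
        alpha = y.mean()
        comps = [np.zeros(L) for _ in self.smoothers]
        coefs = [np.zeros(s.B.shape[1]) for s in self.smoothers]
        offs = [0.0 for _ in self.smoothers]
        converged = False
        for _ in range(self.spec.max_iter):
            delta = 0.0
            for j, s in enumerate(self.smoothers):
                partial = y - alpha - sum(
                    comps[k] for k in range(len(comps)) if k != j)
                c = s.fit_coefs(partial)
                f = s.B @ c
                off = f.mean()
                f = f - off
                delta = max(delta, np.abs(f - comps[j]).max())
                comps[j], coefs[j], offs[j] = f, c, off
            if delta < self.spec.tol:
                converged = True
                break
        self.alpha[i] = alpha
        for j in range(len(self.smoothers)):
            self.coefs[j][:, i] = coefs[j]
            self.offsets[j][i] = offs[j]
        self.converged[i] = converged
        self.fitted[:, i] = alpha + sum(comps)

    def component(self, j: int, x_new: np.ndarray) -> np.ndarray:
        """Evaluate centered component j on new covariate values (L' x N)."""
        B = self.smoothers[j].basis(np.asarray(x_new, dtype=float))
        return B @ self.coefs[j] - self.offsets[j][None, :]

    def predict(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        out = np.tile(self.alpha, (X_new.shape[0], 1))
        for j in range(len(self.smoothers)):
            out += self.component(j, X_new[:, j])
        return out


class SVRStage:
    """Per-observation epsilon-SVR via scikit-learn.

    The fitted machine is kept as the kernel expansion
    ``f(x) = sum_l k(x^l, x) beta_l + b`` over the training points, with
    beta the dual coefficients (zero off the support vectors).
    """

    def __init__(self, X, Y, spec: SVRSpec):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float).reshape(X.shape[0], -1)
        L, N = Y.shape
        self.spec = spec
        self.X_train = X
        kernel = "rbf" if spec.kernel == "rbf" else "poly"
        self.betas = np.zeros((L, N))
        self.bias = np.zeros(N)
        df = np.empty(N)
        self.fitted = np.empty((L, N))
        degenerate = np.ptp(X, axis=0).max() == 0 if L else True
        for i in range(N):
            if degenerate:
                self.bias[i] = Y[:, i].mean()
                df[i] = 1.0
                self.fitted[:, i] = self.bias[i]
                continue
            est = _SkSVR(kernel=kernel, C=spec.C, epsilon=spec.epsilon,
                         gamma=spec.gamma, degree=spec.degree, coef0=1.0)
            est.fit(X, Y[:, i])
            beta = np.zeros(L)
            beta[est.support_] = est.dual_coef_.ravel()
            self.betas[:, i] = beta
            self.bias[i] = float(est.intercept_.ravel()[0])
            df[i] = self._effective_df(beta)
            self.fitted[:, i] = est.predict(X)
        self.df = df if N > 1 else float(df[0])

    def _effective_df(self, beta: np.ndarray) -> float:
        if self.spec.df_mode == "kernel_trace":
            K = self._kernel(self.X_train, self.X_train)
            tr = np.trace(K @ np.linalg.pinv(K + np.eye(K.shape[0]) / self.spec.C))
            return max(float(tr), 1.0)
        # marginal support vectors: dual coefficient strictly inside (0, C)
        a = np.abs(beta)
        margin = (a > 1e-10 * self.spec.C) & (a < self.spec.C * (1 - 1e-10))
        return max(float(margin.sum()), 1.0)

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.spec.kernel == "rbf":
            d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
            return np.exp(-self.spec.gamma * d2)
        return (self.spec.gamma * A @ B.T + 1.0) ** self.spec.degree

    def predict(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        K = self._kernel(X_new, self.X_train)
        return K @ self.betas + self.bias[None, :]


class InterceptStage:
    """Mean-only model, used as the corrector when no correctors exist."""

    def __init__(self, Y):
        Y = np.asarray(Y, dtype=float)
        Y = Y.reshape(Y.shape[0], -1)
        self.mean = Y.mean(axis=0)
        self.df = 0.0
        self.fitted = np.tile(self.mean, (Y.shape[0], 1))

    def predict(self, X_new) -> np.ndarray:
        n = np.atleast_2d(np.asarray(X_new, dtype=float)).shape[0] \
            if np.size(X_new) else 1
        return np.tile(self.mean, (n, 1))


def fit_glm(X, Y, degrees: int | Sequence[int] = 1,
            include_intercept: bool = True) -> GLMStage:
    """Least-squares polynomial GLM (see :class:`GLMStage`)."""
    degs = tuple(degrees) if not isinstance(degrees, int) else degrees
    return GLMStage(X, Y, GLMSpec(degrees=degs), include_intercept)


def fit_gam(X, Y, smoothers: Sequence[SmootherSpec] | SmootherSpec | None = None,
            max_iter: int = 500, tol: float = 1e-6) -> GAMStage:
    """Backfitting GAM (see :class:`GAMStage`)."""
    if smoothers is None:
        smoothers = (SmootherSpec(),)
    if isinstance(smoothers, SmootherSpec):
        smoothers = (smoothers,)
    return GAMStage(X, Y, GAMSpec(smoothers=tuple(smoothers),
                                  max_iter=max_iter, tol=tol))


def fit_svr(X, Y, kernel: str = "rbf", eps: float = 0.1, C: float = 1.0,
            gamma: float = 1.0, degree: int = 3) -> SVRStage:
    """epsilon-SVR (see :class:`SVRStage`)."""
    return SVRStage(X, Y, SVRSpec(kernel=kernel, epsilon=eps, C=C,
                                  gamma=gamma, degree=degree))


def fit_stage(X, Y, spec: FitterSpec, include_intercept: bool = True):
    """Dispatch a stage fit on its spec family."""
    if isinstance(spec, GLMSpec):
        return GLMStage(X, Y, spec, include_intercept=include_intercept)
    if isinstance(spec, GAMSpec):
        return GAMStage(X, Y, spec)
    if isinstance(spec, SVRSpec):
        return SVRStage(X, Y, spec)
    raise TypeError(f"not a fitter spec: {spec!r}")


# ---------------------------------------------------------------------------
# Two-stage model
# ---------------------------------------------------------------------------

@dataclass
class CurveSet:
    """Predictor-component curves evaluated on a common grid (N x T)."""

    grid: np.ndarray
    curves: np.ndarray
    observation_ids: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.grid.size < 5:
            raise ValueError("curve grid needs at least 5 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("curve grid must be strictly increasing")
        if self.observation_ids is None:
            self.observation_ids = np.arange(self.curves.shape[0])

    @property
    def T(self) -> int:
        return self.grid.size

    @property
    def n_curves(self) -> int:
        return self.curves.shape[0]


@dataclass
class FittedModel:
    """Two-stage fit: corrector model on Y, predictor model on residuals."""

    corrector: object
    predictor: object
    XC: np.ndarray
    XP: np.ndarray
    predictor_range: tuple[float, float]

    @property
    def df_correctors(self) -> float:
        # +1 for the always-on intercept of the corrector stage
        df = self.corrector.df
        return float(np.max(df)) + 1.0 if np.ndim(df) else float(df) + 1.0

    @property
    def df_predictors(self):
        df = self.predictor.df
        return np.maximum(df, 1.0) if np.ndim(df) else max(float(df), 1.0)

    @property
    def corrector_fitted(self) -> np.ndarray:
        return self.corrector.fitted

    @property
    def predictor_fitted(self) -> np.ndarray:
        return self.predictor.fitted

    @property
    def fitted(self) -> np.ndarray:
        return self.corrector.fitted + self.predictor.fitted

    @property
    def corrected_observations(self) -> np.ndarray:
        """Training residuals after corrector removal (what curves explain)."""
        return self._corrected

    @property
    def n_observations(self) -> int:
        return self.corrector.fitted.shape[1]


def fit_two_stage(Y, split: DesignSplit, corrector_spec: FitterSpec | None,
                  predictor_spec: FitterSpec) -> FittedModel:
    """Fit the corrector model to Y, then the predictor model to its
    residuals.

    An intercept is always part of the corrector stage, so with an empty
    corrector design the predictor is fitted to mean-centered Y.  Any
    family may serve at either stage; the predictor stage carries no
    extra intercept of its own beyond what its family requires.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y.reshape(Y.shape[0], -1)
    XC, XP = split.XC, split.XP
    if XC.shape[1] == 0 or corrector_spec is None:
        corrector = InterceptStage(Y)
    elif isinstance(corrector_spec, GLMSpec):
        corrector = GLMStage(XC, Y, corrector_spec, include_intercept=True)
    else:
        corrector = fit_stage(XC, Y, corrector_spec)
    residuals = Y - corrector.fitted
    if isinstance(predictor_spec, GLMSpec):
        predictor = GLMStage(XP, residuals, predictor_spec,
                             include_intercept=False)
    else:
        predictor = fit_stage(XP, residuals, predictor_spec)
    model = FittedModel(
        corrector=corrector,
        predictor=predictor,
        XC=XC,
        XP=XP,
        predictor_range=(float(XP[:, 0].min()), float(XP[:, 0].max())),
    )
    model._corrected = residuals
    return model


def predict(model: FittedModel, XC_new=None, XP_new=None) -> np.ndarray:
    """Corrector + predictor predictions for new covariates.

    Omitted corrector covariates are held at the training design (useful
    only when predicting at training rows); predictions outside the
    training predictor range are allowed but trigger a warning.
    """
    XC_new = model.XC if XC_new is None else np.atleast_2d(np.asarray(XC_new))
    XP_new = model.XP if XP_new is None else np.atleast_2d(np.asarray(XP_new))
    lo, hi = model.predictor_range
    if XP_new[:, 0].min() < lo or XP_new[:, 0].max() > hi:
        warnings.warn("predicting beyond the training predictor range "
                      "(extrapolation)")
    return model.corrector.predict(XC_new) + model.predictor.predict(XP_new)


def eval_curves(model: FittedModel, T: int = 100,
                observation_ids=None) -> CurveSet:
    """Predictor-component curves on a uniform grid over the training range.

    Correctors are held at their (centered) reference, i.e. only the
    predictor stage is evaluated.  With a multi-column predictor design,
    the first column is swept and the others held at their training
    means.
    """
    if T < 5:
        raise ValueError("curve grid needs T >= 5")
    lo, hi = model.predictor_range
    grid = np.linspace(lo, hi, T)
    XPg = np.tile(model.XP.mean(axis=0), (T, 1))
    XPg[:, 0] = grid
    curves = model.predictor.predict(XPg).T  # N x T
    if observation_ids is not None:
        curves = curves[np.asarray(observation_ids)]
    return CurveSet(grid=grid, curves=curves, observation_ids=observation_ids)


def _concat_stages(stages):
    """Merge per-chunk stage fits (same design/spec) into one stage."""
    first = stages[0]
    if len(stages) == 1:
        return first
    import copy

    out = copy.copy(first)
    if isinstance(first, InterceptStage):
        out.mean = np.concatenate([s.mean for s in stages])
        out.fitted = np.hstack([s.fitted for s in stages])
    elif isinstance(first, GLMStage):
        out.coefs = np.hstack([s.coefs for s in stages])
        out.fitted = np.hstack([s.fitted for s in stages])
    elif isinstance(first, GAMStage):
        out.alpha = np.concatenate([s.alpha for s in stages])
        out.coefs = [np.hstack([s.coefs[j] for s in stages])
                     for j in range(len(first.smoothers))]
        out.offsets = [np.concatenate([s.offsets[j] for s in stages])
                       for j in range(len(first.smoothers))]
        out.converged = np.concatenate([s.converged for s in stages])
        out.fitted = np.hstack([s.fitted for s in stages])
    elif isinstance(first, SVRStage):
        out.betas = np.hstack([s.betas for s in stages])
        out.bias = np.concatenate([s.bias for s in stages])
        out.df = np.concatenate([np.atleast_1d(s.df) for s in stages])
        out.fitted = np.hstack([s.fitted for s in stages])
    else:
        raise TypeError(f"cannot merge stages of type {type(first)}")
    return out


def fit_two_stage_chunked(Y, split: DesignSplit,
                          corrector_spec: FitterSpec | None,
                          predictor_spec: FitterSpec,
                          chunk_size: int | None = None) -> FittedModel:
    """Two-stage fit processed in contiguous observation chunks.

    Observations are fitted independently, so the merged result is
    bit-identical to the unchunked fit for any chunk size.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y.reshape(Y.shape[0], -1)
    N = Y.shape[1]
    if chunk_size is None or chunk_size >= N:
        return fit_two_stage(Y, split, corrector_spec, predictor_spec)
    parts = [fit_two_stage(Y[:, s:s + chunk_size], split,
                           corrector_spec, predictor_spec)
             for s in range(0, N, chunk_size)]
    model = FittedModel(
        corrector=_concat_stages([p.corrector for p in parts]),
        predictor=_concat_stages([p.predictor for p in parts]),
        XC=split.XC,
        XP=split.XP,
        predictor_range=parts[0].predictor_range,
    )
    model._corrected = np.hstack([p.corrected_observations for p in parts])
    return model


# ---------------------------------------------------------------------------
# SVR hyperparameter grid search
# ---------------------------------------------------------------------------

def _sample_axis(lo: float, hi: float, n: int, sampling: str,
                 rng: np.random.Generator) -> np.ndarray:
    if sampling == "deterministic-linear":
        return np.linspace(lo, hi, n)
    if sampling == "deterministic-log":
        return np.geomspace(lo, hi, n)
    if sampling == "random":
        return rng.uniform(lo, hi, n)
    raise ValueError(f"unknown sampling strategy {sampling!r}")


def grid_search_svr(
    Y,
    split: DesignSplit,
    space: dict,
    sampling: str = "deterministic-log",
    H: int = 9,
    subset_size: int = 50,
    metric: str = "mse",
    iterations: int = 1,
    sigma_min: float = 0.0,
    seed: int = 0,
    base_spec: SVRSpec | None = None,
    corrector_spec: FitterSpec | None = None,
) -> SVRSpec:
    """Grid search for SVR hyperparameters on variance-weighted error.

    ``space`` maps hyperparameter names (among C, gamma, epsilon) either
    to an explicit value list or to a (low, high) range sampled with the
    chosen strategy.  H combinations are drawn (per-axis counts as even
    as possible); for each of ``iterations`` re-drawn subsets G of
    ``subset_size`` eligible observations (variance >= sigma_min) every
    combination is fitted and scored by the chosen per-observation
    metric t_i weighted by the inverse observation variance,
    T_hat = sum_i t_i / sigma_i.  The combination with the smallest
    accumulated T_hat wins; ties break toward smaller C, then smaller
    gamma.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y.reshape(Y.shape[0], -1)
    L, N = Y.shape
    if metric not in {"mse", "ftest", "mallows_cp"}:
        raise ValueError(f"unknown search metric {metric!r}")
    base = base_spec or SVRSpec()
    rng = np.random.default_rng(seed)

    axes_names = [k for k in ("C", "gamma", "epsilon") if k in space]
    if not axes_names:
        raise ValueError("empty hyperparameter space")
    axes = {}
    explicit = {k: v for k, v in space.items()
                if not (isinstance(v, tuple) and len(v) == 2)}
    sampled_names = [k for k in axes_names if k not in explicit]
    per_axis = max(1, int(round(H ** (1 / len(sampled_names))))) \
        if sampled_names else 1
    for k in axes_names:
        if k in explicit:
            axes[k] = np.asarray(list(explicit[k]), dtype=float)
        else:
            lo, hi = space[k]
            axes[k] = _sample_axis(float(lo), float(hi), per_axis, sampling, rng)
    mesh = np.meshgrid(*[axes[k] for k in axes_names], indexing="ij")
    combos = [dict(zip(axes_names, vals))
              for vals in zip(*(m.ravel() for m in mesh))]

    sigma = Y.var(axis=0)
    eligible = np.flatnonzero(sigma >= max(sigma_min, 0.0) * 1.0)
    eligible = eligible[sigma[eligible] > 0]
    if eligible.size == 0:
        raise ValueError("no observations with variance above sigma_min")

    specs = [
        SVRSpec(kernel=base.kernel,
                epsilon=float(c.get("epsilon", base.epsilon)),
                C=float(c.get("C", base.C)),
                gamma=float(c.get("gamma", base.gamma)),
                degree=base.degree, df_mode=base.df_mode)
        for c in combos
    ]
    if len(specs) == 1 and iterations >= 0:
        return specs[0]

    totals = np.zeros(len(specs))
    for _ in range(max(iterations, 1)):
        G = (eligible if subset_size >= eligible.size
             else rng.choice(eligible, size=subset_size, replace=False))
        G = np.sort(G)
        Yg = Y[:, G]
        sg = sigma[G]
        for s_idx, spec in enumerate(specs):
            model = fit_two_stage(Yg, split, corrector_spec, spec)
            resid = Yg - model.fitted
            ss = (resid ** 2).sum(axis=0)
            if metric == "mse":
                t = ss
            elif metric == "ftest":
                from .inference import f_test_arrays
                _, p = f_test_arrays(
                    Yg, model.corrector_fitted, model.fitted,
                    model.df_correctors + np.atleast_1d(model.df_predictors),
                    model.df_correctors, L)
                t = p
            else:  # mallows_cp against the most flexible model in the space
                big = SVRSpec(kernel=base.kernel,
                              epsilon=float(min(a.get("epsilon", base.epsilon)
                                                for a in combos)),
                              C=float(max(a.get("C", base.C) for a in combos)),
                              gamma=float(max(a.get("gamma", base.gamma)
                                              for a in combos)),
                              degree=base.degree)
                big_model = fit_two_stage(Yg, split, corrector_spec, big)
                s2 = ((Yg - big_model.fitted) ** 2).sum(axis=0) / L
                s2 = np.maximum(s2, 1e-30)
                df = np.atleast_1d(model.df_predictors)
                t = ss / s2 - L + 2 * (model.df_correctors + df)
            totals[s_idx] += float((t / sg).sum())

    # ties toward smaller C, then smaller gamma
    order = sorted(
        range(len(specs)),
        key=lambda i: (round(totals[i], 12), specs[i].C, specs[i].gamma),
    )
    return specs[order[0]]
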