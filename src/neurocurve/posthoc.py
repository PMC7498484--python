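"""Model-comparison map algebra and derivative-weighted curve clustering.

Comparison maps merge several stat maps into one: a signed or absolute
difference (2 maps), a squared difference (2 maps), an RGB stack
(3 maps, one per color channel, min-max rescaled) or a best-map (the
winning model index per voxel under the metric's polarity).

Curve clustering groups fitted predictor curves across the brain by a
shape-aware pseudometric

    SD(x, y) = sum_n w_n * d_n(x, y),      n = 0 .. N_D - 1

where d_n is the Euclidean distance between the n-th discrete
derivatives of the two curves.  The defaults N_D = 3 and
w = [0.2, 0.8, 0.2] weight the first derivative (the trend) most.
Clusters are built bottom-up with average linkage until N_C clusters
remain; silhouette and within/between variance diagnostics support the
choice of N_C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_samples

from .fitters import CurveSet
from .inference import StatMap

__all__ = [
    "ComparisonMap",
    "ClusterResult",
    "DEFAULT_DERIVATIVE_WEIGHTS",
    "combine_maps",
    "curve_similarity",
    "similarity_matrix",
    "cluster_curves",
    "cluster_diagnostics",
]

DEFAULT_DERIVATIVE_WEIGHTS = np.array([0.2, 0.8, 0.2])

#: metrics where larger values mean a better fit
HIGHER_IS_BETTER = {"ftest", "f_score", "r2"}
LOWER_IS_BETTER = {"mse", "aic", "prss", "vnprss"}


@dataclass
class ComparisonMap:
    kind: str
    values: np.ndarray
    source_names: list


@dataclass
class ClusterResult:
    labels: np.ndarray
    merge_history: list          # (i, j, linkage distance) per merge
    centroids: np.ndarray        # N_C x T mean curves
    silhouette_mean: float = np.nan
    within_var: float = np.nan
    between_var: float = np.nan


def _polarity(name: str) -> int:
    if name in HIGHER_IS_BETTER:
        return 1
    if name in LOWER_IS_BETTER:
        return -1
    raise ValueError(
        f"metric {name!r} has no known polarity; pass polarity explicitly")


def combine_maps(maps: list[StatMap], kind: str,
                 polarity: int | None = None) -> ComparisonMap:
    """Combine stat maps into a diff/absdiff/se/rgb/best comparison map.

    ``best`` needs a shared metric (or an explicit ``polarity``: +1 for
    higher-better, -1 for lower-better); ties go to the lowest index.
    """
    kind = kind.lower()
    arity = {"diff": 2, "absdiff": 2, "se": 2, "rgb": 3}
    if kind in arity and len(maps) != arity[kind]:
        raise ValueError(f"{kind}-map needs exactly {arity[kind]} maps")
    if kind == "best" and len(maps) < 2:
        raise ValueError("best-map needs at least 2 maps")
    names = [m.name for m in maps]
    V = np.vstack([m.values for m in maps])

    if kind == "diff":
        out = V[0] - V[1]
    elif kind == "absdiff":
        out = np.abs(V[0] - V[1])
    elif kind == "se":
        out = (V[0] - V[1]) ** 2
    elif kind == "rgb":
        chans = []
        for row in V:
            finite = row[np.isfinite(row)]
            lo, hi = (finite.min(), finite.max()) if finite.size else (0, 1)
            span = hi - lo if hi > lo else 1.0
            chans.append(np.clip((row - lo) / span, 0.0, 1.0))
        out = np.stack(chans, axis=1)  # N x 3
    elif kind == "best":
        if polarity is None:
            pols = {_polarity(n) for n in names}
            if len(pols) != 1:
                raise ValueError(
                    "best-map over mixed-polarity metrics; pass polarity")
            polarity = pols.pop()
        score = V if polarity > 0 else -V
        score = np.where(np.isfinite(score), score, -np.inf)
        out = np.argmax(score, axis=0).astype(float)
        out[~np.isfinite(V).any(axis=0)] = np.nan
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")
    return ComparisonMap(kind=kind, values=out, source_names=names)


def _derivative(curve: np.ndarray, n: int, step: float) -> np.ndarray:
    d = curve
    for _ in range(n):
        d = np.diff(d) / step
    return d


def curve_similarity(x_curve, y_curve, weights=None, step: float = 1.0,
                     normalize: bool = True) -> float:
    """Weighted sum of derivative distances between two curves.

    d_n is the Euclidean distance between the n-th discrete derivatives
    (n-fold first differencing scaled by the grid step); derivatives
    shrink the support by n points, and each d_n is divided by
    sqrt(T - n) when ``normalize`` so the weights compare like with
    like.
    """
    x = np.asarray(x_curve, dtype=float)
    y = np.asarray(y_curve, dtype=float)
    if x.shape != y.shape:
        raise ValueError("curves must share the grid")
    w = DEFAULT_DERIVATIVE_WEIGHTS if weights is None else np.asarray(weights)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    T = x.size
    if T < w.size:
        raise ValueError(f"curve of {T} points cannot support "
                         f"{w.size - 1} derivatives")
    total = 0.0
    for n, wn in enumerate(w):
        dx = _derivative(x, n, step)
        dy = _derivative(y, n, step)
        d = float(np.linalg.norm(dx - dy))
        if normalize:
            d /= np.sqrt(T - n)
        total += wn * d
    return total


def similarity_matrix(curves: np.ndarray, weights=None, step: float = 1.0,
                      normalize: bool = True) -> np.ndarray:
    """Pairwise SD distances (symmetric, zero diagonal) — vectorized."""
    C = np.atleast_2d(np.asarray(curves, dtype=float))
    w = DEFAULT_DERIVATIVE_WEIGHTS if weights is None else np.asarray(weights)
    T = C.shape[1]
    D = np.zeros((C.shape[0], C.shape[0]))
    for n, wn in enumerate(w):
        d = C
        for _ in range(n):
            d = np.diff(d, axis=1) / step
        diff = d[:, None, :] - d[None, :, :]
        dn = np.sqrt((diff ** 2).sum(-1))
        if normalize:
            dn = dn / np.sqrt(T - n)
        D += wn * dn
    return D


def _standardize(curves: np.ndarray) -> np.ndarray:
    mu = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (curves - mu) / sd


def cluster_curves(curves: CurveSet | np.ndarray, n_clusters: int,
                   weights=None, standardize: bool = True,
                   normalize: bool = True, step: float = 1.0) -> ClusterResult:
    """Bottom-up average-linkage clustering of curves under SD.

    Every curve starts in its own cluster; the pair of clusters with the
    smallest average inter-cluster SD is merged until ``n_clusters``
    remain.  Ties break toward the smallest pair indices.  Curves are
    z-scored over the grid by default (shapes, not amplitudes, are
    clustered).  Centroids are pointwise mean curves of the original
    (unstandardized) members.
    """
    raw = curves.curves if isinstance(curves, CurveSet) \
        else np.atleast_2d(np.asarray(curves, dtype=float))
    n = raw.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"need 1 <= n_clusters <= {n}")
    data = _standardize(raw) if standardize else raw
    D = similarity_matrix(data, weights=weights, step=step,
                          normalize=normalize)

    # Lance-Williams average-linkage agglomeration on the full matrix.
    active = list(range(n))
    members = {i: [i] for i in range(n)}
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    history = []
    while len(active) > n_clusters:
        sub = work[np.ix_(active, active)]
        flat = np.argmin(sub)            # row-major => smallest (i, j) ties
        ai, aj = divmod(flat, sub.shape[1])
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        history.append((i, j, float(sub[ai, aj])))
        ni, nj = len(members[i]), len(members[j])
        # average linkage update: weighted mean of the two old distances
        for k in active:
            if k in (i, j):
                continue
            work[i, k] = work[k, i] = (
                ni * work[i, k] + nj * work[j, k]) / (ni + nj)
        members[i] = members[i] + members[j]
        del members[j]
        active.remove(j)

    labels = np.empty(n, dtype=int)
    # stable label order: cluster of the lowest original index gets 0
    for lab, root in enumerate(sorted(members, key=lambda r: min(members[r]))):
        labels[members[root]] = lab
    n_c = len(members)
    centroids = np.vstack([raw[labels == lab].mean(axis=0)
                           for lab in range(n_c)])
    result = ClusterResult(labels=labels, merge_history=history,
                           centroids=centroids)
    if 2 <= n_c < n:
        sil, wv, bv = cluster_diagnostics(
            data, labels, weights=weights, step=step, normalize=normalize)
        result.silhouette_mean = sil
        result.within_var = wv
        result.between_var = bv
    return result


def cluster_diagnostics(curves, labels, weights=None, step: float = 1.0,
                        normalize: bool = True):
    """Mean silhouette plus within/between cluster variance under SD.

    Silhouette per curve is s = (b - a) / max(a, b) on the SD distance;
    singleton clusters contribute 0 by convention.  Within variance is
    the mean SD of a curve to its own centroid; between variance is the
    mean SD between distinct centroids.
    """
    if isinstance(curves, CurveSet):
        curves = curves.curves
    C = np.atleast_2d(np.asarray(curves, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("diagnostics need at least 2 clusters")
    D = similarity_matrix(C, weights=weights, step=step, normalize=normalize)
    sil = float(silhouette_samples(D, labels, metric="precomputed").mean())

    centroids = np.vstack([C[labels == u].mean(axis=0) for u in uniq])
    within = np.mean([
        curve_similarity(C[i], centroids[np.flatnonzero(uniq == labels[i])[0]],
                         weights=weights, step=step, normalize=normalize)
        for i in range(C.shape[0])
    ])
    DC = similarity_matrix(centroids, weights=weights, step=step,
                           normalize=normalize)
    iu = np.triu_indices(uniq.size, k=1)
    between = float(DC[iu].mean())
    return sil, float(within), between
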