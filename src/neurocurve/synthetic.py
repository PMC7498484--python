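"""Synthetic phantoms with known ground-truth curve families.

The phantom emulates a cross-sectional morphometry study: L subjects,
each with a small spatially normalized volume, a disease-staging
predictor (an AD-CSF-index-like score, uniform on [0, 2]) and the usual
confounds (age, sex).  Disjoint voxel regions carry one of four
ground-truth response families along the predictor:

* null       — no predictor effect
* linear     — a * x
* quadratic  — a * x^2
* sigmoid    — a / (1 + exp(-b (x - c))), the "accelerating then
  saturating" atrophy pattern (defaults b = 5, c = 1: steepest change
  mid-continuum)

Voxel values add corrector effects (linear + quadratic age terms and a
sex offset) and i.i.d. Gaussian noise.  Everything is driven by a
single seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CovariateTable
from .fitters import CurveSet

__all__ = [
    "PhantomSpec",
    "Region",
    "Phantom",
    "CURVE_FAMILIES",
    "curve_family",
    "generate_phantom",
    "generate_curve_set",
    "default_phantom_spec",
]

SIGMOID_STEEPNESS = 5.0
SIGMOID_MIDPOINT = 1.0


def curve_family(name: str, effect: float):
    """Ground-truth response f(x) for a family at a given effect size."""
    if name == "null":
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    if name == "linear":
        return lambda x: effect * np.asarray(x, dtype=float)
    if name == "quadratic":
        return lambda x: effect * np.asarray(x, dtype=float) ** 2
    if name == "sigmoid":
        return lambda x: effect / (
            1.0 + np.exp(-SIGMOID_STEEPNESS
                         * (np.asarray(x, dtype=float) - SIGMOID_MIDPOINT)))
    raise ValueError(f"unknown curve family {name!r}")


CURVE_FAMILIES = ("null", "linear", "quadratic", "sigmoid")


@dataclass(frozen=True)
class Region:
    """A set of flat voxel indices sharing one response family."""

    voxels: tuple[int, ...]
    family: str
    effect: float


@dataclass
class PhantomSpec:
    L: int = 80
    shape: tuple[int, int, int] = (16, 16, 16)
    regions: tuple[Region, ...] = ()
    age_slope: float = -0.02
    age_quadratic: float = 5e-4
    sex_offset: float = 0.1
    noise_sigma: float = 0.3
    predictor_range: tuple[float, float] = (0.0, 2.0)
    age_range: tuple[float, float] = (45.0, 75.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        seen: set[int] = set()
        for r in self.regions:
            overlap = seen.intersection(r.voxels)
            if overlap:
                raise ValueError(f"regions overlap at voxels {sorted(overlap)}")
            seen.update(r.voxels)


def _cube(shape, corner, size) -> tuple[int, ...]:
    ii, jj, kk = np.meshgrid(*[np.arange(c, c + size) for c in corner],
                             indexing="ij")
    return tuple(np.ravel_multi_index(
        (ii.ravel(), jj.ravel(), kk.ravel()), shape).tolist())


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The standard 16x16x16, L=80 phantom: one cubic region per
    non-null family (linear 0.5, quadratic 0.3, sigmoid 1.0) in an
    otherwise null volume."""
    shape = overrides.pop("shape", (16, 16, 16))
    regions = overrides.pop("regions", None)
    if regions is None:
        if min(shape) < 7:
            raise ValueError("default regions need every dimension >= 7")
        a, b, c = shape
        regions = (
            Region(_cube(shape, (1, 1, 1), 3), "linear", 0.5),
            Region(_cube(shape, (1, b - 4, 1), 3), "quadratic", 0.3),
            Region(_cube(shape, (a - 4, 1, c - 4), 3), "sigmoid", 1.0),
        )
    return PhantomSpec(shape=shape, regions=regions, seed=seed, **overrides)


@dataclass
class Phantom:
    """Generated phantom: data matrix, covariates and ground truth."""

    data: np.ndarray                     # L x N voxel matrix
    covariates: CovariateTable
    spec: PhantomSpec
    truth_curves: CurveSet               # per-region curves on the grid
    region_of_voxel: np.ndarray          # -1 = null background
    affine: np.ndarray = field(
        default_factory=lambda: np.eye(4))

    @property
    def shape(self):
        return self.spec.shape

    def volumes(self) -> np.ndarray:
        """Subject volumes stacked on the last axis (X, Y, Z, L)."""
        return np.moveaxis(
            self.data.reshape((self.spec.L,) + self.spec.shape), 0, -1)

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.covariates.values,
                            columns=self.covariates.names)


def generate_phantom(spec: PhantomSpec | None = None, *,
                     grid_points: int = 100) -> Phantom:
    """Sample covariates and voxel data for a phantom specification."""
    spec = spec or default_phantom_spec()
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    N = int(np.prod(spec.shape))

    predictor = rng.uniform(*spec.predictor_range, size=L)
    age = rng.uniform(*spec.age_range, size=L)
    sex = rng.integers(0, 2, size=L).astype(float)
    covariates = CovariateTable(
        np.column_stack([sex, age, predictor]),
        ["sex", "age", "adindex"],
    )

    corrector = (spec.age_slope * (age - age.mean())
                 + spec.age_quadratic * (age - age.mean()) ** 2
                 + spec.sex_offset * sex)
    signal = np.zeros((L, N))
    region_of_voxel = np.full(N, -1, dtype=int)
    grid = np.linspace(*spec.predictor_range, grid_points)
    truth = []
    for ridx, region in enumerate(spec.regions):
        f = curve_family(region.family, region.effect)
        cols = np.asarray(region.voxels)
        signal[:, cols] = f(predictor)[:, None]
        region_of_voxel[cols] = ridx
        truth.append(f(grid))
    noise = rng.normal(0.0, spec.noise_sigma, size=(L, N)) \
        if spec.noise_sigma > 0 else np.zeros((L, N))
    data = signal + corrector[:, None] + noise

    truth_curves = CurveSet(
        grid=grid,
        curves=np.vstack(truth) if truth else np.zeros((1, grid_points)),
    )
    return Phantom(data=data, covariates=covariates, spec=spec,
                   truth_curves=truth_curves,
                   region_of_voxel=region_of_voxel)


def generate_curve_set(families, n_per_family: int, noise: float = 0.05,
                       seed: int = 0, grid_points: int = 100,
                       effects=None):
    """Curves from named families with i.i.d. grid perturbations.

    Returns (CurveSet, labels) with labels the true family index of each
    curve.  Effect sizes default to 1.0 per family.
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 2.0, grid_points)
    effects = [1.0] * len(families) if effects is None else list(effects)
    curves, labels = [], []
    for fi, fam in enumerate(families):
        base = curve_family(fam, effects[fi])(grid)
        for _ in range(n_per_family):
            curves.append(base + rng.normal(0.0, noise, size=grid.size))
            labels.append(fi)
    return (CurveSet(grid=grid, curves=np.vstack(curves)),
            np.asarray(labels))
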