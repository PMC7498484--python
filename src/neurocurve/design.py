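"""Covariate tables and contrast-based splitting of the design space.

A mass-univariate analysis models every voxel/vertex observation as a
function of M subject-level covariates X (L subjects x M covariates).
A contrast matrix C (M x P) selects the predictor subspace X_P = X @ C;
the complementary null-contrast C0 = I - C @ pinv(C) defines the
corrector (confound) subspace X_C = X @ C0.  The corrector model is
fitted first and the predictor model explains its residuals, so the
split decides which covariate effects are "removed" versus "of
interest".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CovariateTable",
    "ContrastSpec",
    "DesignSplit",
    "DegenerateCovariateError",
    "preprocess_covariates",
    "build_contrast",
    "split_design",
]


class DegenerateCovariateError(ValueError):
    """A covariate column is numerically zero or linearly dependent."""


@dataclass
class CovariateTable:
    """L subjects x M covariates with unique column names.

    ``values`` is subject-major (one row per subject, in the same order
    as the observation image list).  Missing values are rejected at
    construction; categorical covariates are expected pre-encoded as
    numeric/dummy columns.
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate values must be a 2-D (L x M) array")
        if self.L < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.names) != self.M:
            raise ValueError(
                f"{len(self.names)} names for {self.M} covariate columns"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("covariate table contains missing/non-finite values")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, id_column: str | None = None
    ) -> "CovariateTable":
        if id_column is not None and id_column in df.columns:
            df = df.drop(columns=[id_column])
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])

    @classmethod
    def from_file(
        cls, path: str | Path, id_column: str | None = None
    ) -> "CovariateTable":
        """Load covariates from CSV or XLS/XLSX (header row = names)."""
        path = Path(path)
        if path.suffix.lower() in {".xls", ".xlsx"}:
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
        if df.isna().any().any():
            raise ValueError(f"missing values in covariate file {path}")
        return cls.from_dataframe(df, id_column=id_column)


@dataclass
class ContrastSpec:
    """A contrast matrix C and its derived null-contrast C0 = I - C @ C#."""

    C: np.ndarray
    C0: np.ndarray
    pseudoinverse_tol: float = 1e-8

    @property
    def M(self) -> int:
        return self.C.shape[0]

    @property
    def P(self) -> int:
        return self.C.shape[1]


@dataclass
class DesignSplit:
    """Corrector design XC = X @ C0 and predictor design XP = X @ C.

    Zero columns of XC (covariates fully captured by the contrast) are
    dropped; ``corrector_columns`` records the kept indices.
    """

    XC: np.ndarray
    XP: np.ndarray
    df_C: float
    df_P: float
    corrector_columns: list[int] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.XP.shape[0]


def preprocess_covariates(
    table: CovariateTable,
    mode: str,
    demean: bool = False,
    tol: float = 1e-10,
) -> CovariateTable:
    """Normalize, orthogonalize or orthonormalize covariate columns.

    ``normalize`` scales each column to unit Euclidean norm.
    ``orthogonalize`` runs sequential Gram-Schmidt in column order
    (later columns residualized on earlier ones, original scales kept),
    so users should put confounders first.  ``orthonormalize`` does
    both.  With ``demean=True`` every column is first residualized on
    the constant, aligning the preprocessing with the intercept that is
    always part of the corrector model.
    """
    if mode not in {"normalize", "orthogonalize", "orthonormalize"}:
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    V = table.values.copy()
    if demean:
        V = V - V.mean(axis=0, keepdims=True)

    ref = np.linalg.norm(table.values, axis=0).max()
    if mode in {"orthogonalize", "orthonormalize"}:
        for j in range(V.shape[1]):
            for k in range(j):
                nk = V[:, k] @ V[:, k]
                if nk > 0:
                    V[:, j] -= (V[:, k] @ V[:, j]) / nk * V[:, k]
            if np.linalg.norm(V[:, j]) <= tol * max(ref, 1.0):
                raise DegenerateCovariateError(
                    f"column {table.names[j]!r} is linearly dependent on "
                    "earlier columns (orthogonalization left it at zero)"
                )
    if mode in {"normalize", "orthonormalize"}:
        norms = np.linalg.norm(V, axis=0)
        bad = np.flatnonzero(norms <= tol * max(ref, 1.0))
        if bad.size:
            raise DegenerateCovariateError(
                f"column {table.names[bad[0]]!r} has zero norm"
            )
        V = V / norms
    return CovariateTable(V, list(table.names))


def build_contrast(C: np.ndarray, tol: float = 1e-8) -> ContrastSpec:
    """Build the null-contrast C0 = I - C @ C# from a contrast matrix.

    C# is the Moore-Penrose pseudoinverse (SVD-based, singular values
    below ``tol`` relative to the largest treated as zero).  The
    returned spec satisfies C0 @ C = 0 and C0 @ C0 = C0 to tolerance.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.ndim != 2:
        raise ValueError("contrast must be a 2-D M x P matrix")
    M, P = C.shape
    if not 1 <= P < M:
        raise ValueError(f"need 1 <= P < M, got C of shape {C.shape}")
    if not np.any(C):
        raise ValueError("contrast matrix is all zeros")
    C_pinv = np.linalg.pinv(C, rcond=tol)
    C0 = np.eye(M) - C @ C_pinv
    # sanity: the construction guarantees these up to conditioning
    if np.abs(C0 @ C).max() > 1e3 * tol * max(1.0, np.abs(C).max()):
        raise ValueError("null-contrast does not annihilate the contrast; "
                         "C may be too ill-conditioned for the tolerance")
    return ContrastSpec(C=C, C0=C0, pseudoinverse_tol=tol)


def split_design(table: CovariateTable, spec: ContrastSpec,
                 zero_tol: float = 1e-12) -> DesignSplit:
    """Split X into predictor XP = X @ C and corrector XC = X @ C0.

    Numerically zero columns of XC are dropped (their covariate is
    entirely in the predictor subspace); the kept original column
    indices are recorded.  df_C/df_P are the retained column counts.
    """
    if table.M != spec.M:
        raise ValueError(
            f"covariate table has M={table.M} but contrast has {spec.M} rows"
        )
    X = table.values
    XP = X @ spec.C
    XC_full = X @ spec.C0
    scale = max(np.abs(X).max(), 1.0)
    keep = [
        j for j in range(XC_full.shape[1])
        if np.abs(XC_full[:, j]).max() > zero_tol * scale
    ]
    XC = XC_full[:, keep]
    return DesignSplit(
        XC=XC,
        XP=XP,
        df_C=float(len(keep)),
        df_P=float(XP.shape[1]),
        corrector_columns=keep,
    )
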