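"""Readers/writers for volumetric and surface observations, and chunking.

Supported observation formats (all via nibabel): NIfTI-1 (.nii/.nii.gz),
MGH (.mgh/.mgz) and FreeSurfer curv-style per-vertex arrays
(.thickness/.area).  Subjects are aligned to covariate rows by file
order; all files must share geometry.  Stat maps are written back in
the input format with the input affine, masked-out locations as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.freesurfer.io import read_morph_data, write_morph_data

__all__ = [
    "ObservationStack",
    "load_observations",
    "write_map",
    "iter_chunks",
    "mm_to_voxel",
    "show_curves",
    "export_data_distribution",
]

SURFACE_SUFFIXES = {".thickness", ".area", ".curv", ".sulc"}


@dataclass
class ObservationStack:
    """L subjects x N observations with shared geometry and a mask."""

    data: np.ndarray                 # L x N (full, unmasked)
    mask: np.ndarray                 # N booleans
    affine: np.ndarray | None        # volumes only
    shape: tuple                     # spatial shape, or (n_vertices,)
    format: str                      # 'nifti' | 'mgh' | 'surface'

    @property
    def L(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]

    @property
    def masked(self) -> np.ndarray:
        """L x N_masked view of the in-mask observations."""
        return self.data[:, self.mask]


def _classify(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mgh", ".mgz")):
        return "mgh"
    if path.suffix.lower() in SURFACE_SUFFIXES:
        return "surface"
    raise ValueError(f"unsupported observation format: {path}")


def _load_one(path: Path, fmt: str):
    if fmt == "surface":
        arr = np.asarray(read_morph_data(str(path)), dtype=float)
        return arr, None, arr.shape
    img = nib.load(str(path))
    arr = np.asarray(img.get_fdata(), dtype=float)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    return arr, img.affine, arr.shape


def load_observations(paths, mask=None, sigma_min: float = 0.0,
                      n_subjects: int | None = None) -> ObservationStack:
    """Stack subject files into an L x N matrix with a validity mask.

    ``mask`` may be an explicit file or boolean array; otherwise the
    variance rule keeps observations with variance > ``sigma_min``
    (default 0 strictly: exactly-constant background is dropped).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no observation files given")
    fmt = _classify(paths[0])
    first, affine, shape = _load_one(paths[0], fmt)
    rows = [first.ravel()]
    for p in paths[1:]:
        f = _classify(p)
        if f != fmt:
            raise ValueError(f"{p} is {f}, expected {fmt}")
        arr, _, s = _load_one(p, f)
        if s != shape:
            raise ValueError(f"geometry mismatch in {p}: {s} vs {shape}")
        rows.append(arr.ravel())
    data = np.vstack(rows)
    if n_subjects is not None and data.shape[0] != n_subjects:
        raise ValueError(
            f"{data.shape[0]} subject files but covariate table has "
            f"{n_subjects} rows")

    if mask is not None:
        if isinstance(mask, (str, Path)):
            m_arr, _, m_shape = _load_one(Path(mask), _classify(Path(mask)))
            if m_shape != shape:
                raise ValueError("mask geometry differs from observations")
            mask = m_arr.ravel() > 0
        mask = np.asarray(mask, dtype=bool).ravel()
        if mask.size != data.shape[1]:
            raise ValueError("mask length does not match observation count")
    else:
        mask = data.var(axis=0) > sigma_min
    return ObservationStack(data=data, mask=mask, affine=affine,
                            shape=shape, format=fmt)


def write_map(values: np.ndarray, stack: ObservationStack,
              path: str | Path) -> Path:
    """Write per-observation values in the stack's format and geometry.

    ``values`` may be full-length N or mask-length; masked-out and
    non-finite locations are written as 0.  Integer arrays (best-maps,
    cluster labels) keep their values exactly.  An N x 3 RGB array is
    written as a 4D image with three volumes.
    """
    path = Path(path)
    fmt = _classify(path)
    if fmt != stack.format:
        raise ValueError(
            f"output extension implies {fmt}, input format is {stack.format}")
    values = np.asarray(values)
    n_chan = values.shape[1] if values.ndim == 2 else 1
    vals = values.reshape(-1, n_chan).astype(float)
    if vals.shape[0] == int(stack.mask.sum()) and vals.shape[0] != stack.N:
        full = np.zeros((stack.N, n_chan))
        full[stack.mask] = vals
        vals = full
    elif vals.shape[0] != stack.N:
        raise ValueError("value length matches neither N nor the mask")
    vals = np.where(np.isfinite(vals), vals, 0.0)
    vals[~stack.mask] = 0.0

    if stack.format == "surface":
        if n_chan != 1:
            raise ValueError("surface outputs are single-channel")
        write_morph_data(str(path), vals[:, 0])
        return path
    vol = vals.reshape(stack.shape + (n_chan,))
    if n_chan == 1:
        vol = vol[..., 0]
    affine = stack.affine if stack.affine is not None else np.eye(4)
    img = (nib.Nifti1Image(vol.astype(np.float32), affine)
           if stack.format == "nifti"
           else nib.MGHImage(vol.astype(np.float32), affine))
    nib.save(img, str(path))
    return path


def iter_chunks(stack_or_data, chunk_size: int):
    """Contiguous blocks of in-mask observations, covering them once.

    Yields (index_array, L x block data).  The last block may be short.
    """
    if chunk_size < 1:
        raise ValueError("chunk size must be >= 1")
    if isinstance(stack_or_data, ObservationStack):
        data = stack_or_data.masked
    else:
        data = np.asarray(stack_or_data)
    n = data.shape[1]
    for start in range(0, n, chunk_size):
        idx = np.arange(start, min(start + chunk_size, n))
        yield idx, data[:, idx]


def mm_to_voxel(affine: np.ndarray, mm_coord) -> tuple[int, ...]:
    """Nearest voxel index for a world-space mm coordinate."""
    mm = np.asarray(mm_coord, dtype=float)
    ijk = np.linalg.inv(affine) @ np.append(mm, 1.0)
    return tuple(int(round(v)) for v in ijk[:3])


def _locate(stack: ObservationStack, coordinate) -> int:
    """Flat in-mask index for a mm coordinate (volumes) or vertex (surfaces)."""
    if stack.format == "surface":
        v = int(coordinate if np.isscalar(coordinate) else coordinate[0])
        if not 0 <= v < stack.N:
            raise IndexError(f"vertex {v} outside [0, {stack.N})")
        flat = v
    else:
        ijk = mm_to_voxel(stack.affine if stack.affine is not None
                          else np.eye(4), coordinate)
        if not all(0 <= c < s for c, s in zip(ijk, stack.shape)):
            raise IndexError(f"voxel {ijk} outside volume {stack.shape}")
        flat = int(np.ravel_multi_index(ijk, stack.shape))
    if not stack.mask[flat]:
        in_mask = np.flatnonzero(stack.mask)
        nearest = in_mask[np.argmin(np.abs(in_mask - flat))]
        raise IndexError(
            f"location {coordinate} is outside the analysis mask; "
            f"nearest in-mask flat index is {nearest}")
    # convert to position within the masked matrix
    return int(stack.mask[:flat].sum())


def show_curves(models: dict, stack: ObservationStack, coordinate,
                out_path: str | Path, T: int = 100,
                plot: bool = True) -> Path:
    """Export fitted curve(s) and corrected observations at one location.

    ``models`` maps model names to FittedModel objects fitted on the
    masked stack.  Writes a CSV (grid + one curve column per model +
    the corrected observations of the first model against the training
    predictor) and, optionally, a PNG alongside.
    """
    import pandas as pd

    from .fitters import eval_curves

    idx = _locate(stack, coordinate)
    out_path = Path(out_path)
    frames = {}
    grid = None
    for name, model in models.items():
        cs = eval_curves(model, T=T)
        grid = cs.grid
        frames[name] = cs.curves[idx]
    df = pd.DataFrame({"grid": grid, **frames})
    df.to_csv(out_path, index=False)

    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        first = next(iter(models.values()))
        ax.scatter(first.XP[:, 0], first.corrected_observations[:, idx],
                   s=10, alpha=0.5, label="corrected data")
        for name in frames:
            ax.plot(grid, frames[name], label=name)
        ax.set_xlabel("predictor")
        ax.set_ylabel("corrected observation")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_path.with_suffix(".png"), dpi=100)
        plt.close(fig)
    return out_path


def export_data_distribution(covariates, observations: np.ndarray | None,
                             out_dir: str | Path) -> list[Path]:
    """Static data-distribution figures: univariate densities/histograms
    per covariate, pairwise scatter, and an observation boxplot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    V, names = covariates.values, covariates.names
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3))
    axes = np.atleast_1d(axes)
    for ax, j in zip(axes, range(V.shape[1])):
        ax.hist(V[:, j], bins=20)
        ax.set_title(names[j])
    fig.tight_layout()
    p = out_dir / "covariate_distributions.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    if V.shape[1] >= 2:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(V[:, 0], V[:, 1], s=10)
        ax.set_xlabel(names[0])
        ax.set_ylabel(names[1])
        fig.tight_layout()
        p = out_dir / "covariate_bivariate.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

    if observations is not None and observations.size:
        obs = np.asarray(observations)
        sample = obs[:, : min(20, obs.shape[1])]
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.boxplot(sample, showfliers=False)
        ax.set_xlabel("observation (first voxels)")
        fig.tight_layout()
        p = out_dir / "observation_boxplots.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
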