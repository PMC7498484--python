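"""Config-driven stage runner: fit, infer, compare, cluster, exports.

The analysis pipeline is split into stages sharing one YAML config.
Each stage writes its artifacts under the configured output directory
together with a manifest (parameters, seed, version); later stages
check their prerequisites' manifests and fail with an actionable
message when a stage has not been run.  Re-running a stage overwrites
only its own artifacts.

Minimal config::

    output_dir: out
    seed: 0
    observations:
      files: ["subj_*.nii.gz"]     # globs allowed, sorted
      sigma_min: 0.0
    covariates:
      file: covariates.csv
      preprocess: none             # normalize|orthogonalize|orthonormalize
    contrast: [[0], [0], [1]]      # M x P, selects the predictor subspace
    fitters:
      corrector: {family: glm, degrees: 1}
      predictor: {family: glm, degrees: 2}
    inference: {metrics: [ftest], gamma: 1.0}
    chunk_size: 512
"""

from __future__ import annotations

import glob as _glob
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import CovariateTable, build_contrast, preprocess_covariates, \
    split_design
from .fitters import (GAMSpec, GLMSpec, SVRSpec, SmootherSpec, FittedModel,
                      GLMStage, GAMStage, SVRStage, InterceptStage,
                      fit_two_stage_chunked, eval_curves)
from .imaging import (ObservationStack, load_observations, write_map,
                      show_curves, export_data_distribution)
from .inference import make_stat_map, cluster_extent_filter
from .posthoc import combine_maps, cluster_curves
from .synthetic import PhantomSpec, Region, default_phantom_spec, \
    generate_phantom

__all__ = ["load_config", "run_stage", "StageError",
           "save_model", "load_model", "fitter_spec_from_config"]

STAGES = ("generate-phantom", "fit", "infer", "compare", "cluster",
          "show-curves", "show-data-distribution")


class StageError(RuntimeError):
    """A stage cannot run (bad config or missing prerequisite)."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "output_dir" not in cfg:
        raise StageError("config must be a mapping with an output_dir")
    return cfg


def fitter_spec_from_config(d: dict | None):
    """Build a fitter spec from its config mapping (None = intercept only)."""
    if d is None:
        return None
    family = d.get("family", "glm")
    if family == "glm":
        deg = d.get("degrees", 1)
        return GLMSpec(degrees=tuple(deg) if isinstance(deg, list) else deg)
    if family == "gam":
        sm = d.get("smoothers", [{"kind": "linear"}])
        specs = tuple(
            SmootherSpec(kind=s.get("kind", "linear"),
                         df=int(s.get("df", s.get("degree",
                                1 if s.get("kind", "linear") == "linear"
                                else 3))))
            for s in sm)
        return GAMSpec(smoothers=specs,
                       max_iter=int(d.get("max_iter", 500)),
                       tol=float(d.get("tol", 1e-6)))
    if family == "svr":
        return SVRSpec(kernel=d.get("kernel", "rbf"),
                       epsilon=float(d.get("epsilon", 0.1)),
                       C=float(d.get("C", 1.0)),
                       gamma=float(d.get("gamma", 1.0)),
                       degree=int(d.get("degree", 3)))
    raise StageError(f"unknown fitter family {family!r}")


# ---------------------------------------------------------------------------
# Model store (artifact-internal layout: npz arrays + JSON sidecar)
# ---------------------------------------------------------------------------

def _stage_arrays(stage, prefix: str) -> dict:
    if isinstance(stage, InterceptStage):
        return {f"{prefix}mean": stage.mean}
    if isinstance(stage, GLMStage):
        return {f"{prefix}coefs": stage.coefs}
    if isinstance(stage, GAMStage):
        out = {f"{prefix}alpha": stage.alpha,
               f"{prefix}converged": stage.converged}
        for j, (c, o) in enumerate(zip(stage.coefs, stage.offsets)):
            out[f"{prefix}coefs{j}"] = c
            out[f"{prefix}offsets{j}"] = o
        return out
    if isinstance(stage, SVRStage):
        return {f"{prefix}betas": stage.betas, f"{prefix}bias": stage.bias,
                f"{prefix}df": np.atleast_1d(stage.df)}
    raise TypeError(type(stage))


def _stage_meta(stage) -> dict:
    if isinstance(stage, InterceptStage):
        return {"family": "intercept"}
    if isinstance(stage, GLMStage):
        return {"family": "glm", "degrees": list(stage.degrees),
                "include_intercept": stage.include_intercept}
    if isinstance(stage, GAMStage):
        return {"family": "gam",
                "smoothers": [asdict(s.spec) for s in stage.smoothers],
                "max_iter": stage.spec.max_iter, "tol": stage.spec.tol}
    if isinstance(stage, SVRStage):
        d = asdict(stage.spec)
        d.pop("family", None)
        return {"family": "svr", **d}
    raise TypeError(type(stage))


def _rebuild_stage(meta: dict, arrays: dict, prefix: str, X: np.ndarray):
    fam = meta["family"]
    if fam == "intercept":
        st = InterceptStage.__new__(InterceptStage)
        st.mean = arrays[f"{prefix}mean"]
        st.df = 0.0
        st.fitted = np.tile(st.mean, (X.shape[0] if X.size else 1, 1))
        return st
    if fam == "glm":
        st = GLMStage.__new__(GLMStage)
        st.spec = GLMSpec(degrees=tuple(meta["degrees"]))
        st.degrees = tuple(meta["degrees"])
        st.include_intercept = bool(meta["include_intercept"])
        st.coefs = arrays[f"{prefix}coefs"]
        st.df = float(sum(st.degrees))
        st.fitted = st.predict(X)
        return st
    if fam == "gam":
        from .fitters import _Smoother

        st = GAMStage.__new__(GAMStage)
        specs = tuple(SmootherSpec(**s) for s in meta["smoothers"])
        st.spec = GAMSpec(smoothers=specs, max_iter=meta["max_iter"],
                          tol=meta["tol"])
        st.smoothers = [_Smoother(X[:, j], s) for j, s in enumerate(specs)]
        st.df = float(sum(s.df for s in st.smoothers))
        st.alpha = arrays[f"{prefix}alpha"]
        st.converged = arrays[f"{prefix}converged"]
        st.coefs = [arrays[f"{prefix}coefs{j}"] for j in range(len(specs))]
        st.offsets = [arrays[f"{prefix}offsets{j}"]
                      for j in range(len(specs))]
        st.fitted = st.predict(X)
        return st
    if fam == "svr":
        st = SVRStage.__new__(SVRStage)
        st.spec = SVRSpec(**{k: v for k, v in meta.items() if k != "family"})
        st.X_train = X
        st.betas = arrays[f"{prefix}betas"]
        st.bias = arrays[f"{prefix}bias"]
        st.df = arrays[f"{prefix}df"]
        st.fitted = st.predict(X)
        return st
    raise StageError(f"unknown stage family {fam!r}")


def save_model(model: FittedModel, path: str | Path) -> Path:
    """Persist a fitted two-stage model as <path>.npz + <path>.json."""
    path = Path(path)
    arrays = {"XC": model.XC, "XP": model.XP,
              "corrected": model.corrected_observations}
    arrays.update(_stage_arrays(model.corrector, "c_"))
    arrays.update(_stage_arrays(model.predictor, "p_"))
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"corrector": _stage_meta(model.corrector),
            "predictor": _stage_meta(model.predictor),
            "predictor_range": list(model.predictor_range),
            "version": __version__}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> FittedModel:
    path = Path(path)
    arrays = dict(np.load(path.with_suffix(".npz")))
    meta = json.loads(path.with_suffix(".json").read_text())
    XC, XP = arrays["XC"], arrays["XP"]
    corrector = _rebuild_stage(meta["corrector"], arrays, "c_", XC)
    predictor = _rebuild_stage(meta["predictor"], arrays, "p_", XP)
    model = FittedModel(corrector=corrector, predictor=predictor, XC=XC,
                        XP=XP,
                        predictor_range=tuple(meta["predictor_range"]))
    model._corrected = arrays["corrected"]
    return model


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _outdir(cfg: dict) -> Path:
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(cfg: dict, stage: str, payload: dict) -> None:
    out = _outdir(cfg)
    payload = {"stage": stage, "seed": cfg.get("seed", 0),
               "version": __version__, **payload}
    (out / f"{stage}_manifest.json").write_text(
        json.dumps(payload, indent=2, default=str))
    (out / "effective_config.yaml").write_text(
        yaml.safe_dump(cfg, sort_keys=False))


def _require_manifest(cfg: dict, stage: str) -> dict:
    p = _outdir(cfg) / f"{stage}_manifest.json"
    if not p.exists():
        raise StageError(
            f"stage '{stage}' has not been run for this output dir; "
            f"run it first")
    return json.loads(p.read_text())


def _expand_files(patterns) -> list[str]:
    files: list[str] = []
    for pat in patterns:
        hits = sorted(_glob.glob(str(pat)))
        files.extend(hits if hits else [str(pat)])
    return files


def _load_inputs(cfg: dict):
    obs_cfg = cfg.setdefault("observations", {})
    files = _expand_files(obs_cfg.get("files", []))
    cov_cfg = cfg.setdefault("covariates", {})
    phantom_dir = _outdir(cfg) / "phantom"
    if not files and phantom_dir.exists():
        files = sorted(str(p) for p in phantom_dir.glob("subject_*"))
        obs_cfg["files"] = files
        cov_cfg.setdefault("file", str(phantom_dir / "covariates.csv"))
    if not files:
        raise StageError("config lists no observation files (and no phantom "
                         "has been generated); run generate-phantom or set "
                         "observations.files")
    table = CovariateTable.from_file(cov_cfg["file"],
                                     id_column=cov_cfg.get("id_column"))
    stack = load_observations(files, mask=obs_cfg.get("mask"),
                              sigma_min=float(obs_cfg.get("sigma_min", 0.0)),
                              n_subjects=table.L)
    mode = cov_cfg.get("preprocess", "none")
    if mode and mode != "none":
        table = preprocess_covariates(table, mode,
                                      demean=bool(cov_cfg.get("demean",
                                                              False)))
    contrast = np.asarray(cfg["contrast"], dtype=float)
    if contrast.ndim == 1:
        contrast = contrast[:, None]
    split = split_design(table, build_contrast(contrast))
    return stack, table, split


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_generate_phantom(cfg: dict, overrides: dict) -> dict:
    out = _outdir(cfg) / "phantom"
    out.mkdir(exist_ok=True)
    ph_cfg = {**cfg.get("phantom", {}), **overrides}
    seed = int(ph_cfg.pop("seed", cfg.get("seed", 0)))
    ext = ph_cfg.pop("extension", ".nii.gz")
    spec_kwargs = {}
    for key in ("L", "noise_sigma", "age_slope", "age_quadratic",
                "sex_offset"):
        if key in ph_cfg:
            spec_kwargs[key] = ph_cfg[key]
    if "shape" in ph_cfg:
        spec_kwargs["shape"] = tuple(ph_cfg["shape"])
    if "regions" in ph_cfg:
        spec_kwargs["regions"] = tuple(
            Region(tuple(r["voxels"]), r["family"], float(r["effect"]))
            for r in ph_cfg["regions"])
    spec = default_phantom_spec(seed=seed, **spec_kwargs)
    phantom = generate_phantom(spec)

    import nibabel as nib

    vols = phantom.volumes()
    files = []
    for s in range(spec.L):
        p = out / f"subject_{s:03d}{ext}"
        img_cls = nib.MGHImage if ext in {".mgh", ".mgz"} else nib.Nifti1Image
        nib.save(img_cls(vols[..., s].astype(np.float32), phantom.affine),
                 str(p))
        files.append(str(p))
    cov_path = out / "covariates.csv"
    phantom.covariates_frame().to_csv(cov_path, index=False)
    truth = {"regions": [{"family": r.family, "effect": r.effect,
                          "n_voxels": len(r.voxels)}
                         for r in spec.regions],
             "noise_sigma": spec.noise_sigma, "L": spec.L,
             "shape": list(spec.shape)}
    (out / "phantom_manifest.json").write_text(json.dumps(truth, indent=2))
    cfg.setdefault("observations", {})["files"] = files
    cfg.setdefault("covariates", {})["file"] = str(cov_path)
    _write_manifest(cfg, "generate-phantom",
                    {"n_files": len(files), "covariates": str(cov_path)})
    return {"files": files, "covariates": str(cov_path)}


def _stage_fit(cfg: dict, overrides: dict) -> dict:
    stack, table, split = _load_inputs(cfg)
    fit_cfg = {**cfg.get("fitters", {}), **overrides}
    cspec = fitter_spec_from_config(fit_cfg.get("corrector"))
    pspec = fitter_spec_from_config(fit_cfg.get("predictor",
                                                {"family": "glm"}))
    chunk = cfg.get("chunk_size")
    model = fit_two_stage_chunked(stack.masked, split, cspec, pspec,
                                  chunk_size=int(chunk) if chunk else None)
    out = _outdir(cfg)
    store = save_model(model, out / "model_store")
    _write_manifest(cfg, "fit", {
        "model_store": str(store),
        "n_observations": int(stack.mask.sum()),
        "corrector": fit_cfg.get("corrector"),
        "predictor": fit_cfg.get("predictor", {"family": "glm"}),
    })
    return {"model_store": str(store)}


def _reload(cfg: dict):
    _require_manifest(cfg, "fit")
    stack, table, split = _load_inputs(cfg)
    model = load_model(_outdir(cfg) / "model_store")
    return stack, model


def _map_path(cfg: dict, name: str) -> Path:
    ext = ".nii.gz"
    files = cfg.get("observations", {}).get("files", [])
    if files:
        first = _expand_files(files)[0].lower()
        for cand in (".nii.gz", ".nii", ".mgz", ".mgh", ".thickness",
                     ".area"):
            if first.endswith(cand):
                ext = cand
                break
    return _outdir(cfg) / f"{name}_map{ext}"


def _stage_infer(cfg: dict, overrides: dict) -> dict:
    stack, model = _reload(cfg)
    inf_cfg = {**cfg.get("inference", {}), **overrides}
    metrics = inf_cfg.get("metrics", [inf_cfg.get("metric", "ftest")])
    written = {}
    for metric in metrics:
        smap = make_stat_map(model, stack.masked, metric,
                             gamma_penalty=float(inf_cfg.get("gamma", 1.0)),
                             curve_points=int(inf_cfg.get("curve_points",
                                                          100)))
        p = _map_path(cfg, metric)
        write_map(smap.values, stack, p)
        written[metric] = str(p)
        if smap.p_values is not None:
            pv = _map_path(cfg, f"{metric}_pvalue")
            write_map(np.where(np.isfinite(smap.p_values), smap.p_values,
                               1.0), stack, pv)
            sig = _map_path(cfg, f"{metric}_significance")
            write_map(np.where(np.isfinite(smap.p_values),
                               1.0 - smap.p_values, 0.0), stack, sig)
            written[f"{metric}_pvalue"] = str(pv)
            written[f"{metric}_significance"] = str(sig)
    _write_manifest(cfg, "infer", {"maps": written})
    return {"maps": written}


def _stage_compare(cfg: dict, overrides: dict) -> dict:
    manifest = _require_manifest(cfg, "infer")
    stack, model = _reload(cfg)
    cmp_cfg = {**cfg.get("compare", {}), **overrides}
    kind = cmp_cfg.get("kind", "diff")
    sources = cmp_cfg.get("maps")
    if not sources:
        raise StageError("compare needs a 'maps' list (map file paths or "
                         "metric names from the infer stage)")
    from .inference import StatMap
    import nibabel as nib

    maps = []
    for src in sources:
        path = manifest["maps"].get(src, src)
        arr = np.asarray(nib.load(path).get_fdata()).ravel()[stack.mask]
        maps.append(StatMap(values=arr, name=str(src)))
    comp = combine_maps(maps, kind, polarity=cmp_cfg.get("polarity"))
    p = _map_path(cfg, f"compare_{kind}")
    write_map(comp.values, stack, p)
    _write_manifest(cfg, "compare", {"kind": kind, "output": str(p)})
    return {"output": str(p)}


def _stage_cluster(cfg: dict, overrides: dict) -> dict:
    manifest = _require_manifest(cfg, "infer")
    stack, model = _reload(cfg)
    cl_cfg = {**cfg.get("cluster", {}), **overrides}
    n_clusters = int(cl_cfg.get("n_clusters", 2))
    threshold = float(cl_cfg.get("p_threshold", 0.001))
    metric = cl_cfg.get("map", "ftest")
    pv_path = manifest["maps"].get(f"{metric}_pvalue")
    if pv_path is None:
        raise StageError(f"infer stage produced no p-values for {metric!r}; "
                         "run infer with the ftest metric first")
    import nibabel as nib

    p_full = np.asarray(nib.load(pv_path).get_fdata()).ravel()
    surviving = stack.mask & (p_full < threshold)
    extent = int(cl_cfg.get("cluster_extent", 0))
    if extent > 1 and stack.format != "surface":
        keep = cluster_extent_filter(p_full[stack.mask], stack.shape,
                                     mask=stack.mask, threshold=threshold,
                                     extent=extent)
        surviving &= keep
    idx_in_mask = np.flatnonzero(surviving[stack.mask])
    if idx_in_mask.size < n_clusters:
        raise StageError(
            f"only {idx_in_mask.size} observations survive p < {threshold}; "
            "cannot form the requested clusters")
    curves = eval_curves(model, T=int(cl_cfg.get("curve_points", 100)),
                         observation_ids=idx_in_mask)
    result = cluster_curves(curves, n_clusters,
                            standardize=bool(cl_cfg.get("standardize", True)))
    labels_full = np.zeros(stack.N)
    labels_full[np.flatnonzero(surviving)] = result.labels + 1.0
    p = _map_path(cfg, "cluster_labels")
    write_map(labels_full, stack, p)

    import pandas as pd

    cent = pd.DataFrame(result.centroids.T,
                        columns=[f"cluster_{k}" for k in
                                 range(n_clusters)])
    cent.insert(0, "grid", curves.grid)
    cpath = _outdir(cfg) / "cluster_centroids.csv"
    cent.to_csv(cpath, index=False)
    diag = {"silhouette_mean": result.silhouette_mean,
            "within_var": result.within_var,
            "between_var": result.between_var,
            "n_curves": int(idx_in_mask.size)}
    (_outdir(cfg) / "cluster_diagnostics.json").write_text(
        json.dumps(diag, indent=2))
    _write_manifest(cfg, "cluster", {"labels": str(p),
                                     "centroids": str(cpath), **diag})
    return {"labels": str(p), "centroids": str(cpath), **diag}


def _stage_show_curves(cfg: dict, overrides: dict) -> dict:
    stack, model = _reload(cfg)
    sc_cfg = {**cfg.get("show_curves", {}), **overrides}
    coordinate = sc_cfg.get("coordinate")
    if coordinate is None:
        raise StageError("show-curves needs a 'coordinate' (mm x,y,z for "
                         "volumes, vertex index for surfaces)")
    out = _outdir(cfg) / "curves.csv"
    show_curves({"model": model}, stack, coordinate, out,
                T=int(sc_cfg.get("curve_points", 100)))
    _write_manifest(cfg, "show-curves", {"output": str(out)})
    return {"output": str(out)}


def _stage_show_data_distribution(cfg: dict, overrides: dict) -> dict:
    stack, table, split = _load_inputs(cfg)
    out = _outdir(cfg) / "data_distribution"
    written = export_data_distribution(table, stack.masked, out)
    _write_manifest(cfg, "show-data-distribution",
                    {"figures": [str(p) for p in written]})
    return {"figures": [str(p) for p in written]}


_STAGE_FUNCS = {
    "generate-phantom": _stage_generate_phantom,
    "fit": _stage_fit,
    "infer": _stage_infer,
    "compare": _stage_compare,
    "cluster": _stage_cluster,
    "show-curves": _stage_show_curves,
    "show-data-distribution": _stage_show_data_distribution,
}


def run_stage(stage: str, cfg: dict, overrides: dict | None = None) -> dict:
    """Run one pipeline stage; returns a dict of produced artifacts."""
    if stage not in _STAGE_FUNCS:
        raise StageError(f"unknown stage {stage!r}; choose from {STAGES}")
    return _STAGE_FUNCS[stage](cfg, overrides or {})
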