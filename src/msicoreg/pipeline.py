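"""End-to-end orchestration: read → prepare → select → embed → register →
evaluate → export.

Each stage writes its outputs into the run directory as it finishes, so a
failed run leaves a partial-results manifest naming the stage that broke,
and a finished run carries enough provenance (parameters, seeds, package
versions) to re-run any stage.  All randomness flows from one top-level
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import traceback
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .errors import MsicoregError
from .embed import he_representative, tsne_embed_1d
from .features import SSCParams, auto_shrinkage, preprocess_spectra, select_features, ssc_segment
from .imageprep import GeometryConfig, make_tissue_mask, match_geometry, remove_background
from .metrics import evaluate
from .msi_io import (MSIDataset, RasterImage, read_imzml, read_mask, read_optical,
                     write_mask, write_representative_tiff)
from .register import RegistrationConfig, apply_transform, register_images, to_displacement_field

log = logging.getLogger(__name__)


class StageError(MsicoregError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    msi_path: str = ""
    he_path: str = ""
    msi_mask_path: str | None = None
    he_mask_path: str | None = None
    out_dir: str = "msicoreg_out"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    ssc: SSCParams = field(default_factory=lambda: SSCParams(k=5, r=2.0, s=1.0))
    ssc_auto_shrinkage: bool = True
    preprocess: dict = field(default_factory=lambda: {
        "normalize": "tic", "smooth_window": 0, "peak_snr": 0.0, "bin_tol": 0.0})
    perplexity: float = 30.0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    mask_method: str = "otsu"
    mask_threshold: float | None = None
    seed: int = 42
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(os.fspath(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "geometry":
                cfg.geometry = GeometryConfig(**val)
            elif key == "ssc":
                cfg.ssc = SSCParams(**val)
            elif key == "registration":
                cfg.registration = RegistrationConfig(**val)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise MsicoregError(f"unknown config key {key!r}")
        return cfg


def _provenance(cfg: PipelineConfig) -> dict:
    import scipy
    import skimage
    import sklearn

    return {
        "msicoreg": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "seed": cfg.seed,
        "config": _cfg_dict(cfg),
    }


def _cfg_dict(cfg) -> dict:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o

    return enc(cfg)


def run_pipeline(cfg: PipelineConfig,
                 msi: MSIDataset | None = None,
                 he: RasterImage | None = None) -> str:
    """Run the full coregistration workflow; returns the output directory.

    ``msi`` / ``he`` may be passed in-memory (the phantom path); otherwise
    they are read from the configured paths.  Any stage failure raises
    :class:`StageError` naming the stage, after writing a partial-results
    manifest.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = os.fspath(cfg.out_dir)
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"stages_completed": [], "version": __version__}

    def commit(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    def fail(stage: str, exc: Exception) -> "StageError":
        manifest["failed_stage"] = stage
        manifest["error"] = "".join(traceback.format_exception_only(exc)).strip()
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        return StageError(stage, exc)

    # -- read ---------------------------------------------------------------
    try:
        if msi is None:
            msi = read_imzml(cfg.msi_path)
        if he is None:
            he = read_optical(cfg.he_path)
        he_mask_native = read_mask(cfg.he_mask_path) if cfg.he_mask_path else None
    except Exception as exc:
        raise fail("read", exc) from exc
    commit("read")

    # -- preprocess spectra -------------------------------------------------
    try:
        pp = cfg.preprocess
        if pp.get("normalize", "none") != "none" or pp.get("peak_snr", 0) > 0 \
                or pp.get("smooth_window", 0) > 1:
            msi_pp = preprocess_spectra(
                msi, normalize=pp.get("normalize", "tic"),
                smooth_window=int(pp.get("smooth_window", 0)),
                peak_snr=float(pp.get("peak_snr", 0.0)),
                bin_tol=float(pp.get("bin_tol", 0.0)))
        else:
            msi_pp = msi
    except Exception as exc:
        raise fail("preprocess", exc) from exc
    commit("preprocess")

    # -- SSC feature selection ----------------------------------------------
    try:
        ssc_params = cfg.ssc
        if cfg.ssc_auto_shrinkage:
            s = auto_shrinkage(msi_pp, ssc_params)
            ssc_params = SSCParams(k=ssc_params.k, r=ssc_params.r, s=s,
                                   max_iter=ssc_params.max_iter, seed=cfg.seed)
        res = ssc_segment(msi_pp, ssc_params)
        selected = select_features(res)
        res.save(os.path.join(out, "ssc"), mz_axis=msi_pp.mz_axis, coords=msi_pp.coords)
    except Exception as exc:
        raise fail("ssc", exc) from exc
    commit("ssc")

    # -- embed --------------------------------------------------------------
    try:
        n_tissue = msi_pp.n_pixels
        perp = min(cfg.perplexity, max((n_tissue - 1) / 3.0 - 1e-9, 2.0))
        msi_rep_native = tsne_embed_1d(msi_pp, selected, perplexity=perp, seed=cfg.seed)
        msi_rep_native.save(os.path.join(out, "msi_representative_native.tiff"))
    except Exception as exc:
        raise fail("embed", exc) from exc
    commit("embed")

    # -- geometry matching --------------------------------------------------
    try:
        from .embed import RepresentativeImage
        from .msi_io import TissueMask

        msi_img = RasterImage(msi_rep_native.pixels)
        msi_big, he_big = match_geometry(msi_img, he, cfg.geometry)
        if he_mask_native is not None and he_mask_native.shape != he_big.shape:
            mask_img = RasterImage(he_mask_native.pixels.astype(np.float64))
            _, mask_big = match_geometry(msi_img, mask_img, cfg.geometry)
            he_mask = TissueMask((mask_big.gray() > 0.5).astype(np.uint8))
        elif he_mask_native is not None:
            he_mask = he_mask_native
        else:
            he_mask = make_tissue_mask(he_big, cfg.mask_method, threshold=cfg.mask_threshold)
        sup_big = TissueMask((msi_big.gray() > 0).astype(np.uint8))
        fixed_rep = he_representative(remove_background(he_big, he_mask), he_mask)
        moving_rep = RepresentativeImage(
            np.where(sup_big.pixels, msi_big.gray(), 0.0), sup_big,
            dict(msi_rep_native.provenance, spatial_scaling=cfg.geometry.spatial_scaling))
        write_mask(he_mask, os.path.join(out, "he_mask.png"))
        write_mask(sup_big, os.path.join(out, "msi_mask.png"))
        write_representative_tiff(fixed_rep.pixels, os.path.join(out, "he_representative.tiff"))
        write_representative_tiff(moving_rep.pixels, os.path.join(out, "msi_representative.tiff"))
    except Exception as exc:
        raise fail("geometry", exc) from exc
    commit("geometry")

    # -- register -----------------------------------------------------------
    try:
        reg_cfg = dataclasses.replace(cfg.registration, seed=cfg.seed)
        model = register_images(fixed_rep, moving_rep, reg_cfg)
        _save_transform(model, os.path.join(out, "transform.json"))
        warped = apply_transform(moving_rep, model, reg_cfg.interpolator)
        write_representative_tiff(warped.pixels, os.path.join(out, "msi_warped.tiff"))
        _save_overlays(fixed_rep, moving_rep, warped, out)
    except Exception as exc:
        raise fail("register", exc) from exc
    commit("register")

    # -- evaluate -----------------------------------------------------------
    try:
        report = evaluate(he_mask, sup_big, fixed_rep, moving_rep, model)
        report.save(os.path.join(out, "metrics.json"))
        import tifffile

        from .metrics import jacobian_determinant

        jac = jacobian_determinant(to_displacement_field(model))
        tifffile.imwrite(os.path.join(out, "jacobian.tiff"), jac.astype(np.float32))
    except Exception as exc:
        raise fail("evaluate", exc) from exc
    commit("evaluate")

    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(_provenance(cfg), fh, indent=2, default=str)
    commit("export")
    return out


def _normalize_only(msi: MSIDataset, pp: dict) -> MSIDataset:
    return preprocess_spectra(msi, normalize=pp.get("normalize", "tic"),
                              smooth_window=int(pp.get("smooth_window", 0)),
                              peak_snr=0.0, bin_tol=float(pp.get("bin_tol", 0.0)))


def _save_transform(model, path: str) -> None:
    data = {
        "kind": model.kind,
        "fixed_domain": list(model.fixed_domain),
        "matrix": model.matrix.tolist(),
        "translation": model.translation.tolist(),
    }
    if model.kind == "bspline":
        data["spacing"] = model.spacing
        data["coefficients_file"] = os.path.basename(path) + ".coefs.npy.txt"
        coefs = model.coefficients
        np.savetxt(path + ".coefs.npy.txt",
                   coefs.reshape(-1, 2), header=f"grid {coefs.shape[0]} {coefs.shape[1]}")
    if model.kind == "rigid":
        data["angle"] = model.angle
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def _save_overlays(fixed_rep, moving_rep, warped, out: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, mv in (("overlay_before.png", moving_rep), ("overlay_after.png", warped)):
        h, w = fixed_rep.shape
        rgb = np.zeros((h, w, 3))
        rgb[..., 0] = fixed_rep.pixels     # fixed in red
        rgb[..., 1] = mv.pixels            # moving in green
        fig, ax = plt.subplots(figsize=(5, 5 * h / max(w, 1)))
        ax.imshow(rgb)
        ax.set_axis_off()
        fig.savefig(os.path.join(out, name), dpi=120, bbox_inches="tight")
        plt.close(fig)
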