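"""Representative single-channel images for the two modalities.

Registration needs one image per modality.  The H&E side is simply the
inverted channel-mean (tissue bright) restricted to the tissue mask.  The
MSI side collapses the selected ion images into a single channel by running
t-SNE with one output component over the tissue pixels' selected-feature
vectors; the embedding is rescaled to [0, 1] and rasterized back onto the
pixel grid.  A 1-D t-SNE axis has arbitrary sign, so polarity is fixed by
requiring positive rank-correlation with total ion current — mutual
information would not care, but visual overlays and intensity correlations
do.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateInputError
from .msi_io import MSIDataset, RasterImage, TissueMask

__all__ = ["RepresentativeImage", "tsne_embed_1d", "he_representative"]


@dataclass
class RepresentativeImage:
    """Single-channel [0, 1] summary image with its support mask and the
    parameters that produced it."""

    pixels: np.ndarray
    support: TissueMask
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ConfigError("representative image must be single-channel")
        if self.pixels.shape != self.support.shape:
            raise ConfigError("support mask shape must match the image")
        off = ~self.support.pixels
        if off.any() and np.abs(self.pixels[off]).max() > 0:
            raise ConfigError("off-support pixels must be exactly 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path: str | os.PathLike) -> None:
        """16-bit grayscale TIFF plus a JSON provenance sidecar."""
        from .msi_io import write_representative_tiff

        write_representative_tiff(self.pixels, path)
        with open(os.fspath(path) + ".json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _rescale01(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-300:
        return np.ones_like(v)  # degenerate: constant maps to 1 on support
    return (v - lo) / (hi - lo)


def tsne_embed_1d(data: MSIDataset, selected: np.ndarray, perplexity: float = 30.0,
                  seed: int = 42, mask: TissueMask | None = None,
                  grid_shape: tuple[int, int] | None = None) -> RepresentativeImage:
    """Collapse the selected ion images to one channel with 1-D t-SNE.

    Only tissue pixels (all dataset pixels, or those inside ``mask`` when
    given) enter the embedding; background pixels would otherwise dominate
    it.  Perplexity is capped at (n_pixels − 1) / 3.  Output is deterministic
    given the seed.
    """
    from sklearn.manifold import TSNE

    selected = np.asarray(selected, dtype=np.int64)
    if selected.size < 1:
        raise ConfigError("at least one selected feature is required")

    h, w = grid_shape if grid_shape is not None else data.grid_shape()
    if np.any(data.coords[:, 0] >= w) or np.any(data.coords[:, 1] >= h):
        raise ConfigError("grid_shape smaller than the coordinate extent")
    if mask is not None:
        if mask.shape != (h, w):
            raise ConfigError("mask shape does not match the MSI grid")
        keep = mask.pixels[data.coords[:, 1], data.coords[:, 0]]
    else:
        keep = np.ones(data.n_pixels, dtype=bool)
    idx = np.flatnonzero(keep)
    n = idx.size
    if n <= 3:
        raise ConfigError("too few tissue pixels for a t-SNE embedding")
    cap = (n - 1) / 3.0
    if perplexity > cap:
        raise ConfigError(
            f"perplexity {perplexity} too large for {n} pixels (max {cap:.1f})")

    # sort: the embedding must not depend on the order features were selected
    feats = data.intensities[np.sort(selected)][:, idx].T.astype(np.float64)
    sd = feats.std(axis=0)
    feats = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    tsne = TSNE(n_components=1, perplexity=perplexity, random_state=seed,
                init="pca", method="barnes_hut", max_iter=500)
    emb = tsne.fit_transform(feats).ravel()

    tic = data.tic()[idx]
    rho = stats.spearmanr(emb, tic).statistic if np.ptp(tic) > 0 else 0.0
    if np.isfinite(rho) and rho < 0:
        emb = -emb

    vals = _rescale01(emb)
    img = np.zeros((h, w), dtype=np.float64)
    img[data.coords[idx, 1], data.coords[idx, 0]] = vals
    sup = np.zeros((h, w), dtype=np.uint8)
    sup[data.coords[idx, 1], data.coords[idx, 0]] = 1
    prov = {
        "method": "tsne-1d",
        "selected_features": np.sort(selected).tolist(),
        "perplexity": float(perplexity),
        "seed": int(seed),
        "n_pixels": int(n),
    }
    return RepresentativeImage(img, TissueMask(sup), prov)


def he_representative(img: RasterImage, mask: TissueMask) -> RepresentativeImage:
    """H&E-side representative: 1 − mean(RGB) (tissue bright), masked and
    min-max rescaled to [0, 1] over the tissue pixels."""
    if mask.is_empty():
        raise DegenerateInputError("tissue mask is empty")
    if img.shape != mask.shape:
        raise ConfigError("image and mask shapes differ")
    gray = 1.0 - img.gray()
    vals = _rescale01(gray[mask.pixels])
    out = np.zeros(img.shape, dtype=np.float64)
    out[mask.pixels] = vals
    return RepresentativeImage(out, mask, {"method": "he-inverted-gray"})
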