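"""Tissue outlining and geometry harmonization of the two modalities.

MSI and H&E images of the same tissue rarely agree on aspect ratio, frame
position or resolution.  This module provides the preparation steps that run
before any registration: automatic tissue masking, background removal, and
the upscale/downscale strategy that brings both modalities onto one common
pixel grid.  The MSI-derived image is upscaled by an integer
``spatial_scaling`` factor (default 4, which is generally sufficient for
typical raster step sizes) while the high-resolution H&E image is downscaled
with antialiasing to the same grid; aspect-ratio mismatches are resolved by
symmetric zero-padding, never by anisotropic stretch, so tissue geometry is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, transform

from .errors import ConfigError, DegenerateInputError, DimensionError
from .msi_io import RasterImage, TissueMask

__all__ = [
    "GeometryConfig",
    "make_tissue_mask",
    "remove_background",
    "match_geometry",
    "pad_to_shape",
]


@dataclass
class GeometryConfig:
    """Geometry-harmonization settings.

    spatial_scaling : int
        Integer factor by which the MSI grid is upscaled (≥ 1, default 4).
    pad_mode : str
        Only ``"background_zero"`` is supported: padding adds zero-valued
        background pixels.
    target_dims : tuple or None
        Optional (H, W) to center-crop to after padding.
    """

    spatial_scaling: int = 4
    pad_mode: str = "background_zero"
    target_dims: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if int(self.spatial_scaling) != self.spatial_scaling or self.spatial_scaling < 1:
            raise ConfigError("spatial_scaling must be an integer >= 1")
        self.spatial_scaling = int(self.spatial_scaling)
        if self.pad_mode != "background_zero":
            raise ConfigError(f"unsupported pad_mode {self.pad_mode!r}")


def _intensity_channel(img: RasterImage) -> np.ndarray:
    """Tissue-bright scalar channel: 1 - mean(RGB) for color images (stains
    are dark on a light background), the raw channel for grayscale."""
    if img.n_channels == 3:
        return 1.0 - img.gray()
    return img.gray()


def make_tissue_mask(img: RasterImage, method: str = "otsu", *, threshold: float | None = None,
                     vertices: np.ndarray | None = None, tissue_bright: bool | None = None) -> TissueMask:
    """Outline the tissue in an optical or MSI-derived image.

    Parameters
    ----------
    img
        Single- or 3-channel image.  For 3-channel (H&E) input the intensity
        channel is ``1 − mean(RGB)`` so that tissue is bright.
    method
        ``"otsu"`` (automatic threshold), ``"threshold"`` (fixed value in
        [0, 1], pixels strictly above are tissue), or ``"polygon"``
        (vertices in (x, y) pixel coordinates).
    tissue_bright
        Override the channel polarity; by default 3-channel images are
        inverted and grayscale images are used as-is.

    The raw mask is cleaned up by 3×3 morphological closing, hole filling
    and keeping the largest connected component(s): components at least 50%
    the size of the largest are kept so multi-core layouts survive.
    """
    chan = _intensity_channel(img)
    if tissue_bright is False:
        chan = 1.0 - chan

    if method == "otsu":
        if np.ptp(chan) < 1e-12:
            raise DegenerateInputError("constant image: Otsu threshold is undefined")
        t = filters.threshold_otsu(chan)
        raw = chan > t
    elif method == "threshold":
        if threshold is None:
            raise ConfigError("method='threshold' requires a threshold value")
        raw = chan > threshold
    elif method == "polygon":
        if vertices is None:
            raise ConfigError("method='polygon' requires vertices")
        from skimage.draw import polygon2mask

        verts = np.asarray(vertices, dtype=np.float64)
        # polygon2mask expects (row, col); vertices arrive as (x, y)
        raw = polygon2mask(chan.shape, verts[:, ::-1])
    else:
        raise ConfigError(f"unknown mask method {method!r}")

    cleaned = _cleanup(raw)
    return TissueMask(cleaned.astype(np.uint8))


def _cleanup(raw: np.ndarray) -> np.ndarray:
    if not raw.any():
        return raw
    closed = ndimage.binary_closing(raw, structure=np.ones((3, 3)), border_value=0)
    closed |= raw  # closing with border_value=0 may clip the frame edge
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n <= 1:
        return filled
    sizes = ndimage.sum_labels(filled, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= 0.5 * sizes.max()) + 1
    return np.isin(labels, keep)


def remove_background(img: RasterImage, mask: TissueMask) -> RasterImage:
    """Zero out all pixels outside the tissue mask; tissue pixels unchanged."""
    if img.shape != mask.shape:
        raise DimensionError(f"image {img.shape} and mask {mask.shape} differ in shape")
    px = img.pixels.copy()
    if px.ndim == 3:
        px[~mask.pixels, :] = 0.0
    else:
        px[~mask.pixels] = 0.0
    return RasterImage(px, pixel_size_um=img.pixel_size_um)


def pad_to_shape(px: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetrically zero-pad a (H, W[, C]) array to ``shape``; returns the
    padded array and the (row, col) offset of the original content."""
    h, w = px.shape[:2]
    th, tw = shape
    if th < h or tw < w:
        raise DimensionError("target shape smaller than input; crop explicitly")
    top = (th - h) // 2
    left = (tw - w) // 2
    pad = [(top, th - h - top), (left, tw - w - left)] + [(0, 0)] * (px.ndim - 2)
    return np.pad(px, pad, mode="constant"), (top, left)


def _center_crop(px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = px.shape[:2]
    th, tw = min(shape[0], h), min(shape[1], w)
    top = (h - th) // 2
    left = (w - tw) // 2
    return px[top : top + th, left : left + tw]


def match_geometry(msi_img: RasterImage, he_img: RasterImage,
                   cfg: GeometryConfig | None = None) -> tuple[RasterImage, RasterImage]:
    """Bring the MSI-derived and H&E images onto a single pixel grid.

    The MSI image is upscaled by ``cfg.spatial_scaling`` with bilinear
    interpolation; the H&E image is downscaled with antialiasing to the same
    target.  The common grid is the element-wise maximum of the two shapes
    after MSI upscaling/H&E rescaling, so the smaller dimension of either
    image is symmetrically zero-padded rather than stretched.  When
    ``cfg.target_dims`` is set, padding happens first and a center crop to
    the target follows.
    """
    cfg = cfg or GeometryConfig()
    s = cfg.spatial_scaling

    msi_up_shape = (msi_img.shape[0] * s, msi_img.shape[1] * s)
    if s == 1:
        msi_up = msi_img.pixels
    else:
        msi_up = transform.resize(msi_img.pixels, msi_up_shape + msi_img.pixels.shape[2:],
                                  order=1, anti_aliasing=False, preserve_range=True)

    # Downscale H&E isotropically so it fits within the MSI frame, then pad.
    he_px = he_img.pixels
    scale = min(msi_up_shape[0] / he_px.shape[0], msi_up_shape[1] / he_px.shape[1])
    if scale < 1.0:
        he_shape = (max(1, round(he_px.shape[0] * scale)), max(1, round(he_px.shape[1] * scale)))
        he_px = transform.resize(he_px, he_shape + he_px.shape[2:], order=1,
                                 anti_aliasing=True, preserve_range=True)

    common = (max(msi_up_shape[0], he_px.shape[0]), max(msi_up_shape[1], he_px.shape[1]))
    msi_out, _ = pad_to_shape(msi_up, common)
    he_out, _ = pad_to_shape(he_px, common)
    if cfg.target_dims is not None:
        msi_out = _center_crop(msi_out, cfg.target_dims)
        he_out = _center_crop(he_out, cfg.target_dims)
    return (
        RasterImage(np.clip(msi_out, 0, 1), pixel_size_um=msi_img.pixel_size_um / s),
        RasterImage(np.clip(he_out, 0, 1), pixel_size_um=msi_img.pixel_size_um / s),
    )
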