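"""Core data model and I/O for MSI (imzML) and optical (TIFF/PNG) images.

The in-memory representation of an MSI experiment is a dense ``float32``
matrix of intensities over (mass feature, pixel).  Datasets in scope are
desk-scale after peak processing, so a dense cube is deliberate: it keeps
every downstream matrix operation a plain numpy expression.

Coordinates are stored 0-based as ``(x=column, y=row)`` with the origin at
the top-left pixel center.  imzML stores 1-based coordinates; the shift is
applied on read and undone on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

from .errors import DimensionError, FormatError

__all__ = [
    "MSIDataset",
    "RasterImage",
    "TissueMask",
    "read_imzml",
    "write_imzml",
    "read_optical",
    "read_mask",
    "write_mask",
]


@dataclass
class MSIDataset:
    """A peak-processed MSI cube.

    Parameters
    ----------
    coords
        ``(n_pixels, 2)`` int array of 0-based ``(x, y)`` pixel positions.
    mz_axis
        Strictly increasing vector of m/z values in Da, shared by all pixels.
    intensities
        ``(n_features, n_pixels)`` float32 matrix of non-negative abundances;
        column ``j`` is the spectrum at ``coords[j]``.
    pixel_size_um
        Isotropic raster step size in micrometres.
    mode
        ``"continuous"`` or ``"processed"`` — the imzML mode the data came
        from (processed-mode spectra are binned onto the common axis on read).
    """

    coords: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float = 1.0
    mode: str = "continuous"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.validate()

    def validate(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise FormatError("coords must be an (n_pixels, 2) array")
        if self.intensities.ndim != 2:
            raise FormatError("intensities must be a 2-D matrix")
        n_feat, n_pix = self.intensities.shape
        if n_pix != len(self.coords):
            raise DimensionError(
                f"intensities has {n_pix} columns but {len(self.coords)} coordinates"
            )
        if len(self.mz_axis) != n_feat:
            raise DimensionError(
                f"mz_axis has {len(self.mz_axis)} entries but intensities has "
                f"{n_feat} rows"
            )
        if n_feat and np.any(np.diff(self.mz_axis) <= 0):
            raise FormatError("mz_axis must be strictly increasing")
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise FormatError("pixel coordinates must be unique")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities must be finite")
        if self.intensities.size and self.intensities.min() < 0:
            raise FormatError("intensities must be non-negative")
        if self.mode not in ("continuous", "processed"):
            raise FormatError(f"unknown mode {self.mode!r}")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    def grid_shape(self) -> tuple[int, int]:
        """(H, W) of the minimal bounding grid that contains all pixels."""
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def ion_image(self, feature_index: int, fill: float = 0.0) -> np.ndarray:
        """Rasterize one mass feature onto the pixel grid."""
        h, w = self.grid_shape()
        img = np.full((h, w), fill, dtype=np.float32)
        img[self.coords[:, 1], self.coords[:, 0]] = self.intensities[feature_index]
        return img

    def tic(self) -> np.ndarray:
        """Total ion current per pixel."""
        return self.intensities.sum(axis=0)


@dataclass
class RasterImage:
    """A gridded optical image with values normalized into [0, 1].

    ``pixels`` is ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB; an alpha
    channel is never kept past ingest.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 3 and self.pixels.shape[2] == 1:
            self.pixels = self.pixels[:, :, 0]
        if self.pixels.ndim not in (2, 3):
            raise FormatError("image must be H×W or H×W×C")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise FormatError("multi-channel images must have exactly 3 channels")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("image must have at least one pixel")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("image values must be finite")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise FormatError("image values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def gray(self) -> np.ndarray:
        """Channel-mean grayscale view, shape (H, W)."""
        return self.pixels if self.pixels.ndim == 2 else self.pixels.mean(axis=2)


@dataclass
class TissueMask:
    """Binary tissue support on the same grid as the image it annotates."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise FormatError("mask must be a 2-D grid")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError("mask values must be 0 or 1")
        self.pixels = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()


# ---------------------------------------------------------------------------
# imzML


def read_imzml(path: str | os.PathLike) -> MSIDataset:
    """Read an imzML/.ibd pair into an :class:`MSIDataset`.

    Continuous-mode files share one m/z axis and load directly.  Processed-
    mode spectra carry per-pixel axes; they are binned onto a common axis at
    the median native bin width so the cube is a single matrix.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"imzML file not found: {path}")
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise IOError(f"binary file not found: {ibd}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # pragma: no cover - parser internals
        raise FormatError(f"cannot parse imzML file {path}: {exc}") from exc

    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=np.int64)
    n_pix = len(coords)
    spectra = [parser.getspectrum(i) for i in range(n_pix)]

    continuous = all(
        len(s[0]) == len(spectra[0][0]) and np.array_equal(s[0], spectra[0][0])
        for s in spectra
    )
    px_um = float((parser.imzmldict or {}).get("pixel size x", 1.0) or 1.0)

    if continuous:
        mz_axis = np.asarray(spectra[0][0], dtype=np.float64)
        inten = np.stack([np.asarray(s[1], dtype=np.float32) for s in spectra], axis=1)
        mode = "continuous"
    else:
        mz_axis, inten = _bin_processed(spectra)
        mode = "processed"

    inten = np.clip(inten, 0.0, None)
    return MSIDataset(coords, mz_axis, inten, pixel_size_um=px_um, mode=mode)


def _bin_processed(spectra) -> tuple[np.ndarray, np.ndarray]:
    """Resample per-pixel peak lists onto a common axis.

    Bin width is the median spacing of all native m/z values; peaks falling
    into the same bin are summed.
    """
    all_mz = np.concatenate([np.asarray(s[0], dtype=np.float64) for s in spectra])
    if all_mz.size == 0:
        raise FormatError("processed-mode file contains no peaks")
    uniq = np.unique(all_mz)
    if len(uniq) > 1:
        width = float(np.median(np.diff(uniq)))
    else:
        width = 1.0
    lo = uniq[0] - width / 2
    n_bins = int(np.floor((uniq[-1] - lo) / width)) + 1
    axis = lo + width * (np.arange(n_bins) + 0.5)

    inten = np.zeros((n_bins, len(spectra)), dtype=np.float32)
    for j, (mz, ab) in enumerate(spectra):
        mz = np.asarray(mz, dtype=np.float64)
        idx = np.clip(((mz - lo) / width).astype(np.int64), 0, n_bins - 1)
        np.add.at(inten[:, j], idx, np.asarray(ab, dtype=np.float32))
    occupied = inten.any(axis=1)
    return axis[occupied], inten[occupied]


def write_imzml(data: MSIDataset, path: str | os.PathLike) -> None:
    """Write an :class:`MSIDataset` as a continuous-mode imzML/.ibd pair."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    if data.n_pixels == 0:
        raise FormatError("refusing to write a dataset with no pixels")
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"output directory does not exist: {parent}")
    try:
        with ImzMLWriter(path, mode="continuous") as writer:
            for j in range(data.n_pixels):
                x, y = data.coords[j]
                writer.addSpectrum(
                    data.mz_axis, data.intensities[:, j], (int(x) + 1, int(y) + 1, 1)
                )
    except OSError as exc:
        raise IOError(f"cannot write imzML to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Optical images and masks


def read_optical(path: str | os.PathLike, pixel_size_um: float = 1.0) -> RasterImage:
    """Read a TIFF or PNG image, rescale to [0, 1] and drop any alpha channel."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif ext == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise FormatError(f"unsupported image format {ext!r} (expected TIFF or PNG)")

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, 0]
    src_dtype = arr.dtype
    arr = arr.astype(np.float64)
    # Rescale by the full range of the source bit depth
    if np.issubdtype(src_dtype, np.integer):
        arr = arr / float(np.iinfo(src_dtype).max)
    else:
        mx = arr.max()
        if mx > 1.0:
            arr = arr / mx
    return RasterImage(np.clip(arr, 0.0, 1.0), pixel_size_um=pixel_size_um)


def read_mask(path: str | os.PathLike) -> TissueMask:
    """Read a binary mask stored as a single-channel PNG (0/255)."""
    img = read_optical(path)
    return TissueMask((img.gray() > 0.5).astype(np.uint8))


def write_mask(mask: TissueMask, path: str | os.PathLike) -> None:
    Image.fromarray((mask.pixels.astype(np.uint8)) * 255).save(os.fspath(path))


def write_representative_tiff(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0,1] single-channel image as 16-bit grayscale TIFF."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0, 1)
    tifffile.imwrite(os.fspath(path), (arr * 65535).round().astype(np.uint16))
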