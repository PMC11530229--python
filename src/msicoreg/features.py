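"""Spectral preprocessing and spatially-aware feature selection.

Many mass features are noisy, low-abundant or confined to tiny subregions;
feeding all of them to a dimensionality reduction dilutes the morphological
signal.  This module implements spatial shrunken centroids (SSC):
a segmentation of the pixel grid by nearest shrunken centroid, where

* segment centroids are shrunk toward the global mean by soft-thresholding
  their standardized differences (t-statistics) at a level ``s`` — features
  whose t-statistics are all driven to zero contribute nothing to the
  segmentation and are declared uninformative;
* pixel-to-centroid discriminant scores are smoothed over a spatial
  neighborhood of radius ``r`` with Gaussian weights before assignment, so
  segments respect tissue contiguity.

The per-feature informativeness score is the largest soft-thresholded
|t-statistic| across segments; features with a nonzero score are the ones
the representative-image embedding is built from.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigError, DegenerateInputError
from .msi_io import MSIDataset

__all__ = [
    "SSCParams",
    "SSCResult",
    "preprocess_spectra",
    "ssc_segment",
    "select_features",
    "auto_shrinkage",
]

log = logging.getLogger(__name__)


@dataclass
class SSCParams:
    """Spatial shrunken centroids parameters.

    k : number of initial segments (>= 2).
    r : spatial smoothing radius in pixels (0 disables smoothing).
    s : shrinkage level applied to the standardized centroid differences.
    """

    k: int = 5
    r: float = 2.0
    s: float = 1.0
    max_iter: int = 30
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.r < 0 or self.s < 0:
            raise ConfigError("r and s must be non-negative")


@dataclass
class SSCResult:
    """Output of :func:`ssc_segment`.

    labels : (n_pixels,) segment assignment in {1..k_effective}.
    centroids : (k_eff, n_features) shrunken segment centroids.
    tstats : (k_eff, n_features) soft-thresholded t-statistics.
    feature_scores : per-feature max |tstat| over segments.
    selected : indices of features with score > 0, descending score order.
    """

    labels: np.ndarray
    centroids: np.ndarray
    tstats: np.ndarray
    feature_scores: np.ndarray
    selected: np.ndarray
    params: SSCParams | None = None

    @property
    def k_effective(self) -> int:
        return self.centroids.shape[0]

    def save(self, outdir: str | os.PathLike, mz_axis: np.ndarray | None = None,
             coords: np.ndarray | None = None) -> None:
        """Serialize as a directory: labels PNG plus centroid/t-stat CSVs."""
        import csv

        from PIL import Image

        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        if coords is not None:
            h = int(coords[:, 1].max()) + 1
            w = int(coords[:, 0].max()) + 1
            grid = np.zeros((h, w), dtype=np.uint8)
            grid[coords[:, 1], coords[:, 0]] = self.labels
            im = Image.fromarray(grid, mode="P")
            im.putpalette(_label_palette())
            im.save(os.path.join(outdir, "labels.png"))
        mz = mz_axis if mz_axis is not None else np.arange(self.centroids.shape[1])
        for name, mat in (("centroids", self.centroids), ("tstats", self.tstats)):
            with open(os.path.join(outdir, f"{name}.csv"), "w", newline="") as fh:
                wtr = csv.writer(fh)
                wtr.writerow(["mz"] + [f"segment_{i + 1}" for i in range(mat.shape[0])])
                for j in range(mat.shape[1]):
                    wtr.writerow([f"{mz[j]:.6f}"] + [f"{v:.8g}" for v in mat[:, j]])


def _label_palette() -> list[int]:
    base = [
        (0, 0, 0), (230, 25, 75), (60, 180, 75), (0, 130, 200), (245, 130, 48),
        (145, 30, 180), (70, 240, 240), (240, 50, 230), (210, 245, 60), (250, 190, 212),
    ]
    pal: list[int] = []
    for i in range(256):
        pal.extend(base[i % len(base)])
    return pal


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_spectra(data: MSIDataset, normalize: str = "tic", smooth_window: int = 0,
                       peak_snr: float = 3.0, bin_tol: float = 0.0) -> MSIDataset:
    """Standard spectral pre-step: TIC normalization, moving-average
    smoothing, local-maximum peak picking and peak binning.

    Peaks are picked on the mean spectrum: local maxima whose height above
    the baseline (median of the mean spectrum) exceeds ``peak_snr`` times
    the noise level (median absolute deviation, scaled to a Gaussian sigma).
    Peaks closer than ``bin_tol`` Da are merged, keeping the strongest.
    """
    inten = data.intensities.astype(np.float64)

    if normalize == "tic":
        tic = inten.sum(axis=0)
        nonzero = tic > 0
        if not nonzero.any():
            raise DegenerateInputError("all spectra are zero; cannot TIC-normalize")
        if (~nonzero).any():
            warnings.warn(f"{int((~nonzero).sum())} all-zero spectra excluded from TIC scaling")
        mean_tic = tic[nonzero].mean()
        inten[:, nonzero] *= mean_tic / tic[nonzero]
    elif normalize != "none":
        raise ConfigError(f"unknown normalization {normalize!r}")

    if smooth_window and smooth_window > 1:
        inten = ndimage.uniform_filter1d(inten, size=int(smooth_window), axis=0, mode="nearest")

    if peak_snr <= 0:  # normalization/smoothing only, keep every feature
        return MSIDataset(data.coords, data.mz_axis,
                          np.clip(inten, 0, None).astype(np.float32),
                          pixel_size_um=data.pixel_size_um, mode=data.mode)

    mean_spec = inten.mean(axis=1)
    baseline = float(np.median(mean_spec))
    noise = 1.4826 * float(np.median(np.abs(mean_spec - baseline)))
    noise = max(noise, 1e-12)
    if np.isinf(peak_snr):
        raise DegenerateInputError("peak_snr is infinite: no feature can pass")
    peaks, _ = signal.find_peaks(mean_spec, height=baseline + peak_snr * noise)
    # Endpoints can be maxima too; find_peaks excludes them by definition.
    for edge in (0, len(mean_spec) - 1):
        inner = 1 if edge == 0 else len(mean_spec) - 2
        if len(mean_spec) > 1 and mean_spec[edge] > mean_spec[inner] and \
                mean_spec[edge] > baseline + peak_snr * noise:
            peaks = np.sort(np.append(peaks, edge))
    if peaks.size == 0:
        raise DegenerateInputError(
            f"no peaks at SNR >= {peak_snr}; lower peak_snr or check the data")

    if bin_tol > 0 and peaks.size > 1:
        peaks = _merge_peaks(peaks, data.mz_axis, mean_spec, bin_tol)

    return MSIDataset(
        data.coords, data.mz_axis[peaks],
        np.clip(inten[peaks], 0, None).astype(np.float32),
        pixel_size_um=data.pixel_size_um, mode=data.mode,
    )


def _merge_peaks(peaks: np.ndarray, mz: np.ndarray, heights: np.ndarray,
                 tol: float) -> np.ndarray:
    """Greedy merge of peaks within ``tol`` Da; the strongest survives."""
    order = peaks[np.argsort(heights[peaks])[::-1]]
    kept: list[int] = []
    for p in order:
        if all(abs(mz[p] - mz[q]) > tol for q in kept):
            kept.append(int(p))
    return np.sort(np.array(kept, dtype=np.int64))


# ---------------------------------------------------------------------------
# Spatial shrunken centroids


def _shrunken_stats(x: np.ndarray, labels: np.ndarray, k: int, s: float):
    """Per-segment shrunken centroids and soft-thresholded t-statistics.

    Follows the nearest-shrunken-centroid construction: the standardized
    difference between a segment centroid and the overall centroid,
    d_kj = (c_kj − c̄_j) / (m_k (s_j + s0)), is soft-thresholded at ``s``
    and mapped back to a shrunken centroid.
    """
    n, p = x.shape
    counts = np.array([(labels == c + 1).sum() for c in range(k)])
    occupied = counts > 0
    cent = np.zeros((k, p))
    for c in range(k):
        if occupied[c]:
            cent[c] = x[labels == c + 1].mean(axis=0)
    overall = x.mean(axis=0)

    # pooled within-segment sd
    resid_ss = np.zeros(p)
    for c in range(k):
        if occupied[c]:
            resid_ss += ((x[labels == c + 1] - cent[c]) ** 2).sum(axis=0)
    dof = max(n - occupied.sum(), 1)
    sj = np.sqrt(resid_ss / dof)
    s0 = float(np.median(sj))
    denom_sd = sj + s0
    if s0 == 0.0:
        denom_sd = np.maximum(denom_sd, 1e-12)

    with np.errstate(divide="ignore"):
        mk = np.sqrt(np.maximum(1.0 / np.maximum(counts, 1) - 1.0 / n, 1.0 / (n * n)))
    d = (cent - overall) / (mk[:, None] * denom_sd[None, :])
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - s, 0.0)
    cent_shrunk = overall[None, :] + mk[:, None] * denom_sd[None, :] * d_shrunk
    cent_shrunk[~occupied] = overall
    d_shrunk[~occupied] = 0.0
    return cent_shrunk, d_shrunk, denom_sd, occupied


def _smooth_scores(scores: np.ndarray, coords: np.ndarray, r: float) -> np.ndarray:
    """Gaussian-weighted neighborhood average of per-pixel scores (σ = r/2),
    normalized over pixels actually present in the dataset."""
    if r <= 0:
        return scores
    h = int(coords[:, 1].max()) + 1
    w = int(coords[:, 0].max()) + 1
    sigma = r / 2.0
    occ = np.zeros((h, w))
    occ[coords[:, 1], coords[:, 0]] = 1.0
    occ_s = ndimage.gaussian_filter(occ, sigma, truncate=max(r / sigma, 1e-9))
    out = np.empty_like(scores)
    for c in range(scores.shape[1]):
        grid = np.zeros((h, w))
        grid[coords[:, 1], coords[:, 0]] = scores[:, c]
        num = ndimage.gaussian_filter(grid, sigma, truncate=max(r / sigma, 1e-9))
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / occ_s
        out[:, c] = sm[coords[:, 1], coords[:, 0]]
    return out


def nearest_centroid_labels(x: np.ndarray, centroids: np.ndarray,
                            scale: np.ndarray | None = None) -> np.ndarray:
    """Plain nearest-centroid assignment in (optionally scaled) Euclidean
    distance; 1-based labels, ties broken toward the lowest segment index."""
    if scale is None:
        scale = np.ones(x.shape[1])
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2 / scale[None, None, :] ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


def ssc_segment(data: MSIDataset, params: SSCParams) -> SSCResult:
    """Segment the pixel grid and score features by spatial informativeness.

    The iteration alternates (a) shrunken-centroid statistics given labels
    and (b) label assignment by spatially smoothed standardized distance to
    the shrunken centroids, until fewer than 0.1% of labels change or
    ``max_iter`` is reached.  Initial labels come from k-means on the
    standardized spectra with a fixed seed.  Empty segments are dropped.
    """
    from sklearn.cluster import KMeans

    x = data.intensities.T.astype(np.float64)  # pixels × features
    n, p = x.shape
    if params.k > n:
        raise ConfigError(f"k={params.k} exceeds the number of pixels ({n})")

    # internal standardization for the k-means init
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    xz = (x - mu) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=params.k, random_state=params.seed, n_init=10)
    labels = km.fit_predict(xz).astype(np.int64) + 1

    cent = d_shrunk = denom = None
    for it in range(max(params.max_iter, 1)):
        cent, d_shrunk, denom, occupied = _shrunken_stats(x, labels, params.k, params.s)
        scores = ((x[:, None, :] - cent[None, :, :]) ** 2 / denom[None, None, :] ** 2).sum(axis=2)
        scores[:, ~occupied] = np.inf
        scores = _smooth_scores(scores, data.coords, params.r)
        new_labels = scores.argmin(axis=1) + 1
        changed = (new_labels != labels).mean()
        labels = new_labels
        if changed < 0.001:
            break

    # final statistics under the converged labels
    cent, d_shrunk, denom, occupied = _shrunken_stats(x, labels, params.k, params.s)

    # drop empty segments, relabel contiguously
    present = np.flatnonzero(occupied)
    remap = {old + 1: new + 1 for new, old in enumerate(present)}
    labels = np.array([remap[l] for l in labels], dtype=np.int64)
    cent = cent[present]
    d_shrunk = d_shrunk[present]

    feature_scores = np.abs(d_shrunk).max(axis=0) if len(d_shrunk) else np.zeros(p)
    nz = np.flatnonzero(feature_scores > 0)
    selected = nz[np.argsort(feature_scores[nz])[::-1]]
    return SSCResult(labels=labels, centroids=cent, tstats=d_shrunk,
                     feature_scores=feature_scores, selected=selected, params=params)


def select_features(res: SSCResult, top_n: int | None = None) -> np.ndarray:
    """Indices of informative features, sorted by descending score.

    Without ``top_n`` all features with a nonzero score are returned; with
    ``top_n`` the list is truncated (with a warning if fewer are available).
    """
    if res.selected.size == 0:
        raise DegenerateInputError(
            "no feature has a nonzero informativeness score; lower the shrinkage s")
    if top_n is None:
        return res.selected.copy()
    if top_n > res.selected.size:
        warnings.warn(
            f"requested top_n={top_n} but only {res.selected.size} features have "
            "nonzero scores; returning all of them")
    return res.selected[:top_n].copy()


def auto_shrinkage(data: MSIDataset, params: SSCParams,
                   max_fraction: float = 0.5,
                   candidates: np.ndarray | None = None) -> float:
    """Smallest shrinkage level retaining at most ``max_fraction`` of the
    features, holding the segmentation of an unshrunken run fixed."""
    base = ssc_segment(data, SSCParams(k=params.k, r=params.r, s=0.0,
                                       max_iter=params.max_iter, seed=params.seed))
    x = data.intensities.T.astype(np.float64)
    if candidates is None:
        tmax = np.abs(base.tstats).max() if base.tstats.size else 1.0
        candidates = np.linspace(0.0, tmax, 41)
    for s in candidates:
        _, d_shrunk, _, _ = _shrunken_stats(x, base.labels, base.k_effective, float(s))
        frac = (np.abs(d_shrunk).max(axis=0) > 0).mean()
        if frac <= max_fraction:
            return float(s)
    return float(candidates[-1])
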