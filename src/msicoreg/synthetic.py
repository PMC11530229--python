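"""Phantom generator: MSI/H&E pairs with known ground truth.

The generator builds a multi-segment tissue on the MSI pixel grid, draws
segment-specific informative mass features plus pure-noise features, renders
a co-localized H&E-like optical image at a chosen resolution factor, and
applies a known warp (translation, affine, smooth elastic, or independent
per-core rigid motions for tissue-microarray layouts) to the H&E side.
Everything the tests need — segment labels, informative feature indices and
the exact displacement field — is retained.

The default conditions are a 100×100 grid, 3 segments, 50 mass features of
which 5 are informative with a 2-SD mean shift in their segment: a tissue
heterogeneity level at which segment structure is clearly present but
individual ion images remain visibly noisy.  Elastic warps are built from
Gaussian-smoothed white noise with the amplitude clamped to 0.4× the
smoothness scale, which keeps the Jacobian of the warp positive everywhere;
this is asserted at generation time so metric ground truth is always
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .msi_io import MSIDataset, RasterImage, TissueMask
from .register import DisplacementField, warp_by_field

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "corrupt_outline"]


@dataclass
class PhantomSpec:
    """Conditions for one synthetic MSI/H&E pair.

    layout : "contiguous" (elliptical tissue split into Voronoi segments) or
        ``("tma", rows, cols, core_radius)``.
    warp : ``None`` / ``("translation", dx, dy)`` /
        ``("affine", matrix2x2, (tx, ty))`` /
        ``("elastic", amplitude_px, smoothness_px)`` /
        ``("per_core_random", max_shift_px, max_rot_deg)`` — applied to the
        H&E side.
    he_scale : resolution factor of the rendered H&E image relative to the
        MSI grid.
    n_cores : for TMA layouts, keep only the first ``n_cores`` positions
        (row-major); blanks emulate empty array slots.
    """

    grid: tuple[int, int] = (100, 100)
    n_segments: int = 3
    n_features: int = 50
    n_informative_per_segment: int = 2
    n_informative_total: int | None = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    base_intensity: float = 10.0
    texture_amplitude: float = 0.4
    texture_scale_px: float = 4.0
    layout: object = "contiguous"
    warp: object = None
    he_scale: int = 1
    n_cores: int | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.n_features < 1:
            raise ConfigError("n_segments and n_features must be positive")
        if self.he_scale < 1:
            raise ConfigError("he_scale must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")


@dataclass
class Phantom:
    """A generated pair plus every piece of ground truth."""

    msi: MSIDataset
    he: RasterImage
    he_mask: TissueMask
    msi_mask: TissueMask
    label_grid: np.ndarray          # (H, W) on the MSI grid, 0 = background
    pixel_labels: np.ndarray        # per MSI dataset pixel
    informative: np.ndarray         # feature indices carrying segment signal
    informative_by_segment: dict
    true_field: DisplacementField   # on the H&E grid, fixed→moving
    core_centers: np.ndarray | None = None
    spec: PhantomSpec | None = None


def _segment_layout(spec: PhantomSpec, rng: np.random.Generator):
    """Label grid on the MSI grid: 0 background, 1..n_segments tissue."""
    h, w = spec.grid
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.layout == "contiguous":
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        ry, rx = 0.45 * h, 0.45 * w
        tissue = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        # Voronoi segments from random seed points inside the tissue
        ys, xs = np.nonzero(tissue)
        picks = rng.choice(len(ys), size=spec.n_segments, replace=False)
        seeds = np.stack([ys[picks], xs[picks]], axis=1).astype(np.float64)
        d2 = ((yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2)
        labels = np.where(tissue, d2.argmin(axis=2) + 1, 0)
        return labels.astype(np.int64), None
    if isinstance(spec.layout, tuple) and spec.layout[0] == "tma":
        _, rows, cols, radius = spec.layout
        pitch_y = h / rows
        pitch_x = w / cols
        if radius * 2 >= min(pitch_y, pitch_x):
            raise ConfigError("TMA cores do not fit the grid at this radius")
        n_keep = spec.n_cores if spec.n_cores is not None else rows * cols
        labels = np.zeros((h, w), dtype=np.int64)
        centers = []
        idx = 0
        for r in range(rows):
            for c in range(cols):
                if idx >= n_keep:
                    break
                cy = (r + 0.5) * pitch_y
                cx = (c + 0.5) * pitch_x
                d = np.hypot(yy - cy, xx - cx)
                inner = d <= 0.6 * radius
                outer = (d > 0.6 * radius) & (d <= radius)
                labels[inner] = (idx % spec.n_segments) + 1
                labels[outer] = ((idx + 1) % spec.n_segments) + 1
                centers.append((cx, cy))
                idx += 1
        return labels, np.asarray(centers, dtype=np.float64)
    raise ConfigError(f"unknown layout {spec.layout!r}")


def _assign_informative(spec: PhantomSpec, rng: np.random.Generator):
    total = (spec.n_informative_total if spec.n_informative_total is not None
             else spec.n_informative_per_segment * spec.n_segments)
    if total > spec.n_features:
        raise ConfigError("more informative features than features")
    chosen = rng.choice(spec.n_features, size=total, replace=False)
    by_seg: dict[int, list[int]] = {s: [] for s in range(1, spec.n_segments + 1)}
    for i, f in enumerate(chosen):
        by_seg[(i % spec.n_segments) + 1].append(int(f))
    return np.sort(chosen), {s: np.array(v, dtype=np.int64) for s, v in by_seg.items()}


def _build_warp_field(spec: PhantomSpec, he_shape: tuple[int, int],
                      core_centers: np.ndarray | None,
                      rng: np.random.Generator,
                      tissue_labels: np.ndarray | None = None) -> DisplacementField:
    h, w = he_shape
    u = np.zeros((h, w, 2))
    if spec.warp is None or spec.warp == "none":
        return DisplacementField(u)
    kind = spec.warp[0]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if kind == "translation":
        _, dx, dy = spec.warp
        u[..., 0] = dx
        u[..., 1] = dy
    elif kind == "affine":
        _, a, t = spec.warp
        a = np.asarray(a, dtype=np.float64).reshape(2, 2)
        t = np.asarray(t, dtype=np.float64).reshape(2)
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        dxg = a[0, 0] * (xx - cx) + a[0, 1] * (yy - cy) + cx + t[0] - xx
        dyg = a[1, 0] * (xx - cx) + a[1, 1] * (yy - cy) + cy + t[1] - yy
        u[..., 0] = dxg
        u[..., 1] = dyg
    elif kind == "elastic":
        _, amplitude, smoothness = spec.warp
        amplitude = min(float(amplitude), 0.4 * float(smoothness))
        for c in range(2):
            u[..., c] = ndimage.gaussian_filter(rng.standard_normal((h, w)), smoothness)
        mx = np.hypot(u[..., 0], u[..., 1]).max()
        if mx > 0:
            u *= amplitude / mx
    elif kind == "per_core_random":
        if core_centers is None:
            raise ConfigError("per_core_random warp requires a TMA layout")
        _, max_shift, max_rot_deg = spec.warp
        radius = spec.layout[3] * spec.he_scale
        rows, cols = spec.layout[1], spec.layout[2]
        pitch = min(h / rows, w / cols)
        gap = max(pitch - 2 * radius, 1.0)
        # narrow feather: a core's rigid motion must not bleed into its
        # neighbors across the background gap
        feather = gap / 3.0
        wsum = np.zeros((h, w))
        acc = np.zeros((h, w, 2))
        for cx, cy in core_centers * spec.he_scale:
            theta = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
            phi = rng.uniform(0, 2 * np.pi)
            # staining-induced core movement is large on the scale of a core:
            # magnitudes fall in the upper half of the stated bound
            mag = max_shift * rng.uniform(0.5, 1.0)
            shift = mag * np.array([np.cos(phi), np.sin(phi)])
            ca, sa = np.cos(theta), np.sin(theta)
            dx = ca * (xx - cx) - sa * (yy - cy) + cx + shift[0] - xx
            dy = sa * (xx - cx) + ca * (yy - cy) + cy + shift[1] - yy
            d = np.hypot(yy - cy, xx - cx)
            wgt = np.exp(-0.5 * (np.maximum(d - radius, 0) / feather) ** 2)
            acc[..., 0] += wgt * dx
            acc[..., 1] += wgt * dy
            wsum += wgt
        nz = wsum > 1e-12
        u[nz] = acc[nz] / wsum[nz, None]
    else:
        raise ConfigError(f"unknown warp {spec.warp!r}")

    from .metrics import jacobian_determinant

    jac = jacobian_determinant(DisplacementField(u))
    if kind == "per_core_random":
        # cores move rigidly and independently; only the background feather
        # zone between cores can compress, and no tissue lives there
        tissue_hi = np.kron(tissue_labels > 0, np.ones((spec.he_scale, spec.he_scale),
                                                       dtype=bool))
        jmin = float(jac[tissue_hi].min()) if tissue_hi.any() else 1.0
    else:
        jmin = float(jac.min())
    if jmin <= 0:
        raise ConfigError(
            f"generated warp is not diffeomorphic on tissue (min Jacobian "
            f"{jmin:.3f}); reduce the amplitude or increase the smoothness")
    return DisplacementField(u)


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate one MSI/H&E phantom pair with full ground truth.

    The MSI dataset covers the tissue pixels of the label grid; informative
    features get a mean shift of ``effect_size × noise_sd`` inside their
    segment.  The H&E image is rendered at ``he_scale×`` resolution with
    per-segment gray levels (tissue dark on a light background, like a real
    stain) plus texture noise, then warped by the requested ground-truth
    field.  Regeneration with the same spec is bit-identical.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    labels, core_centers = _segment_layout(spec, rng)
    h, w = spec.grid
    ys, xs = np.nonzero(labels > 0)
    coords = np.stack([xs, ys], axis=1).astype(np.int64)
    pix_labels = labels[ys, xs]
    n_pix = len(coords)

    # shared "cellularity" texture: smooth within-tissue heterogeneity visible
    # in both modalities, the signal landmark-free registration relies on
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.texture_scale_px)
    tsd = texture.std()
    texture = texture / tsd if tsd > 0 else texture

    informative, by_seg = _assign_informative(spec, rng)
    inten = spec.base_intensity + spec.noise_sd * rng.standard_normal((spec.n_features, n_pix))
    tex_pix = texture[ys, xs]
    for seg, feats in by_seg.items():
        in_seg = pix_labels == seg
        # the segment effect is modulated by local cellularity: abundance of
        # a segment's analytes varies smoothly within the segment, coherently
        # with the stain density of the optical image
        local = spec.effect_size * spec.noise_sd * (
            1.0 + spec.texture_amplitude * tex_pix[in_seg])
        for f in feats:
            inten[f, in_seg] += local
    inten = np.clip(inten, 0.0, None).astype(np.float32)
    mz_axis = 800.0 + 1.5 * np.arange(spec.n_features)
    msi = MSIDataset(coords, mz_axis, inten, pixel_size_um=150.0, mode="continuous")

    msi_mask = TissueMask((labels > 0).astype(np.uint8))

    # H&E rendering: background light, segments at distinct dark gray levels
    s = spec.he_scale
    lab_hi = np.kron(labels, np.ones((s, s), dtype=np.int64))
    gray_levels = np.linspace(0.25, 0.65, spec.n_segments)
    he_gray = np.where(lab_hi > 0, 0.0, 0.92)
    for seg in range(1, spec.n_segments + 1):
        he_gray[lab_hi == seg] = gray_levels[seg - 1]
    tex_hi = np.kron(texture, np.ones((s, s)))
    he_gray[lab_hi > 0] -= 0.12 * spec.texture_amplitude * tex_hi[lab_hi > 0]
    he_gray = np.clip(he_gray + 0.02 * rng.standard_normal(he_gray.shape), 0.0, 1.0)
    # pinkish tint, eosin-like
    he_rgb = np.stack([np.clip(he_gray * 1.0 + 0.05, 0, 1), he_gray * 0.85, he_gray * 0.95], axis=2)

    true_field = _build_warp_field(spec, lab_hi.shape, core_centers, rng,
                                   tissue_labels=labels)
    he_warped = warp_by_field(he_rgb, true_field, order=1)
    # out-of-frame pixels become background-colored, not black
    sampled = warp_by_field(np.ones(lab_hi.shape), true_field, order=1)
    for c, bgval in enumerate((0.97, 0.78, 0.87)):
        ch = he_warped[..., c]
        ch += (1.0 - sampled) * bgval
        he_warped[..., c] = ch
    he = RasterImage(np.clip(he_warped, 0, 1), pixel_size_um=150.0 / s)

    he_mask_base = (lab_hi > 0).astype(np.float64)
    he_mask = TissueMask((warp_by_field(he_mask_base, true_field, order=0) > 0.5).astype(np.uint8))

    return Phantom(msi=msi, he=he, he_mask=he_mask, msi_mask=msi_mask,
                   label_grid=labels, pixel_labels=pix_labels,
                   informative=informative, informative_by_segment=by_seg,
                   true_field=true_field, core_centers=core_centers, spec=spec)


def corrupt_outline(mask: TissueMask, dilate_px: int) -> TissueMask:
    """Dilate a tissue outline by a disk — emulates a deliberately padded
    background beyond the true tissue margin."""
    if dilate_px < 0:
        raise ConfigError("dilate_px must be >= 0")
    if dilate_px == 0:
        return TissueMask(mask.pixels.astype(np.uint8))
    yy, xx = np.mgrid[-dilate_px:dilate_px + 1, -dilate_px:dilate_px + 1]
    disk = (xx**2 + yy**2) <= dilate_px**2
    return TissueMask(ndimage.binary_dilation(mask.pixels, structure=disk).astype(np.uint8))
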