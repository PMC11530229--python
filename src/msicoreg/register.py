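"""Mutual-information registration of the two representative images.

The MSI representative (moving) is aligned to the H&E representative
(fixed) by maximizing Mattes-style mutual information over the parameters
of a rigid, affine, or cubic B-spline free-form deformation.  Conventions:

* points are ``(x, y)`` with ``x`` the column index, pixel-centered;
* a transform maps **fixed** coordinates to **moving** coordinates — the
  pullback/resampling convention, so warping evaluates the moving image at
  ``T(x)`` for every fixed-grid point ``x``;
* mutual information is estimated from a joint histogram built with
  first-order (linear) Parzen windows on both intensity axes over pixels
  sampled from the union of the two tissue supports.  Linear windows on
  both axes keep the estimate exactly symmetric in its two arguments and
  collapse to a plain histogram when intensities sit on bin centers.

Optimization runs coarse-to-fine: images are Gaussian-smoothed per pyramid
level (heavier smoothing first) and the parameter vector is warm-started
across levels.  The default B-spline run is initialized from a preceding
affine stage — a cold-started B-spline cannot recover large translations.
Gradients are forward finite differences with a step sized for a metric
built on a sampled histogram; L-BFGS-B bounds each B-spline coefficient to
±2 control-point spacings, which prevents folding in the common case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .errors import ConfigError, DegenerateInputError, DimensionError, MsicoregError
from .embed import RepresentativeImage
from .msi_io import RasterImage, TissueMask

__all__ = [
    "RegistrationConfig",
    "TransformModel",
    "DisplacementField",
    "mattes_mi",
    "register_images",
    "to_displacement_field",
    "apply_transform",
    "transfer_annotations",
    "warp_by_field",
]

log = logging.getLogger(__name__)


@dataclass
class RegistrationConfig:
    transform: str = "bspline"
    metric: str = "mattesMI"
    optimizer: str = "lbfgsb"
    interpolator: str = "linear"
    bins: int = 32
    sampling: str = "random:0.25"
    pyramid_levels: int = 3
    bspline_grid_spacing_px: float = 32.0
    bending_weight: float = 1e-3
    support_margin_px: int = 4
    max_iter: int = 100
    seed: int = 42

    def __post_init__(self) -> None:
        if self.transform not in ("rigid", "affine", "bspline"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        if self.metric != "mattesMI":
            raise ConfigError(f"unknown metric {self.metric!r}")
        if self.optimizer not in ("lbfgsb", "gradient_descent"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.interpolator not in ("linear", "nearest"):
            raise ConfigError(f"unknown interpolator {self.interpolator!r}")
        if self.bins < 8:
            raise ConfigError("bins must be >= 8")
        if self.pyramid_levels < 1:
            raise ConfigError("pyramid_levels must be >= 1")
        _parse_sampling(self.sampling)  # validate


def _parse_sampling(spec: str) -> float:
    """Return the sampling fraction (1.0 for 'full')."""
    if spec == "full":
        return 1.0
    if spec.startswith("random:"):
        frac = float(spec.split(":", 1)[1])
        if not 0 < frac <= 1:
            raise ConfigError("sampling fraction must be in (0, 1]")
        return frac
    raise ConfigError(f"unknown sampling spec {spec!r}")


# ---------------------------------------------------------------------------
# Transform models


def _bspline_weights(coords: np.ndarray, spacing: float, n_ctrl: int) -> np.ndarray:
    """Dense (N, n_ctrl) cubic B-spline basis weights for 1-D coordinates.

    Control point ``j`` sits at ``(j - 1) * spacing``; each coordinate is
    supported by 4 consecutive control points.
    """
    t = np.asarray(coords, dtype=np.float64) / spacing
    i0 = np.floor(t).astype(np.int64)
    u = t - i0
    b = np.empty((len(t), 4))
    b[:, 0] = (1 - u) ** 3 / 6.0
    b[:, 1] = (3 * u**3 - 6 * u**2 + 4) / 6.0
    b[:, 2] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    b[:, 3] = u**3 / 6.0
    w = np.zeros((len(t), n_ctrl))
    rows = np.arange(len(t))
    for l in range(4):
        idx = np.clip(i0 + l, 0, n_ctrl - 1)
        np.add.at(w, (rows, idx), b[:, l])
    return w


def _bspline_grid_size(extent: int, spacing: float) -> int:
    return int(np.floor((extent - 1) / spacing)) + 4


def _tensor_displacement(wy: np.ndarray, wx: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Separable evaluation u[n, c] = Σ_ij wy[n,i] wx[n,j] coefs[i,j,c]."""
    ux = ((wy @ coefs[:, :, 0]) * wx).sum(axis=1)
    uy = ((wy @ coefs[:, :, 1]) * wx).sum(axis=1)
    return np.stack([ux, uy], axis=1)


@dataclass
class TransformModel:
    """A recovered fixed→moving spatial mapping.

    kind : "rigid", "affine" or "bspline".
    matrix, translation : the (2, 2) linear part and (2,) offset in pixel
        units, in standard (not center-relative) form.  For a bspline model
        these hold the affine initialization stage; the free-form part is in
        ``coefficients``.
    coefficients : (ncy, ncx, 2) control-point displacement vectors (px,
        (dx, dy)) of the cubic B-spline free-form deformation, applied
        before the affine part: ``T(x) = A (x + u(x)) + t``.
    fixed_domain : (H, W) of the fixed image the transform was estimated on.
    """

    kind: str
    fixed_domain: tuple[int, int]
    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    spacing: float = 32.0
    coefficients: np.ndarray | None = None
    angle: float | None = None  # radians, rigid only

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if self.kind in ("rigid", "affine") and abs(np.linalg.det(self.matrix)) <= 1e-8:
            raise ConfigError("rigid/affine matrix must be invertible")
        if self.kind == "bspline" and self.coefficients is None:
            ncy = _bspline_grid_size(self.fixed_domain[0], self.spacing)
            ncx = _bspline_grid_size(self.fixed_domain[1], self.spacing)
            self.coefficients = np.zeros((ncy, ncx, 2))

    @classmethod
    def identity(cls, fixed_domain: tuple[int, int]) -> "TransformModel":
        return cls(kind="affine", fixed_domain=fixed_domain)

    def displacement_bspline(self, pts: np.ndarray) -> np.ndarray:
        """Free-form displacement u(x) at (N, 2) fixed points, zero for
        non-bspline models."""
        if self.kind != "bspline":
            return np.zeros_like(pts)
        ncy, ncx, _ = self.coefficients.shape
        wx = _bspline_weights(pts[:, 0], self.spacing, ncx)
        wy = _bspline_weights(pts[:, 1], self.spacing, ncy)
        return _tensor_displacement(wy, wx, self.coefficients)

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 2) fixed-space (x, y) points into moving space."""
        pts = np.asarray(pts, dtype=np.float64)
        y = pts + self.displacement_bspline(pts)
        return y @ self.matrix.T + self.translation

    def inverse_points(self, pts_moving: np.ndarray, n_iter: int = 30) -> np.ndarray:
        """Fixed-space preimages of moving-space points.

        Exact for rigid/affine; fixed-point iteration on the residual for
        bspline models (converges for the small, smooth deformations the
        coefficient bounds allow).
        """
        inv_a = np.linalg.inv(self.matrix)
        z = (np.asarray(pts_moving, dtype=np.float64) - self.translation) @ inv_a.T
        if self.kind != "bspline":
            return z
        x = z.copy()
        for _ in range(n_iter):
            x = z - self.displacement_bspline(x)
        return x


@dataclass
class DisplacementField:
    """Dense fixed-grid displacement: ``u[y, x] = T((x, y)) − (x, y)``,
    channels ``(dx, dy)`` in pixels."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[2] != 2:
            raise DimensionError("displacement field must be H × W × 2")
        if not np.all(np.isfinite(self.u)):
            raise MsicoregError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u[..., 0], self.u[..., 1])


def _grid_points(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    return np.stack([xx.ravel(), yy.ravel()], axis=1).astype(np.float64)


def to_displacement_field(t: TransformModel) -> DisplacementField:
    """Sample the transform on the fixed grid as a dense displacement field."""
    pts = _grid_points(t.fixed_domain)
    u = t.map_points(pts) - pts
    return DisplacementField(u.reshape(t.fixed_domain + (2,)))


# ---------------------------------------------------------------------------
# Mattes mutual information


def _support_of(img) -> np.ndarray:
    if isinstance(img, RepresentativeImage):
        return img.support.pixels
    return np.ones(np.asarray(img).shape[:2], dtype=bool)


def _pixels_of(img) -> np.ndarray:
    if isinstance(img, RepresentativeImage):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def _linear_window_hist(fv: np.ndarray, mv: np.ndarray, bins: int):
    """Joint histogram with first-order Parzen windows on both axes."""

    def bin_pos(v):
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-300:
            return None
        z = (v - lo) / (hi - lo) * (bins - 1)
        i = np.minimum(np.floor(z).astype(np.int64), bins - 2)
        return i, z - i

    bf, bm = bin_pos(fv), bin_pos(mv)
    if bf is None or bm is None:
        return None  # constant marginal: MI is 0 by convention
    fi, ff = bf
    mi_, mf = bm
    idx = np.concatenate([
        (fi + df) * bins + (mi_ + dm) for df in (0, 1) for dm in (0, 1)])
    wts = np.concatenate([
        wf * wm for wf in (1 - ff, ff) for wm in (1 - mf, mf)])
    joint = np.bincount(idx, weights=wts, minlength=bins * bins)
    return joint.reshape(bins, bins) / len(fv)


def _mi_from_joint(joint: np.ndarray) -> float:
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    nz = joint > 0
    rows, cols = np.nonzero(nz)
    return float(np.sum(joint[nz] * (np.log(joint[nz]) - np.log(pf[rows]) - np.log(pm[cols]))))


def mattes_mi(fixed, moving, bins: int = 32, sampling: str = "full",
              seed: int = 42) -> float:
    """Mutual information (nats) between two equally-shaped images.

    Sampling is over the union of the two tissue supports (all pixels for
    plain arrays); ``sampling="random:f"`` subsamples a fraction ``f`` with
    the given seed.  Both marginals use linear Parzen windows, so the value
    is exactly symmetric in its arguments under full sampling.  A constant
    image has a zero-entropy marginal and yields MI = 0.
    """
    fpx, mpx = _pixels_of(fixed), _pixels_of(moving)
    if fpx.shape != mpx.shape:
        raise DimensionError(f"image shapes differ: {fpx.shape} vs {mpx.shape}")
    support = _support_of(fixed) | _support_of(moving)
    fv = fpx[support]
    mv = mpx[support]
    frac = _parse_sampling(sampling)
    if frac < 1.0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(fv), size=max(2, int(round(frac * len(fv)))), replace=False)
        fv, mv = fv[idx], mv[idx]
    if np.ptp(fv) < 1e-300 or np.ptp(mv) < 1e-300:
        return 0.0
    joint = _linear_window_hist(fv, mv, bins)
    if joint is None:
        return 0.0
    occ_f = int((joint.sum(axis=1) > 0).sum())
    occ_m = int((joint.sum(axis=0) > 0).sum())
    if occ_f < 2 or occ_m < 2:
        raise DegenerateInputError(
            f"degenerate histogram: {occ_f} fixed / {occ_m} moving bins occupied")
    return _mi_from_joint(joint)


# ---------------------------------------------------------------------------
# Parameterizations for the optimizer


class _Parameterization:
    """Maps a scaled parameter vector (one unit ≈ one pixel of motion at the
    tissue margin) to a TransformModel and back."""

    def __init__(self, kind: str, domain: tuple[int, int], spacing: float):
        self.kind = kind
        self.domain = domain
        self.spacing = spacing
        h, w = domain
        self.center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        self.extent = max(np.hypot(*self.center), 1.0)
        if kind == "bspline":
            ncy = _bspline_grid_size(h, spacing)
            ncx = _bspline_grid_size(w, spacing)
            self.grid_shape = (ncy, ncx)
            self.n_params = ncy * ncx * 2
        elif kind == "affine":
            self.n_params = 6
        elif kind == "rigid":
            self.n_params = 3
        else:  # pragma: no cover
            raise ConfigError(kind)

    def initial(self) -> np.ndarray:
        return np.zeros(self.n_params)

    def bounds(self):
        if self.kind == "bspline":
            b = 2.0 * self.spacing
            return [(-b, b)] * self.n_params
        return None

    def build(self, params: np.ndarray, affine_init: TransformModel | None = None) -> TransformModel:
        c = self.center
        if self.kind == "rigid":
            theta = params[0] / self.extent
            ca, sa = np.cos(theta), np.sin(theta)
            a = np.array([[ca, -sa], [sa, ca]])
            t = params[1:3] + c - a @ c
            return TransformModel("rigid", self.domain, a, t, angle=theta)
        if self.kind == "affine":
            a = np.eye(2) + params[:4].reshape(2, 2) / self.extent
            t = params[4:6] + c - a @ c
            return TransformModel("affine", self.domain, a, t)
        coefs = params.reshape(self.grid_shape + (2,))
        init = affine_init or TransformModel.identity(self.domain)
        return TransformModel("bspline", self.domain, init.matrix, init.translation,
                              spacing=self.spacing, coefficients=coefs)


def _bending_energy_grad(coefs: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared second difference of the control-point grid (px²) and
    its gradient with respect to the coefficients.

    A thin-plate bending penalty on the free-form deformation: it leaves
    affine-like (linear) deformations unpenalized and pulls control points
    that the image content does not constrain — flat tissue interiors —
    toward the smooth interpolant of their neighbors.
    """
    e = 0.0
    n = 0
    grad = np.zeros_like(coefs)
    for c in range(2):
        g = coefs[..., c]
        dyy = g[2:, :] - 2 * g[1:-1, :] + g[:-2, :]
        dxx = g[:, 2:] - 2 * g[:, 1:-1] + g[:, :-2]
        dxy = g[1:, 1:] - g[1:, :-1] - g[:-1, 1:] + g[:-1, :-1]
        e += (dyy**2).sum() + (dxx**2).sum() + 2 * (dxy**2).sum()
        n += dyy.size + dxx.size + 2 * dxy.size
        gc = grad[..., c]
        gc[2:, :] += 2 * dyy
        gc[1:-1, :] += -4 * dyy
        gc[:-2, :] += 2 * dyy
        gc[:, 2:] += 2 * dxx
        gc[:, 1:-1] += -4 * dxx
        gc[:, :-2] += 2 * dxx
        gc[1:, 1:] += 4 * dxy
        gc[1:, :-1] += -4 * dxy
        gc[:-1, 1:] += -4 * dxy
        gc[:-1, :-1] += 4 * dxy
    n = max(n, 1)
    return e / n, grad / n


def _bending_energy(coefs: np.ndarray) -> float:
    return _bending_energy_grad(coefs)[0]


def _bilinear(img: np.ndarray, pts: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(img, [pts[:, 1], pts[:, 0]], order=order,
                                   mode="constant", cval=0.0, prefilter=False)


# -- differentiable Mattes estimator used inside the optimizer --------------
#
# The public ``mattes_mi`` uses linear Parzen windows on both axes, which is
# exactly symmetric and collapses to a plain histogram on quantized data.
# The optimizer instead uses the classic Mattes construction — linear window
# on the fixed axis, cubic B-spline window on the moving axis — because the
# cubic window makes the metric analytically differentiable with respect to
# the moving intensities, and hence to the transform parameters.  Histogram
# objectives are piecewise linear under linear windows; finite differences
# on them measure kink noise instead of slope.


def _cubic_kernel(t: np.ndarray) -> np.ndarray:
    a = np.abs(t)
    out = np.zeros_like(a)
    m1 = a <= 1
    out[m1] = 2.0 / 3.0 - a[m1] ** 2 + 0.5 * a[m1] ** 3
    m2 = (a > 1) & (a < 2)
    out[m2] = (2.0 - a[m2]) ** 3 / 6.0
    return out


def _cubic_kernel_deriv(t: np.ndarray) -> np.ndarray:
    a = np.abs(t)
    out = np.zeros_like(a)
    m1 = a <= 1
    out[m1] = -2.0 * a[m1] + 1.5 * a[m1] ** 2
    m2 = (a > 1) & (a < 2)
    out[m2] = -0.5 * (2.0 - a[m2]) ** 2
    return out * np.sign(t)


class _MattesEstimator:
    """MI value and ∂MI/∂(moving value) for fixed sample intensities.

    Intensity ranges are frozen per pyramid level (the whole smoothed image
    range), so the mapping from value to bin coordinate is constant during
    one optimization stage — matching standard practice.
    """

    def __init__(self, fv: np.ndarray, bins: int, f_range, m_range):
        self.bins = bins
        flo, fhi = f_range
        zf = np.clip((fv - flo) / max(fhi - flo, 1e-300), 0.0, 1.0) * (bins - 1)
        fi = np.minimum(np.floor(zf).astype(np.int64), bins - 2)
        self.fi = fi
        self.wf = np.stack([1.0 - (zf - fi), zf - fi], axis=1)  # (N, 2)
        self.m_lo, self.m_hi = m_range
        self.dz_dv = (bins - 3) / max(self.m_hi - self.m_lo, 1e-300)

    def value_grad(self, mv: np.ndarray):
        bins = self.bins
        zm = (mv - self.m_lo) * self.dz_dv + 1.0
        inside = (zm >= 1.0) & (zm <= bins - 2.0)
        zm = np.clip(zm, 1.0, float(bins - 2))
        j0 = np.minimum(np.floor(zm).astype(np.int64), bins - 3)
        n = len(mv)
        joint = np.zeros(bins * bins)
        offs = (-1, 0, 1, 2)
        wm = [ _cubic_kernel(zm - (j0 + d)) for d in offs ]
        dwm = [ _cubic_kernel_deriv(zm - (j0 + d)) for d in offs ]
        for fcol in (0, 1):
            fidx = self.fi + fcol
            for k, d in enumerate(offs):
                joint += np.bincount(fidx * bins + (j0 + d),
                                     weights=self.wf[:, fcol] * wm[k],
                                     minlength=bins * bins)
        joint = joint.reshape(bins, bins) / n
        pf = joint.sum(axis=1)
        pm = joint.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.log(joint) - np.log(pf)[:, None] - np.log(pm)[None, :]
        logratio[joint <= 0] = 0.0
        mi = float(np.sum(joint[joint > 0] * logratio[joint > 0]))

        dmi_dv = np.zeros(n)
        for fcol in (0, 1):
            fidx = self.fi + fcol
            lr_rows = logratio[fidx]  # (N, bins)
            for k, d in enumerate(offs):
                dmi_dv += self.wf[:, fcol] * dwm[k] * \
                    np.take_along_axis(lr_rows, (j0 + d)[:, None], axis=1).ravel()
        dmi_dv *= self.dz_dv / n
        dmi_dv[~inside] = 0.0
        return mi, dmi_dv


def _smoothed(img: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma) if sigma > 0 else img


def register_images(fixed: RepresentativeImage, moving: RepresentativeImage,
                    cfg: RegistrationConfig | None = None) -> TransformModel:
    """Estimate the fixed→moving transform that maximizes mutual information.

    Runs a Gaussian multi-resolution schedule (heavy smoothing first), with
    the parameter vector warm-started between levels; for the default
    B-spline transform an affine stage runs first and its result seeds the
    free-form stage.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise DimensionError(
            f"fixed {fixed.shape} and moving {moving.shape} differ; run match_geometry first")
    domain = fixed.shape
    support = fixed.support.pixels | moving.support.pixels
    if not support.any():
        raise DegenerateInputError("both supports are empty")
    if cfg.support_margin_px > 0:
        # sample a thin background ring as well: the tissue margin is only
        # localizable when both of its sides contribute to the histogram
        support = ndimage.binary_dilation(support, iterations=cfg.support_margin_px)
    ys, xs = np.nonzero(support)
    all_pts = np.stack([xs, ys], axis=1).astype(np.float64)
    frac = _parse_sampling(cfg.sampling)
    rng = np.random.default_rng(cfg.seed)

    factors = [2 ** (cfg.pyramid_levels - 1 - l) for l in range(cfg.pyramid_levels)]

    def run_stage(kind: str, spacing: float, affine_init: TransformModel | None,
                  x0: np.ndarray | None = None) -> tuple[TransformModel, np.ndarray]:
        par = _Parameterization(kind, domain, spacing)
        x = par.initial() if x0 is None else x0.copy()
        # under random sampling the finest level is followed by a
        # deterministic full-sampling polish that removes the residual bias
        # of any single subsample
        if frac >= 1.0:
            schedule = [(f, frac) for f in factors]
        else:
            schedule = [(f, frac) for f in factors] + [(1, 1.0)]
        amat = (affine_init.matrix if affine_init is not None else np.eye(2))
        avec = (affine_init.translation if affine_init is not None else np.zeros(2))
        center = np.array([(domain[1] - 1) / 2.0, (domain[0] - 1) / 2.0])
        extent = par.extent

        for factor, level_frac in schedule:
            sigma = 0.0 if factor == 1 else factor * 0.5
            f_img = _smoothed(fixed.pixels, sigma)
            m_img = _smoothed(moving.pixels, sigma)
            # bicubic model of the moving image: its analytic derivatives are
            # exactly consistent with the sampled values, which keeps the
            # L-BFGS-B line searches honest
            from scipy.interpolate import RectBivariateSpline

            h_dom, w_dom = m_img.shape
            spl = RectBivariateSpline(np.arange(h_dom), np.arange(w_dom), m_img,
                                      kx=3, ky=3, s=0)

            def sample_moving(mapped):
                xc = np.clip(mapped[:, 0], 0.0, w_dom - 1.0)
                yc = np.clip(mapped[:, 1], 0.0, h_dom - 1.0)
                inside = ((mapped[:, 0] >= 0) & (mapped[:, 0] <= w_dom - 1)
                          & (mapped[:, 1] >= 0) & (mapped[:, 1] <= h_dom - 1))
                mv = spl.ev(yc, xc)
                gvx = spl.ev(yc, xc, dy=1)
                gvy = spl.ev(yc, xc, dx=1)
                mv[~inside] = 0.0
                gvx[~inside] = 0.0
                gvy[~inside] = 0.0
                return mv, gvx, gvy
            n_take = len(all_pts) if level_frac >= 1.0 else \
                max(200, int(round(level_frac * len(all_pts))))
            n_take = min(n_take, len(all_pts))
            sel = rng.choice(len(all_pts), size=n_take, replace=False)
            pts = all_pts[sel]
            fv = _bilinear(f_img, pts)
            if np.ptp(fv) < 1e-300:
                continue
            est = _MattesEstimator(
                fv, cfg.bins,
                (float(f_img.min()), float(f_img.max())),
                (float(m_img.min()), float(m_img.max())))

            if kind == "bspline":
                # basis weights depend only on the sample points: cache them
                # so each evaluation is a pair of matrix products
                ncy, ncx = par.grid_shape
                wx_c = _bspline_weights(pts[:, 0], spacing, ncx)
                wy_c = _bspline_weights(pts[:, 1], spacing, ncy)

                def map_pts(p):
                    u = _tensor_displacement(wy_c, wx_c, p.reshape(ncy, ncx, 2))
                    return (pts + u) @ amat.T + avec
            else:
                def map_pts(p):
                    return par.build(p, affine_init).map_points(pts)

            def objective(p):
                mapped = map_pts(p)
                mv, gvx, gvy = sample_moving(mapped)
                if np.ptp(mv) < 1e-300:
                    return 0.0, np.zeros_like(p)
                mi, dmi_dv = est.value_grad(mv)
                # minimize -MI: flip the sign of the chain-rule factor
                s = -dmi_dv
                if kind == "rigid":
                    theta = p[0] / extent
                    ca, sa = np.cos(theta), np.sin(theta)
                    rel = pts - center
                    dx_dth = (-sa * rel[:, 0] - ca * rel[:, 1]) / extent
                    dy_dth = (ca * rel[:, 0] - sa * rel[:, 1]) / extent
                    grad = np.array([
                        np.sum(s * (gvx * dx_dth + gvy * dy_dth)),
                        np.sum(s * gvx),
                        np.sum(s * gvy),
                    ])
                elif kind == "affine":
                    rel = (pts - center) / extent
                    grad = np.array([
                        np.sum(s * gvx * rel[:, 0]),
                        np.sum(s * gvx * rel[:, 1]),
                        np.sum(s * gvy * rel[:, 0]),
                        np.sum(s * gvy * rel[:, 1]),
                        np.sum(s * gvx),
                        np.sum(s * gvy),
                    ])
                else:
                    # dT/dc_x = A[:,0] wy wx ; dT/dc_y = A[:,1] wy wx
                    qx = gvx * amat[0, 0] + gvy * amat[1, 0]
                    qy = gvx * amat[0, 1] + gvy * amat[1, 1]
                    gcx = (wy_c * (s * qx)[:, None]).T @ wx_c
                    gcy = (wy_c * (s * qy)[:, None]).T @ wx_c
                    grad = np.stack([gcx, gcy], axis=2).ravel()
                val = -mi
                if kind == "bspline" and cfg.bending_weight > 0:
                    # continuation: a stronger smoothness prior at coarse
                    # pyramid levels, relaxed as detail becomes reliable
                    lam = cfg.bending_weight * factor * factor
                    be, dbe = _bending_energy_grad(p.reshape(ncy, ncx, 2))
                    val += lam * be
                    grad = grad + lam * dbe.ravel()
                if not (np.isfinite(val) and np.all(np.isfinite(grad))):
                    raise MsicoregError(
                        f"non-finite metric during optimization (stage {kind}, "
                        f"pyramid factor {factor}, params {p[:6]}...)")
                return val, grad

            is_polish = level_frac >= 1.0 > frac
            maxiter = min(cfg.max_iter, 50) if is_polish else cfg.max_iter
            if cfg.optimizer == "lbfgsb":
                res = optimize.minimize(
                    objective, x, method="L-BFGS-B", jac=True, bounds=par.bounds(),
                    options={"maxiter": maxiter, "maxfun": 50 * maxiter,
                             "ftol": 1e-12, "gtol": 1e-10})
                x = res.x
            else:
                x = _gradient_descent(objective, x, max_iter=maxiter,
                                      bounds=par.bounds())
        return par.build(x, affine_init), x

    if cfg.transform in ("rigid", "affine"):
        model, _ = run_stage(cfg.transform, cfg.bspline_grid_spacing_px, None)
        return model

    affine_model, _ = run_stage("affine", cfg.bspline_grid_spacing_px, None)
    model, _ = run_stage("bspline", cfg.bspline_grid_spacing_px, affine_model)
    return model


def _gradient_descent(fun, x0, max_iter: int, bounds=None,
                      step0: float = 1.0, tol: float = 1e-10):
    """Plain steepest descent with backtracking line search; ``fun`` returns
    (value, gradient)."""
    x = x0.copy()
    f, g = fun(x)
    for _ in range(max_iter):
        gn = np.linalg.norm(g)
        if gn < 1e-12:
            break
        step = step0
        improved = False
        for _ in range(20):
            xn = x - step * g / gn
            if bounds is not None:
                lo = np.array([b[0] for b in bounds])
                hi = np.array([b[1] for b in bounds])
                xn = np.clip(xn, lo, hi)
            fn, gn_new = fun(xn)
            if fn < f - 1e-12:
                x, f, g = xn, fn, gn_new
                improved = True
                break
            step *= 0.5
        if not improved or abs(step) < tol:
            break
    return x


# ---------------------------------------------------------------------------
# Resampling and annotation transfer


def apply_transform(img, t: TransformModel, interpolator: str = "linear"):
    """Resample an image, mask or label grid onto the fixed grid through the
    transform: ``out(x) = input(T(x))``; out-of-domain pixels become 0 /
    background.  Masks and label grids require nearest-neighbor."""
    pts = _grid_points(t.fixed_domain)
    mapped = t.map_points(pts)

    if isinstance(img, TissueMask):
        out = _bilinear(img.pixels.astype(np.float64), mapped, order=0)
        return TissueMask(out.reshape(t.fixed_domain).astype(np.uint8))
    if isinstance(img, RepresentativeImage):
        order = 1 if interpolator == "linear" else 0
        out = _bilinear(img.pixels, mapped, order=order).reshape(t.fixed_domain)
        sup = _bilinear(img.support.pixels.astype(np.float64), mapped, order=0)
        sup_mask = TissueMask(sup.reshape(t.fixed_domain).astype(np.uint8))
        out[~sup_mask.pixels] = 0.0
        return RepresentativeImage(np.clip(out, 0, 1), sup_mask,
                                   {**img.provenance, "resampled": True})
    if isinstance(img, RasterImage):
        order = 1 if interpolator == "linear" else 0
        px = img.pixels
        if px.ndim == 2:
            out = _bilinear(px, mapped, order=order).reshape(t.fixed_domain)
        else:
            out = np.stack([
                _bilinear(px[:, :, c], mapped, order=order).reshape(t.fixed_domain)
                for c in range(px.shape[2])], axis=2)
        return RasterImage(np.clip(out, 0, 1), pixel_size_um=img.pixel_size_um)

    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.integer):
        if interpolator != "nearest":
            raise ConfigError("label grids must be resampled with interpolator='nearest'")
        out = _bilinear(arr.astype(np.float64), mapped, order=0)
        return out.reshape(t.fixed_domain).astype(arr.dtype)
    order = 1 if interpolator == "linear" else 0
    return _bilinear(arr.astype(np.float64), mapped, order=order).reshape(t.fixed_domain)


def warp_by_field(arr: np.ndarray, field_: DisplacementField, order: int = 1) -> np.ndarray:
    """Warp an array by a dense displacement field: out(x) = arr(x + u(x))."""
    arr = np.asarray(arr, dtype=np.float64)
    h, w = field_.shape
    pts = _grid_points((h, w)) + field_.u.reshape(-1, 2)
    if arr.ndim == 3:
        return np.stack([
            _bilinear(arr[:, :, c], pts, order=order).reshape(h, w)
            for c in range(arr.shape[2])], axis=2)
    return _bilinear(arr, pts, order=order).reshape(h, w)


def transfer_annotations(labels: np.ndarray, t: TransformModel, scaling: int = 1,
                         msi_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Pull a fixed-geometry (H&E) label grid back onto MSI pixel centers.

    The MSI native pixel ``(xm, ym)`` corresponds to moving-grid coordinate
    ``scaling · xm + (scaling − 1)/2`` (the center of its upscaled block);
    its fixed-space preimage under ``t`` indexes the label grid with nearest
    neighbor.  Preimages outside the fixed frame receive the background
    label 0 (counted in the log)."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ConfigError("annotation grid must be integer-labelled")
    hf, wf = t.fixed_domain
    if msi_shape is None:
        if hf % scaling or wf % scaling:
            raise ConfigError(
                "cannot infer the MSI grid: fixed domain is not a multiple of the "
                "scaling factor; pass msi_shape explicitly")
        msi_shape = (hf // scaling, wf // scaling)
    hm, wm = msi_shape
    xx, yy = np.meshgrid(np.arange(wm), np.arange(hm))
    centers = np.stack([xx.ravel(), yy.ravel()], axis=1) * scaling + (scaling - 1) / 2.0
    pre = t.inverse_points(centers)
    xi = np.round(pre[:, 0]).astype(np.int64)
    yi = np.round(pre[:, 1]).astype(np.int64)
    inside = (xi >= 0) & (xi < wf) & (yi >= 0) & (yi < hf)
    out = np.zeros(hm * wm, dtype=labels.dtype)
    out[inside] = labels[yi[inside], xi[inside]]
    n_out = int((~inside).sum())
    if n_out:
        log.info("%d MSI pixels fell outside the fixed frame; set to background", n_out)
    return out.reshape(hm, wm)
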