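"""Registration quality metrics.

Global accuracy: dice overlap of the tissue masks and normalized
cross-correlation (Pearson, over the union of tissue supports) of the
representative images.  Local accuracy: the determinant of the Jacobian of
the displacement field, det(I + ∇u), evaluated per pixel — values above 1
mean local expansion of the moving image, below 1 contraction, and
non-positive values mean folding (loss of invertibility).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DegenerateInputError, DimensionError
from .embed import RepresentativeImage
from .msi_io import TissueMask
from .register import DisplacementField, TransformModel, apply_transform, to_displacement_field

__all__ = ["MetricsReport", "dice", "ncc", "jacobian_determinant", "evaluate"]

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    dice_before: float
    dice_after: float
    ncc_before: float
    ncc_after: float
    jacobian_min: float
    jacobian_max: float
    jacobian_mean: float
    fraction_nonpositive_jacobian: float
    border_pixels_one_sided: int = 0

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def dice(a: TissueMask, b: TissueMask) -> float:
    """Dice overlap 2|a∩b| / (|a| + |b|); two empty masks score 1.0 (the
    degenerate case is logged rather than raised, keeping the evaluator
    total)."""
    if a.shape != b.shape:
        raise DimensionError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.area, b.area
    if na + nb == 0:
        log.info("dice of two empty masks: defined as 1.0")
        return 1.0
    inter = int((a.pixels & b.pixels).sum())
    return 2.0 * inter / (na + nb)


def ncc(a, b, support: TissueMask | None = None) -> float:
    """Pearson correlation of two images over the support pixels.

    Without an explicit support, the union of the two representative
    supports is used; zero-zero background matches would otherwise inflate
    the value.
    """
    pa = a.pixels if isinstance(a, RepresentativeImage) else np.asarray(a, dtype=np.float64)
    pb = b.pixels if isinstance(b, RepresentativeImage) else np.asarray(b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise DimensionError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    if support is None:
        sa = a.support.pixels if isinstance(a, RepresentativeImage) else np.ones(pa.shape, bool)
        sb = b.support.pixels if isinstance(b, RepresentativeImage) else np.ones(pb.shape, bool)
        sup = sa | sb
    else:
        if support.shape != pa.shape:
            raise DimensionError("support shape differs from the images")
        sup = support.pixels
    va, vb = pa[sup], pb[sup]
    if len(va) < 2 or va.std() == 0 or vb.std() == 0:
        raise DegenerateInputError("NCC needs >= 2 support pixels with nonzero variance")
    return float(np.corrcoef(va, vb)[0, 1])


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Per-pixel det(I + ∇u) by central differences (one-sided at borders)."""
    ux, uy = field.u[..., 0], field.u[..., 1]
    # gradient axes: 0 = y (rows), 1 = x (cols)
    dux_dy, dux_dx = np.gradient(ux)
    duy_dy, duy_dx = np.gradient(uy)
    return (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx


def evaluate(fixed_mask: TissueMask, moving_mask: TissueMask,
             fixed_rep: RepresentativeImage, moving_rep: RepresentativeImage,
             t: TransformModel) -> MetricsReport:
    """Before/after global metrics plus Jacobian summaries of the transform.

    "Before" compares the raw pair; "after" warps the moving mask and
    representative through ``t`` first.  Jacobian statistics are summarized
    over the fixed tissue mask only; the count of border pixels evaluated
    with one-sided differences is reported alongside.
    """
    d_before = dice(fixed_mask, moving_mask)
    c_before = ncc(fixed_rep, moving_rep)

    warped_mask = apply_transform(moving_mask, t, "nearest")
    warped_rep = apply_transform(moving_rep, t, "linear")
    d_after = dice(fixed_mask, warped_mask)
    c_after = ncc(fixed_rep, warped_rep)

    field = to_displacement_field(t)
    jac = jacobian_determinant(field)
    tissue = fixed_mask.pixels
    if not tissue.any():
        tissue = np.ones_like(jac, dtype=bool)
    jt = jac[tissue]
    border = np.zeros_like(tissue)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    return MetricsReport(
        dice_before=float(d_before), dice_after=float(d_after),
        ncc_before=float(c_before), ncc_after=float(c_after),
        jacobian_min=float(jt.min()), jacobian_max=float(jt.max()),
        jacobian_mean=float(jt.mean()),
        fraction_nonpositive_jacobian=float((jt <= 0).mean()),
        border_pixels_one_sided=int((tissue & border).sum()),
    )
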