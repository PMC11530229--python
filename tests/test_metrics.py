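import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msicoreg import (DegenerateInputError, DimensionError, DisplacementField,
                      PhantomSpec, TissueMask, TransformModel, dice, evaluate,
                      jacobian_determinant, make_phantom, ncc)
from msicoreg.embed import RepresentativeImage, he_representative


def mask_of(arr):
    return TissueMask(np.asarray(arr, dtype=np.uint8))


class TestDice:
    def test_identical_nonempty(self, rng):
        m = mask_of(rng.integers(0, 2, (10, 10)))
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6), np.uint8)
        b = np.zeros((6, 6), np.uint8)
        a[:3] = 1
        b[3:] = 1
        assert dice(mask_of(a), mask_of(b)) == 0.0

    def test_partial_overlap_brute_force(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a.ravel()[[0, 1, 2, 3]] = 1
        b.ravel()[[2, 3, 4, 5]] = 1
        assert dice(mask_of(a), mask_of(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = mask_of(np.zeros((5, 5)))
        assert dice(z, z) == 1.0

    def test_dim_mismatch(self):
        with pytest.raises(DimensionError):
            dice(mask_of(np.ones((4, 4))), mask_of(np.ones((5, 5))))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_fuzz_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = mask_of(rng.integers(0, 2, (8, 8)))
        b = mask_of(rng.integers(0, 2, (8, 8)))
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


class TestNCC:
    def test_self_is_one(self, rng):
        a = rng.random((12, 12))
        assert ncc(a, a) == pytest.approx(1.0)

    def test_inverted_is_minus_one(self, rng):
        a = rng.random((12, 12))
        assert ncc(a, 1.0 - a) == pytest.approx(-1.0)

    def test_affine_intensity_invariance(self, rng):
        a = rng.random((12, 12))
        assert ncc(a, 0.5 * a + 0.2) == pytest.approx(1.0)
        sup = mask_of(rng.integers(0, 2, (12, 12)) | 1)
        assert ncc(3 * a + 0.1, a, support=sup) == pytest.approx(1.0)

    def test_zero_variance_degenerate(self, rng):
        with pytest.raises(DegenerateInputError):
            ncc(np.full((6, 6), 0.5), rng.random((6, 6)))

    def test_support_restricts_computation(self, rng):
        a = rng.random((10, 10))
        b = a.copy()
        b[5:, :] = rng.random((5, 10))  # corrupt outside the support
        sup = np.zeros((10, 10), np.uint8)
        sup[:5] = 1
        assert ncc(a, b, support=mask_of(sup)) == pytest.approx(1.0)


class TestJacobian:
    def test_zero_field_unity(self):
        f = DisplacementField(np.zeros((8, 9, 2)))
        assert np.allclose(jacobian_determinant(f), 1.0)

    def test_linear_diagonal_field_closed_form(self):
        h, w = 12, 12
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        u = np.stack([0.1 * xx, 0.1 * yy], axis=2)
        jac = jacobian_determinant(DisplacementField(u))
        assert np.allclose(jac[1:-1, 1:-1], 1.21, atol=1e-9)

    def test_constructed_fold_detected(self):
        h, w = 20, 20
        xx, _ = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        # displacement reverses x ordering around the center column
        u = np.zeros((h, w, 2))
        u[..., 0] = -2.0 * (xx - w / 2) * np.exp(-((xx - w / 2) / 2.0) ** 2)
        jac = jacobian_determinant(DisplacementField(u))
        assert jac.min() <= 0

    @settings(max_examples=60, deadline=None)
    @given(st.tuples(*[st.floats(-0.5, 0.5) for _ in range(4)]))
    def test_constant_gradient_matches_closed_form(self, entries):
        a = np.array(entries).reshape(2, 2)
        h, w = 10, 11
        xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        pts = np.stack([xx, yy], axis=2)
        u = pts @ a.T
        jac = jacobian_determinant(DisplacementField(u))
        expected = np.linalg.det(np.eye(2) + a)
        assert np.allclose(jac[1:-1, 1:-1], expected, atol=1e-6)

    def test_pure_translation_unity(self):
        u = np.zeros((9, 9, 2))
        u[..., 0] = 4.2
        u[..., 1] = -1.7
        jac = jacobian_determinant(DisplacementField(u))
        assert np.allclose(jac, 1.0)


def _textured_rep(mask, seed):
    rng = np.random.default_rng(seed)
    vals = np.where(mask.pixels, rng.uniform(0.2, 1.0, mask.shape), 0.0)
    return RepresentativeImage(vals, mask)


class TestEvaluate:
    @pytest.fixture()
    def shifted_pair(self):
        ph = make_phantom(PhantomSpec(grid=(60, 60), warp=("translation", 5, 0),
                                      seed=3))
        fixed = he_representative(ph.he, ph.he_mask)
        moving = _textured_rep(ph.msi_mask, 8)
        return ph, fixed, moving

    def test_identity_before_equals_after(self, shifted_pair):
        ph, fixed, moving = shifted_pair
        rep = evaluate(ph.he_mask, ph.msi_mask, fixed, moving,
                       TransformModel.identity((60, 60)))
        assert rep.dice_before == rep.dice_after
        assert rep.ncc_before == pytest.approx(rep.ncc_after, abs=1e-12)
        assert rep.jacobian_min == rep.jacobian_max == 1.0

    def test_ground_truth_shift_improves_dice(self, shifted_pair):
        ph, fixed, moving = shifted_pair
        t = TransformModel("affine", (60, 60), np.eye(2), [5.0, 0.0])
        rep = evaluate(ph.he_mask, ph.msi_mask, fixed, moving, t)
        assert rep.dice_after > rep.dice_before

    def test_diffeomorphic_warp_no_folding(self):
        ph = make_phantom(PhantomSpec(grid=(60, 60), warp=("elastic", 4, 12),
                                      seed=9))
        jac = jacobian_determinant(ph.true_field)
        assert jac.min() > 0
        fixed = he_representative(ph.he, ph.he_mask)
        moving = _textured_rep(ph.msi_mask, 9)
        coefs_t = TransformModel.identity((60, 60))
        rep = evaluate(ph.he_mask, ph.msi_mask, fixed, moving, coefs_t)
        assert rep.fraction_nonpositive_jacobian == 0.0


@pytest.mark.parametrize("shape", [(30, 30)])
def test_jacobian_against_simpleitk(shape, rng):
    sitk = pytest.importorskip("SimpleITK")
    from scipy import ndimage

    u = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), 4),
                  ndimage.gaussian_filter(rng.standard_normal(shape), 4)], axis=2)
    u *= 2.0 / np.abs(u).max()
    mine = jacobian_determinant(DisplacementField(u))
    # SimpleITK expects (dx, dy) vectors on the same grid
    img = sitk.GetImageFromArray(u.astype(np.float64), isVector=True)
    ref = sitk.GetArrayFromImage(sitk.DisplacementFieldJacobianDeterminant(img))
    assert np.allclose(mine[1:-1, 1:-1], ref[1:-1, 1:-1], atol=1e-6)
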