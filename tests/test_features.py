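import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from msicoreg import (ConfigError, DegenerateInputError, MSIDataset, PhantomSpec,
                      SSCParams, make_phantom, preprocess_spectra, select_features,
                      ssc_segment)
from msicoreg.features import _shrunken_stats


def grid_dataset(intensities, w=None):
    n_feat, n_pix = intensities.shape
    w = w or n_pix
    coords = np.array([(i % w, i // w) for i in range(n_pix)])
    mz = 100.0 + np.arange(n_feat)
    return MSIDataset(coords, mz, np.asarray(intensities, np.float32))


class TestPreprocess:
    def test_tic_normalization_definition(self, rng):
        d = grid_dataset(rng.random((10, 20)) + 0.1, w=5)
        out = preprocess_spectra(d, normalize="tic", peak_snr=0.0)
        sums = out.intensities.sum(axis=0)
        mean_tic = d.intensities.sum(axis=0).mean()
        assert np.allclose(sums, mean_tic, rtol=1e-6)

    def test_all_zero_spectrum_left_zero_with_warning(self, rng):
        arr = rng.random((5, 8)) + 0.1
        arr[:, 3] = 0.0
        d = grid_dataset(arr, w=4)
        with pytest.warns(UserWarning):
            out = preprocess_spectra(d, normalize="tic", peak_snr=0.0)
        assert np.all(out.intensities[:, 3] == 0)

    def test_single_gaussian_peak_on_flat_floor_gives_one_peak(self, rng):
        # bounded uniform ripple: its largest excursion is ~1.35 sigma-hat,
        # far below the detection threshold, so only the real peak survives
        n_mz, n_pix = 120, 10
        mz_idx = np.arange(n_mz)
        noise_amp = 0.05
        floor = 1.0 + rng.uniform(-noise_amp, noise_amp, (n_mz, n_pix))
        sigma_hat = 1.4826 * noise_amp / 2  # MAD of U(-a, a) is a/2
        peak = 10 * sigma_hat * np.exp(-0.5 * ((mz_idx - 60) / 2.0) ** 2)
        d = grid_dataset(floor + peak[:, None], w=5)
        out = preprocess_spectra(d, normalize="none", peak_snr=3.0)
        assert out.n_features == 1
        assert out.mz_axis[0] == d.mz_axis[60]

    def test_infinite_snr_errors(self, rng):
        d = grid_dataset(rng.random((10, 4)) + 0.1, w=2)
        with pytest.raises(DegenerateInputError):
            preprocess_spectra(d, normalize="none", peak_snr=np.inf)

    def test_peak_binning_merges_neighbors(self, rng):
        n_mz = 60
        spec = np.full(n_mz, 1.0)
        spec[[20, 22, 40]] = [5.0, 4.0, 6.0]
        d = grid_dataset(np.tile(spec[:, None], (1, 4)) +
                         rng.uniform(-0.01, 0.01, (n_mz, 4)), w=2)
        out = preprocess_spectra(d, normalize="none", peak_snr=3.0, bin_tol=3.0)
        # peaks at mz 120 and 122 merge (within 3 Da), 140 stays
        assert out.n_features == 2


class TestSSC:
    def test_phantom_segmentation_and_feature_recovery(self, default_phantom):
        ph = default_phantom
        res = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=2.0, seed=42))
        ari = adjusted_rand_score(ph.pixel_labels, res.labels)
        assert ari > 0.9
        assert set(ph.informative) <= set(res.selected)

    def test_zero_shrinkage_centroids_equal_segment_means(self, default_phantom):
        ph = default_phantom
        res = ssc_segment(ph.msi, SSCParams(k=3, r=0.0, s=0.0, seed=42))
        x = ph.msi.intensities.T.astype(float)
        for c in range(res.k_effective):
            sel = res.labels == c + 1
            assert np.allclose(res.centroids[c], x[sel].mean(axis=0), atol=1e-8)

    def test_shrinkage_above_all_tstats_kills_everything(self, default_phantom):
        ph = default_phantom
        base = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=0.0, seed=42))
        s_max = np.abs(base.tstats).max() + 1.0
        res = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=s_max, seed=42))
        assert np.all(res.tstats == 0)
        assert np.all(res.feature_scores == 0)
        x = ph.msi.intensities.T.astype(float)
        assert np.allclose(res.centroids, x.mean(axis=0)[None, :], atol=1e-8)
        with pytest.raises(DegenerateInputError):
            select_features(res)

    def test_reduces_to_nearest_centroid_with_r0_s0(self, rng):
        # independent oracle: k-means init then one plain standardized
        # nearest-centroid assignment, written out longhand
        from sklearn.cluster import KMeans

        n_pix, n_feat, k = 150, 8, 3
        x = rng.random((n_feat, n_pix)).astype(np.float32)
        x[:3, :50] += 2.0
        x[3:6, 50:100] += 2.0
        d = grid_dataset(x, w=15)
        res = ssc_segment(d, SSCParams(k=k, r=0.0, s=0.0, max_iter=1, seed=0))

        xt = x.T.astype(float)
        mu, sd = xt.mean(0), xt.std(0)
        xz = (xt - mu) / np.where(sd > 0, sd, 1)
        init = KMeans(n_clusters=k, random_state=0, n_init=10).fit_predict(xz)
        cents = np.stack([xt[init == c].mean(0) for c in range(k)])
        resid = sum(((xt[init == c] - cents[c]) ** 2).sum(0) for c in range(k))
        sj = np.sqrt(resid / (n_pix - k))
        s0 = np.median(sj)
        expected = np.argmin(
            ((xt[:, None, :] - cents[None]) ** 2 / (sj + s0) ** 2).sum(2), axis=1) + 1
        assert np.array_equal(res.labels, expected)

    def test_selection_monotone_in_shrinkage(self, default_phantom):
        ph = default_phantom
        base = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=0.0, seed=42))
        x = ph.msi.intensities.T.astype(float)
        sel_prev = None
        for s in (0.5, 1.5, 3.0, 6.0):
            _, tstats, _, _ = _shrunken_stats(x, base.labels, base.k_effective, s)
            sel = set(np.flatnonzero(np.abs(tstats).max(axis=0) > 0))
            if sel_prev is not None:
                assert sel <= sel_prev
            sel_prev = sel

    def test_permuted_feature_loses_its_score(self, default_phantom, rng):
        ph = default_phantom
        feat = int(ph.informative[0])
        inten = ph.msi.intensities.copy()
        inten[feat] = rng.permutation(inten[feat])
        d = MSIDataset(ph.msi.coords, ph.msi.mz_axis, inten)
        res = ssc_segment(d, SSCParams(k=3, r=2.0, s=2.0, seed=42))
        assert feat not in set(res.selected)

    def test_k_exceeding_pixels_errors(self, rng):
        d = grid_dataset(rng.random((3, 4)).astype(np.float32), w=2)
        with pytest.raises(ConfigError):
            ssc_segment(d, SSCParams(k=10))


class TestSelectFeatures:
    def test_top_n_returns_highest_scoring_informative(self, default_phantom):
        ph = default_phantom
        res = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=2.0, seed=42))
        top = select_features(res, top_n=1)
        assert len(top) == 1
        assert top[0] in set(ph.informative)
        assert res.feature_scores[top[0]] == res.feature_scores.max()

    def test_top_n_truncation_warns(self, default_phantom):
        ph = default_phantom
        res = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=2.0, seed=42))
        with pytest.warns(UserWarning):
            sel = select_features(res, top_n=10_000)
        assert len(sel) == res.selected.size

    def test_scores_sorted_descending(self, default_phantom):
        ph = default_phantom
        res = ssc_segment(ph.msi, SSCParams(k=3, r=2.0, s=2.0, seed=42))
        scores = res.feature_scores[select_features(res)]
        assert np.all(np.diff(scores) <= 0)
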