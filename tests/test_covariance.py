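"""Covariance tensor construction, t-maps and band averaging."""

import numpy as np
import pytest

from covmap.covariance import (
    BandPartition,
    CovarianceTensor,
    band_average,
    covariance_map,
    covariance_tensor,
    reference_bands,
    tmap,
)
from covmap.dynamics import RSNDynamics, T_SENTINEL
from covmap.spectra import SpectralEpochSet, normalize_spectra
from covmap.synthetic import default_bin_freqs


def make_spectra(amp, valid=None, normalized=True):
    return SpectralEpochSet(
        amp, bin_freqs=np.arange(1.0, amp.shape[2] + 1), valid=valid,
        normalized=normalized,
    )


class TestCovarianceMap:
    def test_self_product_identity(self, rng):
        act = rng.standard_normal((1, 6))
        amp = np.repeat(act[0][:, None, None], 3, axis=1)  # every channel = activity
        amp = np.repeat(amp, 2, axis=2)
        cov = covariance_map(make_spectra(amp), RSNDynamics(act))
        np.testing.assert_allclose(cov, np.sum(act[0] ** 2), rtol=1e-12)

    def test_orthogonal_series_give_zero(self):
        act = np.array([[1.0, -1.0, 1.0, -1.0]])
        amp = np.ones((4, 2, 1))  # constant across time, orthogonal to act
        cov = covariance_map(make_spectra(amp), RSNDynamics(act))
        np.testing.assert_allclose(cov, 0.0, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        n_t, n_c, n_f, n_r = 5, 4, 3, 2
        amp = rng.standard_normal((n_t, n_c, n_f))
        act = rng.standard_normal((n_r, n_t))
        cov = covariance_map(make_spectra(amp), RSNDynamics(act))
        for r in range(n_r):
            for f in range(n_f):
                for c in range(n_c):
                    expected = sum(amp[t, c, f] * act[r, t] for t in range(n_t))
                    assert cov[r, f, c] == pytest.approx(expected, rel=1e-12)

    def test_invalid_pairs_dropped_pairwise(self, rng):
        amp = rng.standard_normal((6, 3, 2))
        act = rng.standard_normal((2, 6))
        valid = np.array([True, False, True, True, False, True])
        cov = covariance_map(make_spectra(amp, valid), RSNDynamics(act))
        oracle = covariance_map(
            make_spectra(amp[valid]), RSNDynamics(act[:, valid])
        )
        np.testing.assert_allclose(cov, oracle, rtol=1e-12)

    def test_unnormalized_spectra_rejected(self, rng):
        amp = rng.standard_normal((5, 3, 2))
        with pytest.raises(ValueError, match="normalized"):
            covariance_map(
                make_spectra(amp, normalized=False),
                RSNDynamics(rng.standard_normal((2, 5))),
            )

    def test_bilinearity(self, rng):
        amp1, amp2 = rng.standard_normal((2, 5, 3, 2))
        act = rng.standard_normal((2, 5))
        c1 = covariance_map(make_spectra(amp1), RSNDynamics(act))
        c2 = covariance_map(make_spectra(amp2), RSNDynamics(act))
        c12 = covariance_map(make_spectra(2.0 * amp1 + 3.0 * amp2), RSNDynamics(act))
        np.testing.assert_allclose(c12, 2.0 * c1 + 3.0 * c2, rtol=1e-10)

    def test_shared_time_permutation_invariance(self, rng):
        amp = rng.standard_normal((6, 3, 2))
        act = rng.standard_normal((2, 6))
        perm = rng.permutation(6)
        c1 = covariance_map(make_spectra(amp), RSNDynamics(act))
        c2 = covariance_map(make_spectra(amp[perm]), RSNDynamics(act[:, perm]))
        np.testing.assert_allclose(c1, c2, rtol=1e-12)


class TestTMap:
    def test_hand_computed_t(self):
        subj = np.array([0.5, 0.7, 0.9, 1.1, 1.3])
        cov = CovarianceTensor(
            subj[:, None, None, None], freq_labels=np.array([1.0])
        )
        out = tmap(cov)
        assert out.t[0, 0, 0] == pytest.approx(6.3640, abs=1e-4)

    def test_antisymmetric_values_give_zero(self):
        cov = CovarianceTensor(
            np.array([-2.0, 2.0])[:, None, None, None], freq_labels=np.array([1.0])
        )
        assert tmap(cov).t[0, 0, 0] == 0.0

    def test_identical_nonzero_values_hit_sentinel(self):
        cov = CovarianceTensor(
            np.full((4, 1, 1, 1), 3.0), freq_labels=np.array([1.0])
        )
        out = tmap(cov)
        assert out.t[0, 0, 0] == T_SENTINEL
        assert out.degenerate[0, 0, 0]

    def test_single_subject_rejected(self):
        cov = CovarianceTensor(np.ones((1, 1, 1, 1)), freq_labels=np.array([1.0]))
        with pytest.raises(ValueError):
            tmap(cov)


class TestBandAverage:
    @pytest.fixture
    def partition(self):
        return BandPartition(
            names=("low", "mid", "high"),
            bounds=((0.0, 2.0), (2.0, 4.0), (4.0, 6.0)),
            bin_slices=((0, 1), (1, 3), (3, 6)),
        )

    def test_single_bin_band_is_identity(self, rng, partition):
        vals = rng.standard_normal((3, 2, 6, 4))
        cov = CovarianceTensor(vals, freq_labels=np.arange(1.0, 7.0))
        out = band_average(cov, partition)
        np.testing.assert_array_equal(out.values[:, :, 0, :], vals[:, :, 0, :])

    def test_two_point_mean(self, partition):
        vals = np.zeros((2, 1, 6, 1))
        vals[:, :, 1, :] = 1.0
        vals[:, :, 2, :] = 3.0
        cov = CovarianceTensor(vals, freq_labels=np.arange(1.0, 7.0))
        out = band_average(cov, partition)
        assert out.values[0, 0, 1, 0] == pytest.approx(2.0)

    def test_size_weighted_band_mean_equals_all_bin_mean(self, rng, partition):
        vals = rng.standard_normal((3, 2, 6, 4))
        cov = CovarianceTensor(vals, freq_labels=np.arange(1.0, 7.0))
        out = band_average(cov, partition)
        sizes = np.array([1, 2, 3])
        weighted = (out.values * sizes[None, None, :, None]).sum(axis=2) / 6
        np.testing.assert_allclose(weighted, vals.mean(axis=2), rtol=1e-10)

    def test_gapped_partition_rejected(self, rng):
        with pytest.raises(ValueError, match="contiguous"):
            BandPartition(
                names=("a", "b"),
                bounds=((0.0, 2.0), (2.0, 4.0)),
                bin_slices=((0, 2), (3, 6)),
            )

    def test_partition_not_covering_bins_rejected(self, rng, partition):
        vals = rng.standard_normal((2, 2, 7, 3))
        cov = CovarianceTensor(vals, freq_labels=np.arange(1.0, 8.0))
        with pytest.raises(ValueError, match="cover"):
            band_average(cov, partition)


class TestReferenceBands:
    def test_borders_and_coverage(self):
        freqs = default_bin_freqs()
        p = reference_bands(freqs)
        assert p.names == (
            "delta", "theta1", "theta2", "alpha1", "alpha2", "beta1", "beta2", "beta3",
        )
        # every retained bin in exactly one band
        assert p.bin_slices[0][0] == 0 and p.bin_slices[-1][1] == 75
        # nominal upper edges
        uppers = [hi for _, hi in p.bounds]
        assert uppers == [3.5, 6.25, 8.2, 10.5, 14.0, 18.75, 21.88, 30.0]
        # highest delta bin center <= 3.5 Hz < lowest theta1 center
        assert freqs[p.member_bins("delta")[-1]] <= 3.5 < freqs[p.member_bins("theta1")[0]]
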