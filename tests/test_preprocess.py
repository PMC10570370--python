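"""Peak filters, replicate consensus, recalibration, cleanup filters."""

import numpy as np
import pytest

from c2netms.preprocess import (
    Spectrum,
    filter_peaks,
    flag_c13_isotopologues,
    recalibrate,
    remove_34S_isotopes,
    remove_wiggle_artifacts,
    replicate_consensus,
)


def spec(peaks, timepoint=2.0, replicate=0, channel="unlabeled"):
    peaks = sorted(peaks)
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    sn = np.array([p[2] for p in peaks], dtype=float)
    return Spectrum(mz, inten, sn, timepoint, replicate, channel)


class TestFilterPeaks:
    def test_boundaries(self):
        s = spec([(150, 10, 5), (121, 10, 5), (900, 10, 4.0),
                  (200.0, 100, 3.99), (121.99, 100, 10), (1000.0, 5, 9)])
        out = filter_peaks(s)
        assert out.mz.tolist() == [150.0, 900.0, 1000.0]

    def test_sn_exactly_four_kept(self):
        out = filter_peaks(spec([(500, 1, 4.0)]))
        assert len(out) == 1

    def test_idempotent(self):
        s = spec([(150, 10, 5), (121, 10, 5), (200, 1, 2)])
        once = filter_peaks(s)
        twice = filter_peaks(once)
        assert np.array_equal(once.mz, twice.mz)


class TestReplicateConsensus:
    def three(self, present):
        """Three replicates; a marker peak at 300.0 in the given subset."""
        reps = []
        for r in range(3):
            peaks = [(200.0, 50, 10)]
            if r in present:
                peaks.append((300.0, 100 + 10 * r, 10))
            reps.append(spec(peaks, replicate=r))
        return reps

    def test_two_of_three_kept(self):
        cpl = replicate_consensus(self.three({0, 1}), tol_ppm=1.0)
        assert any(abs(m - 300.0) < 1e-3 for m in cpl.mz)

    def test_one_of_three_removed(self):
        cpl = replicate_consensus(self.three({2}), tol_ppm=1.0)
        assert not any(abs(m - 300.0) < 1e-3 for m in cpl.mz)

    def test_mean_intensity_over_contributors(self):
        reps = [spec([(300.0, 90, 10)], replicate=0),
                spec([(300.0, 110, 10)], replicate=1),
                spec([(200.0, 5, 10)], replicate=2)]
        cpl = replicate_consensus(reps, tol_ppm=1.0)
        assert cpl.intensity[np.argmin(np.abs(cpl.mz - 300))] == pytest.approx(100.0)

    def test_permutation_invariant(self):
        reps = self.three({0, 1})
        a = replicate_consensus(reps, tol_ppm=1.0)
        b = replicate_consensus(reps[::-1], tol_ppm=1.0)
        assert np.array_equal(a.mz, b.mz)
        assert np.array_equal(a.intensity, b.intensity)

    def test_mixed_channels_rejected(self):
        reps = self.three({0, 1})
        reps[1].channel = "13CO"
        with pytest.raises(ValueError):
            replicate_consensus(reps)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_consensus(self.three({0})[:1])


class TestRecalibrate:
    def test_identity_for_exact_calibrants(self):
        s = spec([(200, 1, 10), (400, 1, 10)])
        out, resid = recalibrate(s, [(150.0, 150.0), (350.0, 350.0), (800.0, 800.0)])
        assert out.mz == pytest.approx(s.mz)
        assert np.max(np.abs(resid)) < 1e-9

    def test_corrects_affine_distortion(self):
        true_mz = np.array([150.0, 300.0, 600.0, 900.0])
        distorted = true_mz * (1 + 2e-7) + 1e-4
        s = Spectrum(distorted, np.ones(4), np.ones(4) * 10, 2.0, 0, "unlabeled")
        out, resid = recalibrate(s, list(zip(distorted, true_mz)))
        assert np.max(np.abs(resid)) < 0.01  # ppm
        assert out.mz == pytest.approx(true_mz, abs=1e-8)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            recalibrate(spec([(200, 1, 10)]), [(150.0, 150.0)])


class TestRemove34S:
    def test_matching_satellite_removed(self):
        s = spec([(300.0, 1000, 100), (301.99580, 42, 5)])
        out, log = remove_34S_isotopes(s)
        assert out.mz.tolist() == [300.0]
        assert len(log) == 1

    def test_satellite_outside_band_kept(self):
        s = spec([(300.0, 1000, 100), (301.99580, 500, 50)])
        out, _ = remove_34S_isotopes(s)
        assert len(out) == 2

    def test_no_partner_unchanged(self):
        s = spec([(300.0, 1000, 100), (350.0, 900, 90)])
        out, log = remove_34S_isotopes(s)
        assert len(out) == 2 and len(log) == 0

    def test_idempotent(self):
        s = spec([(300.0, 1000, 100), (301.99580, 42, 5)])
        once, _ = remove_34S_isotopes(s)
        twice, log = remove_34S_isotopes(once)
        assert np.array_equal(once.mz, twice.mz) and len(log) == 0


class TestRemoveWiggles:
    def test_small_satellite_removed(self):
        s = spec([(300.0, 10000, 100), (300.004, 50, 5)])
        out, log = remove_wiggle_artifacts(s)
        assert out.mz.tolist() == [300.0] and len(log) == 1

    def test_five_percent_satellite_kept(self):
        s = spec([(300.0, 10000, 100), (300.004, 500, 5)])
        out, _ = remove_wiggle_artifacts(s)
        assert len(out) == 2

    def test_isolated_peak_kept(self):
        s = spec([(300.0, 10, 5)])
        out, _ = remove_wiggle_artifacts(s)
        assert len(out) == 1

    def test_idempotent(self):
        s = spec([(300.0, 10000, 100), (300.004, 50, 5), (500.0, 10, 5)])
        once, _ = remove_wiggle_artifacts(s)
        twice, log = remove_wiggle_artifacts(once)
        assert np.array_equal(once.mz, twice.mz) and len(log) == 0


def test_flag_c13_isotopologues():
    mz = np.array([300.0, 301.003355, 302.5])
    inten = np.array([1000.0, 50.0, 800.0])
    mask = flag_c13_isotopologues(mz, inten)
    assert mask.tolist() == [False, True, False]


def test_spectrum_rejects_unsorted_or_duplicate_mz():
    with pytest.raises(ValueError):
        Spectrum(np.array([2.0, 1.0]), np.ones(2), np.ones(2), 2.0, 0, "unlabeled")
    with pytest.raises(ValueError):
        Spectrum(np.array([1.0, 1.0 + 1e-7]), np.ones(2), np.ones(2), 2.0, 0, "unlabeled")
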