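"""13C labelling-degree calls and mixed-annotation statistics."""

import numpy as np
import pytest

from c2netms.annotate import Annotation
from c2netms.chem import DELTA_13C, IonType, ion_mz, parse_formula
from c2netms.labeling import (
    classify_label_degrees,
    cross_channel_check,
    expected_natural_fraction,
    mixed_fraction,
)
from c2netms.preprocess import ConsensusPeakList


class TestExpectedNaturalFraction:
    def test_linear_rule_for_single_label(self):
        assert expected_natural_fraction(10, 1) == pytest.approx(0.10)

    def test_degree_zero_is_unity(self):
        assert expected_natural_fraction(5, 0) == 1.0

    def test_binomial_for_higher_degrees(self):
        assert expected_natural_fraction(10, 2) == pytest.approx(0.00415, abs=5e-6)

    def test_degree_above_carbon_count_rejected(self):
        with pytest.raises(ValueError):
            expected_natural_fraction(3, 4)


def _cpl(peaks, channel="unlabeled"):
    mz = np.array(sorted(p[0] for p in peaks))
    inten = np.array([i for _, i in sorted(peaks)])
    return ConsensusPeakList(mz, inten, np.ones(mz.size), timepoint=168.0,
                             channel=channel)


def make_channels(formula, mono_intensity, labelled_peaks):
    """Unlabelled channel with the mono peak; labelled channel as given
    (shift k -> intensity).  Total intensities padded to be equal, so the
    per-channel normalization drops out of the expected arithmetic."""
    comp = parse_formula(formula)
    mono = ion_mz(comp)
    unlab = [(mono, mono_intensity), (900.0, 5000.0)]
    lab = [(mono + k * DELTA_13C, i) for k, i in labelled_peaks.items()]
    pad = sum(i for _, i in unlab) - sum(i for _, i in lab)
    lab.append((950.0, pad))
    ann = Annotation(comp, IonType.DEPROTONATED, mono, 0.0)
    return ann, _cpl(unlab), _cpl(lab, "13CO")


class TestClassifyLabelDegrees:
    def test_doubling_rule_calls_degree_one(self):
        # c = 5: threshold = 2 * (0.01 * 5) * 1000 = 100
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {1: 120.0})
        assert classify_label_degrees(ann, unlab, lab) == {1}

    def test_below_threshold_not_called(self):
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {1: 99.0})
        assert 1 not in classify_label_degrees(ann, unlab, lab)

    def test_no_labelled_peaks_empty_set(self):
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {})
        assert classify_label_degrees(ann, unlab, lab) == set()

    def test_degree_zero_called_for_retained_mono_peak(self):
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {0: 1000.0})
        assert 0 in classify_label_degrees(ann, unlab, lab)

    def test_natural_satellite_of_called_degree_not_called(self):
        """The labelled species' own M+1 must not masquerade as degree k+1."""
        ann, unlab, lab = make_channels(
            "C10H14O3", 1000.0, {2: 1000.0, 3: 1000.0 * 0.011 * 8})
        degrees = classify_label_degrees(ann, unlab, lab)
        assert degrees == {2}

    def test_scale_invariance(self):
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {1: 120.0, 2: 30.0})
        base = classify_label_degrees(ann, unlab, lab)
        unlab2 = ConsensusPeakList(unlab.mz, unlab.intensity * 7.3,
                                   unlab.presence_fraction, 168.0, "unlabeled")
        lab2 = ConsensusPeakList(lab.mz, lab.intensity * 7.3,
                                 lab.presence_fraction, 168.0, "13CO")
        assert classify_label_degrees(ann, unlab2, lab2) == base

    def test_raising_labelled_intensity_never_removes_calls(self):
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {1: 120.0})
        base = classify_label_degrees(ann, unlab, lab)
        lab_hi = ConsensusPeakList(lab.mz, lab.intensity * 3.0,
                                   lab.presence_fraction, 168.0, "13CO")
        assert base <= classify_label_degrees(ann, unlab, lab_hi)

    def test_missing_reference_peak_is_an_error(self):
        ann, unlab, lab = make_channels("C5H8O2", 1000.0, {1: 120.0})
        empty = _cpl([(900.0, 10.0)])
        with pytest.raises(ValueError):
            classify_label_degrees(ann, empty, lab)


def _ann(formula, degrees):
    a = Annotation(parse_formula(formula), IonType.DEPROTONATED, 100.0, 0.0)
    a.label_degrees = set(degrees)
    return a


class TestMixedFraction:
    def test_counting(self):
        anns = [_ann(f"C{4+2*i}H{6+2*i}O3", {1}) for i in range(8)]
        anns += [_ann("C20H22O3", {1, 2}), _ann("C22H24O3", {1, 2})]
        tbl = mixed_fraction(anns)
        row = tbl[(tbl.o_count == 3) & (tbl.s_count == 0)].iloc[0]
        assert row.pct_mixed == pytest.approx(20.0)
        assert row.pct_mixed + row.pct_pure == pytest.approx(100.0)

    def test_all_single_degree_is_pure(self):
        tbl = mixed_fraction([_ann("C4H6O2", {1}), _ann("C6H8O2", {2})])
        assert (tbl.pct_mixed == 0).all()

    def test_recovers_injected_isomer_fraction(self):
        """Pipeline mixed percentage tracks the generator's true mixed rate."""
        from c2netms.pipeline import RunConfig, run_pipeline
        from c2netms.simulate import SimulationConfig
        sim = SimulationConfig(random_seed=21, mixed_isomer_fraction=0.3)
        res = run_pipeline(RunConfig(simulation=sim, random_seed=21))
        truth: dict = {}
        for m in res.molecules:
            truth.setdefault(m.composition, set()).add(m.n_co_carbons)
        annotated = {a.composition.neutral() for a in res.annotations}
        true_rate = 100.0 * np.mean([len(truth[c]) > 1 for c in annotated & set(truth)])
        called = [a for a in res.annotations if a.label_degrees
                  and a.composition.neutral() in truth]
        got_rate = 100.0 * np.mean([len(a.label_degrees) > 1 for a in called])
        assert got_rate == pytest.approx(true_rate, abs=5.0)


class TestCrossChannelCheck:
    @pytest.mark.parametrize(
        "co,acet,ok",
        [({0}, {4}, True), ({1}, {3}, True), ({1}, {1}, False), (set(), {4}, False)],
    )
    def test_closure(self, co, acet, ok):
        ann = _ann("C4H6O2", co)
        assert cross_channel_check(ann, co, acet) is ok

    def test_closure_confirmed_in_pipeline(self, noiseless_result):
        """On clean data most annotated molecules satisfy k_CO + k_C2H2 = c."""
        res = noiseless_result
        true_comps = {m.composition for m in res.molecules}
        flags = [ok for f, ok in res.closure_confirmed.items()
                 if parse_formula(f) in true_comps]
        assert np.mean(flags) >= 0.9
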