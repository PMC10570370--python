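"""Formula assignment: brute-force oracle and network propagation."""

import numpy as np
import pytest

from c2netms.annotate import (
    Annotation,
    ElementBounds,
    brute_force_assign,
    detect_na_adducts,
    filter_annotations,
    mdn_assign,
)
from c2netms.chem import IonType, TRANSFORMATIONS, ion_mz, parse_formula
from c2netms.preprocess import ConsensusPeakList


def peaklist(mzs, intensities=None):
    mzs = np.sort(np.asarray(mzs, dtype=float))
    if intensities is None:
        intensities = np.full(mzs.size, 100.0)
    return ConsensusPeakList(mzs, np.asarray(intensities, dtype=float),
                             np.ones(mzs.size), timepoint=-1.0, channel="unlabeled")


class TestBruteForce:
    def test_acetic_acid_is_top_candidate(self):
        cands = brute_force_assign(59.01385, IonType.DEPROTONATED, tol_ppm=0.5)
        assert str(cands[0].composition) == "C2H4O2"

    def test_exact_synthetic_mass_yields_unique_candidate(self):
        comp = parse_formula("C7H10O3S")
        cands = brute_force_assign(ion_mz(comp), tol_ppm=0.01)
        assert [c.composition for c in cands] == [comp]

    def test_wide_tolerance_candidates_sorted_by_error(self):
        cands = brute_force_assign(150.0, tol_ppm=50.0)
        assert len(cands) > 1
        errs = [abs(c.error_ppm) for c in cands]
        assert errs == sorted(errs)

    def test_ratio_prefilter_is_optional(self):
        comp = parse_formula("C2H6O")  # H/C = 3.0
        mz = ion_mz(comp)
        assert any(c.composition == comp for c in brute_force_assign(mz, tol_ppm=0.5))
        filtered = brute_force_assign(mz, tol_ppm=0.5, apply_ratio_filters=True)
        assert all(c.composition != comp for c in filtered)


class TestMdnAssign:
    def test_propagates_across_one_acetylene_step(self):
        seed_comp = parse_formula("C2H4O2")
        pl = peaklist([59.01385, 85.02950])
        seeds = [Annotation(seed_comp, IonType.DEPROTONATED, 59.01385, 0.0)]
        anns = mdn_assign(pl, seeds, TRANSFORMATIONS, tol_ppm=0.5)
        by_formula = {a.formula: a for a in anns}
        assert set(by_formula) == {"C2H4O2", "C4H6O2"}
        assert by_formula["C4H6O2"].path[-1] == "+acetylene_addition"

    def test_unreachable_peak_stays_unannotated(self):
        pl = peaklist([59.01385, 500.0])
        seeds = [Annotation(parse_formula("C2H4O2"), IonType.DEPROTONATED, 59.01385, 0.0)]
        anns = mdn_assign(pl, seeds, TRANSFORMATIONS, tol_ppm=0.5)
        assert all(abs(a.observed_mz - 500.0) > 1 for a in anns)

    def test_missing_seed_peak_is_an_error(self):
        pl = peaklist([100.0])
        seeds = [Annotation(parse_formula("C2H4O2"), IonType.DEPROTONATED, 59.01385, 0.0)]
        with pytest.raises(ValueError):
            mdn_assign(pl, seeds)

    def test_propagation_soundness(self, noiseless_result):
        """Theoretical m/z of every propagated composition matches its peak."""
        tol = noiseless_result.config.assign_tol_ppm
        for a in noiseless_result.annotations:
            theo = ion_mz(a.composition, a.ion)
            assert abs(a.observed_mz - theo) / theo * 1e6 <= tol


def test_oracle_equivalence_on_noiseless_run(noiseless_result):
    """Network assignment reproduces the brute-force oracle on true peaks."""
    res = noiseless_result
    true_comps = {m.composition for m in res.molecules}
    checked = agree = 0
    for a in res.annotations:
        if a.composition.neutral() not in true_comps:
            continue
        checked += 1
        cands = brute_force_assign(
            a.observed_mz, a.ion, tol_ppm=res.config.assign_tol_ppm,
            bounds=res.config.bounds, apply_ratio_filters=True,
        )
        if cands and cands[0].composition == a.composition.neutral():
            agree += 1
    assert checked > 50
    assert agree / checked >= 0.99


class TestFilterAnnotations:
    @pytest.mark.parametrize(
        "formula,kept",
        [
            ("C2H6O", False),    # H/C = 3.0
            ("C2H4O4", False),   # O/C = 2.0
            ("C10H14O3", True),  # (1.4, 0.3)
            ("C2H5O", True),     # H/C = 2.5 boundary kept
            ("C100H251O2", False),  # H/C = 2.51
            ("C2H4O3", False),   # O/C = 1.5 boundary removed
        ],
    )
    def test_ratio_window(self, formula, kept):
        ann = Annotation(parse_formula(formula), IonType.DEPROTONATED, 100.0, 0.0)
        assert (len(filter_annotations([ann])) == 1) is kept


def test_na_adduct_detection():
    comp = parse_formula("C4H6O4")
    mono = ion_mz(comp)
    adduct = ion_mz(comp, IonType.SODIATED_DEPROTONATED)
    ann = Annotation(comp, IonType.DEPROTONATED, mono, 0.0)
    flagged = detect_na_adducts([ann], peaklist([mono, adduct]), tol_ppm=0.5)
    assert flagged[0].has_na_adduct
    ann2 = Annotation(comp, IonType.DEPROTONATED, mono, 0.0)
    unflagged = detect_na_adducts([ann2], peaklist([mono]), tol_ppm=0.5)
    assert not unflagged[0].has_na_adduct


def test_brute_force_bounds_respected():
    cands = brute_force_assign(500.0, tol_ppm=20.0,
                               bounds=ElementBounds(c=10, h=20, o=2, s=0, na=0))
    for c in cands:
        comp = c.composition
        assert comp.c <= 10 and comp.h <= 20 and comp.o <= 2
        assert comp.s == 0 and comp.na == 0
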