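"""Ground-truth generator: network growth, temporal structure, rendering."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from c2netms.chem import DELTA_13C, TRANSFORMATIONS_BY_NAME, parse_formula
from c2netms.simulate import (
    GroundTruthMolecule,
    SimulationConfig,
    assign_temporal_profiles,
    read_ground_truth,
    render_spectra,
    simulate_reaction_network,
    temporal_kernel,
    write_ground_truth,
)


def _zero_probs():
    return {name: 0.0 for name in TRANSFORMATIONS_BY_NAME}


def test_zero_generations_returns_exactly_the_seeds():
    cfg = SimulationConfig(n_generations=0)
    mols = simulate_reaction_network(cfg)
    assert {(str(m.composition), m.n_co_carbons) for m in mols} == {
        ("C2H4O", 0), ("C3H4O2", 1), ("C2H4OS", 0),
    }


def test_zero_probabilities_equal_zero_generations():
    cfg = SimulationConfig(n_generations=5, transformation_probabilities=_zero_probs())
    assert len(simulate_reaction_network(cfg)) == len(SimulationConfig().seeds)


def test_pure_acetylene_growth_is_the_homologous_series():
    """C2H4O under guaranteed C2H2 addition alone grows by one C2 per generation."""
    probs = _zero_probs() | {"acetylene_addition": 1.0}
    cfg = SimulationConfig(seeds=(("C2H4O", 0),), n_generations=3,
                           transformation_probabilities=probs)
    mols = simulate_reaction_network(cfg)
    assert {str(m.composition) for m in mols} == {"C2H4O", "C4H6O", "C6H8O", "C8H10O"}
    assert all(m.n_co_carbons == 0 for m in mols)


def test_compositions_derive_from_seed_plus_history():
    cfg = SimulationConfig(random_seed=3)
    mols = simulate_reaction_network(cfg)
    seeds = {str(parse_formula(f)): (parse_formula(f), k) for f, k in cfg.seeds}
    for m in mols:
        if not m.synthesis_history:
            continue
        # walk the recorded history backwards to land on some seed
        comp = m.composition
        n_co = m.n_co_carbons
        for step in reversed(m.synthesis_history):
            if step == "isomer_variant":
                continue
            comp = comp - TRANSFORMATIONS_BY_NAME[step].delta
            if step.startswith("carbonylation"):
                n_co -= 1
        assert (comp, n_co) in seeds.values()


def test_carbonylation_counts_co_carbons():
    probs = _zero_probs() | {"carbonylation_h2o": 1.0}
    cfg = SimulationConfig(seeds=(("C2H4O", 0),), n_generations=2,
                           transformation_probabilities=probs)
    by_formula = {str(m.composition): m for m in simulate_reaction_network(cfg)}
    assert by_formula["C3H6O3"].n_co_carbons == 1
    assert by_formula["C4H8O5"].n_co_carbons == 2
    assert by_formula["C4H8O5"].is_dicarboxylic


def test_peak_time_table_lookup_at_zero_jitter():
    cfg = SimulationConfig(peak_time_jitter=0.0)
    mols = [
        GroundTruthMolecule(parse_formula(f), 0)
        for f in ("C6H8O", "C6H8OS", "C6H8OS2", "C6H8OS3", "C4H6OS4")
    ]
    out = assign_temporal_profiles(mols, cfg)
    assert [m.peak_time for m in out] == [168.0, 72.0, 24.0, 2.0, 2.0]


def test_peak_time_monotone_in_sulfur():
    cfg = SimulationConfig(peak_time_jitter=0.0)
    mols = assign_temporal_profiles(simulate_reaction_network(cfg), cfg)
    for a in mols:
        for b in mols:
            if a.composition.s > b.composition.s:
                assert a.peak_time <= b.peak_time


def test_sulfur_peak_time_rank_correlation_negative_under_jitter():
    cfg = SimulationConfig(random_seed=9)
    mols = assign_temporal_profiles(simulate_reaction_network(cfg), cfg)
    s = [m.composition.s for m in mols]
    t = [m.peak_time for m in mols]
    rho = spearmanr(s, t).statistic
    assert rho < 0


def _clean_config(**kw):
    base = dict(mass_error_ppm=0.0, noise_peaks=0, replicate_dropout=0.0,
                peak_time_jitter=0.0)
    return SimulationConfig(**(base | kw))


def test_rendered_monoisotopic_and_m1_peaks():
    """One molecule at its peak time yields M at 59.01385 and M+1 at 2.2%."""
    cfg = _clean_config()
    mol = GroundTruthMolecule(parse_formula("C2H4O2"), 1, peak_time=24.0,
                              amplitude=1.0e6)
    spec = render_spectra([mol], cfg, "unlabeled", 24.0, 0)
    assert spec.mz == pytest.approx([59.01385, 60.01721], abs=5e-6)
    assert spec.intensity[1] / spec.intensity[0] == pytest.approx(0.022)


def test_rendered_13co_channel_shifts_monoisotopic_peak():
    cfg = _clean_config(label_enrichment=1.0)
    mol = GroundTruthMolecule(parse_formula("C2H4O2"), 1, peak_time=24.0,
                              amplitude=1.0e6)
    spec = render_spectra([mol], cfg, "13CO", 24.0, 0)
    assert spec.mz[0] == pytest.approx(60.01721, abs=5e-6)
    assert spec.intensity[0] == pytest.approx(1.0e6)


def test_far_off_peak_time_renders_nothing():
    cfg = _clean_config(kernel_sigma_log=0.3)
    mol = GroundTruthMolecule(parse_formula("C2H4O2"), 0, peak_time=2.0,
                              amplitude=1.0e6)
    spec = render_spectra([mol], cfg, "unlabeled", 168.0, 0)
    assert len(spec) == 0


def test_34s_satellite_rendered_for_sulfur_compounds():
    cfg = _clean_config()
    mol = GroundTruthMolecule(parse_formula("C4H6OS2"), 0, peak_time=24.0,
                              amplitude=1.0e6)
    spec = render_spectra([mol], cfg, "unlabeled", 24.0, 0)
    mono = spec.mz[0]
    sat = [m for m in spec.mz if abs(m - (mono + 1.99580)) < 1e-4]
    assert len(sat) == 1
    i_sat = spec.intensity[np.argmin(np.abs(spec.mz - sat[0]))]
    assert i_sat / spec.intensity[0] == pytest.approx(2 * 0.0421, rel=1e-6)


def test_unknown_channel_rejected():
    cfg = _clean_config()
    with pytest.raises(ValueError):
        render_spectra([], cfg, "deuterium", 2.0, 0)


def test_label_mass_consistency():
    """Labelled-channel m/z shifts are integer multiples of the 13C defect."""
    cfg = _clean_config(label_enrichment=1.0)
    mols = assign_temporal_profiles(simulate_reaction_network(cfg), cfg)
    t = 24.0
    unlab = render_spectra(mols, cfg, "unlabeled", t, 0)
    lab = render_spectra(mols, cfg, "13CO", t, 0)
    from c2netms.chem import ion_mz
    for m in mols:
        base = ion_mz(m.composition)
        if not np.any(np.abs(unlab.mz - base) < 1e-6):
            continue  # below detection at this timepoint
        shifted = base + m.n_co_carbons * DELTA_13C
        assert np.any(np.abs(lab.mz - shifted) < 1e-6)


def test_rendering_is_deterministic():
    cfg = SimulationConfig(random_seed=4)
    mols = assign_temporal_profiles(simulate_reaction_network(cfg), cfg)
    a = render_spectra(mols, cfg, "unlabeled", 24.0, 1)
    b = render_spectra(mols, cfg, "unlabeled", 24.0, 1)
    assert np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)


def test_mixed_isomer_fraction_creates_composition_duplicates():
    cfg = SimulationConfig(random_seed=2, mixed_isomer_fraction=0.3)
    mols = simulate_reaction_network(cfg)
    comps = {}
    for m in mols:
        comps.setdefault(m.composition, set()).add(m.n_co_carbons)
    assert sum(1 for v in comps.values() if len(v) > 1) > 0.2 * len(comps) * 0.3


def test_ground_truth_round_trip(tmp_path):
    cfg = SimulationConfig(random_seed=1)
    mols = assign_temporal_profiles(simulate_reaction_network(cfg), cfg)
    path = tmp_path / "gt.csv"
    write_ground_truth(mols, path)
    back = read_ground_truth(path)
    assert len(back) == len(mols)
    for a, b in zip(mols, back):
        assert a.composition == b.composition
        assert a.n_co_carbons == b.n_co_carbons
        assert a.synthesis_history == b.synthesis_history
        assert a.peak_time == b.peak_time
        assert a.amplitude == pytest.approx(b.amplitude)


def test_ground_truth_empty_and_malformed(tmp_path):
    path = tmp_path / "empty.csv"
    write_ground_truth([], path)
    assert read_ground_truth(path) == []
    bad = tmp_path / "bad.csv"
    bad.write_text("formula,n_co_carbons,s_count,peak_time_h,amplitude,"
                   "is_dicarboxylic,history\nC-2H4,0,0,2,1.0,0,\n")
    with pytest.raises(ValueError):
        read_ground_truth(bad)


def test_temporal_kernel_peaks_at_peak_time():
    assert temporal_kernel(24.0, 24.0, 1.0) == 1.0
    assert temporal_kernel(2.0, 168.0, 1.0) < temporal_kernel(72.0, 168.0, 1.0)
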