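"""Synthetic ground-truth reaction system and peak-list renderer.

Emulates the statistical structure of the direct-infusion FT-ICR-MS study of
an acetylene/CO/NiS reaction mixture, so that every downstream stage can be
tested against a known truth:

* a stochastic reaction network grown from small seed molecules by the six
  reaction mass differences (acetylene addition, hydration, sulfhydration,
  reduction, carbonylation with H2O or H2S);
* carbonylation events mark carbons as CO-derived, defining the expected
  13CO labelling degree of each molecule (and c - n_co for 13C2H2 labelling);
* sulfur-count-dependent temporal peak times (S-rich compounds peak early);
* rendered peak lists per labelling channel / timepoint / technical replicate
  with natural 13C and 34S isotopologue satellites, Na adducts of
  dicarboxylic species, ppm-scale mass error, contaminant noise peaks and
  replicate dropout.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import (
    DELTA_34S,
    ElementalComposition,
    IonType,
    TRANSFORMATIONS_BY_NAME,
    format_formula,
    ion_mz,
    parse_formula,
)
from .preprocess import Spectrum

__all__ = [
    "GroundTruthMolecule",
    "SimulationConfig",
    "CHANNELS",
    "simulate_reaction_network",
    "assign_temporal_profiles",
    "render_spectra",
    "render_all_spectra",
    "write_ground_truth",
    "read_ground_truth",
    "temporal_kernel",
]

#: Labelling channels: unlabelled control, 13C-carbon-monoxide feed,
#: 13C-acetylene feed.
CHANNELS = ("unlabeled", "13CO", "13C-acetylene")


@dataclass
class GroundTruthMolecule:
    """One true compound of the simulated reaction system."""

    composition: ElementalComposition
    n_co_carbons: int
    synthesis_history: tuple[str, ...] = ()
    is_dicarboxylic: bool = False
    peak_time: float | None = None  # hours
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.composition.na != 0 or self.composition.n13c != 0:
            raise ValueError("ground-truth molecules are neutral unlabelled compositions")
        if not 0 <= self.n_co_carbons <= self.composition.c:
            raise ValueError("n_co_carbons must lie in [0, c]")


@dataclass
class SimulationConfig:
    """All knobs of the generator.

    Defaults are the study conditions: six timepoints from 2 h to 7 days,
    technical triplicates, FT-ICR-scale mass error (0.2 ppm s.d.), natural
    isotope abundances, and 99% isotopic purity of the labelled feed gases.
    """

    # reaction network ------------------------------------------------------
    #: (formula, n_co_carbons) of the starting molecules: acetaldehyde/vinyl
    #: alcohol from acetylene hydration, acrylic acid from Reppe
    #: carbonylation, thioacetic acid from acetylene + H2S.
    seeds: tuple[tuple[str, int], ...] = (
        ("C2H4O", 0),
        ("C3H4O2", 1),
        ("C2H4OS", 0),
    )
    #: per-generation application probability of each transformation
    transformation_probabilities: dict[str, float] = field(default_factory=lambda: {
        "acetylene_addition": 0.70,
        "water_addition": 0.30,
        "hydrogen_sulfide_addition": 0.30,
        "carbonylation_h2o": 0.40,
        "carbonylation_h2s": 0.25,
        "reduction": 0.25,
    })
    n_generations: int = 7
    #: fraction of non-seed compositions duplicated with a different
    #: CO-carbon count (co-eluting isomers -> "mixed" label annotations)
    mixed_isomer_fraction: float = 0.0

    # temporal structure ----------------------------------------------------
    timepoints: tuple[float, ...] = (2.0, 15.0, 24.0, 48.0, 72.0, 168.0)
    #: mean peak time (h) by sulfur count; monotone non-increasing in s
    peak_time_by_sulfur: dict[int, float] = field(default_factory=lambda: {
        0: 168.0, 1: 72.0, 2: 24.0, 3: 2.0,
    })
    #: probability that a molecule's peak time moves one timepoint away
    #: from the sulfur-determined mean
    peak_time_jitter: float = 0.25
    #: width (in ln hours) of the unimodal log-time intensity kernel
    kernel_sigma_log: float = 1.0
    #: log-normal amplitude law (natural-log median and sigma)
    amplitude_median: float = 1.0e6
    amplitude_sigma_log: float = 1.0

    # rendering -------------------------------------------------------------
    replicates: int = 3
    mass_error_ppm: float = 0.2
    noise_peaks: int = 150
    noise_intensity_median: float = 2.5e4
    noise_intensity_sigma_log: float = 0.8
    #: instrument noise floor: s/n = intensity / noise_floor
    noise_floor: float = 1.0e4
    #: minimum s/n at which a peak registers at all
    detection_sn: float = 1.0
    replicate_dropout: float = 0.02
    p13: float = 0.011    # natural 13C abundance per carbon
    p34: float = 0.0421   # natural 34S abundance per sulfur
    label_enrichment: float = 0.99
    na_adduct_fraction: float = 0.30
    mz_noise_range: tuple[float, float] = (122.0, 1000.0)

    random_seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.transformation_probabilities.items():
            if name not in TRANSFORMATIONS_BY_NAME:
                raise ValueError(f"unknown transformation {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name} outside [0,1]")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.label_enrichment <= 1.0:
            raise ValueError("label_enrichment must lie in [0,1]")

    def rng(self, *stream: object) -> np.random.Generator:
        """Deterministic per-stream generator fanned out from the run seed.

        Stream labels are folded in with CRC32 (stable across processes,
        unlike built-in string hashing).
        """
        key = [self.random_seed] + [zlib.crc32(str(s).encode()) for s in stream]
        return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# Reaction network growth
# ---------------------------------------------------------------------------

_VALID_RATIO = lambda comp: (  # noqa: E731 - tiny predicate
    comp.c > 0
    and 0.5 <= comp.hc <= 2.5
    and comp.oc < 1.5
    and comp.h <= 2 * comp.c + 2
)


def _seed_molecules(config: SimulationConfig) -> list[GroundTruthMolecule]:
    return [
        GroundTruthMolecule(parse_formula(f), n_co, synthesis_history=())
        for f, n_co in config.seeds
    ]


def simulate_reaction_network(config: SimulationConfig) -> list[GroundTruthMolecule]:
    """Grow the molecule set generation by generation.

    Each generation, every molecule of the previous generation may undergo
    each of the six transformations independently with the configured
    probability.  Products are kept when they stay inside the elemental-ratio
    window of the chemistry (0.5 <= H/C <= 2.5, O/C < 1.5, h <= 2c+2), so
    every synthesis chain is valid end to end.  Molecules are unique by
    (composition, CO-carbon count); the set is cumulative over generations.
    """
    rng = config.rng("reaction-network")
    molecules = _seed_molecules(config)
    seen = {(m.composition, m.n_co_carbons) for m in molecules}
    frontier = list(molecules)

    for _ in range(config.n_generations):
        new_frontier: list[GroundTruthMolecule] = []
        for mol in frontier:
            for name, prob in sorted(config.transformation_probabilities.items()):
                if prob <= 0.0 or rng.random() >= prob:
                    continue
                t = TRANSFORMATIONS_BY_NAME[name]
                product = mol.composition + t.delta
                if not _VALID_RATIO(product):
                    continue
                n_co = mol.n_co_carbons + (1 if name.startswith("carbonylation") else 0)
                key = (product, n_co)
                if key in seen:
                    continue
                seen.add(key)
                history = mol.synthesis_history + (name,)
                child = GroundTruthMolecule(
                    product, n_co, history,
                    is_dicarboxylic=history.count("carbonylation_h2o") >= 2,
                )
                new_frontier.append(child)
        molecules.extend(new_frontier)
        frontier = new_frontier

    if config.mixed_isomer_fraction > 0.0:
        molecules = _add_mixed_isomers(molecules, config, rng)
    return molecules


def _add_mixed_isomers(
    molecules: list[GroundTruthMolecule],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[GroundTruthMolecule]:
    """Duplicate a fraction of compositions with a different CO-carbon count,
    modelling co-eluting isomers with distinct synthesis histories."""
    existing = {(m.composition, m.n_co_carbons) for m in molecules}
    candidates = [m for m in molecules if m.synthesis_history and m.composition.c >= 2]
    n_pick = int(round(config.mixed_isomer_fraction * len(candidates)))
    if n_pick == 0:
        return molecules
    idx = rng.choice(len(candidates), size=min(n_pick, len(candidates)), replace=False)
    extra = []
    for i in sorted(idx):
        m = candidates[i]
        alt = m.n_co_carbons + 1 if m.n_co_carbons < m.composition.c else m.n_co_carbons - 1
        if (m.composition, alt) in existing:
            continue
        existing.add((m.composition, alt))
        extra.append(replace(m, n_co_carbons=alt,
                             synthesis_history=m.synthesis_history + ("isomer_variant",)))
    return molecules + extra


# ---------------------------------------------------------------------------
# Temporal structure
# ---------------------------------------------------------------------------

def _mean_peak_time(s: int, table: dict[int, float]) -> float:
    k = min(s, max(table))
    return table[k]


def assign_temporal_profiles(
    molecules: list[GroundTruthMolecule], config: SimulationConfig
) -> list[GroundTruthMolecule]:
    """Attach a peak time and an amplitude to every molecule.

    Peak time is the sulfur-count-driven table value (monotone: the more
    sulfur, the earlier), optionally jittered by one position on the
    timepoint grid; amplitudes follow a log-normal law.
    """
    rng = config.rng("temporal-profiles")
    grid = sorted(config.timepoints)
    out = []
    for mol in molecules:
        t_mean = _mean_peak_time(mol.composition.s, config.peak_time_by_sulfur)
        # snap the table value to the grid
        i = int(np.argmin([abs(t - t_mean) for t in grid]))
        if config.peak_time_jitter > 0.0 and rng.random() < config.peak_time_jitter:
            i = int(np.clip(i + rng.choice([-1, 1]), 0, len(grid) - 1))
        amplitude = float(
            config.amplitude_median * math.exp(config.amplitude_sigma_log * rng.standard_normal())
        )
        out.append(replace(mol, peak_time=grid[i], amplitude=amplitude))
    return out


def temporal_kernel(t: float, peak_time: float, sigma_log: float) -> float:
    """Unimodal Gaussian-in-log-time abundance kernel, 1 at the peak time."""
    return math.exp(-((math.log(t) - math.log(peak_time)) ** 2) / (2.0 * sigma_log**2))


# ---------------------------------------------------------------------------
# Peak-list rendering
# ---------------------------------------------------------------------------

def _label_count(mol: GroundTruthMolecule, channel: str) -> int:
    if channel == "unlabeled":
        return 0
    if channel == "13CO":
        return mol.n_co_carbons
    if channel == "13C-acetylene":
        return mol.composition.c - mol.n_co_carbons
    raise ValueError(f"unknown labelling channel {channel!r}")


def render_spectra(
    molecules: list[GroundTruthMolecule],
    config: SimulationConfig,
    channel: str,
    timepoint: float,
    replicate: int,
) -> Spectrum:
    """Render one technical-replicate peak list for a channel and timepoint.

    Each molecule contributes its deprotonated monoisotopic peak scaled by
    the temporal kernel, a natural M+1 satellite (p13 x remaining 12C), a
    natural 34S satellite when s > 0, a sodiated-deprotonated adduct for
    dicarboxylic species, and - in labelled channels - the isotopically
    shifted species at the channel's labelling degree with the configured
    enrichment (residual unlabelled species at 1 - enrichment).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown labelling channel {channel!r}")
    rng = config.rng("render", channel, timepoint, replicate)
    noise_rng = config.rng("render-noise", channel, timepoint)

    mzs: list[float] = []
    intensities: list[float] = []

    def emit(comp: ElementalComposition, ion: IonType, intensity: float) -> None:
        if intensity <= 0:
            return
        if intensity / config.noise_floor < config.detection_sn:
            return
        mz = ion_mz(comp, ion)
        if config.mass_error_ppm > 0.0:
            mz *= 1.0 + 1e-6 * config.mass_error_ppm * rng.standard_normal()
        mzs.append(mz)
        intensities.append(intensity)

    def emit_species(mol: GroundTruthMolecule, k: int, base: float) -> None:
        """Monoisotopic + natural satellites of one labelled species."""
        comp = mol.composition.with_label(k)
        emit(comp, IonType.DEPROTONATED, base)
        light_carbons = comp.c - k
        if light_carbons > 0:
            emit(comp.with_label(k + 1), IonType.DEPROTONATED,
                 base * config.p13 * light_carbons)
        if comp.s > 0:
            # natural 34S isotopologue: +1.99580 u on the same species
            mz = ion_mz(comp, IonType.DEPROTONATED) + DELTA_34S
            inten = base * config.p34 * comp.s
            if inten / config.noise_floor >= config.detection_sn:
                mz_err = mz * (1.0 + 1e-6 * config.mass_error_ppm * rng.standard_normal()) \
                    if config.mass_error_ppm > 0 else mz
                mzs.append(mz_err)
                intensities.append(inten)
        if mol.is_dicarboxylic and comp.h >= 2:
            emit(comp, IonType.SODIATED_DEPROTONATED, base * config.na_adduct_fraction)

    for mol in molecules:
        if mol.peak_time is None or mol.amplitude is None:
            raise ValueError("molecules need temporal profiles before rendering")
        base = mol.amplitude * temporal_kernel(timepoint, mol.peak_time, config.kernel_sigma_log)
        if config.replicate_dropout > 0.0 and rng.random() < config.replicate_dropout:
            continue
        k = _label_count(mol, channel)
        if channel == "unlabeled" or k == 0:
            emit_species(mol, 0, base)
        else:
            emit_species(mol, k, base * config.label_enrichment)
            residual = base * (1.0 - config.label_enrichment)
            emit_species(mol, 0, residual)

    # contaminant noise: positions shared across replicates of one
    # channel/timepoint (drawn from noise_rng), per-replicate ppm jitter
    if config.noise_peaks > 0:
        lo, hi = config.mz_noise_range
        n = config.noise_peaks
        noise_mz = noise_rng.uniform(lo, hi, size=n)
        noise_int = config.noise_intensity_median * np.exp(
            config.noise_intensity_sigma_log * noise_rng.standard_normal(n)
        )
        if config.mass_error_ppm > 0.0:
            noise_mz = noise_mz * (1.0 + 1e-6 * config.mass_error_ppm * rng.standard_normal(n))
        keep = noise_int / config.noise_floor >= config.detection_sn
        mzs.extend(noise_mz[keep].tolist())
        intensities.extend(noise_int[keep].tolist())

    mz_arr = np.asarray(mzs, dtype=float)
    int_arr = np.asarray(intensities, dtype=float)
    order = np.argsort(mz_arr)
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    # merge coincident species (e.g. isobaric isomers) within 1e-6 u
    if mz_arr.size:
        groups = np.concatenate([[0], np.cumsum(np.diff(mz_arr) > 1e-6)])
        mz_arr = np.array([mz_arr[groups == g].mean() for g in range(groups[-1] + 1)])
        int_arr = np.array([int_arr[groups == g].sum() for g in range(groups[-1] + 1)])
    sn = int_arr / config.noise_floor
    return Spectrum(
        mz=mz_arr, intensity=int_arr, sn=sn,
        timepoint=timepoint, replicate=replicate, channel=channel,
    )


def render_all_spectra(
    molecules: list[GroundTruthMolecule],
    config: SimulationConfig,
    channels: tuple[str, ...] = CHANNELS,
) -> dict[tuple[str, float, int], Spectrum]:
    """Render every (channel, timepoint, replicate) peak list."""
    out = {}
    for channel in channels:
        for t in config.timepoints:
            for r in range(config.replicates):
                out[(channel, t, r)] = render_spectra(molecules, config, channel, t, r)
    return out


# ---------------------------------------------------------------------------
# Ground-truth I/O (plain CSV)
# ---------------------------------------------------------------------------

_GT_COLUMNS = ["formula", "n_co_carbons", "s_count", "peak_time_h",
               "amplitude", "is_dicarboxylic", "history"]


def write_ground_truth(molecules: list[GroundTruthMolecule], path) -> None:
    rows = [
        {
            "formula": format_formula(m.composition),
            "n_co_carbons": m.n_co_carbons,
            "s_count": m.composition.s,
            "peak_time_h": "" if m.peak_time is None else m.peak_time,
            "amplitude": "" if m.amplitude is None else repr(m.amplitude),
            "is_dicarboxylic": int(m.is_dicarboxylic),
            "history": ";".join(m.synthesis_history),
        }
        for m in molecules
    ]
    pd.DataFrame(rows, columns=_GT_COLUMNS).to_csv(path, index=False)


def read_ground_truth(path) -> list[GroundTruthMolecule]:
    df = pd.read_csv(path, dtype={"history": str}, keep_default_na=False)
    missing = set(_GT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth file missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        comp = parse_formula(row.formula)
        history = tuple(h for h in str(row.history).split(";") if h)
        peak_time = None if row.peak_time_h == "" else float(row.peak_time_h)
        amplitude = None if row.amplitude == "" else float(row.amplitude)
        out.append(GroundTruthMolecule(
            comp, int(row.n_co_carbons), history,
            is_dicarboxylic=bool(int(row.is_dicarboxylic)),
            peak_time=peak_time, amplitude=amplitude,
        ))
    return out
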