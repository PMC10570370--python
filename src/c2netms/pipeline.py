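"""End-to-end orchestration: simulate -> preprocess -> annotate -> label ->
classify -> network -> SOM -> report.

The pipeline runs either on rendered synthetic peak lists (the default: the
generator's ground truth then scores recovery) or on peak-list CSV files laid
out as ``{channel}_{timepoint}h_rep{k}.csv``.  All randomness fans out from
one run seed; artifacts are written with fixed float formatting so a rerun
with the same seed reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann_mod
from . import compound_classes as classes_mod
from . import labeling as label_mod
from . import network as net_mod
from . import som as som_mod
from .annotate import Annotation, ElementBounds
from .chem import IonType, TRANSFORMATIONS, ion_mz
from .preprocess import (
    ConsensusPeakList,
    Spectrum,
    filter_peaks,
    flag_satellites,
    remove_34S_isotopes,
    remove_wiggle_artifacts,
    replicate_consensus,
)
from .simulate import (
    GroundTruthMolecule,
    SimulationConfig,
    render_all_spectra,
    assign_temporal_profiles,
    simulate_reaction_network,
    write_ground_truth,
)

log = logging.getLogger("c2netms")

__all__ = ["RunConfig", "RecoveryReport", "PipelineResult", "run_pipeline",
           "evaluate_recovery", "load_config"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (one input source: files XOR simulation)."""

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_dir: str | None = None

    # preprocessing
    sn_min: float = 4.0
    mz_range: tuple[float, float] = (122.0, 1000.0)
    consensus_tol_ppm: float = 1.0
    min_replicate_fraction: float = 0.66
    apply_34s_filter: bool = True
    apply_wiggle_filter: bool = True

    # annotation
    assign_tol_ppm: float = 0.5
    seed_mz_max: float = 200.0
    seed_source: str = "brute-force"  # or "ground-truth"
    #: assignment enumerates CHOS formulas only: a sodiated-deprotonated ion
    #: is exactly isobaric with the deprotonated ion of the composition
    #: (c, h-1, o, s, Na), so sodium is handled as adduct evidence instead
    bounds: ElementBounds = field(default_factory=lambda: ElementBounds(na=0))

    # labelling
    label_p: float = 0.01
    label_k_max: int = 6
    residual_unlabeled_expectation: float = 0.05

    # SOM
    som_grid: tuple[int, int] = (2, 4)
    som_learning_rate: float = 0.1
    som_iterations: int = 50_000

    random_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("configure exactly one input source: simulation XOR input_dir")
        for name in ("consensus_tol_ppm", "assign_tol_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulation is not None:
            self.simulation.random_seed = self.random_seed


@dataclass
class RecoveryReport:
    """Ground-truth evaluation of one run."""

    formula_precision: float | None = None
    formula_recall: float | None = None
    label_degree_accuracy: float | None = None
    noise_false_annotation_rate: float | None = None
    connectivity_pct: float | None = None
    n_true_observable: int = 0
    n_annotations: int = 0
    n_noise_peaks: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    config: RunConfig
    molecules: list[GroundTruthMolecule] | None
    consensus: dict[tuple[str, float], ConsensusPeakList]
    master: ConsensusPeakList
    per_timepoint_intensity: np.ndarray  # (n_master_peaks, n_timepoints)
    timepoints: tuple[float, ...]
    annotations: list[Annotation]
    acetylene_degrees: dict[str, set[int]]
    closure_confirmed: dict[str, bool]
    network: "net_mod.nx.Graph"
    connectivity_pct: float
    sulfur_shares: pd.DataFrame
    mixed: pd.DataFrame
    subspace_hc: pd.DataFrame
    series: list[classes_mod.HomologousSeries]
    profiles: list[som_mod.TemporalProfile]
    som: som_mod.SOMClusterer | None
    som_labels: np.ndarray | None
    peaktime_distribution: pd.DataFrame
    report: RecoveryReport


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _load_spectra_from_dir(config: RunConfig) -> tuple[dict, tuple[float, ...]]:
    """Read ``{channel}_{timepoint}h_rep{k}.csv`` peak lists."""
    root = Path(config.input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory {root} does not exist")
    spectra: dict[tuple[str, float, int], Spectrum] = {}
    timepoints = set()
    for f in sorted(root.glob("*_rep*.csv")):
        stem = f.stem  # e.g. unlabeled_24h_rep0
        channel, t_part, rep_part = stem.rsplit("_", 2)
        t = float(t_part.rstrip("h"))
        rep = int(rep_part.replace("rep", ""))
        spectra[(channel, t, rep)] = Spectrum.from_csv(f, t, rep, channel)
        timepoints.add(t)
    if not spectra:
        raise FileNotFoundError(f"no peak-list CSVs found under {root}")
    return spectra, tuple(sorted(timepoints))


def _preprocess(
    spectra: dict[tuple[str, float, int], Spectrum], config: RunConfig
) -> dict[tuple[str, float], ConsensusPeakList]:
    """Per-replicate filters, then >66% replicate consensus."""
    by_group: dict[tuple[str, float], list[Spectrum]] = {}
    for (channel, t, _rep), spec in sorted(spectra.items()):
        spec = filter_peaks(spec, sn_min=config.sn_min, mz_range=config.mz_range)
        if config.apply_wiggle_filter:
            spec, wlog = remove_wiggle_artifacts(spec)
            if len(wlog):
                log.info("wiggle filter removed %d peaks (%s, %gh)", len(wlog), channel, t)
        if config.apply_34s_filter:
            spec, slog = remove_34S_isotopes(spec, tol_ppm=config.consensus_tol_ppm)
            if len(slog):
                log.info("34S filter removed %d peaks (%s, %gh)", len(slog), channel, t)
        by_group.setdefault((channel, t), []).append(spec)
    out = {}
    for key, group in by_group.items():
        out[key] = replicate_consensus(
            group, tol_ppm=config.consensus_tol_ppm,
            min_fraction=config.min_replicate_fraction,
        )
        log.info("consensus %s %gh: %d peaks", key[0], key[1], len(out[key]))
    return out


def _build_master(
    consensus: dict[tuple[str, float], ConsensusPeakList],
    timepoints: tuple[float, ...],
    tol_ppm: float,
) -> tuple[ConsensusPeakList, np.ndarray]:
    """Union of the unlabelled consensus lists across timepoints.

    Returns the master peak list (median m/z, maximum intensity over
    timepoints) and the (n_peaks, n_timepoints) intensity matrix.
    """
    mz_all, int_all, tp_all = [], [], []
    for i, t in enumerate(timepoints):
        cpl = consensus.get(("unlabeled", t))
        if cpl is None or len(cpl) == 0:
            continue
        mz_all.append(cpl.mz)
        int_all.append(cpl.intensity)
        tp_all.append(np.full(len(cpl), i))
    if not mz_all:
        empty = ConsensusPeakList(np.empty(0), np.empty(0), np.empty(0),
                                  timepoint=-1.0, channel="unlabeled")
        return empty, np.empty((0, len(timepoints)))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    tp = np.concatenate(tp_all)
    order = np.argsort(mz)
    mz, inten, tp = mz[order], inten[order], tp[order]
    gaps = np.diff(mz) > tol_ppm * 1e-6 * mz[1:]
    group = np.concatenate([[0], np.cumsum(gaps)])
    n_groups = int(group[-1]) + 1
    out_mz = np.empty(n_groups)
    out_int = np.empty(n_groups)
    out_frac = np.empty(n_groups)
    matrix = np.zeros((n_groups, len(timepoints)))
    for g in range(n_groups):
        sel = group == g
        out_mz[g] = np.median(mz[sel])
        out_int[g] = np.max(inten[sel])
        present = np.unique(tp[sel])
        out_frac[g] = len(present) / len(timepoints)
        for j, x in zip(tp[sel], inten[sel]):
            matrix[g, j] = max(matrix[g, j], x)
    master = ConsensusPeakList(out_mz, out_int, out_frac,
                               timepoint=-1.0, channel="unlabeled")
    return master, matrix


def _make_seeds(
    master: ConsensusPeakList,
    config: RunConfig,
    molecules: list[GroundTruthMolecule] | None,
) -> list[Annotation]:
    """Seed annotations for network propagation.

    Default: brute-force enumeration of every master peak below
    ``seed_mz_max`` (low-mass CHOS formulas are unambiguous at FT-ICR
    accuracy).  Optionally, seed from attached ground truth instead.
    """
    seeds: list[Annotation] = []
    if config.seed_source == "ground-truth":
        if molecules is None:
            raise ValueError("ground-truth seeding requires simulated input")
        chosen = sorted(molecules, key=lambda m: m.composition.mass)[:20]
        for m in chosen:
            mz = ion_mz(m.composition, IonType.DEPROTONATED)
            idx = ann_mod._find_peak(master.mz, mz, config.assign_tol_ppm)
            if idx is None:
                continue
            err = (master.mz[idx] - mz) / mz * 1e6
            seeds.append(Annotation(m.composition, IonType.DEPROTONATED,
                                    float(master.mz[idx]), err, source="seed-match"))
        return seeds
    for i in range(len(master)):
        mz = float(master.mz[i])
        if mz > config.seed_mz_max:
            break
        cands = ann_mod.brute_force_assign(
            mz, IonType.DEPROTONATED, tol_ppm=config.assign_tol_ppm,
            bounds=config.bounds, apply_ratio_filters=True,
        )
        if cands:
            seeds.append(cands[0])
    return seeds


def _classify_labels(
    annotations: list[Annotation],
    consensus: dict[tuple[str, float], ConsensusPeakList],
    timepoints: tuple[float, ...],
    config: RunConfig,
) -> tuple[dict[str, set[int]], dict[str, bool]]:
    """Populate CO-channel label degrees (union over timepoints); return the
    acetylene-channel degrees and cross-channel closure flags."""
    acetylene: dict[str, set[int]] = {}
    closure: dict[str, bool] = {}
    for a in annotations:
        co_deg: set[int] = set()
        ac_deg: set[int] = set()
        for t in timepoints:
            unlab = consensus.get(("unlabeled", t))
            if unlab is None or len(unlab) == 0:
                continue
            for channel, sink, k_max in (
                ("13CO", co_deg, config.label_k_max),
                ("13C-acetylene", ac_deg, a.composition.c),
            ):
                lab = consensus.get((channel, t))
                if lab is None or len(lab) == 0:
                    continue
                try:
                    sink |= label_mod.classify_label_degrees(
                        a, unlab, lab, tol_ppm=config.assign_tol_ppm,
                        p=config.label_p, k_max=k_max,
                        residual_unlabeled_expectation=config.residual_unlabeled_expectation,
                    )
                except ValueError:
                    continue  # not detected in the unlabelled channel here
        a.label_degrees = co_deg
        acetylene[a.formula] = ac_deg
        closure[a.formula] = label_mod.cross_channel_check(a, co_deg, ac_deg)
    return acetylene, closure


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------

def _true_peak_mzs(molecules: list[GroundTruthMolecule]) -> np.ndarray:
    """All m/z a true molecule can produce in the unlabelled channel."""
    from .chem import DELTA_13C, DELTA_34S
    mzs = []
    for m in molecules:
        mono = ion_mz(m.composition, IonType.DEPROTONATED)
        mzs.append(mono)
        mzs.append(mono + DELTA_13C)
        if m.composition.s > 0:
            mzs.append(mono + DELTA_34S)
        if m.is_dicarboxylic and m.composition.h >= 2:
            na = ion_mz(m.composition, IonType.SODIATED_DEPROTONATED)
            mzs.extend([na, na + DELTA_13C])
    return np.sort(np.asarray(mzs))


def evaluate_recovery(
    molecules: list[GroundTruthMolecule],
    annotations: list[Annotation],
    master: ConsensusPeakList,
    config: RunConfig,
    connectivity_pct: float | None = None,
) -> RecoveryReport:
    """Score the run against the generator's ground truth.

    * formula recall: fraction of observable true compositions (their
      monoisotopic ion present in the master list) annotated correctly;
    * formula precision: fraction of annotations whose composition is a
      true composition;
    * label-degree accuracy: fraction of annotated true molecules whose
      called degree set contains the molecule's CO-carbon count;
    * noise false-annotation rate: fraction of master peaks explained by no
      true species (noise survivors) that nevertheless received a formula.
    """
    tol = config.assign_tol_ppm
    true_comps = {m.composition for m in molecules}
    annotated = {a.composition.neutral() for a in annotations}
    ann_by_comp: dict = {}
    for a in annotations:
        ann_by_comp.setdefault(a.composition.neutral(), a)

    observable = set()
    for m in molecules:
        mz = ion_mz(m.composition, IonType.DEPROTONATED)
        if ann_mod._find_peak(master.mz, mz, tol) is not None:
            observable.add(m.composition)
    recall = (len(annotated & observable) / len(observable)) if observable else None
    precision = (len([a for a in annotations
                      if a.composition.neutral() in true_comps]) / len(annotations)
                 ) if annotations else None

    n_label_ok = n_label_tot = 0
    for m in molecules:
        if m.composition not in observable:
            continue
        a = ann_by_comp.get(m.composition)
        if a is None:
            continue
        n_label_tot += 1
        if m.n_co_carbons in a.label_degrees:
            n_label_ok += 1
    label_acc = n_label_ok / n_label_tot if n_label_tot else None

    # noise survivors: master peaks matching no true species m/z
    true_mzs = _true_peak_mzs(molecules)
    annotated_mz = np.sort(np.array([a.observed_mz for a in annotations])) \
        if annotations else np.empty(0)
    n_noise = n_noise_annotated = 0
    for mz in master.mz:
        t = tol * 1e-6 * mz
        lo = np.searchsorted(true_mzs, mz - 2 * t)
        hi = np.searchsorted(true_mzs, mz + 2 * t)
        if hi > lo:
            continue
        n_noise += 1
        alo = np.searchsorted(annotated_mz, mz - 1e-9)
        ahi = np.searchsorted(annotated_mz, mz + 1e-9)
        if ahi > alo:
            n_noise_annotated += 1
    noise_rate = n_noise_annotated / n_noise if n_noise else 0.0

    return RecoveryReport(
        formula_precision=precision,
        formula_recall=recall,
        label_degree_accuracy=label_acc,
        noise_false_annotation_rate=noise_rate,
        connectivity_pct=connectivity_pct,
        n_true_observable=len(observable),
        n_annotations=len(annotations),
        n_noise_peaks=n_noise,
    )


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in order and (optionally) write all artifacts."""
    stage = "input"
    try:
        molecules = None
        if config.simulation is not None:
            stage = "simulate"
            molecules = assign_temporal_profiles(
                simulate_reaction_network(config.simulation), config.simulation)
            log.info("simulated %d molecules", len(molecules))
            stage = "render"
            spectra = render_all_spectra(molecules, config.simulation)
            timepoints = tuple(sorted(config.simulation.timepoints))
        else:
            stage = "load"
            spectra, timepoints = _load_spectra_from_dir(config)

        stage = "preprocess"
        consensus = _preprocess(spectra, config)

        stage = "master-list"
        master, matrix = _build_master(consensus, timepoints, config.consensus_tol_ppm)
        log.info("master list: %d peaks over %d timepoints", len(master), len(timepoints))

        stage = "annotate"
        # satellite families (natural M+1 at +1.00336 u, Na adducts at
        # +21.98194 u = Na+ - H+) replicate the reaction network shifted by
        # a constant; keep them out of formula assignment
        from .chem import DELTA_13C, PROTON_MASS, MASS, ELECTRON_MASS
        na_shift = (MASS["Na"] - ELECTRON_MASS) - PROTON_MASS
        iso = (
            flag_satellites(master.mz, master.intensity, DELTA_13C,
                            tol_ppm=config.consensus_tol_ppm, max_ratio=0.6)
            | flag_satellites(master.mz, master.intensity, na_shift,
                              tol_ppm=config.consensus_tol_ppm, max_ratio=1.0)
        )
        master_assignable = ConsensusPeakList(
            master.mz[~iso], master.intensity[~iso],
            master.presence_fraction[~iso],
            timepoint=master.timepoint, channel=master.channel)
        seeds = _make_seeds(master_assignable, config, molecules)
        annotations = ann_mod.mdn_assign(
            master_assignable, seeds, TRANSFORMATIONS, tol_ppm=config.assign_tol_ppm)
        annotations = ann_mod.filter_annotations(annotations)
        annotations = ann_mod.detect_na_adducts(annotations, master, config.assign_tol_ppm)
        log.info("annotated %d of %d master peaks", len(annotations), len(master))

        stage = "detection-times"
        mz_index = {float(m): i for i, m in enumerate(master.mz)}
        for a in annotations:
            i = mz_index[a.observed_mz]
            a.timepoints_detected = {
                timepoints[j] for j in range(len(timepoints)) if matrix[i, j] > 0
            }

        stage = "label"
        acetylene_degrees, closure = _classify_labels(
            annotations, consensus, timepoints, config)

        stage = "classes"
        subspaces = classes_mod.partition_subspaces(annotations)
        hc_rows = []
        for (o, s), anns in sorted(subspaces.items()):
            tbl = classes_mod.mean_hc_by_degree(anns)
            if len(tbl):
                tbl.insert(0, "o_count", o)
                tbl.insert(1, "s_count", s)
                hc_rows.append(tbl)
        subspace_hc = (pd.concat(hc_rows, ignore_index=True) if hc_rows
                       else pd.DataFrame(columns=["o_count", "s_count", "degree",
                                                  "mean_hc", "n"]))
        mixed = label_mod.mixed_fraction(annotations)
        series = []
        for (_o, _s), anns in sorted(subspaces.items()):
            series.extend(classes_mod.detect_c2_series(anns))

        stage = "network"
        net = net_mod.build_network(annotations, TRANSFORMATIONS)
        connectivity = (net_mod.connectivity_fraction(net)
                        if net.number_of_nodes() else None)
        per_tp = {
            t: [a for a in annotations if t in a.timepoints_detected]
            for t in timepoints
        }
        sulfur_shares = net_mod.sulfur_class_shares(per_tp)

        stage = "som"
        profiles = []
        for a in annotations:
            i = mz_index[a.observed_mz]
            profiles.append(som_mod.TemporalProfile(
                a.composition, timepoints, matrix[i]))
        som_fit = labels = None
        peaktime_dist = pd.DataFrame()
        if profiles:
            som_mod.scale_profiles(profiles)
            som_fit, labels = som_mod.train_som(
                profiles, grid_shape=config.som_grid,
                learning_rate=config.som_learning_rate,
                n_iterations=config.som_iterations,
                random_state=config.random_seed,
            )
            peaktime_dist = som_mod.subspace_peaktime_distribution(
                profiles, labels, som_fit, subspaces)

        stage = "evaluate"
        if molecules is not None:
            report = evaluate_recovery(molecules, annotations, master, config,
                                       connectivity_pct=connectivity)
        else:
            report = RecoveryReport(connectivity_pct=connectivity,
                                    n_annotations=len(annotations))

        result = PipelineResult(
            config=config, molecules=molecules, consensus=consensus,
            master=master, per_timepoint_intensity=matrix, timepoints=timepoints,
            annotations=annotations, acetylene_degrees=acetylene_degrees,
            closure_confirmed=closure, network=net,
            connectivity_pct=connectivity if connectivity is not None else float("nan"),
            sulfur_shares=sulfur_shares, mixed=mixed, subspace_hc=subspace_hc,
            series=series, profiles=profiles, som=som_fit, som_labels=labels,
            peaktime_distribution=peaktime_dist, report=report,
        )

        if config.output_dir is not None:
            stage = "write"
            _write_artifacts(result)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_artifacts(result: PipelineResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.8f"
    if result.molecules is not None:
        write_ground_truth(result.molecules, out / "ground_truth.csv")
    for (channel, t), cpl in sorted(result.consensus.items()):
        cpl.to_csv(out / f"consensus_{channel}_{t:g}h.csv")
    result.master.to_csv(out / "master_peaks.csv")
    ann_mod.annotations_to_frame(result.annotations).to_csv(
        out / "annotations.csv", index=False, float_format=ff)
    classes_mod.export_subspace_scatter(result.annotations, out / "subspace_scatter.csv")
    result.mixed.to_csv(out / "mixed_fraction.csv", index=False, float_format=ff)
    result.subspace_hc.to_csv(out / "subspace_mean_hc.csv", index=False, float_format=ff)
    pd.DataFrame(
        [{"series_id": i, "label_degree": s.label_degree, "step": s.step,
          "members": ";".join(s.formulas)} for i, s in enumerate(result.series)]
    ).to_csv(out / "c2_series.csv", index=False)
    result.sulfur_shares.to_csv(out / "class_shares.csv", index=False, float_format=ff)
    net_mod.write_graphml(result.network, out / "network.graphml")
    if result.som is not None:
        rows = []
        for p, l in zip(result.profiles, result.som_labels):
            r, c = result.som.grid_coords_[int(l)]
            rows.append({
                "formula": str(p.composition), "node_row": int(r), "node_col": int(c),
                "cluster": int(l),
                "cluster_peak_time_h": som_mod.peak_time(
                    result.som.cluster_centers_[int(l)], p.timepoints),
            })
        pd.DataFrame(rows).to_csv(out / "som_clusters.csv", index=False)
        centers = pd.DataFrame(
            result.som.cluster_centers_,
            columns=[f"t_{t:g}h" for t in result.timepoints])
        centers.insert(0, "cluster", range(len(centers)))
        centers.to_csv(out / "som_cluster_centers.csv", index=False, float_format=ff)
        result.peaktime_distribution.to_csv(
            out / "subspace_peaktimes.csv", index=False, float_format=ff)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML mapping.

    Top-level keys mirror the RunConfig fields; the ``simulation`` mapping
    mirrors :class:`SimulationConfig` (``simulation: null`` plus
    ``input_dir`` switches to file input).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    if sim_raw is None:
        sim = None
    else:
        if "seeds" in sim_raw:
            sim_raw["seeds"] = tuple((f, int(k)) for f, k in sim_raw["seeds"])
        if "timepoints" in sim_raw:
            sim_raw["timepoints"] = tuple(float(t) for t in sim_raw["timepoints"])
        if "peak_time_by_sulfur" in sim_raw:
            sim_raw["peak_time_by_sulfur"] = {
                int(k): float(v) for k, v in sim_raw["peak_time_by_sulfur"].items()}
        sim = SimulationConfig(**sim_raw)
    if "mz_range" in raw:
        raw["mz_range"] = tuple(float(x) for x in raw["mz_range"])
    if "som_grid" in raw:
        raw["som_grid"] = tuple(int(x) for x in raw["som_grid"])
    if "bounds" in raw:
        raw["bounds"] = ElementBounds(**raw["bounds"])
    return RunConfig(simulation=sim, **raw)
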