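"""Elemental-formula assignment of consensus peaks.

Two independent routes are provided:

* :func:`brute_force_assign` — exhaustive enumeration of CHOS(Na)
  compositions whose ion m/z falls within tolerance; the slow, assumption-free
  oracle, also used to seed the network method from the low-mass region where
  formulas are unambiguous.
* :func:`mdn_assign` — mass-difference-network propagation: verified seed
  formulas are extended peak-by-peak across the exact reaction mass
  differences (both directions), lowest-cumulative-error first, until a fixed
  point.  Element counts must stay valid and the elemental-ratio window
  (0.5 <= H/C <= 2.5, O/C < 1.5) must hold at every step.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    MASS,
    ElementalComposition,
    IonType,
    Transformation,
    TRANSFORMATIONS,
    format_formula,
    ion_mz,
)
from .preprocess import ConsensusPeakList

__all__ = [
    "Annotation",
    "ElementBounds",
    "brute_force_assign",
    "mdn_assign",
    "filter_annotations",
    "detect_na_adducts",
    "annotations_to_frame",
    "annotations_from_frame",
]


@dataclass
class Annotation:
    """A composition bound to an observed peak."""

    composition: ElementalComposition
    ion: IonType
    observed_mz: float
    error_ppm: float
    source: str = "propagated"  # seed-match | propagated | brute-force | adduct
    path: tuple[str, ...] = ()
    timepoints_detected: set[float] = field(default_factory=set)
    label_degrees: set[int] = field(default_factory=set)
    has_na_adduct: bool = False
    intensity: float = 0.0

    @property
    def formula(self) -> str:
        return format_formula(self.composition)


@dataclass(frozen=True)
class ElementBounds:
    """Maximum element counts for brute-force enumeration."""

    c: int = 40
    h: int = 80
    o: int = 10
    s: int = 5
    na: int = 1


def _ratio_ok(comp: ElementalComposition) -> bool:
    return comp.c > 0 and 0.5 <= comp.hc <= 2.5 and comp.oc < 1.5


def brute_force_assign(
    mz: float,
    ion: IonType = IonType.DEPROTONATED,
    tol_ppm: float = 0.5,
    bounds: ElementBounds = ElementBounds(),
    apply_ratio_filters: bool = False,
) -> list[Annotation]:
    """Enumerate all compositions matching ``mz`` within ``tol_ppm``.

    Iterates C, O, S, Na counts and solves the hydrogen count from the mass
    residual, so the enumeration is O(C*O*S*Na).  Candidates are sorted by
    absolute mass error, then fewer heteroatoms, then formula string.
    """
    ion = IonType(ion)
    tol_u = tol_ppm * 1e-6 * mz
    out: list[Annotation] = []
    mH = MASS["H"]
    neutral_target = _neutral_mass_for(mz, ion)
    for na in range(bounds.na + 1):
        for s in range(bounds.s + 1):
            for o in range(bounds.o + 1):
                for c in range(1, bounds.c + 1):
                    base = c * MASS["C"] + o * MASS["O"] + s * MASS["S"] + na * MASS["Na"]
                    # hydrogen count implied by the mass residual
                    h_float = (neutral_target - base) / mH
                    for h in {int(np.floor(h_float)), int(np.ceil(h_float))}:
                        if h < (2 if ion is IonType.SODIATED_DEPROTONATED else 1):
                            continue
                        if h > bounds.h:
                            continue
                        comp = ElementalComposition(c, h, o, s, na)
                        theo = ion_mz(comp, ion)
                        if abs(theo - mz) > tol_u:
                            continue
                        if apply_ratio_filters and not _ratio_ok(comp):
                            continue
                        err = (mz - theo) / theo * 1e6
                        out.append(Annotation(comp, ion, mz, err, source="brute-force"))
    out.sort(key=lambda a: (abs(a.error_ppm), a.composition.heteroatoms, a.formula))
    return out


def _neutral_mass_for(mz: float, ion: IonType) -> float:
    """Neutral monoisotopic mass implied by an observed ion m/z."""
    from .chem import PROTON_MASS, ELECTRON_MASS
    if ion is IonType.DEPROTONATED:
        return mz + PROTON_MASS
    return mz + 2 * PROTON_MASS - (MASS["Na"] - ELECTRON_MASS)


# ---------------------------------------------------------------------------
# Mass-difference-network propagation
# ---------------------------------------------------------------------------

def _find_peak(mz_sorted: np.ndarray, target: float, tol_ppm: float) -> int | None:
    """Index of the peak nearest ``target`` within tol_ppm, else None."""
    tol = tol_ppm * 1e-6 * target
    lo = np.searchsorted(mz_sorted, target - tol, side="left")
    hi = np.searchsorted(mz_sorted, target + tol, side="right")
    if lo == hi:
        return None
    window = mz_sorted[lo:hi]
    return int(lo + np.argmin(np.abs(window - target)))


def mdn_assign(
    peaklist: ConsensusPeakList,
    seeds: list[Annotation],
    transformations: tuple[Transformation, ...] = TRANSFORMATIONS,
    tol_ppm: float = 0.5,
    apply_ratio_filters: bool = True,
) -> list[Annotation]:
    """Propagate seed formulas across reaction mass differences.

    Best-first (Dijkstra-style) propagation: the frontier is ordered by
    cumulative absolute ppm error along the assignment path, so each peak
    receives the assignment reachable with the smallest total error; ties
    break on fewer heteroatoms then formula string.  Targets are computed
    from the *theoretical* m/z of the assigned composition, so errors do not
    accumulate along chains.  Each assignment records its path.
    """
    mz = peaklist.mz
    assigned: dict[int, Annotation] = {}
    # entries: (cumulative_error, heteroatoms, formula, insertion_no, peak_index,
    # annotation); the insertion counter keeps heap comparisons off Annotation
    heap: list[tuple[float, int, str, int, int, Annotation]] = []
    counter = 0

    for seed in seeds:
        idx = _find_peak(mz, ion_mz(seed.composition, seed.ion), tol_ppm)
        if idx is None:
            raise ValueError(f"seed {seed.formula} has no matching peak within {tol_ppm} ppm")
        theo = ion_mz(seed.composition, seed.ion)
        err = (mz[idx] - theo) / theo * 1e6
        ann = Annotation(seed.composition, seed.ion, float(mz[idx]), err,
                         source="seed-match" if seed.source != "brute-force" else "brute-force",
                         path=(f"seed:{seed.formula}",))
        heapq.heappush(heap, (abs(err), ann.composition.heteroatoms, ann.formula,
                              counter, idx, ann))
        counter += 1

    while heap:
        cum_err, _, _, _, idx, ann = heapq.heappop(heap)
        if idx in assigned:
            continue
        assigned[idx] = ann
        ann.intensity = float(peaklist.intensity[idx])
        for t in transformations:
            for sign in (+1, -1):
                try:
                    comp = ann.composition + t.delta if sign > 0 else ann.composition - t.delta
                except ValueError:
                    continue
                if comp.is_empty() or comp.c == 0:
                    continue
                if apply_ratio_filters and not _ratio_ok(comp):
                    continue
                target = ion_mz(comp, ann.ion)
                j = _find_peak(mz, target, tol_ppm)
                if j is None or j in assigned:
                    continue
                err = (mz[j] - target) / target * 1e6
                step = "+" if sign > 0 else "-"
                child = Annotation(
                    comp, ann.ion, float(mz[j]), err, source="propagated",
                    path=ann.path + (f"{step}{t.name}",),
                )
                heapq.heappush(
                    heap,
                    (cum_err + abs(err), comp.heteroatoms, child.formula,
                     counter, j, child),
                )
                counter += 1

    return [assigned[i] for i in sorted(assigned)]


def filter_annotations(annotations: list[Annotation]) -> list[Annotation]:
    """Apply the elemental-ratio window: 0.5 <= H/C <= 2.5 and O/C < 1.5."""
    return [a for a in annotations if _ratio_ok(a.composition)]


def detect_na_adducts(
    annotations: list[Annotation],
    peaklist: ConsensusPeakList,
    tol_ppm: float = 0.5,
) -> list[Annotation]:
    """Flag annotations whose sodiated-deprotonated ion is also observed.

    The [M-2H+Na]- adduct is evidence attached to the neutral composition
    (diagnostic for dicarboxylic acids), not a separate annotation.
    """
    for ann in annotations:
        if ann.ion is not IonType.DEPROTONATED or ann.composition.h < 2:
            continue
        target = ion_mz(ann.composition, IonType.SODIATED_DEPROTONATED)
        if _find_peak(peaklist.mz, target, tol_ppm) is not None:
            ann.has_na_adduct = True
    return annotations


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    """Tabular export: mz, formula, ion, error_ppm, source, path, flags."""
    return pd.DataFrame({
        "mz": [a.observed_mz for a in annotations],
        "formula": [a.formula for a in annotations],
        "ion": [a.ion.value for a in annotations],
        "error_ppm": [a.error_ppm for a in annotations],
        "source": [a.source for a in annotations],
        "path": [";".join(a.path) for a in annotations],
        "na_adduct": [int(a.has_na_adduct) for a in annotations],
        "label_degrees": [";".join(str(k) for k in sorted(a.label_degrees))
                          for a in annotations],
        "timepoints_detected": [";".join(str(t) for t in sorted(a.timepoints_detected))
                                for a in annotations],
    })


def annotations_from_frame(df: pd.DataFrame) -> list[Annotation]:
    """Rebuild annotations from the CSV layout of :func:`annotations_to_frame`."""
    from .chem import parse_formula

    def text(row, attr):
        v = getattr(row, attr, "")
        return "" if pd.isna(v) else str(v)

    out = []
    for row in df.itertuples(index=False):
        a = Annotation(
            parse_formula(row.formula), IonType(row.ion),
            float(row.mz), float(row.error_ppm),
            source=row.source,
            path=tuple(p for p in text(row, "path").split(";") if p),
        )
        na = getattr(row, "na_adduct", 0)
        a.has_na_adduct = bool(int(0 if pd.isna(na) else na))
        # pandas may read a bare single degree back as a float ("1.0")
        a.label_degrees = {int(float(k)) for k in
                           text(row, "label_degrees").split(";") if k}
        a.timepoints_detected = {float(t) for t in
                                 text(row, "timepoints_detected").split(";") if t}
        out.append(a)
    return out
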