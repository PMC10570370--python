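"""13C labelling-degree classification.

Feeding the reaction with 13CO (or 13C-acetylene) shifts each product's
monoisotopic signal by one 13C-12C mass difference per incorporated labelled
carbon.  A degree k is *called* for a composition when the labelled channel
shows, at m/z + k*1.003355, an intensity that surpasses the natural-abundance
expectation by 100% — i.e. observed >= 2 x expected.  The natural expectation
follows the linear 1%-per-carbon rule for k = 1 and the binomial law for
k >= 2.  Intensities are referenced to the unlabelled channel's monoisotopic
peak after per-channel total-intensity normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import Annotation
from .chem import DELTA_13C, ion_mz
from .preprocess import ConsensusPeakList

__all__ = [
    "LabelCall",
    "expected_natural_fraction",
    "classify_label_degrees",
    "mixed_fraction",
    "cross_channel_check",
]


@dataclass
class LabelCall:
    """One tested labelling degree for one composition."""

    formula: str
    degree: int
    observed_relative_intensity: float
    expected_natural: float
    passed: bool


def expected_natural_fraction(n_c: int, k: int, p: float = 0.01) -> float:
    """Expected intensity of the k-fold 13C isotopologue relative to M.

    k = 0 -> 1; k = 1 -> the linear rule p * n_c (1% per carbon); k >= 2 ->
    binomial C(n_c, k) p^k (1-p)^(n_c-k).
    """
    if not 0 <= k <= n_c:
        raise ValueError(f"degree k={k} outside [0, {n_c}]")
    if k == 0:
        return 1.0
    if k == 1:
        return p * n_c
    return math.comb(n_c, k) * p**k * (1.0 - p) ** (n_c - k)


def _peak_intensity(peaklist: ConsensusPeakList, target: float, tol_ppm: float) -> float | None:
    tol = tol_ppm * 1e-6 * target
    lo = np.searchsorted(peaklist.mz, target - tol, side="left")
    hi = np.searchsorted(peaklist.mz, target + tol, side="right")
    if lo == hi:
        return None
    window = slice(lo, hi)
    j = lo + int(np.argmin(np.abs(peaklist.mz[window] - target)))
    return float(peaklist.intensity[j])


def classify_label_degrees(
    annotation: Annotation,
    unlabeled: ConsensusPeakList,
    labelled: ConsensusPeakList,
    tol_ppm: float = 0.5,
    p: float = 0.01,
    k_max: int = 6,
    residual_unlabeled_expectation: float = 0.05,
    calls: list[LabelCall] | None = None,
) -> set[int]:
    """Return the set of labelling degrees called for one annotation.

    Degree k in 1..min(c, k_max) is called when the labelled-channel signal
    at m/z + k*Delta(13C) is at least twice the natural expectation for k
    heavy carbons, relative to the unlabelled monoisotopic intensity (both
    channels normalized by their total intensity).  Degree 0 is called when
    the unshifted monoisotopic signal survives in the labelled channel above
    twice the residual-unlabelled expectation.
    """
    mono_mz = ion_mz(annotation.composition, annotation.ion)
    i_ref = _peak_intensity(unlabeled, mono_mz, tol_ppm)
    if i_ref is None or i_ref <= 0:
        raise ValueError(f"no unlabelled reference peak for {annotation.formula}")
    t_unlab = float(np.sum(unlabeled.intensity)) or 1.0
    t_lab = float(np.sum(labelled.intensity)) or 1.0
    ref_norm = i_ref / t_unlab

    c = annotation.composition.c
    degrees: set[int] = set()
    called_rel: dict[int, float] = {}

    def rel_at(k: int) -> float:
        i_lab = _peak_intensity(labelled, mono_mz + k * DELTA_13C, tol_ppm)
        return 0.0 if i_lab is None else (i_lab / t_lab) / ref_norm

    def test(k: int, expected: float) -> None:
        # a species called at a lower degree k' contributes its own natural
        # (k - k')-fold satellite at this shift; that stack is part of the
        # natural expectation the observed signal must double
        stacked = sum(
            r * expected_natural_fraction(c - kp, k - kp, p)
            for kp, r in called_rel.items()
            if kp < k and (k - kp) <= (c - kp)
        )
        rel = rel_at(k)
        expected_total = expected + stacked
        passed = rel >= 2.0 * expected_total
        if passed:
            degrees.add(k)
            called_rel[k] = max(rel - stacked, 0.0)
        if calls is not None:
            calls.append(LabelCall(annotation.formula, k, rel, expected_total, passed))

    test(0, residual_unlabeled_expectation)
    for k in range(1, min(c, k_max) + 1):
        test(k, expected_natural_fraction(c, k, p))
    return degrees


def mixed_fraction(annotations: list[Annotation]) -> pd.DataFrame:
    """Percentage of mixed vs pure label annotations per heteroatom subspace.

    A composition is *mixed* when it was called at two or more labelling
    degrees (co-eluting isomers with different synthesis histories).  Rows
    are (o_count, s_count) subspaces; pct_mixed + pct_pure = 100 per row.
    """
    rows = []
    by_subspace: dict[tuple[int, int], list[Annotation]] = {}
    for a in annotations:
        if not a.label_degrees:
            continue
        key = (a.composition.o, a.composition.s)
        by_subspace.setdefault(key, []).append(a)
    for (o, s), group in sorted(by_subspace.items()):
        n = len(group)
        # degrees > 0 define isomer multiplicity; degree 0 together with a
        # positive degree also implies two species (unlabelled + labelled)
        n_mixed = sum(1 for a in group if len(a.label_degrees) >= 2)
        rows.append({
            "o_count": o, "s_count": s, "n": n,
            "n_mixed": n_mixed,
            "pct_mixed": 100.0 * n_mixed / n,
            "pct_pure": 100.0 * (n - n_mixed) / n,
        })
    return pd.DataFrame(rows, columns=["o_count", "s_count", "n", "n_mixed",
                                       "pct_mixed", "pct_pure"])


def cross_channel_check(
    annotation: Annotation,
    co_degrees: set[int],
    acetylene_degrees: set[int],
) -> bool:
    """Building-block closure between the two labelled channels.

    Every carbon comes from CO or from acetylene, so a CO-channel degree k
    and an acetylene-channel degree k' are mutually consistent when
    k + k' = c.  Returns True when some called pair satisfies closure.
    """
    c = annotation.composition.c
    return any(k + kp == c for k in co_degrees for kp in acetylene_degrees)
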