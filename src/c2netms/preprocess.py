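"""Peak-level preprocessing preceding formula assignment.

Implements the stated acquisition-side data reduction: s/n and mass-range
filtering, >66% technical-replicate consensus, post-acquisition affine mass
recalibration against a calibrant list, and two heuristic cleanup filters
(natural 34S isotopologues, "wiggle" sideband artifacts).  The in-house
definitions of the two cleanup filters are not public; the reconstructions
here are parameterized, individually switchable, and log every removal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import DELTA_13C, DELTA_34S

__all__ = [
    "Spectrum",
    "ConsensusPeakList",
    "filter_peaks",
    "replicate_consensus",
    "recalibrate",
    "remove_34S_isotopes",
    "remove_wiggle_artifacts",
    "flag_c13_isotopologues",
]


@dataclass
class Spectrum:
    """A peak list (m/z, intensity, s/n) with sample metadata.

    Peaks are kept sorted by m/z; duplicate m/z within 1e-6 u are not
    allowed (merge upstream).
    """

    mz: np.ndarray
    intensity: np.ndarray
    sn: np.ndarray
    timepoint: float
    replicate: int | str
    channel: str

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sn = np.asarray(self.sn, dtype=float)
        if not (self.mz.shape == self.intensity.shape == self.sn.shape):
            raise ValueError("mz/intensity/sn must have identical shape")
        if self.mz.size > 1:
            d = np.diff(self.mz)
            if np.any(d < 0):
                raise ValueError("peaks must be sorted by m/z")
            if np.any(d <= 1e-6):
                raise ValueError("duplicate m/z within 1e-6 u")
        if np.any(self.intensity < 0) or np.any(self.sn < 0):
            raise ValueError("intensity and s/n must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def select(self, mask: np.ndarray) -> "Spectrum":
        return replace(self, mz=self.mz[mask], intensity=self.intensity[mask],
                       sn=self.sn[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity, "sn": self.sn})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8f")

    @classmethod
    def from_csv(cls, path, timepoint: float, replicate, channel: str) -> "Spectrum":
        df = pd.read_csv(path)
        order = np.argsort(df["mz"].to_numpy())
        return cls(
            mz=df["mz"].to_numpy()[order],
            intensity=df["intensity"].to_numpy()[order],
            sn=df["sn"].to_numpy()[order],
            timepoint=timepoint, replicate=replicate, channel=channel,
        )


@dataclass
class ConsensusPeakList:
    """Replicate-consensus peaks of one timepoint and channel.

    Each retained group carries the median m/z over contributing replicates,
    the mean intensity over the replicates in which it was present, and the
    fraction of replicates supporting it (> min_fraction by construction).
    """

    mz: np.ndarray
    intensity: np.ndarray
    presence_fraction: np.ndarray
    timepoint: float
    channel: str
    n_replicates: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.presence_fraction = np.asarray(self.presence_fraction, dtype=float)

    def __len__(self) -> int:
        return int(self.mz.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mz": self.mz,
            "intensity": self.intensity,
            "presence_fraction": self.presence_fraction,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.8f")


# ---------------------------------------------------------------------------


def filter_peaks(
    spec: Spectrum,
    sn_min: float = 4.0,
    mz_range: tuple[float, float] = (122.0, 1000.0),
) -> Spectrum:
    """Keep peaks with s/n >= sn_min inside the closed m/z window."""
    lo, hi = mz_range
    mask = (spec.sn >= sn_min) & (spec.mz >= lo) & (spec.mz <= hi)
    return spec.select(mask)


def replicate_consensus(
    specs: list[Spectrum],
    tol_ppm: float = 1.0,
    min_fraction: float = 0.66,
) -> ConsensusPeakList:
    """Align technical replicates and keep signals present in > min_fraction.

    Alignment is single-linkage on the pooled sorted m/z axis: consecutive
    peaks closer than tol_ppm belong to one group.  A group's presence
    fraction counts distinct replicates; with the default 0.66 threshold a
    2-of-3 signal is kept (2/3 > 66%) and a 1-of-3 signal is not.
    """
    if len(specs) < 2:
        raise ValueError("replicate consensus needs at least two replicates")
    channels = {s.channel for s in specs}
    timepoints = {s.timepoint for s in specs}
    if len(channels) != 1 or len(timepoints) != 1:
        raise ValueError("replicates must share channel and timepoint")
    n_rep = len(specs)

    mz = np.concatenate([s.mz for s in specs])
    inten = np.concatenate([s.intensity for s in specs])
    rep = np.concatenate([np.full(len(s), i) for i, s in enumerate(specs)])
    if mz.size == 0:
        return ConsensusPeakList(
            np.empty(0), np.empty(0), np.empty(0),
            timepoint=specs[0].timepoint, channel=specs[0].channel, n_replicates=n_rep,
        )
    order = np.argsort(mz)
    mz, inten, rep = mz[order], inten[order], rep[order]

    gaps = np.diff(mz) > tol_ppm * 1e-6 * mz[1:]
    group = np.concatenate([[0], np.cumsum(gaps)])

    out_mz, out_int, out_frac = [], [], []
    for g in range(group[-1] + 1):
        sel = group == g
        frac = len(set(rep[sel].tolist())) / n_rep
        if frac > min_fraction:
            out_mz.append(float(np.median(mz[sel])))
            out_int.append(float(np.mean(inten[sel])))
            out_frac.append(frac)
    return ConsensusPeakList(
        np.array(out_mz), np.array(out_int), np.array(out_frac),
        timepoint=specs[0].timepoint, channel=specs[0].channel, n_replicates=n_rep,
    )


def recalibrate(
    spec: Spectrum,
    calibrants: list[tuple[float, float]],
) -> tuple[Spectrum, np.ndarray]:
    """Affine post-acquisition mass recalibration mz' = a*mz + b.

    ``calibrants`` pairs (observed m/z, reference m/z); the least-squares
    fit over >= 2 pairs is applied to all peaks.  Returns the corrected
    spectrum and the per-calibrant residuals in ppm.
    """
    if len(calibrants) < 2:
        raise ValueError("recalibration needs at least two calibrant pairs")
    obs = np.array([c[0] for c in calibrants], dtype=float)
    ref = np.array([c[1] for c in calibrants], dtype=float)
    a, b = np.polyfit(obs, ref, 1)
    residual_ppm = (a * obs + b - ref) / ref * 1e6
    return replace(spec, mz=a * spec.mz + b), residual_ppm


def remove_34S_isotopes(
    spec: Spectrum,
    tol_ppm: float = 1.0,
    p34: float = 0.0421,
    band: tuple[float, float] = (0.3, 3.0),
    s_max: int = 3,
) -> tuple[Spectrum, pd.DataFrame]:
    """Strip natural 34S isotopologue satellites.

    A peak is removed when it lies +1.99580 u above a more intense peak and
    its intensity is within ``band`` of the natural expectation
    p34 * s * parent for some plausible sulfur count s <= s_max.  Removed
    peaks are returned as an audit log.
    """
    removed_rows = []
    keep = np.ones(len(spec), dtype=bool)
    for i in range(len(spec)):
        target = spec.mz[i] - DELTA_34S
        tol = tol_ppm * 1e-6 * spec.mz[i]
        lo = np.searchsorted(spec.mz, target - tol, side="left")
        hi = np.searchsorted(spec.mz, target + tol, side="right")
        for j in range(lo, hi):
            if spec.intensity[j] <= spec.intensity[i]:
                continue
            ratio = spec.intensity[i] / spec.intensity[j]
            for s in range(1, s_max + 1):
                expected = p34 * s
                if band[0] * expected <= ratio <= band[1] * expected:
                    keep[i] = False
                    removed_rows.append({
                        "mz": spec.mz[i], "intensity": spec.intensity[i],
                        "parent_mz": spec.mz[j], "s_assumed": s,
                    })
                    break
            if not keep[i]:
                break
    log = pd.DataFrame(removed_rows, columns=["mz", "intensity", "parent_mz", "s_assumed"])
    return spec.select(keep), log


def flag_satellites(
    mz: np.ndarray,
    intensity: np.ndarray,
    delta: float,
    tol_ppm: float = 1.0,
    max_ratio: float = 0.6,
) -> np.ndarray:
    """Boolean mask of peaks lying ``delta`` u above a stronger peak.

    A peak is flagged when a peak at least ``1/max_ratio`` times more
    intense sits at mz - delta (within tol_ppm).  Satellite families
    (isotopologues, adducts) replicate the reaction-mass-difference network
    shifted by a constant, so they must not enter formula assignment.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    flagged = np.zeros(mz.size, dtype=bool)
    for i in range(mz.size):
        target = mz[i] - delta
        tol = tol_ppm * 1e-6 * mz[i]
        lo = np.searchsorted(mz, target - tol, side="left")
        hi = np.searchsorted(mz, target + tol, side="right")
        for j in range(lo, hi):
            if intensity[i] < max_ratio * intensity[j]:
                flagged[i] = True
                break
    return flagged


def flag_c13_isotopologues(
    mz: np.ndarray,
    intensity: np.ndarray,
    tol_ppm: float = 1.0,
    max_ratio: float = 0.6,
) -> np.ndarray:
    """Mask of natural M+1 13C satellites (+1.00336 u, below ~45% of M for
    CHOS molecules up to C40).  The labelling classifier still reads them
    from the untouched per-timepoint consensus lists."""
    return flag_satellites(mz, intensity, DELTA_13C, tol_ppm, max_ratio)


def remove_wiggle_artifacts(
    spec: Spectrum,
    window_u: float = 0.01,
    rel_max: float = 0.01,
    dominance: float = 50.0,
) -> tuple[Spectrum, pd.DataFrame]:
    """Strip low-level sideband ("wiggle") satellites of dominant peaks.

    A peak is removed when a peak at least ``dominance`` times more intense
    lies within +-window_u and the satellite is below ``rel_max`` of it.
    Removed peaks are returned as an audit log.
    """
    removed_rows = []
    keep = np.ones(len(spec), dtype=bool)
    for i in range(len(spec)):
        lo = np.searchsorted(spec.mz, spec.mz[i] - window_u, side="left")
        hi = np.searchsorted(spec.mz, spec.mz[i] + window_u, side="right")
        for j in range(lo, hi):
            if j == i:
                continue
            if (spec.intensity[j] >= dominance * spec.intensity[i]
                    and spec.intensity[i] < rel_max * spec.intensity[j]):
                keep[i] = False
                removed_rows.append({
                    "mz": spec.mz[i], "intensity": spec.intensity[i],
                    "parent_mz": spec.mz[j],
                })
                break
    log = pd.DataFrame(removed_rows, columns=["mz", "intensity", "parent_mz"])
    return spec.select(keep), log
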