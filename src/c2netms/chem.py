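"""Elemental-composition arithmetic and negative-mode m/z conventions.

The analysis works in the CHOS(Na) compositional space of a reaction system
fed by acetylene and carbon monoxide.  Every downstream stage (formula
assignment, labelling classification, compound classes, networking) operates
on :class:`ElementalComposition` objects and the exact monoisotopic masses
defined here.

Atomic masses are the CODATA/AME2020 monoisotopic values (Wang et al., 2021,
"The AME 2020 atomic mass evaluation"), hard-coded to >=9 decimal places.
All ions carry charge -1 (direct-infusion negative electrospray):

* deprotonated  [M-H]-        : m/z = M - m(proton)
* sodiated-deprotonated [M-2H+Na]- : m/z = M - 2 m(proton) + m(Na+)
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ElementalComposition",
    "IonType",
    "Transformation",
    "TRANSFORMATIONS",
    "MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "DELTA_13C",
    "DELTA_34S",
    "monoisotopic_mass",
    "transformation_mass",
    "ion_mz",
    "ratios",
    "parse_formula",
    "format_formula",
]

#: Monoisotopic isotope masses in unified atomic mass units (AME2020).
MASS = {
    "H": 1.007825031898,
    "C": 12.0,
    "13C": 13.003354835,
    "O": 15.994914619257,
    "S": 31.972071174,
    "34S": 33.967867011,
    "Na": 22.989769282,
}

PROTON_MASS = 1.007276466621
ELECTRON_MASS = 0.000548579909

#: Mass shift per 13C substitution (u).
DELTA_13C = MASS["13C"] - MASS["C"]
#: Mass shift of the natural 34S isotopologue (u).
DELTA_34S = MASS["34S"] - MASS["S"]

#: m/z of the retained Na+ in a sodiated-deprotonated anion.
_NA_CATION_MASS = MASS["Na"] - ELECTRON_MASS


class IonType(str, Enum):
    """Negative-mode ion species considered by the analysis."""

    DEPROTONATED = "[M-H]-"
    SODIATED_DEPROTONATED = "[M-2H+Na]-"


@dataclass(frozen=True, order=True)
class ElementalComposition:
    """Integer element counts C/H/O/S/Na plus a 13C substitution count.

    ``n13c`` counts how many of the ``c`` carbons are the heavy isotope;
    it never exceeds ``c``.  Arithmetic is element-wise and subtraction
    that would produce a negative count raises ``ValueError``.
    """

    c: int = 0
    h: int = 0
    o: int = 0
    s: int = 0
    na: int = 0
    n13c: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "o", "s", "na", "n13c"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"element count {name}={v!r} must be a non-negative int")
        if self.n13c > self.c:
            raise ValueError(f"n13c={self.n13c} exceeds carbon count c={self.c}")

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c + other.c, self.h + other.h, self.o + other.o,
            self.s + other.s, self.na + other.na, self.n13c + other.n13c,
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c - other.c, self.h - other.h, self.o - other.o,
            self.s - other.s, self.na - other.na, self.n13c - other.n13c,
        )

    # -- derived quantities -------------------------------------------------
    @property
    def mass(self) -> float:
        """Monoisotopic mass in u, 13C substitutions counted at the 13C mass."""
        return (
            (self.c - self.n13c) * MASS["C"]
            + self.n13c * MASS["13C"]
            + self.h * MASS["H"]
            + self.o * MASS["O"]
            + self.s * MASS["S"]
            + self.na * MASS["Na"]
        )

    @property
    def hc(self) -> float:
        if self.c == 0:
            raise ZeroDivisionError("H/C undefined for carbon-free composition")
        return self.h / self.c

    @property
    def oc(self) -> float:
        if self.c == 0:
            raise ZeroDivisionError("O/C undefined for carbon-free composition")
        return self.o / self.c

    @property
    def heteroatoms(self) -> int:
        return self.o + self.s + self.na

    def neutral(self) -> "ElementalComposition":
        """The unlabelled, adduct-free composition (strip Na and 13C)."""
        return ElementalComposition(self.c, self.h, self.o, self.s, 0, 0)

    def with_label(self, k: int) -> "ElementalComposition":
        """Same composition with ``k`` 13C substitutions."""
        return ElementalComposition(self.c, self.h, self.o, self.s, self.na, k)

    def is_empty(self) -> bool:
        return (self.c, self.h, self.o, self.s, self.na) == (0, 0, 0, 0, 0)

    # -- text ---------------------------------------------------------------
    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:  # keeps pytest diffs readable
        return f"ElementalComposition({format_formula(self) or 'empty'})"


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass of a composition in u (0 for the empty composition)."""
    return comp.mass


def transformation_mass(delta: ElementalComposition) -> float:
    """Exact mass of a reaction mass-difference (edge) composition in u."""
    return delta.mass


def ion_mz(comp: ElementalComposition, ion: IonType = IonType.DEPROTONATED) -> float:
    """m/z of a singly charged negative ion of ``comp``.

    Deprotonation subtracts the proton mass (the electron stays with the
    anion, so electron mass is handled implicitly).  The sodiated adduct
    loses two protons and retains one Na+; it requires h >= 2.
    """
    ion = IonType(ion)
    if ion is IonType.DEPROTONATED:
        return comp.mass - PROTON_MASS
    if comp.h < 2:
        raise ValueError("[M-2H+Na]- requires at least two hydrogens")
    return comp.mass - 2 * PROTON_MASS + _NA_CATION_MASS


def ratios(comp: ElementalComposition) -> tuple[float, float]:
    """(H/C, O/C) elemental ratios; undefined (raises) for c == 0."""
    return comp.hc, comp.oc


# ---------------------------------------------------------------------------
# Formula strings
#
# Hill-like syntax "C6H10O4S", optional label prefix "[13C2]" and adduct
# suffix " [M-H]-" / " [M-2H+Na]-".  Round-trippable for CSV I/O.
# ---------------------------------------------------------------------------

_ELEMENT_ORDER = (("C", "c"), ("H", "h"), ("O", "o"), ("S", "s"), ("Na", "na"))
_FORMULA_RE = re.compile(r"(Na|C|H|O|S)(\d*)")
_LABEL_RE = re.compile(r"^\[13C(\d*)\]")


def format_formula(comp: ElementalComposition) -> str:
    """Render a composition as e.g. ``[13C2]C6H10O4S`` (empty string if empty)."""
    parts = []
    if comp.n13c:
        parts.append(f"[13C{comp.n13c}]")
    for sym, attr in _ELEMENT_ORDER:
        n = getattr(comp, attr)
        if n == 1:
            parts.append(sym)
        elif n > 1:
            parts.append(f"{sym}{n}")
    return "".join(parts)


def parse_formula(text: str) -> ElementalComposition:
    """Parse the formula syntax produced by :func:`format_formula`."""
    text = text.strip()
    n13c = 0
    m = _LABEL_RE.match(text)
    if m:
        n13c = int(m.group(1) or 1)
        text = text[m.end():]
    counts = {"c": 0, "h": 0, "o": 0, "s": 0, "na": 0}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r}")
        sym = m.group(1)
        attr = {"C": "c", "H": "h", "O": "o", "S": "s", "Na": "na"}[sym]
        counts[attr] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r}")
    return ElementalComposition(n13c=n13c, **counts)


# ---------------------------------------------------------------------------
# Reaction mass differences (molecular-network edges)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transformation:
    """A named reaction mass difference used for assignment and networking."""

    name: str
    delta: ElementalComposition

    @property
    def delta_mass(self) -> float:
        return self.delta.mass


#: The six reaction mass differences of the C2-addition system:
#: hydration/sulfhydration/reduction of a multiple bond, acetylene addition,
#: and Reppe-type carbonylation with water or hydrogen sulfide.
TRANSFORMATIONS: tuple[Transformation, ...] = (
    Transformation("water_addition", ElementalComposition(h=2, o=1)),
    Transformation("hydrogen_sulfide_addition", ElementalComposition(h=2, s=1)),
    Transformation("acetylene_addition", ElementalComposition(c=2, h=2)),
    Transformation("carbonylation_h2o", ElementalComposition(c=1, h=2, o=2)),
    Transformation("carbonylation_h2s", ElementalComposition(c=1, h=2, o=1, s=1)),
    Transformation("reduction", ElementalComposition(h=2)),
)

TRANSFORMATIONS_BY_NAME = {t.name: t for t in TRANSFORMATIONS}
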