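"""Compound-class reasoning over heteroatom subspaces.

Groups annotated compositions into (O-count, S-count) subspaces, summarizes
mean saturation (H/C) per labelling degree, applies the Na-adduct logic that
separates dicarboxylic acids from hydroxy-keto acids in the CHO4 space, and
detects C2 (acetylene) homologous series within a labelling degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import Annotation
from .chem import ElementalComposition, TRANSFORMATIONS_BY_NAME, format_formula

__all__ = [
    "HomologousSeries",
    "partition_subspaces",
    "mean_hc_by_degree",
    "na_adduct_classify",
    "detect_c2_series",
    "export_subspace_scatter",
    "DEFAULT_CLASS_RULES",
]


@dataclass
class HomologousSeries:
    """A maximal chain of compositions differing by one repeated step."""

    members: tuple[ElementalComposition, ...]
    step: str = "acetylene_addition"
    label_degree: int | None = None

    def __len__(self) -> int:
        return len(self.members)

    @property
    def formulas(self) -> list[str]:
        return [format_formula(m) for m in self.members]


def partition_subspaces(
    annotations: list[Annotation],
) -> dict[tuple[int, int], list[Annotation]]:
    """Exhaustive disjoint partition by (o, s) of the neutral composition.

    Na-adduct evidence stays attached to the neutral composition, so sodium
    never defines a subspace.
    """
    out: dict[tuple[int, int], list[Annotation]] = {}
    for a in annotations:
        neutral = a.composition.neutral()
        out.setdefault((neutral.o, neutral.s), []).append(a)
    return out


def mean_hc_by_degree(annotations: list[Annotation]) -> pd.DataFrame:
    """Arithmetic mean H/C per called labelling degree within one subspace.

    Mixed compositions contribute to every degree they were called at;
    degrees with no members are omitted.
    """
    by_degree: dict[int, list[float]] = {}
    for a in annotations:
        for k in a.label_degrees:
            by_degree.setdefault(k, []).append(a.composition.hc)
    rows = [
        {"degree": k, "mean_hc": sum(v) / len(v), "n": len(v)}
        for k, v in sorted(by_degree.items())
    ]
    return pd.DataFrame(rows, columns=["degree", "mean_hc", "n"])


#: (degree, has_na_adduct) -> candidate class for carboxylic-acid-bearing
#: subspaces (the CHO4 logic).  Twice-labelled compositions with a sodium
#: adduct behave as double-deprotonated species retaining Na+ and are
#: dicarboxylic-acid candidates; classes are candidates, not identifications.
DEFAULT_CLASS_RULES: dict[tuple[int, bool], str] = {
    (1, False): "dihydroxy-acid-candidate",
    (2, True): "dicarboxylic-candidate",
    (2, False): "hydroxy-keto-candidate",
    (3, False): "diketo-acid-candidate",
}


def na_adduct_classify(
    annotations: list[Annotation],
    rules: dict[tuple[int, bool], str] | None = None,
) -> pd.DataFrame:
    """Classify annotations of one subspace by (labelling degree, Na adduct).

    Combinations outside the rules table (e.g. a singly labelled composition
    with a sodium adduct, never observed for genuine monocarboxylic species)
    are reported as rule violations.
    """
    rules = DEFAULT_CLASS_RULES if rules is None else rules
    rows = []
    for a in annotations:
        for k in sorted(a.label_degrees) or [None]:
            if k is None:
                rows.append({"formula": a.formula, "degree": -1,
                             "na_adduct": int(a.has_na_adduct),
                             "klass": "unlabelled-data-missing"})
                continue
            key = (k, a.has_na_adduct)
            if key in rules:
                klass = rules[key]
            elif a.has_na_adduct and (k, False) in rules:
                klass = "rule-violation"
            else:
                klass = "unclassified"
            rows.append({"formula": a.formula, "degree": k,
                         "na_adduct": int(a.has_na_adduct), "klass": klass})
    return pd.DataFrame(rows, columns=["formula", "degree", "na_adduct", "klass"])


def export_subspace_scatter(
    annotations: list[Annotation],
    csv_path,
    png_path=None,
) -> pd.DataFrame:
    """Van-Krevelen-style export: m/z vs H/C per annotation, marker ~ intensity.

    Writes a plain CSV (mz, hc, o_count, s_count, degree list, intensity,
    na_adduct) and, when ``png_path`` is given, a simple scatter colored by
    labelling degree with one panel per heteroatom subspace.
    """
    rows = [{
        "mz": a.observed_mz,
        "hc": a.composition.hc,
        "o_count": a.composition.o,
        "s_count": a.composition.s,
        "degrees": ";".join(str(k) for k in sorted(a.label_degrees)),
        "intensity": a.intensity,
        "na_adduct": int(a.has_na_adduct),
    } for a in annotations]
    df = pd.DataFrame(rows, columns=["mz", "hc", "o_count", "s_count",
                                     "degrees", "intensity", "na_adduct"])
    df.to_csv(csv_path, index=False, float_format="%.6f")
    if png_path is not None and len(df):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        keys = sorted({(o, s) for o, s in zip(df.o_count, df.s_count)})
        ncol = min(4, len(keys))
        nrow = -(-len(keys) // ncol)
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                                 squeeze=False)
        scale = df.intensity.max() or 1.0
        for ax, (o, s) in zip(axes.flat, keys):
            sub = df[(df.o_count == o) & (df.s_count == s)]
            deg = [int(d.split(";")[0]) if d else -1 for d in sub.degrees]
            ax.scatter(sub.mz, sub.hc, s=5 + 45 * sub.intensity / scale,
                       c=deg, cmap="viridis", alpha=0.7)
            ax.set_title(f"O{o} S{s}")
            ax.set_xlabel("m/z")
            ax.set_ylabel("H/C")
        for ax in axes.flat[len(keys):]:
            ax.set_visible(False)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return df


def detect_c2_series(
    annotations: list[Annotation],
    step: str = "acetylene_addition",
) -> list[HomologousSeries]:
    """Find maximal homologous chains under repeated ``step`` addition.

    Chains are built per labelling degree (members of a series share the
    degree); each composition belongs to at most one maximal chain per
    degree, and single compositions do not form a series.
    """
    delta = TRANSFORMATIONS_BY_NAME[step].delta
    series: list[HomologousSeries] = []

    degrees = sorted({k for a in annotations for k in a.label_degrees})
    if not degrees and annotations:
        degrees = [None]  # no label data: chain over all compositions

    for k in degrees:
        comps = sorted({
            a.composition.neutral()
            for a in annotations
            if k is None or k in a.label_degrees
        })
        comp_set = set(comps)
        visited: set[ElementalComposition] = set()
        for comp in comps:  # sorted -> deterministic chain starts
            if comp in visited:
                continue
            # only start a chain at its lowest member
            try:
                if comp - delta in comp_set:
                    continue
            except ValueError:
                pass
            chain = [comp]
            nxt = comp + delta
            while nxt in comp_set:
                chain.append(nxt)
                nxt = nxt + delta
            visited.update(chain)
            if len(chain) >= 2:
                series.append(HomologousSeries(tuple(chain), step=step, label_degree=k))
    return series
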