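"""Time-resolved molecular network over annotated compositions.

Nodes are neutral elemental compositions; an undirected edge joins two nodes
whose exact composition difference equals one of the six reaction mass
differences.  Because nodes are already formula-assigned, edges are defined
on exact composition differences, not m/z tolerance windows — isobars cannot
create false edges.  Connectivity and the per-timepoint sulfur/oxygen class
shares summarize the network the way the study's temporal analysis does.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .annotate import Annotation
from .chem import Transformation, TRANSFORMATIONS, format_formula

__all__ = [
    "build_network",
    "connectivity_fraction",
    "first_detection_time",
    "sulfur_class_shares",
    "write_graphml",
]


def build_network(
    annotations: list[Annotation],
    transformations: tuple[Transformation, ...] = TRANSFORMATIONS,
) -> nx.Graph:
    """Build the undirected reaction-mass-difference network.

    Label-degree variants of one composition collapse onto one node keyed by
    the neutral formula; the transformation name and its direction
    (lower-mass -> higher-mass) are stored on each edge.
    """
    g = nx.Graph()
    by_comp = {}
    for a in annotations:
        comp = a.composition.neutral()
        key = format_formula(comp)
        if key not in by_comp:
            by_comp[key] = comp
            g.add_node(
                key,
                mass=comp.mass,
                c=comp.c, h=comp.h, o=comp.o, s=comp.s,
                hc=comp.hc, oc=comp.oc,
                first_detection_h=(min(a.timepoints_detected)
                                   if a.timepoints_detected else float("nan")),
                degrees=";".join(str(k) for k in sorted(a.label_degrees)),
            )
        else:
            node = g.nodes[key]
            if a.timepoints_detected:
                t = min(a.timepoints_detected)
                if not (node["first_detection_h"] <= t):
                    node["first_detection_h"] = t
            merged = set(a.label_degrees) | {
                int(x) for x in node["degrees"].split(";") if x
            }
            node["degrees"] = ";".join(str(k) for k in sorted(merged))

    comps = by_comp
    comp_set = {c: k for k, c in comps.items()}
    for key, comp in comps.items():
        for t in transformations:
            partner = comp + t.delta
            pkey = comp_set.get(partner)
            if pkey is not None:
                g.add_edge(key, pkey, transformation=t.name,
                           low=key, high=pkey)
    return g


def connectivity_fraction(g: nx.Graph) -> float:
    """Percentage of nodes linked to at least one other node."""
    if g.number_of_nodes() == 0:
        raise ValueError("connectivity undefined for an empty network")
    connected = sum(1 for n in g.nodes if g.degree(n) >= 1)
    return 100.0 * connected / g.number_of_nodes()


def first_detection_time(annotation: Annotation) -> float:
    """Earliest timepoint (h) at which the annotation passed consensus."""
    if not annotation.timepoints_detected:
        raise ValueError(f"{annotation.formula} was never detected")
    return min(annotation.timepoints_detected)


def sulfur_class_shares(
    per_timepoint: dict[float, list[Annotation]],
) -> pd.DataFrame:
    """Per-timepoint class shares by sulfur count (and oxygen count for CHO).

    Among sulfur-containing annotations of each timepoint, reports the count
    and percentage per sulfur number; among CHO (sulfur-free) annotations,
    the analogous oxygen-number shares.  Timepoints without members of a
    family yield no rows for that family.
    """
    rows = []
    for t in sorted(per_timepoint):
        anns = per_timepoint[t]
        comps = {a.composition.neutral() for a in anns}
        s_comps = [c for c in comps if c.s > 0]
        cho = [c for c in comps if c.s == 0]
        for family, members, attr in (("CHOS", s_comps, "s"), ("CHO", cho, "o")):
            n_total = len(members)
            if n_total == 0:
                continue
            counts: dict[int, int] = {}
            for c in members:
                k = getattr(c, attr)
                counts[k] = counts.get(k, 0) + 1
            for k in sorted(counts):
                rows.append({
                    "timepoint_h": t, "family": family, "element_count": k,
                    "n": counts[k], "pct": 100.0 * counts[k] / n_total,
                })
    return pd.DataFrame(rows, columns=["timepoint_h", "family", "element_count", "n", "pct"])


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export with stable node ordering (NaN-safe attributes)."""
    h = nx.Graph()
    for node in sorted(g.nodes):
        attrs = dict(g.nodes[node])
        if attrs.get("first_detection_h") != attrs.get("first_detection_h"):
            attrs["first_detection_h"] = -1.0  # GraphML has no NaN
        h.add_node(node, formula=node, **attrs)
    for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
        h.add_edge(u, v, **g.edges[u, v])
    nx.write_graphml(h, path)
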