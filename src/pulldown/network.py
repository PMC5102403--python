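"""Interactome graph assembly and cross-organ overlap statistics.

Graph semantics follow the study's network figures: solid edges are
database-verified interactions between called interactors (same-organ or,
in the combined view, cross-organ), and dashed ``ms_only`` edges connect
the bait to every interactor that has no database path to it — i.e. the
interaction is supported only by the pulldown itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd


def build_graph(
    interactomes: dict[str, set[str]],
    edges: pd.DataFrame | None,
    bait_id: str = "BAIT",
    scope: str | None = None,
) -> nx.Graph:
    """Assemble the interactome graph for one organ or the combined view.

    Parameters
    ----------
    interactomes
        organ -> called interactor set. Pass a single-organ dict (or use
        ``scope``) for a per-organ graph; multiple organs give the
        combined graph with cross-organ database edges.
    edges
        database edge list (protein_a, protein_b[, source]).
    scope
        optional organ name restricting ``interactomes`` to one organ.

    Edge styles: ``database_same_organ`` when the two endpoints share an
    organ (the bait counts as present in every organ),
    ``database_cross_organ`` otherwise, and ``ms_only`` for dashed
    bait-to-orphan edges.
    """
    if scope is not None:
        interactomes = {scope: interactomes[scope]}
    organs_of: dict[str, set[str]] = {}
    for organ, members in interactomes.items():
        for p in members:
            organs_of.setdefault(p, set()).add(organ)
    if not organs_of:
        warnings.warn("empty interactome: graph contains only the bait", stacklevel=2)
    all_organs = set(interactomes)
    organs_of[bait_id] = set(all_organs)

    g = nx.Graph()
    g.add_node(bait_id, category="BAIT", organs=",".join(sorted(all_organs)))
    for p, organs in sorted(organs_of.items()):
        if p == bait_id:
            continue
        g.add_node(p, category="INTERACTOR", organs=",".join(sorted(organs)))

    if edges is not None and len(edges):
        for rec in edges.itertuples(index=False):
            a, b = rec.protein_a, rec.protein_b
            if a == b or a not in g or b not in g:
                continue
            shared = organs_of[a] & organs_of[b]
            style = "database_same_organ" if shared else "database_cross_organ"
            g.add_edge(a, b, style=style, organs=",".join(sorted(shared)))

    # dashed MS-only edges: bait to every node with no database path to it
    db_reachable = nx.node_connected_component(g, bait_id) if g.degree(bait_id) else {bait_id}
    for p in sorted(g.nodes):
        if p != bait_id and p not in db_reachable:
            g.add_edge(bait_id, p, style="ms_only", organs="")
    return g


@dataclass
class OverlapSummary:
    """Cross-organ overlap bookkeeping for the called interactor sets."""

    sizes: dict[str, int]
    unique_counts: dict[str, int]
    unique_fractions: dict[str, float]
    #: directional: shared[(A, B)] = |A n B| / |A|
    pairwise_shared_counts: dict[tuple[str, str], int]
    pairwise_shared_fractions: dict[tuple[str, str], float]
    combined_size: int
    multi_organ_count: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for organ in self.sizes:
            rows.append(
                {
                    "organ_a": organ,
                    "organ_b": "",
                    "statistic": "unique",
                    "count": self.unique_counts[organ],
                    "fraction": self.unique_fractions[organ],
                }
            )
        for (a, b), c in self.pairwise_shared_counts.items():
            rows.append(
                {
                    "organ_a": a,
                    "organ_b": b,
                    "statistic": "shared",
                    "count": c,
                    "fraction": self.pairwise_shared_fractions[(a, b)],
                }
            )
        rows.append(
            {
                "organ_a": "ALL",
                "organ_b": "",
                "statistic": "combined",
                "count": self.combined_size,
                "fraction": 1.0,
            }
        )
        rows.append(
            {
                "organ_a": "ALL",
                "organ_b": "",
                "statistic": "multi_organ",
                "count": self.multi_organ_count,
                "fraction": (
                    self.multi_organ_count / self.combined_size
                    if self.combined_size
                    else 0.0
                ),
            }
        )
        return pd.DataFrame(rows)


def overlap_stats(interactomes: dict[str, set[str]]) -> OverlapSummary:
    """Unique/shared counts and directional pairwise shared fractions.

    ``shared(A, B) = |A n B| / |A|`` is deliberately directional (both
    directions are reported); ``unique(A) = |A \\ union(others)| / |A|``.
    Conservation: sum of unique counts + multi-organ count = combined size.
    """
    if len(interactomes) < 2:
        raise ValueError("overlap statistics need at least two organs")
    organs = list(interactomes)
    sizes = {o: len(interactomes[o]) for o in organs}
    for o, n in sizes.items():
        if n == 0:
            warnings.warn(f"organ {o!r} has an empty interactor set", stacklevel=2)
    unique_counts, unique_fracs = {}, {}
    for o in organs:
        others = set().union(*(interactomes[q] for q in organs if q != o))
        u = len(interactomes[o] - others)
        unique_counts[o] = u
        unique_fracs[o] = u / sizes[o] if sizes[o] else 0.0
    shared_counts, shared_fracs = {}, {}
    for a in organs:
        for b in organs:
            if a == b:
                continue
            c = len(interactomes[a] & interactomes[b])
            shared_counts[(a, b)] = c
            shared_fracs[(a, b)] = c / sizes[a] if sizes[a] else 0.0
    combined = set().union(*interactomes.values())
    multi = sum(
        1 for p in combined if sum(p in interactomes[o] for o in organs) >= 2
    )
    return OverlapSummary(
        sizes=sizes,
        unique_counts=unique_counts,
        unique_fractions=unique_fracs,
        pairwise_shared_counts=shared_counts,
        pairwise_shared_fractions=shared_fracs,
        combined_size=len(combined),
        multi_organ_count=multi,
    )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """SIF export: one line per edge, relation = edge style."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{data.get('style', 'interacts')}\t{b}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")
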