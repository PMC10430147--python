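"""Bipartite overlap graph between two annotations and its match categories.

Two genes — one from the reference set, one from the pipeline set — are
linked when they sit on the same seqid, on the same strand (when stranded),
and their gene spans overlap by at least ``min_overlap_bp``.  Connected
components of that bipartite graph are the units of reconciliation, each
categorized by its side sizes:

=============  =====================
(ref, pipe)    category
=============  =====================
(>=1, 0)       ref_only
(0, >=1)       pipe_only
(1, 1)         one_to_one
(1, >1)        one_to_many
(>1, 1)        many_to_one
(>1, >1)       many_to_many
=============  =====================

Overlap is measured on gene spans, not exon intersections: the comparison
the merge rules need is "do these loci describe the same place", and exon
structure differences are resolved later by homology evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import networkx as nx
from intervaltree import IntervalTree

from .gtf_io import Annotation, GeneModel

__all__ = ["MatchComponent", "classify_matches", "components_to_table"]

CATEGORIES = (
    "ref_only",
    "pipe_only",
    "one_to_one",
    "one_to_many",
    "many_to_one",
    "many_to_many",
)


@dataclass
class MatchComponent:
    """A connected set of overlapping reference/pipeline genes."""

    ref_genes: List[str] = field(default_factory=list)
    pipe_genes: List[str] = field(default_factory=list)

    @property
    def category(self) -> str:
        nr, np_ = len(self.ref_genes), len(self.pipe_genes)
        if nr >= 1 and np_ == 0:
            return "ref_only"
        if nr == 0 and np_ >= 1:
            return "pipe_only"
        if nr == 1 and np_ == 1:
            return "one_to_one"
        if nr == 1:
            return "one_to_many"
        if np_ == 1:
            return "many_to_one"
        return "many_to_many"


def _span_overlap(a: GeneModel, b: GeneModel) -> int:
    """Overlap in bp of two closed gene spans (0 when disjoint)."""
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def genes_overlap(
    a: GeneModel, b: GeneModel, min_overlap_bp: int = 1, stranded: bool = True
) -> bool:
    """The edge predicate of the bipartite overlap graph."""
    if a.seqid != b.seqid:
        return False
    if stranded and a.strand != b.strand:
        return False
    return _span_overlap(a, b) >= min_overlap_bp


def classify_matches(
    ref: Annotation,
    pipe: Annotation,
    min_overlap_bp: int = 1,
    stranded: bool = True,
) -> List[MatchComponent]:
    """Partition both gene sets into categorized overlap components.

    Every gene of both annotations appears in exactly one component.
    Components are returned sorted by the leftmost member's (seqid, start);
    within a component gene ids are sorted by (start, gene_id).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")

    graph: nx.Graph = nx.Graph()
    coords: Dict[Tuple[str, str], GeneModel] = {}
    for g in ref:
        graph.add_node(("ref", g.gene_id))
        coords[("ref", g.gene_id)] = g
    for g in pipe:
        graph.add_node(("pipe", g.gene_id))
        coords[("pipe", g.gene_id)] = g

    # interval index over the reference; candidate edges from pipe lookups.
    # closed GTF intervals -> half-open tree intervals [start, end+1)
    trees: Dict[str, IntervalTree] = {}
    for g in ref:
        trees.setdefault(g.seqid, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    for g in pipe:
        tree = trees.get(g.seqid)
        if tree is None:
            continue
        for iv in tree.overlap(g.start, g.end + 1):
            r = coords[("ref", iv.data)]
            if genes_overlap(r, g, min_overlap_bp, stranded):
                graph.add_edge(("ref", iv.data), ("pipe", g.gene_id))

    comps: List[MatchComponent] = []
    keys: List[Tuple[str, int, str]] = []
    for nodes in nx.connected_components(graph):
        members = sorted(nodes, key=lambda n: (coords[n].start, coords[n].gene_id))
        mc = MatchComponent(
            ref_genes=[gid for side, gid in members if side == "ref"],
            pipe_genes=[gid for side, gid in members if side == "pipe"],
        )
        comps.append(mc)
        gms = [coords[n] for n in nodes]
        lk = min((g.seqid, g.start, g.gene_id) for g in gms)
        keys.append(lk)

    order = sorted(range(len(comps)), key=lambda i: keys[i])
    return [comps[i] for i in order]


def components_to_table(components: List[MatchComponent]) -> "pd.DataFrame":
    """Component table: component_id, category, ref_ids, pipe_ids."""
    import pandas as pd

    rows = [
        {
            "component_id": i,
            "category": c.category,
            "ref_ids": ",".join(c.ref_genes),
            "pipe_ids": ",".join(c.pipe_genes),
        }
        for i, c in enumerate(components)
    ]
    return pd.DataFrame(rows, columns=["component_id", "category", "ref_ids", "pipe_ids"])
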