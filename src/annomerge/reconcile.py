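"""Merge rules: reconcile a reference gene set with a pipeline gene set.

The decision procedure, per overlap component:

* ``ref_only`` — reference genes are always kept.
* ``pipe_only`` — each pipeline gene is kept iff it has a significant
  protein-homology hit (evalue <= ``evalue_max``).
* ``one_to_one`` — the reference structure is kept, the pipeline model
  discarded.
* many-type components (``one_to_many``, ``many_to_one``,
  ``many_to_many``) are arbitrated by homology:

  1. genes without a significant hit are dropped from contention;
  2. hit coordinates are scanned for *fragmentation* (several genes on one
     side whose best hits tile the same subject protein over adjacent,
     non-overlapping residue ranges — that side mis-splits one true locus)
     and *fusion* (one gene whose hits to two distinct subjects occupy
     query regions that are mostly disjoint — that gene glues two true
     loci together).  An event decides the component: fragmentation
     disfavors the fragmented side, fusion disfavors the fused gene's
     side;
  3. otherwise the side whose surviving genes have the higher mean query
     coverage wins; exact ties go to ``coverage_tie_policy``
     (default: reference, mirroring the one_to_one rule).

Kept reference genes retain their reference structure; kept pipeline genes
are added with their pipeline structure.  No coordinates are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .blast_io import (
    DEFAULT_EVALUE_MAX,
    HitSet,
    has_significant_hit,
    merge_intervals,
    query_coverage,
)
from .gtf_io import Annotation
from .overlap import MatchComponent, classify_matches

__all__ = [
    "ReconcileParams",
    "ReconcileReport",
    "Decision",
    "Event",
    "decide_component",
    "detect_fusion_fragmentation",
    "reconcile",
]


@dataclass
class ReconcileParams:
    """Tunable thresholds of the merge.

    evalue_max : significance cutoff for a homology hit (default 1e-5).
    coverage_tie_policy : side kept on an exact mean-coverage tie.
    fragmentation_gap_max : largest subject-residue gap between adjacent
        fragments still read as one tiled protein (default 50).
    fusion_min_disjoint_fraction : minimum fraction of the query length
        covered by exactly one of two subjects for a fusion call
        (default 0.8).
    """

    evalue_max: float = DEFAULT_EVALUE_MAX
    coverage_tie_policy: str = "prefer_reference"
    fragmentation_gap_max: int = 50
    fusion_min_disjoint_fraction: float = 0.8

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.coverage_tie_policy not in ("prefer_reference", "prefer_pipeline"):
            raise ValueError(f"unknown tie policy {self.coverage_tie_policy!r}")
        if not 0.0 <= self.fusion_min_disjoint_fraction <= 1.0:
            raise ValueError("fusion_min_disjoint_fraction must be in [0,1]")
        if self.fragmentation_gap_max < 0:
            raise ValueError("fragmentation_gap_max must be >= 0")


@dataclass
class Event:
    type: str  # "fusion" | "fragmentation"
    gene_ids: List[str]
    subject_id: str
    side: str  # "ref" | "pipe" — the side the event disfavors


@dataclass
class Decision:
    component_id: int
    category: str
    kept_ref: List[str]
    kept_pipe: List[str]
    reason: str
    events: List[Event] = field(default_factory=list)

    @property
    def kept(self) -> List[str]:
        return self.kept_ref + self.kept_pipe


@dataclass
class ReconcileReport:
    """Bookkeeping of the merge.

    Invariants: n_merged = n_ref_total - n_removed_ref + n_added_pipe and
    n_kept_common = n_ref_total - n_removed_ref.
    """

    n_ref_total: int
    n_removed_ref: int
    n_added_pipe: int
    n_fusion_events: int = 0
    n_fragmentation_events: int = 0
    per_component_decisions: List[Decision] = field(default_factory=list)

    @property
    def n_kept_common(self) -> int:
        return self.n_ref_total - self.n_removed_ref

    @property
    def n_merged(self) -> int:
        return self.n_ref_total - self.n_removed_ref + self.n_added_pipe


def _pooled_query_intervals(hs: HitSet) -> Dict[str, List[Tuple[int, int]]]:
    """Merged query intervals per subject."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    for subject, hits in hs.by_subject().items():
        out[subject] = merge_intervals((h.qstart, h.qend) for h in hits)
    return out


def _interval_list_size(ivs: List[Tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in ivs)


def _intersect_size(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _detect_fusion(gene_id: str, hs: HitSet, params: ReconcileParams,
                   side: str) -> List[Event]:
    """One gene whose hits to two subjects occupy disjoint query regions.

    The disjointness measure is the query-length fraction covered by
    exactly one of the two subjects' (merged) query intervals.
    """
    if hs.query_length is None or hs.query_length <= 0 or len(hs) == 0:
        return []
    per_subject = _pooled_query_intervals(hs)
    subjects = sorted(per_subject)
    events = []
    for i in range(len(subjects)):
        for j in range(i + 1, len(subjects)):
            a, b = per_subject[subjects[i]], per_subject[subjects[j]]
            inter = _intersect_size(a, b)
            union = _interval_list_size(merge_intervals(a + b))
            disjoint = (union - inter) / hs.query_length
            if disjoint >= params.fusion_min_disjoint_fraction:
                events.append(
                    Event(
                        type="fusion",
                        gene_ids=[gene_id],
                        subject_id=f"{subjects[i]},{subjects[j]}",
                        side=side,
                    )
                )
    return events


def _detect_fragmentation(
    gene_ids: List[str],
    hits_by_gene: Dict[str, HitSet],
    params: ReconcileParams,
    side: str,
) -> List[Event]:
    """Several genes on one side tiling the same subject protein.

    Best hits of >= 2 genes target one subject over mutually
    non-overlapping subject intervals with gaps <= fragmentation_gap_max,
    jointly ordered: the side fragments one true locus.
    """
    by_subject: Dict[str, List[Tuple[str, int, int]]] = {}
    for gid in gene_ids:
        hs = hits_by_gene.get(gid)
        if hs is None:
            continue
        best = hs.best_hit()
        if best is None:
            continue
        by_subject.setdefault(best.subject_id, []).append(
            (gid, best.sstart, best.send)
        )
    events = []
    for subject, triples in sorted(by_subject.items()):
        if len(triples) < 2:
            continue
        triples.sort(key=lambda t: (t[1], t[2]))
        ok = True
        for (g1, s1, e1), (g2, s2, e2) in zip(triples, triples[1:]):
            gap = s2 - e1 - 1
            if s2 <= e1 or gap > params.fragmentation_gap_max:
                ok = False
                break
        if ok:
            events.append(
                Event(
                    type="fragmentation",
                    gene_ids=[t[0] for t in triples],
                    subject_id=subject,
                    side=side,
                )
            )
    return events


def detect_fusion_fragmentation(
    c: MatchComponent,
    hits_by_gene: Dict[str, HitSet],
    params: ReconcileParams,
) -> List[Event]:
    """Scan a many-type component's hit coordinates for annotation errors.

    Returns the event list; empty hit sets yield no events.  Fusion is
    checked per gene on both sides; fragmentation per side (only sides
    with >= 2 genes can fragment).
    """
    events: List[Event] = []
    for side, gene_ids in (("ref", c.ref_genes), ("pipe", c.pipe_genes)):
        for gid in gene_ids:
            hs = hits_by_gene.get(gid)
            if hs is not None:
                events.extend(_detect_fusion(gid, hs, params, side))
        if len(gene_ids) >= 2:
            events.extend(
                _detect_fragmentation(gene_ids, hits_by_gene, params, side)
            )
    return events


def _mean_coverage(gene_ids: List[str], hits: Dict[str, HitSet]) -> float:
    covs = [query_coverage(hits[g]) for g in gene_ids]
    return sum(covs) / len(covs) if covs else 0.0


def decide_component(
    c: MatchComponent,
    component_id: int,
    ref_hits: Dict[str, HitSet],
    pipe_hits: Dict[str, HitSet],
    params: ReconcileParams,
) -> Decision:
    """Apply the merge rules to one component.

    ``ref_hits``/``pipe_hits`` map gene_id -> HitSet (a missing entry is an
    empty hit set).
    """
    cat = c.category
    if cat == "ref_only":
        return Decision(component_id, cat, list(c.ref_genes), [],
                        "reference-only: always kept")
    if cat == "pipe_only":
        kept = [
            g
            for g in c.pipe_genes
            if g in pipe_hits and has_significant_hit(pipe_hits[g], params.evalue_max)
        ]
        return Decision(
            component_id, cat, [], kept,
            "pipeline-only: kept iff significant homology hit",
        )
    if cat == "one_to_one":
        return Decision(component_id, cat, list(c.ref_genes), [],
                        "one-to-one: reference structure kept")
    if cat not in ("one_to_many", "many_to_one", "many_to_many"):
        raise ValueError(f"unknown component category {cat!r}")

    # many-type arbitration on significant hits only
    sig: Dict[str, HitSet] = {}
    for gid in c.ref_genes:
        if gid in ref_hits:
            sig[gid] = ref_hits[gid].significant(params.evalue_max)
    for gid in c.pipe_genes:
        if gid in pipe_hits:
            sig[gid] = pipe_hits[gid].significant(params.evalue_max)

    ref_live = [g for g in c.ref_genes if len(sig.get(g, HitSet(g))) > 0]
    pipe_live = [g for g in c.pipe_genes if len(sig.get(g, HitSet(g))) > 0]

    if not ref_live and not pipe_live:
        return Decision(component_id, cat, [], [],
                        "no gene on either side has a homology hit: all removed")

    live = MatchComponent(ref_genes=ref_live, pipe_genes=pipe_live)
    events = detect_fusion_fragmentation(live, sig, params)

    disfavored = {e.side for e in events}
    if len(disfavored) == 1:
        loser = disfavored.pop()
        winner = "pipe" if loser == "ref" else "ref"
        kinds = "+".join(sorted({e.type for e in events}))
        kept_side = ref_live if winner == "ref" else pipe_live
        if kept_side:
            return Decision(
                component_id,
                cat,
                kept_side if winner == "ref" else [],
                kept_side if winner == "pipe" else [],
                f"{kinds} event on {loser} side: {winner} side kept",
                events,
            )
        # winning side empty after the no-hit rule: fall through to coverage
    # conflicting events (both sides flagged) or no events: coverage decides
    if not ref_live or not pipe_live:
        winner = "ref" if ref_live else "pipe"
        reason = "only one side retains homology-supported genes"
    else:
        cov_ref = _mean_coverage(ref_live, sig)
        cov_pipe = _mean_coverage(pipe_live, sig)
        if cov_ref > cov_pipe:
            winner = "ref"
        elif cov_pipe > cov_ref:
            winner = "pipe"
        else:
            winner = "ref" if params.coverage_tie_policy == "prefer_reference" else "pipe"
        reason = (
            f"coverage arbitration: ref {cov_ref:.3f} vs pipe {cov_pipe:.3f}, "
            f"{winner} kept"
        )
    return Decision(
        component_id,
        cat,
        ref_live if winner == "ref" else [],
        pipe_live if winner == "pipe" else [],
        reason,
        events,
    )


def reconcile(
    ref: Annotation,
    pipe: Annotation,
    ref_hits: Dict[str, HitSet],
    pipe_hits: Dict[str, HitSet],
    params: Optional[ReconcileParams] = None,
    min_overlap_bp: int = 1,
    stranded: bool = True,
) -> Tuple[Annotation, ReconcileReport]:
    """Merge two annotations under the component decision rules.

    Returns the merged Annotation (kept reference genes with reference
    structure plus kept pipeline genes) and the audit report.  Fully
    deterministic for identical inputs.
    """
    params = params or ReconcileParams()
    components = classify_matches(ref, pipe, min_overlap_bp, stranded)

    merged = Annotation()
    decisions: List[Decision] = []
    n_removed_ref = 0
    n_added_pipe = 0
    n_fusion = 0
    n_frag = 0
    for cid, comp in enumerate(components):
        d = decide_component(comp, cid, ref_hits, pipe_hits, params)
        decisions.append(d)
        for gid in d.kept_ref:
            merged.add(ref[gid])
        for gid in d.kept_pipe:
            merged.add(pipe[gid])
        n_removed_ref += len(comp.ref_genes) - len(d.kept_ref)
        n_added_pipe += len(d.kept_pipe)
        n_fusion += sum(1 for e in d.events if e.type == "fusion")
        n_frag += sum(1 for e in d.events if e.type == "fragmentation")

    report = ReconcileReport(
        n_ref_total=len(ref),
        n_removed_ref=n_removed_ref,
        n_added_pipe=n_added_pipe,
        n_fusion_events=n_fusion,
        n_fragmentation_events=n_frag,
        per_component_decisions=decisions,
    )
    assert report.n_merged == len(merged), "merge bookkeeping out of sync"
    return merged, report


def report_to_tsv(report: ReconcileReport, path: str, params: Optional[ReconcileParams] = None) -> None:
    """Write the per-component decision table plus a summary block."""
    with open(path, "w") as fh:
        if params is not None:
            fh.write(
                f"# params: evalue_max={params.evalue_max} "
                f"coverage_tie_policy={params.coverage_tie_policy} "
                f"fragmentation_gap_max={params.fragmentation_gap_max} "
                f"fusion_min_disjoint_fraction={params.fusion_min_disjoint_fraction}\n"
            )
        fh.write("component_id\tcategory\tkept_ref\tkept_pipe\treason\n")
        for d in report.per_component_decisions:
            fh.write(
                f"{d.component_id}\t{d.category}\t{','.join(d.kept_ref)}\t"
                f"{','.join(d.kept_pipe)}\t{d.reason}\n"
            )
        fh.write(f"# n_ref_total\t{report.n_ref_total}\n")
        fh.write(f"# n_kept_common\t{report.n_kept_common}\n")
        fh.write(f"# n_removed_ref\t{report.n_removed_ref}\n")
        fh.write(f"# n_added_pipe\t{report.n_added_pipe}\n")
        fh.write(f"# n_merged\t{report.n_merged}\n")
        fh.write(f"# n_fusion_events\t{report.n_fusion_events}\n")
        fh.write(f"# n_fragmentation_events\t{report.n_fragmentation_events}\n")
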