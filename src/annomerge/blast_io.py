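"""Parse tabular protein-homology search results and score per-gene support.

Input is the 12-column BLAST tabular dialect (``-outfmt 6``):
qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore.

Two per-gene quantities drive annotation arbitration downstream:

* *query coverage* — the fraction of the gene's protein length covered by
  the union of its HSP query intervals, pooled across subjects.  Coverage
  measures how much of the locus is protein-supported, so HSPs from
  different database subjects contribute to one union.
* *significance* — whether any hit reaches an e-value threshold
  (default 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

__all__ = [
    "BlastHit",
    "HitSet",
    "BLAST6_COLUMNS",
    "DEFAULT_EVALUE_MAX",
    "read_blast_tab",
    "read_query_lengths",
    "query_coverage",
    "subject_coverage",
    "has_significant_hit",
    "merge_intervals",
]

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        # normalize reversed intervals on construction
        if self.qstart > self.qend:
            qs, qe = self.qstart, self.qend
            object.__setattr__(self, "qstart", qe)
            object.__setattr__(self, "qend", qs)
        if self.sstart > self.send:
            ss, se = self.sstart, self.send
            object.__setattr__(self, "sstart", se)
            object.__setattr__(self, "send", ss)
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue} for {self.query_id}")


@dataclass
class HitSet:
    """All hits of one query gene, sorted by descending bitscore."""

    query_id: str
    query_length: Optional[int] = None
    hits: List[BlastHit] = field(default_factory=list)

    def significant(self, evalue_max: float = DEFAULT_EVALUE_MAX) -> "HitSet":
        """A new HitSet restricted to hits with evalue <= evalue_max."""
        return HitSet(
            self.query_id,
            self.query_length,
            [h for h in self.hits if h.evalue <= evalue_max],
        )

    def best_hit(self) -> Optional[BlastHit]:
        return self.hits[0] if self.hits else None

    def by_subject(self) -> Dict[str, List[BlastHit]]:
        out: Dict[str, List[BlastHit]] = {}
        for h in self.hits:
            out.setdefault(h.subject_id, []).append(h)
        return out

    def __len__(self) -> int:
        return len(self.hits)


def read_blast_tab(path: str) -> Dict[str, HitSet]:
    """Read a 12-column tabular file into HitSets keyed by query_id.

    Within each HitSet hits are ordered by descending bitscore (ties broken
    by ascending evalue, then subject_id, for determinism).  An empty file
    yields an empty dict.

    Raises
    ------
    ValueError
        If any line does not have exactly 12 tab-separated columns; the
        message names the line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=BLAST6_COLUMNS,
            header=None,
            comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed BLAST tabular file {path}: {exc}") from exc

    # pandas silently tolerates short rows (NaN-fill); reject them explicitly
    if df.isna().any(axis=None):
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"line {bad}: expected 12 tab-separated columns")

    out: Dict[str, HitSet] = {}
    for row in df.itertuples(index=False):
        hit = BlastHit(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            pct_identity=float(row.pident),
            aln_len=int(row.length),
            qstart=int(row.qstart),
            qend=int(row.qend),
            sstart=int(row.sstart),
            send=int(row.send),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        out.setdefault(hit.query_id, HitSet(hit.query_id)).hits.append(hit)
    for hs in out.values():
        hs.hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id, h.qstart))
    return out


def read_query_lengths(path: str) -> Dict[str, int]:
    """Read a 2-column TSV (query_id, length in residues)."""
    df = pd.read_csv(path, sep="\t", names=["query_id", "length"], header=None,
                     comment="#", dtype={"query_id": str})
    return {str(q): int(l) for q, l in zip(df["query_id"], df["length"])}


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of 1-based closed intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _union_size(intervals: Iterable[Tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def query_coverage(hs: HitSet) -> float:
    """Fraction of the query protein covered by the union of HSP intervals.

    Pooled across subjects; 0.0 for an empty HitSet.

    Raises
    ------
    ValueError
        If query_length is missing or non-positive.
    """
    if hs.query_length is None or hs.query_length <= 0:
        raise ValueError(
            f"query {hs.query_id}: query_length must be positive, "
            f"got {hs.query_length}"
        )
    if not hs.hits:
        return 0.0
    covered = _union_size((h.qstart, h.qend) for h in hs.hits)
    return min(1.0, covered / hs.query_length)


def subject_coverage(hs: HitSet, subject_length: int) -> float:
    """Fraction of a subject protein covered by this query's HSPs to it.

    Computed for completeness; arbitration uses query coverage.
    """
    if subject_length <= 0:
        raise ValueError("subject_length must be positive")
    ivs = [(h.sstart, h.send) for h in hs.hits]
    if not ivs:
        return 0.0
    return min(1.0, _union_size(ivs) / subject_length)


def has_significant_hit(hs: HitSet, evalue_max: float = DEFAULT_EVALUE_MAX) -> bool:
    """True iff any hit has evalue <= evalue_max."""
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    return any(h.evalue <= evalue_max for h in hs.hits)
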