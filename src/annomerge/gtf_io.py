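"""Read and write gene annotations in GTF.

The unit of work throughout the package is the *gene locus*: one
:class:`GeneModel` per distinct ``gene_id``, with its genomic span, strand
and transcript/exon structure.  Coordinates follow the GTF convention —
1-based, closed intervals — and all interval arithmetic in this package
uses that convention.

Two attribute dialects are accepted, ``key "value";`` (GTF proper) and
``key=value`` (GFF-ish), because reference (NCBI) and pipeline (Maker)
exports differ in practice.  Only ``gene_id`` (and, on transcript-level
features, ``transcript_id``) are required.

Genes lacking an explicit ``gene`` feature line are synthesized from the
min/max extent of their features, since pipeline GTFs often carry only
transcript/exon rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

__all__ = [
    "GeneModel",
    "Annotation",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
]

# feature types treated as transcript containers when grouping exons
_TRANSCRIPT_FEATURES = {"transcript", "mrna"}

_ATTR_GTF = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)\s*=\s*([^;]+)")


class GtfParseError(ValueError):
    """Raised on malformed GTF input; message names the offending line."""


@dataclass
class GeneModel:
    """One gene locus.

    Attributes
    ----------
    gene_id : str
        Stable identifier; the merge key across annotations.
    seqid : str
        Chromosome or scaffold name.
    strand : str
        One of ``+``, ``-``, ``.``.
    start, end : int
        1-based closed genomic span of the locus.
    source_tag : str
        Provenance label, ``reference`` or ``pipeline``.
    transcripts : list of (transcript_id, [(exon_start, exon_end), ...])
    protein_length : int or None
        Amino-acid length of the encoded protein, used for homology
        query-coverage computation when available.
    """

    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    source_tag: str = "reference"
    transcripts: List[Tuple[str, List[Tuple[int, int]]]] = field(default_factory=list)
    protein_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def length(self) -> int:
        """Genomic span length in bp (closed interval)."""
        return self.end - self.start + 1


class Annotation:
    """A gene set keyed by gene_id with a per-seqid positional index.

    Iteration order is deterministic: (seqid, start, gene_id).
    """

    def __init__(self, genes: Optional[List[GeneModel]] = None):
        self._genes: Dict[str, GeneModel] = {}
        if genes:
            for g in genes:
                self.add(g)

    def add(self, gene: GeneModel) -> None:
        prev = self._genes.get(gene.gene_id)
        if prev is not None and prev.seqid != gene.seqid:
            raise GtfParseError(
                f"duplicate gene_id {gene.gene_id!r} on different seqids "
                f"({prev.seqid!r} and {gene.seqid!r}); gene identity is the merge key"
            )
        self._genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def get(self, gene_id: str) -> Optional[GeneModel]:
        return self._genes.get(gene_id)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(
            sorted(self._genes.values(), key=lambda g: (g.seqid, g.start, g.gene_id))
        )

    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self]

    def by_seqid(self) -> Dict[str, List[GeneModel]]:
        """Genes grouped by seqid, each group sorted by (start, gene_id)."""
        out: Dict[str, List[GeneModel]] = {}
        for g in self:
            out.setdefault(g.seqid, []).append(g)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return list(self) == list(other)


def _parse_attributes(raw: str, lineno: int) -> Dict[str, str]:
    attrs = dict(_ATTR_GTF.findall(raw))
    if not attrs:
        attrs = {k: v.strip().strip('"') for k, v in _ATTR_EQ.findall(raw)}
    if "gene_id" not in attrs:
        raise GtfParseError(f"line {lineno}: missing gene_id attribute: {raw!r}")
    return attrs


def read_gtf(path: str, source_tag: str = "reference") -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    One :class:`GeneModel` is produced per distinct ``gene_id``; its span is
    the min/max over all its feature lines when no dedicated ``gene`` line
    exists.  Comment lines (``#``) and blank lines are ignored.  An empty
    file yields an empty Annotation.

    Raises
    ------
    GtfParseError
        On a line without 9 tab-separated columns, a missing gene_id,
        non-integer coordinates, or one gene_id spanning two seqids.
    """
    spans: Dict[str, List[int]] = {}  # gene_id -> [start, end] running extent
    meta: Dict[str, Tuple[str, str]] = {}  # gene_id -> (seqid, strand)
    exons: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}  # gene -> tx -> exons
    tx_order: Dict[str, List[str]] = {}
    order: List[str] = []
    plen: Dict[str, int] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, feature, start_s, end_s, _score, strand, _frame, raw = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start > end:
                raise GtfParseError(f"line {lineno}: start {start} > end {end}")
            attrs = _parse_attributes(raw, lineno)
            gid = attrs["gene_id"]

            if gid in meta and meta[gid][0] != seqid:
                raise GtfParseError(
                    f"line {lineno}: gene_id {gid!r} appears on both "
                    f"{meta[gid][0]!r} and {seqid!r}"
                )
            if gid not in meta:
                meta[gid] = (seqid, strand)
                spans[gid] = [start, end]
                exons[gid] = {}
                tx_order[gid] = []
                order.append(gid)
            else:
                spans[gid][0] = min(spans[gid][0], start)
                spans[gid][1] = max(spans[gid][1], end)

            ftype = feature.lower()
            if "protein_length" in attrs:
                try:
                    plen[gid] = int(attrs["protein_length"])
                except ValueError:
                    pass
            tid = attrs.get("transcript_id")
            if tid and (ftype == "exon" or ftype in _TRANSCRIPT_FEATURES):
                if tid not in exons[gid]:
                    exons[gid][tid] = []
                    tx_order[gid].append(tid)
                if ftype == "exon":
                    exons[gid][tid].append((start, end))

    genes = []
    for gid in order:
        seqid, strand = meta[gid]
        start, end = spans[gid]
        transcripts = [
            (tid, sorted(exons[gid][tid])) for tid in tx_order[gid]
        ]
        genes.append(
            GeneModel(
                gene_id=gid,
                seqid=seqid,
                strand=strand,
                start=start,
                end=end,
                source_tag=source_tag,
                transcripts=transcripts,
                protein_length=plen.get(gid),
            )
        )
    return Annotation(genes)


def _fmt_attrs(pairs: List[Tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(ann: Annotation, path: str) -> None:
    """Write an Annotation as GTF, re-readable by :func:`read_gtf`.

    Genes are emitted sorted by (seqid, start, gene_id), each as one
    ``gene`` line followed by its transcript/exon lines, so output is
    byte-stable for a given Annotation.
    """
    with open(path, "w") as fh:
        fh.write("# annomerge GTF export\n")
        for g in ann:
            attrs: List[Tuple[str, str]] = [("gene_id", g.gene_id)]
            if g.protein_length is not None:
                attrs.append(("protein_length", str(g.protein_length)))
            fh.write(
                "\t".join(
                    [
                        g.seqid,
                        g.source_tag,
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for tid, ex in g.transcripts:
                tattrs = [("gene_id", g.gene_id), ("transcript_id", tid)]
                t_start = min((s for s, _ in ex), default=g.start)
                t_end = max((e for _, e in ex), default=g.end)
                fh.write(
                    "\t".join(
                        [
                            g.seqid,
                            g.source_tag,
                            "transcript",
                            str(t_start),
                            str(t_end),
                            ".",
                            g.strand,
                            ".",
                            _fmt_attrs(tattrs),
                        ]
                    )
                    + "\n"
                )
                for s, e in ex:
                    fh.write(
                        "\t".join(
                            [
                                g.seqid,
                                g.source_tag,
                                "exon",
                                str(s),
                                str(e),
                                ".",
                                g.strand,
                                ".",
                                _fmt_attrs(tattrs),
                            ]
                        )
                        + "\n"
                    )
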