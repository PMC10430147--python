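"""Synthetic, ground-truth-labeled inputs for every stage of the pipeline.

Real inputs to annotation reconciliation — a reference GTF, a pipeline GTF
and protein-homology tables — come from large genome projects; this module
emulates them at desk scale.  Each planted overlap component is realized
with the geometry and homology evidence that makes its intended decision
unambiguous:

* ``one_to_one`` — coincident ref/pipe genes, both fully protein-supported
  (reference structure should win);
* ``ref_only`` / ``pipe_only`` — isolated genes, the pipeline-only ones
  split between significant-hit (kept) and no-significant-hit (dropped);
* ``fragmentation`` — two pipeline genes tiling one reference gene, their
  best hits covering adjacent, non-overlapping ranges of one subject
  protein (pipeline side mis-splits the locus; reference should win);
* ``fusion`` — one reference gene spanning two pipeline genes, its hits to
  two distinct subjects occupying disjoint query regions (reference gene
  glues two loci; pipeline side should win);
* ``many_to_one`` / ``many_to_many`` — chained overlaps arbitrated purely
  by query coverage (reference wins the many_to_one plant, pipeline the
  many_to_many plant).

Count matrices are drawn from the standard RNA-seq count model, the
negative binomial parameterized by (mean, dispersion): "signal" genes have
concordant high means across replicates, "noise" genes a low mean with
Bernoulli presence per sample, so an ideal low-expression filter removes
exactly the noise genes.

Same seed, same files, byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gtf_io import Annotation, GeneModel, write_gtf

__all__ = ["FixtureSpec", "CountsSpec", "make_annotation_pair", "make_counts"]

SIGNIFICANT_EVALUE = 1e-30
NON_SIGNIFICANT_EVALUE = 10.0
_WINDOW = 20_000  # bp reserved per planted component


@dataclass
class CountsSpec:
    n_signal_genes: int = 100
    n_noise_genes: int = 100
    conditions: Tuple[str, ...] = ("breba", "main_crop")
    replicates: int = 3
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    noise_mean: float = 2.0
    noise_presence: float = 0.5


@dataclass
class FixtureSpec:
    seed: int = 0
    n_one_to_one: int = 5
    n_ref_only: int = 5
    n_pipe_only_hit: int = 3
    n_pipe_only_nohit: int = 3
    n_fragmentation: int = 2
    n_fusion: int = 2
    n_many_many: int = 2
    n_many_to_one: int = 2
    genome: List[Tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000), ("chr2", 2_000_000)]
    )
    counts: CountsSpec = field(default_factory=CountsSpec)


def _blast_row(q, s, qstart, qend, sstart, send, evalue, bitscore) -> List:
    aln = qend - qstart + 1
    return [q, s, 98.0, aln, 1, 0, qstart, qend, sstart, send, evalue, bitscore]


class _Builder:
    """Accumulates genes, hit rows and truth rows during planting."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.ref: List[GeneModel] = []
        self.pipe: List[GeneModel] = []
        self.ref_rows: List[List] = []
        self.pipe_rows: List[List] = []
        self.truth: List[Dict] = []

    def gene(self, side: str, gid: str, seqid: str, start: int, end: int,
             strand: str = "+") -> GeneModel:
        g = GeneModel(
            gene_id=gid, seqid=seqid, strand=strand, start=start, end=end,
            source_tag="reference" if side == "ref" else "pipeline",
            transcripts=[(f"{gid}.t1", [(start, end)])],
            protein_length=(end - start + 1) // 3,
        )
        (self.ref if side == "ref" else self.pipe).append(g)
        return g

    def hit(self, side: str, g: GeneModel, subject: str, qfrac: Tuple[float, float],
            sstart: int = 1, evalue: float = SIGNIFICANT_EVALUE,
            bitscore: float = 500.0) -> None:
        """Add a hit covering query fraction [qfrac0, qfrac1] of the protein."""
        L = g.protein_length
        qstart = max(1, int(round(qfrac[0] * L)) + 1) if qfrac[0] > 0 else 1
        qend = max(qstart, int(round(qfrac[1] * L)))
        send = sstart + (qend - qstart)
        row = _blast_row(g.gene_id, subject, qstart, qend, sstart, send,
                         evalue, bitscore)
        (self.ref_rows if side == "ref" else self.pipe_rows).append(row)

    def record(self, kind: str, category: str, ref_ids: List[str],
               pipe_ids: List[str], kept_ref: List[str], kept_pipe: List[str],
               event: str = "") -> None:
        self.truth.append(
            {
                "kind": kind,
                "category": category,
                "ref_ids": ",".join(ref_ids),
                "pipe_ids": ",".join(pipe_ids),
                "expected_kept_ref": ",".join(kept_ref),
                "expected_kept_pipe": ",".join(kept_pipe),
                "expected_event": event,
            }
        )


def _plant(b: _Builder, kind: str, idx: int, seqid: str, w: int) -> None:
    """Realize one planted component inside window [w, w+_WINDOW)."""
    tag = f"{kind}{idx}"
    jitter = int(b.rng.integers(0, 2000))
    base = w + 1 + jitter
    if kind == "one2one":
        r = b.gene("ref", f"R_{tag}", seqid, base, base + 2999)
        p = b.gene("pipe", f"P_{tag}", seqid, base, base + 2999)
        b.hit("ref", r, f"U_{tag}", (0.0, 1.0))
        b.hit("pipe", p, f"U_{tag}", (0.0, 1.0))
        b.record(kind, "one_to_one", [r.gene_id], [p.gene_id], [r.gene_id], [])
    elif kind == "refonly":
        r = b.gene("ref", f"R_{tag}", seqid, base, base + 1999)
        b.hit("ref", r, f"U_{tag}", (0.0, 0.9))
        b.record(kind, "ref_only", [r.gene_id], [], [r.gene_id], [])
    elif kind == "pipehit":
        p = b.gene("pipe", f"P_{tag}", seqid, base, base + 1999)
        b.hit("pipe", p, f"U_{tag}", (0.0, 0.9))
        b.record(kind, "pipe_only", [], [p.gene_id], [], [p.gene_id])
    elif kind == "pipenohit":
        p = b.gene("pipe", f"P_{tag}", seqid, base, base + 1999)
        b.hit("pipe", p, f"U_{tag}", (0.0, 0.3),
              evalue=NON_SIGNIFICANT_EVALUE, bitscore=30.0)
        b.record(kind, "pipe_only", [], [p.gene_id], [], [])
    elif kind == "frag":
        # one true locus; pipeline splits it in two adjacent models whose
        # best hits tile the same subject protein
        r = b.gene("ref", f"R_{tag}", seqid, base, base + 2999)  # plen 1000
        p1 = b.gene("pipe", f"P1_{tag}", seqid, base, base + 1499)  # plen 500
        p2 = b.gene("pipe", f"P2_{tag}", seqid, base + 1500, base + 2999)
        subject = f"U_{tag}"
        # pipeline fragments carry slightly higher coverage, so only the
        # fragmentation call (not coverage) can hand the win to the reference
        b.hit("ref", r, subject, (0.0, 0.85), sstart=1)
        b.hit("pipe", p1, subject, (0.0, 1.0), sstart=1)
        b.hit("pipe", p2, subject, (0.0, 1.0), sstart=506)  # gap 5 <= 50
        b.record(kind, "one_to_many", [r.gene_id],
                 [p1.gene_id, p2.gene_id], [r.gene_id], [], "fragmentation")
    elif kind == "fusion":
        # one reference model glues two true loci; its hits to two distinct
        # subjects occupy disjoint query regions
        r = b.gene("ref", f"R_{tag}", seqid, base, base + 5999)  # plen 2000
        q1 = b.gene("pipe", f"P1_{tag}", seqid, base, base + 2999)
        q2 = b.gene("pipe", f"P2_{tag}", seqid, base + 3000, base + 5999)
        b.hit("ref", r, f"UA_{tag}", (0.0, 0.45))
        b.hit("ref", r, f"UB_{tag}", (0.55, 1.0))  # disjoint fraction 0.9
        # fused model out-covers the split models; only the fusion call
        # can hand the win to the pipeline side
        b.hit("pipe", q1, f"UA_{tag}", (0.0, 0.8))
        b.hit("pipe", q2, f"UB_{tag}", (0.0, 0.8))
        b.record(kind, "one_to_many", [r.gene_id],
                 [q1.gene_id, q2.gene_id], [], [q1.gene_id, q2.gene_id],
                 "fusion")
    elif kind == "many2one":
        # two reference genes under one pipeline model; reference side has
        # the higher protein coverage and should win
        r1 = b.gene("ref", f"R1_{tag}", seqid, base, base + 1999)
        r2 = b.gene("ref", f"R2_{tag}", seqid, base + 2500, base + 4499)
        p = b.gene("pipe", f"P_{tag}", seqid, base, base + 4499)
        b.hit("ref", r1, f"UA_{tag}", (0.0, 0.9))
        b.hit("ref", r2, f"UB_{tag}", (0.0, 0.9))
        b.hit("pipe", p, f"UC_{tag}", (0.0, 0.4))
        b.record(kind, "many_to_one", [r1.gene_id, r2.gene_id],
                 [p.gene_id], [r1.gene_id, r2.gene_id], [])
    elif kind == "many2many":
        # chained 2x2 overlap; pipeline side has the higher coverage
        r1 = b.gene("ref", f"R1_{tag}", seqid, base, base + 2999)
        r2 = b.gene("ref", f"R2_{tag}", seqid, base + 3500, base + 6499)
        p1 = b.gene("pipe", f"P1_{tag}", seqid, base + 2500, base + 3799)
        p2 = b.gene("pipe", f"P2_{tag}", seqid, base + 6000, base + 7999)
        b.hit("ref", r1, f"UA_{tag}", (0.0, 0.4))
        b.hit("ref", r2, f"UB_{tag}", (0.0, 0.4))
        b.hit("pipe", p1, f"UC_{tag}", (0.0, 0.9))
        b.hit("pipe", p2, f"UD_{tag}", (0.0, 0.9))
        b.record(kind, "many_to_many", [r1.gene_id, r2.gene_id],
                 [p1.gene_id, p2.gene_id], [],
                 [p1.gene_id, p2.gene_id])
    else:  # pragma: no cover
        raise ValueError(f"unknown plant kind {kind!r}")


def make_annotation_pair(spec: FixtureSpec, outdir: str) -> Dict[str, str]:
    """Write ref.gtf, pipe.gtf, ref_blast.tsv, pipe_blast.tsv and truth.tsv.

    Each planted component occupies its own genomic window so no
    unintended overlaps arise.  Raises ValueError when the genome cannot
    hold all components.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    plan: List[str] = (
        ["one2one"] * spec.n_one_to_one
        + ["refonly"] * spec.n_ref_only
        + ["pipehit"] * spec.n_pipe_only_hit
        + ["pipenohit"] * spec.n_pipe_only_nohit
        + ["frag"] * spec.n_fragmentation
        + ["fusion"] * spec.n_fusion
        + ["many2one"] * spec.n_many_to_one
        + ["many2many"] * spec.n_many_many
    )
    windows: List[Tuple[str, int]] = []
    for seqid, length in spec.genome:
        windows.extend((seqid, w) for w in range(0, length - _WINDOW + 1, _WINDOW))
    if len(plan) > len(windows):
        raise ValueError(
            f"genome holds {len(windows)} component windows but "
            f"{len(plan)} components requested; provide a larger genome"
        )
    order = rng.permutation(len(plan))
    b = _Builder(rng)
    counters: Dict[str, int] = {}
    for slot, k in enumerate(order):
        kind = plan[k]
        counters[kind] = counters.get(kind, 0) + 1
        seqid, w = windows[slot]
        _plant(b, kind, counters[kind], seqid, w)

    paths = {
        "ref_gtf": os.path.join(outdir, "ref.gtf"),
        "pipe_gtf": os.path.join(outdir, "pipe.gtf"),
        "ref_blast": os.path.join(outdir, "ref_blast.tsv"),
        "pipe_blast": os.path.join(outdir, "pipe_blast.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_gtf(Annotation(b.ref), paths["ref_gtf"])
    write_gtf(Annotation(b.pipe), paths["pipe_gtf"])
    for rows, key in ((b.ref_rows, "ref_blast"), (b.pipe_rows, "pipe_blast")):
        pd.DataFrame(sorted(rows)).to_csv(
            paths[key], sep="\t", header=False, index=False
        )
    pd.DataFrame(b.truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def make_counts(spec: FixtureSpec, outdir: str) -> Dict[str, str]:
    """Write counts.tsv, conditions.tsv and counts_truth.tsv.

    Signal genes: negative binomial, per-gene mean lognormally scattered
    around ``nb_mean``, shared across all samples (concordant replicates).
    Noise genes: present in each sample with probability
    ``noise_presence``, and then negative binomial at ``noise_mean``
    (discordant, uninformative signal).
    """
    os.makedirs(outdir, exist_ok=True)
    cs = spec.counts
    rng = np.random.default_rng(spec.seed + 1)

    samples = [
        f"{cond}_rep{r + 1}"
        for cond in cs.conditions
        for r in range(cs.replicates)
    ]
    n_s = len(samples)

    def nb(mean: np.ndarray, size) -> np.ndarray:
        # NB(mean m, dispersion d): size r = 1/d, p = r / (r + m)
        r = 1.0 / cs.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)

    sig_means = cs.nb_mean * rng.lognormal(0.0, 0.5, size=cs.n_signal_genes)
    signal = nb(sig_means[:, None], (cs.n_signal_genes, n_s))

    present = rng.random((cs.n_noise_genes, n_s)) < cs.noise_presence
    noise = nb(np.full((cs.n_noise_genes, n_s), cs.noise_mean),
               (cs.n_noise_genes, n_s)) * present

    gene_ids = [f"sig{i + 1}" for i in range(cs.n_signal_genes)] + [
        f"noise{i + 1}" for i in range(cs.n_noise_genes)
    ]
    counts = np.vstack([signal, noise]).astype(int)
    lengths = rng.integers(500, 5001, size=len(gene_ids))

    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "conditions": os.path.join(outdir, "conditions.tsv"),
        "lengths": os.path.join(outdir, "gene_lengths.tsv"),
        "truth": os.path.join(outdir, "counts_truth.tsv"),
    }
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=samples)
    df.to_csv(paths["counts"], sep="\t")
    with open(paths["conditions"], "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{s.rsplit('_rep', 1)[0]}\n")
    with open(paths["lengths"], "w") as fh:
        for g, L in zip(gene_ids, lengths):
            fh.write(f"{g}\t{L}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g in gene_ids:
            fh.write(f"{g}\t{'signal' if g.startswith('sig') else 'noise'}\n")
    return paths
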