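import numpy as np
import pytest

from annomerge import (
    Annotation,
    CountsMatrix,
    FixtureSpec,
    GeneModel,
    make_annotation_pair,
    make_counts,
    read_blast_tab,
    read_gtf,
)


def attach_query_lengths(ann, hits):
    """Give each gene's HitSet its protein length from the annotation."""
    for g in ann:
        hs = hits.get(g.gene_id)
        if hs is not None:
            hs.query_length = g.protein_length


def load_pair(paths):
    """Parse a generated annotation-pair fixture back into objects."""
    ref = read_gtf(paths["ref_gtf"], source_tag="reference")
    pipe = read_gtf(paths["pipe_gtf"], source_tag="pipeline")
    ref_hits = read_blast_tab(paths["ref_blast"])
    pipe_hits = read_blast_tab(paths["pipe_blast"])
    attach_query_lengths(ref, ref_hits)
    attach_query_lengths(pipe, pipe_hits)
    return ref, pipe, ref_hits, pipe_hits


def random_annotation(rng, n_genes, seqids=("chr1", "chr2"), tag="reference",
                      prefix="g", span=100_000):
    """A random gene set for oracle-equivalence tests (overlaps allowed)."""
    genes = []
    for i in range(n_genes):
        seqid = seqids[int(rng.integers(len(seqids)))]
        start = int(rng.integers(1, span))
        length = int(rng.integers(200, 5000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"{prefix}{i}",
                seqid=seqid,
                strand=strand,
                start=start,
                end=start + length,
                source_tag=tag,
            )
        )
    return Annotation(genes)


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """Default planted annotation pair plus parsed objects (seed 11)."""
    outdir = tmp_path_factory.mktemp("planted")
    spec = FixtureSpec(seed=11)
    paths = make_annotation_pair(spec, str(outdir))
    ref, pipe, ref_hits, pipe_hits = load_pair(paths)
    return {
        "spec": spec,
        "paths": paths,
        "ref": ref,
        "pipe": pipe,
        "ref_hits": ref_hits,
        "pipe_hits": pipe_hits,
    }


@pytest.fixture(scope="session")
def planted_counts(tmp_path_factory):
    """Default planted count matrix with signal/noise truth (seed 11)."""
    outdir = tmp_path_factory.mktemp("planted_counts")
    spec = FixtureSpec(seed=11)
    paths = make_counts(spec, str(outdir))
    cm = CountsMatrix.from_tsv(paths["counts"], paths["conditions"],
                               paths["lengths"])
    return {"spec": spec, "paths": paths, "cm": cm}


@pytest.fixture
def toy_counts():
    """Small deterministic counts matrix: 6 genes x 4 samples, 2 conditions."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 500, size=(6, 4))
    return CountsMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=["a1", "a2", "b1", "b2"],
        counts=counts,
        condition_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        gene_length_bp=np.array([500, 1000, 1500, 2000, 2500, 3000]),
    )
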