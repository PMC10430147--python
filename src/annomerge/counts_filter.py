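"""Count-matrix normalization (TMM scale factors, FPKM) and the
replicate-similarity Jaccard filter for low/uninformative expression.

TMM ("trimmed mean of M-values") computes one scale factor per sample
relative to a reference sample (the one whose upper-quartile of
library-size-scaled counts is closest to the mean upper-quartile).  For
each sample the factor is ``2**f`` where ``f`` is the precision-weighted
mean of the gene-wise log2 expression ratios M, after trimming the most
extreme ``trim_m`` of M values and ``trim_a`` of average-abundance (A)
values; weights are inverse approximate (delta-method) binomial variances.
Factors are rescaled so their geometric mean is 1.

The Jaccard filter chooses a threshold ``s`` on the TMM-normalized count
scale by maximizing replicate agreement: for each candidate ``s`` the
matrix is binarized (normalized count >= s means "expressed") and the
Jaccard index |both| / |either| is computed over every within-condition
replicate pair; the global index is the mean over pairs.  The ``s*`` with
the highest global index is the data-driven threshold, and a gene is
removed iff its normalized count is below ``s*`` in every sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountsMatrix",
    "FilterResult",
    "tmm_factors",
    "fpkm",
    "normalized_counts",
    "jaccard_filter",
]

logger = logging.getLogger(__name__)

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


@dataclass
class CountsMatrix:
    """Raw read counts, genes x samples, with condition labels.

    counts : (n_genes, n_samples) non-negative integer array
    condition_of : sample_id -> condition label
    gene_length_bp : optional per-gene length (for FPKM), aligned to gene_ids
    """

    gene_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray
    condition_of: Dict[str, str] = field(default_factory=dict)
    gene_length_bp: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_length_bp is not None:
            self.gene_length_bp = np.asarray(self.gene_length_bp)
            if self.gene_length_bp.shape != (len(self.gene_ids),):
                raise ValueError("gene_length_bp must align with gene_ids")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str]) -> "CountsMatrix":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        return CountsMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            condition_of=dict(self.condition_of),
            gene_length_bp=(
                self.gene_length_bp[idx] if self.gene_length_bp is not None else None
            ),
        )

    @classmethod
    def from_tsv(
        cls,
        counts_path: str,
        conditions_path: Optional[str] = None,
        lengths_path: Optional[str] = None,
    ) -> "CountsMatrix":
        """Load counts (first column gene_id, header = sample ids) plus an
        optional 2-column (sample_id, condition) map and 2-column
        (gene_id, length_bp) table."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond: Dict[str, str] = {}
        if conditions_path:
            cmap = pd.read_csv(
                conditions_path, sep="\t", names=["sample_id", "condition"],
                header=None, comment="#", dtype=str,
            )
            cond = dict(zip(cmap["sample_id"], cmap["condition"]))
        lengths = None
        if lengths_path:
            lf = pd.read_csv(
                lengths_path, sep="\t", names=["gene_id", "length_bp"],
                header=None, comment="#", dtype={"gene_id": str},
            ).set_index("gene_id")
            lengths = lf.loc[df.index, "length_bp"].to_numpy(dtype=float)
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
            condition_of=cond,
            gene_length_bp=lengths,
        )

    def to_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class FilterResult:
    s_star: float
    jaccard_curve: List[Tuple[float, float]]
    kept_gene_ids: List[str]
    removed_gene_ids: List[str]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Scale factor of one sample against the reference column.

    Direct transcription of the trimmed, precision-weighted mean of
    log-ratios; genes with a zero in either column carry infinite
    log-ratio/abundance and are excluded.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # delta-method variance of M under binomial sampling
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(
    cm: CountsMatrix,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> np.ndarray:
    """Per-sample TMM scale factors, geometric mean 1.

    Raises
    ------
    ValueError
        With fewer than 2 samples, or if some sample has zero total counts
        (named in the message).
    """
    if len(cm.sample_ids) < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = cm.library_sizes
    for sid, total in zip(cm.sample_ids, lib):
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero total counts")

    x = cm.counts.astype(float)
    # upper-quartile of library-size-scaled counts picks the reference
    uq = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx],
                             trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def fpkm(cm: CountsMatrix) -> np.ndarray:
    """Fragments per kilobase per million mapped fragments.

    fpkm[g, s] = counts[g, s] * 1e9 / (gene_length_bp[g] * total_counts[s])
    """
    if cm.gene_length_bp is None:
        raise ValueError("gene_length_bp required for FPKM")
    bad = [g for g, L in zip(cm.gene_ids, cm.gene_length_bp) if not L > 0]
    if bad:
        raise ValueError(f"genes with missing/non-positive length: {bad}")
    lib = cm.library_sizes
    return cm.counts * 1e9 / (cm.gene_length_bp[:, None] * lib[None, :])


def normalized_counts(
    cm: CountsMatrix, factors: Optional[np.ndarray] = None
) -> np.ndarray:
    """TMM-normalized counts on a per-library-scaled count scale.

    value[g, s] = counts[g, s] / (library_size[s] * factor[s]) * mean library
    size, so thresholds on it read as counts in an average-sized library.
    """
    if factors is None:
        factors = tmm_factors(cm)
    lib = cm.library_sizes
    eff = lib * np.asarray(factors)
    return cm.counts / eff[None, :] * lib.mean()


def _replicate_pairs(cm: CountsMatrix) -> List[Tuple[int, int]]:
    by_cond: Dict[str, List[int]] = {}
    for j, sid in enumerate(cm.sample_ids):
        cond = cm.condition_of.get(sid)
        if cond is None:
            raise ValueError(f"sample {sid!r} has no condition label")
        by_cond.setdefault(cond, []).append(j)
    for cond, idx in by_cond.items():
        if len(idx) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(idx)} sample(s); filtering "
                "requires >= 2 replicates per condition"
            )
    pairs: List[Tuple[int, int]] = []
    for cond in sorted(by_cond):
        pairs.extend(combinations(by_cond[cond], 2))
    return pairs


def _global_jaccard(present: np.ndarray, pairs: List[Tuple[int, int]]) -> float:
    vals = []
    for i, j in pairs:
        both = int(np.sum(present[:, i] & present[:, j]))
        either = int(np.sum(present[:, i] | present[:, j]))
        if either == 0:
            warnings.warn(
                "replicate pair with no present gene in either sample; "
                "its Jaccard index is defined as 0",
                stacklevel=3,
            )
            vals.append(0.0)
        else:
            vals.append(both / either)
    return float(np.mean(vals))


def default_s_grid(norm: np.ndarray, n_points: int = 200) -> np.ndarray:
    """Quantiles of the distinct normalized values (n_points of them), plus 0."""
    distinct = np.unique(norm)
    qs = np.quantile(distinct, np.linspace(0.0, 1.0, n_points))
    return np.unique(np.concatenate(([0.0], qs)))


def jaccard_filter(
    cm: CountsMatrix,
    s_grid: Optional[Sequence[float]] = None,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> FilterResult:
    """Data-driven low-expression filter maximizing replicate similarity.

    For each candidate threshold ``s`` the TMM-normalized matrix is
    binarized at ``s`` and the mean Jaccard index over within-condition
    replicate pairs is recorded; ``s*`` is the argmax (smallest such ``s``
    on ties).  A gene is removed iff its normalized value is < ``s*`` in
    ALL samples.
    """
    factors = tmm_factors(cm, trim_m=trim_m, trim_a=trim_a)
    norm = normalized_counts(cm, factors)
    pairs = _replicate_pairs(cm)

    grid = (
        np.asarray(sorted(set(float(s) for s in s_grid)))
        if s_grid is not None
        else default_s_grid(norm)
    )

    curve: List[Tuple[float, float]] = []
    best_s, best_j = float(grid[0]), -1.0
    for s in grid:
        # present = detected (nonzero) at level >= s; the detection clause
        # only matters at s = 0, where an unobserved gene is still absent
        gj = _global_jaccard((norm >= s) & (norm > 0), pairs)
        curve.append((float(s), gj))
        if gj > best_j:  # strict: ties keep the smallest s
            best_s, best_j = float(s), gj

    removed_mask = (norm < best_s).all(axis=1)
    kept = [g for g, r in zip(cm.gene_ids, removed_mask) if not r]
    removed = [g for g, r in zip(cm.gene_ids, removed_mask) if r]
    logger.info(
        "jaccard_filter: s*=%.4g, global Jaccard %.4f, kept %d / removed %d genes",
        best_s, best_j, len(kept), len(removed),
    )
    return FilterResult(
        s_star=best_s, jaccard_curve=curve, kept_gene_ids=kept,
        removed_gene_ids=removed,
    )
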