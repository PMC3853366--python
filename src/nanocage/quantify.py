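"""Gene-level digital-expression statistics.

Aggregates cluster tags to genes (same strand only), computes pairwise
Pearson correlations on TPM (optionally log10), rarefies libraries to a
fixed tag depth by sampling without replacement, counts detected loci,
intersects locus lists across pools, and provides the same-source
resampling null: how many loci would be common if every pool were just a
random subsample of one reference library.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ctss_cluster import tpm_matrix

COUNTED_BASKETS = ("promoter", "exon", "intron")


def gene_counts(
    classified: pd.DataFrame, sample_counts: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Gene x sample tag-count matrix.

    Sums tags of same-strand clusters assigned to each gene (promoter,
    exon and intron baskets); clusters without a gene are excluded.
    """
    keep = classified[
        classified["basket"].isin(COUNTED_BASKETS) & classified["gene_id"].notna()
    ]
    if sample_counts is None:
        df = keep.groupby("gene_id")[["count"]].sum()
        df.columns = ["pooled"]
        return df
    joined = sample_counts.join(
        keep.set_index("cluster_id")["gene_id"], how="inner"
    )
    return joined.groupby("gene_id").sum().astype(int)


def pairwise_pearson(
    matrix: pd.DataFrame,
    pseudocount: float = 1.0,
    log_scale: bool = False,
    normalize: bool = True,
) -> pd.DataFrame:
    """Gene-wise Pearson correlation between every pair of samples.

    Computed on TPM-normalized counts; with ``log_scale`` on
    log10(TPM + pseudocount).  Zero-variance columns yield NaN for their
    pairs (with a warning).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two genes")
    x = tpm_matrix(matrix) if normalize else matrix.astype(float)
    if log_scale:
        x = np.log10(x + pseudocount)
    var = x.var(axis=0)
    if (var == 0).any():
        warnings.warn(
            f"zero-variance sample(s): {list(var.index[var == 0])}; "
            "their correlations are NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return x.corr(method="pearson")


def rarefy(
    counts, n: int = 30_000, seed: int | np.random.Generator | None = None
):
    """Subsample a count vector to exactly ``n`` tags without replacement.

    Multivariate hypergeometric draw; reproducible under ``seed``.
    """
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    if n == 0:
        out = np.zeros_like(arr)
    elif total < n:
        raise ValueError(f"cannot draw {n} tags from a library of {total}")
    elif total == n:
        out = arr.copy()
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        out = rng.multivariate_hypergeometric(arr, n)
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out


def detected_loci(counts) -> int:
    """Number of genes with at least one tag."""
    return int((np.asarray(counts) >= 1).sum())


def common_loci(pools: list[set]) -> int:
    """Size of the intersection of detected-locus sets."""
    if not pools:
        return 0
    it = iter(pools)
    inter = set(next(it))
    for p in it:
        inter &= set(p)
    return len(inter)


def detected_set(counts) -> set:
    s = pd.Series(counts)
    return set(s.index[s >= 1])


def resampling_null(
    reference: pd.Series, sizes: list[int], seed: int | np.random.Generator | None = None
) -> int:
    """Common loci expected when all pools are subsamples of one library.

    Replaces each comparison pool by a without-replacement subsample of
    the reference's tags at that pool's depth, then intersects the
    detected-locus sets (reference included).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pools = [detected_set(reference)]
    for n in sizes:
        sub = rarefy(reference, n, rng)
        pools.append(detected_set(sub))
    return common_loci(pools)
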