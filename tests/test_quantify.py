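"""Gene-level digital expression: counts, correlation, rarefaction, loci."""

import numpy as np
import pandas as pd
import pytest

from nanocage.quantify import (
    common_loci,
    detected_loci,
    detected_set,
    gene_counts,
    pairwise_pearson,
    rarefy,
    resampling_null,
)


def _classified():
    return pd.DataFrame(
        {
            "cluster_id": ["c1", "c2", "c3", "c4"],
            "basket": ["promoter", "exon", "other", "intron"],
            "gene_id": ["g1", "g1", None, "g2"],
            "count": [10, 5, 7, 3],
        }
    )


def test_gene_counts_pools_same_strand_baskets():
    gc = gene_counts(_classified())
    assert gc.loc["g1", "pooled"] == 15  # promoter 10 + exon 5
    assert gc.loc["g2", "pooled"] == 3
    assert "None" not in gc.index  # unassigned clusters excluded


def test_gene_counts_with_sample_matrix():
    counts = pd.DataFrame(
        {"s1": [4, 6, 1, 0], "s2": [0, 2, 9, 1]},
        index=["c1", "c2", "c3", "c4"],
    )
    counts.index.name = "cluster_id"
    gc = gene_counts(_classified(), counts)
    assert gc.loc["g1", "s1"] == 10 and gc.loc["g1", "s2"] == 2
    assert gc.loc["g2", "s2"] == 1


def test_pearson_self_and_scaled_copy():
    rng = np.random.default_rng(0)
    base = rng.poisson(20, 50)
    mat = pd.DataFrame({"a": base, "b": 2 * base})
    corr = pairwise_pearson(mat)
    # TPM normalization makes a scaled copy identical
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "a"] == pytest.approx(1.0)
    assert (corr.values.T == corr.values).all()


def test_pearson_log_scale_changes_value():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(
        {"a": rng.poisson(5, 200) + 1, "b": rng.poisson(5, 200) + 1}
    )
    lin = pairwise_pearson(mat).loc["a", "b"]
    log = pairwise_pearson(mat, log_scale=True).loc["a", "b"]
    assert lin != pytest.approx(log)


def test_pearson_zero_variance_is_nan():
    mat = pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5]})
    with pytest.warns(UserWarning):
        corr = pairwise_pearson(mat)
    assert np.isnan(corr.loc["a", "b"])


def test_pearson_recovers_simulation_truth():
    """Two NB libraries sharing gene means correlate as a Monte-Carlo
    oracle predicts (within 3 SE of the replicate distribution)."""
    rng = np.random.default_rng(7)
    means = rng.gamma(2.0, 50.0, 300)
    disp = 0.2  # NB with var = mu + disp * mu^2

    def nb(mu, rng):
        shape = 1.0 / disp
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam)

    reps = []
    for _ in range(300):
        a, b = nb(means, rng), nb(means, rng)
        with np.errstate(invalid="ignore"):
            reps.append(np.corrcoef(a, b)[0, 1])
    oracle_mean, oracle_sd = np.mean(reps), np.std(reps)

    rng2 = np.random.default_rng(1234)
    mat = pd.DataFrame({"x": nb(means, rng2), "y": nb(means, rng2)})
    r = pairwise_pearson(mat, normalize=False).loc["x", "y"]
    assert abs(r - oracle_mean) < 3 * oracle_sd


def test_rarefy_exact_total_and_bounds():
    rng = np.random.default_rng(0)
    counts = pd.Series(rng.poisson(10, 100), index=[f"g{i}" for i in range(100)])
    sub = rarefy(counts, 300, seed=1)
    assert sub.sum() == 300
    assert (sub <= counts).all()
    assert list(sub.index) == list(counts.index)


def test_rarefy_identity_zero_and_error():
    counts = pd.Series([5, 5])
    assert (rarefy(counts, 10) == counts).all()  # total == n: identity
    assert rarefy(counts, 0).sum() == 0
    with pytest.raises(ValueError, match="10"):
        rarefy(counts, 11)


def test_rarefy_reproducible_under_seed():
    counts = np.arange(1, 50)
    a = rarefy(counts, 500, seed=9)
    b = rarefy(counts, 500, seed=9)
    assert (a == b).all()


def test_rarefied_share_tracks_hypergeometric():
    """A gene holding 10% of tags keeps ~10% after subsampling."""
    counts = np.array([3000] + [27] * 1000)  # 10% + tail
    total, n = counts.sum(), 3000
    p = counts[0] / total
    se = np.sqrt(n * p * (1 - p) * (total - n) / (total - 1)) / n
    rng = np.random.default_rng(5)
    shares = [rarefy(counts, n, rng)[0] / n for _ in range(30)]
    assert abs(np.mean(shares) - p) < 3 * se / np.sqrt(len(shares))


def test_detected_loci_counting():
    assert detected_loci(np.zeros(5)) == 0
    assert detected_loci(pd.Series([0, 1, 5, 0, 2])) == 3


def test_detected_loci_monotone_in_depth():
    rng = np.random.default_rng(11)
    counts = pd.Series(rng.zipf(1.6, 2000).clip(max=500))
    shallow = [detected_loci(rarefy(counts, 500, rng)) for _ in range(50)]
    deep = [detected_loci(rarefy(counts, 5000, rng)) for _ in range(50)]
    assert np.mean(shallow) < np.mean(deep)


def test_common_loci_trivia():
    assert common_loci([{"a", "b"}, {"a", "b"}]) == 2
    assert common_loci([{"a"}, {"b"}]) == 0
    assert common_loci([]) == 0
    assert common_loci([set(), {"a"}]) == 0


def test_resampling_null_exceeds_independent_pools():
    """Subsamples of one library share more loci than independent
    libraries with chemistry-specific noise, and miss low-count loci."""
    rng = np.random.default_rng(21)
    n_genes = 2000
    w = (np.arange(1, n_genes + 1, dtype=float)) ** -1.0
    w /= w.sum()
    genes = [f"g{i}" for i in range(n_genes)]

    def lib(depth, jitter_rng):
        noise = jitter_rng.lognormal(0, 0.8, n_genes)  # chemistry noise
        p = w * noise
        p /= p.sum()
        return pd.Series(jitter_rng.multinomial(depth, p), index=genes)

    ref = pd.Series(rng.multinomial(30_000, w), index=genes)
    indep = [lib(20_000, np.random.default_rng(100 + i)) for i in range(2)]
    independent_common = common_loci(
        [detected_set(ref)] + [detected_set(x) for x in indep]
    )
    null_common = resampling_null(ref, [20_000, 20_000], seed=3)
    assert null_common > independent_common
    assert null_common < detected_loci(ref)  # low-count loci still missed
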