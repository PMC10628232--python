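"""Statistics core: each test checks against an independent oracle
(exhaustive enumeration, closed form, or an established library)."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopdiff import nbstats
from loopdiff.genome import GenomeLayout

from conftest import nb_count_table


# ------------------------------------------------------------------ BH


def test_bh_hand_computed_example():
    # q_i = min_{j: p_(j) >= p_(i)} m p_(j) / j
    q = nbstats.bh_adjust([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])


@pytest.mark.parametrize(
    "pvals,expected",
    [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ([0.07], [0.07])],
)
def test_bh_degenerate_cases(pvals, expected):
    assert np.allclose(nbstats.bh_adjust(pvals), expected)


def test_bh_matches_statsmodels_and_is_monotone():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    for _ in range(50):
        p = rng.random(rng.integers(2, 40))
        q = nbstats.bh_adjust(p)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_ref, rtol=1e-12, atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_nan_propagates_and_excluded_from_m():
    q = nbstats.bh_adjust([0.01, np.nan, 0.02])
    assert np.isnan(q[1])
    # m = 2: q = (2*0.01/1 capped by cummin of 2*0.02/2) -> both 0.02
    assert np.allclose(q[[0, 2]], [0.02, 0.02])


# --------------------------------------------------------------- Fisher


def _fisher_enumeration(table):
    """Independent oracle: enumerate all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    probs = {}
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        probs[k] = comb(c1, k) * comb(n - c1, r1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_no_association():
    orr, p = nbstats.fisher_2x2([[5, 5], [5, 5]])
    assert orr == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


@pytest.mark.parametrize("table", [[[3, 1], [1, 3]], [[10, 0], [0, 10]]])
def test_fisher_enumeration_examples(table):
    _, p = nbstats.fisher_2x2(table)
    assert p == pytest.approx(_fisher_enumeration(table), rel=1e-10)


def test_fisher_random_instances_match_enumeration():
    rng = np.random.default_rng(3)
    checked = 0
    while checked < 60:
        t = rng.integers(0, 25, size=(2, 2))
        if min(t.sum(0).min(), t.sum(1).min()) == 0:
            continue
        _, p = nbstats.fisher_2x2(t)
        assert p == pytest.approx(_fisher_enumeration(t.tolist()), rel=1e-10)
        checked += 1


def test_fisher_zero_margin_rejected():
    with pytest.raises(ValueError):
        nbstats.fisher_2x2([[0, 0], [3, 4]])


# ------------------------------------------------------------- rank sum


def test_ranksum_separated_samples_exact():
    # all x below all y: one ordering per tail of C(6,3)=20 -> doubled 0.1
    w, p = nbstats.rank_sum_test([1, 2, 3], [4, 5, 6])
    assert w == 6.0
    assert p == pytest.approx(0.1)


def test_ranksum_single_observations():
    _, p = nbstats.rank_sum_test([1], [2])
    assert p == pytest.approx(1.0)


def test_ranksum_exact_matches_scipy_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(60):
        nx, ny = rng.integers(1, 7, 2)
        x, y = rng.normal(size=nx), rng.normal(size=ny)
        _, p = nbstats.rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-10)


def test_ranksum_large_sample_calibration():
    rng = np.random.default_rng(5)
    ps = [
        nbstats.rank_sum_test(rng.normal(size=30), rng.normal(size=25))[1]
        for _ in range(300)
    ]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_ranksum_identical_values_rejected():
    with pytest.raises(ValueError):
        nbstats.rank_sum_test([2.0, 2.0], [2.0])


# ------------------------------------------------------- hypergeometric


def test_hypergeom_summation_oracle():
    ratio, p = nbstats.hypergeom_enrich(4, 10, 20, 100)
    direct = sum(stats.hypergeom.pmf(k, 100, 20, 10) for k in range(4, 11))
    assert p == pytest.approx(direct, rel=1e-10)
    assert ratio == pytest.approx((4 / 10) / (20 / 100))


def test_hypergeom_extreme_and_null():
    K, N = 5, 200
    ratio, p = nbstats.hypergeom_enrich(K, K, K, N)
    assert ratio == pytest.approx(N / K)
    assert p == pytest.approx(1 / comb(N, K), rel=1e-10)
    ratio, _ = nbstats.hypergeom_enrich(5, 50, 10, 100)
    assert ratio == pytest.approx(1.0)


def test_hypergeom_random_instances():
    rng = np.random.default_rng(6)
    for _ in range(60):
        N = int(rng.integers(20, 200))
        n = int(rng.integers(1, N))
        K = int(rng.integers(1, N))
        k = int(rng.integers(0, min(K, n) + 1))
        _, p = nbstats.hypergeom_enrich(k, K, n, N)
        direct = sum(
            stats.hypergeom.pmf(x, N, n, K) for x in range(k, min(K, n) + 1)
        )
        assert p == pytest.approx(min(1.0, direct), rel=1e-9, abs=1e-12)


def test_fisher_upper_tail_agrees_with_hypergeom():
    # one-sided Fisher = hypergeometric tail on the same 2x2
    a, b, c, d = 8, 2, 5, 15
    _, p_hyp = nbstats.hypergeom_enrich(a, a + b, a + c, a + b + c + d)
    ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    assert p_hyp == pytest.approx(ref, rel=1e-10)


# ------------------------------------------------------------ dispersion


def test_dispersion_poisson_data_near_zero():
    table = nb_count_table(phi=0.0, m=1500, n=3, seed=2)
    est = nbstats.estimate_dispersion(table)
    assert est.common < 0.01


def test_dispersion_recovery_phi_02():
    table = nb_count_table(phi=0.2, m=2000, n=4, seed=3)
    est = nbstats.estimate_dispersion(table)
    assert 0.15 <= est.common <= 0.25


def test_dispersion_single_sample_per_group_rejected():
    counts = pd.DataFrame({"a": [5, 9], "b": [7, 8]})
    groups = pd.Series(["A", "B"], index=["a", "b"])
    with pytest.raises(ValueError):
        nbstats.estimate_dispersion(nbstats.CountTable(counts, groups))


# --------------------------------------------------------------- NB test


def _binomial_split_oracle(c1, c2):
    """Poisson-limit conditional test: binomial split of the pooled sum."""
    s1, s2 = int(sum(c1)), int(sum(c2))
    s = s1 + s2
    if s == 0:
        return 1.0
    pm = stats.binom.pmf(np.arange(s + 1), s, len(c1) / (len(c1) + len(c2)))
    return min(1.0, pm[pm <= pm[s1] * (1 + 1e-12)].sum())


def test_nb_test_symmetric_counts_null():
    counts = pd.DataFrame({"a1": [10], "a2": [10], "b1": [10], "b2": [10]})
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    ct = nbstats.CountTable(counts, groups, lib_sizes=pd.Series(100.0, index=counts.columns))
    res = nbstats.nb_test(ct, 0.3)
    assert res["log2fc"].iloc[0] == pytest.approx(0.0)
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_nb_test_poisson_limit_matches_binomial_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n1, n2 = rng.integers(2, 5, 2)
        c1 = rng.integers(0, 25, size=n1)
        c2 = rng.integers(0, 25, size=n2)
        if c1.sum() + c2.sum() == 0:
            continue
        counts = pd.DataFrame(
            {
                **{f"A{i}": [int(c1[i])] for i in range(n1)},
                **{f"B{i}": [int(c2[i])] for i in range(n2)},
            }
        )
        groups = pd.Series([c[0] for c in counts.columns], index=counts.columns)
        ct = nbstats.CountTable(
            counts, groups, lib_sizes=pd.Series(1000.0, index=counts.columns)
        )
        res = nbstats.nb_test(ct, 0.0)
        assert res["p"].iloc[0] == pytest.approx(
            _binomial_split_oracle(c1, c2), rel=1e-10
        )


def test_nb_test_fdr_calibration_under_null():
    # null NB features at FDR 10%: false discoveries stay near/below nominal
    fdps = []
    for seed in range(5):
        table = nb_count_table(phi=0.1, m=2000, n=3, seed=100 + seed)
        est = nbstats.estimate_dispersion(table)
        res = nbstats.nb_test(table, est)
        disc = int((res["q"] < 0.1).sum())
        fdps.append(1.0 if disc > 0 else 0.0)
    assert np.mean(fdps) <= 0.15


def test_nb_test_requires_two_groups():
    counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]})
    groups = pd.Series(["A", "B", "C"], index=counts.columns)
    with pytest.raises(ValueError):
        nbstats.nb_test(nbstats.CountTable(counts, groups), 0.1)


# ---------------------------------------------------- permutation overlap


def test_overlap_query_equals_targets(small_layout):
    df = pd.DataFrame(
        {"chrom": ["chr1"] * 5, "start": np.arange(5) * 10_000, "end": np.arange(5) * 10_000 + 500}
    )
    res = nbstats.permutation_overlap_null(df, df, small_layout, n_iter=99, seed=0)
    assert res.observed == 1.0
    if (res.null < 1.0).all():
        assert res.p == pytest.approx(1 / 100)


def test_overlap_empty_targets(small_layout):
    q = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
    t = pd.DataFrame({"chrom": [], "start": [], "end": []})
    res = nbstats.permutation_overlap_null(q, t, small_layout, n_iter=50, seed=0)
    assert res.observed == 0.0
    assert (res.null == 0.0).all()
    assert res.p == 1.0


def test_overlap_null_mean_matches_coverage_fraction():
    layout = GenomeLayout.from_dict({"chr1": 1_000_000})
    # targets covering exactly 20% of the chromosome
    t = pd.DataFrame(
        {"chrom": ["chr1"] * 10, "start": np.arange(10) * 100_000, "end": np.arange(10) * 100_000 + 20_000}
    )
    q = pd.DataFrame(
        {"chrom": ["chr1"] * 200, "start": np.arange(200) * 4_000, "end": np.arange(200) * 4_000 + 1}
    )
    res = nbstats.permutation_overlap_null(q, t, layout, n_iter=400, seed=1)
    se = np.sqrt(0.2 * 0.8 / 200) / np.sqrt(400)
    assert res.null.mean() == pytest.approx(0.2, abs=4 * se)


def test_overlap_element_longer_than_chrom_rejected():
    layout = GenomeLayout.from_dict({"chr1": 1000})
    q = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
    t = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
    with pytest.raises(ValueError):
        nbstats.permutation_overlap_null(q, t, layout, n_iter=10, seed=0)


def test_overlap_reproducible_given_seed(small_layout):
    rng = np.random.default_rng(2)
    q = pd.DataFrame(
        {"chrom": "chr1", "start": (s := rng.integers(0, 1_900_000, 50)), "end": s + 700}
    )
    t = pd.DataFrame(
        {"chrom": "chr1", "start": (u := rng.integers(0, 1_900_000, 30)), "end": u + 5000}
    )
    a = nbstats.permutation_overlap_null(q, t, small_layout, n_iter=100, seed=9)
    b = nbstats.permutation_overlap_null(q, t, small_layout, n_iter=100, seed=9)
    assert np.array_equal(a.null, b.null)
    assert a.p == b.p


def test_child_seed_stable_and_bounded():
    s1 = nbstats.child_seed(42, "contacts", "cond1", 0)
    s2 = nbstats.child_seed(42, "contacts", "cond1", 0)
    s3 = nbstats.child_seed(42, "contacts", "cond2", 0)
    assert s1 == s2 != s3
    assert 0 <= s1 < 2**31
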