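"""Count statistics shared by every analysis stage.

Negative-binomial two-group differential testing (common + shrunken tagwise
dispersion, exact conditional test), Benjamini-Hochberg adjustment, Fisher's
exact 2x2 test, Wilcoxon rank-sum with exact small-sample enumeration,
hypergeometric set enrichment, and a length-preserving permutation null for
genomic interval overlap.

The NB model uses the var = mu + phi * mu^2 parameterization throughout. The
two-group test is an exact conditional test: counts are scaled to a common
library size, summed within groups, and the observed split of the pooled sum
is compared against its conditional NB distribution; the two-sided p-value
sums the probabilities of all splits no more likely than the observed one.
At phi = 0 this reduces to a two-sided binomial split test.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CountTable",
    "DispersionEstimate",
    "estimate_dispersion",
    "nb_test",
    "bh_adjust",
    "fisher_2x2",
    "rank_sum_test",
    "hypergeom_enrich",
    "permutation_overlap_null",
    "child_seed",
]


def child_seed(seed: int, *tags) -> int:
    """Deterministic per-operation seed (< 2**31) derived from a run seed."""
    # crc32, not hash(): stable across interpreter sessions
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, *(zlib.crc32(str(t).encode()) for t in tags)]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# =============================================================== count table


@dataclass
class CountTable:
    """Integer counts (features x samples) with group labels per sample."""

    counts: pd.DataFrame
    groups: pd.Series
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.groups.index):
            raise ValueError("every sample column needs a group label")
        self.groups = self.groups.loc[self.counts.columns]
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.loc[self.counts.columns].astype(float)
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def n_features(self) -> int:
        return len(self.counts)

    def group_names(self) -> list[str]:
        # first-appearance order, stable across runs
        return list(dict.fromkeys(self.groups))

    def scaled_counts(self) -> pd.DataFrame:
        """Counts rescaled to the geometric-mean library size (continuous)."""
        ref = float(np.exp(np.log(self.lib_sizes).mean()))
        return self.counts * (ref / self.lib_sizes)


# ============================================================= dispersion


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    n_dropped: int = 0


def _cond_loglik_matrix(y: np.ndarray, group_sizes, group_cols, phis: np.ndarray):
    """Conditional NB log-likelihood per (feature, phi-grid) summed over groups.

    y: scaled counts (features x samples); conditional on each group's total,
    using the continuous-count lgamma form. Returns (n_features, n_phi).
    """
    out = np.zeros((y.shape[0], len(phis)))
    for k, phi in enumerate(phis):
        r = 1.0 / max(phi, 1e-12)
        ll = np.zeros(y.shape[0])
        for cols, n in zip(group_cols, group_sizes):
            yg = y[:, cols]
            z = yg.sum(axis=1)
            ll += (
                special.gammaln(yg + r).sum(axis=1)
                + special.gammaln(n * r)
                - special.gammaln(z + n * r)
                - n * special.gammaln(r)
            )
        out[:, k] = ll
    return out


def estimate_dispersion(
    table: CountTable, prior_df: float = 20.0, grid_size: int = 60
) -> DispersionEstimate:
    """Common and shrunken per-feature NB dispersion.

    Common dispersion maximizes the conditional log-likelihood pooled over all
    features (counts first scaled to a common library size). Tagwise values
    maximize a weighted likelihood that shrinks each feature toward the common
    value with weight ``prior_df``.
    """
    groups = table.groups
    gnames = table.group_names()
    if not any((groups == g).sum() >= 2 for g in gnames):
        raise ValueError("dispersion needs >= 2 samples in at least one group")
    y_all = table.scaled_counts().values
    keep = y_all.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    y = y_all[keep]
    if y.shape[0] == 0:
        raise ValueError("no nonzero features")
    cols_all = np.arange(len(table.counts.columns))
    group_cols = [cols_all[(groups == g).values] for g in gnames]
    group_sizes = [len(c) for c in group_cols]

    def neg_total(lphi: float) -> float:
        ll = _cond_loglik_matrix(y, group_sizes, group_cols, np.array([10.0**lphi]))
        return -float(ll.sum())

    res = optimize.minimize_scalar(neg_total, bounds=(-8.0, 1.0), method="bounded")
    common = float(10.0 ** res.x)
    if common < 1e-7:
        common = 0.0

    phi_grid = np.concatenate([[1e-8], np.logspace(-4, 1, grid_size - 1)])
    L = _cond_loglik_matrix(y, group_sizes, group_cols, phi_grid)
    Lbar = L.mean(axis=0)  # average per-feature likelihood = shrinkage prior
    W = L + prior_df * Lbar[None, :]
    tag = phi_grid[np.argmax(W, axis=1)]
    tag = np.where(tag < 1e-7, 0.0, tag)
    tagwise = pd.Series(0.0, index=table.counts.index)
    tagwise.loc[table.counts.index[keep]] = tag
    tagwise.loc[table.counts.index[~keep]] = common
    return DispersionEstimate(common=common, tagwise=tagwise, n_dropped=n_dropped)


# ================================================================= NB test


def _exact_split_pvalue(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact conditional p for observing group-1 sum ``s1``.

    Group sums (library-size-scaled, rounded) are NB with means n_i * mu and
    dispersion phi / n_i. Conditional on s = s1 + s2 the distribution over
    splits does not depend strongly on mu; mu-hat = s / (n1 + n2) is plugged
    in. p sums P(k) over all splits with P(k) <= P(observed).
    """
    s1 = int(round(s1))
    s2 = int(round(s2))
    s = s1 + s2
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi <= 1e-8:
        # Poisson limit: split is Binomial(s, n1 / (n1 + n2))
        logp = stats.binom.logpmf(k, s, n1 / (n1 + n2))
    else:
        mu = s / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        m1, m2 = n1 * mu, n2 * mu
        logp = stats.nbinom.logpmf(k, r1, r1 / (r1 + m1)) + stats.nbinom.logpmf(
            s - k, r2, r2 / (r2 + m2)
        )
        logp -= special.logsumexp(logp)
    p_obs = logp[s1]
    mask = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(logp[mask]))))


def nb_test(
    table: CountTable,
    dispersions: DispersionEstimate | float | pd.Series,
    min_count: int = 0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Exact-style NB differential test between exactly two groups.

    Returns a frame indexed like the count table with per-group normalized
    means, log2FC (group2 vs group1, with pseudocount), the dispersion used,
    two-sided p, BH q, and direction. Features with total raw count below
    ``min_count`` are excluded from testing (and from the BH family) and
    reported with NaN p/q.
    """
    gnames = table.group_names()
    if len(gnames) != 2:
        raise ValueError(f"nb_test requires exactly two groups, got {gnames}")
    g1, g2 = gnames
    if isinstance(dispersions, DispersionEstimate):
        phi = dispersions.tagwise
    elif isinstance(dispersions, pd.Series):
        phi = dispersions
    else:
        phi = pd.Series(float(dispersions), index=table.counts.index)

    y = table.scaled_counts()
    cols1 = table.groups[table.groups == g1].index
    cols2 = table.groups[table.groups == g2].index
    n1, n2 = len(cols1), len(cols2)
    s1 = y[cols1].sum(axis=1).values
    s2 = y[cols2].sum(axis=1).values
    mean1 = s1 / n1
    mean2 = s2 / n2
    log2fc = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))

    total_raw = table.counts.sum(axis=1).values
    tested = total_raw >= min_count
    pvals = np.full(len(y), np.nan)
    phi_v = phi.loc[table.counts.index].values.astype(float)
    for i in np.nonzero(tested)[0]:
        pvals[i] = _exact_split_pvalue(s1[i], s2[i], n1, n2, phi_v[i])
    qvals = bh_adjust(pvals)

    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "log2fc": log2fc,
            "dispersion": phi_v,
            "p": pvals,
            "q": qvals,
            "direction": direction,
            "tested": tested,
        },
        index=table.counts.index,
    )


# ======================================================================= BH


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values; NaNs propagate, excluded from m."""
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


# ================================================================== Fisher


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (odds ratio, p). The odds ratio is the sample OR with a Haldane
    0.5 correction when any cell is zero. p sums hypergeometric probabilities
    of all tables with the observed margins whose probability does not exceed
    the observed table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_2x2 needs a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("fisher_2x2 requires positive margins")
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    lo, hi = max(0, r1 - c2), min(r1, c1)
    k = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(k, n, c1, r1)
    p_obs = logp[a - lo]
    p = float(np.exp(special.logsumexp(logp[logp <= p_obs + 1e-10])))
    return float(orr), min(1.0, p)


# ================================================================ rank sum


def rank_sum_test(x, y, exact_max: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    W is the rank sum of ``x`` using mid-ranks for ties. For pooled sample
    sizes <= ``exact_max`` the p-value enumerates every assignment of ranks
    to the x-sample (two-sided by doubling the smaller tail, capped at 1);
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; rank-sum test undefined")
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())

    if n <= exact_max:
        ws = np.array(
            [sum(c) for c in itertools.combinations(ranks, nx)]
        )
        total = len(ws)
        lo_tail = np.sum(ws <= w + 1e-9) / total
        hi_tail = np.sum(ws >= w - 1e-9) / total
        p = min(1.0, 2.0 * min(lo_tail, hi_tail))
        return w, float(p)

    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        raise ValueError("zero variance in rank-sum test")
    z = (w - mean_w - np.sign(w - mean_w) * 0.5) / np.sqrt(var_w)
    p = 2.0 * stats.norm.sf(abs(z))
    return w, float(min(1.0, p))


# =========================================================== hypergeometric


def hypergeom_enrich(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Set enrichment: observed/expected ratio and hypergeometric upper-tail p.

    ``k`` hits in a set of size ``K``, against ``n`` hits in a universe of
    size ``N``: obs/exp = (k/K)/(n/N); p = P(X >= k), X ~ Hypergeom(N, n, K).
    """
    if N <= 0:
        raise ValueError("universe must be nonempty")
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError("invalid hypergeometric configuration")
    if K == 0 or n == 0:
        return float("nan"), 1.0
    ratio = (k / K) / (n / N)
    p = float(stats.hypergeom.sf(k - 1, N, n, K))
    return ratio, min(1.0, p)


# ====================================================== permutation overlap


def _overlap_any(
    starts: np.ndarray, ends: np.ndarray, t_starts: np.ndarray, t_ends: np.ndarray
) -> np.ndarray:
    """Boolean per query interval: >= 1 bp intersection with merged targets."""
    if len(t_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(t_starts, ends, side="left")
    hit = np.zeros(len(starts), dtype=bool)
    has_prev = idx > 0
    hit[has_prev] = t_ends[idx[has_prev] - 1] > starts[has_prev]
    return hit


def _merge_intervals(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s = df["start"].values
    e = df["end"].values
    order = np.argsort(s, kind="mergesort")
    s, e = s[order], e[order]
    ms, me = [], []
    for a, b in zip(s, e):
        if me and a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.asarray(ms), np.asarray(me)


@dataclass
class OverlapNullResult:
    observed: float
    null: np.ndarray
    p: float
    n_query: int


def permutation_overlap_null(
    query: "pd.DataFrame | object",
    targets: "pd.DataFrame | object",
    layout,
    n_iter: int = 1000,
    seed: int = 0,
) -> OverlapNullResult:
    """Permutation null for the fraction of query intervals hitting targets.

    Each iteration re-places every query element uniformly at random within
    its own chromosome, preserving its length; overlap is any >= 1 bp
    intersection. Empirical p = (1 + #{null >= observed}) / (n_iter + 1).
    """
    qdf = query.df if hasattr(query, "df") else query
    tdf = targets.df if hasattr(targets, "df") else targets
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    nq = len(qdf)
    if nq == 0:
        raise ValueError("empty query set")
    rng = np.random.default_rng(seed)
    merged = {
        c: _merge_intervals(g) for c, g in tdf.groupby("chrom")
    }
    obs_hits = 0
    null_hits = np.zeros(n_iter)
    for chrom, g in qdf.groupby("chrom"):
        L = layout.length_of(chrom)
        lens = (g["end"] - g["start"]).values
        if (lens > L).any():
            raise ValueError(f"query element longer than chromosome {chrom}")
        ts, te = merged.get(chrom, (np.array([]), np.array([])))
        obs_hits += int(_overlap_any(g["start"].values, g["end"].values, ts, te).sum())
        # vectorized re-placement: (n_iter, n_elements) random starts
        max_start = (L - lens).astype(np.int64)
        starts = (rng.random((n_iter, len(lens))) * (max_start + 1)).astype(np.int64)
        ends = starts + lens
        for it in range(n_iter):
            null_hits[it] += _overlap_any(starts[it], ends[it], ts, te).sum()
    observed = obs_hits / nq
    null = null_hits / nq
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (n_iter + 1.0)
    return OverlapNullResult(observed=observed, null=null, p=float(p), n_query=nq)
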