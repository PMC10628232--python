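"""Expression-side analyses.

RPKM normalization, NB differential expression with FDR and fold-change
cutoffs, partitioning of a base differential gene set by dependence on a
factor (changed in either of two mutant comparisons), and hypergeometric
term-enrichment comparison between two gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from loopdiff import nbstats

__all__ = [
    "rpkm",
    "call_de",
    "partition_dependence",
    "compare_term_enrichment",
]


def rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million: counts * 1e9 / (length * library size).

    Samples with zero library size are rejected.
    """
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts * 1e9 / np.outer(lengths.values, lib.values)


def call_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    fdr: float = 0.05,
    min_fc: float = 2.0,
    min_count: int = 10,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """NB differential expression between two groups.

    The DE set is q < ``fdr`` AND |fold change| > ``min_fc`` (i.e.
    |log2FC| > log2(min_fc)); the returned frame covers all genes with a
    boolean ``de`` column and ``up``/``down`` direction relative to group2.
    """
    table = nbstats.CountTable(counts, groups)
    for g in table.group_names():
        if (table.groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
    disp = nbstats.estimate_dispersion(table, prior_df=prior_df)
    res = nbstats.nb_test(table, disp, min_count=min_count)
    res = res.copy()
    res["de"] = (res["q"] < fdr) & (np.abs(res["log2fc"]) > np.log2(min_fc))
    res.attrs["fdr"] = fdr
    res.attrs["min_fc"] = min_fc
    return res


def partition_dependence(
    base_de: set, kiko_de: set, dsm_de: set
) -> pd.DataFrame:
    """Split a base DE gene set by whether it also changes in either mutant.

    dependent = base & (kiko | dsm); independent = base minus that union.
    Provenance flags record which mutant comparison(s) each gene changed in.
    """
    base_de = set(base_de)
    changed = set(kiko_de) | set(dsm_de)
    rows = []
    for g in sorted(base_de):
        rows.append(
            {
                "gene": g,
                "dependent": g in changed,
                "changed_in_kiko": g in kiko_de,
                "changed_in_dsm": g in dsm_de,
            }
        )
    df = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["dependent", "changed_in_kiko", "changed_in_dsm"]
    )
    df.attrs["n_dependent"] = int(df["dependent"].sum()) if len(df) else 0
    df.attrs["n_independent"] = int((~df["dependent"]).sum()) if len(df) else 0
    return df


def compare_term_enrichment(
    set_a: set,
    set_b: set,
    universe: set,
    term_map: dict[str, set],
    p_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-term hypergeometric enrichment of two gene sets vs a universe.

    For each term, obs/exp and upper-tail p are computed for both sets
    (classic one-tailed Fisher semantics, no ontology-graph propagation).
    Terms with zero universe genes are skipped. The overlap summary counts
    terms significant in both sets, in A only, and in B only at ``p_cutoff``.
    """
    universe = set(universe)
    set_a = set(set_a) & universe
    set_b = set(set_b) & universe
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    N = len(universe)
    rows = []
    for term in sorted(term_map):
        genes = set(term_map[term]) & universe
        n = len(genes)
        if n == 0:
            continue
        row = {"term": term, "n_term": n}
        for label, s in (("a", set_a), ("b", set_b)):
            K = len(s)
            k = len(genes & s)
            ratio, p = nbstats.hypergeom_enrich(k, K, n, N)
            row[f"k_{label}"] = k
            row[f"obs_exp_{label}"] = ratio
            row[f"p_{label}"] = p
        rows.append(row)
    df = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame()
    if len(df):
        sig_a = df["p_a"] < p_cutoff
        sig_b = df["p_b"] < p_cutoff
        overlap = {
            "both": int((sig_a & sig_b).sum()),
            "a_only": int((sig_a & ~sig_b).sum()),
            "b_only": int((~sig_a & sig_b).sum()),
            "neither": int((~sig_a & ~sig_b).sum()),
        }
    else:
        overlap = {"both": 0, "a_only": 0, "b_only": 0, "neither": 0}
    return df, overlap
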