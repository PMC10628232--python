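"""Differential chromatin-interaction calling between two conditions.

Contact frequencies are tabulated over all cis bin pairs separated by less
than a maximum genomic distance (default 25-kb bins, < 1 Mb), tested with the
NB exact test on raw counts with library-size normalization, and BH-adjusted.
Condition-specific interaction sets are the significant pairs split by fold-
change sign. Fold-change summaries and retained/lost classification against a
second (e.g. mutant-vs-wild-type) comparison support the downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from loopdiff import nbstats
from loopdiff.contacts import ContactMatrix

logger = logging.getLogger("loopdiff")

__all__ = [
    "BinPairTable",
    "build_binpair_table",
    "call_differential",
    "summarize_foldchange",
    "classify_retained_lost",
]


@dataclass
class BinPairTable:
    """Per-sample raw counts over an enumerated cis bin-pair universe."""

    counts: pd.DataFrame  # MultiIndex (chrom, bin1, bin2) x samples
    groups: pd.Series
    resolution: int
    max_sep: int
    n_dropped: int = 0  # pairs removed by the min_total filter

    @property
    def universe_size(self) -> int:
        return len(self.counts)

    def to_count_table(self) -> nbstats.CountTable:
        return nbstats.CountTable(self.counts, self.groups)


def enumerate_universe(
    layout, resolution: int, max_sep: int, include_diagonal: bool = False
) -> pd.MultiIndex:
    """All cis bin pairs with (bin2 - bin1) * resolution < max_sep.

    The diagonal (separation 0) is excluded by default: self-interacting
    pixels are dominated by ligation artifacts rather than looping signal.
    """
    max_d = -(-max_sep // resolution)  # separations strictly below max_sep
    d0 = 0 if include_diagonal else 1
    chroms, b1s, b2s = [], [], []
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom, resolution)
        for d in range(d0, min(max_d, n)):
            if d * resolution >= max_sep:
                break
            i = np.arange(0, n - d)
            chroms.append(np.full(n - d, chrom, dtype=object))
            b1s.append(i)
            b2s.append(i + d)
    if not chroms:
        return pd.MultiIndex.from_arrays([[], [], []], names=["chrom", "bin1", "bin2"])
    idx = pd.MultiIndex.from_arrays(
        [np.concatenate(chroms), np.concatenate(b1s), np.concatenate(b2s)],
        names=["chrom", "bin1", "bin2"],
    )
    return idx.sortlevel([0, 1, 2])[0]


def build_binpair_table(
    matrices: dict[str, ContactMatrix],
    groups: dict[str, str] | pd.Series,
    max_sep: int = 1_000_000,
    min_total: int = 10,
    include_diagonal: bool = False,
) -> BinPairTable:
    """Tabulate raw counts per sample over the shared bin-pair universe.

    All matrices must share layout and resolution. Pairs whose total count
    across samples falls below ``min_total`` are dropped (the number dropped
    is recorded); raw, unbalanced counts are kept for NB testing.
    """
    samples = list(matrices)
    first = matrices[samples[0]]
    res = first.resolution
    for s in samples[1:]:
        if matrices[s].resolution != res:
            raise ValueError("matrices have mixed resolutions")
        if matrices[s].layout != first.layout:
            raise ValueError("matrices have mixed layouts")
    universe = enumerate_universe(first.layout, res, max_sep, include_diagonal)
    cols = {}
    for s in samples:
        px = matrices[s].pixels
        ser = pd.Series(
            px["count"].values,
            index=pd.MultiIndex.from_arrays(
                [px["chrom"], px["bin1"], px["bin2"]],
                names=["chrom", "bin1", "bin2"],
            ),
        )
        cols[s] = ser.reindex(universe, fill_value=0).astype(np.int64)
    counts = pd.DataFrame(cols)
    total = counts.sum(axis=1)
    keep = total >= min_total
    n_dropped = int((~keep).sum())
    counts = counts[keep]
    groups = pd.Series(dict(groups)).loc[samples]
    logger.info(
        "build_binpair_table: universe %d pairs, %d dropped (min_total=%d)",
        len(universe),
        n_dropped,
        min_total,
    )
    return BinPairTable(
        counts=counts,
        groups=groups,
        resolution=res,
        max_sep=max_sep,
        n_dropped=n_dropped,
    )


def call_differential(
    table: BinPairTable,
    fdr: float = 0.01,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """NB differential test over the bin-pair table.

    Returns all tested pairs with means, log2FC (group2 vs group1), p, q and
    a per-pair label: ``"{group2}-specific"`` for q < fdr with positive
    log2FC, ``"{group1}-specific"`` for q < fdr with negative log2FC, else
    ``"ns"``.
    """
    gnames = list(dict.fromkeys(table.groups))
    if len(gnames) != 2:
        raise ValueError("call_differential requires exactly two groups")
    for g in gnames:
        if (table.groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
    ct = table.to_count_table()
    disp = nbstats.estimate_dispersion(ct, prior_df=prior_df)
    res = nbstats.nb_test(ct, disp)
    g1, g2 = gnames
    sig = res["q"] < fdr
    label = np.where(
        sig & (res["log2fc"] > 0),
        f"{g2}-specific",
        np.where(sig & (res["log2fc"] < 0), f"{g1}-specific", "ns"),
    )
    res = res.copy()
    res["label"] = label
    res["significant"] = sig
    res.attrs["fdr"] = fdr
    res.attrs["groups"] = (g1, g2)
    return res


def summarize_foldchange(results: pd.DataFrame, subset=None) -> dict:
    """Median/quartiles of log2FC and the fraction below zero over a subset.

    ``subset`` is an index (or boolean mask) into the tested universe; the
    fraction-negative is reported with its numerator and denominator, and as
    a percentage rounded to one decimal.
    """
    if subset is None:
        sel = results
    elif isinstance(subset, (pd.Series, np.ndarray)) and getattr(subset, "dtype", None) == bool:
        sel = results[subset]
    else:
        missing = subset.difference(results.index) if hasattr(subset, "difference") else None
        if missing is not None and len(missing):
            raise KeyError(f"{len(missing)} subset pairs outside the tested universe")
        sel = results.loc[subset]
    if len(sel) == 0:
        raise ValueError("empty subset")
    lfc = sel["log2fc"].values
    k = int((lfc < 0).sum())
    n = len(lfc)
    return {
        "median": float(np.median(lfc)),
        "q1": float(np.percentile(lfc, 25)),
        "q3": float(np.percentile(lfc, 75)),
        "n_negative": k,
        "n": n,
        "fraction_negative": k / n,
        "percent_negative": round(100.0 * k / n, 1),
    }


def classify_retained_lost(
    reference_set: pd.MultiIndex,
    mutant_results: pd.DataFrame,
    fdr: float = 0.1,
) -> dict:
    """Split condition-specific pairs into lost vs retained in a mutant.

    ``lost`` = significantly reduced in the mutant comparison (q < fdr and
    log2FC < 0, where the mutant is group2); ``retained`` = the rest.
    Reference pairs absent from the mutant's tested universe are labeled
    ``untested`` and excluded from the denominator.
    """
    in_universe = reference_set.isin(mutant_results.index)
    tested_pairs = reference_set[in_universe]
    n_untested = int((~in_universe).sum())
    if n_untested:
        logger.info("classify_retained_lost: %d reference pairs untested", n_untested)
    sub = mutant_results.loc[tested_pairs]
    lost_mask = (sub["q"] < fdr) & (sub["log2fc"] < 0)
    labels = pd.Series(
        np.where(lost_mask, "lost", "retained"), index=tested_pairs
    )
    k = int(lost_mask.sum())
    n = len(tested_pairs)
    return {
        "labels": labels,
        "lost": tested_pairs[lost_mask.values],
        "retained": tested_pairs[~lost_mask.values],
        "n_lost": k,
        "n": n,
        "n_untested": n_untested,
        "fraction_lost": k / n if n else float("nan"),
        "percent_lost": round(100.0 * k / n, 1) if n else float("nan"),
    }


def results_to_bedpe(results: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Flatten a differential-result frame into BEDPE-ready columns."""
    idx = results.index
    chrom = idx.get_level_values("chrom")
    b1 = idx.get_level_values("bin1").astype(np.int64)
    b2 = idx.get_level_values("bin2").astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom1": chrom,
            "start1": b1 * resolution,
            "end1": (b1 + 1) * resolution,
            "chrom2": chrom,
            "start2": b2 * resolution,
            "end2": (b2 + 1) * resolution,
        }
    )
    for col in results.columns:
        out[col] = results[col].values
    return out
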