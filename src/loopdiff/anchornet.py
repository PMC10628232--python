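"""Anchor-level analyses of differential interactions.

Each differential bin pair contributes two anchors (its 25-kb bins). This
module counts distinct differential partners per anchor, stratifies
DEG-contact rates by partner count, and computes Fisher enrichment of gene
classes and peak tracks over condition-specific interaction sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from loopdiff import nbstats
from loopdiff.iohub import AnnotationSet, PeakSet

__all__ = [
    "anchor_partner_histogram",
    "deg_fraction_by_partner_count",
    "class_enrichment",
    "peak_enrichment",
]

PARTNER_STRATA = (1, 2, 3, 4)  # plus ">4"


def anchor_partner_histogram(diff_pairs: pd.MultiIndex):
    """Distinct-partner counts per anchor of a differential-interaction set.

    Returns (anchors, histogram): ``anchors`` maps (chrom, bin) to its
    partner count; ``histogram`` is a Series over counts 1, 2, ...
    """
    if len(diff_pairs) == 0:
        raise ValueError("empty differential set")
    partners: dict[tuple, set] = {}
    for chrom, b1, b2 in diff_pairs:
        partners.setdefault((chrom, b1), set()).add(b2)
        partners.setdefault((chrom, b2), set()).add(b1)
    anchors = pd.Series(
        {k: len(v) for k, v in sorted(partners.items())}, name="partner_count"
    )
    hist = anchors.value_counts().sort_index()
    hist.index.name = "partner_count"
    return anchors, hist


def _anchor_genes(
    anchors, tss: AnnotationSet, resolution: int
) -> dict[tuple, set]:
    """Genes whose TSS coordinate falls inside each anchor bin."""
    out: dict[tuple, set] = {a: set() for a in anchors}
    tdf = tss.tss_positions()
    by_chrom = {c: g for c, g in tdf.groupby("chrom")}
    for chrom, b in out:
        g = by_chrom.get(chrom)
        if g is None:
            continue
        lo, hi = b * resolution, (b + 1) * resolution
        hit = g[(g["pos"] >= lo) & (g["pos"] < hi)]
        out[(chrom, b)] = set(hit["gene"])
    return out


def deg_fraction_by_partner_count(
    anchors: pd.Series,
    tss: AnnotationSet,
    deg: set,
    resolution: int,
) -> pd.DataFrame:
    """Fraction of anchors contacting >= 1 DEG TSS, by partner-count stratum.

    Strata are 1, 2, 3, 4 and ">4" partners; empty strata are reported with
    n = 0 and NaN fraction.
    """
    genes = _anchor_genes(list(anchors.index), tss, resolution)
    has_deg = pd.Series(
        {a: bool(genes[a] & deg) for a in anchors.index}
    )
    rows = []
    for stratum in PARTNER_STRATA:
        sel = anchors == stratum
        rows.append(_stratum_row(str(stratum), has_deg[sel]))
    rows.append(_stratum_row(">4", has_deg[anchors > PARTNER_STRATA[-1]]))
    return pd.DataFrame(rows).set_index("stratum")


def _stratum_row(name: str, hits: pd.Series) -> dict:
    n = len(hits)
    k = int(hits.sum())
    return {
        "stratum": name,
        "n_anchors": n,
        "n_with_deg": k,
        "fraction": k / n if n else float("nan"),
    }


def class_enrichment(
    gene_classes: dict[str, set],
    interaction_sets: dict[str, pd.MultiIndex],
    tss: AnnotationSet,
    resolution: int,
) -> pd.DataFrame:
    """Fisher 2x2 of gene class membership vs interaction-anchor overlap.

    ``gene_classes`` are disjoint sets partitioning the gene universe (e.g.
    cond2-specific / cond1-specific / non-DE); for each (gene class,
    interaction set) the 2x2 is {in class vs not} x {TSS overlaps an anchor
    of the set vs not} over the union of all classes. Empty combinations are
    skipped with a 'skipped' flag.
    """
    universe: set = set().union(*gene_classes.values())
    classes = list(gene_classes)
    if len(universe) != sum(len(s) for s in gene_classes.values()):
        raise ValueError("gene classes must be disjoint")
    rows = []
    for iname, pairs in interaction_sets.items():
        anchors = sorted(
            {(c, b) for c, b1, b2 in pairs for b in (b1, b2)}
        )
        agenes = _anchor_genes(anchors, tss, resolution)
        overlapped: set = set().union(*agenes.values()) if agenes else set()
        overlapped &= universe
        for cname in classes:
            cls = gene_classes[cname]
            a = len(cls & overlapped)
            b = len(cls - overlapped)
            c = len(overlapped - cls)
            d = len(universe - cls - overlapped)
            row = {
                "interaction_set": iname,
                "gene_class": cname,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "fraction_overlap": a / len(cls) if cls else float("nan"),
            }
            try:
                orr, p = nbstats.fisher_2x2([[a, b], [c, d]])
                row.update({"odds_ratio": orr, "p": p, "skipped": False})
            except ValueError:
                row.update({"odds_ratio": float("nan"), "p": float("nan"), "skipped": True})
            rows.append(row)
    return pd.DataFrame(rows)


def _bins_with_peak(peaks: PeakSet, chrom: str, resolution: int) -> np.ndarray:
    """Sorted unique bin indices on ``chrom`` intersecting >= 1 peak."""
    sub = peaks.for_chrom(chrom)
    if len(sub) == 0:
        return np.array([], dtype=np.int64)
    bins = set()
    for s, e in zip(sub["start"].values, sub["end"].values):
        bins.update(range(s // resolution, (e - 1) // resolution + 1))
    return np.array(sorted(bins), dtype=np.int64)


def pairs_with_peak(
    pairs: pd.MultiIndex, peaks: PeakSet, resolution: int
) -> np.ndarray:
    """Boolean per bin pair: either anchor bin intersects >= 1 peak."""
    chrom_bins = {
        c: _bins_with_peak(peaks, c, resolution)
        for c in pd.unique(pairs.get_level_values("chrom"))
    }
    chrom = pairs.get_level_values("chrom").values
    b1 = pairs.get_level_values("bin1").values
    b2 = pairs.get_level_values("bin2").values
    out = np.zeros(len(pairs), dtype=bool)
    for c, pb in chrom_bins.items():
        sel = chrom == c
        if pb.size:
            out[sel] = np.isin(b1[sel], pb) | np.isin(b2[sel], pb)
    return out


def peak_enrichment(
    peaksets: dict[str, PeakSet],
    interaction_sets: dict[str, pd.MultiIndex],
    universe: pd.MultiIndex,
    resolution: int,
) -> pd.DataFrame:
    """Per-peakset fold enrichment of peak-containing pairs in each set.

    enrichment = (fraction of the set's pairs with a peak at either anchor)
    / (the same fraction over the whole tested universe); p from the Fisher
    2x2 of {in set vs rest of universe} x {peak vs no peak}. Empty peak sets
    yield NA enrichment with zero numerators.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    rows = []
    for pname, peaks in peaksets.items():
        uni_has = pairs_with_peak(universe, peaks, resolution)
        uni_frac = uni_has.mean()
        for iname, pairs in interaction_sets.items():
            in_set = universe.isin(pairs)
            a = int((uni_has & in_set).sum())
            b = int((~uni_has & in_set).sum())
            c = int((uni_has & ~in_set).sum())
            d = int((~uni_has & ~in_set).sum())
            set_frac = a / (a + b) if (a + b) else float("nan")
            if uni_frac > 0 and (a + b) > 0:
                enr = set_frac / uni_frac
            else:
                enr = float("nan")
            try:
                orr, p = nbstats.fisher_2x2([[a, b], [c, d]])
            except ValueError:
                orr, p = float("nan"), float("nan")
            rows.append(
                {
                    "peakset": pname,
                    "interaction_set": iname,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "set_fraction": set_frac,
                    "universe_fraction": uni_frac,
                    "enrichment": enr,
                    "odds_ratio": orr,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
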