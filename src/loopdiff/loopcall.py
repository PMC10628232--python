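"""Focal loop calling and loop-anchor annotation.

Loops are detected HiCCUPS-style: each pixel of a balanced matrix is scored
against a distance-decay-scaled local background estimated from four kernels
(donut ring, lower-left quadrant, horizontal stripe, vertical stripe, all
excluding the center peak window). The expected value is the maximum over the
four kernels; significance is a Poisson upper tail on the raw count with the
expectation rescaled by the anchor balancing weights, BH-corrected within
distance strata. Significant pixels merge by 8-connectivity into loops whose
summit is the most significant pixel.

Anchor annotation classifies each anchor as Gene (TSS in the anchor bin),
Enh (distal-enhancer interval intersecting it), or Un, with precedence
Gene > Enh > Un; observed pair-class frequencies are compared against a
uniform re-placement permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import fftconvolve

from loopdiff import nbstats
from loopdiff.contacts import ContactMatrix, expected_by_distance
from loopdiff.genome import GenomeLayout
from loopdiff.iohub import AnnotationSet, PeakSet
from loopdiff.nbstats import child_seed

logger = logging.getLogger("loopdiff")

__all__ = [
    "call_focal_loops",
    "annotate_loop_anchors",
    "expected_class_frequencies",
    "loop_peak_association",
    "deg_distance_cdf",
    "distal_enhancers",
]

KERNELS = ("donut", "lowerleft", "horizontal", "vertical")
PAIR_CLASSES = ("Gene-Gene", "Gene-Enh", "Enh-Enh", "Gene-Un", "Enh-Un", "Un-Un")


def _kernel_masks(peak_w: int, donut_w: int) -> dict[str, np.ndarray]:
    """Boolean kernel masks over offsets in [-donut_w, donut_w]^2."""
    w, p = donut_w, peak_w
    di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    in_peak = (np.abs(di) <= p) & (np.abs(dj) <= p)
    donut = ~in_peak & ~(di == 0) & ~(dj == 0)
    lowerleft = (di >= 1) & (dj <= -1) & ~in_peak
    horizontal = (np.abs(di) <= 1) & (np.abs(dj) > p)
    vertical = (np.abs(dj) <= 1) & (np.abs(di) > p)
    return {
        "donut": donut,
        "lowerleft": lowerleft,
        "horizontal": horizontal,
        "vertical": vertical,
    }


def _correlate(m: np.ndarray, mask: np.ndarray) -> np.ndarray:
    # fftconvolve with a flipped kernel = cross-correlation
    k = mask.astype(float)[::-1, ::-1]
    out = fftconvolve(m, k, mode="same")
    return np.maximum(out, 0.0)  # clip FFT noise


@dataclass
class _UnionFind:
    parent: dict

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def call_focal_loops(
    matrix: ContactMatrix,
    peak_w: int = 1,
    donut_w: int = 5,
    min_sep: int = 2,
    max_sep: int = 2_000_000,
    fdr: float = 0.1,
    stratum_width: int = 10,
    fold_donut: float = 1.75,
    fold_stripe: float = 1.5,
) -> pd.DataFrame:
    """Call focal loops on a balanced matrix.

    Returns one row per loop: summit pixel (chrom, bin1, bin2 and bp
    coordinates), observed balanced value, the four balanced expected
    components, Poisson p, BH q (within separation strata of
    ``stratum_width`` bins), and the merged footprint pixel count. Called
    loops must additionally clear observed/expected fold thresholds:
    ``fold_donut`` over the donut and lower-left expectations and
    ``fold_stripe`` over the horizontal/vertical stripes (the conventional
    HiCCUPS enrichment filters), which suppresses pixels that are
    statistically extreme but only marginally enriched.
    """
    if not matrix.balanced:
        raise ValueError("call_focal_loops requires a balanced matrix")
    if min_sep < 2:
        raise ValueError("min_sep must be >= 2 bins")
    res = matrix.resolution
    max_sep_bins = max_sep // res
    decay = expected_by_distance(matrix)
    masks = _kernel_masks(peak_w, donut_w)

    cand_frames = []
    for chrom in matrix.layout.chrom_names:
        n = matrix.layout.n_bins(chrom, res)
        w = matrix.weights[chrom]
        valid = ~np.isnan(w)
        if valid.sum() == 0 or n < min_sep + 1:
            continue
        B = matrix.dense(chrom, balanced=True)
        B = np.nan_to_num(B, nan=0.0)
        R = matrix.dense(chrom, balanced=False)
        pooled = decay.pooled
        sep_m = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        D = pooled[np.minimum(sep_m, len(pooled) - 1)]
        vmask = np.outer(valid, valid)
        D = np.where(vmask, D, 0.0)

        lam_comp = {}
        for name, mask in masks.items():
            num = _correlate(B, mask)
            den = _correlate(D, mask)
            with np.errstate(invalid="ignore", divide="ignore"):
                lam_comp[name] = np.where(den > 0, num / den, np.nan) * D
        lam_stack = np.stack([lam_comp[k] for k in KERNELS])
        lam_filled = np.where(np.isnan(lam_stack), -np.inf, lam_stack)
        lam_bal = lam_filled.max(axis=0)
        lam_bal[~np.isfinite(lam_bal)] = np.nan

        iu, ju = np.triu_indices(n, k=min_sep)
        sep = ju - iu
        keep = (sep <= max_sep_bins) & vmask[iu, ju] & (D[iu, ju] > 0)
        keep &= np.isfinite(lam_bal[iu, ju]) & (lam_bal[iu, ju] > 0)
        iu, ju, sep = iu[keep], ju[keep], sep[keep]
        wp = w[iu] * w[ju]
        lam_raw = lam_bal[iu, ju] / wp
        obs_raw = R[iu, ju]
        p = stats.poisson.sf(obs_raw - 1, lam_raw)
        cand_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin1": iu,
                    "bin2": ju,
                    "sep": sep,
                    "obs_raw": obs_raw,
                    "obs_balanced": B[iu, ju],
                    "exp_donut": lam_comp["donut"][iu, ju],
                    "exp_lowerleft": lam_comp["lowerleft"][iu, ju],
                    "exp_horizontal": lam_comp["horizontal"][iu, ju],
                    "exp_vertical": lam_comp["vertical"][iu, ju],
                    "lam_raw": lam_raw,
                    "p": p,
                }
            )
        )
    if not cand_frames:
        return _empty_loops(res)
    cand = pd.concat(cand_frames, ignore_index=True)

    # BH within separation strata
    cand["q"] = np.nan
    strata = cand["sep"] // stratum_width
    for _, idx in cand.groupby(strata).groups.items():
        cand.loc[idx, "q"] = nbstats.bh_adjust(cand.loc[idx, "p"].values)

    obs = cand["obs_balanced"]
    enriched = (
        (obs > fold_donut * cand["exp_donut"].fillna(0))
        & (obs > fold_donut * cand["exp_lowerleft"].fillna(0))
        & (obs > fold_stripe * cand["exp_horizontal"].fillna(0))
        & (obs > fold_stripe * cand["exp_vertical"].fillna(0))
    )
    sig = cand[(cand["q"] < fdr) & enriched]
    if len(sig) == 0:
        return _empty_loops(res)

    # merge significant pixels by 8-connectivity within each chromosome
    loops = []
    for chrom, g in sig.groupby("chrom", sort=True):
        pix = list(zip(g["bin1"].values.tolist(), g["bin2"].values.tolist()))
        uf = _UnionFind({p: p for p in pix})
        pset = set(pix)
        for (i, j) in pix:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    nb = (i + di, j + dj)
                    if nb != (i, j) and nb in pset:
                        uf.union((i, j), nb)
        clusters: dict = {}
        for p_ in pix:
            clusters.setdefault(uf.find(p_), []).append(p_)
        gg = g.set_index(["bin1", "bin2"])
        for members in clusters.values():
            sub = gg.loc[members].reset_index()
            summit = sub.sort_values(["p", "bin1", "bin2"]).iloc[0]
            loops.append(
                {
                    "chrom": chrom,
                    "bin1": int(summit["bin1"]),
                    "bin2": int(summit["bin2"]),
                    "obs_balanced": summit["obs_balanced"],
                    "obs_raw": summit["obs_raw"],
                    "exp_donut": summit["exp_donut"],
                    "exp_lowerleft": summit["exp_lowerleft"],
                    "exp_horizontal": summit["exp_horizontal"],
                    "exp_vertical": summit["exp_vertical"],
                    "p": summit["p"],
                    "q": summit["q"],
                    "n_pixels": len(members),
                }
            )
    out = pd.DataFrame(loops).sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)
    out["start1"] = out["bin1"] * res
    out["end1"] = (out["bin1"] + 1) * res
    out["start2"] = out["bin2"] * res
    out["end2"] = (out["bin2"] + 1) * res
    out.attrs["resolution"] = res
    return out


def _empty_loops(res: int) -> pd.DataFrame:
    cols = [
        "chrom", "bin1", "bin2", "obs_balanced", "obs_raw", "exp_donut",
        "exp_lowerleft", "exp_horizontal", "exp_vertical", "p", "q",
        "n_pixels", "start1", "end1", "start2", "end2",
    ]
    out = pd.DataFrame({c: [] for c in cols})
    out.attrs["resolution"] = res
    return out


# --------------------------------------------------------------- annotation


def distal_enhancers(peaks: PeakSet, tss: AnnotationSet, min_dist: int = 2000) -> PeakSet:
    """Peaks whose midpoint is farther than ``min_dist`` from every TSS."""
    tpos = {c: np.sort(g["pos"].values) for c, g in tss.tss_positions().groupby("chrom")}
    keep = []
    for row in peaks.df.itertuples(index=False):
        mid = (row.start + row.end) // 2
        pos = tpos.get(row.chrom)
        if pos is None or len(pos) == 0:
            keep.append(True)
            continue
        idx = np.searchsorted(pos, mid)
        d = min(
            abs(mid - pos[idx - 1]) if idx > 0 else np.inf,
            abs(pos[idx] - mid) if idx < len(pos) else np.inf,
        )
        keep.append(d > min_dist)
    return PeakSet(peaks.df[np.array(keep, dtype=bool)].reset_index(drop=True))


def _classify_anchor_bins(
    chroms, bins, tss: AnnotationSet, enhancers: PeakSet, resolution: int
) -> np.ndarray:
    """Gene/Enh/Un per anchor bin, precedence Gene > Enh > Un."""
    tpos = {c: np.sort(g["pos"].values) for c, g in tss.tss_positions().groupby("chrom")}
    enh = {c: g for c, g in enhancers.df.groupby("chrom")}
    out = np.empty(len(bins), dtype=object)
    for k, (c, b) in enumerate(zip(chroms, bins)):
        lo, hi = b * resolution, (b + 1) * resolution
        pos = tpos.get(c)
        if pos is not None and np.searchsorted(pos, lo) < np.searchsorted(pos, hi):
            out[k] = "Gene"
            continue
        e = enh.get(c)
        if e is not None and ((e["start"].values < hi) & (e["end"].values > lo)).any():
            out[k] = "Enh"
        else:
            out[k] = "Un"
    return out


def _pair_class(c1: str, c2: str) -> str:
    order = {"Gene": 0, "Enh": 1, "Un": 2}
    a, b = sorted((c1, c2), key=order.get)
    return f"{a}-{b}"


def annotate_loop_anchors(
    loops: pd.DataFrame,
    tss: AnnotationSet,
    enhancers: PeakSet,
    resolution: int,
    proximity_bins: int = 1,
    binding_peaks: PeakSet | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series | None]:
    """Annotate loop anchors and tabulate pair-class frequencies.

    Returns (annotated loops, pair-class frequency table, proximity table).
    The proximity table (only if ``binding_peaks`` given) splits anchors into
    {contains site, within +/- proximity_bins, neither}.
    """
    ann = loops.copy()
    ann["class1"] = _classify_anchor_bins(
        ann["chrom"], ann["bin1"].astype(int), tss, enhancers, resolution
    )
    ann["class2"] = _classify_anchor_bins(
        ann["chrom"], ann["bin2"].astype(int), tss, enhancers, resolution
    )
    ann["pair_class"] = [
        _pair_class(a, b) for a, b in zip(ann["class1"], ann["class2"])
    ]
    freq = ann["pair_class"].value_counts(normalize=True).reindex(
        PAIR_CLASSES, fill_value=0.0
    )
    freq.index.name = "pair_class"

    prox = None
    if binding_peaks is not None:
        anchors = sorted(
            set(zip(ann["chrom"], ann["bin1"].astype(int)))
            | set(zip(ann["chrom"], ann["bin2"].astype(int)))
        )
        peak_bins = {
            c: {
                bb
                for s, e in zip(g["start"].values, g["end"].values)
                for bb in range(s // resolution, (e - 1) // resolution + 1)
            }
            for c, g in binding_peaks.df.groupby("chrom")
        }
        counts = {"contains": 0, "proximal": 0, "neither": 0}
        for c, b in anchors:
            pb = peak_bins.get(c, set())
            if b in pb:
                counts["contains"] += 1
            elif any(b + d in pb for d in range(-proximity_bins, proximity_bins + 1)):
                counts["proximal"] += 1
            else:
                counts["neither"] += 1
        prox = pd.Series(counts, name="anchors")
    return ann, freq, prox


def expected_class_frequencies(
    loops: pd.DataFrame,
    tss: AnnotationSet,
    enhancers: PeakSet,
    layout: GenomeLayout,
    resolution: int,
    n_iter: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-expected pair-class frequencies and observed/expected.

    Anchor bins are re-drawn uniformly within their own chromosome (pairing
    preserved) ``n_iter`` times; the expected frequency of each pair class is
    the mean over iterations.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    ann, obs_freq, _ = annotate_loop_anchors(loops, tss, enhancers, resolution)
    rng = np.random.default_rng(child_seed(seed, "classfreq"))
    chroms = ann["chrom"].values
    nbins = np.array([layout.n_bins(c, resolution) for c in chroms])
    acc = pd.Series(0.0, index=pd.Index(PAIR_CLASSES, name="pair_class"))
    for _ in range(n_iter):
        r1 = (rng.random(len(chroms)) * nbins).astype(np.int64)
        r2 = (rng.random(len(chroms)) * nbins).astype(np.int64)
        c1 = _classify_anchor_bins(chroms, r1, tss, enhancers, resolution)
        c2 = _classify_anchor_bins(chroms, r2, tss, enhancers, resolution)
        pc = pd.Series([_pair_class(a, b) for a, b in zip(c1, c2)])
        acc = acc.add(pc.value_counts(normalize=True), fill_value=0.0)
    exp_freq = (acc / n_iter).reindex(PAIR_CLASSES, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp_freq > 0, obs_freq / exp_freq, np.nan)
    return pd.DataFrame(
        {"observed": obs_freq, "expected": exp_freq, "obs_over_exp": ratio}
    )


def loop_anchor_intervals(loops: pd.DataFrame, resolution: int) -> PeakSet:
    """Distinct anchor bins of a loop set as genomic intervals."""
    rows = set()
    for _, r in loops.iterrows():
        rows.add((r["chrom"], int(r["bin1"]) * resolution, (int(r["bin1"]) + 1) * resolution))
        rows.add((r["chrom"], int(r["bin2"]) * resolution, (int(r["bin2"]) + 1) * resolution))
    if not rows:
        return PeakSet.empty()
    df = pd.DataFrame(sorted(rows), columns=["chrom", "start", "end"])
    return PeakSet(df)


def loop_peak_association(
    loops: pd.DataFrame,
    peaks: PeakSet,
    layout: GenomeLayout,
    resolution: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> nbstats.OverlapNullResult:
    """Fraction of peaks at loop anchors vs a length-preserving random null."""
    anchors = loop_anchor_intervals(loops, resolution)
    if len(loops) == 0:
        return nbstats.OverlapNullResult(
            observed=0.0, null=np.zeros(n_iter), p=1.0, n_query=len(peaks)
        )
    return nbstats.permutation_overlap_null(
        peaks, anchors, layout, n_iter=n_iter, seed=child_seed(seed, "loop_peaks")
    )


def deg_distance_cdf(
    differential_peaks: PeakSet,
    all_peaks: PeakSet,
    deg_tss: AnnotationSet,
) -> dict:
    """Peak-to-nearest-DEG-TSS distances for two peak sets, with rank-sum p.

    Distance = min over same-chromosome DEG TSS of |peak midpoint - TSS|;
    peaks on chromosomes without any DEG TSS are excluded (count reported).
    """
    if len(differential_peaks) == 0 or len(all_peaks) == 0:
        raise ValueError("both peak sets must be nonempty")
    tpos = {c: np.sort(g["pos"].values) for c, g in deg_tss.tss_positions().groupby("chrom")}

    def dists(peaks: PeakSet) -> tuple[np.ndarray, int]:
        out, skipped = [], 0
        for row in peaks.df.itertuples(index=False):
            pos = tpos.get(row.chrom)
            if pos is None or len(pos) == 0:
                skipped += 1
                continue
            mid = (row.start + row.end) // 2
            idx = np.searchsorted(pos, mid)
            d = min(
                abs(mid - pos[idx - 1]) if idx > 0 else np.inf,
                abs(pos[idx] - mid) if idx < len(pos) else np.inf,
            )
            out.append(float(d))
        return np.array(out), skipped

    d_diff, skip_diff = dists(differential_peaks)
    d_all, skip_all = dists(all_peaks)
    if len(d_diff) == 0 or len(d_all) == 0:
        raise ValueError("no peaks with a same-chromosome DEG TSS")
    w, p = nbstats.rank_sum_test(d_diff, d_all)
    return {
        "distances_differential": np.sort(d_diff),
        "distances_all": np.sort(d_all),
        "n_skipped": skip_diff + skip_all,
        "W": w,
        "p": p,
    }
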