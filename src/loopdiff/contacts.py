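"""Binned contact matrices: construction, ICE balancing, distance decay.

A :class:`ContactMatrix` stores sparse upper-triangle cis pixels
(chrom, bin_i <= bin_j, raw count) at one resolution, with optional per-bin
balancing weights. The balanced value of a pixel is count * w_i * w_j;
masked (low-coverage) bins carry weight NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from loopdiff.genome import GenomeLayout
from loopdiff.iohub import PairRecord

logger = logging.getLogger("loopdiff")

__all__ = [
    "ContactMatrix",
    "filter_pairs",
    "bin_contacts",
    "ice_balance",
    "expected_by_distance",
    "DecayProfile",
    "write_matrix",
    "read_matrix",
]


@dataclass
class ContactMatrix:
    layout: GenomeLayout
    resolution: int
    pixels: pd.DataFrame  # columns: chrom, bin1, bin2, count
    weights: dict | None = None  # chrom -> float array (NaN = masked)
    converged: bool | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if len(px):
            if (px["bin1"] > px["bin2"]).any():
                raise ValueError("pixels must satisfy bin1 <= bin2")
            if (px["count"] < 0).any():
                raise ValueError("counts must be nonnegative")

    @property
    def balanced(self) -> bool:
        return self.weights is not None

    def total(self) -> int:
        return int(self.pixels["count"].sum())

    def copy(self) -> "ContactMatrix":
        w = None if self.weights is None else {c: a.copy() for c, a in self.weights.items()}
        return ContactMatrix(
            self.layout, self.resolution, self.pixels.copy(), w, self.converged, self.sample
        )

    def pixel_weights(self) -> np.ndarray:
        """w_i * w_j per pixel row (NaN where either bin is masked)."""
        if self.weights is None:
            raise ValueError("matrix is not balanced")
        out = np.empty(len(self.pixels))
        for chrom, idx in self.pixels.groupby("chrom").groups.items():
            w = self.weights[chrom]
            sub = self.pixels.loc[idx]
            out[self.pixels.index.get_indexer(idx)] = (
                w[sub["bin1"].values] * w[sub["bin2"].values]
            )
        return out

    def balanced_values(self) -> np.ndarray:
        return self.pixels["count"].values * self.pixel_weights()

    def dense(self, chrom: str, balanced: bool = False) -> np.ndarray:
        """Symmetric dense matrix for one chromosome (NaN-masked if balanced)."""
        n = self.layout.n_bins(chrom, self.resolution)
        m = np.zeros((n, n))
        sub = self.pixels[self.pixels["chrom"] == chrom]
        i = sub["bin1"].values
        j = sub["bin2"].values
        c = sub["count"].values.astype(float)
        m[i, j] = c
        m[j, i] = c
        if balanced:
            w = self.weights[chrom]
            m = m * np.outer(w, w)
        return m


# -------------------------------------------------------------- pair filter


def filter_pairs(
    records: Iterable[PairRecord], mapq_min: int = 30, dedup: bool = True
) -> list[PairRecord]:
    """MAPQ filtering and PCR-duplicate removal.

    Keeps records with min(mapq1, mapq2) >= ``mapq_min``; with ``dedup``,
    records identical in (chrom1, pos1, strand1, chrom2, pos2, strand2)
    collapse to one (first occurrence kept).
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    out: list[PairRecord] = []
    seen: set = set()
    n_mapq = n_dup = 0
    for rec in records:
        if min(rec.mapq1, rec.mapq2) < mapq_min:
            n_mapq += 1
            continue
        if dedup:
            key = (rec.chrom1, rec.pos1, rec.strand1, rec.chrom2, rec.pos2, rec.strand2)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
        out.append(rec)
    logger.info("filter_pairs: removed %d low-MAPQ, %d duplicates", n_mapq, n_dup)
    return out


# ----------------------------------------------------------------- binning


def bin_contacts(
    records: Iterable[PairRecord],
    layout: GenomeLayout,
    resolution: int,
    sample: str = "",
) -> ContactMatrix:
    """Accumulate cis read pairs into a binned upper-triangle matrix.

    Trans records are dropped (counted); pixel (i, j) holds the number of
    pairs whose positions fall in bins i and j (ordered i <= j), so total
    pixel mass equals the retained record count.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    counts: dict[tuple[str, int, int], int] = {}
    n_trans = 0
    for rec in records:
        if not rec.is_cis:
            n_trans += 1
            continue
        b1 = layout.bin_of(rec.chrom1, rec.pos1, resolution)
        b2 = layout.bin_of(rec.chrom2, rec.pos2, resolution)
        if b1 > b2:
            b1, b2 = b2, b1
        key = (rec.chrom1, b1, b2)
        counts[key] = counts.get(key, 0) + 1
    if n_trans:
        logger.info("bin_contacts: dropped %d trans records", n_trans)
    if counts:
        keys = sorted(counts)
        px = pd.DataFrame(
            {
                "chrom": [k[0] for k in keys],
                "bin1": np.array([k[1] for k in keys], dtype=np.int64),
                "bin2": np.array([k[2] for k in keys], dtype=np.int64),
                "count": np.array([counts[k] for k in keys], dtype=np.int64),
            }
        )
    else:
        px = _empty_pixels()
    return ContactMatrix(layout, resolution, px, sample=sample)


def _empty_pixels() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "bin1": pd.Series(dtype=np.int64),
            "bin2": pd.Series(dtype=np.int64),
            "count": pd.Series(dtype=np.int64),
        }
    )


def matrix_from_arrays(
    layout: GenomeLayout,
    resolution: int,
    chroms,
    bin1,
    bin2,
    count,
    sample: str = "",
) -> ContactMatrix:
    """Build a matrix directly from pixel arrays (used by the simulator)."""
    px = pd.DataFrame(
        {
            "chrom": np.asarray(chroms),
            "bin1": np.asarray(bin1, dtype=np.int64),
            "bin2": np.asarray(bin2, dtype=np.int64),
            "count": np.asarray(count, dtype=np.int64),
        }
    )
    px = px[px["count"] > 0].reset_index(drop=True)
    px = px.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)
    return ContactMatrix(layout, resolution, px, sample=sample)


# ------------------------------------------------------------ ICE balancing


def ice_balance(
    matrix: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: equalize bin marginals on cis counts.

    Bins with zero coverage, plus the lowest ``mask_frac`` fraction of
    covered bins, are masked. Each iteration divides every unmasked bin's
    weight by its current balanced marginal (relative to the mean marginal)
    until the coefficient of variation of unmasked marginals drops below
    ``tol`` or ``max_iter`` is reached; non-convergence sets
    ``converged=False`` rather than raising. Weights are rescaled so the
    mean unmasked marginal equals 1.
    """
    layout = matrix.layout
    res = matrix.resolution
    offsets = layout.bin_offsets(res)
    n_total = layout.total_bins(res)

    px = matrix.pixels
    gi = np.array([offsets[c] for c in px["chrom"]], dtype=np.int64) + px["bin1"].values
    gj = np.array([offsets[c] for c in px["chrom"]], dtype=np.int64) + px["bin2"].values
    cnt = px["count"].values.astype(float)

    coverage = np.bincount(gi, weights=cnt, minlength=n_total)
    off = gi != gj
    coverage += np.bincount(gj[off], weights=cnt[off], minlength=n_total)
    masked = coverage <= 0
    covered = coverage[~masked]
    if covered.size:
        cutoff = np.quantile(covered, mask_frac)
        masked |= (coverage <= cutoff) & (coverage > 0) if mask_frac > 0 else False
        # keep at least one unmasked bin per chromosome
        for c in layout.chrom_names:
            o, n = offsets[c], layout.n_bins(c, res)
            if masked[o : o + n].all() and (coverage[o : o + n] > 0).any():
                masked[o + int(np.argmax(coverage[o : o + n]))] = False
    if masked.all():
        raise ValueError("no unmasked bins; cannot balance")

    w = np.ones(n_total)
    w[masked] = np.nan
    keep = ~(np.isnan(w[gi]) | np.isnan(w[gj]))
    gi_k, gj_k, cnt_k = gi[keep], gj[keep], cnt[keep]
    off_k = gi_k != gj_k
    converged = False
    for _ in range(max_iter):
        bal = cnt_k * w[gi_k] * w[gj_k]
        marg = np.bincount(gi_k, weights=bal, minlength=n_total)
        marg += np.bincount(gj_k[off_k], weights=bal[off_k], minlength=n_total)
        um = marg[~masked]
        mean_m = um.mean()
        if mean_m == 0:
            break
        cv = um.std() / mean_m
        if cv < tol:
            converged = True
            break
        adjust = marg / mean_m
        adjust[masked] = 1.0
        adjust[adjust == 0] = 1.0
        w = w / adjust

    # rescale so mean unmasked marginal is exactly 1
    bal = cnt_k * w[gi_k] * w[gj_k]
    marg = np.bincount(gi_k, weights=bal, minlength=n_total)
    marg += np.bincount(gj_k[off_k], weights=bal[off_k], minlength=n_total)
    mean_m = marg[~masked].mean()
    if mean_m > 0:
        w = w / np.sqrt(mean_m)

    weights = {
        c: w[offsets[c] : offsets[c] + layout.n_bins(c, res)].copy()
        for c in layout.chrom_names
    }
    out = matrix.copy()
    out.weights = weights
    out.converged = converged
    return out


# ----------------------------------------------------------- distance decay


@dataclass
class DecayProfile:
    """Mean balanced count per bin separation, per chromosome and pooled."""

    per_chrom: dict  # chrom -> array over separations
    pooled: np.ndarray
    n_pairs: dict = field(default_factory=dict)  # chrom -> valid positions per sep

    def fit_exponent(self, min_sep: int = 1, max_sep: int | None = None) -> float:
        """Log-log slope magnitude of the pooled decay (power-law exponent)."""
        y = self.pooled
        hi = len(y) if max_sep is None else min(max_sep + 1, len(y))
        s = np.arange(min_sep, hi)
        v = y[min_sep:hi]
        ok = v > 0
        if ok.sum() < 2:
            raise ValueError("too few separations to fit a decay exponent")
        slope = np.polyfit(np.log(s[ok]), np.log(v[ok]), 1)[0]
        return -float(slope)


def expected_by_distance(matrix: ContactMatrix) -> DecayProfile:
    """Mean balanced count at each bin separation (masked bins excluded).

    The pooled profile is the coverage-weighted mean of per-chromosome
    profiles: total balanced sum at separation s over the total number of
    unmasked pixel positions at s. Separation 0 is the diagonal. No
    smoothing or monotonicity is applied.
    """
    if not matrix.balanced:
        raise ValueError("expected_by_distance requires a balanced matrix")
    layout, res = matrix.layout, matrix.resolution
    per_chrom: dict[str, np.ndarray] = {}
    n_pairs: dict[str, np.ndarray] = {}
    max_len = 0
    sums: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom, res)
        w = matrix.weights[chrom]
        valid = ~np.isnan(w)
        sub = matrix.pixels[matrix.pixels["chrom"] == chrom]
        sep = (sub["bin2"] - sub["bin1"]).values
        bal = sub["count"].values * w[sub["bin1"].values] * w[sub["bin2"].values]
        ok = ~np.isnan(bal)
        ssum = np.bincount(sep[ok], weights=bal[ok], minlength=n)
        # number of unmasked (i, i+s) positions per separation
        vi = valid.astype(np.int64)
        npos = np.array(
            [int((vi[: n - s] & vi[s:]).sum()) for s in range(n)], dtype=np.int64
        )
        sums[chrom] = ssum
        n_pairs[chrom] = npos
        with np.errstate(invalid="ignore", divide="ignore"):
            per_chrom[chrom] = np.where(npos > 0, ssum / np.maximum(npos, 1), 0.0)
        max_len = max(max_len, n)
    pooled_sum = np.zeros(max_len)
    pooled_n = np.zeros(max_len, dtype=np.int64)
    for chrom in layout.chrom_names:
        L = len(sums[chrom])
        pooled_sum[:L] += sums[chrom]
        pooled_n[:L] += n_pairs[chrom]
    pooled = np.where(pooled_n > 0, pooled_sum / np.maximum(pooled_n, 1), 0.0)
    return DecayProfile(per_chrom=per_chrom, pooled=pooled, n_pairs=n_pairs)


# -------------------------------------------------------------- persistence


def write_matrix(matrix: ContactMatrix, pixels_path: str | Path, bins_path: str | Path) -> None:
    """Persist as sorted COO text plus a BED-like bin/weight sidecar."""
    px = matrix.pixels.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)
    out = px.copy()
    if matrix.balanced:
        bal = np.empty(len(px))
        for chrom in matrix.layout.chrom_names:
            sel = (px["chrom"] == chrom).values
            w = matrix.weights[chrom]
            bal[sel] = px.loc[sel, "count"].values * w[px.loc[sel, "bin1"].values] * w[
                px.loc[sel, "bin2"].values
            ]
        out["balanced"] = bal
    out.to_csv(pixels_path, sep="\t", index=False, float_format="%.8g")

    bins = matrix.layout.bin_table(matrix.resolution)
    if matrix.balanced:
        bins["weight"] = [
            matrix.weights[c][b] for c, b in zip(bins["chrom"], bins["bin"])
        ]
    with open(bins_path, "w") as fh:
        fh.write(f"#resolution={matrix.resolution}\n")
        conv = "" if matrix.converged is None else f"#converged={matrix.converged}\n"
        fh.write(conv)
        bins.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_matrix(pixels_path: str | Path, bins_path: str | Path) -> ContactMatrix:
    resolution = None
    converged = None
    header_lines = 0
    with open(bins_path) as fh:
        for line in fh:
            if line.startswith("#resolution="):
                resolution = int(line.strip().split("=")[1])
                header_lines += 1
            elif line.startswith("#converged="):
                converged = line.strip().split("=")[1] == "True"
                header_lines += 1
            else:
                break
    if resolution is None:
        raise ValueError("bin sidecar missing #resolution header")
    bins = pd.read_csv(bins_path, sep="\t", skiprows=header_lines)
    sizes = bins.groupby("chrom", sort=False)["end"].max()
    layout = GenomeLayout.from_dict(sizes.to_dict())
    px = pd.read_csv(pixels_path, sep="\t")
    weights = None
    if "weight" in bins.columns:
        weights = {
            c: g.sort_values("bin")["weight"].values.astype(float)
            for c, g in bins.groupby("chrom", sort=False)
        }
    keep = [c for c in ("chrom", "bin1", "bin2", "count") if c in px.columns]
    return ContactMatrix(layout, resolution, px[keep], weights, converged)
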