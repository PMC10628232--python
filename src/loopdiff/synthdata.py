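"""Synthetic contact maps, peak tracks, and expression counts with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: power-law distance decay of cis contact frequency, TAD blocks with
elevated within-block contacts, focal loops as multiplicatively enriched
pixels, condition-specific differential loops at configured fold changes,
negative-binomial replicate noise (var = mu + phi * mu^2), peak tracks
co-located with planted loop anchors, and gene expression counts whose
differential genes are linked to differential loop anchors. Every output is
a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from loopdiff.genome import GenomeLayout
from loopdiff.iohub import AnnotationSet, PairRecord, PeakSet
from loopdiff.contacts import ContactMatrix, matrix_from_arrays
from loopdiff.nbstats import child_seed

__all__ = [
    "SimulationConfig",
    "TruthModel",
    "build_truth_model",
    "sample_contact_replicates",
    "simulate_peaks",
    "simulate_expression",
    "pairs_from_matrix",
    "write_truth_json",
]

CONDITIONS = ("cond1", "cond2")


@dataclass
class SimulationConfig:
    """Study-scale defaults: two small chromosomes, Hi-C-like decay and noise.

    ``depth`` is the expected cis pair count per replicate; ``alpha`` the
    power-law decay exponent (contact mean ~ separation^-alpha); ``phi`` the
    NB dispersion of replicate noise. Differential loops get multiplier
    ``loop_mult`` in cond2 and ``loop_mult / diff_fold`` in cond1, i.e. a
    cond2-vs-cond1 fold change of ``diff_fold``.
    """

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 8_000_000}
    )
    resolution: int = 25_000
    alpha: float = 1.0
    phi: float = 0.1
    depth: int = 2_000_000
    n_tads: int = 6
    tad_mult: float = 2.0
    tad_size_bins: tuple = (10, 30)
    n_loops: int = 30
    loop_mult: float = 8.0
    n_differential: int = 10
    diff_fold: float = 4.0
    min_loop_sep_bins: int = 4
    max_loop_sep_bins: int = 36
    peak_link_prob: float = 0.9
    background_peak_rate_per_mb: float = 3.0
    peak_width: int = 500
    n_genes: int = 400
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    expr_mu: float = 200.0
    expr_phi: float = 0.1
    gene_length_range: tuple = (500, 5000)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class TruthModel:
    """Planted structure: layout, decay, TADs, loops, differential set, genes."""

    layout: GenomeLayout
    resolution: int
    alpha: float
    phi: float
    depth: int
    tad_blocks: list  # (chrom, start_bin, end_bin, multiplier)
    loops: list  # (chrom, bin_i, bin_j, multiplier)
    differential: dict  # loop index -> {condition: multiplier}
    peak_link_prob: float
    config: SimulationConfig
    genes: pd.DataFrame | None = None  # gene, chrom, tss, length, log2fc, is_de

    def differential_pixels(self) -> set:
        """(chrom, bin_i, bin_j) footprint (3x3) of every differential loop."""
        out = set()
        for li in self.differential:
            chrom, bi, bj, _ = self.loops[li]
            n = self.layout.n_bins(chrom, self.resolution)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = bi + di, bj + dj
                    if 0 <= a < n and 0 <= b < n and a < b:
                        out.add((chrom, a, b))
        return out

    def loop_summits(self) -> list:
        return [(c, i, j) for c, i, j, _ in self.loops]

    def expected_matrix(self, chrom: str, condition: str = "cond1") -> np.ndarray:
        """Per-pixel expected count (dense, symmetric) for one replicate."""
        return _expected_dense(self, chrom, condition)


def _expected_dense(model: TruthModel, chrom: str, condition: str) -> np.ndarray:
    n = model.layout.n_bins(chrom, model.resolution)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    base = (sep + 1.0) ** (-model.alpha)
    for c, s, e, mult in model.tad_blocks:
        if c != chrom:
            continue
        inside = (idx >= s) & (idx < e)
        base *= np.where(np.outer(inside, inside), mult, 1.0)
    for li, (c, bi, bj, mult) in enumerate(model.loops):
        if c != chrom:
            continue
        m = model.differential.get(li, {}).get(condition, mult)
        lo_i, hi_i = max(bi - 1, 0), min(bi + 2, n)
        lo_j, hi_j = max(bj - 1, 0), min(bj + 2, n)
        base[lo_i:hi_i, lo_j:hi_j] *= m
        base[lo_j:hi_j, lo_i:hi_i] *= m
    return base


def _depth_scale(model: TruthModel, condition: str) -> float:
    """Scale factor so the genome-wide expected upper-triangle sum = depth."""
    total = 0.0
    for chrom in model.layout.chrom_names:
        e = _expected_dense(model, chrom, condition)
        total += np.triu(e).sum()
    return model.depth / total if total > 0 else 0.0


def build_truth_model(config: SimulationConfig) -> TruthModel:
    """Place TADs, loops, the differential subset, and gene annotations.

    Deterministic given ``config.seed``. Loops are placed at separations in
    [min_loop_sep_bins, max_loop_sep_bins] with non-overlapping 3x3
    footprints; differential loops take multiplier ``loop_mult`` in cond2 and
    ``loop_mult / diff_fold`` in cond1. DE genes have their TSS placed inside
    differential loop anchor bins (cycling if there are more DE genes than
    anchors); other genes are placed uniformly.
    """
    if config.alpha <= 0 or config.phi < 0 or config.loop_mult < 1:
        raise ValueError("invalid config: need alpha > 0, phi >= 0, mult >= 1")
    if not 0 <= config.peak_link_prob <= 1:
        raise ValueError("peak_link_prob must be in [0, 1]")
    layout = GenomeLayout.from_dict(config.chrom_sizes)
    res = config.resolution
    rng = np.random.default_rng(child_seed(config.seed, "truth"))
    chroms = list(layout.chrom_names)
    nbins = {c: layout.n_bins(c, res) for c in chroms}

    # genome-proportional assignment of TADs/loops to chromosomes
    probs = np.array([nbins[c] for c in chroms], dtype=float)
    probs /= probs.sum()

    tads = []
    for _ in range(config.n_tads):
        c = chroms[rng.choice(len(chroms), p=probs)]
        size = int(rng.integers(config.tad_size_bins[0], config.tad_size_bins[1] + 1))
        size = min(size, nbins[c] - 1)
        s = int(rng.integers(0, nbins[c] - size))
        tads.append((c, s, s + size, config.tad_mult))

    loops: list = []
    occupied: set = set()
    attempts = 0
    while len(loops) < config.n_loops and attempts < 10_000:
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=probs)]
        sep = int(
            rng.integers(config.min_loop_sep_bins, config.max_loop_sep_bins + 1)
        )
        if sep + 2 >= nbins[c]:
            continue
        bi = int(rng.integers(1, nbins[c] - sep - 1))
        bj = bi + sep
        footprint = {(c, bi + di, bj + dj) for di in (-2, -1, 0, 1, 2) for dj in (-2, -1, 0, 1, 2)}
        if footprint & occupied:
            continue
        occupied |= footprint
        loops.append((c, bi, bj, config.loop_mult))
    if len(loops) < config.n_loops:
        raise ValueError("could not place the requested number of loops")
    for c, bi, bj, _ in loops:
        if not (0 <= bi < nbins[c] and 0 <= bj < nbins[c]):
            raise ValueError("loop coordinates outside chromosome bounds")

    n_diff = min(config.n_differential, len(loops))
    diff_idx = sorted(rng.choice(len(loops), size=n_diff, replace=False).tolist())
    differential = {
        int(li): {
            "cond1": config.loop_mult / config.diff_fold,
            "cond2": config.loop_mult,
        }
        for li in diff_idx
    }

    model = TruthModel(
        layout=layout,
        resolution=res,
        alpha=config.alpha,
        phi=config.phi,
        depth=config.depth,
        tad_blocks=tads,
        loops=loops,
        differential=differential,
        peak_link_prob=config.peak_link_prob,
        config=config,
    )
    model.genes = _place_genes(model, rng)
    return model


def _place_genes(model: TruthModel, rng: np.random.Generator) -> pd.DataFrame:
    cfg = model.config
    layout, res = model.layout, model.resolution
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.length_of(c) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    diff_anchor_bins = []
    for li in sorted(model.differential):
        c, bi, bj, _ = model.loops[li]
        diff_anchor_bins += [(c, bi), (c, bj)]

    rows = []
    for g in range(cfg.n_genes):
        is_de = g < cfg.n_de_genes
        if is_de and diff_anchor_bins:
            c, b = diff_anchor_bins[g % len(diff_anchor_bins)]
            lo = b * res
            hi = min((b + 1) * res, layout.length_of(c))
            tss = int(rng.integers(lo, hi))
            lfc = cfg.de_log2fc * (1 if rng.random() < 0.5 else -1)
        else:
            c = chroms[rng.choice(len(chroms), p=probs)]
            tss = int(rng.integers(0, layout.length_of(c)))
            lfc = 0.0
        length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1]))
        rows.append(
            {
                "gene": f"gene{g:04d}",
                "chrom": c,
                "tss": tss,
                "length": length,
                "log2fc": lfc,
                "is_de": is_de,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- contact maps


def sample_contact_replicates(
    model: TruthModel, condition: str, n_reps: int, seed: int
) -> list[ContactMatrix]:
    """Draw replicate contact matrices with NB noise around the truth means.

    Pixel counts are NB(mean = depth-scaled expectation, dispersion phi);
    phi = 0 gives Poisson draws. Only the upper triangle is sampled (the
    matrix is symmetric by construction).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; use one of {CONDITIONS}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scale = _depth_scale(model, condition)
    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng(child_seed(seed, "contacts", condition, rep))
        chroms_l, b1_l, b2_l, cnt_l = [], [], [], []
        for chrom in model.layout.chrom_names:
            mu = _expected_dense(model, chrom, condition) * scale
            n = mu.shape[0]
            iu, ju = np.triu_indices(n)
            m = mu[iu, ju]
            if model.phi > 0:
                r = 1.0 / model.phi
                lam = rng.gamma(shape=r, scale=m / r)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(m)
            nz = counts > 0
            chroms_l.append(np.full(nz.sum(), chrom, dtype=object))
            b1_l.append(iu[nz])
            b2_l.append(ju[nz])
            cnt_l.append(counts[nz])
        mat = matrix_from_arrays(
            model.layout,
            model.resolution,
            np.concatenate(chroms_l) if chroms_l else [],
            np.concatenate(b1_l) if b1_l else [],
            np.concatenate(b2_l) if b2_l else [],
            np.concatenate(cnt_l) if cnt_l else [],
            sample=f"{condition}_rep{rep + 1}",
        )
        out.append(mat)
    return out


def pairs_from_matrix(matrix: ContactMatrix, seed: int, mapq: int = 60):
    """Scatter each pixel count into read pairs uniform within their bins."""
    rng = np.random.default_rng(child_seed(seed, "pairs", matrix.sample))
    res = matrix.resolution
    for row in matrix.pixels.itertuples(index=False):
        L = matrix.layout.length_of(row.chrom)
        lo1, hi1 = row.bin1 * res, min((row.bin1 + 1) * res, L)
        lo2, hi2 = row.bin2 * res, min((row.bin2 + 1) * res, L)
        p1 = rng.integers(lo1, hi1, size=row.count)
        p2 = rng.integers(lo2, hi2, size=row.count)
        s1 = rng.random(row.count) < 0.5
        s2 = rng.random(row.count) < 0.5
        for a, b, sa, sb in zip(p1, p2, s1, s2):
            yield PairRecord(
                chrom1=row.chrom,
                pos1=int(a),
                chrom2=row.chrom,
                pos2=int(b),
                strand1="+" if sa else "-",
                strand2="+" if sb else "-",
                mapq1=mapq,
                mapq2=mapq,
            )


# ------------------------------------------------------------------- peaks


def simulate_peaks(
    model: TruthModel,
    seed: int,
    background_rate_per_mb: float | None = None,
    width: int | None = None,
) -> PeakSet:
    """Peaks at planted loop anchors plus uniform background.

    Each distinct planted anchor bin carries a fixed-width peak centered in
    the bin with probability ``peak_link_prob``; background peak count is
    Poisson(rate * genome Mb), placed uniformly.
    """
    cfg = model.config
    rate = cfg.background_peak_rate_per_mb if background_rate_per_mb is None else background_rate_per_mb
    width = cfg.peak_width if width is None else width
    rng = np.random.default_rng(child_seed(seed, "peaks"))
    res = model.resolution
    anchors = sorted({(c, b) for c, bi, bj, _ in model.loops for b in (bi, bj)})
    rows = []
    for c, b in anchors:
        if rng.random() < model.peak_link_prob:
            L = model.layout.length_of(c)
            center = min(b * res + res // 2, L - 1)
            start = max(0, center - width // 2)
            rows.append({"chrom": c, "start": start, "end": min(start + width, L)})
    genome_mb = model.layout.genome_size() / 1e6
    n_bg = rng.poisson(rate * genome_mb)
    chroms = list(model.layout.chrom_names)
    lens = np.array([model.layout.length_of(c) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    for _ in range(n_bg):
        c = chroms[rng.choice(len(chroms), p=probs)]
        L = model.layout.length_of(c)
        start = int(rng.integers(0, max(1, L - width)))
        rows.append({"chrom": c, "start": start, "end": min(start + width, L)})
    if not rows:
        return PeakSet.empty()
    df = pd.DataFrame(rows)
    df["name"] = [f"peak{i}" for i in range(len(df))]
    return PeakSet(df)


def tss_annotation(model: TruthModel) -> AnnotationSet:
    """TSS records (1-bp intervals at the TSS) for the planted genes."""
    g = model.genes
    df = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": g["tss"],
            "end": g["tss"] + 1,
            "gene": g["gene"],
            "strand": "+",
        }
    )
    return AnnotationSet(df)


# -------------------------------------------------------------- expression


def simulate_expression(
    model: TruthModel, n_reps: int, seed: int
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """NB expression counts per gene x sample with planted DE genes.

    Returns (counts, groups, lengths). True-DE genes change by the configured
    log2FC between cond1 and cond2 (split symmetrically around the baseline
    mean); all genes share dispersion ``expr_phi``.
    """
    if n_reps < 2:
        raise ValueError("simulate_expression requires >= 2 replicates per condition")
    cfg = model.config
    genes = model.genes
    rng = np.random.default_rng(child_seed(seed, "expression"))
    base = cfg.expr_mu * np.exp(rng.normal(0, 1, size=len(genes)))
    lfc = genes["log2fc"].values
    mu1 = base * 2.0 ** (-lfc / 2)
    mu2 = base * 2.0 ** (lfc / 2)
    cols, data = [], []
    for cond, mu in (("cond1", mu1), ("cond2", mu2)):
        for rep in range(n_reps):
            rrng = np.random.default_rng(child_seed(seed, "expr", cond, rep))
            if cfg.expr_phi > 0:
                r = 1.0 / cfg.expr_phi
                lam = rrng.gamma(shape=r, scale=mu / r)
                counts = rrng.poisson(lam)
            else:
                counts = rrng.poisson(mu)
            cols.append(f"{cond}_rep{rep + 1}")
            data.append(counts)
    counts = pd.DataFrame(
        np.column_stack(data), index=genes["gene"].values, columns=cols
    )
    groups = pd.Series([c.rsplit("_", 1)[0] for c in cols], index=cols)
    lengths = pd.Series(genes["length"].values, index=genes["gene"].values)
    return counts, groups, lengths


# ------------------------------------------------------------------- truth


def write_truth_json(model: TruthModel, path: str | Path) -> None:
    payload = {
        "chrom_sizes": dict(zip(model.layout.chrom_names, model.layout.chrom_lengths)),
        "resolution": model.resolution,
        "alpha": model.alpha,
        "phi": model.phi,
        "depth": model.depth,
        "tad_blocks": [list(t) for t in model.tad_blocks],
        "loops": [list(l) for l in model.loops],
        "differential": {str(k): v for k, v in model.differential.items()},
        "de_genes": model.genes.loc[model.genes["is_de"], "gene"].tolist(),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(model.config).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
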