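"""Focal loop calling, anchor annotation, and permutation analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopdiff import contacts, loopcall, synthdata
from loopdiff.genome import GenomeLayout
from loopdiff.iohub import AnnotationSet, PeakSet


def _plac_map(seed, n_loops=12, depth=1_000_000, n_tads=3):
    cfg = synthdata.SimulationConfig(
        chrom_sizes={"chr1": 8_000_000},
        resolution=10_000,
        depth=depth,
        n_tads=n_tads,
        n_loops=n_loops,
        n_differential=0,
        phi=0.0,
        loop_mult=8.0,
        min_loop_sep_bins=6,
        max_loop_sep_bins=80,
        seed=seed,
    )
    model = synthdata.build_truth_model(cfg)
    mat = synthdata.sample_contact_replicates(model, "cond1", 1, seed=seed)[0]
    return model, contacts.ice_balance(mat)


def _tss(records):
    df = pd.DataFrame(records, columns=["chrom", "start", "gene"])
    df["end"] = df["start"] + 1
    return AnnotationSet(df[["chrom", "start", "end", "gene"]])


def test_unbalanced_matrix_rejected(truth_model):
    mat = synthdata.sample_contact_replicates(truth_model, "cond1", 1, seed=0)[0]
    with pytest.raises(ValueError):
        loopcall.call_focal_loops(mat)


def test_kernel_masks_partition_sensibly():
    masks = loopcall._kernel_masks(peak_w=1, donut_w=5)
    center = (5, 5)
    for m in masks.values():
        assert not m[center]  # peak pixel excluded everywhere
    assert masks["donut"].sum() > masks["horizontal"].sum()
    # lower-left quadrant strictly below-left of center
    di, dj = np.nonzero(masks["lowerleft"])
    assert (di > 5).all() and (dj < 5).all()


def test_planted_loops_recovered_with_summit_accuracy():
    recovered = total = 0
    for seed in (3, 4):
        model, bal = _plac_map(seed)
        loops = loopcall.call_focal_loops(bal, fdr=0.1)
        for c, bi, bj in model.loop_summits():
            total += 1
            recovered += bool(
                (
                    (loops["chrom"] == c)
                    & (np.abs(loops["bin1"] - bi) <= 1)
                    & (np.abs(loops["bin2"] - bj) <= 1)
                ).any()
            )
    assert recovered / total >= 0.9


def test_null_maps_yield_rare_calls():
    counts = []
    for seed in range(3):
        _, bal = _plac_map(seed, n_loops=0, n_tads=0)
        loops = loopcall.call_focal_loops(bal, fdr=0.1)
        counts.append(len(loops))
    assert np.mean(counts) <= 1.5


def test_pixel_pvalue_matches_poisson_tail_oracle():
    _, bal = _plac_map(5, n_loops=6)
    loops = loopcall.call_focal_loops(bal, fdr=0.1)
    assert len(loops) > 0
    w = bal.weights["chr1"]
    for _, r in loops.iterrows():
        lam_bal = max(
            r["exp_donut"], r["exp_lowerleft"], r["exp_horizontal"], r["exp_vertical"]
        )
        lam_raw = lam_bal / (w[int(r["bin1"])] * w[int(r["bin2"])])
        assert r["p"] == pytest.approx(
            stats.poisson.sf(r["obs_raw"] - 1, lam_raw), rel=1e-9
        )
        # called loops exceed every expected component
        assert r["obs_balanced"] > lam_bal


def test_merging_unique_assignment():
    model, bal = _plac_map(6)
    loops = loopcall.call_focal_loops(bal, fdr=0.1)
    # loop summits unique; count bounded by pixel count
    assert loops[["chrom", "bin1", "bin2"]].duplicated().sum() == 0
    assert (loops["n_pixels"] >= 1).all()
    # summits of distinct loops are not 8-adjacent (else they would merge)
    arr = loops[["bin1", "bin2"]].values
    for a in range(len(arr)):
        for b in range(a + 1, len(arr)):
            assert max(abs(arr[a, 0] - arr[b, 0]), abs(arr[a, 1] - arr[b, 1])) > 1


# --------------------------------------------------------------- annotation


def test_annotate_precedence_and_trivial_classes():
    res = 10_000
    loops = pd.DataFrame(
        {"chrom": ["chr1"], "bin1": [2], "bin2": [8]}
    )
    tss = _tss([("chr1", 2 * res + 100, "gA"), ("chr1", 8 * res + 50, "gB")])
    enh = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [2 * res + 500], "end": [2 * res + 900]}))
    ann, freq, _ = loopcall.annotate_loop_anchors(loops, tss, enh, res)
    # both TSS and enhancer in bin 2 -> Gene wins
    assert ann["class1"].iloc[0] == "Gene"
    assert ann["pair_class"].iloc[0] == "Gene-Gene"
    assert freq["Gene-Gene"] == 1.0


def test_annotate_class_table_matches_recount():
    rng = np.random.default_rng(7)
    res = 10_000
    loops = pd.DataFrame(
        {
            "chrom": "chr1",
            "bin1": (b1 := rng.integers(0, 100, 40)),
            "bin2": b1 + rng.integers(5, 40, 40),
        }
    )
    tss = _tss([("chr1", int(b) * res + 10, f"g{b}") for b in rng.integers(0, 140, 30)])
    enh = PeakSet(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "start": (s := rng.integers(0, 140 * res, 25)),
                "end": s + 400,
            }
        )
    )
    ann, freq, _ = loopcall.annotate_loop_anchors(loops, tss, enh, res)
    # brute-force recount per anchor
    tset = set(tss.df["start"] // res)
    for _, r in ann.iterrows():
        for side in (1, 2):
            b = int(r[f"bin{side}"])
            if b in tset:
                expect = "Gene"
            elif (
                (enh.df["start"] < (b + 1) * res) & (enh.df["end"] > b * res)
            ).any():
                expect = "Enh"
            else:
                expect = "Un"
            assert r[f"class{side}"] == expect
    assert freq.sum() == pytest.approx(1.0)


def test_expected_class_frequencies_analytic_limit():
    # point annotations of genomic fraction f: expected Gene-Gene -> f^2
    rng = np.random.default_rng(8)
    res = 10_000
    layout = GenomeLayout.from_dict({"chr1": 2_000_000})  # 200 bins
    n_gene_bins = 40  # f = 0.2
    tss = _tss([("chr1", b * res + 5, f"g{b}") for b in range(n_gene_bins)])
    enh = PeakSet.empty()
    loops = pd.DataFrame(
        {
            "chrom": "chr1",
            "bin1": (b1 := rng.integers(0, 150, 60)),
            "bin2": b1 + rng.integers(5, 40, 60),
        }
    )
    out = loopcall.expected_class_frequencies(
        loops, tss, enh, layout, res, n_iter=300, seed=1
    )
    f = n_gene_bins / 200
    se = np.sqrt(f * f * (1 - f * f) / (300 * 60))
    assert out.loc["Gene-Gene", "expected"] == pytest.approx(f * f, abs=4 * se)


def test_expected_class_frequencies_deterministic():
    model, bal = _plac_map(9, n_loops=6)
    loops = loopcall.call_focal_loops(bal, fdr=0.1)
    res = 10_000
    tss = _tss([("chr1", 100_000, "g1")])
    enh = PeakSet.empty()
    a = loopcall.expected_class_frequencies(loops, tss, enh, model.layout, res, n_iter=100, seed=5)
    b = loopcall.expected_class_frequencies(loops, tss, enh, model.layout, res, n_iter=100, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_distal_enhancer_filter():
    res = 10_000
    tss = _tss([("chr1", 50_000, "g")])
    peaks = PeakSet(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [49_600, 80_000],
                "end": [50_400, 80_500],
            }
        )
    )
    distal = loopcall.distal_enhancers(peaks, tss, min_dist=2000)
    assert len(distal) == 1
    assert distal.df["start"].iloc[0] == 80_000


# ---------------------------------------------------------- loop-peak null


def test_loop_peak_association_peaks_only_at_anchors():
    model, bal = _plac_map(10, n_loops=8)
    loops = loopcall.call_focal_loops(bal, fdr=0.1)
    res = 10_000
    anchors = loopcall.loop_anchor_intervals(loops, res)
    peaks = PeakSet(anchors.df.assign(start=anchors.df["start"] + 100, end=anchors.df["start"] + 600))
    out = loopcall.loop_peak_association(loops, peaks, model.layout, res, n_iter=200, seed=0)
    assert out.observed == 1.0
    if (out.null < 1.0).all():
        assert out.p == pytest.approx(1 / 201)


def test_loop_peak_association_empty_loops():
    layout = GenomeLayout.from_dict({"chr1": 1_000_000})
    peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [600]}))
    out = loopcall.loop_peak_association(
        loopcall._empty_loops(10_000), peaks, layout, 10_000, n_iter=100, seed=0
    )
    assert out.observed == 0.0


# ------------------------------------------------------------ distance CDF


def test_deg_distance_trivial_cases():
    deg = _tss([("chr1", 100_000, "g1")])
    at_tss = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [99_900], "end": [100_100]}))
    far = PeakSet(
        pd.DataFrame(
            {"chrom": ["chr1"] * 4, "start": [5_000, 300_000, 600_000, 900_000],
             "end": [6_000, 301_000, 601_000, 901_000]}
        )
    )
    out = loopcall.deg_distance_cdf(at_tss, far, deg)
    assert out["distances_differential"][0] == 0.0
    assert (out["distances_all"] > 0).all()
    # single peak 5 kb from the only TSS
    single = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [104_500], "end": [105_500]}))
    out2 = loopcall.deg_distance_cdf(single, far, deg)
    assert out2["distances_differential"].tolist() == [5000.0]


def test_deg_distance_same_law_calibrated():
    rng = np.random.default_rng(11)
    deg = _tss([("chr1", int(p), f"g{k}") for k, p in enumerate(rng.integers(0, 2_000_000, 10))])
    ps = []
    for rep in range(100):
        rr = np.random.default_rng(rep)
        a = PeakSet(pd.DataFrame({"chrom": "chr1", "start": (s := rr.integers(0, 1_999_000, 15)), "end": s + 500}))
        b = PeakSet(pd.DataFrame({"chrom": "chr1", "start": (u := rr.integers(0, 1_999_000, 40) * 1), "end": u + 500}))
        ps.append(loopcall.deg_distance_cdf(a, b, deg)["p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_deg_distance_chrom_without_tss_excluded():
    deg = _tss([("chr1", 100_000, "g1")])
    diff_peaks = PeakSet(
        pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [50_000, 10_000], "end": [50_500, 10_500]}
        )
    )
    all_peaks = PeakSet(
        pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "start": [20_000, 180_000, 30_000],
             "end": [20_500, 180_500, 30_500]}
        )
    )
    out = loopcall.deg_distance_cdf(diff_peaks, all_peaks, deg)
    assert out["n_skipped"] == 2  # one chr2 peak skipped in each set
    assert len(out["distances_differential"]) == 1
    assert len(out["distances_all"]) == 2
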