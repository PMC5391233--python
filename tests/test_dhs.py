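"""TSS window counting, clustering, contrasts and gene-set accessibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import epidrift as ed
from epidrift.dhs import WindowMatrix


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


@pytest.fixture(scope="module")
def sim2000():
    spec = ed.DhsSimSpec(n_tss=2000, seed=90)
    tss_bed = ed.make_tss_annotation(2000, seed=90)
    beds, truth = ed.simulate_dhs_fragments(spec, tss_bed)
    tss = ed.load_tss(tss_bed)
    hd = ed.count_windows(beds["HD"], tss, group="HD")
    wt = ed.count_windows(beds["wt"], tss, group="wt")
    return spec, truth, hd, wt


# ---------------------------------------------------------------------------
# TSS loading


def test_load_tss_strand_conventions_and_dedup():
    bed = _bed(
        [
            ("chr1", 1000, 2000, "geneA", 0, "+"),
            ("chr1", 1000, 2000, "geneB", 0, "-"),
            ("chr1", 1000, 2000, "geneA", 0, "+"),  # duplicate
            ("chr1", 5000, 6000, "geneC", 0, "."),  # no strand
        ]
    )
    tss = ed.load_tss(bed)
    assert len(tss) == 2
    assert tss.set_index("gene").loc["geneA", "tss"] == 1000
    assert tss.set_index("gene").loc["geneB", "tss"] == 1999


# ---------------------------------------------------------------------------
# Window counting


def test_midpoint_bin_conventions():
    tss = ed.load_tss(_bed([("chr1", 10_000, 12_000, "g", 0, "+")]))
    frags = _bed(
        [
            ("chr1", 9_970, 10_030, "at_tss", 0, "."),  # midpoint 10_000 -> bin 20
            ("chr1", 7_970, 8_030, "left_edge", 0, "."),  # midpoint 8_000 -> bin 0
            ("chr1", 11_970, 12_030, "right_edge", 0, "."),  # midpoint 12_000 -> out
        ]
    )
    m = ed.count_windows(frags, tss)
    row = m.counts.iloc[0]
    assert row["bin_20"] == 1 and row["bin_0"] == 1
    assert row.sum() == 2
    assert m.tallies["out_of_window"] == 1


def test_minus_strand_bins_are_flipped():
    plus = ed.load_tss(_bed([("chr1", 10_000, 12_000, "g", 0, "+")]))
    minus = ed.load_tss(_bed([("chr1", 8_001, 10_001, "g", 0, "-")]))  # TSS 10_000
    frag = _bed([("chr1", 10_470, 10_530, "f", 0, ".")])  # midpoint +500
    p = ed.count_windows(frag, plus).counts.iloc[0]
    m = ed.count_windows(frag, minus).counts.iloc[0]
    assert p["bin_25"] == 1  # +500 downstream on the plus strand
    assert m["bin_14"] == 1  # +500 genomic = 500 upstream in gene orientation


def test_simulated_totals_match_truth_exactly(sim2000):
    _, truth, hd, wt = sim2000
    assert (hd.totals.to_numpy() == truth.counts["HD"].to_numpy()).all()
    assert (wt.totals.to_numpy() == truth.counts["wt"].to_numpy()).all()


def test_fragment_conservation():
    tss = ed.load_tss(_bed([("chr1", 10_000, 12_000, "g", 0, "+")]))
    frags = _bed(
        [
            ("chr1", 10_000, 10_060, "in", 0, "."),
            ("chr1", 50_000, 50_060, "far", 0, "."),
            ("chr9", 10_000, 10_060, "other_chrom", 0, "."),
        ]
    )
    m = ed.count_windows(frags, tss)
    t = m.tallies
    assert t["counted"] + t["out_of_window"] + t["unknown_chromosome"] == t["total_fragments"]
    assert t["unknown_chromosome"] == 1 and t["counted"] == 1


def test_strand_reflection_symmetry():
    """Mirroring the genome and flipping strands leaves every profile unchanged.

    Exact away from the measure-zero edge cases of midpoint binning: fragments
    of odd length (integer-grid reflection preserves the midpoint) whose
    midpoints do not sit exactly on a bin boundary.
    """
    rng = np.random.default_rng(91)
    tss_pos = 50_000
    n = 500
    offs = rng.integers(-1999, 2000, size=n)
    offs = np.where(offs % 100 == 0, offs + 1, offs)
    mids = tss_pos + offs
    lens = 2 * rng.integers(25, 50, size=n) + 1  # odd, 51..99
    starts = mids - lens // 2
    frags = _bed(
        [("chr1", int(s), int(s + L), f"f{i}", 0, ".") for i, (s, L) in enumerate(zip(starts, lens))]
    )
    tss_fwd = ed.load_tss(_bed([("chr1", tss_pos, tss_pos + 2000, "g", 0, "+")]))
    fwd = ed.count_windows(frags, tss_fwd).counts.iloc[0]
    # reflect the integer grid around axis C: cell x -> 2C - 1 - x
    C = 1_000_000
    r_mids = 2 * C - 1 - mids
    r_starts = r_mids - lens // 2
    refl = _bed(
        [("chr1", int(s), int(s + L), f"f{i}", 0, ".") for i, (s, L) in enumerate(zip(r_starts, lens))]
    )
    t_rev = 2 * C - 1 - tss_pos  # minus-strand TSS = interval end - 1
    tss_rev = ed.load_tss(_bed([("chr1", t_rev + 1 - 2000, t_rev + 1, "g", 0, "-")]))
    rev = ed.count_windows(refl, tss_rev).counts.iloc[0]
    assert (fwd.to_numpy() == rev.to_numpy()).all()


# ---------------------------------------------------------------------------
# Depth normalization & differential classification


def test_depth_normalization_factors(sim2000):
    _, _, hd, wt = sim2000
    hd_n, wt_n = ed.normalize_depth(hd, wt)
    assert hd_n.scale == pytest.approx(1e6 / hd.total_fragments)
    ratio = hd.totals / wt.totals.replace(0, np.nan)
    ratio_n = hd_n.totals / wt_n.totals.replace(0, np.nan)
    if hd.total_fragments == wt.total_fragments:
        assert np.allclose(ratio.dropna(), ratio_n.dropna())


def test_normalize_depth_rejects_empty_group():
    empty = WindowMatrix(pd.DataFrame(), "HD", 2000, 100, 0, {})
    other = WindowMatrix(pd.DataFrame(), "wt", 2000, 100, 10, {})
    with pytest.raises(ValueError, match="zero fragments"):
        ed.normalize_depth(empty, other)


def test_classification_thresholds():
    idx = ["a", "b"]
    hd = WindowMatrix(pd.DataFrame({"bin_0": [40, 15]}, index=idx), "HD", 2000, 100, 55, {})
    wt = WindowMatrix(pd.DataFrame({"bin_0": [10, 10]}, index=idx), "wt", 2000, 100, 20, {})
    res = ed.classify_differential(hd, wt)
    assert res.loc["a", "label"] == "HD_high"  # ~4-fold
    assert res.loc["b", "label"] == "neutral"  # 1.5-fold < 2


def test_null_classification_balanced():
    """With no group effect, HD-high and wt-high counts agree to binomial noise."""
    n_hd = n_wt = 0
    for rep in range(6):
        spec = ed.DhsSimSpec(n_tss=300, fold_high=1.0, fold_low=1.0,
                             mean_high=50, mean_low=8, seed=200 + rep)
        tss_bed = ed.make_tss_annotation(300, seed=200 + rep)
        beds, _ = ed.simulate_dhs_fragments(spec, tss_bed)
        tss = ed.load_tss(tss_bed)
        hd = ed.count_windows(beds["HD"], tss, group="HD")
        wt = ed.count_windows(beds["wt"], tss, group="wt")
        res = ed.classify_differential(*ed.normalize_depth(hd, wt))
        n_hd += (res["label"] == "HD_high").sum()
        n_wt += (res["label"] == "wt_high").sum()
    p = sps.binomtest(n_hd, n_hd + n_wt, 0.5).pvalue
    assert p > 1e-3


# ---------------------------------------------------------------------------
# Clustering & contrasts


def test_cluster_recovery_and_determinism(sim2000):
    spec, truth, hd, wt = sim2000
    res = ed.cluster_tss(hd, wt, seed=0)
    expected_high = int(np.ceil(spec.high_cluster_fraction * spec.n_tss))
    assert abs(res.sizes[1] - expected_high) <= 0.02 * expected_high
    agreement = (res.labels.to_numpy() == truth.cluster.to_numpy()).mean()
    assert agreement >= 0.95
    res2 = ed.cluster_tss(hd, wt, seed=0)
    assert (res.labels == res2.labels).all()


def test_cluster_rejects_identical_profiles():
    counts = pd.DataFrame(np.ones((20, 40)), columns=[f"bin_{i}" for i in range(40)])
    m = WindowMatrix(counts, "HD", 2000, 100, 800, {})
    with pytest.raises(ValueError, match="distinct profiles"):
        ed.cluster_tss(m, m)


def test_contrast_identity_and_rescaling_invariance(sim2000):
    _, _, hd, wt = sim2000
    res = ed.cluster_tss(hd, wt, seed=0)
    ident = ed.cluster_contrast(res, hd, hd)
    assert np.allclose(ident["fold_change"], 1.0)
    assert (ident["p"] == 1.0).all()
    con = ed.cluster_contrast(res, hd, wt)
    scaled_hd = WindowMatrix(hd.counts * 3.0, "HD", 2000, 100, hd.total_fragments, {})
    scaled_wt = WindowMatrix(wt.counts * 3.0, "wt", 2000, 100, wt.total_fragments, {})
    con_s = ed.cluster_contrast(res, scaled_hd, scaled_wt)
    assert np.allclose(con["fold_change"], con_s["fold_change"])


def test_planted_fold_effects_recovered(sim2000):
    spec, _, hd, wt = sim2000
    res = ed.cluster_tss(hd, wt, seed=0)
    con = ed.cluster_contrast(res, hd, wt).set_index("cluster")
    assert con.loc[1, "fold_change"] == pytest.approx(spec.fold_high, rel=0.05)
    assert con.loc[2, "fold_change"] == pytest.approx(spec.fold_low, rel=0.05)
    assert (con["p"] < 1e-10).all()


# ---------------------------------------------------------------------------
# Gene sets


def test_geneset_accessibility(sim2000):
    _, truth, hd, wt = sim2000
    res = ed.cluster_tss(hd, wt, seed=0)
    genes = list(truth.cluster.index[:16])
    table, prop, misses = ed.geneset_accessibility(res, hd, wt, genes + ["missing_gene"])
    assert misses == ["missing_gene"]
    assert len(table) == 16
    informative = table[table["direction"] != "neutral"]
    assert prop == pytest.approx((informative["direction"] == "HD_high").mean())


def test_geneset_empty_list(sim2000):
    _, _, hd, wt = sim2000
    res = ed.cluster_tss(hd, wt, seed=0)
    table, prop, misses = ed.geneset_accessibility(res, hd, wt, [])
    assert len(table) == 0 and misses == [] and np.isnan(prop)


def test_geneset_tie_is_neutral_and_excluded():
    counts_hd = pd.DataFrame(np.ones((3, 40)), index=list("abc"),
                             columns=[f"bin_{i}" for i in range(40)])
    counts_wt = counts_hd.copy()
    counts_wt.loc["b"] *= 0.5
    hd = WindowMatrix(counts_hd, "HD", 2000, 100, 120, {})
    wt = WindowMatrix(counts_wt, "wt", 2000, 100, 100, {})
    from epidrift.dhs import TssClusterResult

    res = TssClusterResult(labels=pd.Series([2, 2, 2], index=list("abc")), sizes={2: 3}, seed=0)
    table, prop, _ = ed.geneset_accessibility(res, hd, wt, list("abc"))
    assert (table.set_index("gene").loc["a", "direction"] == "neutral")
    assert prop == 1.0  # only 'b' informative, HD-high
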