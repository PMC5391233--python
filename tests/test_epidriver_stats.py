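"""Differential expression, category contrasts, QC and bipartition."""

import numpy as np
import pandas as pd
import pytest

import epidrift as ed
from epidrift.simulate import DEFAULT_EFFECTS
from epidrift.stats import bh_adjust
from tests.conftest import age_groups, ra_matrix


def _null_effects(panel, genotypes=("HD",)):
    cats = {a.category for a in panel}
    return {g: {c: 0.0 for c in cats} for g in genotypes}


def _prg_only_effects(panel, lfc=3.0, genotypes=("wt", "HD"), hd_only=True):
    cats = {a.category for a in panel}
    out = {}
    for g in genotypes:
        out[g] = {c: 0.0 for c in cats}
        if g == "HD" or not hd_only:
            out[g]["PRG"] = lfc
    return out


@pytest.fixture(scope="module")
def study100():
    spec = ed.SyntheticPanelSpec(n_amplicons=100, seed=42)
    panel, _ = ed.make_ortholog_panel(spec)
    return panel


# ---------------------------------------------------------------------------
# BH oracle


def _bh_bruteforce(pvals):
    """Step-up BH computed from the definition: q_i = min over j>=i of m*p_(j)/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        q[i] = running
    return q


@pytest.mark.parametrize("seed", range(8))
def test_bh_adjustment_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(1, 13))
    assert np.allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)


# ---------------------------------------------------------------------------
# DETS


def test_identical_groups_yield_no_dets(study100):
    panel = study100
    design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                            category_log2fc=_null_effects(panel))
    samples, _, _ = ed.generate_study(design, panel, seed=70)
    ra = ra_matrix(samples)
    young, _ = age_groups(samples, "HD")
    res = ed.detect_dets(ra[young + young], young, young)
    assert (res["log2fc"] == 0).all()
    assert not res["passes"].any()


def test_detect_dets_requires_replicates(study100):
    design = ed.StudyDesign(genotypes=("HD",), replicates=2,
                            category_log2fc=_null_effects(study100))
    samples, _, _ = ed.generate_study(design, study100, seed=71)
    ra = ra_matrix(samples)
    young, aged = age_groups(samples, "HD")
    with pytest.raises(ValueError, match="replicates"):
        ed.detect_dets(ra, young[:1], aged)


def test_null_calibration(study100):
    """Without planted effects, false DETS average <= 1 per replicate."""
    panel = study100
    counts = []
    for rep in range(40):
        design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                                category_log2fc=_null_effects(panel))
        samples, _, _ = ed.generate_study(design, panel, seed=800 + rep)
        ra = ra_matrix(samples)
        young, aged = age_groups(samples, "HD")
        counts.append(int(ed.detect_dets(ra, young, aged)["passes"].sum()))
    assert np.mean(counts) <= 1.0


def test_planted_effect_detected(study100):
    """|log2FC| = 3 planted on the PRG category is detected with high sensitivity."""
    panel = study100
    planted = [a.amplicon_id for a in panel if a.category == "PRG"]
    sens = []
    for rep in range(10):
        design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                                category_log2fc={"HD": DEFAULT_EFFECTS["HD"]})
        samples, _, _ = ed.generate_study(design, panel, seed=900 + rep)
        ra = ra_matrix(samples)
        young, aged = age_groups(samples, "HD")
        res = ed.detect_dets(ra, young, aged)
        sens.append(res.loc[planted, "passes"].mean())
    assert np.mean(sens) >= 0.9


def test_label_permutation_symmetry(study100):
    """Reordering samples within a group leaves every statistic unchanged."""
    panel = study100
    design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                            category_log2fc={"HD": DEFAULT_EFFECTS["HD"]})
    samples, _, _ = ed.generate_study(design, panel, seed=72)
    ra = ra_matrix(samples)
    young, aged = age_groups(samples, "HD")
    a = ed.detect_dets(ra, young, aged)
    b = ed.detect_dets(ra, young[::-1], list(reversed(aged)))
    pd.testing.assert_frame_equal(a, b)


def test_nb_wald_variant_agrees_on_strong_effects(study100):
    panel = study100
    design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                            category_log2fc={"HD": DEFAULT_EFFECTS["HD"]})
    samples, _, _ = ed.generate_study(design, panel, seed=73)
    ra = ra_matrix(samples)
    counts = pd.DataFrame({s.sample_id: s.mouse_counts for s in samples})
    young, aged = age_groups(samples, "HD")
    nb = ed.detect_dets(ra, young, aged, method="nb_wald", counts=counts)
    planted = [a.amplicon_id for a in panel if a.category == "PRG"]
    assert (nb.loc[planted, "p"] < 0.01).mean() > 0.8


# ---------------------------------------------------------------------------
# Category summaries


def _flat_matrix(panel, samples_per_group=2):
    amp_ids = [a.amplicon_id for a in panel]
    cols = {}
    meta = []
    for g in ("wt", "HD"):
        for age in ("young", "aged"):
            for r in range(samples_per_group):
                sid = f"{g}_{age}_{r + 1}"
                cols[sid] = np.ones(len(amp_ids))
                meta.append({"sample_id": sid, "genotype": g, "age": age})
    return pd.DataFrame(cols, index=amp_ids), pd.DataFrame(meta)


def test_category_summary_null_identity(small_panel):
    panel, _ = small_panel
    mat, meta = _flat_matrix(panel)
    cats = {a.amplicon_id: a.category for a in panel}
    res = ed.category_summary(mat, meta, cats)
    assert np.allclose(res.table["mean_fc"], 1.0)
    assert ((res.table["p"].isna()) | (res.table["p"] == 1.0)).all()


def test_category_fold_change_inverts_under_label_swap(study100):
    panel = study100
    design = ed.StudyDesign(replicates=2, category_log2fc={
        g: DEFAULT_EFFECTS[g] for g in ("wt", "HD")})
    samples, sheet, _ = ed.generate_study(design, panel, seed=74)
    ra = ra_matrix(samples)
    cats = {a.amplicon_id: a.category for a in panel}
    res = ed.category_summary(ra, sheet, cats)
    swapped_meta = sheet.assign(age=sheet["age"].map({"young": "aged", "aged": "young"}))
    res_sw = ed.category_summary(ra, swapped_meta, cats)
    merged = res.fold_changes.join(res_sw.fold_changes, rsuffix="_sw")
    assert np.allclose(merged["HD"], 1.0 / merged["HD_sw"])
    assert np.allclose(merged["wt"], 1.0 / merged["wt_sw"])


def test_prg_only_effect_gives_significant_hd_vs_wt_contrast(study100):
    panel = study100
    cats = {a.amplicon_id: a.category for a in panel}
    design = ed.StudyDesign(replicates=4, category_log2fc=_prg_only_effects(panel))
    samples, sheet, _ = ed.generate_study(design, panel, seed=75)
    ra = ra_matrix(samples)
    res = ed.category_summary(ra, sheet, cats)
    row = res.table[(res.table.category == "PRG")
                    & (res.table.comparison == "age_effect_HD_vs_wt")]
    assert row["p"].iloc[0] < 0.01
    assert row["mean_fc"].iloc[0] > 2.0


def test_category_summary_rejects_uncategorized(small_panel):
    panel, _ = small_panel
    mat, meta = _flat_matrix(panel)
    with pytest.raises(ValueError, match="uncategorized"):
        ed.category_summary(mat, meta, {})


# ---------------------------------------------------------------------------
# PRG contrasts


def test_prg_contrast_identity_is_zero(small_panel):
    panel, _ = small_panel
    mat, meta = _flat_matrix(panel)
    prg = [a.amplicon_id for a in panel][:4]
    res = ed.prg_contrast(mat, meta, prg)
    assert np.allclose(res["mean_log2_fold_difference"], 0.0)
    assert (res["p"] == 1.0).all()


def test_prg_contrast_recovers_planted_shift(study100):
    """A uniform +2 log2 shift on PRGs appears in the aged-HD contrast."""
    panel = study100
    prg = [a.amplicon_id for a in panel if a.category == "PRG"]
    design = ed.StudyDesign(replicates=4,
                            category_log2fc=_prg_only_effects(panel, lfc=2.0),
                            baseline_depth=2000.0)
    samples, sheet, _ = ed.generate_study(design, panel, seed=76)
    # raw (un-normalized) ratios avoid compositional compression of the shift
    from epidrift.quant import calibrate_bias, compute_ratios, tables_from_study

    raw = calibrate_bias(compute_ratios(tables_from_study(samples))).corrected
    res = ed.prg_contrast(raw, sheet, prg).set_index("contrast")
    est = res.loc["aged_HD_vs_young_HD", "mean_log2_fold_difference"]
    assert abs(est - 2.0) < 0.2
    assert abs(res.loc["young_HD_vs_young_wt", "mean_log2_fold_difference"]) < 0.2


def test_prg_contrast_rejects_unknown_amplicon(small_panel):
    panel, _ = small_panel
    mat, meta = _flat_matrix(panel)
    with pytest.raises(KeyError, match="nope"):
        ed.prg_contrast(mat, meta, ["nope"])


# ---------------------------------------------------------------------------
# QC


def test_pca_separates_shifted_groups(study100):
    from sklearn.metrics import silhouette_score

    panel = study100
    design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                            category_log2fc={"HD": DEFAULT_EFFECTS["HD"]})
    samples, _, _ = ed.generate_study(design, panel, seed=77)
    ra = ra_matrix(samples)
    coords, evr = ed.pca_qc(ra)
    labels = [s.age for s in samples]
    assert silhouette_score(coords[["PC1"]], labels) > 0.5
    assert evr.sum() <= 1.0 + 1e-12


def test_pca_duplicated_sample_has_identical_coordinates(study100):
    panel = study100
    design = ed.StudyDesign(genotypes=("HD",), replicates=2,
                            category_log2fc=_null_effects(panel))
    samples, _, _ = ed.generate_study(design, panel, seed=78)
    ra = ra_matrix(samples)
    dup = ra.copy()
    dup["dup"] = dup.iloc[:, 0]
    coords, _ = ed.pca_qc(dup)
    assert np.allclose(coords.iloc[0], coords.loc["dup"])


def test_pca_rejects_constant_matrix():
    mat = pd.DataFrame(np.ones((10, 4)), columns=list("abcd"))
    with pytest.raises(ValueError, match="zero variance|constant"):
        ed.pca_qc(mat)


def test_correlation_matrix_properties(study100):
    panel = study100
    design = ed.StudyDesign(genotypes=("HD",), replicates=3,
                            category_log2fc=_null_effects(panel))
    samples, _, _ = ed.generate_study(design, panel, seed=79)
    ra = ra_matrix(samples)
    corr, summary = ed.correlation_heatmap(
        ra, groups={s.sample_id: s.age for s in samples}
    )
    assert np.allclose(corr, corr.T, atol=1e-12)
    assert np.allclose(np.diag(corr), 1.0)
    assert set(summary["kind"]) == {"within", "between"}


def test_noisier_group_has_lower_within_correlation(study100):
    """Higher within-group dispersion in 'aged' lowers its within-group r."""
    panel = study100
    rng = np.random.default_rng(80)
    amp_ids = [a.amplicon_id for a in panel]
    base = rng.lognormal(0, 1, size=len(amp_ids))
    cols, groups = {}, {}
    for i in range(4):
        cols[f"young_{i}"] = base * rng.lognormal(0, 0.05, size=len(amp_ids))
        groups[f"young_{i}"] = "young"
        cols[f"aged_{i}"] = base * rng.lognormal(0, 0.8, size=len(amp_ids))
        groups[f"aged_{i}"] = "aged"
    mat = pd.DataFrame(cols, index=amp_ids)
    _, summary = ed.correlation_heatmap(mat, groups=groups)
    s = summary.set_index(["group_a", "group_b"])["mean_r"]
    assert s.loc[("aged", "aged")] < s.loc[("young", "young")]


# ---------------------------------------------------------------------------
# Bipartition


def test_bipartition_recovers_aged_high_prgs(study100):
    panel = study100
    cats = {a.amplicon_id: a.category for a in panel}
    design = ed.StudyDesign(genotypes=("HD",), replicates=4,
                            category_log2fc=_prg_only_effects(panel))
    samples, _, _ = ed.generate_study(design, panel, seed=81)
    ra = ra_matrix(samples)
    _, aged = age_groups(samples, "HD")
    bip = ed.bipartition_and_enrichment(ra, aged, cats, seed=0)
    assert bip.proportions.loc["PRG", "aged_high"] >= 0.8
    assert np.allclose(bip.proportions.sum(axis=1), 1.0)


def test_bipartition_rejects_degenerate_profiles(small_panel):
    panel, _ = small_panel
    mat, meta = _flat_matrix(panel)
    cats = {a.amplicon_id: a.category for a in panel}
    with pytest.raises(ValueError, match="degenerate|constant"):
        ed.bipartition_and_enrichment(mat, [mat.columns[0]], cats)
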