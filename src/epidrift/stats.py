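"""Expression statistics on normalized relative-abundance (RA) matrices.

All operations take an amplicons x samples matrix of normalized RA values
plus sample metadata (genotype, age). The differential test for DETS
(differentially expressed target sequences: |log2FC| > 1 and BH-FDR < 0.01)
is a Welch t-test on log2 RA with Benjamini-Hochberg adjustment; a
negative-binomial Wald variant on raw mouse counts is available behind
``method="nb_wald"``. Category summaries and Polycomb-target (PRG)
contrasts use paired-sample t-tests with the amplicon as the pairing unit —
the amplicon is the only object shared across the compared conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTRASTS = (
    ("aged_HD_vs_young_HD", ("aged", "HD"), ("young", "HD")),
    ("aged_HD_vs_aged_wt", ("aged", "HD"), ("aged", "wt")),
    ("aged_wt_vs_young_wt", ("aged", "wt"), ("young", "wt")),
    ("young_HD_vs_young_wt", ("young", "HD"), ("young", "wt")),
)


def _log2(matrix: pd.DataFrame, pseudo: float = 0.0) -> pd.DataFrame:
    vals = matrix + pseudo
    if (vals <= 0).any().any():
        raise ValueError(
            "non-positive RA values; pass a positive log pseudocount"
        )
    return np.log2(vals)


def _group_cols(sample_meta: pd.DataFrame, age: str, genotype: str) -> list[str]:
    sel = sample_meta[(sample_meta["age"] == age) & (sample_meta["genotype"] == genotype)]
    return sel["sample_id"].tolist()


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values over one testing family."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DETS


def detect_dets(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
    category_map: Mapping[str, str] | None = None,
    log_pseudo: float = 0.0,
    method: str = "welch",
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Detect differentially expressed target sequences between two groups.

    ``log2fc`` is the mean log2 RA of ``group_b`` minus ``group_a`` (read:
    b vs a, e.g. aged vs young). Raw p-values come from a Welch two-sample
    t-test per amplicon (default) or a negative-binomial Wald test on raw
    counts (``method="nb_wald"``, requires ``counts``); q-values are BH over
    all tested amplicons. ``passes`` is |log2FC| > log2(fc_threshold) and
    FDR < fdr_threshold. Zero-variance amplicons are excluded from testing
    with a log entry.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    logm = _log2(matrix, log_pseudo)
    a = logm[list(group_a)].to_numpy()
    b = logm[list(group_b)].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    var = np.concatenate([a, b], axis=1).var(axis=1)
    testable = var > 0
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("detect_dets: %d zero-variance amplicon(s) not tested", n_dropped)
    pvals = np.full(len(matrix), np.nan)
    if method == "welch":
        if testable.any():
            res = sps.ttest_ind(b[testable], a[testable], axis=1, equal_var=False)
            pvals[testable] = res.pvalue
    elif method == "nb_wald":
        if counts is None:
            raise ValueError("nb_wald requires the raw mouse count matrix")
        pvals = _nb_wald_pvalues(counts, list(group_a), list(group_b), testable)
    else:
        raise ValueError(f"unknown method {method!r}")
    fdr = np.full(len(matrix), np.nan)
    mask = np.isfinite(pvals)
    if mask.any():
        fdr[mask] = bh_adjust(pvals[mask])
    out = pd.DataFrame(
        {
            "amplicon": matrix.index,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    ).set_index("amplicon")
    out["passes"] = (
        (np.abs(out["log2fc"]) > np.log2(fc_threshold))
        & (out["fdr"] < fdr_threshold)
    ).fillna(False)
    if category_map is not None:
        out.insert(0, "category", pd.Series(category_map).reindex(out.index))
    return out


def _nb_wald_pvalues(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    testable: np.ndarray,
) -> np.ndarray:
    import statsmodels.api as sm

    cols = group_a + group_b
    design = np.column_stack(
        [np.ones(len(cols)), np.array([0] * len(group_a) + [1] * len(group_b))]
    )
    pvals = np.full(len(counts), np.nan)
    y_all = counts[cols].to_numpy()
    for i in range(len(counts)):
        if not testable[i]:
            continue
        try:
            model = sm.NegativeBinomial(y_all[i], design)
            fit = model.fit(disp=0, maxiter=200)
            pvals[i] = fit.pvalues[1]
        except Exception:  # convergence failure on a degenerate amplicon
            pvals[i] = np.nan
    return pvals


# ---------------------------------------------------------------------------
# Category summaries


@dataclass
class CategorySummary:
    table: pd.DataFrame  # per (category, comparison): mean_fc, std_fc, n, p
    fold_changes: pd.DataFrame  # per amplicon: fc per genotype + category


def category_summary(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    category_map: Mapping[str, str],
    log_pseudo: float = 0.0,
) -> CategorySummary:
    """Per-category aged/young mean fold changes, STD and paired t-tests.

    Per amplicon and genotype, FC = mean RA(aged) / mean RA(young). Per
    category three tests are reported: one-sample t on log2 FC vs 0 within
    each genotype, and the HD-vs-wt age-effect paired t across amplicons
    (each amplicon's HD fold change paired with its wt fold change).
    Categories with < 2 amplicons get p = NaN.
    """
    cats = pd.Series(category_map)
    missing = matrix.index.difference(cats.index)
    if len(missing):
        raise ValueError(f"uncategorized amplicons: {list(missing)[:5]}")
    logm = _log2(matrix, log_pseudo)
    lfc = {}
    for g in ("wt", "HD"):
        aged = _group_cols(sample_meta, "aged", g)
        young = _group_cols(sample_meta, "young", g)
        if not aged or not young:
            continue
        lfc[g] = logm[aged].mean(axis=1) - logm[young].mean(axis=1)
    fc_df = pd.DataFrame({g: 2.0 ** v for g, v in lfc.items()})
    fc_df["category"] = cats.reindex(fc_df.index)
    rows = []
    for cat, sub in fc_df.groupby("category", sort=True):
        for g in lfc:
            vals = np.log2(sub[g].to_numpy())
            p = _one_sample_t(vals)
            rows.append(
                {
                    "category": cat,
                    "comparison": f"aged_vs_young_{g}",
                    "n_amplicons": len(sub),
                    "mean_fc": float(sub[g].mean()),
                    "std_fc": float(sub[g].std(ddof=1)) if len(sub) > 1 else np.nan,
                    "p": p,
                }
            )
        if "wt" in lfc and "HD" in lfc:
            d = np.log2(sub["HD"].to_numpy()) - np.log2(sub["wt"].to_numpy())
            rows.append(
                {
                    "category": cat,
                    "comparison": "age_effect_HD_vs_wt",
                    "n_amplicons": len(sub),
                    "mean_fc": float((sub["HD"] / sub["wt"]).mean()),
                    "std_fc": float((sub["HD"] / sub["wt"]).std(ddof=1))
                    if len(sub) > 1
                    else np.nan,
                    "p": _one_sample_t(d),
                }
            )
    return CategorySummary(table=pd.DataFrame(rows), fold_changes=fc_df)


def _one_sample_t(vals: np.ndarray) -> float:
    """One-sample t of `vals` vs 0; NaN for n < 2 or zero variance at 0."""
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        return float("nan")
    if np.allclose(vals.var(ddof=0), 0.0):
        # exactly-zero differences are perfectly consistent with the null;
        # constant nonzero differences reject it outright
        return 1.0 if np.allclose(vals.mean(), 0.0) else 0.0
    return float(sps.ttest_1samp(vals, 0.0).pvalue)


# ---------------------------------------------------------------------------
# PRG contrasts


def prg_contrast(
    matrix: pd.DataFrame,
    sample_meta: pd.DataFrame,
    prg_amplicons: Sequence[str],
    log_pseudo: float = 0.0,
) -> pd.DataFrame:
    """The four Polycomb-target contrasts with paired t-tests across amplicons.

    For each contrast (aged-HD/young-HD, aged-HD/aged-wt, aged-wt/young-wt,
    young-HD/young-wt) the per-amplicon log2 fold difference between the two
    group means is computed over the PRG amplicon list, and a paired-sample
    t-test (equivalently a one-sample t of the differences vs 0) is reported.
    """
    if not len(prg_amplicons):
        raise ValueError("empty PRG list")
    missing = [a for a in prg_amplicons if a not in matrix.index]
    if missing:
        raise KeyError(f"PRG amplicons absent from matrix: {missing}")
    logm = _log2(matrix.loc[list(prg_amplicons)], log_pseudo)
    rows = []
    for label, (age1, g1), (age2, g2) in CONTRASTS:
        c1 = _group_cols(sample_meta, age1, g1)
        c2 = _group_cols(sample_meta, age2, g2)
        diff = logm[c1].mean(axis=1) - logm[c2].mean(axis=1)
        rows.append(
            {
                "contrast": label,
                "n_amplicons": len(diff),
                "mean_log2_fold_difference": float(diff.mean()),
                "sem": float(diff.sem()) if len(diff) > 1 else np.nan,
                "p": _one_sample_t(diff.to_numpy()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC


def pca_qc(matrix: pd.DataFrame, log_pseudo: float = 0.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates on the first two principal components.

    Input is log2-transformed and centered per amplicon; components are of
    the sample x amplicon matrix, deterministic up to sign. Returns
    (coordinates DataFrame with PC1/PC2 per sample, explained variance
    ratios).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    X = _log2(matrix, log_pseudo).to_numpy().T  # samples x amplicons
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant matrix: zero variance")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    df = pd.DataFrame(coords, index=matrix.columns, columns=["PC1", "PC2"])
    return df, pca.explained_variance_ratio_


def correlation_heatmap(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Sample x sample Pearson correlation, plus group-wise mean off-diagonal r.

    Zero-variance samples get NaN rows/columns. When ``groups`` maps sample
    to group label, the second return value summarizes mean off-diagonal r
    within and between groups.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    corr = matrix.corr(method="pearson")
    ok = matrix.std(axis=0) > 0
    for s in ok.index[~ok]:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
    np.fill_diagonal(corr.values, np.where(ok, 1.0, np.nan))
    summary = None
    if groups is not None:
        g = pd.Series(groups)
        rows = []
        labels = sorted(set(g))
        for i, ga in enumerate(labels):
            for gb in labels[i:]:
                sa = g.index[g == ga]
                sb = g.index[g == gb]
                block = corr.loc[sa, sb].to_numpy(dtype=float)
                if ga == gb:
                    iu = np.triu_indices_from(block, k=1)
                    vals = block[iu]
                else:
                    vals = block.ravel()
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "kind": "within" if ga == gb else "between",
                        "mean_r": float(np.nanmean(vals)) if vals.size else np.nan,
                    }
                )
        summary = pd.DataFrame(rows)
    return corr, summary


# ---------------------------------------------------------------------------
# Bipartition


@dataclass
class AmpliconBipartition:
    labels: pd.Series  # amplicon -> "aged_high" | "other"
    proportions: pd.DataFrame  # per category: aged_high / other fractions


def bipartition_and_enrichment(
    matrix: pd.DataFrame,
    aged_samples: Sequence[str],
    category_map: Mapping[str, str],
    seed: int = 0,
    log_pseudo: float = 0.0,
    method: str = "kmeans",
) -> AmpliconBipartition:
    """Split amplicons into aged-high vs other profiles and tally categories.

    Profiles are z-scored log2 RA across samples, clustered by 2-means
    (default, fixed seed with 10 restarts) or by cutting a Ward hierarchy in
    two (``method="ward"``). The cluster with the higher mean over the aged
    samples is labeled ``aged_high``. Per category, the proportions of
    amplicons in the two clusters are reported (rows sum to 1).
    """
    logm = _log2(matrix, log_pseudo)
    sd = logm.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValueError("degenerate input: all amplicon profiles constant")
    z = logm.sub(logm.mean(axis=1), axis=0).div(sd.replace(0, 1.0), axis=0)
    X = z.to_numpy()
    if method == "kmeans":
        labels = None
        for attempt in range(10):
            km = KMeans(n_clusters=2, n_init=10, random_state=seed + attempt)
            cand = km.fit_predict(X)
            if len(np.unique(cand)) == 2:
                labels = cand
                break
        if labels is None:
            raise ValueError("k-means degenerate after 10 re-seeds")
    elif method == "ward":
        from scipy.cluster.hierarchy import fcluster, linkage

        labels = fcluster(linkage(X, method="ward"), t=2, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            raise ValueError("hierarchical cut degenerate")
    else:
        raise ValueError(f"unknown method {method!r}")
    aged_mean = {
        c: z.loc[labels == c, list(aged_samples)].to_numpy().mean()
        for c in (0, 1)
    }
    high = max(aged_mean, key=aged_mean.get)
    lab = pd.Series(
        np.where(labels == high, "aged_high", "other"), index=matrix.index
    )
    cats = pd.Series(category_map).reindex(matrix.index)
    prop = (
        pd.crosstab(cats, lab, normalize="index")
        .reindex(columns=["aged_high", "other"], fill_value=0.0)
    )
    return AmpliconBipartition(labels=lab, proportions=prop)
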