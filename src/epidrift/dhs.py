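"""DNase-I hypersensitivity profiling around transcription start sites.

Fragment intervals (BED, 0-based half-open) are counted into strand-oriented
+/-2 kb windows around TSSs (40 bins of 100 bp by default; a fragment falls
in the bin containing its midpoint). Downstream operations: counts-per-million
depth scaling, 2-fold differential classification of per-TSS totals, k-means
(k = 2) clustering of the joint HD+wt profiles, per-cluster mean-density
contrasts in the +/-300 bp core, and gene-set accessibility comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class WindowMatrix:
    """Per-TSS binned fragment counts for one sample group.

    ``counts`` is TSS x bin with bins ordered 5'->3' in the transcription
    direction (minus-strand windows are flipped so upstream is on the left).
    """

    counts: pd.DataFrame
    group: str
    flank: int
    bin_size: int
    total_fragments: int
    tallies: dict
    scale: float = 1.0

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def core_density(self, core_flank: int = 300) -> pd.Series:
        """Mean per-bin count over the central +/-core_flank window."""
        nb = self.counts.shape[1]
        half = nb // 2
        k = core_flank // self.bin_size
        cols = self.counts.columns[half - k : half + k]
        return self.counts[cols].mean(axis=1)


def load_tss(annotation: pd.DataFrame | str) -> pd.DataFrame:
    """Normalize a BED6 annotation into TSS records.

    TSS = interval start on '+', interval end - 1 on '-'. Records without a
    valid strand are dropped with a log entry; duplicated (gene, position)
    records collapse to one.
    """
    if isinstance(annotation, str):
        from epidrift.simulate import read_bed

        annotation = read_bed(annotation)
    df = annotation.copy()
    ok = df["strand"].isin(["+", "-"])
    if (~ok).any():
        logger.warning("load_tss: dropped %d record(s) without strand", int((~ok).sum()))
        df = df[ok]
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = pd.DataFrame(
        {
            "gene": df["name"].to_numpy(),
            "chrom": df["chrom"].to_numpy(),
            "tss": tss,
            "strand": df["strand"].to_numpy(),
        }
    ).drop_duplicates(subset=["gene", "tss"], ignore_index=True)
    return out


def count_windows(
    fragments: pd.DataFrame,
    tss: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 100,
    group: str = "group",
) -> WindowMatrix:
    """Count fragment midpoints into per-TSS bins spanning [TSS-flank, TSS+flank).

    A fragment contributes to the single bin containing its midpoint
    ((start + end) // 2). Windows on the minus strand are orientation-flipped.
    Fragments on chromosomes absent from the TSS set are ignored and tallied;
    the conservation tally counts each fragment once even when windows
    overlap (counted = midpoint inside the union of windows).
    """
    if 2 * flank % bin_size:
        raise ValueError("window must divide evenly into bins")
    tss = tss.reset_index(drop=True)
    n_bins = 2 * flank // bin_size
    mids = ((fragments["start"] + fragments["end"]) // 2).to_numpy()
    chroms = fragments["chrom"].to_numpy()
    mat = np.zeros((len(tss), n_bins), dtype=np.int64)
    tss_chroms = set(tss["chrom"])
    unknown = int((~np.isin(chroms, list(tss_chroms))).sum())
    counted_mask = np.zeros(len(fragments), dtype=bool)
    for chrom in tss_chroms:
        sel = chroms == chrom
        if not sel.any():
            continue
        m = np.sort(mids[sel])
        sub = tss[tss["chrom"] == chrom]
        starts = sub["tss"].to_numpy() - flank
        edges = starts[:, None] + bin_size * np.arange(n_bins + 1)[None, :]
        pos = np.searchsorted(m, edges)  # rows: TSS, cols: bin edges
        rows = np.diff(pos, axis=1)
        flip = (sub["strand"] == "-").to_numpy()
        rows[flip] = rows[flip, ::-1]
        mat[sub.index.to_numpy()] = rows
        # conservation: midpoint inside the union of (possibly overlapping) windows
        iv = np.stack([starts, starts + 2 * flank], axis=1)
        iv = iv[np.argsort(iv[:, 0])]
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        merged = np.array(merged)
        local = mids[sel]
        j = np.searchsorted(merged[:, 0], local, side="right") - 1
        inside = (j >= 0) & (local < merged[np.clip(j, 0, None), 1])
        counted_mask[np.nonzero(sel)[0][inside]] = True
    counted = int(counted_mask.sum())
    bins = [f"bin_{i}" for i in range(n_bins)]
    counts = pd.DataFrame(mat, index=tss["gene"].to_numpy(), columns=bins)
    tallies = {
        "total_fragments": len(fragments),
        "counted": counted,
        "out_of_window": len(fragments) - counted - unknown,
        "unknown_chromosome": unknown,
    }
    return WindowMatrix(
        counts=counts,
        group=group,
        flank=flank,
        bin_size=bin_size,
        total_fragments=len(fragments),
        tallies=tallies,
    )


def normalize_depth(a: WindowMatrix, b: WindowMatrix) -> tuple[WindowMatrix, WindowMatrix]:
    """Scale both matrices to counts per million fragments of their group."""
    out = []
    for m in (a, b):
        if m.total_fragments == 0:
            raise ValueError(f"group {m.group!r} has zero fragments")
        scale = 1e6 / m.total_fragments
        out.append(
            WindowMatrix(
                counts=m.counts * scale,
                group=m.group,
                flank=m.flank,
                bin_size=m.bin_size,
                total_fragments=m.total_fragments,
                tallies=dict(m.tallies),
                scale=scale,
            )
        )
    return out[0], out[1]


def classify_differential(
    hd: WindowMatrix,
    wt: WindowMatrix,
    fold: float = 2.0,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Label each TSS HD_high / wt_high / neutral by its window-total ratio.

    The ratio is (HD + floor) / (wt + floor): the pseudo-floor keeps
    zero-count promoters finite and damps fold estimates at negligible
    counts. Returns per-TSS totals, ratio and label.
    """
    h = hd.totals
    w = wt.totals.reindex(h.index)
    ratio = (h + floor) / (w + floor)
    label = np.where(ratio >= fold, "HD_high", np.where(ratio <= 1 / fold, "wt_high", "neutral"))
    return pd.DataFrame(
        {"hd_total": h, "wt_total": w, "ratio": ratio, "label": label}, index=h.index
    )


@dataclass
class TssClusterResult:
    labels: pd.Series  # per TSS: 1 (dense) or 2 (shallow)
    sizes: dict[int, int]
    seed: int


def cluster_tss(
    hd: WindowMatrix,
    wt: WindowMatrix,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> TssClusterResult:
    """k-means (k = 2) on the joint per-TSS accessibility profiles.

    The feature vector of a TSS is its HD profile concatenated with its wt
    profile, log1p-transformed. Cluster 1 is the one with the higher mean
    signal (the dense minority); determinism is fixed by the seed.
    """
    X = np.log1p(
        np.concatenate([hd.counts.to_numpy(), wt.counts.reindex(hd.counts.index).to_numpy()], axis=1)
    )
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct profiles than clusters")
    labels = None
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        cand = km.fit_predict(X)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        raise ValueError("degenerate clustering after 10 restarts")
    means = {c: X[labels == c].mean() for c in np.unique(labels)}
    order = sorted(means, key=means.get, reverse=True)  # densest first
    remap = {c: i + 1 for i, c in enumerate(order)}
    lab = pd.Series([remap[c] for c in labels], index=hd.counts.index)
    sizes = lab.value_counts().to_dict()
    return TssClusterResult(labels=lab, sizes=sizes, seed=seed)


def cluster_contrast(
    result: TssClusterResult,
    hd: WindowMatrix,
    wt: WindowMatrix,
    core_flank: int = 300,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Per-cluster HD/wt mean-density fold change in the +/-core window.

    Density is the mean bin count over the central +/-core_flank; the fold
    change is mean(HD)/mean(wt) over the cluster's TSSs with a two-sided
    Wilcoxon rank-sum test across TSSs (``test="ttest"`` for Welch).
    """
    hdc = hd.core_density(core_flank)
    wtc = wt.core_density(core_flank).reindex(hdc.index)
    rows = []
    for c in sorted(set(result.labels)):
        sel = result.labels == c
        h = hdc[sel].to_numpy()
        w = wtc[sel].to_numpy()
        if len(h) == 0:
            rows.append(
                {"cluster": c, "n_tss": 0, "hd_mean": np.nan, "wt_mean": np.nan,
                 "fold_change": np.nan, "p": np.nan}
            )
            continue
        fold = h.mean() / w.mean() if w.mean() > 0 else np.nan
        if np.array_equal(h, w):
            p = 1.0
        elif test == "ranksum":
            p = float(sps.mannwhitneyu(h, w, alternative="two-sided").pvalue)
        elif test == "ttest":
            p = float(sps.ttest_ind(h, w, equal_var=False).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "cluster": c,
                "n_tss": int(sel.sum()),
                "hd_mean": float(h.mean()),
                "wt_mean": float(w.mean()),
                "fold_change": float(fold),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def geneset_accessibility(
    result: TssClusterResult,
    hd: WindowMatrix,
    wt: WindowMatrix,
    genes: Sequence[str],
    core_flank: int = 300,
) -> tuple[pd.DataFrame, float, list[str]]:
    """Cluster membership and HD-vs-wt direction for a list of genes.

    For each resolvable gene, reports its cluster and whether HD core
    density exceeds wt at its TSS; exact ties are neutral and excluded from
    the summary proportion. Returns (per-gene table, HD-high proportion,
    unresolved gene list).
    """
    hdc = hd.core_density(core_flank)
    wtc = wt.core_density(core_flank).reindex(hdc.index)
    rows = []
    misses = []
    for gene in genes:
        if gene not in result.labels.index:
            misses.append(gene)
            continue
        h, w = float(hdc[gene]), float(wtc[gene])
        direction = "HD_high" if h > w else ("wt_high" if w > h else "neutral")
        rows.append(
            {
                "gene": gene,
                "cluster": int(result.labels[gene]),
                "hd_density": h,
                "wt_density": w,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "cluster", "hd_density", "wt_density", "direction"])
    informative = table[table["direction"] != "neutral"]
    prop = (
        float((informative["direction"] == "HD_high").mean())
        if len(informative)
        else float("nan")
    )
    return table, prop, misses
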