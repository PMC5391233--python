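"""Competitive spike-in quantification: from paired FASTQ to normalized RA.

Stages, each a separate operation so intermediate products can be inspected:

1. :func:`merge_pairs` — overlap-merge read pairs (quality-aware overlap
   resolution; pairs failing the overlap criteria or containing an ambiguous
   base are rejected with a reason).
2. :func:`assign_read` / :func:`assign_reads` — assign each merged read to
   (amplicon, species) iff it matches a consensus sequence with 100%
   identity over a terminal span covering >= 90% of that reference.
3. :func:`tabulate` — per-amplicon mouse/rat counts with read conservation.
4. :func:`compute_ratios` -> :func:`calibrate_bias` -> :func:`normalize` —
   raw mouse/rat (M/R) ratio, optional control-based amplicon-bias
   correction, and normalization by the all-amplicon mean so the mean
   relative abundance RA is 1 per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from epidrift.reference import IsvReference
from epidrift.seqio import encode, decode, revcomp_arr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    overlap: int


class Assignment(NamedTuple):
    read_id: str
    amplicon: str | None
    species: str | None
    reason: str | None  # None when assigned


# ---------------------------------------------------------------------------
# Pair merging


def _strip_mate(rid: str) -> str:
    return rid[:-2] if rid.endswith(("/1", "/2")) else rid


def merge_pairs(
    r1: Iterable[tuple[str, str, str]],
    r2: Iterable[tuple[str, str, str]],
    min_overlap: int = 20,
    max_overlap_mismatch: float = 0.1,
) -> tuple[list[MergedRead], dict[str, int], pd.DataFrame]:
    """Overlap-merge synchronized paired reads.

    The merged sequence is R1 followed by the reverse complement of R2,
    overlapped at the offset maximizing (matches - 4 x mismatches) among
    offsets with overlap >= ``min_overlap`` and mismatch fraction <=
    ``max_overlap_mismatch``. Overlap disagreements take the base with the
    higher Phred quality; ties keep R1's base. Pairs with no acceptable
    overlap are rejected (``no_overlap``), merged reads containing an
    ambiguous base are rejected (``ambiguous_base``).

    Returns (merged reads, tally dict, reject table). Tally keys:
    ``total_pairs``, ``merged``, ``no_overlap``, ``ambiguous_base``.
    """
    r1 = list(r1)
    r2 = list(r2)
    if len(r1) != len(r2):
        raise ValueError(f"R1/R2 record counts differ: {len(r1)} vs {len(r2)}")
    for (id1, _, _), (id2, _, _) in zip(r1, r2):
        if _strip_mate(id1) != _strip_mate(id2):
            raise ValueError(f"R1/R2 out of sync: {id1!r} vs {id2!r}")
    tally = {"total_pairs": len(r1), "merged": 0, "no_overlap": 0, "ambiguous_base": 0}
    merged: list[MergedRead] = []
    rejects: list[dict] = []
    # batch pairs by length so scoring is one vector op per candidate offset
    groups: dict[tuple[int, int], list[int]] = {}
    for i, ((_, s1, _), (_, s2, _)) in enumerate(zip(r1, r2)):
        groups.setdefault((len(s1), len(s2)), []).append(i)
    for (l1, l2), idx in groups.items():
        if min(l1, l2) < min_overlap:
            for i in idx:
                rejects.append({"read_id": _strip_mate(r1[i][0]), "reason": "no_overlap"})
                tally["no_overlap"] += 1
            continue
        a = np.stack([encode(r1[i][1]) for i in idx])
        b = np.stack([revcomp_arr(encode(r2[i][1])) for i in idx])
        qa = np.stack([encode(r1[i][2]) for i in idx])
        qb = np.stack([encode(r2[i][2])[::-1] for i in idx])
        overlaps = np.arange(min_overlap, min(l1, l2) + 1)
        n = len(idx)
        best_score = np.full(n, -np.inf)
        best_o = np.zeros(n, dtype=int)
        for o in overlaps:
            mm = (a[:, l1 - o :] != b[:, :o]).sum(axis=1)
            valid = mm <= max_overlap_mismatch * o
            score = np.where(valid, (o - mm) - 4 * mm, -np.inf)
            # ties prefer the larger overlap (shorter merged sequence)
            better = score >= best_score
            best_score = np.where(better, score, best_score)
            best_o = np.where(better, o, best_o)
        for j, i in enumerate(idx):
            rid = _strip_mate(r1[i][0])
            if not np.isfinite(best_score[j]):
                rejects.append({"read_id": rid, "reason": "no_overlap"})
                tally["no_overlap"] += 1
                continue
            o = int(best_o[j])
            left = a[j, : l1 - o]
            ov_a, ov_b = a[j, l1 - o :], b[j, :o]
            ov = np.where(qb[j, :o] > qa[j, l1 - o :], ov_b, ov_a)
            right = b[j, o:]
            seq_arr = np.concatenate([left, ov, right])
            if (seq_arr == ord("N")).any():
                rejects.append({"read_id": rid, "reason": "ambiguous_base"})
                tally["ambiguous_base"] += 1
                continue
            merged.append(MergedRead(rid, decode(seq_arr), o))
            tally["merged"] += 1
    reject_df = pd.DataFrame(rejects, columns=["read_id", "reason"])
    return merged, tally, reject_df


# ---------------------------------------------------------------------------
# Assignment


class _RefIndex:
    """Lookup structures for the 100%-identity / 90%-coverage rule."""

    def __init__(self, ref: IsvReference):
        self.exact: dict[str, list[tuple[str, str]]] = {}
        self.entries: list[tuple[str, str, str]] = []  # (amplicon, species, seq)
        for e in ref.entries.values():
            for species, seqs in (("mouse", e.mouse_sequences), ("rat", e.rat_sequences)):
                for seq in seqs:
                    self.exact.setdefault(seq, []).append((e.amplicon_id, species))
                    self.entries.append((e.amplicon_id, species, seq))


def _index(ref: IsvReference | _RefIndex) -> _RefIndex:
    return ref if isinstance(ref, _RefIndex) else _RefIndex(ref)


def assign_read(
    read: MergedRead | str,
    ref: IsvReference | _RefIndex,
    min_coverage: float = 0.9,
) -> Assignment:
    """Assign one merged read under the exact-identity rule.

    A read is assigned to (amplicon, species) iff it equals a consensus
    sequence, or a terminal (prefix/suffix) span of one, with 100% identity
    over >= ``min_coverage`` of the reference length. Reads matching
    consensus sequences of more than one amplicon — or of both species,
    impossible for a validated reference but checked — are
    ``unassigned(ambiguous)``; perfect terminal matches below the coverage
    floor are ``unassigned(low_coverage)``; everything else is
    ``unassigned(no_perfect_match)``.
    """
    idx = _index(ref)
    rid, seq = (read.read_id, read.sequence) if isinstance(read, MergedRead) else ("read", read)
    hits: set[tuple[str, str]] = set(idx.exact.get(seq, []))
    low_cov = False
    if not hits:
        L = len(seq)
        for amp, species, ref_seq in idx.entries:
            R = len(ref_seq)
            if L >= R:
                continue  # full-length handled by the exact lookup
            if ref_seq.startswith(seq) or ref_seq.endswith(seq):
                if L >= min_coverage * R:
                    hits.add((amp, species))
                else:
                    low_cov = True
    if not hits:
        reason = "low_coverage" if low_cov else "no_perfect_match"
        return Assignment(rid, None, None, reason)
    amps = {h[0] for h in hits}
    species = {h[1] for h in hits}
    if len(amps) > 1 or len(species) > 1:
        return Assignment(rid, None, None, "ambiguous")
    return Assignment(rid, amps.pop(), species.pop(), None)


def assign_reads(
    reads: Iterable[MergedRead],
    ref: IsvReference,
    min_coverage: float = 0.9,
) -> list[Assignment]:
    idx = _RefIndex(ref)
    return [assign_read(r, idx, min_coverage=min_coverage) for r in reads]


# ---------------------------------------------------------------------------
# Tabulation


@dataclass
class AmpliconCountTable:
    """Per-amplicon mouse/rat read counts for one sample, with stage tallies."""

    counts: pd.DataFrame  # index amplicon, columns mouse_count / rat_count
    tallies: dict = field(default_factory=dict)
    sample_id: str = "sample"

    def conservation_ok(self) -> bool:
        assigned = int(self.counts.to_numpy().sum())
        t = self.tallies
        return (
            assigned + t.get("unassigned", 0) == t.get("merged", assigned)
            and t.get("merged", 0) <= t.get("total_pairs", t.get("merged", 0))
        )


def tabulate(
    assignments: Iterable[Assignment],
    panel_amplicons: Sequence[str],
    sample_id: str = "sample",
    merge_tally: Mapping[str, int] | None = None,
) -> AmpliconCountTable:
    """Count assigned reads per amplicon and species; zero-filled over the panel."""
    counts = pd.DataFrame(
        0, index=list(panel_amplicons), columns=["mouse_count", "rat_count"], dtype=int
    )
    unassigned: dict[str, int] = {}
    n = 0
    for a in assignments:
        n += 1
        if a.reason is None:
            if a.amplicon not in counts.index:
                raise ValueError(f"assignment to unknown amplicon {a.amplicon!r}")
            counts.loc[a.amplicon, f"{a.species}_count"] += 1
        else:
            unassigned[a.reason] = unassigned.get(a.reason, 0) + 1
    tallies = dict(merge_tally or {})
    tallies.setdefault("merged", n)
    tallies["assigned"] = int(counts.to_numpy().sum())
    tallies["unassigned"] = sum(unassigned.values())
    tallies["unassigned_reasons"] = unassigned
    return AmpliconCountTable(counts=counts, tallies=tallies, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Ratios / correction / normalization


@dataclass
class ExpressionProfile:
    """Per-amplicon M/R ratios at each processing stage (amplicons x samples)."""

    raw: pd.DataFrame
    corrected: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    pseudocount: float = 0.0
    correction_factors: pd.Series | None = None


def compute_ratios(
    tables: AmpliconCountTable | Mapping[str, AmpliconCountTable],
    pseudocount: float = 0.0,
) -> ExpressionProfile:
    """Raw M/R ratio per amplicon: mouse count over rat spike-in count.

    With ``pseudocount`` c > 0 the ratio is (mouse + c) / (rat + c); with the
    default c = 0 an amplicon with zero rat reads gets NaN (flagged missing)
    so downstream arithmetic stays exact.
    """
    if isinstance(tables, AmpliconCountTable):
        tables = {tables.sample_id: tables}
    cols = {}
    for sid, tab in tables.items():
        m = tab.counts["mouse_count"].astype(float)
        r = tab.counts["rat_count"].astype(float)
        if pseudocount > 0:
            cols[sid] = (m + pseudocount) / (r + pseudocount)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = m / r
            cols[sid] = ratio.where(r > 0)
    return ExpressionProfile(raw=pd.DataFrame(cols), pseudocount=pseudocount)


def calibrate_bias(
    profile: ExpressionProfile,
    control: pd.Series | AmpliconCountTable | None = None,
    expected: float | pd.Series = 1.0,
) -> ExpressionProfile:
    """Remove per-amplicon efficiency bias using a known-mixture control.

    The control sample's observed raw ratio divided by its expected ratio
    (default 1.0, an equimolar mixture) is the per-amplicon correction
    factor; sample ratios are divided by it. Without a control the stage is
    the identity. Amplicons missing from the control get factor 1 with a
    warning.
    """
    if control is None:
        profile.corrected = profile.raw.copy()
        profile.correction_factors = pd.Series(1.0, index=profile.raw.index)
        return profile
    if isinstance(control, AmpliconCountTable):
        control = compute_ratios(control, pseudocount=profile.pseudocount).raw.iloc[:, 0]
    factors = (control / expected).reindex(profile.raw.index)
    missing = factors.index[factors.isna()]
    if len(missing):
        logger.warning(
            "calibrate_bias: %d amplicon(s) missing from control, identity factor",
            len(missing),
        )
        factors = factors.fillna(1.0)
    profile.corrected = profile.raw.div(factors, axis=0)
    profile.correction_factors = factors
    return profile


def normalize(profile: ExpressionProfile) -> ExpressionProfile:
    """Divide each sample's corrected ratios by their mean over amplicons.

    After normalization the mean relative abundance (RA) over non-missing
    amplicons is exactly 1 in every sample. Samples with fewer than two
    non-missing amplicons are rejected.
    """
    base = profile.corrected if profile.corrected is not None else profile.raw
    n_ok = base.notna().sum(axis=0)
    bad = n_ok.index[n_ok < 2]
    if len(bad):
        raise ValueError(f"samples with < 2 non-missing amplicons: {list(bad)}")
    profile.normalized = base.div(base.mean(axis=0, skipna=True), axis=1)
    return profile


def tables_from_study(samples) -> dict[str, AmpliconCountTable]:
    """Wrap simulated per-sample counts as count tables (skipping the read layer)."""
    return {
        s.sample_id: AmpliconCountTable(
            counts=pd.DataFrame(
                {"mouse_count": s.mouse_counts, "rat_count": s.rat_counts}
            ),
            sample_id=s.sample_id,
        )
        for s in samples
    }


def quantify_sample(
    r1: Iterable[tuple[str, str, str]],
    r2: Iterable[tuple[str, str, str]],
    ref: IsvReference,
    sample_id: str = "sample",
    min_overlap: int = 20,
    max_overlap_mismatch: float = 0.1,
    min_coverage: float = 0.9,
) -> AmpliconCountTable:
    """Convenience: merge, assign and tabulate one sample's read pairs."""
    merged, tally, _ = merge_pairs(
        r1, r2, min_overlap=min_overlap, max_overlap_mismatch=max_overlap_mismatch
    )
    assignments = assign_reads(merged, ref, min_coverage=min_coverage)
    return tabulate(
        assignments,
        panel_amplicons=list(ref.entries),
        sample_id=sample_id,
        merge_tally=tally,
    )
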