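"""Synthetic-data generators for the full pipeline.

Every generator is a pure function of its spec and seed, and returns a
machine-readable truth record alongside the simulated data, so downstream
operations can be scored by parameter recovery without any external data.

Four generators are provided:

* :func:`make_ortholog_panel` — homologous mouse/rat amplicon pairs that
  differ at a controlled number of inter-species variant (ISV) positions.
* :func:`simulate_amplicon_reads` — paired-end reads from a competitive
  mouse-cDNA / rat-genome pool at planted per-amplicon mixing ratios, with
  independent per-base substitution errors.
* :func:`generate_study` — a 2x2 genotype-by-age study with per-category
  planted fold changes; mouse counts are negative-binomial around
  baseline x effect, rat spike-in counts are independent of expression.
* :func:`simulate_dhs_fragments` — DNase-digestion fragment intervals around
  TSSs with a planted minority high-signal cluster and per-cluster group
  fold effects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from epidrift.seqio import BASES, decode, encode, revcomp_arr, write_fasta, write_fastq

#: Functional categories used for the default panel, matching the epi-driver
#: vocabulary: senescence, histone acetylation, lysine (de)methylation,
#: arginine methylation, DNA methylation, Polycomb complex and its targets.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "Aging",
    "Acet",
    "K-meth",
    "K-demeth",
    "Arg_meth",
    "DNA_meth",
    "PRC",
    "PRG",
)

#: Default planted aged-vs-young log2 fold changes per genotype. Signs follow
#: the study's summary of category-level changes: acetylation down with age in
#: both genotypes; lysine-(de)methylation up in aged HD but down in aged wt;
#: Polycomb-complex genes down and their targets (PRG) strongly up in aged HD,
#: weakly in wt; maintenance DNA methylation down in aged HD; senescence
#: markers up in both genotypes.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "HD": {
        "Aging": 2.0,
        "Acet": -1.0,
        "K-meth": 1.0,
        "K-demeth": 1.0,
        "Arg_meth": 1.0,
        "DNA_meth": -1.0,
        "PRC": -1.0,
        "PRG": 3.0,
    },
    "wt": {
        "Aging": 2.0,
        "Acet": -1.0,
        "K-meth": -0.5,
        "K-demeth": -0.5,
        "Arg_meth": 0.0,
        "DNA_meth": 0.0,
        "PRC": -0.5,
        "PRG": 1.0,
    },
}


@dataclass(frozen=True)
class AmpliconDefinition:
    """One panel amplicon: co-aligned mouse and rat sequences plus metadata."""

    amplicon_id: str
    gene: str
    category: str
    mouse_seq: str
    rat_seq: str
    isv_positions: tuple[int, ...]


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Parameters of a synthetic ortholog amplicon panel.

    ``n_isv_per_amplicon`` is the exact Hamming distance planted between the
    mouse and rat sequence of every amplicon (0 makes them identical, which
    the reference builder must later discard). Categories are assigned
    round-robin so every study category is represented.
    """

    n_amplicons: int
    amplicon_length: int = 150
    n_isv_per_amplicon: int = 2
    gc_fraction: float = 0.5
    seed: int = 0
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if self.n_amplicons < 1:
            raise ValueError("n_amplicons must be >= 1")
        if not 0 <= self.n_isv_per_amplicon <= self.amplicon_length:
            raise ValueError(
                f"n_isv_per_amplicon must lie in [0, {self.amplicon_length}]"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


class Truth:
    """Base for truth records: serializable echo of what was planted."""

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="index")
            if isinstance(v, pd.Series):
                return v.to_dict()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            if isinstance(v, tuple):
                return list(v)
            return v

        return {
            f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


@dataclass
class PanelTruth(Truth):
    spec: dict
    isv_positions: dict[str, list[int]]
    categories: dict[str, str]


@dataclass
class ReadSimTruth(Truth):
    mouse_count: dict[str, int]
    rat_count: dict[str, int]
    mouse_fraction: dict[str, float]
    params: dict


@dataclass
class StudyTruth(Truth):
    mouse_counts: pd.DataFrame  # sample x amplicon realized mouse read counts
    rat_counts: pd.DataFrame
    expected_expression: pd.DataFrame  # sample x amplicon NB mean
    planted_log2fc: dict[str, dict[str, float]]
    params: dict


@dataclass
class DhsTruth(Truth):
    cluster: pd.Series  # per-TSS: 1 = high-signal cluster, 2 = low
    group_fold: pd.Series  # per-TSS planted HD/wt fold
    counts: pd.DataFrame  # TSS x group realized fragment counts
    params: dict


# ---------------------------------------------------------------------------
# Panel


def make_ortholog_panel(
    spec: SyntheticPanelSpec,
) -> tuple[list[AmpliconDefinition], PanelTruth]:
    """Generate a panel of mouse/rat ortholog amplicon pairs.

    Each pair differs at exactly ``spec.n_isv_per_amplicon`` positions; the
    planted positions are recorded in the truth. Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    panel: list[AmpliconDefinition] = []
    isv_rec: dict[str, list[int]] = {}
    cat_rec: dict[str, str] = {}
    for i in range(spec.n_amplicons):
        gene = f"G{i + 1:04d}"
        amp_id = f"{gene}_1"
        category = spec.categories[i % len(spec.categories)]
        idx = rng.choice(4, size=spec.amplicon_length, p=probs)
        mouse = BASES[idx]
        rat = mouse.copy()
        pos = np.sort(
            rng.choice(spec.amplicon_length, size=spec.n_isv_per_amplicon, replace=False)
        )
        # substitute a uniformly chosen different base at each ISV position
        shift = rng.integers(1, 4, size=spec.n_isv_per_amplicon)
        rat[pos] = BASES[(idx[pos] + shift) % 4]
        panel.append(
            AmpliconDefinition(
                amplicon_id=amp_id,
                gene=gene,
                category=category,
                mouse_seq=decode(mouse),
                rat_seq=decode(rat),
                isv_positions=tuple(int(p) for p in pos),
            )
        )
        isv_rec[amp_id] = [int(p) for p in pos]
        cat_rec[amp_id] = category
    truth = PanelTruth(
        spec=dataclasses.asdict(spec) | {"categories": list(spec.categories)},
        isv_positions=isv_rec,
        categories=cat_rec,
    )
    return panel, truth


def write_panel_fasta(panel: Sequence[AmpliconDefinition], path: str | Path) -> None:
    """Write the panel with ``ampliconID|species|gene|category`` headers."""
    records = []
    for amp in panel:
        records.append((f"{amp.amplicon_id}|mouse|{amp.gene}|{amp.category}", amp.mouse_seq))
        records.append((f"{amp.amplicon_id}|rat|{amp.gene}|{amp.category}", amp.rat_seq))
    write_fasta(path, records)


def read_panel_fasta(path: str | Path) -> list[AmpliconDefinition]:
    from epidrift.seqio import read_fasta, mismatch_positions

    by_amp: dict[str, dict] = {}
    for rid, seq in read_fasta(path):
        amp_id, species, gene, category = rid.split("|")
        entry = by_amp.setdefault(amp_id, {"gene": gene, "category": category})
        entry[species] = seq
    panel = []
    for amp_id, entry in by_amp.items():
        if "mouse" not in entry or "rat" not in entry:
            raise ValueError(f"panel FASTA missing one species for {amp_id}")
        panel.append(
            AmpliconDefinition(
                amplicon_id=amp_id,
                gene=entry["gene"],
                category=entry["category"],
                mouse_seq=entry["mouse"],
                rat_seq=entry["rat"],
                isv_positions=mismatch_positions(entry["mouse"], entry["rat"]),
            )
        )
    return panel


# ---------------------------------------------------------------------------
# Reads


def _mutate(arr2d: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply independent per-base substitutions to a (reads x length) array."""
    if rate <= 0:
        return arr2d
    mask = rng.random(arr2d.shape) < rate
    n = int(mask.sum())
    if n == 0:
        return arr2d
    # map ASCII -> 0..3, shift by 1..3, map back: always a different base
    lut = np.zeros(256, dtype=np.uint8)
    lut[BASES] = np.arange(4)
    idx = lut[arr2d[mask]]
    arr2d[mask] = BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr2d


def _inject_n(arr2d: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr2d
    mask = rng.random(arr2d.shape) < rate
    arr2d[mask] = ord("N")
    return arr2d


def simulate_amplicon_reads(
    panel: Sequence[AmpliconDefinition],
    mouse_fraction: float | Mapping[str, float],
    depth: int | Mapping[str, int],
    substitution_error_rate: float = 0.001,
    read_length: int = 100,
    seed: int = 0,
    n_rate: float = 0.0,
    quality_char: str = "I",
    min_overlap: int = 40,
    exact_counts: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], ReadSimTruth]:
    """Simulate paired-end reads from a competitive mouse/rat amplicon pool.

    Per amplicon, the number of mouse-origin read pairs is drawn
    Binomial(depth, mouse_fraction) unless ``exact_counts`` pins
    (mouse, rat) counts directly. R1 is the amplicon prefix, R2 the
    reverse-complement of the suffix; substitution errors are applied
    independently to the two mates. Returns (R1 records, R2 records, truth)
    where records are (id, sequence, quality) triples.
    """
    if not 0.0 <= substitution_error_rate <= 0.05:
        raise ValueError("substitution_error_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    r1_out: list[tuple[str, str, str]] = []
    r2_out: list[tuple[str, str, str]] = []
    m_count: dict[str, int] = {}
    r_count: dict[str, int] = {}
    frac_rec: dict[str, float] = {}
    qual = quality_char * read_length
    serial = 0
    for amp in panel:
        amp_len = len(amp.mouse_seq)
        if 2 * read_length - amp_len < min_overlap:
            raise ValueError(
                f"{amp.amplicon_id}: reads of length {read_length} overlap by "
                f"{2 * read_length - amp_len} < min_overlap={min_overlap}"
            )
        if exact_counts is not None:
            n_mouse, n_rat = exact_counts[amp.amplicon_id]
            d = n_mouse + n_rat
            frac = n_mouse / d if d else float("nan")
        else:
            d = depth[amp.amplicon_id] if isinstance(depth, Mapping) else int(depth)
            frac = (
                mouse_fraction[amp.amplicon_id]
                if isinstance(mouse_fraction, Mapping)
                else float(mouse_fraction)
            )
            n_mouse = int(rng.binomial(d, frac)) if d else 0
            n_rat = d - n_mouse
        m_count[amp.amplicon_id] = n_mouse
        r_count[amp.amplicon_id] = n_rat
        frac_rec[amp.amplicon_id] = frac
        for species, n in (("mouse", n_mouse), ("rat", n_rat)):
            if n == 0:
                continue
            template = encode(amp.mouse_seq if species == "mouse" else amp.rat_seq)
            r1 = np.tile(template[:read_length], (n, 1))
            r2 = np.tile(revcomp_arr(template[amp_len - read_length :]), (n, 1))
            _mutate(r1, substitution_error_rate, rng)
            _mutate(r2, substitution_error_rate, rng)
            _inject_n(r1, n_rate, rng)
            _inject_n(r2, n_rate, rng)
            for j in range(n):
                rid = f"sim_{serial}|{amp.amplicon_id}|{species}"
                r1_out.append((rid, decode(r1[j]), qual))
                r2_out.append((rid, decode(r2[j]), qual))
                serial += 1
    truth = ReadSimTruth(
        mouse_count=m_count,
        rat_count=r_count,
        mouse_fraction=frac_rec,
        params={
            "substitution_error_rate": substitution_error_rate,
            "read_length": read_length,
            "seed": seed,
            "n_rate": n_rate,
        },
    )
    return r1_out, r2_out, truth


# ---------------------------------------------------------------------------
# Study


@dataclass(frozen=True)
class StudyDesign:
    """A 2x2 genotype-by-age design with planted per-category age effects.

    ``category_log2fc[genotype][category]`` is the planted aged-vs-young
    log2 fold change of mouse expression for amplicons of that category.
    Mouse counts are negative-binomial with mean ``baseline_depth x 2^lfc``
    (aged) or ``baseline_depth`` (young) and dispersion ``dispersion``
    (variance = m + dispersion * m^2). Rat spike-in counts are Poisson with a
    constant mean set by ``spike_in_fraction``, independent of expression —
    a fixed genomic competitor.
    """

    genotypes: tuple[str, ...] = ("wt", "HD")
    ages: tuple[str, ...] = ("young", "aged")
    replicates: int = 4
    category_log2fc: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_EFFECTS
    )
    baseline_depth: float = 2000.0
    spike_in_fraction: float = 0.5
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for any statistical test")
        if not 0.0 < self.spike_in_fraction < 1.0:
            raise ValueError("spike_in_fraction must lie in (0, 1)")
        for g, eff in self.category_log2fc.items():
            for c, v in eff.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite planted log2FC for {g}/{c}")


@dataclass
class SampleSim:
    sample_id: str
    genotype: str
    age: str
    mouse_counts: pd.Series
    rat_counts: pd.Series


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def generate_study(
    design: StudyDesign,
    panel: Sequence[AmpliconDefinition],
    seed: int = 0,
    baseline: Mapping[str, float] | None = None,
) -> tuple[list[SampleSim], pd.DataFrame, StudyTruth]:
    """Draw per-sample per-amplicon mouse and rat spike-in read counts.

    Returns (samples, sample sheet, truth). FASTQ materialization is a
    separate step (:func:`study_to_fastq`) so count-level analyses can skip
    the read layer entirely.
    """
    known = {c for eff in design.category_log2fc.values() for c in eff}
    for amp in panel:
        if amp.category not in known:
            raise ValueError(f"panel category not in design: {amp.category!r}")
    for g in design.genotypes:
        if g not in design.category_log2fc:
            raise ValueError(f"design lacks planted effects for genotype {g!r}")
    rng = np.random.default_rng(seed)
    amp_ids = [a.amplicon_id for a in panel]
    base = np.array(
        [
            (baseline[a] if baseline is not None else design.baseline_depth)
            for a in amp_ids
        ],
        dtype=float,
    )
    cats = [a.category for a in panel]
    s = design.spike_in_fraction
    rat_mean = design.baseline_depth * s / (1.0 - s)
    samples: list[SampleSim] = []
    sheet_rows = []
    mouse_rows, rat_rows, mean_rows, index = [], [], [], []
    for genotype in design.genotypes:
        eff = design.category_log2fc[genotype]
        for age in design.ages:
            fold = np.array(
                [2.0 ** eff[c] if age == "aged" else 1.0 for c in cats]
            )
            for rep in range(1, design.replicates + 1):
                sid = f"{genotype}_{age}_{rep}"
                mean = base * fold
                mouse = _nb_draw(rng, mean, design.dispersion)
                rat = rng.poisson(rat_mean, size=len(amp_ids))
                samples.append(
                    SampleSim(
                        sample_id=sid,
                        genotype=genotype,
                        age=age,
                        mouse_counts=pd.Series(mouse, index=amp_ids),
                        rat_counts=pd.Series(rat, index=amp_ids),
                    )
                )
                sheet_rows.append(
                    {"sample_id": sid, "genotype": genotype, "age": age}
                )
                index.append(sid)
                mouse_rows.append(mouse)
                rat_rows.append(rat)
                mean_rows.append(mean)
    truth = StudyTruth(
        mouse_counts=pd.DataFrame(mouse_rows, index=index, columns=amp_ids),
        rat_counts=pd.DataFrame(rat_rows, index=index, columns=amp_ids),
        expected_expression=pd.DataFrame(mean_rows, index=index, columns=amp_ids),
        planted_log2fc={g: dict(e) for g, e in design.category_log2fc.items()},
        params={
            "seed": seed,
            "baseline_depth": design.baseline_depth,
            "spike_in_fraction": design.spike_in_fraction,
            "dispersion": design.dispersion,
            "replicates": design.replicates,
        },
    )
    sheet = pd.DataFrame(sheet_rows)
    return samples, sheet, truth


def study_to_fastq(
    samples: Sequence[SampleSim],
    panel: Sequence[AmpliconDefinition],
    out_dir: str | Path,
    substitution_error_rate: float = 0.001,
    read_length: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Materialize a study as per-sample paired FASTQ files.

    Read pair counts equal the realized counts in each sample exactly.
    Returns the sample sheet extended with fastq paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, smp in enumerate(samples):
        exact = {
            a.amplicon_id: (
                int(smp.mouse_counts[a.amplicon_id]),
                int(smp.rat_counts[a.amplicon_id]),
            )
            for a in panel
        }
        r1, r2, _ = simulate_amplicon_reads(
            panel,
            mouse_fraction=0.0,
            depth=0,
            substitution_error_rate=substitution_error_rate,
            read_length=read_length,
            seed=seed + i,
            exact_counts=exact,
        )
        p1 = out_dir / f"{smp.sample_id}_R1.fastq"
        p2 = out_dir / f"{smp.sample_id}_R2.fastq"
        write_fastq(p1, r1)
        write_fastq(p2, r2)
        rows.append(
            {
                "sample_id": smp.sample_id,
                "genotype": smp.genotype,
                "age": smp.age,
                "fastq_r1": str(p1),
                "fastq_r2": str(p2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DHS fragments


@dataclass(frozen=True)
class DhsSimSpec:
    """Parameters of the DNase-fragment simulation.

    A minority of TSSs (``high_cluster_fraction``) carry dense accessibility
    signal; the rest are shallow. Per-cluster HD-vs-wt fold effects default to
    the contrasts used throughout the accessibility analysis (high cluster
    slightly depleted in HD, low cluster enriched). Fragment midpoints follow
    a truncated Gaussian around the TSS.
    """

    n_tss: int = 2000
    high_cluster_fraction: float = 0.136
    mean_high: float = 400.0
    mean_low: float = 40.0
    fold_high: float = 0.704
    fold_low: float = 1.287
    frag_len_min: int = 50
    frag_len_max: int = 100
    profile_sd: float = 300.0
    flank: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.high_cluster_fraction < 1.0:
            raise ValueError("high_cluster_fraction must lie in (0, 1)")
        if self.fold_high <= 0 or self.fold_low <= 0:
            raise ValueError("fold effects must be > 0")
        if not 0 < self.frag_len_min <= self.frag_len_max:
            raise ValueError("invalid fragment length range")


def make_tss_annotation(
    n_tss: int, spacing: int = 10_000, seed: int = 0, chrom: str = "chrS"
) -> pd.DataFrame:
    """Synthetic BED6 TSS annotation: evenly spaced genes, random strands.

    Spacing well above 2x the window flank keeps windows disjoint.
    """
    rng = np.random.default_rng(seed)
    start = spacing + spacing * np.arange(n_tss)
    strand = np.where(rng.random(n_tss) < 0.5, "+", "-")
    # gene body of 2 kb; TSS = start on '+', end-1 on '-'
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + 2000,
            "name": [f"T{i + 1:05d}" for i in range(n_tss)],
            "score": 0,
            "strand": strand,
        }
    )


def _truncated_normal_int(
    rng: np.random.Generator, n: int, sd: float, bound: int
) -> np.ndarray:
    """Integer offsets ~ N(0, sd) truncated to [-bound, bound], by rejection."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(0.0, sd, size=max(n - filled, 16))
        draw = draw[np.abs(draw) <= bound]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = np.rint(draw[:take]).astype(np.int64)
        filled += take
    return out


def simulate_dhs_fragments(
    spec: DhsSimSpec,
    tss_annotation: pd.DataFrame,
    bernoulli_assignment: bool = False,
) -> tuple[dict[str, pd.DataFrame], DhsTruth]:
    """Simulate DNase fragment BED intervals for an HD and a wt group.

    The first ``ceil(fraction * n)`` TSSs form the high-signal cluster
    (deterministic by default so cluster sizes are exact; Bernoulli
    assignment is available). Per-TSS fragment counts are Poisson with mean
    ``cluster_mean`` (wt) or ``cluster_mean x fold`` (HD); every fragment
    midpoint lands inside the +/-flank window, so window totals match the
    truth exactly. Returns ({"HD": bed, "wt": bed}, truth) with BED sorted,
    0-based half-open.
    """
    if tss_annotation is None or len(tss_annotation) == 0:
        raise ValueError("empty TSS annotation")
    tss_df = tss_annotation.reset_index(drop=True)
    n = len(tss_df)
    rng = np.random.default_rng(spec.seed)
    if bernoulli_assignment:
        high = rng.random(n) < spec.high_cluster_fraction
    else:
        n_high = int(np.ceil(spec.high_cluster_fraction * n))
        high = np.zeros(n, dtype=bool)
        high[:n_high] = True
    mean = np.where(high, spec.mean_high, spec.mean_low)
    fold = np.where(high, spec.fold_high, spec.fold_low)
    tss_pos = np.where(
        tss_df["strand"].to_numpy() == "+",
        tss_df["start"].to_numpy(),
        tss_df["end"].to_numpy() - 1,
    )
    names = tss_df["name"].tolist()
    beds: dict[str, pd.DataFrame] = {}
    counts = {}
    # midpoint must stay in [tss-flank, tss+flank) for both strands
    bound = spec.flank - 1
    for group, group_mean in (("wt", mean), ("HD", mean * fold)):
        per_tss = rng.poisson(group_mean)
        counts[group] = per_tss
        total = int(per_tss.sum())
        mid = np.repeat(tss_pos, per_tss) + _truncated_normal_int(
            rng, total, spec.profile_sd, bound
        )
        length = rng.integers(spec.frag_len_min, spec.frag_len_max + 1, size=total)
        start = mid - length // 2
        end = start + length
        chrom = np.repeat(tss_df["chrom"].to_numpy(), per_tss)
        bed = pd.DataFrame(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": [f"{group}_f{i}" for i in range(total)],
                "score": 0,
                "strand": ".",
            }
        ).sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)
        beds[group] = bed
    truth = DhsTruth(
        cluster=pd.Series(np.where(high, 1, 2), index=names),
        group_fold=pd.Series(fold, index=names),
        counts=pd.DataFrame(
            {"HD": counts["HD"], "wt": counts["wt"]}, index=names
        ),
        params=dataclasses.asdict(spec),
    )
    return beds, truth


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df
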