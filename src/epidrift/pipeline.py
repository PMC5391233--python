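"""End-to-end orchestration: simulate -> reference -> quant -> stats; dhs.

Stage outputs are plain files under the configured output directory so any
stage can be rerun or inspected independently; a JSON manifest with
parameters, per-stage tallies and output checksums is written even when a
stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from pathlib import Path

import pandas as pd

from epidrift import (
    DhsSimSpec,
    StudyDesign,
    SyntheticPanelSpec,
    build_isv_ref,
    build_temp_ref,
    calibrate_bias,
    category_summary,
    classify_differential,
    cluster_contrast,
    cluster_tss,
    compute_ratios,
    correlation_heatmap,
    count_windows,
    detect_dets,
    geneset_accessibility,
    load_tss,
    make_ortholog_panel,
    make_tss_annotation,
    match_reads_to_temp_ref,
    merge_pairs,
    normalize,
    normalize_depth,
    pca_qc,
    simulate_amplicon_reads,
    simulate_dhs_fragments,
)
from epidrift.config import RunConfig
from epidrift.quant import assign_reads, tabulate
from epidrift.reference import IsvReference, call_consensus_set
from epidrift.simulate import generate_study, study_to_fastq, write_bed, write_panel_fasta, read_panel_fasta
from epidrift.seqio import read_fastq, write_fastq

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(config.__dict__, default=str)),
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    state: dict = {}
    try:
        for stage in [s for s in ("panel", "calibration", "reference", "study", "quant", "stats", "dhs") if s in config.stages]:
            try:
                _STAGES[stage](config, out, state, manifest)
            except Exception as exc:  # halt, but keep the manifest
                manifest["status"] = "failed"
                manifest["error"] = {
                    "stage": stage,
                    "message": str(exc),
                    "traceback": traceback.format_exc(),
                }
                raise StageError(stage, exc) from exc
        manifest["status"] = "ok"
    finally:
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_panel(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    spec = SyntheticPanelSpec(
        n_amplicons=cfg.n_amplicons,
        amplicon_length=cfg.amplicon_length,
        n_isv_per_amplicon=cfg.n_isv_per_amplicon,
        gc_fraction=cfg.gc_fraction,
        seed=cfg.seed,
    )
    panel, truth = make_ortholog_panel(spec)
    write_panel_fasta(panel, out / "panel.fasta")
    truth.save(out / "panel_truth.json")
    state["panel"] = panel
    manifest["stages"]["panel"] = {"n_amplicons": len(panel)}


def _stage_calibration(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    panel = state.get("panel") or read_panel_fasta(out / "panel.fasta")
    state.setdefault("panel", panel)
    for species, frac, sub in (("mouse", 1.0, 1), ("rat", 0.0, 2)):
        r1, r2, _ = simulate_amplicon_reads(
            panel,
            mouse_fraction=frac,
            depth=cfg.calibration_depth,
            substitution_error_rate=cfg.substitution_error_rate,
            read_length=cfg.read_length,
            seed=cfg.seed + sub,
        )
        write_fastq(out / f"calibration_{species}_R1.fastq", r1)
        write_fastq(out / f"calibration_{species}_R2.fastq", r2)
    manifest["stages"]["calibration"] = {
        "depth_per_amplicon": cfg.calibration_depth,
        "error_rate": cfg.substitution_error_rate,
    }


def _stage_reference(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    panel = state.get("panel") or read_panel_fasta(out / "panel.fasta")
    temp_ref = build_temp_ref(panel)
    consensus = {}
    tallies = {}
    for species in ("mouse", "rat"):
        r1 = list(read_fastq(out / f"calibration_{species}_R1.fastq"))
        r2 = list(read_fastq(out / f"calibration_{species}_R2.fastq"))
        merged, tally, _ = merge_pairs(
            r1, r2, min_overlap=cfg.min_overlap, max_overlap_mismatch=cfg.max_overlap_mismatch
        )
        pileups, aside = match_reads_to_temp_ref(
            [(m.read_id, m.sequence) for m in merged], temp_ref, min_identity=cfg.min_identity
        )
        consensus[species] = call_consensus_set(
            pileups, threshold=cfg.consensus_threshold, min_reads=cfg.min_pileup_reads
        )
        tallies[species] = tally | {"set_aside": len(aside)}
    ref = build_isv_ref(consensus["mouse"], consensus["rat"])
    ref.write(out / "isv_ref.fasta", out / "isv_ref.tsv")
    state["ref"] = ref
    manifest["stages"]["reference"] = {
        "retained": len(ref),
        "discarded": len(ref.discarded),
        "tallies": tallies,
    }


def _stage_study(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    panel = state.get("panel") or read_panel_fasta(out / "panel.fasta")
    design = StudyDesign(
        replicates=cfg.replicates,
        baseline_depth=cfg.baseline_depth,
        spike_in_fraction=cfg.spike_in_fraction,
        dispersion=cfg.dispersion,
    )
    samples, sheet, truth = generate_study(design, panel, seed=cfg.seed + 10)
    sheet = study_to_fastq(
        samples,
        panel,
        out / "reads",
        substitution_error_rate=cfg.substitution_error_rate,
        read_length=cfg.read_length,
        seed=cfg.seed + 20,
    )
    # paths stored relative to the run directory so runs are relocatable and
    # byte-identical under the same seed regardless of where they execute
    sheet["fastq_r1"] = [str(Path(p).relative_to(out)) for p in sheet["fastq_r1"]]
    sheet["fastq_r2"] = [str(Path(p).relative_to(out)) for p in sheet["fastq_r2"]]
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth.save(out / "study_truth.json")
    state["sheet"] = sheet
    manifest["stages"]["study"] = {
        "n_samples": len(sheet),
        "replicates": cfg.replicates,
    }


def _stage_quant(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    ref = state.get("ref")
    if ref is None:
        fasta = cfg.reference_fasta or out / "isv_ref.fasta"
        tsv = cfg.reference_tsv or out / "isv_ref.tsv"
        ref = IsvReference.from_files(fasta, tsv)
    sheet = state.get("sheet")
    if sheet is None:
        sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    tables = {}
    run_log = {}
    count_rows = []
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        p1, p2 = Path(row["fastq_r1"]), Path(row["fastq_r2"])
        r1 = list(read_fastq(p1 if p1.is_absolute() else out / p1))
        r2 = list(read_fastq(p2 if p2.is_absolute() else out / p2))
        merged, tally, _ = merge_pairs(
            r1, r2, min_overlap=cfg.min_overlap, max_overlap_mismatch=cfg.max_overlap_mismatch
        )
        assignments = assign_reads(merged, ref, min_coverage=cfg.min_coverage)
        table = tabulate(assignments, list(ref.entries), sample_id=sid, merge_tally=tally)
        tables[sid] = table
        total = tally["total_pairs"]
        run_log[sid] = table.tallies | {
            "exact_mapping_rate_of_raw": table.tallies["assigned"] / total if total else 0.0,
            "exact_mapping_rate_of_merged": (
                table.tallies["assigned"] / table.tallies["merged"]
                if table.tallies["merged"]
                else 0.0
            ),
        }
        for amp, r in table.counts.iterrows():
            count_rows.append(
                {"sample_id": sid, "amplicon": amp, "mouse_count": r["mouse_count"], "rat_count": r["rat_count"]}
            )
    pd.DataFrame(count_rows).to_csv(out / "counts.tsv", sep="\t", index=False)
    profile = compute_ratios(tables, pseudocount=cfg.pseudocount)
    profile = calibrate_bias(profile, control=None)
    profile = normalize(profile)
    profile.normalized.rename_axis("amplicon").to_csv(out / "expression_matrix.tsv", sep="\t")
    (out / "quant_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True, default=int))
    state["profile"] = profile
    manifest["stages"]["quant"] = {"n_samples": len(tables)}


def _stage_stats(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    profile = state.get("profile")
    if profile is None:
        raise ValueError("stats stage requires the quant stage in the same run")
    sheet = state["sheet"]
    matrix = profile.normalized
    panel = state.get("panel") or read_panel_fasta(out / "panel.fasta")
    categories = {a.amplicon_id: a.category for a in panel}
    categories = {k: v for k, v in categories.items() if k in matrix.index}
    meta = sheet[["sample_id", "genotype", "age"]]
    young_hd = meta[(meta.age == "young") & (meta.genotype == "HD")]["sample_id"].tolist()
    aged_hd = meta[(meta.age == "aged") & (meta.genotype == "HD")]["sample_id"].tolist()
    dets = detect_dets(
        matrix,
        young_hd,
        aged_hd,
        fc_threshold=cfg.fc_threshold,
        fdr_threshold=cfg.fdr_threshold,
        category_map=categories,
        log_pseudo=cfg.log_pseudo,
    )
    dets.to_csv(out / "dets.tsv", sep="\t")
    summary = category_summary(matrix, meta, categories, log_pseudo=cfg.log_pseudo)
    summary.table.to_csv(out / "category_summary.tsv", sep="\t", index=False)
    prg = [a for a, c in categories.items() if c == "PRG"]
    if prg:
        from epidrift import prg_contrast

        prg_contrast(matrix, meta, prg, log_pseudo=cfg.log_pseudo).to_csv(
            out / "prg_contrast.tsv", sep="\t", index=False
        )
    coords, evr = pca_qc(matrix, log_pseudo=cfg.log_pseudo)
    coords.assign(explained_var_pc1=evr[0], explained_var_pc2=evr[1]).to_csv(
        out / "pca.tsv", sep="\t"
    )
    corr, corr_summary = correlation_heatmap(
        matrix, groups=dict(zip(meta.sample_id, meta.genotype + "_" + meta.age))
    )
    corr.to_csv(out / "correlation.tsv", sep="\t")
    from epidrift import bipartition_and_enrichment

    bip = bipartition_and_enrichment(
        matrix, aged_hd, categories, seed=cfg.seed, log_pseudo=cfg.log_pseudo
    )
    bip.labels.rename("cluster").rename_axis("amplicon").to_csv(out / "bipartition.tsv", sep="\t")
    manifest["stages"]["stats"] = {
        "n_dets": int(dets["passes"].sum()),
        "n_tested": int(dets["p"].notna().sum()),
    }


def _stage_dhs(cfg: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    tss_bed = make_tss_annotation(cfg.n_tss, seed=cfg.seed + 30)
    write_bed(tss_bed, out / "tss.bed")
    spec = DhsSimSpec(
        n_tss=cfg.n_tss,
        high_cluster_fraction=cfg.high_cluster_fraction,
        mean_high=cfg.dhs_mean_high,
        mean_low=cfg.dhs_mean_low,
        fold_high=cfg.dhs_fold_high,
        fold_low=cfg.dhs_fold_low,
        flank=cfg.flank,
        seed=cfg.seed + 31,
    )
    beds, truth = simulate_dhs_fragments(spec, tss_bed)
    for group, bed in beds.items():
        write_bed(bed, out / f"dhs_{group}.bed")
    truth.save(out / "dhs_truth.json")
    tss = load_tss(tss_bed)
    hd = count_windows(beds["HD"], tss, flank=cfg.flank, bin_size=cfg.bin_size, group="HD")
    wt = count_windows(beds["wt"], tss, flank=cfg.flank, bin_size=cfg.bin_size, group="wt")
    hd_n, wt_n = normalize_depth(hd, wt)
    diff = classify_differential(hd_n, wt_n)
    diff.rename_axis("gene").to_csv(out / "dhs_differential.tsv", sep="\t")
    result = cluster_tss(hd, wt, k=cfg.dhs_k, seed=cfg.seed)
    result.labels.rename("cluster").rename_axis("gene").to_csv(out / "dhs_clusters.tsv", sep="\t")
    contrast = cluster_contrast(result, hd, wt, core_flank=cfg.core_flank)
    contrast.to_csv(out / "dhs_contrast.tsv", sep="\t", index=False)
    genes = truth.cluster.index[: min(16, len(truth.cluster))].tolist()
    table, prop, misses = geneset_accessibility(result, hd, wt, genes, core_flank=cfg.core_flank)
    table.to_csv(out / "dhs_geneset.tsv", sep="\t", index=False)
    manifest["stages"]["dhs"] = {
        "n_tss": len(tss),
        "cluster_sizes": {str(k): int(v) for k, v in result.sizes.items()},
        "labels": diff["label"].value_counts().to_dict(),
        "geneset_hd_high_proportion": prop,
        "fragment_tallies": {"HD": hd.tallies, "wt": wt.tallies},
    }


_STAGES = {
    "panel": _stage_panel,
    "calibration": _stage_calibration,
    "reference": _stage_reference,
    "study": _stage_study,
    "quant": _stage_quant,
    "stats": _stage_stats,
    "dhs": _stage_dhs,
}
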