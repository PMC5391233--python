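"""Run configuration: a YAML-round-trippable record of every stage parameter."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import epidrift

ALL_STAGES = ("panel", "calibration", "reference", "study", "quant", "stats", "dhs")


@dataclass
class RunConfig:
    """All parameters of an end-to-end run, with documented defaults.

    ``stages`` selects which stages execute (dependency order is enforced by
    the pipeline). Paths for externally supplied inputs are optional; the
    simulate stages generate them when absent.
    """

    out_dir: str = "epidrift_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    version: str = epidrift.__version__

    # synthetic panel
    n_amplicons: int = 48
    amplicon_length: int = 150
    n_isv_per_amplicon: int = 2
    gc_fraction: float = 0.5

    # reads / calibration
    read_length: int = 100
    substitution_error_rate: float = 0.001
    calibration_depth: int = 50

    # study
    replicates: int = 4
    baseline_depth: float = 2000.0
    spike_in_fraction: float = 0.5
    dispersion: float = 0.05

    # reference building
    consensus_threshold: float = 0.25
    min_pileup_reads: int = 10
    min_identity: float = 0.9

    # quantification
    min_overlap: int = 20
    max_overlap_mismatch: float = 0.1
    min_coverage: float = 0.9
    pseudocount: float = 0.0

    # stats
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    log_pseudo: float = 0.0

    # DHS
    n_tss: int = 2000
    high_cluster_fraction: float = 0.136
    dhs_mean_high: float = 400.0
    dhs_mean_low: float = 40.0
    dhs_fold_high: float = 0.704
    dhs_fold_low: float = 1.287
    flank: int = 2000
    bin_size: int = 100
    core_flank: int = 300
    dhs_k: int = 2

    # externally supplied inputs (optional; overrides simulation)
    reference_fasta: str | None = None
    reference_tsv: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if "quant" in self.stages and "reference" not in self.stages:
            if not (self.reference_fasta and self.reference_tsv):
                raise ValueError(
                    "quant without the reference stage requires "
                    "reference_fasta and reference_tsv"
                )
        if self.replicates < 2 and "stats" in self.stages:
            raise ValueError("stats stage requires replicates >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)
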