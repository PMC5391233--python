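import pandas as pd
import pytest

import epidrift as ed
from epidrift.quant import calibrate_bias, compute_ratios, merge_pairs, normalize, tables_from_study
from epidrift.reference import call_consensus_set


@pytest.fixture(scope="session")
def small_panel():
    spec = ed.SyntheticPanelSpec(n_amplicons=12, seed=11)
    panel, truth = ed.make_ortholog_panel(spec)
    return panel, truth


def build_reference(panel, depth=20, error_rate=0.0, seed=100, min_reads=10):
    """Build a validated ISV reference from pure-species calibration reads."""
    temp_ref = ed.build_temp_ref(panel)
    consensus = {}
    for species, frac, sub in (("mouse", 1.0, 1), ("rat", 0.0, 2)):
        r1, r2, _ = ed.simulate_amplicon_reads(
            panel, frac, depth, error_rate, seed=seed + sub
        )
        merged, _, _ = merge_pairs(r1, r2)
        pileups, _ = ed.match_reads_to_temp_ref(
            [(m.read_id, m.sequence) for m in merged], temp_ref
        )
        consensus[species] = call_consensus_set(pileups, min_reads=min_reads)
    return ed.build_isv_ref(consensus["mouse"], consensus["rat"])


@pytest.fixture(scope="session")
def small_ref(small_panel):
    panel, _ = small_panel
    return build_reference(panel)


def ra_matrix(samples, pseudocount=0.0) -> pd.DataFrame:
    """Normalized RA matrix straight from simulated count tables."""
    profile = normalize(
        calibrate_bias(compute_ratios(tables_from_study(samples), pseudocount))
    )
    return profile.normalized


def age_groups(samples, genotype):
    young = [s.sample_id for s in samples if s.age == "young" and s.genotype == genotype]
    aged = [s.sample_id for s in samples if s.age == "aged" and s.genotype == genotype]
    return young, aged
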