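import numpy as np
import pandas as pd
import pytest

from methpair import SimConfig, simulate_annotations, simulate_cohort
from methpair.hmm import StateCalls


def calls_from_truth(truth, pair_id: str) -> StateCalls:
    """StateCalls carrying the simulated ground-truth states (used where a
    test exercises downstream logic independently of decoding quality)."""
    df = truth.states[pair_id].assign(
        delta=0.0, gamma_minus=0.0, gamma_eq=0.0, gamma_plus=0.0
    )
    return StateCalls(
        pair_id=pair_id, patient_id=truth.pair_patient[pair_id], records=df
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(
        n_patients=4,
        pairs_per_patient=[1, 2, 1, 3],
        n_chromosomes=2,
        cpgs_per_chromosome=1000,
        seed=11,
    )
    sample_pairs, profiles, truth = simulate_cohort(cfg)
    return cfg, sample_pairs, profiles, truth


@pytest.fixture(scope="session")
def annotated_cohort(small_cohort):
    cfg, sample_pairs, profiles, truth = small_cohort
    cpgs = profiles[0].records[["cpg_id", "chrom", "pos"]]
    annot, tables = simulate_annotations(cpgs, truth, cfg)
    return cfg, profiles, truth, annot, tables


@pytest.fixture(scope="session")
def truth_calls(small_cohort):
    _, _, profiles, truth = small_cohort
    return {p.pair_id: calls_from_truth(truth, p.pair_id) for p in profiles}
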