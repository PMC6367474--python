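import numpy as np
import pandas as pd
import pytest

from ighap import load_default_reference


@pytest.fixture(scope="session")
def reference():
    return load_default_reference()


def make_records(rows, subject="S1"):
    """Build a rearrangement DataFrame from (v_call, d_call, j_call) tuples.

    Rows may carry two extra entries: v_mutation_count, d_mutation_count.
    """
    out = []
    for i, row in enumerate(rows):
        v, d, j = row[:3]
        vm = row[3] if len(row) > 3 else 0
        dm = row[4] if len(row) > 4 else 0
        out.append(
            {
                "sequence_id": f"{subject}_{i}",
                "v_call": v,
                "d_call": d,
                "j_call": j,
                "v_mutation_count": vm,
                "d_mutation_count": dm,
                "duplicate_count": 1,
                "subject_id": subject,
            }
        )
    return pd.DataFrame(out)


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture(scope="session")
def het_subject():
    """A deep simulated subject with a heterozygous J6 anchor and known deletions."""
    from ighap import SimulationConfig, simulate_genome, simulate_repertoire

    cfg = SimulationConfig(
        n_sequences=10_000,
        epsilon=0.005,
        forced_genotype={
            "IGHJ6": ("02", "03"),
            "IGHV3-23": ("01", "02"),
            "IGHD3-10": ("01", "02"),
        },
        single_deletions=[("IGHV3-53", "B"), ("IGHD3-3", "A")],
        subject_id="S1",
    )
    genome = simulate_genome(cfg, seed=7)
    rep = simulate_repertoire(genome, cfg, seed=8)
    return cfg, genome, rep
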