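import numpy as np
import pandas as pd
import pytest

import twostep_rnaseq as tr


@pytest.fixture(scope="session")
def small_cfg():
    """One treatment vs control, 3 replicates each, 800 genes."""
    return tr.SimConfig(n_genes=800, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    """Simulated shallow counts + design + annotation + truth (shared across tests)."""
    ann = tr.simulate_annotation(small_cfg)
    truth = tr.make_truth(small_cfg, ann)
    counts = tr.simulate_counts(small_cfg, truth, 2e6, ann)
    design = tr.make_design(small_cfg)
    return counts, design, ann, truth


@pytest.fixture()
def toy_counts():
    """Tiny hand-written count matrix with a known strong effect."""
    return pd.DataFrame(
        {
            "control_1": [10, 100, 7],
            "control_2": [10, 110, 9],
            "control_3": [10, 90, 8],
            "treated_1": [40, 100, 8],
            "treated_2": [40, 95, 9],
            "treated_3": [40, 105, 7],
        },
        index=pd.Index(["TA", "TB", "TC"], name="transcript_id"),
    )


@pytest.fixture()
def toy_design():
    return pd.DataFrame(
        {
            "individual": ["i1", "i2", "i3", "i1", "i2", "i3"],
            "condition": ["control"] * 3 + ["treated"] * 3,
            "control": [""] * 3 + ["control"] * 3,
        },
        index=pd.Index(
            ["control_1", "control_2", "control_3", "treated_1", "treated_2", "treated_3"],
            name="sample_id",
        ),
    )
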