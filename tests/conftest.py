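import dataclasses

import numpy as np
import pandas as pd
import pytest

from mirhub.syndata import CohortConfig, desk_cohort, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with strong planted structure, shared across tests."""
    cfg = dataclasses.replace(desk_cohort(), n_samples=160, seed=42)
    return generate_cohort(cfg) + (cfg,)


@pytest.fixture(scope="session")
def null_cohort():
    """No subtype effect anywhere: every feature is null."""
    cfg = CohortConfig(
        n_samples=160,
        n_mirna=30,
        n_gene=300,
        n_hubs=1,
        targets_per_hub=1,
        n_panel_genes=1,
        n_de_mirna_extra=2,
        n_de_gene_extra=0,
        hub_log2fc=0.0,
        target_log2fc=0.0,
        coupling=0.0,
        panel_log2fc=0.0,
        branch_panel_shift=0.0,
        hazard_ratio_c1=1.0,
        seed=7,
    )
    return generate_cohort(cfg) + (cfg,)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_survival():
    """Six subjects, two groups, hand-checkable event times."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 1.5, 2.5, 4.0],
            "event": [1, 1, 0, 1, 1, 0],
            "group": [0, 0, 0, 1, 1, 1],
        },
        index=[f"s{i}" for i in range(6)],
    )
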