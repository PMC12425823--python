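import numpy as np
import pandas as pd
import pytest

from methevolve.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured cohort shared by read-only tests."""
    cfg = SimulationConfig(n_patients=4, regions_per_patient=3, n_cpgs=3000,
                           n_genes=60, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_contexts():
    rows = []
    for p in range(2):
        for r in range(2):
            rows.append((f"P{p}_R{r+1}", f"P{p}", f"R{r+1}", "tumor", 0.6, "LUAD", 2.0))
        rows.append((f"P{p}_N", f"P{p}", "N", "normal", 1.0, "NAT", 2.0))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "region_id",
                                       "tissue", "purity", "histology", "ploidy"])
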