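import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import prscox as px

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_cox_data() -> pd.DataFrame:
    """Six subjects, no tied times, one binary covariate, all events.

    The covariate alternates across the event order so the partial
    likelihood has an interior maximum (a covariate that perfectly orders
    the events has a monotone likelihood and no finite estimate).
    """
    return pd.DataFrame(
        {
            "follow_up_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )


@pytest.fixture
def tied_cox_data() -> pd.DataFrame:
    """Eight subjects with tied event times (exercises the Efron correction)."""
    return pd.DataFrame(
        {
            "follow_up_years": [1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 1, 1, 1, 0, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        }
    )


@pytest.fixture(scope="session")
def sim_cohort() -> pd.DataFrame:
    """One mid-sized default-condition cohort shared across tests."""
    cohort = px.simulate_cohort(px.SimulationConfig(n_participants=20_000, seed=42))
    df = cohort.phenotypes.copy()
    df["prs_z"] = cohort.prs_z
    return df


@pytest.fixture
def five_variant_catalog() -> list[px.VariantWeight]:
    """Five variants spanning three loci with contrasting n, p and MAF."""
    return [
        px.VariantWeight("rs1", "1", 100, "A", "G", 0.10, 0.30, "L1", 50_000, 1e-8),
        px.VariantWeight("rs2", "1", 200, "C", "G", 0.12, 0.25, "L1", 80_000, 1e-6),
        px.VariantWeight("rs3", "2", 300, "G", "T", 0.20, 0.005, "L2", 90_000, 1e-12),
        px.VariantWeight("rs4", "2", 400, "T", "C", 0.15, 0.40, "L2", 60_000, 1e-9),
        px.VariantWeight("rs5", "3", 500, "A", "C", 0.08, 0.10, "L3", 60_000, 1e-7),
    ]
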