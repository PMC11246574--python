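"""Shared fixtures: small hand-written tables and simulated study triples."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.datatypes import SUMSTATS_COLUMNS, SummaryStatsTable
from mrmediate.simulate import SimulationConfig, simulate_study_triple


def make_table(rows, trait_id="trait", trait_role="exposure"):
    """Build a SummaryStatsTable from dicts; unspecified fields get defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-9,
        "n": 10_000,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"snp_id": f"rs{i + 1}", **defaults, **row}
        records.append(rec)
    df = pd.DataFrame(records)[SUMSTATS_COLUMNS]
    df["pos"] = df["pos"].astype("int64")
    df["n"] = df["n"].astype("Int64")
    return SummaryStatsTable(trait_id, trait_role, df)


@pytest.fixture
def small_exposure():
    return make_table(
        [
            {"pos": 1000, "beta": 0.10, "pval": 1e-10},
            {"pos": 2000, "beta": 0.12, "pval": 1e-9},
            {"pos": 3000, "chrom": "2", "beta": -0.11, "pval": 1e-8},
        ],
        trait_id="exp",
    )


@pytest.fixture(scope="session")
def default_triple():
    """Reference-condition study triple (seed 42): 15% mediated effect."""
    cfg = SimulationConfig(seed=42)
    exposure, mediator, outcome, truth = simulate_study_triple(cfg)
    return cfg, exposure, mediator, outcome, truth


@pytest.fixture(scope="session")
def null_triple():
    """No-pleiotropy, no-mediation condition with true effect 0.5."""
    cfg = SimulationConfig(seed=7, tau_direct=0.5, delta=0.0, beta2=0.0)
    exposure, mediator, outcome, truth = simulate_study_triple(cfg)
    return cfg, exposure, mediator, outcome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
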