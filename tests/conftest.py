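import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from privateqtl import simdata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    return simdata.simulate_panel(n_lineages=80, n_markers=120,
                                  ld_block_size=4, ld_rho=0.8, seed=11)


@pytest.fixture(scope="session")
def small_covariates(small_panel):
    return simdata.simulate_covariates(small_panel, n_pcs=5, seed=12)


@pytest.fixture(scope="session")
def planted_truth(small_panel):
    return simdata.SimTruth(
        planted_effects=[
            simdata.PlantedEffect(small_panel.marker_ids[50], "GxSxD", 0.15),
        ],
        seed=13,
    )


@pytest.fixture(scope="session")
def planted_records(small_panel, small_covariates, planted_truth):
    return simdata.simulate_individuals(
        small_panel, small_covariates, planted_truth,
        design={"n_per_group": 10, "n_blocks": 3}, seed=14)


@pytest.fixture(scope="session")
def lineage_summary(planted_records):
    from privateqtl import phenotypes
    summary, _, _ = phenotypes.summarize_lineages(planted_records, min_n=5)
    return summary


def make_noise_free_records(panel, truth, n_per_group=2):
    """Records under zero variance: pure fixed + planted structure."""
    vc = simdata.VarianceComponents(0, 0, 0, 0, 0, 0)
    truth0 = simdata.SimTruth(planted_effects=truth.planted_effects,
                              fixed_effects=truth.fixed_effects,
                              variance_components=vc, seed=truth.seed)
    return simdata.simulate_individuals(
        panel, None, truth0, design={"n_per_group": n_per_group, "n_blocks": 1},
        seed=truth.seed)


def cell_means(records: pd.DataFrame) -> pd.DataFrame:
    return (records.groupby(["lineage_id", "sex", "diet"], observed=True)
            ["size_log"].mean().unstack(["sex", "diet"]))


def ssp_contrast(records: pd.DataFrame) -> pd.Series:
    """Per-lineage (fed-starved of female-male) double contrast of cell means."""
    cm = cell_means(records)
    return ((cm[("F", "fed")] - cm[("F", "starved")])
            - (cm[("M", "fed")] - cm[("M", "starved")]))
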