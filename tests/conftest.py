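"""Shared fixtures: small simulated datasets reused across test modules."""

import pandas as pd
import pytest

from epidrift.admp import adjust_pvalues, fit_admp
from epidrift.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def purified_config():
    return SimulationConfig(
        n_probes=3000,
        n_individuals=200,
        cell_types=("monocyte", "tcell"),
        admp_fraction=0.30,
        share_probability=0.70,
        noise_precision=150.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def purified_monocyte(purified_config):
    """Purified monocyte dataset plus ground truth."""
    return simulate_dataset(purified_config, cell_type="monocyte")


@pytest.fixture(scope="session")
def monocyte_table(purified_monocyte):
    """Adjusted aDMP table for the purified monocyte dataset."""
    ds, _ = purified_monocyte
    return adjust_pvalues(fit_admp(ds, ["sex", "batch"]))


@pytest.fixture(scope="session")
def tcell_table(purified_config):
    ds, _ = simulate_dataset(purified_config, cell_type="tcell", cohort=1)
    return adjust_pvalues(fit_admp(ds, ["sex", "batch"]))


def make_admp_table(probes, slope, t, p, q=None, bonf_p=None, degenerate=None):
    """Hand-build an AdmpTable for fixture-driven tests."""
    import numpy as np

    from epidrift.admp import AdmpTable

    n = len(probes)
    df = pd.DataFrame(
        {
            "slope": slope,
            "se": np.ones(n),
            "t": t,
            "p": p,
            "degenerate": degenerate if degenerate is not None else [False] * n,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    if bonf_p is not None:
        df["bonf_p"] = bonf_p
    if q is not None:
        df["q"] = q
    return AdmpTable(table=df, covariates=(), n_samples=10)
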