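"""Build a cell-type reference from sorted profiles and deconvolve a tissue.

Simulates sorted neuron/glia profiles, derives marker CpGs (moderated
t-test, Bonferroni 0.05, delta-beta >= 0.70), then estimates cell fractions
in mixed 'brain' samples by constrained projection and compares them with
the simulated truth.
"""

import numpy as np
import pandas as pd

from epidrift import (
    MethylationDataset,
    SimulationConfig,
    build_reference,
    estimate_cell_fractions,
    simulate_dataset,
)

config = SimulationConfig(
    n_probes=3000,
    n_individuals=60,
    cell_types=("neuron", "glia"),
    dirichlet_alpha=(3.0, 2.0),
    admp_fraction=0.0,
    marker_fraction=0.08,
    noise_precision=150.0,
    seed=5,
)

# sorted profiles: one purified dataset per cell type, same individuals
sorted_parts = [
    simulate_dataset(config, cell_type=ct)[0] for ct in config.cell_types
]
beta = pd.concat([d.beta for d in sorted_parts], axis=1)
beta.columns = [
    f"{ct}:{s}" for ct, d in zip(config.cell_types, sorted_parts) for s in d.sample_ids
]
labels = pd.Series(
    [ct for ct, d in zip(config.cell_types, sorted_parts) for _ in d.sample_ids],
    index=beta.columns,
)
sorted_ds = MethylationDataset(
    beta=beta, annotations=pd.DataFrame({"age": 50.0, "group": labels}, index=beta.columns)
)
reference = build_reference(sorted_ds, labels)
print(f"reference: {len(reference.marker_ids)} markers x {reference.cell_types}")

mixed, truth = simulate_dataset(config, tissue="brain", cohort=1)
estimate = estimate_cell_fractions(mixed, reference)
err = estimate.fractions.to_numpy() - truth.cell_fractions.to_numpy()
print(estimate.fractions.head().round(3))
print(f"RMSE vs simulated truth: {np.sqrt((err ** 2).mean()):.4f}")
# Sub-0.05 RMSE means the estimated fractions are accurate enough to serve
# as covariates in the age models of heterogeneous tissues.
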