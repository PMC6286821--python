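"""Pan-tissue sharing of a fixed CpG panel (an epigenetic-clock-style list).

Simulates five purified blood cell types over a common probe truth, takes a
100-CpG panel enriched for truly shared aDMPs, and asks: in how many cell
types is each panel CpG an aDMP (FDR < 0.05)?
"""

import numpy as np

from epidrift import (
    SimulationConfig,
    adjust_pvalues,
    fit_admp,
    panel_sharing,
    simulate_dataset,
)

config = SimulationConfig(
    n_probes=2000,
    n_individuals=300,
    cell_types=("monocyte", "cd4t", "cd8t", "bcell", "neutrophil"),
    admp_fraction=0.30,
    share_probability=0.80,
    noise_precision=200.0,
    seed=6,
)
tables, truth = [], None
for k, ct in enumerate(config.cell_types):
    ds, truth = simulate_dataset(config, cell_type=ct, cohort=k)
    tables.append((ct, adjust_pvalues(fit_admp(ds, ["sex", "batch"]))))

rng = np.random.default_rng(6)
panel = list(rng.choice(sorted(truth.shared_set), 60, replace=False))
panel += list(rng.choice(sorted(set(truth.is_admp.index) - truth.shared_set), 40,
                         replace=False))

summary = panel_sharing(panel, tables)
print("cumulative proportion of the panel that is an aDMP in >= k cell types:")
for k, prop in summary.cumulative_proportion.items():
    print(f"  k >= {k}: {prop:.2f}")
print(f"cell-type-specific CpGs (flagged in exactly 1): "
      f"{len(summary.specific_cpgs())} of {len(summary.sharing_count)}")
# Most truly shared panel CpGs are flagged in all five cell types; only a
# small minority look cell-type specific.
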