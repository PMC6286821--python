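"""Why small EWAS miss most age-DMPs: an empirical power curve.

Defines a gold-standard aDMP set on a full 600-sample dataset (Bonferroni
0.05), then re-calls aDMPs on random subsamples of 50-500 samples and
reports the sensitivity to recover the gold standard.
"""

from epidrift import (
    SelectionCriterion,
    SimulationConfig,
    define_gold_standard,
    simulate_dataset,
    subsample_sensitivity,
)

config = SimulationConfig(
    n_probes=5000,
    n_individuals=600,
    cell_types=("monocyte",),
    admp_fraction=0.30,
    share_probability=1.0,
    seed=3,
)
dataset, _ = simulate_dataset(config, cell_type="monocyte")
bonf = SelectionCriterion.bonferroni(0.05)
gold = define_gold_standard(dataset, ["sex", "batch"], bonf)
print(f"gold standard: {len(gold)} aDMPs at n={dataset.n_samples}")

curve = subsample_sensitivity(
    dataset, ["sex", "batch"], gold, bonf,
    sizes=[50, 100, 200, 300, 400, 500], runs=5, seed=3,
)
print(curve.summary().round(3))
# Sensitivity climbs steeply with sample size: a study of 100 samples
# recovers only a small fraction of the aDMPs that the full cohort defines,
# so sparse overlap between small studies does not imply tissue-specificity.
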