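"""Simulate a purified-cell ageing EWAS and call age-DMPs.

Generates a 5,000-probe, 300-sample purified monocyte dataset in which 30%
of probes drift with age, fits a per-probe linear model of DNAm on age
(adjusting for sex and batch), and compares three selection criteria.
"""

from epidrift import (
    SelectionCriterion,
    SimulationConfig,
    adjust_pvalues,
    estimate_pi0,
    fit_admp,
    select_admps,
    simulate_dataset,
    truth_sensitivity,
)

config = SimulationConfig(
    n_probes=5000,
    n_individuals=300,
    cell_types=("monocyte",),
    admp_fraction=0.30,
    share_probability=1.0,
    seed=1,
)
dataset, truth = simulate_dataset(config, cell_type="monocyte")
table = adjust_pvalues(fit_admp(dataset, ["sex", "batch"]))

print(f"{dataset.n_probes} probes x {dataset.n_samples} samples")
for crit in (
    SelectionCriterion.fdr(0.05),
    SelectionCriterion.bonferroni(0.05),
    SelectionCriterion.effect_size(0.002),
):
    called = select_admps(table, crit)
    sens = truth_sensitivity(called, truth, "monocyte")
    print(f"  {crit.label:16s} -> {len(called):5d} aDMPs, sensitivity {sens:.2f}")

pi0 = estimate_pi0(table)
print(
    f"Storey pi0 = {pi0.pi0:.3f}: an estimated {pi0.admp_fraction:.0%} of the "
    f"methylome drifts with age (simulated truth: 30%)."
)
# The FDR criterion recovers most true aDMPs; Bonferroni is far more
# conservative; the effect-size rule picks a small, biased subset.
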