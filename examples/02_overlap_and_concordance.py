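"""How shared is epigenetic drift between two blood cell subtypes?

Simulates purified monocyte and T-cell datasets over the same probe truth
(70% of age-affected probes shared), then quantifies sharing three ways:
hypergeometric overlap significance, t-statistic sign concordance, and the
model-based shared-fraction estimate.
"""

from epidrift import (
    SelectionCriterion,
    SimulationConfig,
    adjust_pvalues,
    estimate_shared_fraction,
    fit_admp,
    hypergeometric_overlap,
    select_admps,
    simulate_dataset,
    tstat_concordance,
)

config = SimulationConfig(
    n_probes=6000,
    n_individuals=400,
    cell_types=("monocyte", "tcell"),
    admp_fraction=0.30,
    share_probability=0.70,
    noise_precision=300.0,
    seed=2,
)
ds_mono, _ = simulate_dataset(config, cell_type="monocyte")
ds_tcell, _ = simulate_dataset(config, cell_type="tcell", cohort=1)
t_mono = adjust_pvalues(fit_admp(ds_mono, ["sex", "batch"]))
t_tcell = adjust_pvalues(fit_admp(ds_tcell, ["sex", "batch"]))

fdr = SelectionCriterion.fdr(0.05)
set_m = select_admps(t_mono, fdr)
set_t = select_admps(t_tcell, fdr)
p_overlap = hypergeometric_overlap(set_m, set_t, config.n_probes)
print(f"monocyte aDMPs: {len(set_m)}, T-cell aDMPs: {len(set_t)}")
print(f"overlap {len(set_m & set_t)} of {config.n_probes} probes, "
      f"hypergeometric p = {p_overlap:.3g}")

conc = tstat_concordance(t_mono, t_tcell)
print(f"sign-concordance quadrants {conc.quadrant_counts}, "
      f"one-tailed Fisher p = {conc.fisher_p:.3g}")

shared, validated = estimate_shared_fraction(
    t_mono, t_tcell, n_cell_types=2,
    discovery_criterion=SelectionCriterion.bonferroni(0.05),
)
print(f"validated fraction {validated:.2f} -> shared-drift estimate "
      f"{shared:.2f} (simulated truth: 0.70)")
# A tiny overlap p and off-diagonal quadrant counts near zero mean sharing
# is the norm; the final line inverts the sharing model to recover the
# simulated shared fraction.
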