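"""Age-regression fitting, multiple-testing adjustment, selection criteria
and Storey pi0 — checked against closed-form oracles and null simulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_admp_table
from epidrift.admp import (
    SelectionCriterion,
    adjust_pvalues,
    estimate_pi0,
    fit_admp,
    select_admps,
    storey_pi0,
    storey_qvalues,
)
from epidrift.dataset import MethylationDataset
from epidrift.simulate import SimulationConfig, simulate_dataset


def dataset_from_matrix(beta, ages, extra_ann=None):
    beta = pd.DataFrame(
        beta,
        index=[f"cg{i}" for i in range(np.shape(beta)[0])],
        columns=[f"s{j}" for j in range(np.shape(beta)[1])],
    )
    ann = pd.DataFrame({"age": ages}, index=beta.columns)
    if extra_ann:
        for k, v in extra_ann.items():
            ann[k] = v
    return MethylationDataset(beta=beta, annotations=ann)


class TestFitAdmp:
    def test_five_sample_fixture_matches_matrix_algebra_oracle(self):
        ages = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
        y = np.array([0.10, 0.22, 0.29, 0.41, 0.50])
        table = fit_admp(dataset_from_matrix([y], ages)).table

        # independent closed-form OLS oracle
        X = np.column_stack([np.ones(5), ages])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        s2 = resid @ resid / (5 - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t_exp = beta_hat[1] / se
        from scipy.stats import t as tdist

        p_exp = 2 * tdist.sf(abs(t_exp), 3)
        row = table.iloc[0]
        assert row["slope"] == pytest.approx(beta_hat[1], rel=1e-12)
        assert row["se"] == pytest.approx(se, rel=1e-12)
        assert row["t"] == pytest.approx(t_exp, rel=1e-12)
        assert row["p"] == pytest.approx(p_exp, rel=1e-12)

    def test_constant_probe_flagged_degenerate(self):
        ages = [20.0, 30.0, 40.0, 50.0, 60.0]
        table = fit_admp(dataset_from_matrix([[0.5] * 5], ages)).table
        row = table.iloc[0]
        assert row["degenerate"]
        assert row["slope"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == 1.0

    def test_sample_permutation_invariance(self, purified_monocyte):
        ds, _ = purified_monocyte
        perm = list(ds.sample_ids[::-1])
        t1 = fit_admp(ds, ["sex", "batch"]).table
        t2 = fit_admp(ds.subset_samples(perm), ["sex", "batch"]).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_admp(dataset_from_matrix([[0.1, 0.2, 0.3]], [40.0, 40.0, 40.0]))

    def test_collinear_covariates_named(self):
        ages = [20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
        ds = dataset_from_matrix(
            [np.linspace(0.2, 0.4, 6)], ages,
            extra_ann={"dup_age": [a * 2 for a in ages]},
        )
        with pytest.raises(ValueError, match="dup_age"):
            fit_admp(ds, ["dup_age"])

    def test_missing_covariate_rejected(self, purified_monocyte):
        ds, _ = purified_monocyte
        with pytest.raises(ValueError, match="nope"):
            fit_admp(ds, ["nope"])

    def test_t_and_slope_share_sign(self, monocyte_table):
        df = monocyte_table.table
        ok = ~df["degenerate"] & (df["t"] != 0)
        assert (np.sign(df.loc[ok, "t"]) == np.sign(df.loc[ok, "slope"])).all()

    def test_slope_recovery_on_purified_data(self, purified_monocyte, monocyte_table):
        """Estimated slopes of true aDMPs match the logit-attenuated truth
        with small relative bias."""
        _, truth = purified_monocyte
        admps = sorted(truth.admp_set("monocyte"))
        est = monocyte_table.table.loc[admps, "slope"]
        expected = truth.beta_scale_slope("monocyte").loc[admps]
        ratio = (est * np.sign(expected)).sum() / np.abs(expected).sum()
        assert ratio == pytest.approx(1.0, abs=0.10)


class TestAdjustment:
    def test_all_ones_stay_ones(self):
        tab = make_admp_table(["a", "b", "c"], [0.1] * 3, [1.0] * 3, [1.0] * 3)
        adj = adjust_pvalues(tab).table
        assert (adj["bonf_p"] == 1.0).all()

    def test_bonferroni_is_p_times_n_capped(self):
        p = [1e-8, 0.002, 0.4, 0.9]
        tab = make_admp_table(list("abcd"), [0.1] * 4, [5.0] * 4, p)
        adj = adjust_pvalues(tab).table
        np.testing.assert_allclose(
            adj["bonf_p"], np.minimum(1.0, np.array(p) * 4)
        )

    def test_genome_scale_bonferroni_cutoff(self):
        # selecting at alpha=0.05 over 482091 probes means p < ~1.037e-7
        n = 482091
        cutoff = 0.05 / n
        assert cutoff == pytest.approx(1.037e-7, rel=1e-3)
        rng = np.random.default_rng(1)
        p = rng.random(1000)
        p[0] = cutoff * 0.99  # passes after scaling by n
        p[1] = cutoff * 1.01  # fails
        bonf = np.minimum(1.0, p * n)
        assert bonf[0] < 0.05 < bonf[1]

    def test_qvalues_monotone_in_p(self, monocyte_table):
        df = monocyte_table.table.sort_values("p")
        assert (np.diff(df["q"].to_numpy()) >= -1e-15).all()

    def test_bonferroni_dominates_p(self, monocyte_table):
        df = monocyte_table.table
        assert (df["bonf_p"] >= df["p"] - 1e-15).all()

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(0)
        pi0 = storey_pi0(rng.random(10_000))
        assert 0.9 <= pi0 <= 1.0

    def test_saturated_alternative_pi0_near_zero(self):
        p = np.full(5000, 1e-12)
        est = estimate_pi0(p)
        assert est.pi0 == pytest.approx(0.0, abs=0.01)
        assert est.admp_fraction == pytest.approx(1.0, abs=0.01)

    def test_pi0_recovery_with_true_signal(self):
        """30% true aDMPs at high power -> drifting fraction within 0.05."""
        cfg = SimulationConfig(
            n_probes=10_000, n_individuals=500, cell_types=("monocyte",),
            admp_fraction=0.30, share_probability=1.0,
            noise_precision=300.0, seed=7,
        )
        ds, _ = simulate_dataset(cfg, cell_type="monocyte")
        est = estimate_pi0(fit_admp(ds, ["sex", "batch"]))
        assert est.admp_fraction == pytest.approx(0.30, abs=0.05)

    def test_nan_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.1, np.nan]))


class TestSelection:
    def test_fdr_alpha_one_selects_all_non_degenerate(self, monocyte_table):
        sel = select_admps(monocyte_table, SelectionCriterion.fdr(1.0))
        df = monocyte_table.table
        assert sel == set(df.index[~df["degenerate"]])

    def test_effect_size_boundary_is_strict(self):
        tab = make_admp_table(
            ["at", "above", "below"],
            [0.002, 0.0021, 0.0019],
            [3.0, 3.0, 3.0],
            [0.01] * 3,
        )
        sel = select_admps(tab, SelectionCriterion.effect_size(0.002))
        assert sel == {"above"}

    def test_conjunction_on_hand_fixture(self):
        # six probes with known bonf_p and slope; enumerate by hand:
        # pass bonferroni: a, b, c ; pass |slope|>0.002: b, c, e
        tab = make_admp_table(
            list("abcdef"),
            slope=[0.001, 0.003, -0.004, 0.005, 0.0025, 0.0001],
            t=[5, 6, -7, 1, 1.2, 0.1],
            p=[1e-9, 1e-9, 1e-9, 0.2, 0.3, 0.9],
            bonf_p=[6e-9, 6e-9, 6e-9, 1.0, 1.0, 1.0],
            q=[1e-9] * 3 + [0.4, 0.4, 0.9],
        )
        crit = SelectionCriterion.all_of(
            SelectionCriterion.bonferroni(0.05), SelectionCriterion.effect_size(0.002)
        )
        assert select_admps(tab, crit) == {"b", "c"}

    def test_degenerate_probes_never_selected(self):
        tab = make_admp_table(
            ["x", "y"], [0.01, 0.01], [0.0, 5.0], [1.0, 1e-6],
            degenerate=[True, False],
        )
        tab = adjust_pvalues(tab)
        sel = select_admps(tab, SelectionCriterion.effect_size(0.002))
        assert sel == {"y"}

    def test_missing_adjusted_columns_rejected(self):
        tab = make_admp_table(["a"], [0.1], [2.0], [0.01])
        with pytest.raises(ValueError, match="adjust_pvalues"):
            select_admps(tab, SelectionCriterion.fdr())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fdr_selection_contains_bonferroni_selection(self, seed):
        """q <= Bonferroni-adjusted p under the q-value construction, so at
        any alpha the FDR set contains the Bonferroni set."""
        rng = np.random.default_rng(seed)
        n = 200
        p = np.concatenate([rng.random(n) ** 3, rng.random(n)])
        tab = make_admp_table(
            [f"cg{i}" for i in range(2 * n)],
            slope=rng.normal(0, 0.003, 2 * n),
            t=rng.normal(0, 3, 2 * n),
            p=p,
        )
        tab = adjust_pvalues(tab)
        alpha = 0.05
        fdr = select_admps(tab, SelectionCriterion.fdr(alpha))
        bonf = select_admps(tab, SelectionCriterion.bonferroni(alpha))
        assert bonf <= fdr

    def test_criterion_parsing_round_trip(self):
        crit = SelectionCriterion.parse("bonferroni:0.01+effect_size:0.003")
        assert crit.kind.value == "and"
        assert crit.parts[0].alpha == 0.01
        assert crit.parts[1].tau == 0.003
        with pytest.raises(ValueError):
            SelectionCriterion.parse("magic:1")


class TestCellFractionAdjustment:
    def test_adjusting_for_fractions_raises_sensitivity(self):
        """When mixture fractions drift with age, including the true
        fractions as covariates recovers aDMPs that unadjusted models miss."""
        cfg = SimulationConfig(
            n_probes=4000,
            n_individuals=300,
            cell_types=("epithelial", "immune"),
            admp_fraction=0.25,
            share_probability=0.3,
            slope_range=(0.003, 0.01),
            noise_precision=200.0,
            dirichlet_alpha=1.0,
            mixture_age_trend=0.1,
            baseline_divergence_sd=1.0,
            seed=13,
        )
        ds, truth = simulate_dataset(cfg, tissue="buccal")
        crit = SelectionCriterion.fdr(0.05)
        unadj = select_admps(adjust_pvalues(fit_admp(ds, ["sex", "batch"])), crit)
        adj = select_admps(
            adjust_pvalues(fit_admp(ds, ["sex", "batch", "frac_epithelial"])), crit
        )
        truth_set = truth.any_admp_set()
        sens_unadj = len(unadj & truth_set) / len(truth_set)
        sens_adj = len(adj & truth_set) / len(truth_set)
        assert sens_adj > sens_unadj
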