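"""Overlap significance, t-statistic concordance and selection-bias
diagnostics — all checked against exhaustive enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_admp_table
from epidrift.admp import SelectionCriterion, adjust_pvalues, fit_admp, select_admps
from epidrift.dataset import MethylationDataset
from epidrift.overlap import (
    cross_validation_fractions,
    estimate_shared_fraction,
    hypergeometric_overlap,
    mean_dnam_profile,
    nested_overlap,
    tstat_concordance,
)
from epidrift.simulate import SimulationConfig, simulate_dataset


def hypergeom_tail_oracle(k: int, M: int, K: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(M population, K successes, N draws),
    by exhaustive tail summation with integer binomials."""
    total = comb(M, N)
    acc = 0
    for j in range(k, min(K, N) + 1):
        acc += comb(K, j) * comb(M - K, N - j)
    return acc / total


class TestHypergeometricOverlap:
    def test_full_universe_set_gives_p_one(self):
        universe = [f"p{i}" for i in range(10)]
        assert hypergeometric_overlap(universe, universe[:5], 10) == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        assert hypergeometric_overlap({"a"}, {"b"}, 10) == pytest.approx(1.0)

    def test_worked_example_by_full_enumeration(self):
        """|A|=4 drawn from a 10-universe with |B|=5: overlap 4 has
        probability C(5,4)C(5,0)/C(10,4) = 5/210 under the null."""
        universe = list(range(10))
        B = set(range(5))
        A = {0, 1, 2, 3}
        p = hypergeometric_overlap(A, B, 10)
        count = sum(
            1 for draw in itertools.combinations(universe, 4) if len(set(draw) & B) >= 4
        )
        assert p == pytest.approx(count / comb(10, 4), rel=1e-12)
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_hundred_random_configs_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            M = int(rng.integers(5, 21))
            na, nb = int(rng.integers(1, M + 1)), int(rng.integers(1, M + 1))
            universe = [f"p{i}" for i in range(M)]
            A = set(rng.choice(universe, na, replace=False))
            B = set(rng.choice(universe, nb, replace=False))
            p = hypergeometric_overlap(A, B, M)
            expected = hypergeom_tail_oracle(len(A & B), M, nb, na)
            assert p == pytest.approx(expected, rel=1e-12)

    def test_sets_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(set(range(11)), set(), 10)

    def test_super_uniform_under_random_sets(self):
        rng = np.random.default_rng(2)
        universe = np.arange(500)
        ps = []
        for _ in range(300):
            A = set(rng.choice(universe, 100, replace=False))
            B = set(rng.choice(universe, 100, replace=False))
            ps.append(hypergeometric_overlap(A, B, 500))
        ps = np.asarray(ps)
        # P(p <= t) <= t at every threshold (conservative/valid test)
        for t in (0.01, 0.05, 0.2, 0.5):
            assert (ps <= t).mean() <= t + 3 * np.sqrt(t * (1 - t) / 300)


class TestNestedOverlap:
    def test_identical_sets(self):
        k, M = 6, 25
        s = {f"p{i}" for i in range(k)}
        res = nested_overlap([s, s, s], M)
        assert res.triple_count == k
        expected = hypergeom_tail_oracle(k, M, k, k)
        assert res.triple_p == pytest.approx(expected, rel=1e-12)
        assert res.triple_p < 1e-4

    def test_disjoint_sets(self):
        a = {f"a{i}" for i in range(4)}
        b = {f"b{i}" for i in range(4)}
        c = {f"c{i}" for i in range(4)}
        res = nested_overlap([a, b, c], 30)
        assert res.triple_count == 0
        assert res.triple_p == pytest.approx(1.0)

    def test_universe_20_example_against_brute_force(self):
        """A∩B of size 6, |C| = 8, triple overlap 5 on a 20-universe."""
        universe = [f"p{i}" for i in range(20)]
        A = set(universe[:10])
        B = set(universe[4:14])  # A∩B = p4..p9, size 6
        C = set(universe[5:11]) | {universe[15], universe[16]}  # size 8
        assert len(A & B) == 6 and len(C) == 8 and len(A & B & C) == 5
        res = nested_overlap([A, B, C], 20)
        # oracle: enumerate all C(20,6) placements of an A∩B-sized draw
        ab, hits = 0, 0
        for draw in itertools.combinations(universe, 6):
            ab += 1
            if len(set(draw) & C) >= 5:
                hits += 1
        assert res.triple_p == pytest.approx(hits / ab, rel=1e-12)

    def test_seven_venn_regions_partition_the_union(self):
        rng = np.random.default_rng(7)
        universe = [f"p{i}" for i in range(50)]
        A = set(rng.choice(universe, 20, replace=False))
        B = set(rng.choice(universe, 15, replace=False))
        C = set(rng.choice(universe, 25, replace=False))
        res = nested_overlap([A, B, C], 50)
        assert sum(res.region_counts.values()) == len(A | B | C)


class TestConcordance:
    def test_self_concordance_has_no_disagreement(self, monocyte_table):
        res = tstat_concordance(monocyte_table, monocyte_table)
        assert res.quadrant_counts[("+", "-")] == 0
        assert res.quadrant_counts[("-", "+")] == 0
        assert res.quadrant_counts[("+", "+")] >= 5
        assert res.quadrant_counts[("-", "-")] >= 5
        assert res.fisher_p < 1e-10

    def test_two_by_two_fixture_matches_enumeration_oracle(self):
        """Quadrants (30, 2; 3, 25): one-tailed Fisher p equals the exact
        hypergeometric tail sum over the fixed margins."""
        counts = {("+", "+"): 30, ("+", "-"): 2, ("-", "+"): 3, ("-", "-"): 25}
        probes, slopes, td, tv, pv = [], [], [], [], []
        i = 0
        for (sd, sv), nq in counts.items():
            for _ in range(nq):
                probes.append(f"cg{i}")
                i += 1
                slopes.append(0.003 if sd == "+" else -0.003)
                td.append(4.0 if sd == "+" else -4.0)
                tv.append(3.0 if sv == "+" else -3.0)
                pv.append(1e-4)
        disc = make_admp_table(probes, slopes, td, [1e-8] * len(probes),
                               q=[1e-8] * len(probes), bonf_p=[1e-5] * len(probes))
        val = make_admp_table(probes, slopes, tv, pv)
        res = tstat_concordance(disc, val)
        assert res.quadrant_counts == counts
        # oracle: margins rows (32, 28), cols (33, 27), N = 60
        N, r1, c1 = 60, 32, 33
        total = comb(N, c1)
        tail = sum(
            comb(r1, a) * comb(N - r1, c1 - a)
            for a in range(30, min(r1, c1) + 1)
        )
        assert res.fisher_p == pytest.approx(tail / total, rel=1e-12)

    def test_not_validated_probes_counted_separately(self):
        probes = [f"cg{i}" for i in range(20)]
        disc = make_admp_table(probes, [0.003] * 20, [4.0] * 20, [1e-8] * 20,
                               q=[1e-8] * 20, bonf_p=[1e-5] * 20)
        pv = [1e-4] * 12 + [0.5] * 8  # 8 fail the validation threshold
        val = make_admp_table(probes, [0.003] * 20, [3.0] * 20, pv)
        res = tstat_concordance(disc, val)
        assert res.n_validated == 12
        assert res.n_not_validated == 8
        assert res.n_discovery == 20

    def test_null_concordance_p_roughly_uniform(self):
        """Independent validation t-statistics: Fisher p passes a KS
        uniformity check over 120 replicates."""
        rng = np.random.default_rng(11)
        n = 1500
        probes = [f"cg{i}" for i in range(n)]
        ps = []
        for _ in range(120):
            td = rng.normal(0, 1, n) + np.where(rng.random(n) < 0.5, 4, -4)
            tv = rng.normal(0, 1, n)
            pv = 2 * stats.norm.sf(np.abs(tv))
            disc = make_admp_table(probes, np.sign(td) * 0.003, td, [1e-8] * n,
                                   q=[1e-8] * n, bonf_p=[1e-5] * n)
            val = make_admp_table(probes, np.sign(tv) * 0.001, tv, pv)
            ps.append(tstat_concordance(disc, val).fisher_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_concordance_strengthens_with_sharing(self):
        """Fisher concordance p drops (log-scale) as share_probability rises."""
        logps = []
        for share in (0.2, 0.9):
            cfg = SimulationConfig(
                n_probes=2000, n_individuals=200,
                cell_types=("monocyte", "tcell"), admp_fraction=0.3,
                share_probability=share, noise_precision=150.0, seed=17,
            )
            dsA, _ = simulate_dataset(cfg, cell_type="monocyte")
            dsB, _ = simulate_dataset(cfg, cell_type="tcell", cohort=1)
            tA = adjust_pvalues(fit_admp(dsA, ["sex", "batch"]))
            tB = adjust_pvalues(fit_admp(dsB, ["sex", "batch"]))
            res = tstat_concordance(tA, tB)
            logps.append(np.log10(max(res.fisher_p, 1e-300)))
        assert logps[1] < logps[0]

    def test_empty_discovery_set_rejected(self, monocyte_table):
        with pytest.raises(ValueError, match="empty"):
            tstat_concordance(
                monocyte_table, monocyte_table,
                discovery_criterion=SelectionCriterion.fdr(1e-300),
            )


class TestCrossValidationFractions:
    def test_self_validation_is_total(self, monocyte_table):
        crit = SelectionCriterion.fdr(0.05)
        df = cross_validation_fractions(
            monocyte_table, monocyte_table, crit, [crit]
        )
        assert df.loc[crit.label, "fraction"] == 1.0

    def test_fdr_validates_more_than_effect_size_near_bounds(
        self, monocyte_table, tcell_table
    ):
        es = SelectionCriterion.effect_size(0.002)
        fdr = SelectionCriterion.fdr(0.05)
        df = cross_validation_fractions(monocyte_table, tcell_table, es, [es, fdr])
        assert df.loc[fdr.label, "fraction"] >= df.loc[es.label, "fraction"]


class TestSharedFractionEstimate:
    def test_formula_inverts_the_sharing_model(self):
        # v = s/(s+(1-s)/C) then s back out exactly
        for s, C in [(0.7, 2), (0.3, 5), (1.0, 3), (0.0, 2)]:
            v = s / (s + (1 - s) / C) if (s + (1 - s) / C) > 0 else 0.0
            probes = [f"cg{i}" for i in range(100)]
            # direct algebraic check of the inversion
            est = v / (C - (C - 1) * v)
            assert est == pytest.approx(s, abs=1e-12)

    def test_requires_two_cell_types(self, monocyte_table):
        with pytest.raises(ValueError):
            estimate_shared_fraction(monocyte_table, monocyte_table, 1)


class TestMeanDnamProfile:
    def test_singleton_constant_probe(self):
        beta = pd.DataFrame(
            {"s0": [0.5, 0.2], "s1": [0.5, 0.4]}, index=["flat", "other"]
        )
        ds = MethylationDataset(
            beta=beta,
            annotations=pd.DataFrame({"age": [40.0, 50.0]}, index=["s0", "s1"]),
        )
        per_set, summary = mean_dnam_profile(ds, {"one": {"flat"}})
        assert per_set["one"]["flat"] == pytest.approx(0.5)
        assert summary.loc["one", "mean"] == pytest.approx(0.5)

    def test_symmetric_baseline_gives_balanced_tails(self):
        cfg = SimulationConfig(n_probes=5000, n_individuals=50, seed=19)
        ds, _ = simulate_dataset(cfg)
        _, summary = mean_dnam_profile(ds, {"all": set(ds.probe_ids)})
        low, high = summary.loc["all", ["frac_low", "frac_high"]]
        assert low == pytest.approx(high, abs=0.05)
        assert low > 0.2  # bimodal baseline puts mass near both bounds

    def test_unknown_probes_dropped_with_warning(self):
        cfg = SimulationConfig(n_probes=50, n_individuals=10, seed=1)
        ds, _ = simulate_dataset(cfg)
        with pytest.warns(UserWarning, match="unknown probes"):
            per_set, summary = mean_dnam_profile(
                ds, {"x": {ds.probe_ids[0], "bogus"}}
            )
        assert summary.loc["x", "n"] == 1
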