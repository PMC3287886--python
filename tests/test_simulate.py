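"""Generator contracts: HWE sampling, phenotype models, case-control draws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from generank.simulate import (
    CaseControlScenario,
    ConfigurationError,
    ExomeConfig,
    case_control_genotype_distributions,
    case_control_status,
    simulate_case_control,
    simulate_causal_gene,
    simulate_exome,
    simulate_phenotypes,
)
from generank._glm import linear_marginal_stats, logistic_marginal_stats


def _flat_config(**kw):
    """Config with only common markers (no near-monomorphic columns)."""
    defaults = dict(
        rare_fraction=0.0,
        maf_common_range=(0.05, 0.5),
        n_causal_genes={"Q1": 0, "Q2": 0, "AFF": 0},
    )
    defaults.update(kw)
    return ExomeConfig(**defaults)


class TestSimulateExome:
    def test_shape_and_range(self):
        cfg = ExomeConfig(n_individuals=697, n_genes=200, seed=1)
        study, truth = simulate_exome(cfg)
        assert study.genotypes.shape[0] == 697
        assert study.genotypes.shape[1] == len(study.markers)
        assert set(np.unique(study.genotypes)) <= {0, 1, 2}
        # causal markers are nonsynonymous only
        nonsyn = set(
            study.markers.loc[
                study.markers["func_class"] == "nonsynonymous", "marker_id"
            ]
        )
        for endpoint in ("Q1", "Q2", "AFF"):
            assert set(truth.causal_markers(endpoint)["marker_id"]) <= nonsyn

    def test_empirical_maf_matches_generating_maf(self):
        cfg = _flat_config(
            n_individuals=50_000,
            n_genes=1,
            markers_per_gene={5: 1.0},
            maf_common_range=(0.2, 0.2),
            seed=5,
        )
        study, _ = simulate_exome(cfg)
        emp = study.genotypes.mean(axis=0) / 2.0
        assert np.all(np.abs(emp - 0.2) < 0.01)

    def test_hardy_weinberg_goodness_of_fit(self):
        cfg = _flat_config(
            n_individuals=50_000, n_genes=40, markers_per_gene={5: 1.0}, seed=7
        )
        study, _ = simulate_exome(cfg)
        pvals = []
        for j in range(study.n_markers):
            g = study.genotypes[:, j]
            obs = np.bincount(g, minlength=3)
            p_hat = obs @ np.array([0, 1, 2]) / (2 * len(g))
            exp = len(g) * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
            )
            stat = ((obs - exp) ** 2 / exp).sum()
            pvals.append(stats.chi2.sf(stat, 1))
        assert np.mean(np.asarray(pvals) > 0.001) >= 0.99

    def test_seed_determinism(self):
        cfg = ExomeConfig(n_genes=30, seed=42)
        s1, t1 = simulate_exome(cfg)
        s2, t2 = simulate_exome(ExomeConfig(n_genes=30, seed=42))
        np.testing.assert_array_equal(s1.genotypes, s2.genotypes)
        pd.testing.assert_frame_equal(s1.markers, s2.markers)
        for ep in t1.effects:
            pd.testing.assert_frame_equal(t1.effects[ep], t2.effects[ep])

    def test_invalid_distribution_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            ExomeConfig(markers_per_gene={})
        with pytest.raises(ConfigurationError):
            ExomeConfig(markers_per_gene={0: 1.0})
        with pytest.raises(ConfigurationError):
            ExomeConfig(maf_rare_range=(0.005, 0.02))
        with pytest.raises(ConfigurationError):
            ExomeConfig(n_genes=5, n_causal_genes={"Q1": 6})


class TestSimulatePhenotypes:
    def test_null_t_statistics_standard_normal(self):
        cfg = _flat_config(
            n_individuals=500, n_genes=400, markers_per_gene={5: 1.0}, seed=21
        )
        study, truth = simulate_exome(cfg)
        ph = simulate_phenotypes(study, truth, cfg, seed=22)
        C = ph[["Q2", "age", "sex", "smoking"]].to_numpy(float)
        res = linear_marginal_stats(study.genotypes, ph["Q1"].to_numpy(), C)
        t = res["stat"][res["ok"]]
        assert len(t) >= 1900
        assert stats.kstest(t, "norm").pvalue > 0.01

    def test_causal_beta_recovered_by_regression(self):
        cfg = _flat_config(
            n_individuals=10_000,
            n_genes=1,
            markers_per_gene={1: 1.0},
            maf_common_range=(0.3, 0.3),
            nonsyn_fraction=1.0,
            n_causal_genes={"Q1": 1, "Q2": 0, "AFF": 0},
            causal_beta_range=(0.5, 0.5),
            seed=31,
        )
        study, truth = simulate_exome(cfg)
        ph = simulate_phenotypes(study, truth, cfg, seed=32)
        C = ph[["Q2", "age", "sex", "smoking"]].to_numpy(float)
        res = linear_marginal_stats(study.genotypes[:, :1], ph["Q1"].to_numpy(), C)
        assert abs(res["beta"][0] - 0.5) < 0.05

    def test_prevalence_matches_config(self):
        cfg = _flat_config(n_individuals=10_000, n_genes=20, prevalence=0.3, seed=41)
        study, truth = simulate_exome(cfg)
        ph = simulate_phenotypes(study, truth, cfg, seed=42)
        assert abs(ph["AFF"].mean() - 0.3) < 0.02

    def test_unknown_truth_marker_rejected(self, exome):
        cfg, study, _ = exome
        from generank.types import TruthTable

        bad = TruthTable(
            effects={
                "Q1": pd.DataFrame(
                    {"gene_id": ["X"], "marker_id": ["NOPE"], "beta": [1.0]}
                )
            }
        )
        with pytest.raises(ValueError, match="unknown markers"):
            simulate_phenotypes(study, bad, cfg)


class TestCaseControl:
    def test_scenario_invariants(self):
        with pytest.raises(ConfigurationError):
            CaseControlScenario(n_causal_markers=3, markers_per_null_gene=2)
        with pytest.raises(ConfigurationError):
            CaseControlScenario(odds_ratio=0.8)

    def test_null_scenario_type_one_error(self):
        sc = CaseControlScenario(
            n_null_genes=1000,
            markers_per_null_gene=2,
            odds_ratio=1.0,
            n_cases=1000,
            seed=51,
        )
        study, y, truth = simulate_case_control(sc)
        assert truth.causal_genes("CC") == []
        res = logistic_marginal_stats(study.genotypes[:, : 2 * 1000], y, None)
        rej = np.mean(np.abs(res["stat"][res["ok"]]) > 1.96)
        assert abs(rej - 0.05) < 0.015

    def test_case_allele_frequency_matches_enumeration(self):
        p_case, p_control = case_control_genotype_distributions(0.2, 1.5, 0.01)
        expected_case_af = float(p_case @ np.arange(3)) / 2.0
        sc = CaseControlScenario(
            n_null_genes=1,
            markers_per_null_gene=1,
            n_causal_markers=1,
            causal_maf=0.2,
            odds_ratio=1.5,
            n_cases=50_000,
            n_controls=100,
            baseline_prevalence=0.01,
            seed=61,
        )
        G, _ = simulate_causal_gene(sc)
        emp = G[:50_000, 0].mean() / 2.0
        assert expected_case_af > 0.2  # risk allele enriched in cases
        assert abs(emp - expected_case_af) < 0.01
        # control AF only slightly depleted at 1% prevalence
        assert abs(float(p_control @ np.arange(3)) / 2.0 - 0.2) < 0.005

    def test_af_difference_monotone_in_odds_ratio(self):
        diffs = []
        for orr in (1.2, 1.3, 1.5, 1.7):
            sc = CaseControlScenario(
                n_null_genes=1,
                markers_per_null_gene=1,
                causal_maf=0.2,
                odds_ratio=orr,
                n_cases=10_000,
                seed=71,
            )
            G, _ = simulate_causal_gene(sc)
            case_af = G[: sc.n_cases, 0].mean() / 2.0
            ctrl_af = G[sc.n_cases :, 0].mean() / 2.0
            diffs.append(case_af - ctrl_af)
        assert np.all(np.diff(diffs) > 0)

    def test_status_and_determinism(self):
        sc = CaseControlScenario(n_null_genes=10, n_cases=50, seed=81)
        s1, y1, _ = simulate_case_control(sc)
        s2, y2, _ = simulate_case_control(sc)
        np.testing.assert_array_equal(s1.genotypes, s2.genotypes)
        np.testing.assert_array_equal(y1, y2)
        assert y1.sum() == 50 and len(y1) == 100
        np.testing.assert_array_equal(case_control_status(sc), y1)
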