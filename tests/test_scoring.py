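"""The four gene scores: examples, limits and cross-method invariants."""

import numpy as np
import pandas as pd
import pytest

from generank import penalized
from generank.datasets import study_as_dataset
from generank.scoring import (
    EndpointModel,
    MarginalResult,
    endpoint_model,
    fit_marginal,
    score_all_genes,
    score_hotelling,
    score_lasso,
    score_max,
    score_multivariate,
)

from conftest import make_study


def _marg(t_values):
    return [
        MarginalResult(f"m{i}", np.nan, np.nan, t, np.nan, ok=np.isfinite(t))
        for i, t in enumerate(t_values)
    ]


class TestEndpointModels:
    def test_standard_adjustments(self):
        assert endpoint_model("Q1") == EndpointModel(
            "Q1", "linear", ("Q2", "age", "sex", "smoking")
        )
        assert endpoint_model("Q2").covariates[0] == "Q1"
        aff = endpoint_model("AFF")
        assert aff.family == "logistic"
        assert aff.covariates == ("Q1", "Q2", "Q4", "age", "sex", "smoking")

    def test_unknown_endpoint(self):
        with pytest.raises(ValueError):
            endpoint_model("Q9")


class TestFitMarginal:
    def test_constant_marker_flagged(self, phenotypes, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            res = fit_marginal(
                np.zeros(len(phenotypes)), endpoint_model("Q1"), phenotypes, "mX"
            )
        assert not res.ok
        assert "zero variance" in caplog.text

    def test_rank_deficient_covariates_named(self, phenotypes):
        data = phenotypes.copy()
        data["Q2"] = 2.0 * data["age"]  # force collinearity
        g = np.tile([0, 1, 2], len(data) // 3 + 1)[: len(data)]
        with pytest.raises(ValueError, match="collinear"):
            fit_marginal(g, endpoint_model("Q1"), data)


class TestScoreMax:
    @pytest.mark.parametrize(
        "t_values, expected",
        [((1.2, -2.5, 0.3), 2.5), ((-1.7,), 1.7), ((2.0, -2.0), 2.0)],
    )
    def test_examples(self, t_values, expected):
        assert score_max(_marg(t_values)).score == pytest.approx(expected)

    def test_all_flagged_gives_missing(self):
        assert np.isnan(score_max(_marg([np.nan, np.nan])).score)


class TestScoreHotelling:
    def test_single_marker_is_t_squared(self):
        g = np.array([0, 1, 2, 0, 1, 1], dtype=float)[:, None]
        score = score_hotelling(_marg([3.0]), g)
        assert score.score == pytest.approx(9.0)
        assert score.df == 1

    def test_two_markers_explicit_inverse(self):
        # columns constructed with empirical correlation exactly 0.5
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
        score = score_hotelling(_marg([2.0, 2.0]), np.column_stack([a, b]))
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.5)
        assert score.score == pytest.approx((4 + 4 - 2 * 0.5 * 4) / (1 - 0.25))
        assert score.score == pytest.approx(16 / 3)

    def test_duplicated_column_equals_deduplicated(self):
        a = np.array([0, 1, 2, 0, 1, 0, 2, 1], dtype=float)
        dup = score_hotelling(_marg([2.0, 2.0]), np.column_stack([a, a]))
        single = score_hotelling(_marg([2.0]), a[:, None])
        assert dup.score == pytest.approx(single.score, abs=1e-10)
        assert dup.df == 1

    def test_flagged_marginal_excluded(self):
        a = np.array([0, 1, 2, 0, 1, 0], dtype=float)
        b = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        score = score_hotelling(_marg([2.0, np.nan]), np.column_stack([a, b]))
        assert score.score == pytest.approx(4.0)


class TestScoreMultivariate:
    def test_zero_variance_gene_scores_zero(self, phenotypes):
        G = np.zeros((len(phenotypes), 3))
        score = score_multivariate(G, endpoint_model("Q1"), phenotypes)
        assert score.score == 0.0 and score.df == 0

    def test_single_marker_ranking_matches_abs_t(self, datasets, phenotypes):
        ds = datasets["CR1%"]
        model = endpoint_model("Q1")
        singles = [g for g, cols in ds.gene_to_cols.items() if len(cols) == 1]
        assert len(singles) >= 5
        ms, mv = [], []
        for gene in singles:
            marg = fit_marginal(ds.gene_matrix(gene)[:, 0], model, phenotypes)
            ms.append(abs(marg.t))
            mv.append(score_multivariate(ds.gene_matrix(gene), model, phenotypes).score)
        assert np.array_equal(np.argsort(ms), np.argsort(mv))


@pytest.fixture(scope="module")
def gene(datasets):
    ds = datasets["CR1%"]
    widest = max(ds.gene_to_cols, key=lambda g: len(ds.gene_to_cols[g]))
    return ds.gene_matrix(widest)


class TestScoreLasso:
    @pytest.mark.parametrize("endpoint", ["Q1", "AFF"])
    def test_lambda_zero_equals_multivariate(self, gene, phenotypes, endpoint):
        model = endpoint_model(endpoint)
        mv = score_multivariate(gene, model, phenotypes)
        la = score_lasso(gene, model, phenotypes, lambda_override=0.0)
        assert la.score == pytest.approx(mv.score, rel=1e-6)

    def test_lambda_above_max_scores_zero(self, gene, phenotypes):
        la = score_lasso(gene, endpoint_model("Q1"), phenotypes, lambda_override=1e9)
        assert la.score == 0.0 and la.df == 0

    def test_covariates_unpenalized_at_lambda_max(self, gene, phenotypes):
        model = endpoint_model("Q1")
        y = phenotypes["Q1"].to_numpy(float)
        C = phenotypes[list(model.covariates)].to_numpy(float)
        Gs = (gene - gene.mean(0)) / gene.std(0)
        lmax = penalized.lambda_max(y, C, Gs, "linear")
        fit = penalized.lasso_path(y, C, gene, "linear", lambdas=np.array([lmax]))
        b0, bc, bg = fit.at(lmax)
        assert np.abs(bg).max() < 1e-10  # boundary float dust only
        null = penalized.null_fit(y, C, "linear")
        assert b0 == pytest.approx(null[0], abs=1e-6)
        np.testing.assert_allclose(bc, null[1:], atol=1e-6)

    def test_la_never_exceeds_mv(self, datasets, phenotypes):
        ds = datasets["CR5%"]
        model = endpoint_model("Q2")
        for gene in list(ds.gene_to_cols)[:10]:
            G = ds.gene_matrix(gene)
            mv = score_multivariate(G, model, phenotypes).score
            la = score_lasso(G, model, phenotypes, seed=5).score
            assert la <= mv + 1e-6

    def test_cv_folds_validation(self, gene, phenotypes):
        with pytest.raises(ValueError):
            score_lasso(gene, endpoint_model("Q1"), phenotypes, cv_folds=2)


class TestScoreAllGenes:
    def test_ms_scores_every_gene(self, datasets, phenotypes):
        ds = datasets["CR1%"]
        scores = score_all_genes(ds, endpoint_model("Q1"), "MS", phenotypes)
        assert len(scores) == len(ds.gene_to_cols)
        assert all(np.isfinite(s.score) for s in scores)
        assert [s.gene_id for s in scores] == list(ds.gene_to_cols)

    def test_lasso_deterministic_given_seed(self, datasets, phenotypes):
        ds = datasets["C5%"]
        a = score_all_genes(ds, endpoint_model("Q1"), "LA", phenotypes, seed=9)
        b = score_all_genes(ds, endpoint_model("Q1"), "LA", phenotypes, seed=9)
        assert [s.score for s in a] == [s.score for s in b]

    def test_supermarker_only_gene_in_cr_not_c(self):
        rng = np.random.default_rng(2)
        rare = (rng.random((3000, 4)) < 0.003).astype(int)
        common = rng.binomial(2, 0.3, size=(3000, 2))
        study = make_study(
            np.column_stack([rare, common]), ["G_rare"] * 4 + ["G_common"] * 2
        )
        from generank.datasets import build_analysis_dataset

        data = pd.DataFrame({"y": rng.normal(size=3000)})
        model = EndpointModel("y", "linear", ())
        cr = build_analysis_dataset(study, 0.01, True)
        c = build_analysis_dataset(study, 0.01, False)
        cr_genes = {s.gene_id for s in score_all_genes(cr, model, "MS", data)}
        c_genes = {s.gene_id for s in score_all_genes(c, model, "MS", data)}
        assert "G_rare" in cr_genes and "G_rare" not in c_genes

    def test_unknown_method_rejected(self, datasets, phenotypes):
        with pytest.raises(ValueError, match="unknown method"):
            score_all_genes(datasets["C1%"], endpoint_model("Q1"), "XX", phenotypes)

    def test_single_marker_genes_rank_identically_across_ms_ht_mv(
        self, datasets, phenotypes
    ):
        ds = datasets["C1%"]
        model = endpoint_model("Q1")
        singles = {g for g, cols in ds.gene_to_cols.items() if len(cols) == 1}
        out = {}
        for method in ("MS", "HT", "MV"):
            scores = score_all_genes(ds, model, method, phenotypes)
            vals = {s.gene_id: s.score for s in scores if s.gene_id in singles}
            genes = sorted(vals)
            out[method] = np.argsort([-vals[g] for g in genes], kind="stable")
        np.testing.assert_array_equal(out["MS"], out["HT"])
        np.testing.assert_array_equal(out["MS"], out["MV"])
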