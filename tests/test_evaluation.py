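"""Ranking, top-N recovery, scenario contrasts and permutation p-values."""

import numpy as np
import pandas as pd
import pytest

from generank.evaluation import (
    average_over_replicates,
    compare_scenarios_mixed_model,
    count_causal_topn,
    permutation_pvalues,
    rank_genes,
)
from generank.scoring import EndpointModel, GeneScore
from generank.datasets import study_as_dataset

from conftest import make_study


def _scores(values):
    return [
        GeneScore(f"g{i}", "MS", "Q1", v) for i, v in enumerate(values)
    ]


class TestRankGenes:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((5, 3, 9), (2, 3, 1)),
            ((4, 4), (1.5, 1.5)),
            ((7, np.nan, 2), (1, 3, 2)),
        ],
    )
    def test_examples(self, values, expected):
        ranked = rank_genes(_scores(values)).set_index("gene_id")
        for i, e in enumerate(expected):
            assert ranked.loc[f"g{i}", "rank"] == pytest.approx(e)

    def test_missing_flagged_and_all_missing_rejected(self):
        ranked = rank_genes(_scores((7, np.nan, 2)))
        assert ranked.set_index("gene_id").loc["g1", "missing"]
        with pytest.raises(ValueError):
            rank_genes(_scores((np.nan, np.nan)))

    def test_ranks_are_tie_adjusted_permutation(self, rng):
        values = rng.choice([1.0, 2.0, 3.5], size=40)
        ranked = rank_genes(_scores(values))
        assert ranked["rank"].sum() == pytest.approx(40 * 41 / 2)


class TestCountCausalTopn:
    def test_example_counts(self):
        ranked = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "rank": [4, 15, 600]}
        )
        counts = count_causal_topn(ranked, ["a", "b", "c"])
        assert counts == {10: 1, 20: 2, 50: 2, 100: 2, 200: 2, 500: 2}

    def test_all_beyond_500(self):
        ranked = pd.DataFrame({"gene_id": ["a"], "rank": [501]})
        assert all(v == 0 for v in count_causal_topn(ranked, ["a"]).values())

    def test_empty_truth_warns(self):
        ranked = pd.DataFrame({"gene_id": ["a"], "rank": [1]})
        with pytest.warns(UserWarning):
            counts = count_causal_topn(ranked, [])
        assert all(v == 0 for v in counts.values())

    def test_counts_nondecreasing_in_n(self, rng):
        genes = [f"g{i}" for i in range(300)]
        ranked = rank_genes(_scores(rng.normal(size=300)))
        causal = list(rng.choice(genes, 15, replace=False))
        counts = list(count_causal_topn(ranked, causal).values())
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_random_labels_match_hypergeometric_mean(self, rng):
        G, K, N, reps = 500, 10, 50, 300
        means = []
        for _ in range(reps):
            ranked = rank_genes(_scores(rng.normal(size=G)))
            causal = [f"g{i}" for i in rng.choice(G, K, replace=False)]
            means.append(count_causal_topn(ranked, causal, (N,))[N])
        expected = N * K / G
        var = N * (K / G) * (1 - K / G) * (G - N) / (G - 1)
        se = np.sqrt(var / reps)
        assert abs(np.mean(means) - expected) < 3 * se


class TestAverage:
    def test_mean_and_single_replicate(self):
        frame = pd.DataFrame(
            {
                "method": ["MS"] * 3,
                "cutoff": [0.01] * 3,
                "includes_rare": [True] * 3,
                "endpoint": ["Q1"] * 3,
                "replicate": [0, 1, 2],
                "topn": [10] * 3,
                "count": [2, 3, 4],
            }
        )
        out = average_over_replicates(frame)
        assert out["mean_count"].iloc[0] == pytest.approx(3.0)
        assert out["n_replicates"].iloc[0] == 3
        single = average_over_replicates(frame.iloc[:1])
        assert single["mean_count"].iloc[0] == 2


def _balanced_results(rng, methods=("MS", "HT", "MV", "LA"), reps=5, effects=None):
    effects = effects or {}
    rows = []
    for rep in range(reps):
        base = rng.normal(2.0, 0.4)
        for m in methods:
            for cutoff in (0.01, 0.05):
                for rare in (True, False):
                    mu = base + effects.get(m, 0.0)
                    rows.append(
                        dict(
                            method=m,
                            cutoff=cutoff,
                            includes_rare=rare,
                            endpoint="Q1",
                            replicate=rep,
                            topn=100,
                            count=mu + rng.normal(0, 0.2),
                        )
                    )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_contrast_equals_mean_paired_difference(self, rng):
        frame = _balanced_results(rng, methods=("MS", "HT"), effects={"MS": 0.5})
        out = compare_scenarios_mixed_model(frame)
        est = out.loc[out["contrast"] == "MS vs HT", "estimate"].iloc[0]
        key = ["replicate", "cutoff", "includes_rare"]
        ms = frame[frame.method == "MS"].sort_values(key)["count"].to_numpy()
        ht = frame[frame.method == "HT"].sort_values(key)["count"].to_numpy()
        assert est == pytest.approx((ms - ht).mean(), abs=1e-8)

    def test_identical_counts_give_zero_contrasts(self, rng):
        frame = _balanced_results(rng)
        frame["count"] = 3.0
        out = compare_scenarios_mixed_model(frame)
        assert np.allclose(out["estimate"], 0.0)

    def test_random_intercept_absorbs_per_replicate_shifts(self, rng):
        frame = _balanced_results(rng, effects={"MS": 0.3})
        out1 = compare_scenarios_mixed_model(frame)
        shifted = frame.copy()
        shifted["count"] += shifted["replicate"].map(
            {r: 10.0 * r for r in range(5)}
        )
        out2 = compare_scenarios_mixed_model(shifted)
        method_rows = out1["contrast"].str.contains(" vs ")
        np.testing.assert_allclose(
            out1.loc[method_rows, "estimate"],
            out2.loc[method_rows, "estimate"],
            atol=1e-7,
        )

    def test_unbalanced_design_rejected(self, rng):
        frame = _balanced_results(rng)
        with pytest.raises(ValueError, match="unbalanced"):
            compare_scenarios_mixed_model(frame.iloc[:-1])


class TestPermutation:
    def _single_marker_dataset(self, g):
        study = make_study(np.asarray(g, dtype=int)[:, None], ["G1"])
        return study_as_dataset(study)

    def test_strong_association_gives_minimum_p(self, rng):
        g = rng.binomial(2, 0.4, size=40)
        data = pd.DataFrame({"y": g + rng.normal(0, 0.05, size=40)})
        ds = self._single_marker_dataset(g)
        out = permutation_pvalues(
            ds, EndpointModel("y", "linear", ()), "MS", data, B=99, seed=1
        )
        assert out["perm_p"].iloc[0] == pytest.approx(0.01)

    def test_zero_statistic_gives_p_one(self):
        # y orthogonal to the centred genotype: observed |t| = 0, every
        # permutation is at least as extreme
        g = np.array([0, 1, 2, 0, 1, 2])
        y = np.array([1.0, 0, -1, -1, 0, 1])
        ds = self._single_marker_dataset(g)
        out = permutation_pvalues(
            ds, EndpointModel("y", "linear", ()), "MS", pd.DataFrame({"y": y}),
            B=19, seed=2,
        )
        assert out["perm_p"].iloc[0] == pytest.approx(1.0)

    def test_b_below_minimum_rejected(self, rng):
        ds = self._single_marker_dataset(rng.binomial(2, 0.3, 30))
        with pytest.raises(ValueError):
            permutation_pvalues(
                ds, EndpointModel("y", "linear", ()), "MS",
                pd.DataFrame({"y": rng.normal(size=30)}), B=10,
            )

    def test_p_on_achievable_grid(self, rng):
        g = rng.binomial(2, 0.3, size=50)
        data = pd.DataFrame({"y": rng.normal(size=50)})
        ds = self._single_marker_dataset(g)
        out = permutation_pvalues(
            ds, EndpointModel("y", "linear", ()), "MS", data, B=39, seed=3
        )
        p = out["perm_p"].iloc[0]
        assert p in {k / 40 for k in range(1, 41)}
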