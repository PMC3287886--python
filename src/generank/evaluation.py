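"""Ranking genes, counting causal recoveries, scenario contrasts, permutation p.

The pipeline's power surrogate is the number of truly causal genes among
the N best-ranked genes (N in {10, 20, 50, 100, 200, 500} by default),
averaged over phenotype replicates.  Analysis scenarios -- scoring method,
rare-variant cutoff, inclusion of rare variants -- are compared with a
linear mixed model treating the replicate as a random factor, fitted
separately per endpoint and per top-N cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import marginal_stats
from .scoring import EndpointModel, GeneScore, METHODS, score_all_genes
from .types import AnalysisDataset

logger = logging.getLogger(__name__)

DEFAULT_TOPN = (10, 20, 50, 100, 200, 500)


def rank_genes(scores: list[GeneScore] | pd.DataFrame) -> pd.DataFrame:
    """Rank genes by descending score; rank 1 is best.

    Ties receive the average rank.  Missing scores are ranked last (worst,
    averaged among themselves) and flagged in the ``missing`` column.
    """
    if isinstance(scores, pd.DataFrame):
        frame = scores[["gene_id", "score"]].copy()
    else:
        frame = pd.DataFrame(
            {"gene_id": [s.gene_id for s in scores], "score": [s.score for s in scores]}
        )
    values = frame["score"].to_numpy(dtype=float)
    missing = ~np.isfinite(values)
    if missing.all():
        raise ValueError("all gene scores are missing; nothing to rank")
    ranks = np.empty(len(values))
    present = ~missing
    ranks[present] = stats.rankdata(-values[present], method="average")
    n_present = int(present.sum())
    if missing.any():
        # missing genes share the average of the remaining (worst) positions
        worst = (n_present + 1 + len(values)) / 2.0
        ranks[missing] = worst
    out = frame.assign(rank=ranks, missing=missing)
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def count_causal_topn(
    ranked: pd.DataFrame,
    causal_genes: list[str],
    cutoffs: tuple[int, ...] = DEFAULT_TOPN,
) -> dict[int, int]:
    """Causal genes among the top N, for each N.

    A gene counts for cutoff N when its rank value is below N + 0.5, so a
    tie group straddling N contributes its members with average rank < N+0.5.
    """
    if not causal_genes:
        warnings.warn("empty causal gene list; all top-N counts are 0", stacklevel=2)
        return {n: 0 for n in cutoffs}
    causal = set(causal_genes)
    is_causal = ranked["gene_id"].isin(causal).to_numpy()
    ranks = ranked["rank"].to_numpy()
    return {n: int(((ranks < n + 0.5) & is_causal).sum()) for n in cutoffs}


def average_over_replicates(results: pd.DataFrame) -> pd.DataFrame:
    """Mean causal count per scenario cell over replicates.

    ``results`` must have columns method, cutoff, includes_rare, endpoint,
    replicate, topn, count.  Returns one row per scenario cell and top-N
    with the replicate count.
    """
    grouped = (
        results.groupby(["method", "cutoff", "includes_rare", "endpoint", "topn"])
        .agg(mean_count=("count", "mean"), n_replicates=("count", "size"))
        .reset_index()
    )
    return grouped


_METHOD_PAIRS = [
    ("MS", "HT"),
    ("MS", "MV"),
    ("MS", "LA"),
    ("HT", "MV"),
    ("HT", "LA"),
    ("MV", "LA"),
]


def _check_balance(frame: pd.DataFrame) -> None:
    keys = ["method", "cutoff", "includes_rare", "replicate"]
    cells = frame.groupby(keys).size()
    expected = int(np.prod([frame[k].nunique() for k in keys]))
    if len(cells) != expected or (cells != 1).any():
        counts = frame.groupby(keys[:3])["replicate"].nunique()
        missing = counts[counts < counts.max()]
        raise ValueError(
            "unbalanced scenario design; incomplete cells:\n" + missing.to_string()
        )


def compare_scenarios_mixed_model(
    results: pd.DataFrame,
    topn: tuple[int, ...] | None = None,
    endpoints: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mixed-model contrasts of analysis scenarios, per endpoint and top-N.

    Fits, for each (endpoint, N) stratum, a linear mixed model of the causal
    count on method (fixed, 4 levels), allele-frequency cutoff (fixed, 1% vs
    5%), rare-variant use (fixed, common-only vs with-rare) and the
    cutoff x use interaction, with a random intercept per simulation
    replicate (REML).  Emits the pairwise method contrasts (MS-HT, MS-MV,
    MS-LA, HT-MV, HT-LA, MV-LA), the cutoff contrast (1% - 5%), the use
    contrast (common-only - with-rare) and the interaction
    (difference-in-differences for cutoff=1% under common-only), each with
    SE and p-value.
    """
    import statsmodels.formula.api as smf

    frame = results.copy()
    if endpoints is None:
        endpoints = tuple(dict.fromkeys(frame["endpoint"]))
    if topn is None:
        topn = tuple(sorted(frame["topn"].unique()))

    rows = []
    for endpoint in endpoints:
        for n in topn:
            sub = frame[(frame["endpoint"] == endpoint) & (frame["topn"] == n)].copy()
            if sub.empty:
                continue
            _check_balance(sub)
            sub["cutoff_1pct"] = (sub["cutoff"] == 0.01).astype(int)
            sub["common_only"] = (~sub["includes_rare"]).astype(int)
            methods_present = [m for m in METHODS if m in set(sub["method"])]
            # constant factors would make the design singular; drop them
            terms = []
            if len(methods_present) > 1:
                terms.append(f"C(method, levels={methods_present})")
            has_cutoff = sub["cutoff_1pct"].nunique() > 1
            has_use = sub["common_only"].nunique() > 1
            if has_cutoff:
                terms.append("cutoff_1pct")
            if has_use:
                terms.append("common_only")
            if has_cutoff and has_use:
                terms.append("cutoff_1pct:common_only")
            formula = "count ~ " + (" + ".join(terms) if terms else "1")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, sub, groups=sub["replicate"])
                fit = model.fit(reml=True)
            params = fit.params
            names = list(fit.model.exog_names)

            def method_effect(m: str) -> np.ndarray:
                vec = np.zeros(len(names))
                col = f"C(method, levels={methods_present})[T.{m}]"
                if col in names:
                    vec[names.index(col)] = 1.0
                return vec

            def emit(label: str, vec: np.ndarray) -> None:
                # contrast on fixed effects only (pad for variance component)
                full = np.concatenate([vec, [0.0] * (len(fit.params) - len(vec))])
                est = float(full @ fit.params.to_numpy())
                se = float(np.sqrt(full @ fit.cov_params().to_numpy() @ full))
                z = est / se if se > 0 else np.nan
                rows.append(
                    {
                        "endpoint": endpoint,
                        "topn": n,
                        "contrast": label,
                        "estimate": est,
                        "se": se,
                        "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    }
                )

            for a, b in _METHOD_PAIRS:
                if a in methods_present and b in methods_present:
                    emit(f"{a} vs {b}", method_effect(a) - method_effect(b))
            has_ia = "cutoff_1pct:common_only" in names
            vec = np.zeros(len(names))
            if "cutoff_1pct" in names:
                # main effect evaluated at the average of the use factor
                vec[names.index("cutoff_1pct")] = 1.0
                if has_ia:
                    vec[names.index("cutoff_1pct:common_only")] = 0.5
                emit("AF=1% vs AF=5%", vec)
            vec = np.zeros(len(names))
            if "common_only" in names:
                vec[names.index("common_only")] = 1.0
                if has_ia:
                    vec[names.index("cutoff_1pct:common_only")] = 0.5
                emit("CV vs RV", vec)
            if has_ia:
                vec = np.zeros(len(names))
                vec[names.index("cutoff_1pct:common_only")] = 1.0
                emit("IA AF=1% and CV", vec)
    return pd.DataFrame(rows)


def permutation_pvalues(
    dataset: AnalysisDataset,
    model: EndpointModel,
    method: str,
    data: pd.DataFrame,
    B: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical permutation p-values per gene.

    Phenotype and covariate rows are permuted jointly (preserving their
    mutual association while breaking all genotype links); every gene sees
    the same B permutations.  p = (1 + #{permuted score >= observed}) /
    (B + 1).  Genes with a missing observed score get a missing p.
    """
    if B < 19:
        raise ValueError("B must be at least 19 for a meaningful empirical p-value")
    rng = np.random.default_rng(seed)
    observed = score_all_genes(dataset, model, method, data, seed=seed)
    obs = np.array([s.score for s in observed])
    exceed = np.zeros(len(obs))
    for _ in range(B):
        perm = rng.permutation(len(data))
        permuted = data.iloc[perm].reset_index(drop=True)
        perm_scores = score_all_genes(dataset, model, method, permuted, seed=seed)
        ps = np.array([s.score for s in perm_scores])
        with np.errstate(invalid="ignore"):
            exceed += (ps >= obs).astype(float)
    p = (1.0 + exceed) / (B + 1.0)
    p[~np.isfinite(obs)] = np.nan
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in observed],
            "score": obs,
            "perm_p": p,
        }
    )
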