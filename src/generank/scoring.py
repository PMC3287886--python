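"""Gene-wise scores: MS, HT, MV and LA.

Every endpoint is analysed with an additive genetic model and its standard
covariate adjustment: Q1 is linear adjusted for Q2, age, sex, smoking; Q2
linear adjusted for Q1, age, sex, smoking; AFF logistic adjusted for Q1,
Q2, Q4, age, sex, smoking.

* MS -- maximum of the absolute marginal regression statistics over the
  gene's markers (supermarker included), unadjusted for marker count.
* HT -- Hotelling's T^2: the marginal statistics combined through the
  Moore-Penrose pseudo-inverse of the markers' genotype correlation matrix.
* MV -- likelihood-ratio test of the joint model with all of the gene's
  markers against the covariates-only null model.
* LA -- deviance improvement of an L1-penalised joint genetic model
  (covariates unpenalised, lambda by K-fold cross-validation) over the null
  model.

Genes are ranked by the raw scores; the chi-square p-values stored for HT
and MV are informational.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import penalized
from ._glm import (
    add_intercept,
    linear_deviance_pair,
    logistic_fit,
    logistic_loglik,
    marginal_stats,
    prune_collinear,
)
from .types import AnalysisDataset

logger = logging.getLogger(__name__)

METHODS = ("MS", "HT", "MV", "LA")

_STANDARD_MODELS = {
    "Q1": ("linear", ["Q2", "age", "sex", "smoking"]),
    "Q2": ("linear", ["Q1", "age", "sex", "smoking"]),
    "AFF": ("logistic", ["Q1", "Q2", "Q4", "age", "sex", "smoking"]),
}


@dataclass(frozen=True)
class EndpointModel:
    """Response column, regression family and covariate adjustment set."""

    endpoint: str
    family: str  # 'linear' | 'logistic'
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))


def endpoint_model(endpoint: str) -> EndpointModel:
    """The standard model for Q1, Q2 or AFF."""
    try:
        family, covs = _STANDARD_MODELS[endpoint]
    except KeyError:
        raise ValueError(f"no standard model for endpoint {endpoint!r}") from None
    return EndpointModel(endpoint, family, tuple(covs))


@dataclass
class MarginalResult:
    """Single-marker regression result (Wald statistic ``t = beta/se``)."""

    marker_id: str
    beta: float
    se: float
    t: float
    p: float
    ok: bool = True


@dataclass
class GeneScore:
    gene_id: str
    method: str
    endpoint: str
    score: float
    df: int | None = None
    p: float | None = None

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.score)


def _design(model: EndpointModel, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
    y = data[model.endpoint].to_numpy(dtype=float)
    if not model.covariates:
        return y, None
    C = data[list(model.covariates)].to_numpy(dtype=float)
    X0 = add_intercept(C, len(y))
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        # identify which covariate columns are linearly dependent
        bad = []
        for k, name in enumerate(model.covariates):
            sub = np.delete(X0, k + 1, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X0):
                bad.append(name)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    return y, C


def fit_marginal(
    marker: np.ndarray,
    model: EndpointModel,
    data: pd.DataFrame,
    marker_id: str = "marker",
) -> MarginalResult:
    """Marginal additive single-marker fit with covariate adjustment.

    A constant marker or a non-converged (separated) logistic fit yields a
    flagged result with missing statistics rather than an exception.
    """
    g = np.asarray(marker, dtype=float)
    if g.std() == 0:
        logger.warning("marker %s has zero variance; skipped", marker_id)
        return MarginalResult(marker_id, np.nan, np.nan, np.nan, np.nan, ok=False)
    y, C = _design(model, data)
    res = marginal_stats(g[:, None], y, C, model.family)
    ok = bool(res["ok"][0])
    if not ok:
        logger.warning("marginal fit failed for marker %s (separation?)", marker_id)
    return MarginalResult(
        marker_id,
        float(res["beta"][0]),
        float(res["se"][0]),
        float(res["stat"][0]),
        float(res["p"][0]),
        ok=ok,
    )


def _usable(marginals: list[MarginalResult]) -> list[MarginalResult]:
    return [m for m in marginals if m.ok and np.isfinite(m.t)]


def score_max(
    marginals: list[MarginalResult], gene_id: str = "", endpoint: str = ""
) -> GeneScore:
    """Gene score = max over markers of |t| (no marker-count adjustment)."""
    usable = _usable(marginals)
    if not usable:
        return GeneScore(gene_id, "MS", endpoint, np.nan)
    score = max(abs(m.t) for m in usable)
    return GeneScore(gene_id, "MS", endpoint, float(score))


def score_hotelling(
    marginals: list[MarginalResult],
    genotype_submatrix: np.ndarray,
    gene_id: str = "",
    endpoint: str = "",
) -> GeneScore:
    """Hotelling's T^2 = t' R^- t with R the genotype correlation matrix.

    ``genotype_submatrix`` holds the gene's marker columns in the order of
    ``marginals``.  Flagged marginals and zero-variance columns are dropped
    from both t and R; the pseudo-inverse handles singular R, with df =
    rank(R) and a chi-square reference distribution.
    """
    G = np.asarray(genotype_submatrix, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    keep = [
        j
        for j, m in enumerate(marginals)
        if m.ok and np.isfinite(m.t) and G[:, j].std() > 0
    ]
    if not keep:
        return GeneScore(gene_id, "HT", endpoint, np.nan)
    t = np.array([marginals[j].t for j in keep])
    Gk = G[:, keep]
    if len(keep) == 1:
        R = np.array([[1.0]])
    else:
        R = np.corrcoef(Gk, rowvar=False)
    R_pinv = np.linalg.pinv(R, rcond=1e-10)
    score = float(t @ R_pinv @ t)
    df = int(np.linalg.matrix_rank(R, tol=1e-10))
    p = float(stats.chi2.sf(score, df)) if df > 0 else np.nan
    return GeneScore(gene_id, "HT", endpoint, score, df=df, p=p)


def score_multivariate(
    gene_markers: np.ndarray,
    model: EndpointModel,
    data: pd.DataFrame,
    gene_id: str = "",
) -> GeneScore:
    """Likelihood-ratio test of all gene markers jointly against the null.

    Gene columns are pruned for collinearity (deterministically, in marker
    order) before fitting; score = 2*(loglik_full - loglik_null) with df =
    number of retained columns.  For linear models this is
    n*log(RSS_null/RSS_full) under the normal likelihood.
    """
    G = np.asarray(gene_markers, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y, C = _design(model, data)
    kept = prune_collinear(G, C)
    if kept.size == 0:
        return GeneScore(gene_id, "MV", endpoint=model.endpoint, score=0.0, df=0, p=1.0)
    Gk = G[:, kept]
    if model.family == "linear":
        rss0, rss1, n = linear_deviance_pair(y, C, Gk)
        score = n * math.log(rss0 / rss1) if rss1 > 0 else np.inf
    else:
        X0 = add_intercept(C, len(y))
        b0, _, conv0 = logistic_fit(X0, y)
        b1, _, conv1 = logistic_fit(np.column_stack([X0, Gk]), y)
        if not (conv0 and conv1):
            logger.warning("MV logistic fit failed to converge for gene %s", gene_id)
            return GeneScore(gene_id, "MV", model.endpoint, np.nan)
        score = 2.0 * (logistic_loglik(np.column_stack([X0, Gk]), y, b1)
                       - logistic_loglik(X0, y, b0))
    df = int(kept.size)
    score = max(float(score), 0.0)
    return GeneScore(gene_id, "MV", model.endpoint, score, df=df,
                     p=float(stats.chi2.sf(score, df)))


def score_lasso(
    gene_markers: np.ndarray,
    model: EndpointModel,
    data: pd.DataFrame,
    cv_folds: int = 10,
    seed: int = 0,
    gene_id: str = "",
    lambda_override: float | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> GeneScore:
    """Deviance improvement of the L1-penalised joint genetic model.

    Only genetic columns are shrunk; lambda is chosen by ``cv_folds``-fold
    cross-validated deviance on a geometric lambda path (fold assignment
    seeded, hence deterministic).  ``lambda_override`` bypasses CV and
    evaluates the path at the given penalty; 0 recovers the unpenalised
    joint fit and anything above lambda_max gives score 0.
    """
    if cv_folds < 3:
        raise ValueError("cv_folds must be >= 3")
    G = np.asarray(gene_markers, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y, C = _design(model, data)
    nonconst = np.flatnonzero(G.std(axis=0) > 0)
    if nonconst.size == 0:
        return GeneScore(gene_id, "LA", model.endpoint, 0.0, df=0)
    Gk = G[:, nonconst]

    mean = Gk.mean(axis=0)
    sd = Gk.std(axis=0)
    lmax = penalized.lambda_max(y, C, (Gk - mean) / sd, model.family)

    if lambda_override is not None:
        lam = float(lambda_override)
        if lam >= lmax > 0 or lmax <= 0:
            lambdas = np.array([max(lam, lmax, 1e-12)])
        else:
            path = lmax * np.logspace(0, np.log10(max(lam / lmax, 1e-6)), 30)
            lambdas = np.unique(np.append(path, lam))
    else:
        if lmax <= 0:
            return GeneScore(gene_id, "LA", model.endpoint, 0.0, df=0)
        lambdas = lmax * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)
        lam = penalized.cv_choose_lambda(y, C, Gk, model.family, lambdas, cv_folds, seed)

    fit = penalized.lasso_path(y, C, Gk, model.family, lambdas=lambdas)
    b0, bc, bg = fit.at(lam)
    # coefficients at the soft-threshold boundary can carry float dust
    bg = np.where(np.abs(bg) < 1e-10, 0.0, bg)
    n_active = int(np.count_nonzero(bg))
    if n_active == 0:
        return GeneScore(gene_id, "LA", model.endpoint, 0.0, df=0)

    null_b = penalized.null_fit(y, C, model.family)
    dev_null = penalized.model_deviance(
        y, C, Gk, null_b[0], null_b[1:], np.zeros(Gk.shape[1]), model.family
    )
    dev_pen = penalized.model_deviance(y, C, Gk, b0, bc, bg, model.family)
    if model.family == "linear":
        score = len(y) * math.log(dev_null / dev_pen) if dev_pen > 0 else np.inf
    else:
        score = dev_null - dev_pen
    return GeneScore(gene_id, "LA", model.endpoint, max(float(score), 0.0), df=n_active)


def score_all_genes(
    dataset: AnalysisDataset,
    model: EndpointModel,
    method: str,
    data: pd.DataFrame,
    seed: int = 0,
    **kwargs,
) -> list[GeneScore]:
    """One score per gene of the dataset, in stable gene order.

    Per-gene failures are downgraded to missing scores; the scan never
    aborts.  For MS and HT the marginal fits are computed in one vectorised
    pass over all dataset columns.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    y, C = _design(model, data)
    scores: list[GeneScore] = []

    if method in ("MS", "HT"):
        res = marginal_stats(dataset.genotypes, y, C, model.family)
        marker_ids = dataset.markers["marker_id"].tolist()
        all_marginals = [
            MarginalResult(
                marker_ids[j],
                float(res["beta"][j]),
                float(res["se"][j]),
                float(res["stat"][j]),
                float(res["p"][j]),
                ok=bool(res["ok"][j]),
            )
            for j in range(dataset.n_markers)
        ]
        for gene, cols in dataset.gene_to_cols.items():
            marginals = [all_marginals[j] for j in cols]
            if method == "MS":
                scores.append(score_max(marginals, gene, model.endpoint))
            else:
                scores.append(
                    score_hotelling(
                        marginals, dataset.genotypes[:, cols], gene, model.endpoint
                    )
                )
        return scores

    for i, (gene, cols) in enumerate(dataset.gene_to_cols.items()):
        G = dataset.genotypes[:, cols]
        try:
            if method == "MV":
                scores.append(score_multivariate(G, model, data, gene_id=gene))
            else:
                gene_seed = int(
                    np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31
                )
                scores.append(
                    score_lasso(G, model, data, seed=gene_seed, gene_id=gene, **kwargs)
                )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("scoring gene %s failed: %s", gene, exc)
            scores.append(GeneScore(gene, method, model.endpoint, np.nan))
    return scores


def scores_to_frame(scores: list[GeneScore], dataset_label: str | None = None) -> pd.DataFrame:
    """Tabular view of a list of gene scores."""
    frame = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "method": [s.method for s in scores],
            "endpoint": [s.endpoint for s in scores],
            "score": np.array([s.score for s in scores], dtype=float),
            "df": np.array(
                [np.nan if s.df is None else s.df for s in scores], dtype=float
            ),
            "p": np.array(
                [np.nan if s.p is None else s.p for s in scores], dtype=float
            ),
        }
    )
    if dataset_label is not None:
        frame.insert(0, "dataset", dataset_label)
    return frame
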