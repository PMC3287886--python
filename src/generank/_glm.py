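"""Regression kernels behind the scoring module.

Marginal single-marker fits are the pipeline's hot loop (every marker of
every gene, for every permutation or simulation replicate), so they are
implemented directly in numpy:

* linear fits use the Frisch-Waugh-Lovell projection -- residualise the
  response and all marker columns on the covariates once, then every
  marker's OLS slope, SE and t follow from vectorised inner products;
  results are exact OLS (validated against statsmodels in the test suite);
* logistic fits use Newton-Raphson on the full likelihood; the
  intercept-plus-marker case (no covariates) is vectorised across markers.

Joint (multi-marker) fits delegate to closed-form least squares or the same
Newton solver.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

MAX_ABS_LOGISTIC_BETA = 25.0  # beyond this, treat the fit as separated


def add_intercept(C: np.ndarray | None, n: int) -> np.ndarray:
    if C is None or C.size == 0:
        return np.ones((n, 1))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


# ---------------------------------------------------------------------------
# linear marginals (exact OLS through FWL)


def linear_marginal_stats(
    G: np.ndarray, y: np.ndarray, C: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """OLS slope, SE, t and two-sided p for each column of ``G``.

    Equivalent to fitting ``y ~ 1 + C + g`` per column ``g``; the covariate
    block is projected out once with a QR decomposition.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X0 = add_intercept(C, n)
    Q, _ = np.linalg.qr(X0)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    yy = float(y_r @ y_r)
    df = n - X0.shape[1] - 1

    ok = (gg > 0) & (df > 0)
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[ok] = gy[ok] / gg[ok]
        rss = np.maximum(yy - beta[ok] ** 2 * gg[ok], 0.0)
        sigma2 = rss / df
        se[ok] = np.sqrt(sigma2 / gg[ok])
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    ok = ok & np.isfinite(t)
    return {"beta": beta, "se": se, "stat": t, "p": p, "ok": ok, "df_resid": df}


# ---------------------------------------------------------------------------
# logistic fits


def logistic_fit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic MLE.

    Returns ``(beta, cov, converged)`` where ``cov`` is the inverse observed
    information.  Separation (diverging coefficients) or a singular
    information matrix yields ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    p_bar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[0] = np.log(p_bar / (1 - p_bar))  # warm-start the intercept
    cov = np.full((X.shape[1], X.shape[1]), np.nan)
    ll = logistic_loglik(X, y, beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, cov, False
        # step-halving line search guards against Newton overshoot
        factor = 1.0
        for _ in range(12):
            candidate = beta + factor * step
            ll_new = logistic_loglik(X, y, candidate)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta = beta + factor * step
        ll = logistic_loglik(X, y, beta)
        if np.abs(beta).max() > MAX_ABS_LOGISTIC_BETA:
            return beta, cov, False
        if np.abs(factor * step).max() < tol:
            break
    else:
        return beta, cov, False
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, cov, False
    return beta, cov, True


def logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.asarray(X, float) @ beta
    # log-likelihood written in the numerically stable log1p(exp) form
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _logistic_marginals_simple(G: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised intercept+marker logistic fits across all columns of G."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    p_bar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    a = np.full(m, np.log(p_bar / (1 - p_bar)))
    b = np.zeros(m)
    active = np.ones(m, dtype=bool)
    ok = np.ones(m, dtype=bool)
    se = np.full(m, np.nan)

    # constant columns can never be fit
    const = G.std(axis=0) == 0
    ok[const] = False
    active[const] = False

    h00 = h01 = h11 = np.zeros(m)
    for _ in range(60):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Ga = G[:, idx]
        eta = a[idx][None, :] + Ga * b[idx][None, :]
        mu = expit(eta)
        W = mu * (1 - mu)
        g0 = (y[:, None] - mu).sum(axis=0)
        g1 = np.einsum("ij,ij->j", Ga, y[:, None] - mu)
        h00 = W.sum(axis=0)
        h01 = np.einsum("ij,ij->j", W, Ga)
        h11 = np.einsum("ij,ij,ij->j", W, Ga, Ga)
        det = h00 * h11 - h01 * h01
        bad = det <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (h11 * g0 - h01 * g1) / det
            db = (h00 * g1 - h01 * g0) / det
        a[idx] += np.where(bad, 0.0, da)
        b[idx] += np.where(bad, 0.0, db)
        diverged = bad | (np.abs(b[idx]) > MAX_ABS_LOGISTIC_BETA)
        ok[idx[diverged]] = False
        active[idx[diverged]] = False
        converged = (np.abs(da) < 1e-10) & (np.abs(db) < 1e-10) & ~diverged
        done = idx[converged]
        if done.size:
            # SE of the slope from the 2x2 observed information at the MLE
            sub = np.searchsorted(idx, done)
            se[done] = np.sqrt(h00[sub] / (h00[sub] * h11[sub] - h01[sub] ** 2))
            active[done] = False
    ok[active] = False  # never converged

    stat = np.where(ok, b / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    beta_out = np.where(ok, b, np.nan)
    return {"beta": beta_out, "se": se, "stat": stat, "p": p, "ok": ok, "df_resid": n - 2}


def logistic_marginal_stats(
    G: np.ndarray, y: np.ndarray, C: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Wald slope statistics of ``y ~ 1 + C + g`` logistic fits per column."""
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(y, dtype=float)
    if C is None or np.size(C) == 0:
        return _logistic_marginals_simple(G, y)

    n, m = G.shape
    X0 = add_intercept(C, n)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)
    for j in range(m):
        g = G[:, j]
        if g.std() == 0:
            continue
        X = np.column_stack([X0, g])
        b, cov, converged = logistic_fit(X, y)
        if not converged:
            continue
        beta[j] = b[-1]
        se[j] = np.sqrt(cov[-1, -1])
        ok[j] = True
    stat = beta / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return {"beta": beta, "se": se, "stat": stat, "p": p, "ok": ok, "df_resid": n - X0.shape[1] - 1}


def marginal_stats(
    G: np.ndarray, y: np.ndarray, C: np.ndarray | None, family: str
) -> dict[str, np.ndarray]:
    """Dispatch marginal fits by family ('linear' or 'logistic')."""
    if family == "linear":
        return linear_marginal_stats(G, y, C)
    if family == "logistic":
        return logistic_marginal_stats(G, y, C)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# joint fits for the likelihood-ratio scores


def linear_deviance_pair(
    y: np.ndarray, C: np.ndarray | None, G: np.ndarray
) -> tuple[float, float, int]:
    """(2*loglik difference, RSS ratio score inputs) for linear LRT.

    Returns ``(rss_null, rss_full, n)`` for the OLS fits of
    ``y ~ 1 + C`` and ``y ~ 1 + C + G``.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X0 = add_intercept(C, n)
    r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
    X1 = np.column_stack([X0, np.asarray(G, dtype=float)])
    r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
    return float(r0 @ r0), float(r1 @ r1), n


def prune_collinear(
    G: np.ndarray, C: np.ndarray | None, tol: float = 1e-10
) -> np.ndarray:
    """Indices of gene columns retained after greedy collinearity pruning.

    Columns are visited in marker order; a column is dropped when its
    residual variance after projection on the intercept, covariates and the
    previously retained columns falls below ``tol`` times its own variance
    (zero-variance columns are dropped outright).
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    basis = add_intercept(C, n)
    Q, _ = np.linalg.qr(basis)
    kept: list[int] = []
    for j in range(G.shape[1]):
        g = G[:, j]
        v0 = float(g @ g)
        if v0 == 0 or g.std() == 0:
            continue
        r = g - Q @ (Q.T @ g)
        if float(r @ r) <= tol * v0:
            continue
        kept.append(j)
        # extend the orthonormal basis with the new column
        r_norm = np.linalg.norm(r)
        Q = np.column_stack([Q, r / r_norm])
    return np.array(kept, dtype=int)
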