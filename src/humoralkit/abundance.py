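"""Compositional differential abundance via Dirichlet regression.

The model is the common-parameterization Dirichlet GLM: each category's
concentration gets a log link, ``log alpha_ic = x_i . beta_c``, fitted by
quasi-Newton maximum likelihood with the analytic digamma gradient.
Group effects are tested with a likelihood-ratio test (chi-square, one
degree of freedom per category) plus per-category Wald tests adjusted by
Benjamini–Hochberg. A Wilcoxon signed-rank helper covers the paired
tumor-vs-adjacent enrichment comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

MAX_ITER = 500
GTOL = 1e-8


class OptimizerFailure(RuntimeError):
    pass


# --------------------------------------------------------------------------
# composition handling
# --------------------------------------------------------------------------

def proportions_from_counts(
    counts: pd.DataFrame, category_cols: Sequence[str]
) -> pd.DataFrame:
    """Smoothed proportions strictly inside the simplex.

    Applies ``y* = (y*(n-1) + 1/K) / n`` per row, where ``n`` is the row's
    total cell count and ``K`` the number of categories, so zero counts
    map into (0, 1) and rows still sum to 1. Rows with zero total are
    dropped (logged).
    """
    category_cols = list(category_cols)
    values = counts[category_cols].to_numpy(dtype=float)
    totals = values.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.info("proportions_from_counts: dropping %d zero-count rows",
                    int((~keep).sum()))
    values, totals = values[keep], totals[keep]
    k = len(category_cols)
    y = values / totals[:, None]
    y_star = (y * (totals[:, None] - 1.0) + 1.0 / k) / totals[:, None]
    out = counts.loc[keep].copy()
    out[category_cols] = y_star
    return out.reset_index(drop=True)


def dirichlet_loglik(Y: np.ndarray, alpha: np.ndarray) -> float:
    """Sum of Dirichlet log densities; alpha may be (K,) or (n, K)."""
    Y = np.asarray(Y, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), Y.shape)
    return float(
        np.sum(
            special.gammaln(alpha.sum(axis=1))
            - special.gammaln(alpha).sum(axis=1)
            + ((alpha - 1.0) * np.log(Y)).sum(axis=1)
        )
    )


def composition_from_annotation(
    annotation: pd.DataFrame,
    category_col: str = "cluster",
    sample_col: str = "sample",
    meta_cols: Sequence[str] = ("patient", "tissue", "timepoint", "response"),
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-sample category counts with carried sample metadata.

    Returns ``(table, category_columns)``; the table has one row per
    sample, the metadata columns, and one count column per category.
    """
    counts = (
        annotation.groupby([sample_col, category_col], sort=True)
        .size()
        .unstack(category_col, fill_value=0)
    )
    category_cols = [str(c) for c in counts.columns]
    counts.columns = category_cols
    meta = annotation[[sample_col, *meta_cols]].drop_duplicates(sample_col)
    table = meta.merge(counts.reset_index(), on=sample_col).reset_index(drop=True)
    return table, category_cols


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class DirichletFit:
    beta: np.ndarray  # (K categories, P covariates) on the log-alpha scale
    loglik: float
    converged: bool
    n_iter: int
    covariate_names: Tuple[str, ...]
    category_names: Tuple[str, ...]
    Y: np.ndarray
    X: np.ndarray

    def alpha(self, x: np.ndarray) -> np.ndarray:
        """Concentration vector for covariate vector(s) *x*."""
        return np.exp(np.atleast_2d(x) @ self.beta.T)

    def mean_proportions(self, x: np.ndarray) -> np.ndarray:
        a = self.alpha(x)
        return np.squeeze(a / a.sum(axis=1, keepdims=True))


def _neg_loglik_and_grad(
    flat_beta: np.ndarray, Y: np.ndarray, X: np.ndarray, logY: np.ndarray
) -> Tuple[float, np.ndarray]:
    n, k = Y.shape
    p = X.shape[1]
    beta = flat_beta.reshape(k, p)
    alpha = np.exp(X @ beta.T)  # (n, K)
    a0 = alpha.sum(axis=1)
    ll = np.sum(special.gammaln(a0) - special.gammaln(alpha).sum(axis=1)
                + ((alpha - 1.0) * logY).sum(axis=1))
    # d ll / d beta_ck = sum_i x_ik * alpha_ic * (psi(a0_i) - psi(alpha_ic) + log y_ic)
    core = alpha * (special.digamma(a0)[:, None] - special.digamma(alpha) + logY)
    grad = core.T @ X  # (K, P)
    return -ll, -grad.ravel()


def _initial_beta(Y: np.ndarray, X: np.ndarray,
                  intercept_col: int) -> np.ndarray:
    """Zeros except method-of-moments intercepts."""
    k, p = Y.shape[1], X.shape[1]
    m = Y.mean(axis=0)
    v = Y.var(axis=0, ddof=1) if Y.shape[0] > 1 else np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = m * (1.0 - m) / v - 1.0
    s = s[np.isfinite(s) & (s > 0)]
    precision = float(np.median(s)) if s.size else float(k)
    beta = np.zeros((k, p))
    beta[:, intercept_col] = np.log(np.clip(m * precision, 1e-8, None))
    return beta


def fit_dirichlet_regression(
    proportions: pd.DataFrame | np.ndarray,
    design: pd.DataFrame | np.ndarray,
    category_cols: Optional[Sequence[str]] = None,
    max_iter: int = MAX_ITER,
    gtol: float = GTOL,
) -> DirichletFit:
    """Maximum-likelihood Dirichlet regression with a log link on alphas.

    *proportions* rows must lie strictly inside the simplex (see
    :func:`proportions_from_counts`); *design* should include an intercept
    column named ``intercept`` (one is used if present, else column 0 is
    treated as the intercept for initialization).
    """
    if isinstance(proportions, pd.DataFrame):
        category_cols = list(category_cols or proportions.columns)
        Y = proportions[category_cols].to_numpy(dtype=float)
        cat_names = tuple(category_cols)
    else:
        Y = np.asarray(proportions, dtype=float)
        cat_names = tuple(category_cols or [f"cat{i}" for i in range(Y.shape[1])])
    if isinstance(design, pd.DataFrame):
        cov_names = tuple(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        cov_names = tuple(f"x{i}" for i in range(X.shape[1]))

    if np.any(Y <= 0) or np.any(Y >= 1):
        raise ValueError("proportions must be strictly inside (0, 1)")
    logY = np.log(Y)
    intercept_col = cov_names.index("intercept") if "intercept" in cov_names else 0
    beta0 = _initial_beta(Y, X, intercept_col)

    res = optimize.minimize(
        _neg_loglik_and_grad,
        beta0.ravel(),
        args=(Y, X, logY),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    beta = res.x.reshape(Y.shape[1], X.shape[1])
    # L-BFGS-B occasionally reports ABNORMAL line searches at an already
    # stationary point; accept the solution when the gradient is flat.
    _, grad = _neg_loglik_and_grad(res.x, Y, X, logY)
    converged = bool(res.success) or float(np.abs(grad).max()) < 1e-4 * max(len(Y), 1)
    fit = DirichletFit(
        beta=beta,
        loglik=-float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
        covariate_names=cov_names,
        category_names=cat_names,
        Y=Y,
        X=X,
    )
    if not fit.converged:
        logger.warning("Dirichlet regression did not converge after %d iterations: %s",
                       fit.n_iter, res.message)
    return fit


def _observed_information(fit: DirichletFit) -> np.ndarray:
    """Numerical Hessian of the negative log-likelihood at the optimum."""
    logY = np.log(fit.Y)
    flat = fit.beta.ravel()
    n_par = flat.size
    eps = 1e-5
    hess = np.empty((n_par, n_par))
    for j in range(n_par):
        hi = flat.copy()
        lo = flat.copy()
        hi[j] += eps
        lo[j] -= eps
        _, g_hi = _neg_loglik_and_grad(hi, fit.Y, fit.X, logY)
        _, g_lo = _neg_loglik_and_grad(lo, fit.Y, fit.X, logY)
        hess[:, j] = (g_hi - g_lo) / (2.0 * eps)
    return 0.5 * (hess + hess.T)


# --------------------------------------------------------------------------
# testing
# --------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end  # 1-based rank of this p-value
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def lrt_and_fdr(
    full: DirichletFit,
    null: DirichletFit,
    tested_covariate: str,
    tol: float = 1e-6,
) -> Tuple[pd.DataFrame, dict]:
    """Likelihood-ratio test for a covariate plus per-category Wald/BH table.

    Returns ``(per_category_table, global_test)`` where the global test is
    ``{"lrt_stat", "df", "p_value"}``. Per-category log2 fold changes are
    taken on the fitted mean-proportion scale between covariate values 1
    and 0 (all other covariates at 0, intercept at 1).
    """
    if not (full.converged and null.converged):
        raise OptimizerFailure("refusing LRT on unconverged fits")
    if full.loglik < null.loglik - tol:
        raise OptimizerFailure(
            f"nested-model violation: loglik(full)={full.loglik:.6f} < "
            f"loglik(null)={null.loglik:.6f}"
        )
    k = len(full.category_names)
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    global_test = {
        "lrt_stat": stat,
        "df": k,
        "p_value": float(stats.chi2.sf(stat, df=k)) if stat > 0 else 1.0,
    }

    j = full.covariate_names.index(tested_covariate)
    intercept_col = (full.covariate_names.index("intercept")
                     if "intercept" in full.covariate_names else 0)
    x0 = np.zeros(len(full.covariate_names))
    x0[intercept_col] = 1.0
    x1 = x0.copy()
    x1[j] = 1.0
    mean0 = full.mean_proportions(x0)
    mean1 = full.mean_proportions(x1)
    log2fc = np.log2(mean1 / mean0)

    # Wald per-category on the tested coefficient
    p = len(full.covariate_names)
    info = _observed_information(full)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(k, p)[:, j]
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = full.beta[:, j] / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p = np.where(np.isfinite(wald_p), wald_p, 1.0)

    table = pd.DataFrame(
        {
            "category": full.category_names,
            "log2fc": log2fc,
            "beta": full.beta[:, j],
            "se": se,
            "wald_p": wald_p,
            "fdr": bh_adjust(wald_p),
            "lrt_stat": stat,
            "df": k,
            "lrt_p": global_test["p_value"],
        }
    )
    return table, global_test


def differential_abundance(
    counts: pd.DataFrame,
    category_cols: Sequence[str],
    group_col: str = "response",
    reference: str = "NR",
) -> Tuple[pd.DataFrame, dict]:
    """Convenience wrapper: smoothing, full/null fits, LRT + BH table."""
    props = proportions_from_counts(counts, category_cols)
    indicator = (props[group_col] != reference).astype(float)
    X_full = pd.DataFrame({"intercept": 1.0, group_col: indicator})
    X_null = X_full[["intercept"]]
    full = fit_dirichlet_regression(props, X_full, category_cols)
    null = fit_dirichlet_regression(props, X_null, category_cols)
    return lrt_and_fdr(full, null, group_col)


# --------------------------------------------------------------------------
# tumor-vs-adjacent enrichment
# --------------------------------------------------------------------------

def wilcoxon_signed_rank(scores: Sequence[float], exact_max_n: int = 25) -> float:
    """Two-sided signed-rank p vs 0; exact for n <= *exact_max_n*.

    Zeros are dropped (standard treatment); an all-zero vector returns 1.
    Larger samples use the normal approximation with continuity
    correction.
    """
    x = np.asarray(scores, dtype=float)
    x = x[x != 0]
    if x.size == 0:
        return 1.0
    method = "exact" if x.size <= exact_max_n else "approx"
    res = stats.wilcoxon(x, alternative="two-sided", correction=True, method=method)
    return float(res.pvalue)


def tumor_enrichment(
    composition: pd.DataFrame,
    category_cols: Sequence[str],
    patient_col: str = "patient",
    tissue_col: str = "tissue",
    eps: Optional[float] = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Paired tumor-vs-adjacent enrichment per category.

    Per patient per category: ``score = log2((p_tumor + eps) / (p_adj + eps))``
    with ``eps`` defaulting to 1 / median(sample cell count). Per category,
    a two-sided Wilcoxon signed-rank of the scores against 0, BH-adjusted
    across categories; categories with fewer than *min_pairs* paired
    patients keep their scores but report p = NaN.
    """
    category_cols = list(category_cols)
    totals = composition[category_cols].sum(axis=1)
    if eps is None:
        eps = 1.0 / float(np.median(totals))
    props = composition.copy()
    props[category_cols] = composition[category_cols].div(totals, axis=0)

    rows = []
    pair_scores = {cat: [] for cat in category_cols}
    for patient, grp in props.groupby(patient_col, sort=True):
        tum = grp[grp[tissue_col] == "tumor"]
        adj = grp[grp[tissue_col] == "adjacent"]
        if tum.empty or adj.empty:
            continue
        pt = tum[category_cols].mean(axis=0)
        pa = adj[category_cols].mean(axis=0)
        for cat in category_cols:
            pair_scores[cat].append(np.log2((pt[cat] + eps) / (pa[cat] + eps)))

    p_raw = []
    for cat in category_cols:
        scores = np.asarray(pair_scores[cat])
        n = scores.size
        p = wilcoxon_signed_rank(scores) if n >= min_pairs else np.nan
        p_raw.append(p)
        rows.append((cat, n, float(np.mean(scores)) if n else np.nan,
                     float(np.median(scores)) if n else np.nan, p))

    result = pd.DataFrame(
        rows, columns=["category", "n_pairs", "mean_score", "median_score", "p_value"]
    )
    computed = result["p_value"].notna()
    fdr = np.full(len(result), np.nan)
    if computed.any():
        fdr[computed.to_numpy()] = bh_adjust(result.loc[computed, "p_value"].to_numpy())
    result["fdr"] = fdr
    return result
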