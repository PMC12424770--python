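"""Weighted phylogenetic GLS with jointly estimated Pagel's lambda.

Model
-----
For n species with response ``y`` (already transformed) and design ``X``,

    y ~ Normal(X beta, V),    V = sigma^2 * C(lambda) + tau^2 * diag(w^2)

where C is the Brownian-motion variance-covariance matrix of the phylogeny
(shared root-to-MRCA branch lengths), C(lambda) rescales its off-diagonal
entries by Pagel's lambda in [0, 1], and ``w`` is a per-species sampling-error
scale (here 1/sqrt(necropsy count)). ``beta`` is profiled out by GLS at each
covariance; (lambda, sigma^2, tau^2) maximise the exact multivariate-normal
log-likelihood. By default tau^2 is estimated, absorbing the unknown scale of
the sampling errors after trait transformation; a strict mode pins tau = 1.

lambda = 0 removes phylogenetic correlation (tips independent), lambda = 1 is
plain Brownian motion. AIC = -2 lnL + 2k compares fits at lambda in
{0, lambda_hat, 1}; the estimated-lambda model nests both fixed fits, so its
log-likelihood can never be lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

import dendropy

__all__ = [
    "PhyloCovariance",
    "PglsFit",
    "read_tree",
    "prune_tree",
    "vcv_from_tree",
    "lambda_transform",
    "fit_pgls",
    "aic",
    "compare_lambda_models",
    "bh_fdr",
    "vif",
    "pearson_r",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class PhyloCovariance:
    """Brownian VCV matrix with its tip-label order."""

    C: np.ndarray
    labels: list[str]

    def reorder(self, species: Sequence[str]) -> "PhyloCovariance":
        pos = {s: i for i, s in enumerate(self.labels)}
        missing = [s for s in species if s not in pos]
        if missing:
            raise KeyError(f"species not in covariance: {missing}")
        idx = np.array([pos[s] for s in species])
        return PhyloCovariance(C=self.C[np.ix_(idx, idx)], labels=list(species))


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def prune_tree(tree: dendropy.Tree, species: Sequence[str]) -> dendropy.Tree:
    """Non-destructively prune a tree to a tip subset (labels must all exist)."""
    tips = {t.taxon.label for t in tree.leaf_node_iter()}
    missing = sorted(set(species) - tips)
    if missing:
        raise KeyError(f"species missing from tree: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(list(species))
    return pruned


def vcv_from_tree(tree: dendropy.Tree, species: Optional[Sequence[str]] = None) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths between every tip pair.

    C_ij is the depth of the MRCA of tips i and j; C_ii the root-to-tip depth.
    If ``species`` is given the tree is pruned to that subset first (branch
    lengths on the retained paths are preserved), and the matrix rows follow
    the given order.
    """
    work = prune_tree(tree, species) if species is not None else tree
    tips = list(work.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    n = len(tips)
    index = {id(t): i for i, t in enumerate(tips)}

    # depth of every node measured from the root
    depth: dict[int, float] = {}
    for node in work.preorder_node_iter():
        el = node.edge.length or 0.0
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + el

    C = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            groups = [below.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = d
            below[id(node)] = [i for g in groups for i in g]
    pc = PhyloCovariance(C=C, labels=labels)
    return pc.reorder(species) if species is not None else pc


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of C by Pagel's lambda (diagonal fixed)."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


@dataclass
class PglsFit:
    """A fitted weighted phylogenetic regression."""

    names: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    lambda_hat: float
    lambda_mode: str
    sigma2_hat: float
    tau2_hat: Optional[float]
    loglik: float
    k_params: int
    aic: float
    r2: float
    r2_adj: Optional[float]
    n: int
    residuals: np.ndarray
    normalized_residuals: np.ndarray
    fitted: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        slope_idx = 1 if len(self.beta) > 1 else 0
        return {
            "n": self.n,
            "slope": float(self.beta[slope_idx]),
            "p": float(self.p_values[slope_idx]),
            "lambda_hat": self.lambda_hat,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "aic": self.aic,
        }


def _chol_loglik_core(M: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS at covariance M (unit scale): returns whitened pieces.

    Returns (beta, rss, logdet, Xs, ys) where Xs = L^-1 X, ys = L^-1 y.
    """
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(M + 1e-10 * np.mean(np.diag(M)) * np.eye(M.shape[0]))
    from scipy.linalg import solve_triangular

    ys = solve_triangular(L, y, lower=True, check_finite=False)
    Xs = solve_triangular(L, X, lower=True, check_finite=False)
    beta, _, rank, _ = np.linalg.lstsq(Xs, ys, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, Xs, ys, L


def _profiled_loglik(M: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """ML log-likelihood with beta and the overall scale sigma^2 profiled out."""
    n = len(y)
    _, rss, logdet, _, _, _ = _chol_loglik_core(M, X, y)
    s2 = rss / n
    return -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + n)


def _full_loglik(V: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """ML log-likelihood at a fully specified covariance V (beta profiled)."""
    n = len(y)
    _, rss, logdet, _, _, _ = _chol_loglik_core(V, X, y)
    return -0.5 * (n * _LOG2PI + logdet + rss)


_MULTISTART_LAMBDA = (0.1, 0.5, 0.9)


def _optimize_lambda_profiled(C, X, y, W2, estimate_g: bool):
    """Maximise the profiled likelihood over lambda (and g = tau^2/sigma^2)."""

    def M_of(lam, g):
        M = lambda_transform(C, lam)
        if g > 0:
            M = M + g * W2
        return M

    def nll(params):
        lam = min(max(params[0], 0.0), 1.0)
        g = np.exp(params[1]) if len(params) > 1 else 0.0
        return -_profiled_loglik(M_of(lam, g), X, y)

    candidates: list[tuple[float, float, float]] = []  # (ll, lam, g)

    def scalar_lambda_opt(g: float) -> tuple[float, float]:
        res = optimize.minimize_scalar(
            lambda l: -_profiled_loglik(M_of(l, g), X, y),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return -res.fun, float(res.x)

    if not estimate_g:
        ll, lam = scalar_lambda_opt(0.0)
        candidates.append((ll, lam, 0.0))
        for l0 in (0.0, 1.0) + _MULTISTART_LAMBDA:
            candidates.append((_profiled_loglik(M_of(l0, 0.0), X, y), l0, 0.0))
    else:
        for l0 in _MULTISTART_LAMBDA:
            res = optimize.minimize(
                nll,
                x0=np.array([l0, 0.0]),
                method="L-BFGS-B",
                bounds=[(0.0, 1.0), (-12.0, 12.0)],
            )
            candidates.append((-res.fun, float(res.x[0]), float(np.exp(res.x[1]))))
        # boundary candidates: lambda pinned at 0 / 1, g free
        for lb in (0.0, 1.0):
            res = optimize.minimize_scalar(
                lambda u: -_profiled_loglik(M_of(lb, np.exp(u)), X, y),
                bounds=(-12.0, 12.0),
                method="bounded",
                options={"xatol": 1e-6},
            )
            candidates.append((-res.fun, lb, float(np.exp(res.x))))
            candidates.append((_profiled_loglik(M_of(lb, 0.0), X, y), lb, 0.0))
        # g = 0 candidate (no extra sampling-error variance needed)
        ll, lam = scalar_lambda_opt(0.0)
        candidates.append((ll, lam, 0.0))
    best = max(candidates, key=lambda c: c[0])
    return best  # (loglik, lambda, g)


def _optimize_g_profiled(C, X, y, W2, lam: float):
    """Fixed lambda; maximise over g only (weights present, tau estimated)."""

    def nll(u):
        return -_profiled_loglik(lambda_transform(C, lam) + np.exp(u) * W2, X, y)

    res = optimize.minimize_scalar(nll, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-6})
    g_candidates = [(-res.fun, float(np.exp(res.x)))]
    g_candidates.append((_profiled_loglik(lambda_transform(C, lam), X, y), 0.0))
    return max(g_candidates, key=lambda c: c[0])


def _optimize_strict(C, X, y, W2, lambda_mode):
    """Strict mode: V = sigma^2 C(lambda) + diag(w^2) with tau pinned at 1."""

    def V_of(lam, s2):
        return s2 * lambda_transform(C, lam) + W2

    v0 = np.log(max(np.var(y), 1e-8))
    bounds_v = (v0 - 20.0, v0 + 20.0)

    def opt_s2(lam):
        res = optimize.minimize_scalar(
            lambda v: -_full_loglik(V_of(lam, np.exp(v)), X, y),
            bounds=bounds_v, method="bounded", options={"xatol": 1e-8},
        )
        return -res.fun, float(np.exp(res.x))

    if lambda_mode in ("fixed_0", "fixed_1"):
        lam = 0.0 if lambda_mode == "fixed_0" else 1.0
        ll, s2 = opt_s2(lam)
        return ll, lam, s2
    candidates = []
    for l0 in _MULTISTART_LAMBDA:
        res = optimize.minimize(
            lambda p: -_full_loglik(V_of(min(max(p[0], 0.0), 1.0), np.exp(p[1])), X, y),
            x0=np.array([l0, v0]),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0), bounds_v],
        )
        candidates.append((-res.fun, float(res.x[0]), float(np.exp(res.x[1]))))
    for lb in (0.0, 1.0):
        ll, s2 = opt_s2(lb)
        candidates.append((ll, lb, s2))
    return max(candidates, key=lambda c: c[0])


def fit_pgls(
    y: Sequence[float],
    X: np.ndarray,
    C: np.ndarray,
    weights: Optional[Sequence[float]] = None,
    lambda_mode: str = "estimate",
    error_scale: str = "estimate",
    names: Optional[Sequence[str]] = None,
    compute_diagnostics: bool = True,
) -> PglsFit:
    """Fit y ~ Normal(X beta, sigma^2 C(lambda) + tau^2 diag(w^2)) by ML.

    Parameters
    ----------
    y, X
        Response vector and design matrix (include the intercept column).
    C
        Brownian VCV aligned to the rows of ``X``.
    weights
        Per-species sampling-error scale w (e.g. 1/sqrt(necropsy count));
        None or all-zero means no sampling-error term.
    lambda_mode
        "estimate", "fixed_0", "fixed_1", or a float in [0, 1].
    error_scale
        "estimate" fits the proportionality tau^2 of the sampling-error
        variance; "fixed" pins tau = 1 so ``weights`` are absolute standard
        deviations on the response scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n or C.shape != (n, n):
        raise ValueError("y, X, and C dimensions disagree")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
        raise ValueError("missing values in y or X")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    w = np.zeros(n) if weights is None else np.asarray(weights, dtype=float)
    has_weights = bool(np.any(w > 0))
    W2 = np.diag(w**2)

    fixed_lam: Optional[float] = None
    if isinstance(lambda_mode, (int, float)) and not isinstance(lambda_mode, bool):
        fixed_lam = float(lambda_mode)
        lambda_mode = f"fixed_{fixed_lam:g}"
    elif lambda_mode == "fixed_0":
        fixed_lam = 0.0
    elif lambda_mode == "fixed_1":
        fixed_lam = 1.0
    elif lambda_mode != "estimate":
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    strict = has_weights and error_scale == "fixed"
    if strict:
        mode = "estimate" if fixed_lam is None else (
            "fixed_0" if fixed_lam == 0.0 else "fixed_1" if fixed_lam == 1.0 else None
        )
        if mode is None:  # arbitrary fixed lambda in strict mode
            res = optimize.minimize_scalar(
                lambda v: -_full_loglik(
                    np.exp(v) * lambda_transform(C, fixed_lam) + W2, X, y),
                bounds=(np.log(max(np.var(y), 1e-8)) - 20, np.log(max(np.var(y), 1e-8)) + 20),
                method="bounded",
            )
            ll, lam_hat, s2 = -res.fun, fixed_lam, float(np.exp(res.x))
        else:
            ll, lam_hat, s2 = _optimize_strict(C, X, y, W2, mode)
        V = s2 * lambda_transform(C, lam_hat) + W2
        tau2 = 1.0
        g = None
    else:
        estimate_g = has_weights  # error_scale == "estimate"
        if fixed_lam is not None:
            if estimate_g:
                ll, g = _optimize_g_profiled(C, X, y, W2, fixed_lam)
            else:
                M = lambda_transform(C, fixed_lam)
                ll, g = _profiled_loglik(M, X, y), 0.0
            lam_hat = fixed_lam
        else:
            ll, lam_hat, g = _optimize_lambda_profiled(C, X, y, W2, estimate_g)
        M = lambda_transform(C, lam_hat) + (g * W2 if g > 0 else 0.0)
        _, rss, _, _, _, _ = _chol_loglik_core(M, X, y)
        s2 = rss / n
        tau2 = s2 * g if has_weights else None
        V = s2 * M

    beta, rssV, _, Xs, ys, L = _chol_loglik_core(V, X, y)
    XtVinvX_inv = np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(XtVinvX_inv))
    df = n - p
    t_stats = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df)

    fitted = X @ beta
    resid = y - fitted
    from scipy.linalg import solve_triangular
    nresid = solve_triangular(L, resid, lower=True, check_finite=False)

    # GLS-weighted R^2 against the GLS intercept-only mean
    ones = np.ones(n)
    os_ = solve_triangular(L, ones, lower=True, check_finite=False)
    mu = float((os_ @ ys) / (os_ @ os_))
    yc = solve_triangular(L, y - mu, lower=True, check_finite=False)
    denom = float(yc @ yc)
    r2 = 1.0 - rssV / denom if denom > 0 else np.nan
    n_pred = p - 1
    r2_adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - n_pred - 1)
        if n_pred >= 2 and n - n_pred - 1 > 0
        else None
    )

    lam_estimated = fixed_lam is None
    k = p + 1 + (1 if lam_estimated else 0)
    if has_weights and not strict:
        k += 1  # tau^2 (the sampling-error proportionality scale)

    diagnostics: dict = {}
    if compute_diagnostics:
        diagnostics = _residual_diagnostics(nresid, Xs, X)

    return PglsFit(
        names=list(names) if names is not None else [f"b{i}" for i in range(p)],
        beta=beta,
        se_beta=se,
        t_stats=t_stats,
        p_values=p_values,
        lambda_hat=float(lam_hat),
        lambda_mode="estimate" if lam_estimated else f"fixed_{fixed_lam:g}",
        sigma2_hat=float(s2),
        tau2_hat=tau2,
        loglik=float(ll),
        k_params=k,
        aic=aic(float(ll), k),
        r2=float(r2),
        r2_adj=r2_adj,
        n=n,
        residuals=resid,
        normalized_residuals=nresid,
        fitted=fitted,
        diagnostics=diagnostics,
    )


def _residual_diagnostics(nresid: np.ndarray, Xs: np.ndarray, X: np.ndarray) -> dict:
    out: dict = {}
    if 3 <= len(nresid) <= 5000:
        out["residual_normality_p"] = float(stats.shapiro(nresid).pvalue)
    # Breusch-Pagan-type score test of squared normalized residuals on the
    # whitened design (plus a constant)
    try:
        from statsmodels.stats.diagnostic import het_breuschpagan

        exog = np.column_stack([np.ones(len(nresid)), Xs])
        exog = exog[:, ~_duplicate_cols(exog)]
        _, bp_p, _, _ = het_breuschpagan(nresid, exog)
        out["heteroscedasticity_p"] = float(bp_p)
    except Exception:
        out["heteroscedasticity_p"] = None
    if X.shape[1] >= 3:  # intercept + >= 2 predictors
        out["vif"] = [float(v) for v in vif(X[:, 1:])]
    return out


def _duplicate_cols(A: np.ndarray) -> np.ndarray:
    keep = np.zeros(A.shape[1], dtype=bool)
    seen: list[np.ndarray] = []
    for j in range(A.shape[1]):
        col = A[:, j]
        if any(np.allclose(col, s) for s in seen):
            keep[j] = True
        else:
            seen.append(col)
    return keep


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2 lnL + 2k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * loglik + 2.0 * k


def compare_lambda_models(
    y, X, C, weights=None, error_scale: str = "estimate", names=None
) -> pd.DataFrame:
    """Fit at lambda in {0, lambda_hat, 1} and tabulate log-likelihoods and AICs.

    The estimated-lambda fit nests both fixed fits, so its log-likelihood is
    the maximum of the three (its AIC pays one extra parameter).
    """
    rows = []
    fits = {}
    for mode, label in (("fixed_0", "lambda_0"), ("estimate", "lambda_hat"), ("fixed_1", "lambda_1")):
        fit = fit_pgls(
            y, X, C, weights=weights, lambda_mode=mode, error_scale=error_scale,
            names=names, compute_diagnostics=False,
        )
        fits[label] = fit
        rows.append(
            {
                "model": label,
                "lambda": fit.lambda_hat,
                "loglik": fit.loglik,
                "k": fit.k_params,
                "aic": fit.aic,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["fits"] = fits
    return df


def bh_fdr(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags at q."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor per predictor column (intercept added
    internally to each auxiliary regression); perfect collinearity -> inf."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if n <= p:
        raise ValueError("VIF needs more rows than predictors")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        ssr = float(resid @ resid)
        if sst == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ssr / sst
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant or mismatched input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r: constant input")
    return float(stats.pearsonr(x, y).statistic)
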