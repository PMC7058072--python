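"""Sparse structural equation models estimated by penalized two-stage least squares.

Endogenous variables y_1..y_M (expressions, phenotypes) are modelled as

    y_i = Y_{-i} gamma_i + X_i beta_i + e_i = W_i Delta_i + e_i

with exogenous instruments X (genotypes).  Premultiplying by X^T gives the
moment system whose weighted least-squares criterion is the quadratic form

    f(Delta_i) = (X^T y_i - X^T W_i Delta_i)^T (X^T X)^{-1} (X^T y_i - X^T W_i Delta_i),

minimized with an L1 penalty, min f(Delta_i) + lambda ||Delta_i||_1, by an
accelerated proximal-gradient method.  The penalty weight is
chosen by BIC over a log-spaced grid; the selected support is then refit by
unpenalized 2SLS, which supplies debiased path coefficients and asymptotic
normal p-values.  Assembling the per-node fits gives the "SEM" network
estimator: a directed graph of significant path coefficients, with no
acyclicity mechanism (cycles can and do occur; the integer-programming
stage adds the DAG constraint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datasets import OmicsDataset

__all__ = [
    "TwoStageObjective",
    "SEMNodeFit",
    "SEMNetwork",
    "two_stage_objective",
    "fit_sparse_sem_node",
    "fit_sem_network",
]


class TwoStageObjective:
    """The 2SLS quadratic form f(Delta) for one structural equation.

    Evaluates f(Delta) = (X'y - X'W Delta)' (X'X)^{-1} (X'y - X'W Delta),
    with gradient and unpenalized minimizer.  A rank-deficient X'X is
    handled by a small trace-scaled ridge when ``regularize`` is true (the
    ``ridged`` attribute records this); otherwise it is an error.
    """

    def __init__(self, y: np.ndarray, w: np.ndarray, x: np.ndarray, regularize: bool = True):
        y = np.asarray(y, dtype=float).ravel()
        w = np.atleast_2d(np.asarray(w, dtype=float))
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if y.shape[0] != w.shape[0] or y.shape[0] != x.shape[0]:
            raise ValueError("sample counts of y, W and X must match")
        xtx = x.T @ x
        self.ridged = False
        rank = np.linalg.matrix_rank(xtx)
        if rank < xtx.shape[0]:
            if not regularize:
                raise np.linalg.LinAlgError("X is rank deficient; enable regularization")
            xtx = xtx + (1e-8 * np.trace(xtx) / xtx.shape[0]) * np.eye(xtx.shape[0])
            self.ridged = True
            warnings.warn("rank-deficient X'X ridge-regularized")
        self.m = np.linalg.inv(xtx)
        self.b = x.T @ y  # X'y
        self.a = x.T @ w  # X'W
        self.n, self.p = w.shape
        # quadratic expansion: f(d) = d'H d - 2 g'd + c0
        self.h = self.a.T @ self.m @ self.a
        self.g = self.a.T @ self.m @ self.b
        self.c0 = float(self.b @ self.m @ self.b)

    def __call__(self, delta: np.ndarray) -> float:
        d = np.asarray(delta, dtype=float).ravel()
        r = self.b - self.a @ d
        return float(r @ self.m @ r)

    def gradient(self, delta: np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float).ravel()
        return 2 * (self.h @ d - self.g)

    def minimizer(self) -> np.ndarray:
        """Unpenalized minimizer by the normal equations (minimum-norm when
        the moment system is underdetermined)."""
        return np.linalg.lstsq(self.h, self.g, rcond=None)[0]


def two_stage_objective(y_i, w_i, x, regularize: bool = True) -> TwoStageObjective:
    """Build the 2SLS quadratic-form evaluator for one equation."""
    return TwoStageObjective(y_i, w_i, x, regularize=regularize)


def _prox_lasso(
    obj: TwoStageObjective,
    lam: float,
    max_iter: int = 50_000,
    tol: float = 1e-8,
    warm_start: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize f(Delta) + lam*||Delta||_1 by accelerated proximal gradient.

    FISTA with adaptive restart and step 1/L (L = largest eigenvalue of the
    quadratic's Hessian).  The quadratic piece may be rank deficient (fewer
    instruments than candidates); the method needs no modification for that.
    Stops when the proximal-gradient fixed-point residual, in coefficient
    units, falls below ``tol`` relative to the iterate scale.
    """
    p = obj.p
    q = 2 * obj.h  # Hessian of f
    lin = 2 * obj.g  # grad f(d) = q d - lin
    l_const = float(np.linalg.eigvalsh(q)[-1]) if p else 1.0
    if l_const <= 0:  # f is constant; penalty alone decides
        return np.zeros(p)
    step = 1.0 / l_const
    x = warm_start.copy() if warm_start is not None else np.zeros(p)
    z = x.copy()
    t = 1.0
    for it in range(max_iter):
        grad = q @ z - lin
        v = z - step * grad
        x_new = np.sign(v) * np.maximum(np.abs(v) - step * lam, 0.0)
        if (z - x_new) @ (x_new - x) > 0:  # adaptive restart
            t = 1.0
            z = x.copy()
            continue
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        if it % 10 == 9:
            g_x = q @ x - lin
            w_x = x - step * g_x
            px = np.sign(w_x) * np.maximum(np.abs(w_x) - step * lam, 0.0)
            if np.max(np.abs(x - px)) <= tol * max(1.0, np.max(np.abs(x))):
                return x
    raise RuntimeError(
        f"proximal gradient did not converge in {max_iter} iterations (lambda {lam:.3g})"
    )


@dataclass
class SEMNodeFit:
    """Penalized 2SLS fit of one structural equation."""

    node: str
    candidates: list[str]
    delta_hat: pd.Series
    lambda_: float
    objective: float
    p_values: pd.Series
    gamma_hat: pd.Series
    beta_hat: pd.Series
    bic_path: pd.DataFrame | None = None

    @property
    def support(self) -> list[str]:
        return [c for c in self.candidates if self.delta_hat[c] != 0.0]


def _tsls_refit(y, w_support, x, m):
    """Unpenalized 2SLS on a support: coefficients, SEs and p-values."""
    n, k = w_support.shape
    if k == 0:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    proj = x @ m @ (x.T @ w_support)  # P_X W_S
    gram = w_support.T @ proj
    rhs = proj.T @ y
    try:
        coef = np.linalg.solve(gram, rhs)
        cov_core = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("underidentified support; pseudo-inverse refit")
        coef = np.linalg.lstsq(gram, rhs, rcond=None)[0]
        cov_core = np.linalg.pinv(gram)
    resid = y - w_support @ coef
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(cov_core) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p = 2 * stats.norm.sf(np.abs(z))
    return coef, se, p


def default_lambda_grid(obj: TwoStageObjective, n_lambda: int = 20, ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced grid from the smallest all-zero lambda down by ``ratio``."""
    lam_max = float(np.max(np.abs(2 * obj.g)))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_sparse_sem_node(
    y_i,
    candidate_parents: list[str],
    data: pd.DataFrame,
    exogenous: list[str],
    node: str = "y",
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 20,
    endogenous_candidates: list[str] | None = None,
    max_iter: int = 10_000,
) -> SEMNodeFit:
    """Fit one sparse structural equation and select lambda by BIC.

    ``candidate_parents`` names the columns of ``data`` entering W_i;
    ``exogenous`` names the instrument columns X.  Every variable is centred,
    so no intercept is carried.  For each lambda on the grid the proximal
    solution's support is refit by unpenalized 2SLS and scored by
    BIC = n log(RSS/n) + |S| log n; the smallest-BIC support wins and its
    refit supplies coefficients and p-values.
    """
    if not candidate_parents:
        raise ValueError("candidate_parents must be non-empty")
    if not exogenous:
        raise ValueError("2SLS needs at least one exogenous instrument")
    y = np.asarray(y_i, dtype=float).ravel()
    y = y - y.mean()
    w = data[candidate_parents].to_numpy(dtype=float)
    w = w - w.mean(axis=0)
    x = data[exogenous].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    obj = TwoStageObjective(y, w, x)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(obj, n_lambda=n_lambda)
    if len(lambda_grid) == 0:
        raise ValueError("lambda_grid must be non-empty")

    n = y.shape[0]
    tss = float(y @ y)
    best = None
    path_rows = []
    for lam in np.sort(np.asarray(lambda_grid, dtype=float))[::-1]:
        z = _prox_lasso(obj, lam, max_iter=max_iter)
        support_idx = np.flatnonzero(np.abs(z) > 1e-8)
        if support_idx.size:
            coef, _, _ = _tsls_refit(y, w[:, support_idx], x, obj.m)
            resid = y - w[:, support_idx] @ coef
            rss = float(resid @ resid)
        else:
            rss = tss
        sigma2 = max(rss / n, 1e-12)
        bic = n * np.log(sigma2) + support_idx.size * np.log(n)
        path_rows.append({"lambda": lam, "support_size": support_idx.size, "bic": bic})
        if best is None or bic < best[0] - 1e-12:
            best = (bic, lam, support_idx, z)

    _, lam_best, support_idx, z_best = best
    delta = np.zeros(len(candidate_parents))
    pvals = np.full(len(candidate_parents), np.nan)
    if support_idx.size:
        coef, _, p = _tsls_refit(y, w[:, support_idx], x, obj.m)
        delta[support_idx] = coef
        pvals[support_idx] = p
    delta_s = pd.Series(delta, index=candidate_parents)
    p_s = pd.Series(pvals, index=candidate_parents)
    endo_set = set(endogenous_candidates if endogenous_candidates is not None else
                   [c for c in candidate_parents if c not in set(exogenous)])
    gamma = delta_s[[c for c in candidate_parents if c in endo_set]]
    beta = delta_s[[c for c in candidate_parents if c not in endo_set]]
    return SEMNodeFit(
        node=node,
        candidates=list(candidate_parents),
        delta_hat=delta_s,
        lambda_=float(lam_best),
        objective=float(obj(delta)),
        p_values=p_s,
        gamma_hat=gamma,
        beta_hat=beta,
        bic_path=pd.DataFrame(path_rows),
    )


@dataclass
class SEMNetwork:
    """Directed network of significant structural path coefficients.

    Edges carry ``coefficient`` and ``p_value`` attributes; the graph may be
    cyclic (no acyclicity is enforced by this estimator).
    """

    graph: nx.DiGraph
    alpha: float
    node_fits: dict[str, SEMNodeFit] = field(default_factory=dict)


def fit_sem_network(
    dataset: OmicsDataset,
    alpha: float = 0.05,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 20,
) -> SEMNetwork:
    """Fit every endogenous node's sparse equation and keep significant edges.

    Candidates for node i are all other endogenous nodes plus all exogenous
    (genotype) nodes; instruments are the exogenous nodes.  A directed edge
    parent -> i is retained when the refit coefficient is nonzero with
    p < ``alpha``.
    """
    endo = dataset.endogenous_nodes
    exo = dataset.genotype_nodes
    if len(endo) < 2:
        raise ValueError("need at least 2 endogenous variables")
    if not exo:
        raise ValueError("2SLS needs at least one exogenous instrument")
    g = nx.DiGraph()
    for n in dataset.nodes:
        g.add_node(n, layer=dataset.layers[n])
    fits: dict[str, SEMNodeFit] = {}
    for node in endo:
        candidates = [c for c in endo if c != node] + exo
        fit = fit_sparse_sem_node(
            dataset.data[node].to_numpy(),
            candidates,
            dataset.data,
            exogenous=exo,
            node=node,
            lambda_grid=lambda_grid,
            n_lambda=n_lambda,
        )
        fits[node] = fit
        for parent in fit.support:
            p = fit.p_values[parent]
            if np.isfinite(p) and p < alpha:
                g.add_edge(parent, node, coefficient=float(fit.delta_hat[parent]), p_value=float(p))
    return SEMNetwork(graph=g, alpha=alpha, node_fits=fits)
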