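"""Functional principal component summaries of genotypes and feature groups.

Genotypes in a gene region are encoded as a *genotype function* x_i(t) over
genomic position t: at each position with alleles Q and q (frequencies P_Q,
P_q), the three genotypes map to

    QQ -> 2 P_q,    Qq -> P_q - P_Q,    qq -> -2 P_Q,

a coding whose population mean is zero under Hardy-Weinberg proportions.
Functional PCA of these curves yields per-sample functional principal
component scores (FPCS) that summarize every variant in the region, which
downstream modules discretize for causal testing or use as exogenous node
values.  A plain PCA summary of arbitrary feature groups (pathways,
clusters) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "GenotypeFunctionMatrix",
    "FPCResult",
    "code_genotype_function",
    "fpc_scores",
    "group_summary_pca",
]


@dataclass
class GenotypeFunctionMatrix:
    """Frequency-centred genotype curves sampled at variant positions.

    ``values`` is samples x positions; ``positions`` are rescaled to [0, 1];
    ``allele_freqs`` holds (P_Q, P_q) per position.
    """

    values: np.ndarray
    positions: np.ndarray
    allele_freqs: np.ndarray  # (positions, 2) columns P_Q, P_q
    imputed: np.ndarray | None = None  # boolean mask of imputed entries

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.shape[1] != self.positions.shape[0]:
            raise ValueError("positions must match the number of value columns")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")


@dataclass
class FPCResult:
    """Functional PCA decomposition of a genotype-function matrix.

    ``scores`` (samples x components) are the per-sample coordinates
    eta_l; ``eigenfunctions`` (components x positions) are the functions
    phi_l sampled at the observation grid, orthonormal under the trapezoid
    quadrature inner product; ``variance_explained`` are fractions of total
    variance, non-increasing.
    """

    scores: np.ndarray
    eigenfunctions: np.ndarray
    variance_explained: np.ndarray
    positions: np.ndarray
    quad_weights: np.ndarray


def code_genotype_function(
    genotypes: np.ndarray | pd.DataFrame,
    positions: np.ndarray,
    allele_freqs: np.ndarray | None = None,
) -> GenotypeFunctionMatrix:
    """Apply the three-branch frequency coding to a 0/1/2 dosage matrix.

    ``genotypes`` counts copies of allele Q per sample and position; NaN
    entries are imputed to the per-position mean of the coded values and
    flagged in the result.  ``allele_freqs`` gives P_Q per position; when
    omitted it is estimated from the sample.  Monomorphic positions code to
    zero columns with a warning.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be 2-D (samples x positions)")
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    observed = ~np.isnan(g)
    valid = np.where(observed, g, 0.0)
    if not np.all(np.isin(valid[observed], (0.0, 1.0, 2.0))):
        raise ValueError("genotype entries must be in {0, 1, 2} or missing")

    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p_q_allele = np.nansum(g, axis=0) / (2 * observed.sum(axis=0))
        p_big_q = p_q_allele  # frequency of the counted allele Q
    else:
        p_big_q = np.asarray(allele_freqs, dtype=float)
        if p_big_q.ndim == 2:
            p_big_q = p_big_q[:, 0]
    p_small_q = 1.0 - p_big_q

    mono = (p_big_q <= 0.0) | (p_big_q >= 1.0)
    if np.any(mono):
        warnings.warn(f"{int(mono.sum())} monomorphic position(s) coded as zeros")

    # QQ (g=2) -> 2 P_q; Qq (g=1) -> P_q - P_Q; qq (g=0) -> -2 P_Q
    coded = np.where(
        g == 2, 2 * p_small_q, np.where(g == 1, p_small_q - p_big_q, -2 * p_big_q)
    )
    coded = np.where(mono, 0.0, coded)
    imputed = ~observed
    if np.any(imputed):
        col_mean = np.nanmean(np.where(observed, coded, np.nan), axis=0)
        col_mean = np.nan_to_num(col_mean)
        coded = np.where(imputed, col_mean, coded)

    span = positions.max() - positions.min()
    rescaled = (positions - positions.min()) / span if span > 0 else np.zeros_like(positions)
    freqs = np.column_stack([p_big_q, p_small_q])
    return GenotypeFunctionMatrix(
        values=coded, positions=rescaled, allele_freqs=freqs, imputed=imputed
    )


def _bspline_design(positions: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    n_interior = n_basis - degree - 1
    interior = np.quantile(positions, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior > 0 else []
    knots = np.concatenate(
        [np.repeat(positions.min(), degree + 1), interior, np.repeat(positions.max(), degree + 1)]
    )
    return BSpline.design_matrix(positions, knots, degree, extrapolate=True).toarray()


def _trapezoid_weights(positions: np.ndarray) -> np.ndarray:
    p = np.asarray(positions, dtype=float)
    if p.size < 2 or p.max() == p.min():
        return np.full(p.size, 1.0 / max(p.size, 1))
    w = np.zeros_like(p)
    d = np.diff(p)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def fpc_scores(
    gfm: GenotypeFunctionMatrix | np.ndarray,
    n_components: int | None = None,
    variance_threshold: float = 0.8,
    n_basis: int | None = None,
    degree: int = 3,
    smooth: bool = True,
) -> FPCResult:
    """Functional PCA of genotype curves.

    The curves are first least-squares smoothed on a cubic B-spline basis
    (``n_basis`` defaults to min(15, #positions); raw-grid PCA is used when
    there are fewer positions than basis functions require), then the sample
    covariance operator is eigen-decomposed under the trapezoid quadrature
    inner product on [0, 1].  The number of components kept is ``n_components``
    if given, else the smallest L whose cumulative variance fraction reaches
    ``variance_threshold``.  Eigenfunction signs are fixed by making each
    one's largest-magnitude loading positive.
    """
    if isinstance(gfm, GenotypeFunctionMatrix):
        x = gfm.values
        positions = gfm.positions
    else:
        x = np.asarray(gfm, dtype=float)
        positions = np.linspace(0, 1, x.shape[1])
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 positions")
    if n_components is not None and n_components < 1:
        raise ValueError("n_components must be >= 1")

    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("zero-variance matrix has no principal components")

    if n_basis is None:
        n_basis = min(15, p)
    if smooth and p >= n_basis and n_basis >= degree + 1 and np.unique(positions).size > degree:
        basis = _bspline_design(positions, n_basis, degree)
        coef, *_ = np.linalg.lstsq(basis, xc.T, rcond=None)
        xs = (basis @ coef).T
    else:
        xs = xc

    w = _trapezoid_weights(positions)
    sw = np.sqrt(w)
    # symmetric eigenproblem of the covariance operator under the quadrature metric
    a = (xs * sw) / np.sqrt(max(n - 1, 1))
    _, svals, vt = np.linalg.svd(a, full_matrices=False)
    eigvals = svals**2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = eigvals / eigvals.sum()
    phi = vt / sw  # rows orthonormal under sum(w * phi_a * phi_b)

    # deterministic sign: largest-|loading| entry positive
    for row in phi:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1

    if n_components is None:
        cum = np.cumsum(frac)
        n_components = int(np.searchsorted(cum, variance_threshold) + 1)
    n_components = min(n_components, phi.shape[0])

    phi = phi[:n_components]
    scores = xc @ (w[:, None] * phi.T)
    return FPCResult(
        scores=scores,
        eigenfunctions=phi,
        variance_explained=frac[:n_components],
        positions=positions,
        quad_weights=w,
    )


def group_summary_pca(
    feature_matrix: pd.DataFrame,
    group_map: pd.DataFrame | dict,
    variance_threshold: float = 0.8,
) -> pd.DataFrame:
    """Summarize feature groups (pathways, clusters) by standardized PCA scores.

    ``group_map`` is either a mapping group -> list of features or a
    two-column DataFrame (feature, group).  Per group, member features are
    z-scored and the PCA scores retaining ``variance_threshold`` of the
    variance are returned, standardized to unit variance, in columns named
    ``group::PCk``.  Groups whose features are all constant are dropped with
    a warning.
    """
    if isinstance(group_map, pd.DataFrame):
        groups: dict[str, list[str]] = {}
        fcol, gcol = group_map.columns[:2]
        for _, row in group_map.iterrows():
            groups.setdefault(str(row[gcol]), []).append(str(row[fcol]))
    else:
        groups = {k: list(v) for k, v in group_map.items()}

    out = {}
    for group, members in groups.items():
        if not members:
            raise ValueError(f"group {group!r} has no member features")
        sub = feature_matrix[members].to_numpy(dtype=float)
        sd = sub.std(axis=0, ddof=0)
        keep = sd > 0
        if not np.any(keep):
            warnings.warn(f"group {group!r} has only constant features; dropped")
            continue
        z = (sub[:, keep] - sub[:, keep].mean(axis=0)) / sd[keep]
        u, svals, _ = np.linalg.svd(z, full_matrices=False)
        var = svals**2
        frac = var / var.sum()
        ncomp = int(np.searchsorted(np.cumsum(frac), variance_threshold) + 1)
        ncomp = min(ncomp, len(frac))
        for k in range(ncomp):
            col = u[:, k] * svals[k]
            colsd = col.std(ddof=0)
            if colsd > 0:
                col = col / colsd
            j = np.argmax(np.abs(col))
            if col[j] < 0:
                col = -col
            out[f"{group}::PC{k + 1}"] = col
    return pd.DataFrame(out, index=feature_matrix.index)
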