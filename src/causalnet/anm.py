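"""Bivariate causal discovery for discrete variables by additive noise models.

For a candidate cause X and effect Y (genotype and disease status, say), fit
the integer regression Y = f(X) + N_Y and the reverse X = g(Y) + N_X, where
f-hat is the dependence-minimizing level assignment (coordinate descent
from a conditional-median start).  In the causal direction the residual is
(approximately) independent of the cause; in the anti-causal direction it
is not.  Dependence is measured on the
residual x cause contingency table by Fisher's exact test (chi-square above
a configurable table size), on the -log10 p scale:

    Delta_{X->Y} = -log10 p(N_Y-hat independent of X)

and the causation statistic is T_C = |Delta_{X->Y} - Delta_{Y->X}|.  Its
null distribution is intractable, so p-values come from permutations of Y.
Gene-level tests summarize the rare variants of a region by functional
principal component scores, discretize the leading score into quantile bins
and run the same test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .fpca import code_genotype_function, fpc_scores

__all__ = [
    "DiscreteSeries",
    "CausalTestResult",
    "fit_discrete_regression",
    "independence_delta",
    "causation_test",
    "gene_level_causation",
    "gwcs_scan",
]

# exact-test policy: Fisher's exact test is used when the (reduced) table has
# at most EXACT_MAX_CELLS cells and at most EXACT_MAX_N observations, with the
# classic 2x2 case always exact; larger tables fall back to Pearson chi-square.
EXACT_MAX_CELLS = 6
EXACT_MAX_N = 200
_TINY_P = 1e-300


@dataclass
class DiscreteSeries:
    """A vector of integers over a finite ordered support."""

    values: np.ndarray
    support: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D vector")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded):
                raise ValueError("values must be integers")
            self.values = rounded.astype(np.int64)
        if self.support is None:
            self.support = np.unique(self.values)
        else:
            self.support = np.asarray(self.support)
            if not np.all(np.isin(self.values, self.support)):
                raise ValueError("every value must lie in the support")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class CausalTestResult:
    """Outcome of one bivariate causation test."""

    delta_xy: float
    delta_yx: float
    t_c: float
    p_value: float
    direction: str  # "x_to_y" | "y_to_x" | "undecided"
    n_permutations: int


def _as_values(x) -> np.ndarray:
    if isinstance(x, DiscreteSeries):
        return x.values
    return DiscreteSeries(np.asarray(x)).values


def _encode(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(values, return_inverse=True)
    return levels, codes


def _median_init(counts: np.ndarray) -> np.ndarray:
    """Conditional lower-median column index per cause level (fit start)."""
    kx, _ = counts.shape
    idx = np.zeros(kx, dtype=np.intp)
    for i in range(kx):
        row = counts[i]
        total = row.sum()
        if total == 0:
            continue
        cum = np.cumsum(row)
        idx[i] = np.searchsorted(cum, total / 2.0)
    return idx


class _FitWorkspace:
    """Precomputed residual-value bookkeeping for one effect-level set.

    Residual values are differences of effect levels; ``idx[p, j]`` is the
    row of residual value ``levels[j] - levels[p]`` in the residual-by-cause
    table.  Depends only on the levels, so it is shared across permutations.
    """

    def __init__(self, eff_levels: np.ndarray):
        self.levels = eff_levels
        diffs = eff_levels[None, :] - eff_levels[:, None]  # [pred, j]
        self.d_values = np.unique(diffs)
        self.idx = np.searchsorted(self.d_values, diffs)
        self.ke = eff_levels.size
        self.nd = self.d_values.size


def _chi2_p_fast(table: np.ndarray) -> float:
    """Pearson chi-square independence p, skipping empty rows/columns."""
    rs = table.sum(axis=1)
    cs = table.sum(axis=0)
    nr = int((rs > 0).sum())
    nc = int((cs > 0).sum())
    if nr < 2 or nc < 2:
        return 1.0
    n = rs.sum()
    expected = np.outer(rs, cs) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (table - expected) ** 2 / expected
    stat = contrib[expected > 0].sum()
    return float(special.chdtrc((nr - 1) * (nc - 1), stat))


def _dependence_min_fit(
    counts: np.ndarray, ws: _FitWorkspace, max_sweeps: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Dependence-minimizing integer regression over the cause's levels.

    The additive-noise fit of a discrete regression is the level assignment
    f whose residual y - f(x) is least dependent on x; conditional
    summaries (mode, median) are only surrogates and become unstable when
    the conditional distribution sits near a quantile boundary.  Starting
    from the conditional lower medians, each cause level's prediction is
    coordinate-descended over all effect levels to maximize the residual's
    chi-square independence p-value, sweeping until no assignment changes.
    Ties prefer the value closest to the conditional-median start, then the
    smaller level (via the candidate evaluation order), so the fit is
    deterministic.  Returns (prediction indices, residual-by-cause table).
    """
    kc = counts.shape[0]
    pred = _median_init(counts)
    start_vals = ws.levels[pred].astype(float)
    # candidate order fixes tie-breaking: distance to the median start, then value
    orders = [
        sorted(range(ws.ke), key=lambda j, i=i: (abs(ws.levels[j] - start_vals[i]), ws.levels[j]))
        for i in range(kc)
    ]
    table = np.zeros((ws.nd, kc))
    for i in range(kc):
        table[ws.idx[pred[i]], i] = counts[i]
    occupied = np.flatnonzero(counts.sum(axis=1) > 0)
    for _ in range(max_sweeps):
        changed = False
        for i in occupied:
            table[ws.idx[pred[i]], i] = 0.0
            best_j, best_p = -1, -1.0
            for j in orders[i]:
                table[ws.idx[j], i] = counts[i]
                p = _chi2_p_fast(table)
                table[ws.idx[j], i] = 0.0
                if p > best_p + 1e-12:
                    best_j, best_p = j, p
            table[ws.idx[best_j], i] = counts[i]
            if best_j != pred[i]:
                pred[i] = best_j
                changed = True
        if not changed:
            break
    return pred, table


def fit_discrete_regression(x, y) -> tuple[dict, DiscreteSeries]:
    """Fit the integer regression y = f(x) + N by dependence minimization.

    f-hat assigns each cause level the effect level that makes the residual
    N-hat = y - f-hat(x) as independent of x as possible (chi-square
    p-value maximized by coordinate descent from a conditional-median
    start).  Returns the fitted map {x level -> integer prediction} and the
    residual series.
    """
    xv, yv = _as_values(x), _as_values(y)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    x_levels, x_codes = _encode(xv)
    y_levels, y_codes = _encode(yv)
    counts = np.zeros((x_levels.size, y_levels.size), dtype=np.int64)
    np.add.at(counts, (x_codes, y_codes), 1)
    pred_idx, _ = _dependence_min_fit(counts, _FitWorkspace(y_levels))
    pred = y_levels[pred_idx]
    residuals = yv - pred[x_codes]
    fitted = {int(lvl): int(p) for lvl, p in zip(x_levels, pred)}
    return fitted, DiscreteSeries(residuals)


def _reduce_table(table: np.ndarray) -> np.ndarray:
    table = table[table.sum(axis=1) > 0]
    return table[:, table.sum(axis=0) > 0]


def _fisher_2x2_p(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table via the hypergeometric pmf."""
    a = int(table[0, 0])
    r1, r2 = int(table[0].sum()), int(table[1].sum())
    c1 = int(table[:, 0].sum())
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        special.gammaln(r1 + 1)
        - special.gammaln(k + 1)
        - special.gammaln(r1 - k + 1)
        + special.gammaln(r2 + 1)
        - special.gammaln(c1 - k + 1)
        - special.gammaln(r2 - c1 + k + 1)
        - (special.gammaln(n + 1) - special.gammaln(c1 + 1) - special.gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def _fisher_rxc_p(table: np.ndarray, max_tables: int = 500_000) -> float | None:
    """Two-sided Fisher exact p for a small r x c table by full enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  Returns None if the
    enumeration would exceed ``max_tables``.
    """
    rows = table.sum(axis=1).astype(int)
    cols = table.sum(axis=0).astype(int)
    n = int(rows.sum())
    const = (
        special.gammaln(rows + 1).sum()
        + special.gammaln(cols + 1).sum()
        - special.gammaln(n + 1)
    )
    # enumeration accumulates only the -sum(lgamma(cell+1)) part; compare on
    # that same scale
    log_p_obs = -special.gammaln(table + 1).sum()

    total = 0.0
    count = 0

    def rec(row_idx: int, remaining_cols: np.ndarray, log_acc: float):
        nonlocal total, count
        if count > max_tables:
            raise OverflowError
        if row_idx == len(rows) - 1:
            count += 1
            lp = log_acc - special.gammaln(remaining_cols + 1).sum()
            if lp <= log_p_obs + 1e-9:
                total += np.exp(const + lp)
            return
        r = rows[row_idx]
        c = len(cols)

        def fill(j: int, left: int, cell_log: float, rem: np.ndarray):
            if j == c - 1:
                if left <= rem[j]:
                    new_rem = rem.copy()
                    new_rem[j] -= left
                    rec(row_idx + 1, new_rem, cell_log - special.gammaln(left + 1))
                return
            for v in range(min(left, rem[j]) + 1):
                new_rem = rem.copy()
                new_rem[j] -= v
                fill(j + 1, left - v, cell_log - special.gammaln(v + 1), new_rem)

        fill(0, int(r), log_acc, remaining_cols)

    try:
        rec(0, cols.copy(), 0.0)
    except OverflowError:
        return None
    return float(min(1.0, total))


def _chi2_p(table: np.ndarray) -> float:
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = rows * cols / n
    stat = ((table - expected) ** 2 / expected).sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(special.chdtrc(dof, stat))


def _table_pvalue(table: np.ndarray, exact_max_cells: int, exact_max_n: int) -> float | None:
    """Independence p-value for a contingency table; None when degenerate."""
    table = _reduce_table(np.asarray(table, dtype=np.int64))
    if table.shape[0] < 2 or table.shape[1] < 2:
        return None
    n = int(table.sum())
    if table.shape == (2, 2):
        return _fisher_2x2_p(table)
    if table.size <= exact_max_cells and n <= exact_max_n:
        p = _fisher_rxc_p(table)
        if p is not None:
            return p
    return _chi2_p(table)


def independence_delta(
    residuals,
    cause,
    exact_max_cells: int = EXACT_MAX_CELLS,
    exact_max_n: int = EXACT_MAX_N,
) -> float:
    """Dependence of residuals on the cause: Delta = -log10 p.

    Builds the residual x cause contingency table and returns -log10 of the
    Fisher exact p-value (chi-square fallback above the configured table
    size).  A degenerate table (a single occupied row or column) carries no
    dependence information and yields Delta = 0 with a warning.
    """
    rv, cv = _as_values(residuals), _as_values(cause)
    if rv.size != cv.size:
        raise ValueError("residuals and cause must have equal length")
    _, rc = _encode(rv)
    _, cc = _encode(cv)
    table = np.zeros((rc.max() + 1, cc.max() + 1), dtype=np.int64)
    np.add.at(table, (rc, cc), 1)
    p = _table_pvalue(table, exact_max_cells, exact_max_n)
    if p is None:
        warnings.warn("degenerate contingency table; Delta set to 0")
        return 0.0
    return float(-np.log10(max(p, _TINY_P)))


def _delta_pair(counts, ws_fwd: _FitWorkspace, ws_rev: _FitWorkspace, exact_cfg) -> tuple[float, float]:
    """Both-direction Deltas from the joint counts (permutation hot path)."""

    def one_direction(counts_dir, ws):
        _, table = _dependence_min_fit(counts_dir, ws)
        p = _table_pvalue(np.rint(table).astype(np.int64), *exact_cfg)
        return 0.0 if p is None else float(-np.log10(max(p, _TINY_P)))

    return one_direction(counts, ws_fwd), one_direction(counts.T, ws_rev)


def causation_test(
    x,
    y,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    exact_max_cells: int = EXACT_MAX_CELLS,
    exact_max_n: int = EXACT_MAX_N,
) -> CausalTestResult:
    """Permutation test of causation between two discrete series.

    T_C = |Delta_{X->Y} - Delta_{Y->X}| is compared with its distribution
    under up to ``n_permutations`` random permutations of y; the p-value
    uses the add-one estimator (1 + #{T_perm >= T_obs}) / (n_permutations + 1).
    Because the permutation distribution of T_C has atoms (both fits are
    often constant, giving exact ties at zero), ties are resolved by a
    uniform auxiliary variable attached to every permutation — the standard
    randomization that restores exact size for discrete statistics.  A
    sequential early stop ends the loop once enough exceedances have
    accrued for the p-value to exceed ``alpha`` regardless of the remaining
    permutations.  The direction is called toward the side whose residual
    is the more independent of its cause (the smaller Delta) when the test
    rejects at ``alpha``; otherwise (and whenever T_C = 0) no decision is
    made.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    xv, yv = _as_values(x), _as_values(y)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    # canonical orientation: the pair is processed in a fixed order so that
    # causation_test(x, y) and causation_test(y, x) run the identical
    # computation and differ only in the direction labels
    swap = (tuple(np.unique(xv).tolist()), tuple(xv.tolist())) > (
        tuple(np.unique(yv).tolist()),
        tuple(yv.tolist()),
    )
    if swap:
        xv, yv = yv, xv
    x_levels, x_codes = _encode(xv)
    y_levels, y_codes = _encode(yv)
    if x_levels.size < 2 or y_levels.size < 2:
        raise ValueError("both series need at least 2 occupied levels")
    exact_cfg = (exact_max_cells, exact_max_n)
    rng = np.random.default_rng(rng)
    ws_fwd = _FitWorkspace(y_levels)
    ws_rev = _FitWorkspace(x_levels)

    counts = np.zeros((x_levels.size, y_levels.size), dtype=np.int64)
    np.add.at(counts, (x_codes, y_codes), 1)
    d_xy, d_yx = _delta_pair(counts, ws_fwd, ws_rev, exact_cfg)
    t_obs = abs(d_xy - d_yx)
    u_obs = rng.random()

    # Besag-Clifford sequential stop: once `stop_at` exceedances have been
    # seen the p-value cannot fall below alpha, so stop and report h/L.
    stop_at = int(np.ceil(alpha * (n_permutations + 1))) + 1
    exceed = 0
    done = 0
    p_value = None
    for b in range(n_permutations):
        perm = rng.permutation(y_codes)
        pcounts = np.zeros_like(counts)
        np.add.at(pcounts, (x_codes, perm), 1)
        pd_xy, pd_yx = _delta_pair(pcounts, ws_fwd, ws_rev, exact_cfg)
        t_perm = abs(pd_xy - pd_yx)
        if t_perm > t_obs + 1e-12 or (abs(t_perm - t_obs) <= 1e-12 and rng.random() >= u_obs):
            exceed += 1
        done = b + 1
        if exceed >= stop_at:
            p_value = exceed / done
            break
    if p_value is None:
        p_value = (1 + exceed) / (n_permutations + 1)

    if p_value < alpha and t_obs > 0:
        direction = "x_to_y" if d_xy < d_yx else "y_to_x"
    else:
        direction = "undecided"
    if swap:
        d_xy, d_yx = d_yx, d_xy
        direction = {"x_to_y": "y_to_x", "y_to_x": "x_to_y"}.get(direction, direction)
    return CausalTestResult(
        delta_xy=d_xy,
        delta_yx=d_yx,
        t_c=t_obs,
        p_value=p_value,
        direction=direction,
        n_permutations=n_permutations,
    )


def _discretize_quantiles(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right").astype(np.int64)


def gene_level_causation(
    rare_genotypes,
    positions,
    disease,
    n_bins: int = 3,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> CausalTestResult:
    """Causation test of a gene's rare variants against disease status.

    Rare variants are summarized by the leading functional principal
    component score of the region's genotype function; the continuous score
    is discretized into ``n_bins`` quantile bins (default 3, mimicking
    genotype coding) and tested against the disease with the discrete ANM.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2 to give a discrete contingency structure")
    g = np.asarray(rare_genotypes, dtype=float)
    observed = g[~np.isnan(g)]
    if observed.size == 0 or np.all(observed == observed.flat[0]):
        raise ValueError("monomorphic gene: no genotype variation to test")
    gfm = code_genotype_function(g, positions)
    if not np.any(gfm.values - gfm.values.mean(axis=0)):
        raise ValueError("monomorphic gene: no genotype variation to test")
    fpc = fpc_scores(gfm, n_components=1)
    score = fpc.scores[:, 0]
    binned = _discretize_quantiles(score, n_bins)
    if np.unique(binned).size < 2:
        raise ValueError("FPCS discretization produced a single level")
    return causation_test(binned, disease, n_permutations=n_permutations, rng=rng, alpha=alpha)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def gwcs_scan(
    genotypes,
    regions: pd.DataFrame,
    disease,
    maf_threshold: float = 0.05,
    n_bins: int = 3,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    multiple_testing: str = "bh",
) -> pd.DataFrame:
    """Genome-wide causation scan: test every variant/gene against disease.

    ``genotypes`` is a :class:`causalnet.io.GenotypeData` (or any object with
    ``dosages`` samples x variants and ``variants`` with columns variant_id,
    chrom, pos).  ``regions`` is BED-style (chrom, start, end, name; 0-based
    half-open).  Common variants (MAF >= ``maf_threshold``) are tested one by
    one on their 0/1/2 codes; the rare variants of each region are pooled
    into one gene-level FPCS test.  Rows are ordered by genomic coordinate;
    the ``fdr`` column holds Benjamini-Hochberg adjusted p-values (or the raw
    p-values when ``multiple_testing='raw'``).
    """
    if regions is None or len(regions) == 0:
        raise ValueError("region list must be non-empty")
    if multiple_testing not in ("bh", "raw"):
        raise ValueError("multiple_testing must be 'bh' or 'raw'")
    dosages: pd.DataFrame = genotypes.dosages
    variants: pd.DataFrame = genotypes.variants
    dv = _as_values(disease)
    rng = np.random.default_rng(rng)

    rows = []
    for _, region in regions.iterrows():
        chrom, start, end = region["chrom"], int(region["start"]), int(region["end"])
        name = region.get("name", f"{chrom}:{start}-{end}")
        in_region = variants[
            (variants["chrom"].astype(str) == str(chrom))
            & (variants["pos"] >= start)
            & (variants["pos"] < end)
        ]
        base = {"region": name, "chrom": chrom, "start": start, "end": end}
        if len(in_region) == 0:
            warnings.warn(f"region {name} contains no variants")
            rows.append({**base, "unit": name, "type": "gene", "delta_xy": np.nan,
                         "delta_yx": np.nan, "t_c": np.nan, "p": np.nan, "direction": "undecided"})
            continue
        g = dosages[in_region["variant_id"]].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            maf = np.nanmean(g, axis=0) / 2
        maf = np.minimum(maf, 1 - maf)
        rare = (maf < maf_threshold) & (maf > 0)
        common = maf >= maf_threshold

        if rare.sum() >= 1:
            try:
                res = gene_level_causation(
                    g[:, rare], in_region["pos"].to_numpy()[rare], dv,
                    n_bins=n_bins, n_permutations=n_permutations, rng=rng, alpha=alpha,
                )
                rows.append({**base, "unit": name, "type": "gene", "delta_xy": res.delta_xy,
                             "delta_yx": res.delta_yx, "t_c": res.t_c, "p": res.p_value,
                             "direction": res.direction})
            except ValueError as exc:
                warnings.warn(f"gene test skipped for {name}: {exc}")
        for idx in np.flatnonzero(common):
            vid = in_region["variant_id"].iloc[idx]
            dos = g[:, idx]
            dos = np.where(np.isnan(dos), np.rint(np.nanmean(dos)), dos)
            if np.unique(dos).size < 2 or np.unique(dv).size < 2:
                continue
            res = causation_test(dos.astype(int), dv, n_permutations=n_permutations,
                                 rng=rng, alpha=alpha)
            rows.append({**base, "unit": str(vid), "type": "variant",
                         "pos": int(in_region["pos"].iloc[idx]),
                         "delta_xy": res.delta_xy, "delta_yx": res.delta_yx,
                         "t_c": res.t_c, "p": res.p_value, "direction": res.direction})
    columns = ["region", "chrom", "start", "end", "unit", "type", "pos",
               "delta_xy", "delta_yx", "t_c", "p", "direction"]
    table = pd.DataFrame(rows, columns=columns)
    table = table.sort_values(["chrom", "start", "unit"], kind="stable").reset_index(drop=True)
    table["fdr"] = _bh_adjust(table["p"].to_numpy()) if multiple_testing == "bh" else table["p"]
    return table
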