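"""Score-and-search causal DAG learning by integer linear programming.

Every candidate (node, parent set) pair gets a decomposable score: the
residual sum of squares of the node regressed on the parent set,

    C(v, W_v) = y_v' (I - D (D'D)^{-1} D') y_v + c |W_v| log n,

plus a BIC-style complexity penalty (the raw projection score alone always
prefers the densest admissible graph).  Structure learning then minimizes
sum_v C(v, W_v) x(W_v -> v) over binary indicators subject to

* the convexity constraint: exactly one parent set selected per node, and
* cluster constraints: every subset C of nodes contains at least one node
  whose selected parent set lies outside C (acyclicity).

The exponentially many cluster constraints are added lazily as cutting
planes: solve the relaxed MILP, find a cycle in the induced graph, add the
violated constraint, re-solve.  The MILP backend is HiGHS branch-and-bound
(`scipy.optimize.milp`).  The joint multilevel variant scores methylation,
expression, phenotype and disease nodes with layer-restricted candidate
sets (genotype exogenous, causality flowing downstream only) in one ILP.

The "SEMIP" estimator = sparse-SEM candidate screening -> parent-set
enumeration -> ILP solve.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .datasets import LAYER_ORDER, OmicsDataset

__all__ = [
    "ParentSetScore",
    "LayeredNetwork",
    "SemipSettings",
    "node_score",
    "enumerate_parent_sets",
    "solve_ilp",
    "exhaustive_dag_search",
    "learn_semip_network",
    "learn_multilevel_network",
]


@dataclass(frozen=True)
class ParentSetScore:
    """A (child, candidate parent set, score) triple feeding the ILP."""

    child: str
    parents: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(sorted(self.parents)))
        if self.child in self.parents:
            raise ValueError(f"child {self.child!r} cannot be its own parent")
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass
class LayeredNetwork:
    """A learned DAG with layer labels, chosen parent sets and total score."""

    graph: nx.DiGraph
    parent_sets: dict[str, tuple[str, ...]]
    total_score: float
    optimal: bool = True
    n_cluster_constraints: int = 0

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("learned network must be acyclic")

    @property
    def edges(self):
        return list(self.graph.edges())

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "parent": u,
                "child": v,
                "parent_layer": self.graph.nodes[u].get("layer", ""),
                "child_layer": self.graph.nodes[v].get("layer", ""),
            }
            for u, v in self.graph.edges()
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "parent_layer", "child_layer"])

    def write_edge_tsv(self, path) -> None:
        self.to_edge_dataframe().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def node_score(
    child_values,
    parent_matrix=None,
    penalty_c: float = 1.0,
    instruments=None,
) -> float:
    """Projection score of a node on a parent design, plus complexity penalty.

    The default score is the residual sum of squares of the child regressed
    on the parents (intercept always included; the empty parent set scores
    the centred total sum of squares).  When ``instruments`` is supplied the
    alternative 2SLS score is used instead: the quadratic form
    f(Delta) = (X'y - X'D Delta)'(X'X)^{-1}(X'y - X'D Delta) evaluated at
    its restricted minimizer, which limits identification to the instrument
    span.  Both get the complexity penalty c * |parents| * log(n).  A
    singular design is handled by the least-squares pseudo-inverse
    (equivalent to a vanishing ridge) with a warning.
    """
    y = np.asarray(child_values, dtype=float).ravel()
    n = y.shape[0]
    if parent_matrix is None or (hasattr(parent_matrix, "shape") and parent_matrix.shape[1] == 0):
        d = None
        k = 0
    else:
        d = np.atleast_2d(np.asarray(parent_matrix, dtype=float))
        if d.shape[0] != n:
            raise ValueError("parent design must have one row per sample")
        if d.shape[1] >= n:
            raise ValueError("parent design must have fewer columns than samples")
        k = d.shape[1]
    if instruments is not None:
        from .sem import TwoStageObjective

        x = np.atleast_2d(np.asarray(instruments, dtype=float))
        yc = y - y.mean()
        if d is None:
            obj = TwoStageObjective(yc, np.zeros((n, 0)), x - x.mean(axis=0))
            base = obj.c0
        else:
            obj = TwoStageObjective(yc, d - d.mean(axis=0), x - x.mean(axis=0))
            base = obj(obj.minimizer())
        return base + penalty_c * k * np.log(n)
    if d is None:
        resid = y - y.mean()
        rss = float(resid @ resid)
    else:
        design = np.column_stack([np.ones(n), d])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("singular parent design; pseudo-inverse projection")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        rss = float(resid @ resid)
    return rss + penalty_c * k * np.log(n)


def _score_subsets_rss(y, w, subsets, penalty_c):
    """RSS scores for many subsets from one precomputed Gram (same math as
    :func:`node_score`, computed via the normal equations)."""
    n = y.shape[0]
    yc = y - y.mean()
    wc = w - w.mean(axis=0)
    gram = wc.T @ wc
    xty = wc.T @ yc
    tss = float(yc @ yc)
    out = {}
    logn = np.log(n)
    for combo_idx in subsets:
        k = len(combo_idx)
        if k == 0:
            out[combo_idx] = tss
            continue
        ii = np.ix_(combo_idx, combo_idx)
        g = xty[list(combo_idx)]
        coef = np.linalg.lstsq(gram[ii], g, rcond=None)[0]
        out[combo_idx] = tss - float(g @ coef) + penalty_c * k * logn
    return out


def _score_subsets_tsls(y, w, x, subsets, penalty_c):
    """2SLS quadratic-form scores for many subsets via precomputed moments."""
    n = y.shape[0]
    yc = y - y.mean()
    wc = w - w.mean(axis=0)
    xc = x - x.mean(axis=0)
    xtx = xc.T @ xc
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        xtx = xtx + (1e-8 * np.trace(xtx) / xtx.shape[0]) * np.eye(xtx.shape[0])
    m = np.linalg.inv(xtx)
    b = xc.T @ yc
    a_full = xc.T @ wc
    mb = m @ b
    base = float(b @ mb)
    out = {}
    logn = np.log(n)
    for combo_idx in subsets:
        k = len(combo_idx)
        if k == 0:
            out[combo_idx] = base
            continue
        a = a_full[:, list(combo_idx)]
        h = a.T @ m @ a
        g = a.T @ mb
        coef = np.linalg.lstsq(h, g, rcond=None)[0]
        out[combo_idx] = base - float(g @ coef) + penalty_c * k * logn
    return out


def enumerate_parent_sets(
    child: str,
    candidates: list[str],
    data: pd.DataFrame,
    max_parents: int = 3,
    prune: bool = True,
    penalty_c: float = 1.0,
    score: str = "rss",
    instruments: list[str] | None = None,
) -> list[ParentSetScore]:
    """Score all parent subsets of ``candidates`` up to size ``max_parents``.

    The empty set is always included.  ``score`` selects the regression-RSS
    projection score (default) or the 2SLS quadratic-form score (``tsls``,
    requires ``instruments`` column names).  With ``prune``, any set scoring
    no better than one of its proper subsets is dropped (dominance pruning:
    a subset is acyclicity-feasible whenever its superset is, so the optimum
    is preserved).
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if child in candidates:
        raise ValueError("candidate list must not contain the child")
    if score not in ("rss", "tsls"):
        raise ValueError("score must be 'rss' or 'tsls'")
    cand = sorted(candidates)
    y = data[child].to_numpy(dtype=float)
    w = data[cand].to_numpy(dtype=float) if cand else np.zeros((len(y), 0))
    subsets = [
        combo
        for size in range(0, max_parents + 1)
        for combo in itertools.combinations(range(len(cand)), size)
    ]
    if score == "tsls":
        if not instruments:
            raise ValueError("tsls score requires instrument columns")
        x = data[list(instruments)].to_numpy(dtype=float)
        idx_scores = _score_subsets_tsls(y, w, x, subsets, penalty_c)
    else:
        idx_scores = _score_subsets_rss(y, w, subsets, penalty_c)
    scored = {tuple(cand[i] for i in combo): s for combo, s in idx_scores.items()}
    if prune:
        kept = {}
        for parents, score in scored.items():
            dominated = False
            for r in range(len(parents)):
                for sub in itertools.combinations(parents, r):
                    if scored.get(sub, np.inf) <= score:
                        dominated = True
                        break
                if dominated:
                    break
            if not dominated:
                kept[parents] = score
        scored = kept
    return [ParentSetScore(child=child, parents=p, score=s) for p, s in sorted(scored.items())]


def _induced_graph(choice: dict[str, tuple[str, ...]], layers: dict[str, str] | None) -> nx.DiGraph:
    g = nx.DiGraph()
    for child, parents in choice.items():
        g.add_node(child)
        for p in parents:
            g.add_edge(p, child)
    if layers:
        nx.set_node_attributes(g, {n: layers.get(n, "") for n in g.nodes}, "layer")
    return g


def solve_ilp(
    scores: list[ParentSetScore],
    layers: dict[str, str] | None = None,
    time_limit_s: float | None = None,
    max_rounds: int = 200,
) -> LayeredNetwork:
    """Select one parent set per scored node, minimizing the total score
    subject to acyclicity.

    Convexity constraints force exactly one indicator per node; acyclicity
    is enforced lazily: after each MILP solve, any directed cycle among the
    chosen parent sets triggers the corresponding cluster constraint (at
    least one node of the cycle must pick a parent set disjoint from it) and
    a re-solve.  Nodes that never appear as children (exogenous genotype
    nodes) cannot lie on cycles, so constraints involve scored nodes only.
    A tiny lexicographic perturbation makes the selected optimum unique and
    reproducible across solver versions; the reported total score is the sum
    of the unperturbed chosen scores.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    children = sorted({s.child for s in scores})
    by_child: dict[str, list[ParentSetScore]] = {c: [] for c in children}
    for s in scores:
        by_child[s.child].append(s)
    for c, lst in by_child.items():
        if not any(len(s.parents) == 0 for s in lst):
            raise ValueError(f"node {c!r} lacks an empty candidate parent set")
        lst.sort(key=lambda s: (len(s.parents), s.parents))

    variables: list[ParentSetScore] = []
    var_index: dict[tuple[str, tuple[str, ...]], int] = {}
    for c in children:
        for s in by_child[c]:
            var_index[(c, s.parents)] = len(variables)
            variables.append(s)
    n_var = len(variables)

    scale = max(np.mean([abs(v.score) for v in variables]), 1.0)
    eps = 1e-9 * scale
    cost = np.array([v.score + eps * i / max(n_var, 1) for i, v in enumerate(variables)])

    rows, cols = [], []
    for ci, c in enumerate(children):
        for s in by_child[c]:
            rows.append(ci)
            cols.append(var_index[(c, s.parents)])
    a_eq = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(children), n_var))
    constraints = [optimize.LinearConstraint(a_eq, 1.0, 1.0)]

    integrality = np.ones(n_var)
    bounds = optimize.Bounds(0.0, 1.0)
    options = {}
    if time_limit_s is not None:
        options["time_limit"] = float(time_limit_s)

    scored_set = set(children)
    n_cluster = 0
    optimal = True
    for _ in range(max_rounds):
        res = optimize.milp(
            c=cost,
            constraints=constraints,
            integrality=integrality,
            bounds=bounds,
            options=options,
        )
        if res.status == 2:
            raise RuntimeError("ILP infeasible under the given layer constraints")
        if res.x is None:
            raise RuntimeError(f"MILP solver failed: {res.message}")
        if res.status == 1:
            optimal = False
        chosen = np.flatnonzero(res.x > 0.5)
        choice = {variables[i].child: variables[i].parents for i in chosen}
        induced = _induced_graph(choice, layers)
        try:
            cycle = nx.find_cycle(induced)
        except nx.NetworkXNoCycle:
            total = float(sum(variables[i].score for i in chosen))
            g = nx.DiGraph()
            node_layers = layers or {}
            for child, parents in choice.items():
                g.add_node(child, layer=node_layers.get(child, ""))
                for p in parents:
                    g.add_node(p, layer=node_layers.get(p, ""))
                    g.add_edge(p, child)
            return LayeredNetwork(
                graph=g,
                parent_sets=choice,
                total_score=total,
                optimal=optimal,
                n_cluster_constraints=n_cluster,
            )
        cluster = {u for u, v, *_ in cycle} & scored_set
        idx, vals = [], []
        for c in cluster:
            for s in by_child[c]:
                if not set(s.parents) & cluster:
                    idx.append(var_index[(c, s.parents)])
                    vals.append(1.0)
        a_cl = sparse.csr_matrix((vals, (np.zeros(len(idx)), idx)), shape=(1, n_var))
        constraints.append(optimize.LinearConstraint(a_cl, 1.0, np.inf))
        n_cluster += 1
    raise RuntimeError("cutting-plane loop did not terminate (max_rounds reached)")


def exhaustive_dag_search(
    scores: list[ParentSetScore],
    layers: dict[str, str] | None = None,
    max_nodes: int = 6,
) -> LayeredNetwork:
    """Brute-force optimum over all parent-set assignments that form a DAG.

    A test oracle for :func:`solve_ilp` on tiny instances; ties break toward
    the lexicographically smallest parent-set assignment.
    """
    children = sorted({s.child for s in scores})
    if len(children) > max_nodes:
        raise ValueError(f"exhaustive search limited to {max_nodes} scored nodes")
    by_child: dict[str, list[ParentSetScore]] = {c: [] for c in children}
    for s in scores:
        by_child[s.child].append(s)
    for c, lst in by_child.items():
        if not any(len(s.parents) == 0 for s in lst):
            raise ValueError(f"node {c!r} lacks an empty candidate parent set")
        lst.sort(key=lambda s: (len(s.parents), s.parents))

    best = None
    for combo in itertools.product(*(by_child[c] for c in children)):
        choice = {s.child: s.parents for s in combo}
        induced = _induced_graph(choice, None)
        if not nx.is_directed_acyclic_graph(induced):
            continue
        total = sum(s.score for s in combo)
        key = (total, tuple(choice[c] for c in children))
        if best is None or key < best[0]:
            best = (key, choice)
    if best is None:
        raise RuntimeError("no acyclic assignment exists")
    (total, _), choice = best
    g = nx.DiGraph()
    node_layers = layers or {}
    for child, parents in choice.items():
        g.add_node(child, layer=node_layers.get(child, ""))
        for p in parents:
            g.add_node(p, layer=node_layers.get(p, ""))
            g.add_edge(p, child)
    return LayeredNetwork(graph=g, parent_sets=choice, total_score=float(total))


@dataclass
class SemipSettings:
    """Tuning knobs of the SEMIP pipeline."""

    max_parents: int = 3
    penalty_c: float = 1.0
    #: "lasso" = neighborhood-selection screening (lasso regression path);
    #: "sem" = union of sparse-2SLS supports over the lambda grid;
    #: None = no screening (all admissible candidates enumerated).
    screening: str | None = "lasso"
    #: cap on screened candidates per node.
    max_candidates: int = 12
    #: candidate counts at or below this skip screening entirely.
    screen_above: int = 8
    n_lambda: int = 20
    #: node-score family: regression RSS ("rss") or the 2SLS quadratic form
    #: ("tsls"), both plus the c*|W|*log(n) complexity penalty.
    score: str = "rss"
    time_limit_s: float | None = None
    prune: bool = True


def _screen_lasso(y: np.ndarray, data: pd.DataFrame, candidates: list[str], cap: int) -> list[str]:
    """Neighborhood selection: first ``cap`` candidates entering the lasso path."""
    from sklearn.linear_model import lars_path

    x = data[candidates].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    yc = y - y.mean()
    _, _, coefs = lars_path(x, yc, method="lasso", max_iter=max(4 * cap, 32))
    entered: list[int] = []
    for col in range(coefs.shape[1]):
        for j in np.flatnonzero(coefs[:, col]):
            if j not in entered:
                entered.append(int(j))
    return sorted(candidates[j] for j in entered[:cap])


def _screen_sem(
    y: np.ndarray,
    data: pd.DataFrame,
    candidates: list[str],
    exogenous: list[str],
    cap: int,
    n_lambda: int,
) -> list[str]:
    """Union of sparse-2SLS supports over the lambda grid, capped by entry order."""
    from .sem import TwoStageObjective, _prox_lasso, default_lambda_grid

    w = data[candidates].to_numpy(dtype=float)
    w = w - w.mean(axis=0)
    x = data[exogenous].to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    obj = TwoStageObjective(y - y.mean(), w, x)
    entered: list[int] = []
    for lam in default_lambda_grid(obj, n_lambda=n_lambda):
        z = _prox_lasso(obj, lam)
        for j in np.flatnonzero(np.abs(z) > 1e-8):
            if j not in entered:
                entered.append(int(j))
        if len(entered) >= cap:
            break
    return sorted(candidates[j] for j in entered[:cap])


def _screen(y, data, candidates, exogenous, settings: SemipSettings) -> list[str]:
    if settings.screening is None or len(candidates) <= settings.screen_above:
        return sorted(candidates)
    if settings.screening == "lasso":
        return _screen_lasso(y, data, candidates, settings.max_candidates)
    if settings.screening == "sem":
        return _screen_sem(y, data, candidates, exogenous, settings.max_candidates, settings.n_lambda)
    raise ValueError(f"unknown screening mode {settings.screening!r}")


def _candidate_map_for_layers(dataset: OmicsDataset) -> dict[str, list[str]]:
    """Admissible candidate parents per endogenous node under the layer rules.

    Methylation may depend on methylation and genotype; expression on
    expression, methylation and genotype; phenotype on any non-disease node;
    disease on any non-disease node.  Genotype nodes are exogenous.
    """
    upstream = {
        "methylation": {"methylation", "genotype"},
        "expression": {"expression", "methylation", "genotype"},
        "phenotype": {"phenotype", "expression", "methylation", "genotype"},
        "disease": {"phenotype", "expression", "methylation", "genotype"},
    }
    out = {}
    for node in dataset.endogenous_nodes:
        layer = dataset.layers[node]
        allowed = upstream[layer]
        out[node] = [c for c in dataset.nodes if c != node and dataset.layers[c] in allowed]
    return out


def _learn_from_candidates(
    dataset: OmicsDataset,
    candidate_map: dict[str, list[str]],
    settings: SemipSettings,
) -> LayeredNetwork:
    exo = dataset.genotype_nodes
    all_scores: list[ParentSetScore] = []
    for node, candidates in candidate_map.items():
        y = dataset.data[node].to_numpy(dtype=float)
        screened = _screen(y, dataset.data, candidates, exo, settings)
        all_scores.extend(
            enumerate_parent_sets(
                node,
                screened,
                dataset.data,
                max_parents=settings.max_parents,
                prune=settings.prune,
                penalty_c=settings.penalty_c,
                score=settings.score,
                instruments=exo if settings.score == "tsls" else None,
            )
        )
    net = solve_ilp(all_scores, layers=dataset.layers, time_limit_s=settings.time_limit_s)
    for n in dataset.nodes:  # isolated nodes stay in the output
        if n not in net.graph:
            net.graph.add_node(n, layer=dataset.layers[n])
    return net


def learn_semip_network(dataset: OmicsDataset, settings: SemipSettings | None = None) -> LayeredNetwork:
    """The SEMIP estimator: screening -> parent-set scores -> ILP DAG.

    Every endogenous node is scored against candidate parents drawn from the
    other endogenous nodes plus the genotype nodes (genotype enters only as
    a parent).  The returned graph is a DAG respecting the layer rules.
    """
    settings = settings or SemipSettings()
    endo = dataset.endogenous_nodes
    if not endo:
        raise ValueError("dataset has no endogenous layer")
    exo = dataset.genotype_nodes
    candidate_map = {node: [c for c in endo if c != node] + exo for node in endo}
    return _learn_from_candidates(dataset, candidate_map, settings)


def learn_multilevel_network(
    genotype: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    phenotype: pd.DataFrame | None = None,
    disease: pd.DataFrame | None = None,
    settings: SemipSettings | None = None,
) -> LayeredNetwork:
    """Joint multilevel causal network over all supplied omics layers.

    All matrices must be sample-aligned (same row count and order).  One
    single ILP scores every endogenous node with layer-respecting candidate
    sets: methylation <- {methylation, genotype}, expression <- {expression,
    methylation, genotype}, phenotype and disease <- all non-disease nodes.
    With a single endogenous layer this reduces exactly to
    :func:`learn_semip_network`.
    """
    settings = settings or SemipSettings()
    supplied = {
        "genotype": genotype,
        "methylation": methylation,
        "expression": expression,
        "phenotype": phenotype,
        "disease": disease,
    }
    frames = {k: v for k, v in supplied.items() if v is not None}
    if not any(k != "genotype" for k in frames):
        raise ValueError("need at least one endogenous layer")
    n_rows = {k: len(v) for k, v in frames.items()}
    if len(set(n_rows.values())) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in sorted(n_rows.items()))
        raise ValueError(f"sample misalignment across matrices: {detail}")

    data = pd.concat([frames[k].reset_index(drop=True) for k in LAYER_ORDER if k in frames], axis=1)
    if data.columns.duplicated().any():
        raise ValueError("duplicate column names across layers")
    layers = {}
    for layer in LAYER_ORDER:
        if layer in frames:
            layers.update({c: layer for c in frames[layer].columns})
    dataset = OmicsDataset(data=data, layers=layers)
    candidate_map = _candidate_map_for_layers(dataset)
    return _learn_from_candidates(dataset, candidate_map, settings)
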