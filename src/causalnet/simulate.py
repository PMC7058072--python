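"""Random layered causal DAGs, linear-SEM data generation and benchmarking.

The generative model: a directed acyclic graph over ``n_genotype_nodes``
exogenous genotype nodes and ``n_nodes - n_genotype_nodes`` endogenous
(expression/phenotype) nodes.  Endogenous values follow the linear recursion

    y_i = sum_{j in pa(y_i)} gamma_ji * y_j + sum_{k in pa(y_i)} beta_ki * x_k + e_i

with coefficient magnitudes drawn from U(coeff_low, coeff_high) (default
U(1, 2)) and e_i ~ N(0, noise_sd^2).  Estimated networks are scored against
the simulated truth by edge-wise power and false-discovery rates, and
:func:`run_benchmark` drives the power/FDR comparison of a correlation
baseline, the sparse-SEM estimator and the SEM+integer-programming (SEMIP)
estimator over a grid of network sizes and sample sizes.
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
    "SimulationConfig",
    "TrueModel",
    "PowerFDR",
    "random_dag",
    "simulate_dataset",
    "evaluate_network",
    "correlation_baseline",
    "run_benchmark",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated-network scenario.

    Defaults mirror the benchmark's smallest scenario: 20 nodes of which 5
    are genotype nodes, a mean of 30 directed edges, coefficient magnitudes
    U(1, 2) and unit-variance Gaussian noise.
    """

    n_nodes: int = 20
    n_genotype_nodes: int = 5
    target_edges: int = 30
    n_samples: int = 1000
    coeff_low: float = 1.0
    coeff_high: float = 2.0
    noise_sd: float = 1.0
    n_replicates: int = 1
    seed: int = 0
    #: multiply each coefficient by an independent random sign; switch off to
    #: draw strictly positive coefficients.
    random_sign: bool = True
    #: "gaussian" draws standardized N(0,1) genotype scores; "hwe" draws 0/1/2
    #: genotypes at Hardy-Weinberg proportions and standardizes them.
    genotype_mode: str = "gaussian"
    maf: float = 0.3

    def __post_init__(self) -> None:
        if self.n_nodes <= 0 or self.n_genotype_nodes <= 0:
            raise ValueError("node counts must be positive")
        if self.n_genotype_nodes >= self.n_nodes:
            raise ValueError("n_genotype_nodes must be < n_nodes")
        if self.target_edges <= 0 or self.n_samples <= 0 or self.n_replicates <= 0:
            raise ValueError("target_edges, n_samples, n_replicates must be positive")
        if not self.coeff_low < self.coeff_high:
            raise ValueError("coeff_low must be < coeff_high")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.genotype_mode not in ("gaussian", "hwe"):
            raise ValueError("genotype_mode must be 'gaussian' or 'hwe'")
        m = self.n_nodes - self.n_genotype_nodes
        max_edges = self.n_genotype_nodes * m + m * (m - 1) // 2
        if self.target_edges > max_edges:
            raise ValueError(
                f"target_edges={self.target_edges} exceeds the maximum "
                f"{max_edges} admissible under the layer constraint"
            )

    @property
    def n_endogenous(self) -> int:
        return self.n_nodes - self.n_genotype_nodes

    @property
    def max_edges(self) -> int:
        m = self.n_endogenous
        return self.n_genotype_nodes * m + m * (m - 1) // 2


@dataclass
class TrueModel:
    """A simulated causal DAG with its structural coefficients.

    ``gamma`` holds endogenous->endogenous edge coefficients, ``beta`` the
    genotype->endogenous ones.  Genotype nodes have in-degree zero.
    """

    dag: nx.DiGraph
    gamma: dict[tuple[str, str], float]
    beta: dict[tuple[str, str], float]
    noise_sd: float = 1.0
    genotype_mode: str = "gaussian"
    maf: float = 0.3

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("true model graph must be acyclic")
        for u, v in self.dag.edges():
            key = (u, v)
            n_coef = (key in self.gamma) + (key in self.beta)
            if n_coef != 1:
                raise ValueError(f"edge {key} must have exactly one coefficient")
        for node, layer in nx.get_node_attributes(self.dag, "layer").items():
            if layer == "genotype" and self.dag.in_degree(node) > 0:
                raise ValueError(f"genotype node {node} has parents")

    @property
    def genotype_nodes(self) -> list[str]:
        return [n for n, d in self.dag.nodes(data=True) if d.get("layer") == "genotype"]

    @property
    def endogenous_nodes(self) -> list[str]:
        return [n for n, d in self.dag.nodes(data=True) if d.get("layer") != "genotype"]

    def coefficient(self, u: str, v: str) -> float:
        return self.gamma.get((u, v), self.beta.get((u, v)))


@dataclass
class PowerFDR:
    """Confusion counts and rates for one estimated-vs-true graph comparison.

    ``fdr_paper`` is N_False / N_0 (false edges over absent edges, a false
    positive rate); ``fdr_conventional`` is N_False / (N_True + N_False).
    """

    n_t: int
    n_0: int
    n_true: int
    n_false: int

    @property
    def power(self) -> float:
        return self.n_true / self.n_t if self.n_t else 0.0

    @property
    def fdr_paper(self) -> float:
        return self.n_false / self.n_0 if self.n_0 else 0.0

    @property
    def fdr_conventional(self) -> float:
        detected = self.n_true + self.n_false
        return self.n_false / detected if detected else 0.0


def _node_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    geno = [f"X{i + 1}" for i in range(config.n_genotype_nodes)]
    endo = [f"Y{i + 1}" for i in range(config.n_endogenous)]
    return geno, endo


def random_dag(config: SimulationConfig, rng: np.random.Generator | int | None = None) -> TrueModel:
    """Draw a random layered DAG with expected edge count ``target_edges``.

    Endogenous nodes get a uniformly random topological order; every
    admissible ordered pair (genotype -> endogenous, or earlier -> later
    endogenous) is included independently with probability
    ``target_edges / max_edges``, so the expected number of directed edges
    equals ``target_edges``.  Coefficient magnitudes are i.i.d.
    U(coeff_low, coeff_high), optionally with independent random signs.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    geno, endo = _node_names(config)
    order = list(rng.permutation(endo))
    p_edge = config.target_edges / config.max_edges

    g = nx.DiGraph()
    for n in geno:
        g.add_node(n, layer="genotype")
    for n in endo:
        g.add_node(n, layer="expression")

    admissible: list[tuple[str, str, bool]] = []
    for x in geno:
        for y in endo:
            admissible.append((x, y, True))
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            admissible.append((u, v, False))

    keep = rng.random(len(admissible)) < p_edge
    magnitudes = rng.uniform(config.coeff_low, config.coeff_high, len(admissible))
    signs = rng.choice([-1.0, 1.0], len(admissible)) if config.random_sign else np.ones(len(admissible))

    gamma: dict[tuple[str, str], float] = {}
    beta: dict[tuple[str, str], float] = {}
    for (u, v, is_geno), k, mag, s in zip(admissible, keep, magnitudes, signs):
        if not k:
            continue
        g.add_edge(u, v)
        coef = float(mag * s)
        (beta if is_geno else gamma)[(u, v)] = coef
    return TrueModel(
        dag=g,
        gamma=gamma,
        beta=beta,
        noise_sd=config.noise_sd,
        genotype_mode=config.genotype_mode,
        maf=config.maf,
    )


def simulate_dataset(
    model: TrueModel, n_samples: int, rng: np.random.Generator | int | None = None
) -> OmicsDataset:
    """Simulate a dataset from a :class:`TrueModel` by the linear recursion.

    Genotype nodes are exogenous: standardized N(0,1) scores by default, or
    standardized Hardy-Weinberg 0/1/2 genotypes in ``hwe`` mode.  Endogenous
    nodes are filled in topological order with independent N(0, noise_sd^2)
    errors.  Column order is genotype nodes then endogenous nodes, each in
    name order, so output is deterministic given the node labels and seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng)
    geno = sorted(model.genotype_nodes)
    endo = sorted(model.endogenous_nodes)
    values: dict[str, np.ndarray] = {}
    for x in geno:
        if model.genotype_mode == "hwe":
            maf = model.maf
            dosage = rng.binomial(2, maf, n_samples).astype(float)
            mu, sd = 2 * maf, np.sqrt(2 * maf * (1 - maf))
            values[x] = (dosage - mu) / sd
        else:
            values[x] = rng.standard_normal(n_samples)

    order = [n for n in nx.topological_sort(model.dag) if n in set(endo)]
    for y in order:
        acc = rng.normal(0.0, model.noise_sd, n_samples)
        for parent in model.dag.predecessors(y):
            acc = acc + model.coefficient(parent, y) * values[parent]
        values[y] = acc

    cols = geno + endo
    data = pd.DataFrame({c: values[c] for c in cols})
    layers = {n: model.dag.nodes[n].get("layer", "expression") for n in cols}
    return OmicsDataset(data=data, layers=layers)


def _edge_sets(graph, directed: bool) -> set:
    if isinstance(graph, nx.Graph):
        edges = graph.edges()
    else:
        edges = graph
    if directed:
        return {(u, v) for u, v in edges}
    return {frozenset((u, v)) for u, v in edges}


def evaluate_network(truth, estimate, mode: str = "directed") -> PowerFDR:
    """Compare an estimated graph with the true DAG edge by edge.

    In ``directed`` mode every ordered node pair is classified (N_0 counts
    ordered pairs absent from the truth, so a reversed true edge counts as
    false).  In ``undirected`` mode the two skeletons are compared over
    unordered pairs.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError("mode must be 'directed' or 'undirected'")
    t_nodes = set(truth.nodes())
    e_nodes = set(estimate.nodes())
    if t_nodes != e_nodes:
        raise ValueError("truth and estimate must share the same node set")
    n = len(t_nodes)
    directed = mode == "directed"
    true_edges = _edge_sets(truth.edges(), directed)
    est_edges = _edge_sets(estimate.edges(), directed)
    # self-loops are never admissible
    n_pairs = n * (n - 1) if directed else n * (n - 1) // 2
    n_t = len(true_edges)
    n_0 = n_pairs - n_t
    n_true = len(true_edges & est_edges)
    n_false = len(est_edges - true_edges)
    return PowerFDR(n_t=n_t, n_0=n_0, n_true=n_true, n_false=n_false)


def correlation_baseline(data: OmicsDataset | pd.DataFrame, alpha: float = 0.05) -> nx.Graph:
    """Undirected co-variation network: edge where the Pearson correlation
    test rejects at level ``alpha``.

    A deliberately simple stand-in for weighted co-expression networks,
    which estimate undirected structure only.
    """
    df = data.data if isinstance(data, OmicsDataset) else data
    n = df.shape[0]
    if n < 3:
        raise ValueError("correlation test needs at least 3 samples")
    g = nx.Graph()
    g.add_nodes_from(df.columns)
    sd = df.std(ddof=0).to_numpy()
    constant = set(df.columns[sd == 0])
    if constant:
        warnings.warn(f"constant columns get no edges: {sorted(constant)[:5]}")
    cols = [c for c in df.columns if c not in constant]
    x = df[cols].to_numpy()
    x = (x - x.mean(0)) / x.std(0, ddof=0)
    r = x.T @ x / n
    # t-test p-value for Pearson correlation
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.clip(r, -0.9999999999, 0.9999999999)
        t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    for i, u in enumerate(cols):
        for j in range(i + 1, len(cols)):
            if p[i, j] < alpha:
                g.add_edge(u, cols[j])
    return g


_METHODS = ("correlation_baseline", "sem", "semip")


def _fit_method(method: str, dataset: OmicsDataset, settings: dict):
    if method == "correlation_baseline":
        return correlation_baseline(dataset, alpha=settings.get("alpha", 0.05))
    if method == "sem":
        from .sem import fit_sem_network

        return fit_sem_network(dataset, alpha=settings.get("alpha", 0.05)).graph
    if method == "semip":
        from .ilp import SemipSettings, learn_semip_network

        semip_settings = settings.get("semip_settings") or SemipSettings()
        return learn_semip_network(dataset, semip_settings).graph
    raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")


def run_benchmark(
    configs: list[SimulationConfig],
    methods: list[str],
    rng: np.random.Generator | int | None = None,
    settings: dict | None = None,
) -> pd.DataFrame:
    """Power/FDR benchmark over a grid of scenarios and estimators.

    For every (config, method) cell: draw ``config.n_replicates`` random
    models, simulate data, fit the estimator and average the edge-wise power
    and FDR over replicates.  Directed rows are reported for directed
    estimators; the correlation baseline contributes undirected rows only.
    Returns a long-format table with columns method, nodes, samples, mode,
    power, fdr, fdr_paper, replicates.
    """
    for m in methods:
        if m not in _METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {_METHODS}")
    rng = np.random.default_rng(rng)
    settings = settings or {}
    rows = []
    for config in configs:
        for method in methods:
            modes = ("undirected",) if method == "correlation_baseline" else ("directed", "undirected")
            acc = {mode: [] for mode in modes}
            for _ in range(config.n_replicates):
                model = random_dag(config, rng)
                dataset = simulate_dataset(model, config.n_samples, rng)
                estimate = _fit_method(method, dataset, settings)
                for mode in modes:
                    acc[mode].append(evaluate_network(model.dag, estimate, mode))
            for mode in modes:
                results = acc[mode]
                rows.append(
                    {
                        "method": method,
                        "nodes": config.n_nodes,
                        "samples": config.n_samples,
                        "mode": mode,
                        "power": float(np.mean([r.power for r in results])),
                        "fdr": float(np.mean([r.fdr_conventional for r in results])),
                        "fdr_paper": float(np.mean([r.fdr_paper for r in results])),
                        "replicates": config.n_replicates,
                    }
                )
    return pd.DataFrame(rows)


def write_benchmark_tsv(table: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a benchmark table as TSV with seed recorded in a '#' header."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        table.to_csv(fh, sep="\t", index=False)
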