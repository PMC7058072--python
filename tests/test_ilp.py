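import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from causalnet.datasets import OmicsDataset
from causalnet.ilp import (
    ParentSetScore,
    SemipSettings,
    enumerate_parent_sets,
    exhaustive_dag_search,
    learn_multilevel_network,
    learn_semip_network,
    node_score,
    solve_ilp,
)
from causalnet.simulate import SimulationConfig, random_dag, simulate_dataset

from conftest import make_chain_dataset


def normal_equations_rss(y, d):
    """Independent projection-score oracle via explicit normal equations."""
    design = np.column_stack([np.ones(len(y)), d]) if d is not None else np.ones((len(y), 1))
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ coef
    return float(resid @ resid)


def random_parent_set_scores(rng, n_nodes, max_parents=3):
    nodes = [f"n{i}" for i in range(n_nodes)]
    scores = []
    for child in nodes:
        cands = [c for c in nodes if c != child]
        for k in range(0, max_parents + 1):
            for combo in itertools.combinations(cands, k):
                scores.append(ParentSetScore(child, combo, float(rng.normal())))
    return scores


class TestNodeScore:
    def test_child_in_parent_span_leaves_only_the_penalty(self, rng):
        d = rng.standard_normal((50, 2))
        y = d @ np.array([2.0, -1.0]) + 3.0
        score = node_score(y, d, penalty_c=1.0)
        assert score == pytest.approx(2 * np.log(50), abs=1e-8)

    def test_empty_parent_set_scores_centred_tss(self, rng):
        y = rng.standard_normal(80) * 2 + 1
        assert node_score(y, None) == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 30))
            k = int(rng.integers(1, 4))
            d = rng.standard_normal((n, k))
            y = rng.standard_normal(n)
            expected = normal_equations_rss(y, d) + k * np.log(n)
            assert node_score(y, d) == pytest.approx(expected, abs=1e-10)

    def test_too_wide_design_is_an_error(self, rng):
        with pytest.raises(ValueError, match="fewer columns"):
            node_score(rng.standard_normal(4), rng.standard_normal((4, 5)))

    def test_tsls_variant_is_bounded_by_projected_outcome(self, rng):
        n = 100
        x = rng.standard_normal((n, 3))
        d = x @ rng.standard_normal((3, 2)) + 0.3 * rng.standard_normal((n, 2))
        y = d[:, 0] + rng.standard_normal(n)
        with_parents = node_score(y, d, instruments=x)
        empty = node_score(y, None, instruments=x)
        assert with_parents - 2 * np.log(n) <= empty + 1e-9


class TestEnumerateParentSets:
    data = pd.DataFrame(
        np.random.default_rng(0).standard_normal((60, 5)), columns=list("abcde")
    )

    def test_no_candidates_gives_only_the_empty_set(self):
        out = enumerate_parent_sets("a", [], self.data)
        assert len(out) == 1 and out[0].parents == ()

    def test_subset_count_bounded_by_binomials(self):
        out = enumerate_parent_sets("a", list("bcde"), self.data, max_parents=2, prune=False)
        assert len(out) == 1 + 4 + 6

    def test_child_among_candidates_is_an_error(self):
        with pytest.raises(ValueError, match="child"):
            enumerate_parent_sets("a", ["a", "b"], self.data)

    def test_empty_set_survives_pruning(self):
        out = enumerate_parent_sets("a", list("bcd"), self.data, prune=True)
        assert any(s.parents == () for s in out)

    def test_pruning_preserves_the_ilp_optimum(self, rng):
        for _ in range(20):
            data = pd.DataFrame(rng.standard_normal((40, 5)), columns=list("abcde"))
            all_scores, pruned_scores = [], []
            for child in data.columns:
                cands = [c for c in data.columns if c != child]
                all_scores += enumerate_parent_sets(child, cands, data, max_parents=2, prune=False)
                pruned_scores += enumerate_parent_sets(child, cands, data, max_parents=2, prune=True)
            full = solve_ilp(all_scores)
            pruned = solve_ilp(pruned_scores)
            assert full.total_score == pytest.approx(pruned.total_score, abs=1e-9)


class TestSolveIlp:
    def test_empty_sets_cheapest_gives_empty_graph(self):
        scores = []
        for child in ["a", "b", "c"]:
            scores.append(ParentSetScore(child, (), 0.0))
            for other in ["a", "b", "c"]:
                if other != child:
                    scores.append(ParentSetScore(child, (other,), 5.0))
        net = solve_ilp(scores)
        assert net.graph.number_of_edges() == 0
        assert net.total_score == 0.0

    def test_chain_preferred_when_scores_favor_it(self):
        scores = [
            ParentSetScore("a", (), 0.0),
            ParentSetScore("b", (), 10.0),
            ParentSetScore("b", ("a",), 1.0),
            ParentSetScore("c", (), 10.0),
            ParentSetScore("c", ("b",), 1.0),
        ]
        net = solve_ilp(scores)
        assert set(net.graph.edges()) == {("a", "b"), ("b", "c")}
        oracle = exhaustive_dag_search(scores)
        assert net.total_score == pytest.approx(oracle.total_score, abs=1e-12)

    def test_cycle_favoring_scores_return_best_acyclic_subset(self):
        scores = []
        for child, parent in [("a", "c"), ("b", "a"), ("c", "b")]:
            scores.append(ParentSetScore(child, (), 10.0))
            scores.append(ParentSetScore(child, (parent,), 0.0))
        net = solve_ilp(scores)
        assert nx.is_directed_acyclic_graph(net.graph)
        oracle = exhaustive_dag_search(scores)
        assert net.total_score == pytest.approx(oracle.total_score, abs=1e-12)
        assert net.n_cluster_constraints >= 1

    def test_missing_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            solve_ilp([ParentSetScore("a", ("b",), 1.0), ParentSetScore("b", (), 0.0)])

    def test_total_score_decomposes_over_chosen_sets(self, rng):
        scores = random_parent_set_scores(rng, 5, max_parents=2)
        lookup = {(s.child, s.parents): s.score for s in scores}
        net = solve_ilp(scores)
        total = sum(lookup[(c, p)] for c, p in net.parent_sets.items())
        assert net.total_score == pytest.approx(total, abs=1e-9)
        assert set(net.parent_sets) == {f"n{i}" for i in range(5)}


class TestExhaustiveDagSearch:
    def test_single_node(self):
        net = exhaustive_dag_search([ParentSetScore("a", (), 2.5)])
        assert net.total_score == 2.5 and not net.graph.edges()

    def test_two_nodes_picks_best_of_three_cases(self):
        scores = [
            ParentSetScore("a", (), 1.0),
            ParentSetScore("a", ("b",), 0.2),
            ParentSetScore("b", (), 1.0),
            ParentSetScore("b", ("a",), 0.1),
        ]
        net = exhaustive_dag_search(scores)
        # both single edges beat the empty graph; a->b is the cheaper one
        assert set(net.graph.edges()) == {("a", "b")}
        assert net.total_score == pytest.approx(1.1)

    def test_rejects_large_instances(self, rng):
        with pytest.raises(ValueError, match="limited"):
            exhaustive_dag_search(random_parent_set_scores(rng, 8, 1))


class TestLearnSemip:
    def test_pure_noise_yields_sparse_graph(self, rng):
        cols = ["X1", "X2"] + [f"Y{i}" for i in range(1, 7)]
        data = pd.DataFrame(rng.standard_normal((400, 8)), columns=cols)
        layers = {"X1": "genotype", "X2": "genotype"}
        layers.update({f"Y{i}": "expression" for i in range(1, 7)})
        net = learn_semip_network(OmicsDataset(data=data, layers=layers))
        assert net.graph.number_of_edges() <= 3

    def test_recovers_planted_chain(self):
        ds = make_chain_dataset(n=1000, seed=11)
        net = learn_semip_network(ds)
        assert set(net.graph.edges()) == {("X1", "Y1"), ("Y1", "Y2")}

    def test_five_node_model_recovery(self):
        config = SimulationConfig(
            n_nodes=5, n_genotype_nodes=2, target_edges=4, n_samples=1000, random_sign=False
        )
        powers = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            model = random_dag(config, r)
            if model.dag.number_of_edges() == 0:
                continue
            ds = simulate_dataset(model, 1000, r)
            net = learn_semip_network(ds)
            from causalnet.simulate import evaluate_network

            powers.append(evaluate_network(model.dag, net.graph, "directed").power)
        assert np.mean(powers) >= 0.8

    def test_deterministic_given_data(self):
        ds = make_chain_dataset(n=400, seed=2)
        a = learn_semip_network(ds)
        b = learn_semip_network(ds)
        assert set(a.graph.edges()) == set(b.graph.edges())
        assert a.total_score == b.total_score

    def test_genotype_nodes_never_acquire_parents(self, rng):
        config = SimulationConfig(n_nodes=8, n_genotype_nodes=3, target_edges=10, random_sign=False)
        model = random_dag(config, rng)
        ds = simulate_dataset(model, 500, rng)
        net = learn_semip_network(ds)
        for g in ds.genotype_nodes:
            assert net.graph.in_degree(g) == 0


def _layer_frames(rng, n=800):
    snp = pd.DataFrame({"SNP1": rng.standard_normal(n)})
    meth = pd.DataFrame({"M1": 1.5 * snp["SNP1"] + rng.standard_normal(n)})
    expr = pd.DataFrame({"E1": 1.5 * meth["M1"] + rng.standard_normal(n)})
    phen = pd.DataFrame({"P1": 1.5 * expr["E1"] + rng.standard_normal(n)})
    dis = pd.DataFrame({"D1": 1.5 * phen["P1"] + rng.standard_normal(n)})
    return snp, meth, expr, phen, dis


class TestLearnMultilevel:
    def test_planted_layer_chain_recovered(self, rng):
        snp, meth, expr, phen, dis = _layer_frames(rng)
        net = learn_multilevel_network(
            genotype=snp, methylation=meth, expression=expr, phenotype=phen, disease=dis
        )
        expected = {("SNP1", "M1"), ("M1", "E1"), ("E1", "P1"), ("P1", "D1")}
        assert expected <= set(net.graph.edges())

    def test_layer_rules_respected_on_random_data(self, rng):
        n = 300
        geno = pd.DataFrame(rng.standard_normal((n, 2)), columns=["S1", "S2"])
        meth = pd.DataFrame(rng.standard_normal((n, 3)), columns=["M1", "M2", "M3"])
        expr = pd.DataFrame(rng.standard_normal((n, 3)), columns=["E1", "E2", "E3"])
        phen = pd.DataFrame(rng.standard_normal((n, 2)), columns=["P1", "P2"])
        dis = pd.DataFrame(rng.standard_normal((n, 1)), columns=["D1"])
        net = learn_multilevel_network(
            genotype=geno, methylation=meth, expression=expr, phenotype=phen, disease=dis
        )
        layer = {n_: net.graph.nodes[n_]["layer"] for n_ in net.graph.nodes}
        allowed = {
            "methylation": {"methylation", "genotype"},
            "expression": {"expression", "methylation", "genotype"},
            "phenotype": {"phenotype", "expression", "methylation", "genotype"},
            "disease": {"phenotype", "expression", "methylation", "genotype"},
        }
        for u, v in net.graph.edges():
            assert layer[u] in allowed[layer[v]]

    def test_single_layer_reduces_to_semip(self, rng):
        config = SimulationConfig(n_nodes=8, n_genotype_nodes=3, target_edges=8, random_sign=False)
        model = random_dag(config, rng)
        ds = simulate_dataset(model, 600, rng)
        direct = learn_semip_network(ds)
        via_multilevel = learn_multilevel_network(
            genotype=ds.data[ds.genotype_nodes],
            expression=ds.data[ds.endogenous_nodes],
        )
        assert set(direct.graph.edges()) == set(via_multilevel.graph.edges())
        assert direct.total_score == pytest.approx(via_multilevel.total_score, abs=1e-9)

    def test_sample_misalignment_names_the_matrices(self, rng):
        snp = pd.DataFrame({"S1": rng.standard_normal(100)})
        expr = pd.DataFrame({"E1": rng.standard_normal(90)})
        with pytest.raises(ValueError, match="misalignment.*expression"):
            learn_multilevel_network(genotype=snp, expression=expr)

    def test_requires_an_endogenous_layer(self, rng):
        snp = pd.DataFrame({"S1": rng.standard_normal(50)})
        with pytest.raises(ValueError, match="endogenous"):
            learn_multilevel_network(genotype=snp)


def test_semip_settings_rejects_unknown_screening():
    ds = make_chain_dataset(n=100)
    with pytest.raises(ValueError, match="screening"):
        learn_semip_network(ds, SemipSettings(screening="magic", screen_above=0))
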