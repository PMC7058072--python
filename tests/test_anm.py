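import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from causalnet.anm import (
    DiscreteSeries,
    causation_test,
    fit_discrete_regression,
    gene_level_causation,
    gwcs_scan,
    independence_delta,
)
from causalnet.io import GenotypeData

from conftest import make_rare_gene


def fisher_enumeration_oracle(table):
    """Two-sided Fisher exact p by brute-force enumeration of all tables
    with the observed margins (probability-ordering definition)."""
    table = np.asarray(table, int)
    rows, cols = table.sum(1), table.sum(0)
    n = rows.sum()

    def log_p(t):
        return (
            special.gammaln(rows + 1).sum()
            + special.gammaln(cols + 1).sum()
            - special.gammaln(n + 1)
            - special.gammaln(np.asarray(t) + 1).sum()
        )

    lp_obs = log_p(table)
    total = 0.0
    r, c = table.shape
    ranges = [range(min(rows[i], cols[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for combo in itertools.product(*ranges):
        t = np.zeros((r, c), int)
        t[: r - 1, : c - 1] = np.reshape(combo, (r - 1, c - 1))
        t[: r - 1, c - 1] = rows[: r - 1] - t[: r - 1, : c - 1].sum(1)
        t[r - 1, :] = cols - t[: r - 1, :].sum(0)
        if (t < 0).any():
            continue
        lp = log_p(t)
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return min(total, 1.0)


class TestDiscreteSeries:
    def test_rejects_non_integers_and_empty(self):
        with pytest.raises(ValueError):
            DiscreteSeries(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            DiscreteSeries(np.array([]))

    def test_support_inferred_and_checked(self):
        s = DiscreteSeries(np.array([2, 0, 2, 1]))
        assert list(s.support) == [0, 1, 2]
        with pytest.raises(ValueError):
            DiscreteSeries(np.array([0, 3]), support=np.array([0, 1]))


class TestFitDiscreteRegression:
    def test_identity_mechanism_has_zero_residuals(self):
        x = np.array([0, 1, 2, 0, 1, 2])
        fitted, resid = fit_discrete_regression(x, x)
        assert fitted == {0: 0, 1: 1, 2: 2}
        assert not resid.values.any()

    def test_two_level_example_matches_hand_count(self):
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 2, 2, 3]
        fitted, resid = fit_discrete_regression(x, y)
        assert fitted == {0: 0, 1: 2}
        assert list(resid.values) == [0, 0, 1, 0, 0, 1]

    def test_constant_effect_fits_constant(self):
        fitted, resid = fit_discrete_regression([0, 1, 0, 1], [5, 5, 5, 5])
        assert set(fitted.values()) == {5}
        assert not resid.values.any()

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            fit_discrete_regression([0, 1], [0, 1, 2])


class TestIndependenceDelta:
    def test_constant_residuals_give_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            delta = independence_delta(np.zeros(20, int), np.arange(20) % 2)
        assert delta == 0.0

    def test_diagonal_2x2_matches_enumeration_oracle(self):
        resid = np.repeat([0, 1], 10)
        cause = np.repeat([0, 1], 10)  # table [[10, 0], [0, 10]]
        delta = independence_delta(resid, cause)
        p_oracle = fisher_enumeration_oracle([[10, 0], [0, 10]])
        assert delta == pytest.approx(-np.log10(p_oracle), abs=1e-9)

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
    def test_matches_enumeration_oracle_on_small_tables(self, shape, rng):
        for _ in range(30):
            n = int(rng.integers(6, 21))
            table = rng.multinomial(n, np.ones(shape[0] * shape[1]) / (shape[0] * shape[1]))
            table = table.reshape(shape)
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            resid = np.repeat(np.arange(shape[0]), table.sum(1))
            cause = np.concatenate(
                [np.repeat(np.arange(shape[1]), table[i]) for i in range(shape[0])]
            )
            delta = independence_delta(resid, cause)
            p_oracle = fisher_enumeration_oracle(table)
            assert delta == pytest.approx(-np.log10(p_oracle), abs=1e-7)

    def test_2x2_agrees_with_scipy(self, rng):
        for _ in range(20):
            table = rng.integers(0, 12, (2, 2))
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            resid = np.repeat([0, 1], table.sum(1))
            cause = np.concatenate([np.repeat([0, 1], table[i]) for i in range(2)])
            delta = independence_delta(resid, cause)
            p_scipy = stats.fisher_exact(table)[1]
            assert delta == pytest.approx(-np.log10(p_scipy), abs=1e-9)


class TestCausationTest:
    def test_identical_series_are_undecidable(self):
        x = np.tile([0, 1, 2], 30)
        res = causation_test(x, x, n_permutations=99, rng=0)
        assert res.t_c == 0.0
        assert res.delta_xy == res.delta_yx == 0.0
        assert res.direction == "undecided"

    def test_single_level_series_is_an_error(self):
        with pytest.raises(ValueError, match="levels"):
            causation_test(np.zeros(10, int), np.arange(10) % 2, n_permutations=9)

    def test_symmetry_of_the_pair(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 2, 200)
        a = causation_test(x, y, n_permutations=99, rng=11)
        b = causation_test(y, x, n_permutations=99, rng=11)
        assert a.t_c == b.t_c
        assert a.p_value == b.p_value
        assert a.delta_xy == b.delta_yx and a.delta_yx == b.delta_xy

    def test_p_value_respects_add_one_floor(self, rng):
        x = rng.integers(0, 3, 300)
        y = (2 * x) % 3 + rng.choice([-1, 0, 1], 300, p=[0.1, 0.8, 0.1])
        res = causation_test(x, y, n_permutations=49, rng=1)
        assert 1 / 50 <= res.p_value <= 1.0

    def test_planted_mechanism_recovers_direction(self, rng):
        correct = 0
        for _ in range(15):
            x = rng.integers(0, 3, 500)
            y = (2 * x) % 3 + rng.choice([-1, 0, 1], 500, p=[0.1, 0.8, 0.1])
            res = causation_test(x, y, n_permutations=199, rng=rng)
            correct += res.direction == "x_to_y"
        assert correct >= 13

    def test_deterministic_given_seed(self, rng):
        x = rng.integers(0, 3, 200)
        y = rng.integers(0, 2, 200)
        a = causation_test(x, y, n_permutations=99, rng=3)
        b = causation_test(x, y, n_permutations=99, rng=3)
        assert a == b


class TestGeneLevelCausation:
    def test_planted_deterministic_mechanism(self):
        from causalnet.anm import _discretize_quantiles
        from causalnet.fpca import code_genotype_function, fpc_scores

        g, pos = make_rare_gene()
        score = fpc_scores(code_genotype_function(g, pos), n_components=1).scores[:, 0]
        disease = (_discretize_quantiles(score, 3) == 2).astype(int)
        res = gene_level_causation(g, pos, disease, n_permutations=199, rng=2)
        assert res.p_value < 0.05
        assert res.direction == "x_to_y"

    def test_permuted_labels_are_null(self, rng):
        g, pos = make_rare_gene()
        disease = rng.permutation(np.repeat([0, 1], 150))
        res = gene_level_causation(g, pos, disease, n_permutations=199, rng=3)
        assert res.p_value > 0.05

    def test_monomorphic_gene_is_an_error(self):
        g = np.zeros((50, 5))
        with pytest.raises(ValueError, match="monomorphic"):
            gene_level_causation(g, np.arange(5), np.arange(50) % 2, n_permutations=9)

    def test_single_bin_is_an_error(self):
        g, pos = make_rare_gene()
        with pytest.raises(ValueError, match="n_bins"):
            gene_level_causation(g, pos, np.arange(300) % 2, n_bins=1, n_permutations=9)


def _toy_genome(rng, n=300, n_genes=8, variants_per_gene=30):
    """Dosage matrix with one causal gene (last) and null genes."""
    ids, chroms, positions, cols = [], [], [], []
    for gi in range(n_genes):
        for vi in range(variants_per_gene):
            ids.append(f"g{gi}v{vi}")
            chroms.append("1")
            positions.append(1000 * gi + 10 * vi)
    dosages = {}
    causal = None
    for gi in range(n_genes):
        if gi == n_genes - 1:
            latent = rng.gamma(2, 1, n)
            block = (rng.random((n, variants_per_gene)) < (0.04 * latent[:, None] / latent.mean()))
        else:
            block = rng.random((n, variants_per_gene)) < 0.04
        for vi in range(variants_per_gene):
            dosages[f"g{gi}v{vi}"] = block[:, vi].astype(float)
        if gi == n_genes - 1:
            causal = block.astype(float)
    genotypes = GenotypeData(
        dosages=pd.DataFrame(dosages),
        variants=pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": positions}),
    )
    regions = pd.DataFrame(
        {
            "chrom": "1",
            "start": [1000 * gi for gi in range(n_genes)],
            "end": [1000 * gi + 10 * variants_per_gene for gi in range(n_genes)],
            "name": [f"gene{gi}" for gi in range(n_genes)],
        }
    )
    return genotypes, regions, causal


class TestGwcsScan:
    def test_planted_gene_attains_minimum_p(self, rng):
        from causalnet.anm import _discretize_quantiles
        from causalnet.fpca import code_genotype_function, fpc_scores

        genotypes, regions, causal = _toy_genome(rng)
        pos = np.arange(causal.shape[1], dtype=float)
        score = fpc_scores(code_genotype_function(causal, pos), n_components=1).scores[:, 0]
        disease = (_discretize_quantiles(score, 3) == 2).astype(int)
        table = gwcs_scan(genotypes, regions, disease, maf_threshold=0.2, n_permutations=99, rng=1)
        genes = table[table["type"] == "gene"].dropna(subset=["p"])
        best = genes.loc[genes["p"].idxmin(), "unit"]
        assert best == f"gene{len(regions) - 1}"

    def test_empty_region_list_is_an_error(self, rng):
        genotypes, regions, _ = _toy_genome(rng)
        with pytest.raises(ValueError, match="non-empty"):
            gwcs_scan(genotypes, regions.iloc[:0], np.arange(300) % 2)

    def test_region_without_variants_yields_na_row_and_warning(self, rng):
        genotypes, regions, _ = _toy_genome(rng)
        empty = pd.DataFrame(
            {"chrom": ["1"], "start": [900_000], "end": [900_100], "name": ["desert"]}
        )
        disease = rng.integers(0, 2, 300)
        with pytest.warns(UserWarning, match="no variants"):
            table = gwcs_scan(
                genotypes, pd.concat([regions, empty]), disease, n_permutations=19, rng=0
            )
        row = table[table["unit"] == "desert"]
        assert len(row) == 1 and np.isnan(row["p"].iloc[0])

    def test_bh_adjustment_never_below_raw_p(self, rng):
        genotypes, regions, _ = _toy_genome(rng)
        disease = rng.integers(0, 2, 300)
        table = gwcs_scan(genotypes, regions, disease, n_permutations=19, rng=0)
        ok = table.dropna(subset=["p"])
        assert (ok["fdr"] >= ok["p"] - 1e-12).all()
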