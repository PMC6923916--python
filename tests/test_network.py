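"""Correlation networks, single-sample perturbation and ΔPCC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from ssnet import (
    ConstantInputError,
    ExpressionMatrix,
    ValidationError,
    build_network,
    build_patient_network,
    build_perturbed_network,
    count_delta_pccs,
    delta_pcc,
    pcc_pvalue,
    pearson_cc,
    spearman_cc,
)
from ssnet.network import delta_pcc_tensor, pair_index


def naive_pearson(x, y):
    """Element-by-element evaluation of the correlation formula (oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[k] - mx) * (y[k] - my) for k in range(n))
    den = math.sqrt(sum((x[k] - mx) ** 2 for k in range(n))
                    * sum((y[k] - my) ** 2 for k in range(n)))
    return num / den


def t_density(t, df):
    c = special.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * special.gamma(df / 2))
    return c * (1 + t * t / df) ** (-(df + 1) / 2)


def pvalue_by_integration(r, n):
    """Two-sided p from numerically integrating the t density (oracle)."""
    df = n - 2
    t = abs(r) * math.sqrt(df / (1 - r * r))
    tail, _ = integrate.quad(t_density, t, np.inf, args=(df,))
    return 2 * tail


finite_vec = st.lists(st.floats(-50, 50), min_size=4, max_size=20)


class TestPearson:
    def test_exact_linear(self):
        assert pearson_cc([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_exact_anti_linear(self):
        assert pearson_cc([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_matches_naive_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        assert pearson_cc(x, y) == pytest.approx(naive_pearson(x, y), abs=1e-12)

    def test_matches_naive_on_random_vectors(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert pearson_cc(x, y) == pytest.approx(naive_pearson(list(x), list(y)),
                                                     abs=1e-10)

    def test_constant_vector_signalled(self):
        with pytest.raises(ConstantInputError):
            pearson_cc([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_cc([1, 2, 3], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=50)
    @given(finite_vec, finite_vec)
    def test_symmetry_and_bounds(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r = pearson_cc(x, y)
        assert r == pytest.approx(pearson_cc(y, x), abs=1e-12)
        assert abs(r) <= 1 + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(finite_vec, st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, x, a, b):
        if np.ptp(x) == 0:
            return
        y = [v * 1.7 + 0.3 for v in x]  # any non-constant companion
        y[0] += 1.0
        if np.ptp(y) == 0:
            return
        r = pearson_cc(x, y)
        assert pearson_cc([a * v + b for v in x], y) == pytest.approx(r, abs=1e-9)
        assert pearson_cc([-a * v + b for v in x], y) == pytest.approx(-r, abs=1e-9)


class TestPValue:
    def test_null_correlation(self):
        assert pcc_pvalue(0.0, 10) == pytest.approx(1.0)
        assert pcc_pvalue(0.0, 100) == pytest.approx(1.0)

    def test_perfect_correlation(self):
        assert pcc_pvalue(1.0, 10) == 0.0
        assert pcc_pvalue(-1.0, 5) == 0.0

    @pytest.mark.parametrize("r,n", [(0.5, 20), (0.3, 50), (-0.7, 12), (0.05, 200)])
    def test_matches_numerical_integration(self, r, n):
        assert pcc_pvalue(r, n) == pytest.approx(pvalue_by_integration(r, n),
                                                 abs=1e-10)

    def test_monotone_decreasing_in_abs_r(self):
        ps = [pcc_pvalue(r, 30) for r in np.linspace(0, 0.99, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pcc_pvalue(0.5, 2)


class TestBuildNetwork:
    def test_perfectly_correlated_pair(self):
        expr = ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(5)],
                                np.array([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10.0]]))
        net = build_network(expr)
        assert net.pcc[0, 1] == pytest.approx(1.0)
        assert net.pvalue[0, 1] < 1e-20
        assert net.n_samples == 5

    def test_distinct_offdiagonal_count(self, rng):
        k = 6
        expr = ExpressionMatrix([f"G{i}" for i in range(k)],
                                [f"S{i}" for i in range(10)],
                                rng.normal(size=(k, 10)))
        net = build_network(expr)
        iu = np.triu_indices(k, 1)
        assert len(net.pcc[iu]) == k * (k - 1) // 2

    def test_elementwise_oracle(self, rng):
        values = rng.normal(size=(10, 30))
        expr = ExpressionMatrix([f"G{i}" for i in range(10)],
                                [f"S{i}" for i in range(30)], values)
        net = build_network(expr)
        for i in range(10):
            for j in range(i + 1, 10):
                r = pearson_cc(values[i], values[j])
                assert net.pcc[i, j] == pytest.approx(r, abs=1e-10)
                assert net.pvalue[i, j] == pytest.approx(
                    pcc_pvalue(r, 30), abs=1e-10)

    def test_symmetric_and_unit_diagonal(self, rng):
        expr = ExpressionMatrix([f"G{i}" for i in range(5)],
                                [f"S{i}" for i in range(8)],
                                rng.normal(size=(5, 8)))
        net = build_network(expr)
        np.testing.assert_allclose(net.pcc, net.pcc.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(net.pcc), 1.0)
        np.testing.assert_allclose(np.diag(net.pvalue), 0.0)

    def test_degenerate_gene_flagged_and_unselectable(self, rng):
        values = rng.normal(size=(3, 10))
        values[1] = 4.2  # constant gene
        expr = ExpressionMatrix(["A", "FLAT", "C"],
                                [f"S{i}" for i in range(10)], values)
        net = build_network(expr)
        assert net.degenerate_genes == ["FLAT"]
        assert net.pcc[0, 1] == 0.0
        assert net.pvalue[0, 1] == 1.0

    def test_too_few_samples_rejected(self, rng):
        expr = ExpressionMatrix(["A", "B"], ["S1", "S2"], rng.normal(size=(2, 2)))
        with pytest.raises(ValidationError):
            build_network(expr)


class TestPerturbedNetwork:
    def test_equals_explicitly_augmented_matrix(self, rng):
        values = rng.normal(size=(6, 12))
        expr = ExpressionMatrix([f"G{i}" for i in range(6)],
                                [f"S{i}" for i in range(12)], values)
        vec = rng.normal(size=6)
        pert = build_perturbed_network(expr, vec)
        explicit = build_network(ExpressionMatrix(
            expr.gene_ids, expr.sample_ids + ["X"],
            np.column_stack([values, vec])))
        np.testing.assert_allclose(pert.pcc, explicit.pcc, atol=1e-12)
        np.testing.assert_allclose(pert.pvalue, explicit.pvalue, atol=1e-12)
        assert pert.n_samples == expr.n_samples + 1

    def test_duplicating_a_sample_changes_little(self, rng):
        values = rng.normal(size=(4, 20))
        expr = ExpressionMatrix([f"G{i}" for i in range(4)],
                                [f"S{i}" for i in range(20)], values)
        ref = build_network(expr)
        pert = build_perturbed_network(expr, values[:, 0])
        assert np.abs(delta_pcc(ref, pert)).max() < 0.2

    def test_gene_count_mismatch(self, rng):
        expr = ExpressionMatrix([f"G{i}" for i in range(4)],
                                [f"S{i}" for i in range(5)],
                                rng.normal(size=(4, 5)))
        with pytest.raises(ValidationError):
            build_perturbed_network(expr, np.zeros(3))


class TestDeltaPcc:
    def test_identical_networks_give_zero(self, rng):
        expr = ExpressionMatrix([f"G{i}" for i in range(5)],
                                [f"S{i}" for i in range(9)],
                                rng.normal(size=(5, 9)))
        net = build_network(expr)
        d = delta_pcc(net, net)
        np.testing.assert_allclose(d, 0.0)

    def test_maximum_bound_attained(self):
        up = ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(4)],
                              np.array([[1, 2, 3, 4], [1, 2, 3, 4.0]]))
        down = ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(4)],
                                np.array([[1, 2, 3, 4], [4, 3, 2, 1.0]]))
        d = delta_pcc(build_network(up), build_network(down))
        assert d[0, 1] == pytest.approx(2.0)

    def test_elementwise_oracle_and_bounds(self, rng):
        a = build_network(ExpressionMatrix(
            [f"G{i}" for i in range(8)], [f"S{i}" for i in range(15)],
            rng.normal(size=(8, 15))))
        b = build_network(ExpressionMatrix(
            [f"G{i}" for i in range(8)], [f"T{i}" for i in range(15)],
            rng.normal(size=(8, 15))))
        d = delta_pcc(a, b)
        assert d.min() >= 0 and d.max() <= 2
        np.testing.assert_allclose(np.diag(d), 0)
        for i in range(8):
            for j in range(8):
                assert d[i, j] == pytest.approx(abs(b.pcc[i, j] - a.pcc[i, j]),
                                                abs=1e-12)


class TestPatientNetwork:
    def test_zero_alpha_gives_empty_network(self, reference_cohort):
        normal, tumor, _, _ = reference_cohort
        net = build_patient_network(normal, tumor.values[:, 0], "P0",
                                    alpha_edge=1e-300)
        assert len(net) == 0

    def test_dual_significance_filter(self, reference_cohort):
        normal, tumor, _, _ = reference_cohort
        ref = build_network(normal)
        net = build_patient_network(normal, tumor.values[:, 0], "P0",
                                    alpha_edge=0.05, reference=ref)
        pert = build_perturbed_network(normal, tumor.values[:, 0])
        for a, b, d, r_ref, r_pert, p_ref, p_pert in net.edges:
            assert p_ref < 0.05 and p_pert < 0.05
            i, j = normal.gene_index(a), normal.gene_index(b)
            assert d == pytest.approx(abs(pert.pcc[i, j] - ref.pcc[i, j]),
                                      abs=1e-12)
        # a pair significant in only one of the two networks is excluded
        sig_ref_only = (ref.pvalue < 0.05) & (pert.pvalue >= 0.05)
        iu = np.triu_indices(normal.n_genes, 1)
        excluded = {(normal.gene_ids[i], normal.gene_ids[j])
                    for i, j in zip(*iu) if sig_ref_only[i, j]}
        present = {(a, b) for a, b, *_ in net.edges}
        assert not (excluded & present)

    def test_planted_pair_edge_present(self, reference_cohort):
        normal, tumor, _, truth = reference_cohort
        affected = sorted(truth.affected_samples)[0]
        vec = tumor.sample_vector(affected)
        net = build_patient_network(normal, vec, affected)
        assert set(truth.planted_pairs) & set(net.pair_ids)

    def test_exports(self, tmp_path, reference_cohort):
        normal, tumor, _, _ = reference_cohort
        net = build_patient_network(normal, tumor.values[:, 0], "P0")
        net.write_tsv(tmp_path / "n.tsv")
        net.write_graphml(tmp_path / "n.graphml")
        net.write_json(tmp_path / "n.json")
        assert (tmp_path / "n.tsv").read_text().startswith("gene_a\t")
        assert len(net.to_graph().edges) == len(net)


class TestCountDeltaPccs:
    @pytest.mark.parametrize("n,k,expected", [
        (1050, 516, 139_513_500),
        (286, 466, 30_986_670),
        (405, 410, 33_957_225),
        (0, 10, 0),
    ])
    def test_published_cohort_totals(self, n, k, expected):
        assert count_delta_pccs(n, k) == expected

    def test_matches_explicit_enumeration(self):
        for n in range(6):
            for k in range(2, 11):
                pairs = [(s, i, j) for s in range(n)
                         for i in range(k) for j in range(i + 1, k)]
                assert count_delta_pccs(n, k) == len(pairs)

    def test_degenerate_gene_count_rejected(self):
        with pytest.raises(ValueError):
            count_delta_pccs(10, 1)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [1.0, 2.5, 3.1, 7.2, 9.9]
        y = [math.exp(v) for v in x]
        assert spearman_cc(x, y) == pytest.approx(1.0)

    def test_robust_to_outlier_that_flips_pearson(self):
        x = [1, 2, 3, 4, 5, 100.0]
        y = [2, 3, 4, 5, 6, -500.0]
        assert pearson_cc(x, y) < 0  # the outlier dominates the product moment
        assert spearman_cc(x, y) == pytest.approx(
            spearman_cc([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 1]))

    def test_equals_pearson_of_mean_ranks_with_ties(self, rng):
        x = rng.integers(0, 5, size=25).astype(float)
        y = rng.integers(0, 5, size=25).astype(float)
        assert spearman_cc(x, y) == pytest.approx(
            pearson_cc(stats.rankdata(x), stats.rankdata(y)), abs=1e-12)
        assert spearman_cc(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12)


class TestDeltaTensor:
    def test_matches_per_patient_recomputation(self, rng):
        normal = ExpressionMatrix([f"G{i}" for i in range(6)],
                                  [f"N{i}" for i in range(20)],
                                  rng.normal(size=(6, 20)))
        tumor = ExpressionMatrix([f"G{i}" for i in range(6)],
                                 [f"T{i}" for i in range(5)],
                                 rng.normal(size=(6, 5)))
        delta, edge = delta_pcc_tensor(normal, tumor, alpha_edge=0.2)
        ref = build_network(normal)
        assert list(delta.index) == pair_index(normal.gene_ids)
        for s, sid in enumerate(tumor.sample_ids):
            pert = build_perturbed_network(normal, tumor.values[:, s])
            dmat = delta_pcc(ref, pert)
            k = 0
            for i in range(6):
                for j in range(i + 1, 6):
                    assert delta.iloc[k][sid] == pytest.approx(dmat[i, j],
                                                               abs=1e-12)
                    assert edge.iloc[k][sid] == (
                        ref.pvalue[i, j] < 0.2 and pert.pvalue[i, j] < 0.2)
                    k += 1
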