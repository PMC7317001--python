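import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modminer.candidates import build_variation_matrix
from modminer.dysreg import (
    DysregulationNetwork,
    RegressionInputs,
    RegulatoryNetwork,
    build_group_network,
    filter_training_genes,
    fit_gene_model,
    xor_networks,
)
from modminer.io import align_samples
from modminer.synthetic import (
    SimulationConfig,
    generate_cohort,
    generate_differential_expression,
    make_regression_problem,
)

from conftest import make_matrix


class TestFilterTrainingGenes:
    def test_no_fold_change_gives_empty_list(self, rng):
        base = rng.uniform(5, 10, size=20)
        tumor = make_matrix("expression", base[:, None] + rng.standard_normal((20, 30)))
        normal = make_matrix("expression", base[:, None] + rng.standard_normal((20, 25)))
        assert filter_training_genes(tumor, normal) == []

    def test_strong_fold_change_included(self, rng):
        tumor = make_matrix("expression", np.full((1, 30), 8.0) + 0.1 * rng.standard_normal((1, 30)))
        normal = make_matrix("expression", np.full((1, 25), 2.0) + 0.1 * rng.standard_normal((1, 25)))
        assert filter_training_genes(tumor, normal) == ["g0"]

    def test_planted_fold_change_genes_recovered(self):
        tumor, normal, planted = generate_differential_expression(seed=20260927)
        assert sorted(filter_training_genes(tumor, normal)) == sorted(planted)

    def test_down_regulated_genes_also_pass(self, rng):
        tumor = make_matrix("expression", np.full((1, 30), 2.0) + 0.1 * rng.standard_normal((1, 30)))
        normal = make_matrix("expression", np.full((1, 25), 9.0) + 0.1 * rng.standard_normal((1, 25)))
        assert filter_training_genes(tumor, normal) == ["g0"]

    def test_zero_normal_mean_skipped_with_warning(self, rng):
        tumor = make_matrix("expression", np.full((1, 10), 4.0))
        normal = make_matrix("expression", np.zeros((1, 10)))
        with pytest.warns(UserWarning, match="fold-change undefined"):
            assert filter_training_genes(tumor, normal) == []


class TestFitGeneModel:
    def test_exact_recovery_of_pure_cnv_model(self, rng):
        n = 200
        cn = rng.choice([-2, -1, 0, 1, 2], size=n).astype(float)
        ge = 2.0 * cn
        inputs = RegressionInputs(
            gene_id="g", ge=ge, dm=rng.beta(2, 5, n), cn=cn,
            tf={"t1": rng.standard_normal(n)}, mir={"m1": rng.standard_normal(n)},
        )
        fit = fit_gene_model(inputs)
        assert fit.weights["cn"] == pytest.approx(2 * cn.std() / ge.std(), abs=1e-10)
        for name, w in fit.weights.items():
            if name != "cn":
                assert abs(w) < 0.05
        assert fit.raw_weights["cn"] == pytest.approx(2.0, abs=1e-10)

    def test_constant_response_gives_zero_weights(self, rng):
        inputs = RegressionInputs(
            gene_id="g", ge=np.full(50, 3.0), tf={"t1": rng.standard_normal(50)})
        fit = fit_gene_model(inputs)
        assert all(w == 0.0 for w in fit.weights.values())

    def test_constant_covariate_gets_zero_weight(self, rng):
        n = 60
        x = rng.standard_normal(n)
        inputs = RegressionInputs(gene_id="g", ge=2 * x, cn=np.zeros(n), tf={"t1": x})
        fit = fit_gene_model(inputs)
        assert fit.weights["cn"] == 0.0
        assert fit.weights["tf:t1"] == pytest.approx(1.0, abs=1e-10)

    def test_planted_weight_recovery_within_tolerance(self):
        inputs, true = make_regression_problem(n_samples=150, noise_sd=0.1, seed=20260927)
        fit = fit_gene_model(inputs)
        assert fit.weights.keys() == true.keys()
        for name in true:
            assert fit.raw_weights[name] == pytest.approx(true[name], abs=0.1)

    def test_noiseless_recovery_is_exact(self):
        inputs, true = make_regression_problem(n_samples=150, noise_sd=0.0, seed=20260927)
        fit = fit_gene_model(inputs)
        for name in true:
            assert fit.raw_weights[name] == pytest.approx(true[name], abs=1e-8)

    def test_recovery_error_decreases_with_sample_size(self):
        # average worst-case weight error over seeds, fitted on nested subsets
        errors = {n: [] for n in (50, 100, 200)}
        for seed in range(12):
            inputs, true = make_regression_problem(
                n_samples=200, noise_sd=0.5, seed=1000 + seed)
            for n in errors:
                sub = RegressionInputs(
                    gene_id="g", ge=inputs.ge[:n], dm=inputs.dm[:n], cn=inputs.cn[:n],
                    tf={k: v[:n] for k, v in inputs.tf.items()},
                    mir={k: v[:n] for k, v in inputs.mir.items()},
                    lnc={k: v[:n] for k, v in inputs.lnc.items()},
                )
                fit = fit_gene_model(sub)
                errors[n].append(max(abs(fit.raw_weights[k] - true[k]) for k in true))
        means = {n: np.mean(v) for n, v in errors.items()}
        assert means[50] > means[100] > means[200]

    def test_too_few_samples_rejected(self, rng):
        inputs = RegressionInputs(
            gene_id="g", ge=rng.standard_normal(3),
            tf={f"t{i}": rng.standard_normal(3) for i in range(5)})
        with pytest.raises(ValueError, match="cannot identify"):
            fit_gene_model(inputs)

    def test_rank_deficient_design_uses_ridge(self, rng, caplog):
        n = 40
        x = rng.standard_normal(n)
        inputs = RegressionInputs(gene_id="g", ge=x + 0.1 * rng.standard_normal(n),
                                  tf={"t1": x, "t2": x.copy()})
        with caplog.at_level("WARNING"):
            fit = fit_gene_model(inputs)
        assert "ridge fallback" in caplog.text
        assert np.isfinite(list(fit.weights.values())).all()


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SimulationConfig(seed=20260927, module_sizes=(3, 3),
                                            n_samples=100, n_background_genes=20))


@pytest.fixture(scope="module")
def small_cohort_layers(small_cohort):
    co = small_cohort
    expr, mut, cnv, meth, mirna, lnc = align_samples(
        [co.expression, co.mutation, co.cnv, co.methylation, co.mirna, co.lncrna])
    M = build_variation_matrix(mut, cnv)
    layers = {"expression": expr, "methylation": meth, "cnv": cnv,
              "mirna": mirna, "lncrna": lnc}
    return M, layers


class TestBuildGroupNetwork:
    def test_infinite_threshold_gives_empty_network(self, small_cohort, small_cohort_layers):
        M, layers = small_cohort_layers
        co = small_cohort
        net = build_group_network("KG01", "mutated", M, layers, co.catalog,
                                  list(co.truth.training_genes),
                                  weight_threshold=np.inf)
        assert net.edges == frozenset()

    def test_zero_threshold_keeps_every_catalog_tf(self, small_cohort, small_cohort_layers):
        M, layers = small_cohort_layers
        co = small_cohort
        net = build_group_network("KG01", "mutated", M, layers, co.catalog,
                                  list(co.truth.training_genes), weight_threshold=0.0)
        fitted = {(tf, g) for g in co.truth.training_genes
                  for tf in co.catalog.tfs_of(g)}
        # every TF->gene pair of the catalog appears except those whose TF is
        # constant within the group (weight exactly zero by convention)
        expected = set()
        member = M.row("KG01").astype(bool)
        for tf, g in fitted:
            if layers["expression"].row(tf)[member].std() > 0:
                expected.add((tf, g))
        assert net.edge_pairs() == frozenset(expected)

    def test_planted_dysregulated_edge_active_in_variant_group_only(
            self, small_cohort, small_cohort_layers):
        M, layers = small_cohort_layers
        co = small_cohort
        training = list(co.truth.training_genes)
        net_mut = build_group_network("KG02", "mutated", M, layers, co.catalog, training)
        net_non = build_group_network("KG02", "non_mutated", M, layers, co.catalog, training)
        for edge in co.truth.dysregulated_edges["KG02"]:
            assert edge in net_mut.edge_pairs()
            assert edge not in net_non.edge_pairs()
        for edge in co.truth.stable_edges["KG02"]:
            assert edge in net_mut.edge_pairs()
            assert edge in net_non.edge_pairs()

    def test_too_small_group_raises_naming_group(self, small_cohort, small_cohort_layers):
        M, layers = small_cohort_layers
        co = small_cohort
        with pytest.raises(ValueError, match="mutated group"):
            build_group_network("KG01", "mutated", M, layers, co.catalog,
                                list(co.truth.training_genes), min_group_size=1000)


def net(key, group, pairs):
    return RegulatoryNetwork(key, group, frozenset((r, t, 1.0) for r, t in pairs))


class TestXorNetworks:
    def test_self_xor_is_empty(self):
        a = net("k", "mutated", [("a", "g"), ("b", "g")])
        b = net("k", "non_mutated", [("a", "g"), ("b", "g")])
        assert xor_networks(a, b).edges == frozenset()

    def test_disjoint_edge_sets_give_union(self):
        a = net("k", "mutated", [("a", "g")])
        b = net("k", "non_mutated", [("c", "g")])
        assert xor_networks(a, b).edges == frozenset({("a", "g"), ("c", "g")})

    def test_worked_overlap_example(self):
        a = net("k", "mutated", [("a", "g"), ("b", "g")])
        b = net("k", "non_mutated", [("b", "g"), ("c", "g")])
        assert xor_networks(a, b).edges == frozenset({("a", "g"), ("c", "g")})

    def test_weights_do_not_affect_membership(self):
        a = RegulatoryNetwork("k", "mutated", frozenset({("a", "g", 0.9)}))
        b = RegulatoryNetwork("k", "non_mutated", frozenset({("a", "g", -0.5)}))
        assert xor_networks(a, b).edges == frozenset()

    def test_mismatched_key_gene_rejected(self):
        with pytest.raises(ValueError, match="different key genes"):
            xor_networks(net("k1", "mutated", []), net("k2", "non_mutated", []))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_algebra_on_random_network_pairs(self, data):
        regs = [f"r{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(4)]
        universe = [(r, g) for r in regs for g in genes]
        pairs_a = data.draw(st.sets(st.sampled_from(universe), max_size=12))
        pairs_b = data.draw(st.sets(st.sampled_from(universe), max_size=12))
        a = net("k", "mutated", pairs_a)
        b = net("k", "non_mutated", pairs_b)
        # commutativity
        assert xor_networks(a, b).edges == xor_networks(b, a).edges
        # involution: xor(xor(A,B),B) = A
        ab = xor_networks(a, b)
        back = ab.edges ^ b.edge_pairs()
        assert back == a.edge_pairs()
        # self-annihilation
        assert xor_networks(a, a).edges == frozenset()


def test_group_invariant_weights_give_empty_xor_networks():
    """With no dysregulation effect and no noise, both group fits agree and
    the symmetric difference is empty even at threshold zero."""
    co = generate_cohort(SimulationConfig(
        seed=20260927, n_samples=500, module_sizes=(3, 3), n_background_genes=20,
        dysreg_effect=0.0, noise_sd=0.0))
    expr, mut, cnv, meth, mirna, lnc = align_samples(
        [co.expression, co.mutation, co.cnv, co.methylation, co.mirna, co.lncrna])
    M = build_variation_matrix(mut, cnv)
    layers = {"expression": expr, "methylation": meth, "cnv": cnv,
              "mirna": mirna, "lncrna": lnc}
    training = list(co.truth.training_genes)
    for key in list(co.truth.key_genes)[:3]:
        net_mut = build_group_network(key, "mutated", M, layers, co.catalog, training,
                                      weight_threshold=0.0)
        net_non = build_group_network(key, "non_mutated", M, layers, co.catalog,
                                      training, weight_threshold=0.0)
        assert len(xor_networks(net_mut, net_non).edges) <= 1
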