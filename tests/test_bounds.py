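"""Initial ensemble bounds: z-scores, weights, signed LTR, ConTREx."""

import itertools

import numpy as np
import pandas as pd
import pytest

from traceplus import (
    EnsembleBounds,
    SignedDigraph,
    accessibility_from_z,
    build_initial_bounds,
    contrex_unsigned,
    corrected_stats,
    edge_weights,
    generate_compendium,
    random_kinetic_model,
    signed_closure,
    signed_ltr,
    single_ko_design,
    transitive_reduction_dag,
    zscore_matrix,
)
from traceplus.simulate import ExpressionDataset


def make_dataset(genes, ko_sets, table, replicates=3, jitter=0.0, seed=0):
    """Dataset from a {(gene, ko_index): value} table; default value 1.0."""
    rng = np.random.default_rng(seed)
    values = np.ones((len(genes), len(ko_sets), replicates))
    for (g, k), v in table.items():
        values[genes.index(g), k, :] = v
    if jitter:
        values = values * np.exp(rng.normal(0, jitter, values.shape))
    return ExpressionDataset(tuple(genes), ko_sets, values)


class TestCorrectedStats:
    def test_constant_input(self):
        assert corrected_stats([1, 1, 1, 1]) == (1.0, 0.0)

    def test_single_outlier_excluded(self):
        # 100 deviates from mu'=20 by 80 = 1.79 s'; any cutoff below that
        # excludes it and the corrected stats collapse onto the zeros
        mu, s = corrected_stats([0, 0, 0, 0, 100], z_cutoff=1.5)
        assert mu == 0.0 and s == 0.0

    def test_outlier_within_default_cutoff_is_kept(self):
        # at z_cutoff=3 the same outlier stays: max attainable deviation
        # in 5 points is (n-1)/sqrt(n) = 1.79 sample stds
        mu, s = corrected_stats([0, 0, 0, 0, 100])
        assert mu == pytest.approx(20.0)

    def test_all_excluded_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="uncorrected"):
            mu, s = corrected_stats([0.0, 0.0, 3.0], z_cutoff=0.01)
        assert mu == pytest.approx(1.0)

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            corrected_stats([1.0, 2.0])


class TestZScoreMatrix:
    def test_ko_halving_gives_strong_negative_z(self):
        # 20 genes; KO of G01 halves gene G05, all other KOs leave it
        # unchanged (apart from G05's own deletion).  The one-pass
        # exclusion removes the own-KO zero, after which the halving sits
        # far outside the corrected spread.
        genes = [f"G{k:02d}" for k in range(1, 21)]
        kos = single_ko_design(genes)
        table = {(g, k + 1): 0.0 for k, g in enumerate(genes)}  # self-KOs
        table[("G05", 1)] = 0.5  # KO of G01 halves G05
        data = make_dataset(genes, kos, table)
        z = zscore_matrix(data)
        assert z.loc["G01", "G05"] < -2
        # hand-computed: excluding the own-KO zero leaves 19 ones and one
        # 0.5; mu = 0.975, s = 0.1118 -> z = -4.25
        assert z.loc["G01", "G05"] == pytest.approx(-4.249, abs=0.01)

    def test_unaffected_gene_row_is_zero(self):
        # a gene whose expression column is constant across every
        # experiment carries no differential signal at all
        genes = [f"G{k:02d}" for k in range(1, 11)]
        kos = single_ko_design(genes)
        table = {(g, k + 1): 0.0 for k, g in enumerate(genes[:-1])}
        data = make_dataset(genes, kos, table)
        z = zscore_matrix(data)
        col = z["G10"].drop("G10")
        assert np.allclose(col, 0.0)

    def test_invariant_under_experiment_permutation(self):
        genes = ["A", "B", "C"]
        kos = single_ko_design(genes)
        data = make_dataset(genes, kos, {("B", 1): 0.2, ("A", 1): 0.0,
                                         ("B", 2): 0.0, ("C", 3): 0.0},
                            jitter=0.05)
        perm = [2, 0, 3, 1]
        permuted = ExpressionDataset(
            data.genes, [data.ko_sets[k] for k in perm], data.values[:, perm, :]
        )
        pd.testing.assert_frame_equal(zscore_matrix(data), zscore_matrix(permuted))

    def test_incomplete_design_rejected(self):
        genes = ["A", "B", "C"]
        data = make_dataset(genes, [frozenset(), frozenset("A")], {})
        with pytest.raises(ValueError, match="incomplete"):
            zscore_matrix(data)


class TestAccessibilityFromZ:
    def test_sign_rule_and_threshold(self):
        z = pd.DataFrame(
            [[np.nan, -5.0, 2.0], [0.0, np.nan, 3.0], [0.0, 0.0, np.nan]],
            index=list("ABC"), columns=list("ABC"),
        )
        g = accessibility_from_z(z, z_threshold=2.0)
        assert ("A", "B") in g and g.sign("A", "B") == 1  # Z<=0 -> activation
        assert ("A", "C") not in g  # |Z| = 2 exactly: strict inequality
        assert ("B", "C") in g and g.sign("B", "C") == -1  # Z>0 -> repression


class TestEdgeWeights:
    def test_perfect_linear_coupling(self):
        genes = ["A", "B", "C", "D"]
        kos = single_ko_design(genes)
        rng = np.random.default_rng(0)
        values = np.ones((4, 5, 3))
        base = rng.uniform(0.5, 2.0, 5)
        values[0, :, :] = base[:, None]
        values[1, :, :] = 2.0 * base[:, None]  # B = 2A exactly
        values[2, :, :] = rng.uniform(0.5, 2.0, (5, 3))
        data = ExpressionDataset(tuple(genes), kos, values)
        w = edge_weights(data)
        assert w.loc["A", "B"] == pytest.approx(1.0)

    def test_independent_noise_gives_small_weights(self):
        genes = [f"G{k}" for k in range(4)]
        n_exp = 50
        kos = [frozenset()] + [frozenset([g]) for g in genes]
        kos += [frozenset([genes[0], f"X{k}"]) for k in range(n_exp)]
        # only single-KO + WT experiments are used by edge_weights; build
        # a wide single-KO-like dataset instead via many genes
        genes = [f"G{k}" for k in range(30)]
        kos = single_ko_design(genes)
        rng = np.random.default_rng(1)
        values = rng.lognormal(0, 0.3, (30, 31, 3))
        data = ExpressionDataset(tuple(genes), kos, values)
        w = edge_weights(data)
        off = w.to_numpy()[~np.eye(30, dtype=bool)]
        assert np.nanmedian(off) < 0.3

    def test_asymmetric_exclusion(self):
        genes = ["A", "B", "C", "D"]
        kos = single_ko_design(genes)
        rng = np.random.default_rng(2)
        values = rng.lognormal(0, 0.5, (4, 5, 4))
        data = ExpressionDataset(tuple(genes), kos, values)
        w = edge_weights(data)
        assert w.loc["A", "B"] != pytest.approx(w.loc["B", "A"])


class TestSignedLtr:
    def triangle(self, s_ij, s_ik, s_kj, weights=None):
        g = SignedDigraph(
            edges=[("I", "J", s_ij), ("I", "K", s_ik), ("K", "J", s_kj)]
        )
        if weights:
            for e, w in weights.items():
                g.set_weight(*e, w)
        return g

    def test_sign_consistent_shortcut_removed_at_zero_cut(self):
        lower = signed_ltr(self.triangle(1, 1, 1), w_cut=0.0)
        assert ("I", "J") not in lower

    def test_sign_inconsistent_shortcut_retained(self):
        lower = signed_ltr(self.triangle(-1, 1, 1), w_cut=0.0)
        assert ("I", "J") in lower

    def test_weight_condition_strict_inequality(self):
        # w_cut * W(i,j) == W(i,k) * W(k,j): tie -> edge retained
        g = self.triangle(1, 1, 1, weights={("I", "J"): 0.5,
                                            ("I", "K"): 0.5, ("K", "J"): 0.5})
        assert ("I", "J") in signed_ltr(g, w_cut=0.5)
        assert ("I", "J") not in signed_ltr(g, w_cut=0.49)

    def test_order_independent(self):
        rng = np.random.default_rng(5)
        from conftest import random_digraph

        g = random_digraph(rng, 8, 0.3)
        for (u, v) in g.edge_pairs:
            g.set_weight(u, v, float(rng.uniform(0, 1)))
        ref = signed_ltr(g, w_cut=0.3)
        edges = sorted(g.edge_pairs)
        for _ in range(20):
            rng.shuffle(edges)
            assert signed_ltr(g, w_cut=0.3, edge_order=list(edges)) == ref

    def test_reduces_to_transitive_reduction_on_positive_closed_dag(self):
        # all-positive DAG equal to its own closure
        base = SignedDigraph(edges=[("A", "B", 1), ("B", "C", 1), ("C", "D", 1)])
        clos = signed_closure(base)
        lower = signed_ltr(clos, w_cut=0.0)
        assert lower.edge_pairs == transitive_reduction_dag(clos)

    def test_lower_bound_monotone_in_w_cut(self):
        rng = np.random.default_rng(9)
        from conftest import random_digraph

        g = random_digraph(rng, 9, 0.3)
        for (u, v) in g.edge_pairs:
            g.set_weight(u, v, float(rng.uniform(0, 1)))
        sizes = [signed_ltr(g, w_cut=w).m for w in np.linspace(0, 1, 6)]
        assert sizes == sorted(sizes)

    def test_w_cut_range_validated(self):
        with pytest.raises(ValueError):
            signed_ltr(self.triangle(1, 1, 1), w_cut=1.2)

    def test_worked_example_uncertain_edges(self):
        from traceplus import load_worked_example

        ref, bounds = load_worked_example(w_cut=0.3)
        assert bounds.uncertain == {("A", "D"), ("A", "E"), ("C", "E")}


class TestContrex:
    def test_dag_equals_plain_transitive_reduction(self):
        g = signed_closure(
            SignedDigraph(edges=[("A", "B", 1), ("B", "C", 1), ("C", "D", 1)])
        )
        lower = contrex_unsigned(g)
        assert lower.edge_pairs == transitive_reduction_dag(g)

    def test_cycle_incoming_edge_removed_cycle_kept(self):
        g = SignedDigraph(edges=[("D", "E", 1), ("E", "D", 1), ("B", "D", 1)])
        lower = contrex_unsigned(g)
        assert ("B", "D") not in lower
        assert ("D", "E") in lower and ("E", "D") in lower

    def test_worked_example_manual_contrex(self):
        # manual application of the three steps to the example closure:
        # condense {D,E}; reduce the quotient (A->DE is a shortcut via C);
        # expand keeping only the 2-cycle edges
        from traceplus import load_worked_example

        _, bounds = load_worked_example()
        lower = contrex_unsigned(bounds.upper)
        assert lower.edge_pairs == {("A", "C"), ("D", "E"), ("E", "D")}


@pytest.fixture(scope="module")
def shallow_dag_run():
    # 20-gene depth-2 DAG: every gene has at most 2 ancestors, so each
    # expression column carries at most 3 KO effects and the z-score
    # criterion clears its threshold for all of them
    edges = [("G01", "G08", 1), ("G01", "G09", -1), ("G02", "G10", 1),
             ("G02", "G11", 1), ("G03", "G12", -1), ("G04", "G16", 1),
             ("G05", "G17", -1), ("G08", "G13", 1), ("G10", "G14", -1),
             ("G12", "G15", 1)]
    nodes = [f"G{k:02d}" for k in range(1, 21)]
    net = SignedDigraph(nodes, edges=edges)
    model = random_kinetic_model(net, seed=12, sigma_int=0.01, sigma_meas=0.02)
    data = generate_compendium(model, single_ko_design(net.nodes), 10, seed=13)
    return net, data


class TestBuildInitialBounds:

    def test_every_reference_edge_recovered_with_sign(self, shallow_dag_run):
        net, data = shallow_dag_run
        bounds = build_initial_bounds(data, w_cut=0.0)
        assert net.edges <= bounds.upper.edges

    def test_noise_free_upper_is_signed_closure_on_tree(self):
        # 20-gene fan-out tree of depth 2: no gene has more than two
        # ancestors, no cancellation, closure fully detectable
        edges = [("R01", "A01", 1), ("R01", "A02", -1), ("R02", "A03", 1),
                 ("A01", "B01", 1), ("A01", "B02", -1), ("A02", "B03", -1),
                 ("A03", "B04", 1)]
        nodes = (
            ["R01", "R02"]
            + [f"A{k:02d}" for k in range(1, 4)]
            + [f"B{k:02d}" for k in range(1, 5)]
            + [f"X{k:02d}" for k in range(1, 12)]
        )
        net = SignedDigraph(nodes, edges=edges)
        model = random_kinetic_model(net, seed=3, sigma_int=0.0, sigma_meas=0.0)
        data = generate_compendium(model, single_ko_design(net.nodes), 3, seed=4)
        bounds = build_initial_bounds(data, w_cut=0.0)
        assert bounds.upper.edges == signed_closure(net).edges

    def test_lower_size_non_increasing_in_w_cut_reversed(self, shallow_dag_run):
        _, data = shallow_dag_run
        sizes = [build_initial_bounds(data, w_cut=w).lower.m for w in (0.0, 0.5, 1.0)]
        assert sizes == sorted(sizes)

    def test_reduced_upper_yields_empty_uncertain_set(self):
        # independent edges: the recovered upper bound has no length-2
        # paths, so it is its own LTR fixed point and nothing is uncertain
        edges = [("A", "B", 1), ("C", "D", -1), ("E", "F", 1)]
        nodes = list("ABCDEF") + [f"X{k:02d}" for k in range(1, 15)]
        net = SignedDigraph(nodes, edges=edges)
        model = random_kinetic_model(net, seed=5, sigma_int=0.0, sigma_meas=0.0)
        data = generate_compendium(model, single_ko_design(net.nodes), 3, seed=6)
        bounds = build_initial_bounds(data, w_cut=0.0)
        assert bounds.upper.edges == net.edges
        assert bounds.uncertain == set()

    def test_trace_mode_uses_contrex(self, shallow_dag_run):
        _, data = shallow_dag_run
        b_trace = build_initial_bounds(data, w_cut=0.0, mode="trace")
        assert b_trace.lower.edge_pairs == contrex_unsigned(b_trace.upper).edge_pairs


class TestEnsembleBounds:
    def test_lower_must_be_subset_with_matching_signs(self):
        upper = SignedDigraph(edges=[("A", "B", 1)])
        bad = SignedDigraph(edges=[("A", "B", -1)])
        with pytest.raises(ValueError):
            EnsembleBounds(upper=upper, lower=bad)

    def test_confirm_overwrites_upper_sign(self):
        upper = SignedDigraph(edges=[("A", "B", 1)])
        bounds = EnsembleBounds(upper=upper, lower=SignedDigraph(["A", "B"]))
        bounds.confirm_edge("A", "B", -1)
        assert bounds.upper.sign("A", "B") == -1
        assert bounds.uncertain == set()
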