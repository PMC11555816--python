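"""Correlation-entropy closed forms and the combinatorial edge screen."""

import math

import numpy as np
import pytest

from dnentropy import (
    ExpressionMatrix,
    RegNetwork,
    ScreenConfig,
    corr_with_normality_switch,
    correlation_matrix,
    network_entropy,
    node_entropy,
    screen_edges,
)

from conftest import star_corr


def _expr(n_genes, n_times=24, seed=0, genes=None):
    rng = np.random.default_rng(seed)
    genes = genes or [f"G{i + 1}" for i in range(n_genes)]
    return ExpressionMatrix(
        genes, 10.0 * np.arange(n_times), rng.normal(size=(n_genes, n_times))
    )


class TestCorrSwitch:
    def test_gaussian_self_correlation_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        c, kind = corr_with_normality_switch(x, x.copy())
        assert c == pytest.approx(1.0)
        assert kind == "pearson"

    def test_heavy_tail_monotone_transform_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.standard_t(df=1, size=80)  # heavy-tailed, fails normality
        y = np.exp(np.clip(x, -20, 20))
        c, kind = corr_with_normality_switch(x, y)
        assert kind == "spearman"
        assert c == pytest.approx(1.0)

    def test_anticorrelation_magnitude(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        c, _ = corr_with_normality_switch(x, -x)
        assert abs(c) == pytest.approx(1.0)

    def test_constant_series_raises(self):
        x = np.zeros(10)
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="constant"):
            corr_with_normality_switch(x, y)


class TestNodeEntropy:
    def test_single_neighbor_zero(self):
        net = RegNetwork.from_edges(["A", "B", "C"], [("A", "B")])
        e = _expr(3, genes=["A", "B", "C"])
        assert node_entropy(net, e, "A") == 0.0
        assert node_entropy(net, e, "B") == 0.0
        assert node_entropy(net, e, "C") == 0.0  # isolated

    def test_two_equal_neighbors_ln2(self, star_expr):
        net = RegNetwork.from_edges(["H", "L1", "L2", "L3"], [("H", "L1"), ("H", "L2")])
        h = node_entropy(net, star_expr, "H", corr=star_corr(0.6))
        assert h == pytest.approx(math.log(2), abs=1e-9)

    def test_three_equal_neighbors_ln3(self, star_network, star_expr):
        h = node_entropy(star_network, star_expr, "H", corr=star_corr(0.4))
        assert h == pytest.approx(math.log(3), abs=1e-9)

    def test_unequal_correlations_closed_form(self, star_expr):
        net = RegNetwork.from_edges(["H", "L1", "L2", "L3"], [("H", "L1"), ("H", "L2")])
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.8
        corr[0, 2] = corr[2, 0] = 0.2
        h = node_entropy(net, star_expr, "H", corr=corr)
        expected = -0.8 * math.log(0.8) - 0.2 * math.log(0.2)
        assert h == pytest.approx(expected, abs=1e-9)
        assert h == pytest.approx(0.5004, abs=5e-5)

    def test_direction_irrelevant_for_neighborhood(self, star_expr):
        fwd = RegNetwork.from_edges(["H", "L1", "L2", "L3"], [("H", "L1"), ("H", "L2")])
        rev = RegNetwork.from_edges(["H", "L1", "L2", "L3"], [("L1", "H"), ("L2", "H")])
        c = star_corr(0.3)
        assert node_entropy(fwd, star_expr, "H", corr=c) == pytest.approx(
            node_entropy(rev, star_expr, "H", corr=c)
        )

    def test_probabilities_normalize_on_random_graphs(self):
        # sum_j p_ij = 1 is implied by H <= log(degree); verify directly
        rng = np.random.default_rng(9)
        for trial in range(100):
            n = int(rng.integers(3, 7))
            genes = [f"G{i + 1}" for i in range(n)]
            edges = [
                (genes[i], genes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.5
            ]
            net = RegNetwork.from_edges(genes, edges)
            corr = np.clip(rng.uniform(0.05, 1.0, size=(n, n)), 0, 1)
            corr = (corr + corr.T) / 2
            np.fill_diagonal(corr, 1.0)
            e = _expr(n, seed=trial, genes=genes)
            for g in genes:
                deg = len(net.neighbors(g))
                h = node_entropy(net, e, g, corr=corr)
                assert h >= 0.0
                assert h <= math.log(deg) + 1e-9 if deg else h == 0.0
                # explicit normalization check
                i = e.gene_index(g)
                nbrs = [e.gene_index(x) for x in net.neighbors(g)]
                if nbrs:
                    p = np.abs(corr[i, nbrs]) / np.abs(corr[i, nbrs]).sum()
                    assert p.sum() == pytest.approx(1.0)

    def test_invariant_under_common_rescaling_of_correlations(self, star_network, star_expr):
        corr = star_corr(0.4)
        h1 = node_entropy(star_network, star_expr, "H", corr=corr)
        h2 = node_entropy(star_network, star_expr, "H", corr=0.5 * corr)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_log_base_two(self, star_network, star_expr):
        h = node_entropy(star_network, star_expr, "H", corr=star_corr(0.4), log_base=2)
        assert h == pytest.approx(math.log2(3), abs=1e-9)


class TestNetworkEntropy:
    def test_edgeless_network_zero(self):
        net = RegNetwork.from_edges(["A", "B"], [])
        assert network_entropy(net, _expr(2, genes=["A", "B"])) == 0.0

    def test_star_total_is_ln3(self, star_network, star_expr):
        total = network_entropy(star_network, star_expr, corr=star_corr(0.5))
        assert total == pytest.approx(math.log(3), abs=1e-9)

    def test_new_pair_edge_adds_nothing(self, star_expr):
        # both endpoints become degree-1 nodes with H = 0
        before = RegNetwork.from_edges(["H", "L1", "L2", "L3"], [])
        after = before.with_edge("L2", "L3")
        c = star_corr(0.7)
        assert network_entropy(after, star_expr, corr=c) == pytest.approx(
            network_entropy(before, star_expr, corr=c)
        )


def _screen_setup(seed=0):
    genes = ["A", "B", "C", "D", "E"]
    e = _expr(5, seed=seed, genes=genes)
    corr, _ = correlation_matrix(e)
    return genes, e, corr


class TestScreenEdges:
    def test_no_unconfirmed_returns_confirmed(self):
        genes, e, corr = _screen_setup()
        net = RegNetwork(["A", "B", "C", "D", "E"], {("A", "B"): "confirmed"})
        out, report = screen_edges(net, e, ScreenConfig(a=0.3, b=1), corr=corr)
        assert out.edges == {("A", "B"): "confirmed"}
        assert report["n_accepted"] == 0

    def test_infinite_a_accepts_everything(self):
        genes, e, corr = _screen_setup(1)
        net = RegNetwork(
            genes,
            {("A", "B"): "confirmed", ("A", "C"): "unconfirmed", ("B", "D"): "unconfirmed"},
        )
        out, report = screen_edges(net, e, ScreenConfig(a=math.inf, b=1), corr=corr)
        assert report["n_accepted"] == 2
        assert out.edges[("A", "C")] == "candidate-added"

    def test_minus_infinite_a_b1_rejects_all_with_contexts(self):
        genes, e, corr = _screen_setup(2)
        net = RegNetwork(
            genes,
            {("A", "B"): "confirmed", ("A", "C"): "unconfirmed", ("B", "D"): "unconfirmed"},
        )
        out, report = screen_edges(net, e, ScreenConfig(a=-math.inf, b=1), corr=corr)
        assert report["n_accepted"] == 0

    def test_edge_with_no_context_is_accepted(self):
        genes, e, corr = _screen_setup(3)
        net = RegNetwork(genes, {("A", "C"): "unconfirmed"})
        out, report = screen_edges(net, e, ScreenConfig(a=-math.inf, b=1), corr=corr)
        assert report["n_accepted"] == 1  # zero contexts, zero violations

    def test_monotone_in_b(self):
        genes, e, corr = _screen_setup(4)
        net = RegNetwork(
            genes,
            {
                ("A", "B"): "unconfirmed",
                ("A", "C"): "unconfirmed",
                ("B", "C"): "unconfirmed",
                ("C", "D"): "unconfirmed",
            },
        )
        accepted_prev: set = set()
        for b in (1, 2, 4, 8):
            out, _ = screen_edges(net, e, ScreenConfig(a=0.05, b=b), corr=corr)
            acc = set(out.edges_with_status("candidate-added"))
            assert accepted_prev <= acc
            accepted_prev = acc

    def test_entropy_raising_edge_rejected_lowering_accepted(self):
        # attaching H-L2 on top of H-L1 (equal |corr|) raises H's entropy
        # by exactly ln 2 in its only context: violation iff a < ln 2
        genes = ["H", "L1", "L2"]
        e = _expr(3, seed=5, genes=genes)
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.9
        corr[0, 2] = corr[2, 0] = 0.9
        net = RegNetwork(
            genes, {("H", "L1"): "unconfirmed", ("H", "L2"): "unconfirmed"}
        )
        # context = the other edge; adding e creates a 2-neighbor hub: d - c = ln 2
        out, report = screen_edges(net, e, ScreenConfig(a=0.3, b=1), corr=corr)
        assert report["n_accepted"] == 0
        out, report = screen_edges(net, e, ScreenConfig(a=0.8, b=1), corr=corr)
        assert report["n_accepted"] == 2  # ln 2 < 0.8: no violations

    def test_group_specific_thresholds(self):
        genes, e, corr = _screen_setup(6)
        edges = {
            ("A", "B"): "unconfirmed",
            ("A", "C"): "unconfirmed",
            ("B", "D"): "unconfirmed",
            ("C", "E"): "unconfirmed",
        }
        net = RegNetwork(genes, edges)
        groups = [
            ([("A", "B"), ("A", "C")], 1),
            ([("B", "D"), ("C", "E")], 1000),
        ]
        cfg = ScreenConfig(a=-math.inf, b=1, groups=groups)
        out, report = screen_edges(net, e, cfg, corr=corr)
        # first group: every context violates, b=1 -> rejected
        assert out.edges.get(("A", "B")) is None
        # second group: huge b accepts despite violations
        assert out.edges[("B", "D")] == "candidate-added"

    def test_large_group_without_cap_refused(self):
        genes = [f"G{i}" for i in range(30)]
        e = _expr(30, seed=7, genes=genes)
        edges = {(genes[i], genes[i + 1]): "unconfirmed" for i in range(25)}
        net = RegNetwork(genes, edges)
        with pytest.raises(ValueError, match="max_context_size"):
            screen_edges(net, e, ScreenConfig(a=0.3, b=1), corr=np.eye(30))

    def test_literal_semantics_accepts_all(self):
        genes, e, corr = _screen_setup(8)
        net = RegNetwork(
            genes, {("A", "B"): "unconfirmed", ("A", "C"): "unconfirmed"}
        )
        out, report = screen_edges(
            net, e, ScreenConfig(a=-math.inf, b=1, semantics="literal"), corr=corr
        )
        assert report["n_accepted"] == 2

    def test_context_counts_match_combinatorics(self):
        genes, e, corr = _screen_setup(9)
        edges = {
            ("A", "B"): "unconfirmed",
            ("A", "C"): "unconfirmed",
            ("B", "D"): "unconfirmed",
            ("C", "D"): "unconfirmed",
        }
        net = RegNetwork(genes, edges)
        _, report = screen_edges(net, e, ScreenConfig(a=math.inf, b=10), corr=corr)
        for info in report["edges"].values():
            assert info["contexts"] == 2**3 - 1  # subsets of the other 3 edges
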