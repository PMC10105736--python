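"""Null-ensemble enrichment, hypergeometric tests, binned adjacency."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import random_network
from y2hnet.netcore import Network, Pair
from y2hnet.null_stats import (
    adjacency_bin_matrix,
    cocitation_counts,
    coexpression_shared_celltypes,
    colocalization_fraction,
    enrichment_vs_null,
    hypergeom_enrichment,
    shared_term_fraction,
)
from y2hnet.screen_sim import simulate_interactome


class TestSharedTermFraction:
    def test_single_annotated_edge(self):
        net = Network.from_edges([("A", "B")])
        assert shared_term_fraction(net, {"T": {"A", "B"}}) == 1.0

    def test_no_annotations(self):
        net = Network.from_edges([("A", "B")])
        assert shared_term_fraction(net, {}) == 0.0

    def test_large_term_filtered(self):
        net = Network.from_edges([("A", "B"), ("C", "D"), ("E", "F")])
        sets = {
            "small": {"A", "B"},
            "huge": {c for c in "CDEFGHIJKL"},  # > max_term_size: filtered out
            "t1": {"C", "E"},
            "t2": {"D", "F"},
        }
        # without the filter C-D and E-F would share "huge"; with it only A-B shares
        assert shared_term_fraction(net, sets, max_term_size=None) == 1.0
        assert shared_term_fraction(net, sets, max_term_size=4) == pytest.approx(1 / 3)


class TestEnrichmentVsNull:
    def test_label_invariant_statistic_p_one(self, toy_net):
        res = enrichment_vs_null(toy_net, lambda n: float(n.n_edges), n_null=20, seed=0)
        assert res.empirical_p == 1.0
        assert res.degenerate

    def test_n_null_one_bounds(self, toy_net):
        res = enrichment_vs_null(toy_net, lambda n: float(n.n_edges), n_null=1, seed=0)
        assert res.empirical_p in (0.5, 1.0)

    def test_planted_modules_detected(self):
        net, bundle = simulate_interactome(150, 4.0, module_count=5, mixing=0.1, seed=11)
        res = enrichment_vs_null(
            net,
            lambda n: shared_term_fraction(n, bundle.gene_sets, 30),
            n_null=199,
            seed=2,
            name="shared_terms",
        )
        assert res.observed > res.null_mean
        assert res.empirical_p <= 0.01

    def test_independent_annotations_calibrated(self):
        """With annotations unrelated to topology the observed statistic is
        an ordinary draw from its own null (central 99% coverage)."""
        from y2hnet.netcore import node_label_shuffle

        inside = 0
        n_seeds = 40
        for s in range(n_seeds):
            local = np.random.default_rng(1000 + s)
            net = random_network(local, 30, 45)
            genes = sorted(net.nodes)
            sets = {}
            for t in range(6):
                take = local.choice(len(genes), size=8, replace=False)
                sets[f"T{t}"] = {genes[i] for i in take}
            observed = shared_term_fraction(net, sets, 30)
            null = [
                shared_term_fraction(node_label_shuffle(net, child), sets, 30)
                for child in np.random.default_rng(2000 + s).spawn(199)
            ]
            lo, hi = np.quantile(null, [0.005, 0.995])
            inside += lo <= observed <= hi
        assert inside / n_seeds >= 0.9

    def test_reproducible(self, toy_net):
        organelle = {g: "nucleus" if g < "D" else "cytosol" for g in toy_net.nodes}
        f = lambda n: colocalization_fraction(n, organelle)
        r1 = enrichment_vs_null(toy_net, f, n_null=50, seed=9)
        r2 = enrichment_vs_null(toy_net, f, n_null=50, seed=9)
        assert r1 == r2


class TestHypergeomEnrichment:
    def test_worked_example(self):
        universe = set("ABCDEFGHIJ")
        res = hypergeom_enrichment(set("ABCDE"), {"T": set("ABCF")}, universe)
        k, expected, p = res["T"]
        assert k == 3
        assert expected == pytest.approx(2.0)
        assert p == pytest.approx(66 / 252)

    def test_set_equals_universe(self):
        universe = set("ABCDEF")
        _, _, p = hypergeom_enrichment(set("AB"), {"T": universe}, universe)["T"]
        assert p == pytest.approx(1.0)

    def test_zero_overlap_tail_is_one(self):
        universe = set("ABCDEF")
        _, _, p = hypergeom_enrichment(set("AB"), {"T": {"E", "F"}}, universe)["T"]
        assert p <= 1.0
        k0, _, p0 = hypergeom_enrichment(set(), {"T": {"E"}}, universe)["T"]
        assert (k0, p0) == (0, 1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        """Tail probability equals brute-force enumeration of all draws."""
        for _ in range(30):
            n_uni = int(rng.integers(5, 13))
            universe = {f"g{i}" for i in range(n_uni)}
            genes = sorted(universe)
            term = set(
                genes[i]
                for i in rng.choice(n_uni, size=int(rng.integers(1, n_uni)), replace=False)
            )
            q_size = int(rng.integers(1, n_uni + 1))
            query = set(
                genes[i] for i in rng.choice(n_uni, size=q_size, replace=False)
            )
            k_obs = len(query & term)
            total = hits = 0
            for draw in itertools.combinations(genes, q_size):
                total += 1
                hits += len(set(draw) & term) >= k_obs
            _, _, p = hypergeom_enrichment(query, {"T": term}, universe)["T"]
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"A"}, {"T": {"A"}}, set())


class TestCocitation:
    def test_shared_small_publication(self):
        net = Network.from_edges([("A", "B")])
        counts, mean = cocitation_counts(net, {"p1": {"A", "B", "C"}}, 100)
        assert counts[Pair("A", "B")] == 1 and mean == 1.0

    def test_genome_scale_publication_filtered(self):
        net = Network.from_edges([("A", "B")])
        big = {f"g{i}" for i in range(150)} | {"A", "B"}
        counts, _ = cocitation_counts(net, {"big": big}, 100)
        assert counts[Pair("A", "B")] == 0

    def test_mixed_filtering(self):
        net = Network.from_edges([("A", "B")])
        pubs = {
            "small": {"A", "B"},
            "big": {f"g{i}" for i in range(120)} | {"A", "B"},
        }
        counts, _ = cocitation_counts(net, pubs, 100)
        assert counts[Pair("A", "B")] == 1


class TestCoexpression:
    def _expr(self, rows):
        return pd.DataFrame(rows).T.astype(int)

    def test_identical_memberships(self):
        net = Network.from_edges([("A", "B")])
        expr = self._expr({"A": [1, 1, 1, 0], "B": [1, 1, 1, 0]})
        assert coexpression_shared_celltypes(net, expr) == 3.0

    def test_disjoint_memberships(self):
        net = Network.from_edges([("A", "B")])
        expr = self._expr({"A": [1, 0], "B": [0, 1]})
        assert coexpression_shared_celltypes(net, expr) == 0.0

    def test_mean_over_covered_edges(self):
        net = Network.from_edges([("A", "B"), ("C", "D"), ("E", "F")])
        expr = self._expr(
            {"A": [1, 1], "B": [1, 1], "C": [1, 0], "D": [0, 1]}
        )  # E, F uncovered
        assert coexpression_shared_celltypes(net, expr) == pytest.approx(1.0)

    def test_no_covered_edges_rejected(self):
        net = Network.from_edges([("A", "B")])
        expr = self._expr({"X": [1]})
        with pytest.raises(ValueError):
            coexpression_shared_celltypes(net, expr)


class TestColocalization:
    def test_fractions(self):
        net = Network.from_edges([("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")])
        same = {g: "nucleus" for g in "ABCDEFGH"}
        assert colocalization_fraction(net, same) == 1.0
        distinct = {g: f"org{i}" for i, g in enumerate("ABCDEFGH")}
        assert colocalization_fraction(net, distinct) == 0.0
        mixed = dict(same)
        mixed["H"] = "cytosol"
        assert colocalization_fraction(net, mixed) == pytest.approx(0.75)

    def test_unannotated_edges_excluded(self):
        net = Network.from_edges([("A", "B"), ("C", "D")])
        assert colocalization_fraction(net, {"A": "n", "B": "n"}) == 1.0


class TestAdjacencyBins:
    def test_single_bin_cell(self):
        net = Network.from_edges([("A", "B"), ("A", "C")])
        counts = {"A": 1, "B": 1, "C": 1}
        mat = adjacency_bin_matrix(net, counts, 1)
        assert mat.tolist() == [[2]]

    def test_cross_bin_symmetric_double_entry(self):
        net = Network.from_edges([("low", "high")])
        counts = {"low": 0, "high": 100}
        mat = adjacency_bin_matrix(net, counts, 2)
        assert mat[0, 1] == 1 and mat[1, 0] == 1 and mat[0, 0] == 0

    def test_upper_triangle_sums_to_edges(self, rng):
        net = random_network(rng, 20, 30)
        counts = {g: int(rng.integers(0, 50)) for g in net.nodes}
        mat = adjacency_bin_matrix(net, counts, 4, symmetric=False)
        assert mat.sum() == net.n_edges
        sym = adjacency_bin_matrix(net, counts, 4, symmetric=True)
        assert (sym == sym.T).all()

    def test_hand_checked_two_bins(self):
        # genes ranked by count: D(0) E(1) | A(5) B(7) C(9)  (2-bin split 3+2)
        net = Network.from_edges([("A", "B"), ("A", "D"), ("D", "E")])
        net.add_node("C")  # annotated but unconnected gene still occupies a bin slot
        counts = {"A": 5, "B": 7, "C": 9, "D": 0, "E": 1}
        mat = adjacency_bin_matrix(net, counts, 2, symmetric=False)
        # bins: [D, E, A] and [B, C] with equal-frequency split of 5 genes
        assert mat[0, 0] == 2  # A-D and D-E
        assert mat[0, 1] == 1  # A-B
        assert mat.sum() == 3

    def test_more_bins_than_genes_rejected(self):
        net = Network.from_edges([("A", "B")])
        with pytest.raises(ValueError):
            adjacency_bin_matrix(net, {"A": 1, "B": 2}, 3)
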