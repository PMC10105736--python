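"""L3 scoring against brute-force walk enumeration, ranking, precision."""

import itertools

import numpy as np
import pytest

from conftest import random_network
from y2hnet.netcore import Network, Pair
from y2hnet.l3_predict import l3_score, l3_score_matrix, precision_at_k, rank_candidates
from y2hnet.screen_sim import simulate_interactome


def brute_force_l3(net: Network, x: str, y: str) -> float:
    """Independent oracle: direct enumeration of x-u-v-y walks."""
    adj = {g: set() for g in net.nodes}
    for p in net.edges:
        if p.a != p.b:
            adj[p.a].add(p.b)
            adj[p.b].add(p.a)
    deg = {g: len(adj[g]) for g in net.nodes}
    total = 0.0
    for u in net.nodes:
        for v in net.nodes:
            if u == v or u in (x, y) or v in (x, y):
                continue
            if u in adj[x] and v in adj[u] and y in adj[v]:
                total += 1.0 / np.sqrt(deg[u] * deg[v])
    return total


class TestL3Score:
    def test_single_path(self):
        net = Network.from_edges([("x", "u"), ("u", "v"), ("v", "y")])
        assert l3_score(net, "x", "y") == pytest.approx(0.5)  # 1/sqrt(2*2)

    def test_no_length3_walk_zero(self):
        net = Network.from_edges([("x", "u"), ("v", "y")])
        assert l3_score(net, "x", "y") == 0.0

    def test_triangle_double_walk(self):
        net = Network.from_edges(
            [("x", "u1"), ("x", "u2"), ("u1", "u2"), ("u1", "y"), ("u2", "y")]
        )
        # walks x-u1-u2-y and x-u2-u1-y, k_u1 = k_u2 = 3
        assert l3_score(net, "x", "y") == pytest.approx(2.0 / 3.0)

    def test_input_errors(self):
        net = Network.from_edges([("x", "u")])
        with pytest.raises(ValueError):
            l3_score(net, "x", "x")
        with pytest.raises(ValueError):
            l3_score(net, "x", "missing")

    def test_matrix_equals_enumeration_random_graphs(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            net = random_network(rng, n, int(rng.integers(3, 2 * n)))
            genes, P = l3_score_matrix(net)
            idx = {g: i for i, g in enumerate(genes)}
            for a, b in itertools.combinations(genes, 2):
                if Pair(a, b) in net.edges:
                    continue
                assert P[idx[a], idx[b]] == pytest.approx(
                    brute_force_l3(net, a, b), abs=1e-12
                )

    def test_relabeling_invariance(self, rng):
        net = random_network(rng, 9, 14)
        mapping = {g: f"Z{g}" for g in net.nodes}
        relabeled = net.relabel(mapping)
        for a, b in itertools.combinations(sorted(net.nodes), 2):
            if Pair(a, b) in net.edges:
                continue
            assert l3_score(net, a, b) == pytest.approx(
                l3_score(relabeled, mapping[a], mapping[b])
            )


class TestRankCandidates:
    def test_k_exceeds_candidates(self):
        net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        preds = rank_candidates(net, 10_000, include_zero_scores=True)
        n_nodes = net.n_nodes
        assert len(preds) == n_nodes * (n_nodes - 1) // 2 - net.n_edges

    def test_ties_broken_lexicographically(self):
        # symmetric graph: candidates (a,d) and (b,c)-like ties
        net = Network.from_edges([("a", "m"), ("m", "n"), ("n", "d"), ("a", "n"), ("m", "d")])
        preds = rank_candidates(net, 10, include_zero_scores=True)
        for first, second in zip(preds, preds[1:]):
            assert first.score > second.score or (
                first.score == second.score and first.pair < second.pair
            )

    def test_ranks_contiguous_scores_sorted(self, rng):
        net = random_network(rng, 12, 20)
        preds = rank_candidates(net, 15)
        assert [p.rank for p in preds] == list(range(1, len(preds) + 1))
        assert all(x.score >= y.score for x, y in zip(preds, preds[1:]))
        assert all(p.score > 0 for p in preds)  # zero scores excluded by default

    def test_top3_matches_exhaustive_oracle(self, rng):
        net = random_network(rng, 10, 16)
        scored = sorted(
            (
                (brute_force_l3(net, a, b), Pair(a, b))
                for a, b in itertools.combinations(sorted(net.nodes), 2)
                if Pair(a, b) not in net.edges
            ),
            key=lambda t: (-t[0], t[1]),
        )
        top3 = rank_candidates(net, 3, include_zero_scores=True)
        assert [p.pair for p in top3] == [p for _, p in scored[:3]]

    def test_existing_edges_and_self_excluded(self, rng):
        net = random_network(rng, 8, 12)
        preds = rank_candidates(net, 100, include_zero_scores=True)
        assert all(p.pair not in net.edges for p in preds)
        assert all(not p.pair.is_homodimer for p in preds)


class TestPrecisionAtK:
    def _preds(self, n):
        return [
            type("S", (), {"pair": Pair(f"a{i}", f"b{i}"), "score": 1.0 / (i + 1), "rank": i + 1})()
            for i in range(n)
        ]

    def test_mixed_calls(self):
        preds = self._preds(10)
        calls = {}
        for i, p in enumerate(preds):
            if i < 2:
                calls[p.pair] = "NA"
            elif i < 6:
                calls[p.pair] = "positive"
            else:
                calls[p.pair] = "negative"
        n_tested, n_und, n_pos, prec = precision_at_k(preds, calls, 10)
        assert (n_tested, n_und, n_pos) == (10, 2, 4)
        assert prec == pytest.approx(0.5)

    def test_all_positive(self):
        preds = self._preds(5)
        calls = {p.pair: "positive" for p in preds}
        assert precision_at_k(preds, calls, 5)[3] == 1.0

    def test_all_undetermined_flagged(self):
        preds = self._preds(3)
        calls = {p.pair: "autoactivator_undetermined" for p in preds}
        with pytest.raises(ZeroDivisionError):
            precision_at_k(preds, calls, 3)


class TestHeldOutRecovery:
    def test_held_out_edges_rank_better_than_random_nonedges(self):
        """Held-out module edges score higher than random non-edges (link
        prediction recovers planted structure)."""
        net, _ = simulate_interactome(
            120, mean_degree=6.0, module_count=4, mixing=0.1, seed=5
        )
        rng = np.random.default_rng(7)
        intra = sorted(net.edges)
        held_idx = rng.choice(len(intra), size=len(intra) // 2, replace=False)
        held = {intra[i] for i in held_idx}
        observed = Network.from_edges(net.edges - held)
        for g in net.nodes:
            observed.add_node(g)
        genes, P = l3_score_matrix(observed)
        idx = {g: i for i, g in enumerate(genes)}

        def mean_score(pairs):
            return float(np.mean([P[idx[p.a], idx[p.b]] for p in pairs]))

        nonedges = []
        nodes = sorted(observed.nodes)
        while len(nonedges) < len(held):
            a, b = rng.choice(len(nodes), size=2, replace=False)
            p = Pair(nodes[a], nodes[b])
            if p not in net.edges:
                nonedges.append(p)
        assert mean_score(held) > 2 * mean_score(nonedges)
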