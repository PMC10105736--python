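"""Degree-normalized length-3 path (L3) link prediction.

Two proteins x and y that do *not* interact directly but are joined by
many length-3 paths x–u–v–y tend to be an undetected interacting pair:
the u–v edge implies complementary interaction interfaces, and x
resembling v / y resembling u completes the argument.  Raw path counts
are dominated by hubs, so each path is down-weighted by the degrees of
its two intermediate nodes:

    p_xy = sum_{u,v} A_xu * A_uv * A_vy / sqrt(k_u * k_v)

with A the (zero-diagonal) adjacency matrix and k_u the node degrees.
Candidates (non-adjacent node pairs) are ranked by p_xy and the top k
are put forward for experimental retest; precision is then the fraction
of retested predictions scored positive, after excluding pairs whose
retest was undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .netcore import GeneId, Network, Pair

__all__ = ["L3Score", "l3_score", "l3_score_matrix", "rank_candidates", "precision_at_k"]


@dataclass(frozen=True)
class L3Score:
    pair: Pair
    score: float
    rank: int


def _adjacency(net: Network) -> tuple[list[GeneId], np.ndarray]:
    """Sorted node list and dense zero-diagonal adjacency matrix.

    Homodimer edges are kept in the network but contribute no length-3
    paths (an intermediate step u–u is not a path), so the diagonal is
    zeroed here.
    """
    genes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)))
    for p in net.edges:
        if p.a == p.b:
            continue
        i, j = idx[p.a], idx[p.b]
        A[i, j] = A[j, i] = 1.0
    return genes, A


def l3_score_matrix(net: Network) -> tuple[list[GeneId], np.ndarray]:
    """All-pairs L3 scores as A @ (D^-1/2 A D^-1/2) @ A.

    With a zero diagonal and the score read only at non-adjacent (x, y),
    the matrix product equals the constrained walk sum with u, v distinct
    from each other and from the endpoints.
    """
    genes, A = _adjacency(net)
    k = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(k > 0, 1.0 / np.sqrt(np.maximum(k, 1e-300)), 0.0)
    Ahat = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    P = A @ Ahat @ A
    return genes, P


def l3_score(net: Network, x: GeneId, y: GeneId) -> float:
    """L3 score of one candidate pair (walk enumeration; symmetric in x, y)."""
    if x == y:
        raise ValueError("L3 score is defined for distinct genes")
    if x not in net.nodes or y not in net.nodes:
        raise ValueError("both genes must be nodes of the network")
    deg = {g: 0 for g in net.nodes}
    adj: dict[GeneId, set[GeneId]] = {g: set() for g in net.nodes}
    for p in net.edges:
        if p.a == p.b:
            continue
        adj[p.a].add(p.b)
        adj[p.b].add(p.a)
        deg[p.a] += 1
        deg[p.b] += 1
    total = 0.0
    for u in adj[x]:
        if u in (x, y):
            continue
        for v in adj[u]:
            if v in (x, y) or v == u:
                continue
            if y in adj[v]:
                total += 1.0 / np.sqrt(deg[u] * deg[v])
    return total


def rank_candidates(
    net: Network,
    k: int,
    candidate_filter: Iterable[Pair] | set[GeneId] | None = None,
    include_zero_scores: bool = False,
) -> list[L3Score]:
    """Top-k non-adjacent pairs by L3 score.

    ``candidate_filter`` restricts the candidate space: a set of gene ids
    limits candidates to pairs within those genes (e.g. the screened ORF
    space); an iterable of pairs scores exactly those pairs.  Existing
    edges and self-pairs are always excluded.  Ties are broken by
    canonical pair order; zero-score candidates are dropped unless
    ``include_zero_scores``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes, P = l3_score_matrix(net)
    idx = {g: i for i, g in enumerate(genes)}

    explicit_pairs: list[Pair] | None = None
    restrict: set[GeneId] | None = None
    if candidate_filter is not None:
        flt = list(candidate_filter) if not isinstance(candidate_filter, set) else candidate_filter
        if flt and isinstance(next(iter(flt)), Pair):
            explicit_pairs = sorted(flt)  # type: ignore[arg-type]
        else:
            restrict = set(flt)  # type: ignore[arg-type]

    scored: list[tuple[float, Pair]] = []
    if explicit_pairs is not None:
        for p in explicit_pairs:
            if p.is_homodimer or p in net.edges:
                continue
            if p.a not in idx or p.b not in idx:
                continue
            scored.append((float(P[idx[p.a], idx[p.b]]), p))
    else:
        pool = genes if restrict is None else [g for g in genes if g in restrict]
        for i_pos, a in enumerate(pool):
            ia = idx[a]
            for b in pool[i_pos + 1:]:
                p = Pair(a, b)
                if p in net.edges:
                    continue
                scored.append((float(P[ia, idx[b]]), p))

    if not include_zero_scores:
        scored = [(s, p) for s, p in scored if s > 0]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [L3Score(p, s, r + 1) for r, (s, p) in enumerate(scored[:k])]


def precision_at_k(
    predictions: list[L3Score],
    calls: Mapping[Pair, str],
    k: int,
) -> tuple[int, int, int, float]:
    """Retest precision of the top-k predictions.

    Returns ``(n_tested, n_undetermined, n_positive, precision)`` where
    undetermined covers auto-activator and unscorable (NA) retests and
    precision = n_positive / (n_tested - n_undetermined).
    """
    top = predictions[:k]
    n_tested = 0
    n_und = 0
    n_pos = 0
    for s in top:
        if s.pair not in calls:
            raise KeyError(f"no retest call for predicted pair {s.pair}")
        call = calls[s.pair]
        n_tested += 1
        if call in ("autoactivator_undetermined", "NA"):
            n_und += 1
        elif call == "positive":
            n_pos += 1
    denom = n_tested - n_und
    if denom == 0:
        raise ZeroDivisionError("all retested predictions were undetermined")
    return n_tested, n_und, n_pos, n_pos / denom
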