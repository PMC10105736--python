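"""Canonical gene / pair / network data model.

Every stage of the pipeline speaks in terms of three things: a gene
identifier (an opaque normalized string such as ``FBgn0000001`` or a
synthetic ``G0001``), an *unordered* gene pair (the universal edge unit —
a bait A / prey B record and a bait B / prey A record are the same
interaction), and an undirected network with per-edge provenance tags.

Conventions adopted here and relied on everywhere else:

* Pairs are stored canonically with the lexicographically smaller id
  first, so set membership is orientation independent.
* Homodimers (A–A) are legal, flagged, contribute 1 to the degree of
  their gene, and appear in neighbor sets.
* Node-label shuffling permutes labels among the network's own nodes,
  which preserves topology (and hence the degree sequence) exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

GeneId = str

__all__ = [
    "GeneId",
    "Pair",
    "Network",
    "canonicalize_pair",
    "dedupe_pairs",
    "node_label_shuffle",
    "neighbors",
    "collapse_ids",
    "load_id_map",
    "read_edge_tsv",
    "write_edge_tsv",
    "read_mitab",
    "write_mitab",
]


@dataclass(frozen=True, order=True)
class Pair:
    """Unordered gene pair in canonical (lexicographic) storage order."""

    a: GeneId
    b: GeneId

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise ValueError("gene ids must be non-empty")
        if self.b < self.a:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def is_homodimer(self) -> bool:
        return self.a == self.b

    def genes(self) -> tuple[GeneId, GeneId]:
        return (self.a, self.b)

    def __iter__(self) -> Iterator[GeneId]:
        return iter((self.a, self.b))


def canonicalize_pair(a: GeneId, b: GeneId) -> Pair:
    """Return the canonical unordered pair for two gene ids.

    Idempotent: ``canonicalize_pair(*canonicalize_pair(a, b)) ==
    canonicalize_pair(a, b)``.  Comparison is plain string order, so
    e.g. ``"FBgn10" < "FBgn2"``.
    """
    return Pair(a, b)


def dedupe_pairs(directed_records: Iterable[tuple[GeneId, GeneId]]) -> set[Pair]:
    """Collapse directed bait–prey records to orientation-independent pairs."""
    return {Pair(bait, prey) for bait, prey in directed_records}


@dataclass
class Network:
    """Undirected PPI network with optional per-edge provenance tags."""

    nodes: set[GeneId] = field(default_factory=set)
    edges: set[Pair] = field(default_factory=set)
    provenance: dict[Pair, list[str]] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Pair | tuple[GeneId, GeneId]],
        source: str | None = None,
    ) -> "Network":
        net = cls()
        for e in edges:
            p = e if isinstance(e, Pair) else Pair(*e)
            net.add_edge(p, source)
        return net

    def add_edge(self, pair: Pair, source: str | None = None) -> None:
        self.nodes.add(pair.a)
        self.nodes.add(pair.b)
        self.edges.add(pair)
        if source is not None:
            tags = self.provenance.setdefault(pair, [])
            if source not in tags:
                tags.append(source)

    def add_node(self, gene: GeneId) -> None:
        self.nodes.add(gene)

    def has_edge(self, a: GeneId, b: GeneId) -> bool:
        return Pair(a, b) in self.edges

    def neighbors(self, g: GeneId) -> set[GeneId]:
        out: set[GeneId] = set()
        for p in self.edges:
            if p.a == g:
                out.add(p.b)
            elif p.b == g:
                out.add(p.a)
        return out

    def degree(self, g: GeneId) -> int:
        """Number of incident edges; a homodimer edge counts once."""
        return sum(1 for p in self.edges if g in (p.a, p.b))

    def degree_sequence(self) -> list[int]:
        deg: dict[GeneId, int] = {g: 0 for g in self.nodes}
        for p in self.edges:
            deg[p.a] += 1
            if p.b != p.a:
                deg[p.b] += 1
        return sorted(deg.values())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def relabel(self, mapping: Mapping[GeneId, GeneId]) -> "Network":
        net = Network()
        net.nodes = {mapping.get(g, g) for g in self.nodes}
        for p in self.edges:
            q = Pair(mapping.get(p.a, p.a), mapping.get(p.b, p.b))
            net.edges.add(q)
            if p in self.provenance:
                net.provenance[q] = list(self.provenance[p])
        return net

    def copy(self) -> "Network":
        net = Network()
        net.nodes = set(self.nodes)
        net.edges = set(self.edges)
        net.provenance = {p: list(t) for p, t in self.provenance.items()}
        return net


def neighbors(net: Network, g: GeneId) -> set[GeneId]:
    """Interaction partners of ``g``; includes ``g`` itself only for a homodimer."""
    return net.neighbors(g)


def node_label_shuffle(
    net: Network,
    rng_seed: int | np.random.Generator,
    universe: Sequence[GeneId] | None = None,
) -> Network:
    """Randomized network with the same topology but permuted node labels.

    The default mode permutes labels among the network's own nodes, so the
    edge count and the sorted degree sequence are preserved exactly (each
    individual gene's degree generally changes).  When ``universe`` is
    given, replacement labels are drawn from it without replacement
    instead, emulating relabeling into a larger gene space.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot shuffle an empty network")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    old = sorted(net.nodes)
    if universe is None:
        new = [old[i] for i in rng.permutation(len(old))]
    else:
        pool = sorted(set(universe))
        if len(pool) < len(old):
            raise ValueError("universe smaller than node set")
        new = [pool[i] for i in rng.choice(len(pool), size=len(old), replace=False)]
    return net.relabel(dict(zip(old, new)))


# ---------------------------------------------------------------------------
# Identifier collapse (clone / isoform ids -> gene-level ids)
# ---------------------------------------------------------------------------

def load_id_map(path: str | Path) -> dict[str, list[GeneId]]:
    """Read a two-column TSV mapping old ids to updated gene-level ids.

    An old id may occur on several lines; all targets are retained so the
    caller can drop ambiguous (multi-target) records.
    """
    mapping: dict[str, list[GeneId]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            old, new = line.split("\t")[:2]
            mapping.setdefault(old, [])
            if new not in mapping[old]:
                mapping[old].append(new)
    return mapping


def collapse_ids(
    records: Iterable[tuple[str, str]],
    id_map: Mapping[str, list[GeneId]] | None,
) -> list[tuple[GeneId, GeneId]]:
    """Map clone/isoform-level records to gene level.

    Ids absent from the map pass through unchanged; records in which
    either id maps to multiple updated gene ids are dropped (ambiguous
    identity after annotation update).
    """
    if id_map is None:
        return list(records)
    out: list[tuple[GeneId, GeneId]] = []
    for x, y in records:
        tx = id_map.get(x, [x])
        ty = id_map.get(y, [y])
        if len(tx) != 1 or len(ty) != 1:
            continue
        out.append((tx[0], ty[0]))
    return out


# ---------------------------------------------------------------------------
# Edge-list TSV and minimal PSI-MITAB 2.5 I/O
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["gene_a", "gene_b", "source", "score"]


def write_edge_tsv(
    net: Network,
    path: str | Path,
    scores: Mapping[Pair, float] | None = None,
) -> None:
    """Write ``gene_a gene_b source score`` TSV; missing score written as '.'."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for p in sorted(net.edges):
            src = ",".join(net.provenance.get(p, [])) or "."
            sc = "." if scores is None or p not in scores else repr(float(scores[p]))
            fh.write(f"{p.a}\t{p.b}\t{src}\t{sc}\n")


def read_edge_tsv(path: str | Path) -> Network:
    net = Network()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_a", "gene_b"]:
            raise ValueError(f"unexpected edge-list header in {path}: {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            a, b = fields[0], fields[1]
            src = fields[2] if len(fields) > 2 else "."
            p = Pair(a, b)
            if src and src != ".":
                for tag in src.split(","):
                    net.add_edge(p, tag)
            else:
                net.add_edge(p)
    return net


def write_mitab(
    net: Network,
    path: str | Path,
    method_id: str = "MI:0018",
    pub_id: str = "-",
) -> None:
    """Export as minimal PSI-MITAB 2.5 (15 columns, unused columns '-')."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(net.edges):
            cols = ["-"] * 15
            cols[0] = p.a
            cols[1] = p.b
            cols[6] = method_id
            cols[8] = pub_id
            fh.write("\t".join(cols) + "\n")


def read_mitab(path: str | Path) -> list[tuple[Pair, str, str]]:
    """Read minimal PSI-MITAB 2.5; returns (pair, method_id, pub_id) records."""
    out: list[tuple[Pair, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            out.append((Pair(cols[0], cols[1]), cols[6], cols[8]))
    return out


def all_non_edges(net: Network, restrict: set[GeneId] | None = None) -> Iterator[Pair]:
    """Yield all non-adjacent distinct node pairs (the L3 candidate space)."""
    genes = sorted(net.nodes if restrict is None else net.nodes & restrict)
    for a, b in itertools.combinations(genes, 2):
        p = Pair(a, b)
        if p not in net.edges:
            yield p
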