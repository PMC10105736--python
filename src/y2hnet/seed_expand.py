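"""Seed-list network expansion and RNAi modifier-rate comparison.

Starting from a curated seed list of pathway regulators (List 1), the
screen network is mined breadth-first for direct interactors (List 2,
the first shell) and their interactors (List 3, the second shell); the
shells are strictly disjoint, so the combined candidate set size is
additive.  Candidates and a same-network random control set are then
scored in an in-vivo RNAi modifier assay; because candidates are often
covered by several RNAi lines while controls get one line per gene, a
fair rate comparison subsamples one line per gene several times and
averages the per-subsample modifier rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .netcore import GeneId, Network, Pair

__all__ = [
    "ExpansionResult",
    "RnaiLine",
    "expand_seeds",
    "random_control_set",
    "modifier_rate",
    "subsample_one_line_per_gene",
    "build_regulator_network",
]


@dataclass(frozen=True)
class ExpansionResult:
    seeds: frozenset[GeneId]         # List 1
    first_shell: frozenset[GeneId]   # List 2: direct interactors of seeds
    second_shell: frozenset[GeneId]  # List 3: interactors of the first shell

    @property
    def combined(self) -> frozenset[GeneId]:
        return self.seeds | self.first_shell | self.second_shell

    def sizes(self) -> tuple[int, int, int, int]:
        return (
            len(self.seeds),
            len(self.first_shell),
            len(self.second_shell),
            len(self.combined),
        )


@dataclass(frozen=True)
class RnaiLine:
    gene: GeneId
    line_id: str
    modifier: bool
    set_label: str  # e.g. "autophagy" | "random"


def expand_seeds(net: Network, seeds: set[GeneId]) -> ExpansionResult:
    """Two-shell breadth-first expansion of a seed list.

    first_shell = N(seeds) \\ seeds; second_shell = N(first_shell) \\
    (seeds ∪ first_shell).  Seeds absent from the network contribute no
    neighbors but remain part of the seed list (and of the combined set).
    """
    if not seeds:
        raise ValueError("seed list must be non-empty")
    first: set[GeneId] = set()
    for s in seeds:
        if s in net.nodes:
            first |= net.neighbors(s)
    first -= seeds
    second: set[GeneId] = set()
    for g in first:
        second |= net.neighbors(g)
    second -= seeds | first
    return ExpansionResult(frozenset(seeds), frozenset(first), frozenset(second))


def random_control_set(
    net: Network,
    n: int,
    exclude: set[GeneId] | None = None,
    seed: int | np.random.Generator = 0,
) -> set[GeneId]:
    """Uniform random control genes from the network, minus exclusions."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pool = sorted(net.nodes - (exclude or set()))
    if n > len(pool):
        raise ValueError(f"requested {n} genes but only {len(pool)} available")
    chosen = rng.choice(len(pool), size=n, replace=False)
    return {pool[i] for i in chosen}


def modifier_rate(lines: Sequence[RnaiLine]) -> float:
    """Fraction of RNAi lines scored as phenotype modifiers."""
    if not lines:
        raise ZeroDivisionError("modifier rate undefined for an empty line table")
    return sum(1 for ln in lines if ln.modifier) / len(lines)


def subsample_one_line_per_gene(
    lines: Sequence[RnaiLine],
    n_repeats: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[list[float], float]:
    """Repeatedly pick one line per gene and compute per-repeat modifier rates.

    Equalizes per-gene line coverage before comparing against a control
    set screened with one line per gene.  Returns the per-repeat rates
    and their mean.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    by_gene: dict[GeneId, list[RnaiLine]] = {}
    for ln in lines:
        by_gene.setdefault(ln.gene, []).append(ln)
    genes = sorted(by_gene)
    if not genes:
        raise ZeroDivisionError("no genes in the line table")
    rates: list[float] = []
    for _ in range(n_repeats):
        picked = [
            by_gene[g][int(rng.integers(len(by_gene[g])))] for g in genes
        ]
        rates.append(modifier_rate(picked))
    return rates, float(np.mean(rates))


def build_regulator_network(
    net: Network,
    confirmed_genes: set[GeneId],
    coip_confirmed: set[Pair] | None = None,
) -> Network:
    """Induced subnetwork on confirmed genes, edges tiered by evidence.

    Every screen edge between confirmed genes is tagged ``screen``; edges
    additionally confirmed by co-immunoprecipitation get a ``screen+coip``
    tag.  A co-IP pair absent from the screen network is recorded as
    ``coip_only`` (with a warning) so orthogonal-only evidence is not
    silently lost.
    """
    import warnings

    coip = coip_confirmed or set()
    sub = Network()
    for g in confirmed_genes & net.nodes:
        sub.add_node(g)
    for e in net.edges:
        if e.a in confirmed_genes and e.b in confirmed_genes:
            tier = "screen+coip" if e in coip else "screen"
            sub.add_edge(e, tier)
    for e in coip:
        if e not in net.edges and e.a in confirmed_genes and e.b in confirmed_genes:
            warnings.warn(f"co-IP pair {e} not present in the screen network")
            sub.add_edge(e, "coip_only")
    return sub


def load_seed_list(path: str) -> set[GeneId]:
    """Read a seed list: one gene id per line, '#' comments allowed."""
    seeds: set[GeneId] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                seeds.add(line)
    return seeds


def load_rnai_tsv(path: str) -> list[RnaiLine]:
    """Read an RNAi line table ``gene line_id modifier set_label`` (header)."""
    out: list[RnaiLine] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene":
            raise ValueError("RNAi table must start with a 'gene' header row")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, line_id, modifier, label = line.split("\t")[:4]
            out.append(
                RnaiLine(gene, line_id, modifier.lower() in ("1", "true", "yes"), label)
            )
    return out
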