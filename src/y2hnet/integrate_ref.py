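"""Literature-evidence classification and reference-network assembly.

A binary reference interactome is assembled from three sources: the new
screen positives, legacy high-throughput pairs filtered to a confidence
cutoff shown (by orthogonal validation) to be of equivalent quality, and
literature pairs with *multiple* lines of binary evidence (Lit-BM).  A
literature pair counts as Lit-BM when a direct-interaction detection
method supports it in at least two publications, or at least two distinct
direct methods support it; a single line of direct evidence makes it
Lit-BS (binary-single).  Method ids are classified direct/indirect via a
user-supplied lookup in the molecular-interaction (MI) vocabulary style.

The module also provides dataset-overlap statistics: a Fisher exact test
on a 2x2 table over an explicit *search space* (unordered bait x prey
combinations, corrected by appending detected pairs that fall outside
the grid), and interolog mapping of pairs into another species' network
through a possibly many-to-many ortholog table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .netcore import GeneId, Network, Pair

__all__ = [
    "EvidenceRecord",
    "ScoredLegacyPair",
    "SearchSpace",
    "classify_literature",
    "filter_legacy_by_score",
    "build_reference",
    "overlap_fisher",
    "map_pairs_via_orthology",
]


@dataclass(frozen=True)
class EvidenceRecord:
    pair: Pair
    publication: str
    method: str
    method_class: str  # binary_direct | indirect


@dataclass(frozen=True)
class ScoredLegacyPair:
    pair: Pair
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class SearchSpace:
    """Unordered bait x prey combination space, plus out-of-grid extras."""

    baits: set[GeneId]
    preys: set[GeneId]
    extra_pairs: set[Pair] = field(default_factory=set)

    def pairs(self) -> set[Pair]:
        grid = {
            Pair(b, p)
            for b in self.baits
            for p in self.preys
        }
        return grid | self.extra_pairs

    def size(self) -> int:
        return len(self.pairs())

    def __contains__(self, pair: Pair) -> bool:
        a_in = pair.a in self.baits and pair.b in self.preys
        b_in = pair.b in self.baits and pair.a in self.preys
        return a_in or b_in or pair in self.extra_pairs


def classify_evidence_records(
    rows: Iterable[tuple[str, str, str, str, str]],
    method_classes: Mapping[str, str] | None = None,
) -> list[EvidenceRecord]:
    """Build evidence records from (gene_a, gene_b, pub, method, class) rows.

    When ``method_classes`` is given, the class column is ignored and the
    lookup decides; unknown method ids are skipped with a warning.
    """
    out = []
    for a, b, pub, method, mclass in rows:
        if method_classes is not None:
            if method not in method_classes:
                warnings.warn(f"unknown method id {method!r}: record skipped")
                continue
            mclass = method_classes[method]
        out.append(EvidenceRecord(Pair(a, b), pub, method, mclass))
    return out


def classify_literature(
    evidence: Iterable[EvidenceRecord],
) -> dict[Pair, str]:
    """Classify each literature pair as Lit-BM, Lit-BS, or none.

    Lit-BM: direct binary evidence in >=2 distinct publications, or by
    >=2 distinct direct methods.  Lit-BS: exactly one distinct
    (publication, method) line of direct evidence.  none: no direct
    evidence at all.  Duplicate evidence lines (same pair, publication
    and method) do not add support.
    """
    direct: dict[Pair, set[tuple[str, str]]] = {}
    seen: set[Pair] = set()
    for rec in evidence:
        seen.add(rec.pair)
        if rec.method_class == "binary_direct":
            direct.setdefault(rec.pair, set()).add((rec.publication, rec.method))
    result: dict[Pair, str] = {}
    for pair in seen:
        lines = direct.get(pair, set())
        if not lines:
            result[pair] = "none"
            continue
        pubs = {pub for pub, _ in lines}
        methods = {m for _, m in lines}
        if len(pubs) >= 2 or len(methods) >= 2:
            result[pair] = "Lit-BM"
        else:
            result[pair] = "Lit-BS"
    return result


def filter_legacy_by_score(
    pairs: Iterable[ScoredLegacyPair],
    cutoff: float,
) -> set[Pair]:
    """Legacy pairs at or above the confidence cutoff, deduplicated."""
    return {sp.pair for sp in pairs if sp.confidence >= cutoff}


def build_reference(
    screen: set[Pair],
    legacy_filtered: set[Pair],
    litbm: set[Pair],
    source_names: tuple[str, str, str] = ("screen", "legacy", "lit-bm"),
) -> Network:
    """Union of the three inputs with per-edge source provenance tags."""
    net = Network()
    for pairs, name in zip((screen, legacy_filtered, litbm), source_names):
        for p in pairs:
            net.add_edge(p, name)
    return net


def overlap_fisher(
    setA: set[Pair],
    setB: set[Pair],
    space: SearchSpace | set[Pair],
) -> tuple[list[list[int]], float, float]:
    """Fisher exact test of overlap between two pair sets in a search space.

    Both sets are restricted to the space before tabulation.  Returns
    the 2x2 table [[both, A-only], [B-only, neither]], the odds ratio
    (both * neither) / (A-only * B-only), and the two-sided p-value from
    the hypergeometric distribution.  A zero margin makes the sample
    odds ratio degenerate (inf or nan); the p-value is still defined.
    """
    space_pairs = space.pairs() if isinstance(space, SearchSpace) else set(space)
    A = setA & space_pairs
    B = setB & space_pairs
    both = len(A & B)
    a_only = len(A - B)
    b_only = len(B - A)
    neither = len(space_pairs) - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    res = stats.fisher_exact(table, alternative="two-sided")
    if a_only == 0 or b_only == 0 or both == 0 or neither == 0:
        warnings.warn("zero margin in overlap table: odds ratio is degenerate")
    odds = (both * neither) / (a_only * b_only) if a_only and b_only else float("inf")
    return table, odds, float(res.pvalue)


def map_pairs_via_orthology(
    pairs: set[Pair],
    ortholog_map: Mapping[GeneId, Sequence[GeneId]],
    target_pairs: set[Pair],
) -> tuple[int, int]:
    """Interolog counting through a many-to-many ortholog table.

    A pair is *mappable* when each endpoint has at least one ortholog
    among the target network's nodes; it is *overlapping* when any
    combination of the endpoints' orthologs is a target edge (counted
    once per source pair, however many combinations hit).
    """
    target_nodes: set[GeneId] = set()
    for p in target_pairs:
        target_nodes.add(p.a)
        target_nodes.add(p.b)
    mappable = 0
    overlapping = 0
    for p in pairs:
        orth_a = [g for g in ortholog_map.get(p.a, ()) if g in target_nodes]
        orth_b = [g for g in ortholog_map.get(p.b, ()) if g in target_nodes]
        if not orth_a or not orth_b:
            continue
        mappable += 1
        if any(
            Pair(x, y) in target_pairs
            for x, y in itertools.product(orth_a, orth_b)
        ):
            overlapping += 1
    return mappable, overlapping


def load_legacy_tsv(path: str) -> list[ScoredLegacyPair]:
    """Read a legacy pair table ``gene_a gene_b confidence`` (header row)."""
    out: list[ScoredLegacyPair] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError("legacy table must start with a gene_a header row")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b, conf = line.split("\t")[:3]
            out.append(ScoredLegacyPair(Pair(a, b), float(conf)))
    return out


def load_evidence_tsv(
    path: str,
    method_classes: Mapping[str, str] | None = None,
) -> list[EvidenceRecord]:
    """Read ``gene_a gene_b pub_id method_id method_class`` evidence TSV."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError("evidence table must start with a gene_a header row")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 4:
                fields.append("")
            rows.append(tuple(fields[:5]))
    return classify_evidence_records(rows, method_classes)
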