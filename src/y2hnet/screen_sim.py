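"""Synthetic screens: ground-truth interactomes and every downstream readout.

The generators in this module produce data with the statistical
structure the pipeline assumes, so each stage — and the pipeline end to
end — is testable against a known ground truth without any download:

* a ground-truth interactome with heavy-tailed degrees and planted
  functional modules, plus an annotation bundle (GO-like terms,
  publications, organelles, a gene x cell-type expression matrix) whose
  structure follows the modules so enrichment is recoverable;
* pooled-well read counts: each DB bait is mated against prey pools in
  separate wells; a prey's AD reads are Poisson around the signal rate
  when the bait–prey edge is true and detected (Bernoulli per assay
  version), around the background rate otherwise; auto-activator baits
  produce signal-level reads for every prey in the pool;
* pairwise-retest growth observations for candidate pairs, including
  cycloheximide-plate growth for auto-activating baits and AD-null
  control growth;
* orthogonal validation measurement tables whose derived scores are
  log-normal — null pairs and the random reference set share one
  distribution, true pairs a shifted one;
* RNAi modifier outcomes with different per-line hit rates for
  network-derived and random gene sets.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mappit_fdr import ValidationMeasurement
from .netcore import GeneId, Network, Pair
from .seed_expand import RnaiLine
from .swim_calling import RetestObservation

__all__ = [
    "BatchParams",
    "ScreenTruth",
    "AnnotationBundle",
    "simulate_interactome",
    "make_screen_truth",
    "simulate_pooled_screen",
    "simulate_screen_set",
    "simulate_retests",
    "simulate_validation_scores",
    "simulate_rnai_outcomes",
]

# Illustrative distributional defaults for the simulated screens (read
# rates, pseudo-counts, sensitivities, auto-activator fraction).  They
# describe a clean, well-behaved screen rather than any particular real
# campaign; see docs/methods.md.
DEFAULTS = {
    "pool_size": 1000,          # "kilopool" prey pools
    "assay_sensitivity": {"v1": 0.8, "v3": 0.8},
    "replicates_per_version": 2,  # two screens per assay version
    "lam_sig": 50.0,            # mean reads of a detected prey / the bait
    "lam_bg": 0.5,              # mean background reads per prey
    "M": 10.0,                  # AD pseudo-count per batch
    "N": 10.0,                  # DB pseudo-count per batch
    "depth": 1.0,               # total-read scale factor
    "aa_fraction": 0.05,        # fraction of baits that auto-activate
    "aa_prey_rate": 0.1,        # preys reaching signal level in an AA bait's well
    "retest_sensitivity": 0.9,  # per-orientation retest detection
    "retest_false_rate": 0.0005,  # spurious growth for a non-interacting pair
    "mu0": 0.0,                 # log-score location of null / RRS pairs
    "mu1": 1.5,                 # log-score location of true pairs
    "sigma": 0.5,               # log-score scale
    "n_rrs": 216,               # RRS block size per validation batch
    "n_prs": 150,               # PRS (positive-control) block size per batch
    "p_net": 0.5,               # per-line modifier rate, network-derived genes
    "p_rand": 0.25,             # per-line modifier rate, random genes
}


@dataclass(frozen=True)
class BatchParams:
    """Per-sequencing-batch nuisance parameters."""

    M: float = DEFAULTS["M"]
    N: float = DEFAULTS["N"]
    lam_sig: float = DEFAULTS["lam_sig"]
    lam_bg: float = DEFAULTS["lam_bg"]
    depth: float = DEFAULTS["depth"]

    def __post_init__(self) -> None:
        if not (self.lam_sig > self.lam_bg >= 0):
            raise ValueError("need lam_sig > lam_bg >= 0")
        if self.M < 0 or self.N < 0:
            raise ValueError("pseudo-counts must be non-negative")


@dataclass
class AnnotationBundle:
    """Simulated annotation structure tied to the planted modules."""

    gene_sets: dict[str, set[GeneId]]
    gene_pubs: dict[str, set[GeneId]]
    pub_counts: dict[GeneId, int]
    organelle: dict[GeneId, str]
    expr: pd.DataFrame  # gene x cell-type binary membership
    module_of: dict[GeneId, int]


@dataclass
class ScreenTruth:
    """Ground truth and nuisance parameters behind a simulated campaign."""

    truth_net: Network
    autoactivators: set[GeneId]
    assay_sensitivity: dict[str, float]
    pool_assignment: dict[GeneId, int]
    batch_params: dict[str, BatchParams]
    replicates_per_version: int = DEFAULTS["replicates_per_version"]
    # An auto-activating bait grows regardless of prey, so the colonies
    # picked from its well carry an arbitrary subset of the pool; each
    # prey reaches signal-level reads with this probability.
    aa_prey_rate: float = DEFAULTS["aa_prey_rate"]

    def __post_init__(self) -> None:
        for v, s in self.assay_sensitivity.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"sensitivity of {v} outside [0, 1]")

    def batches(self) -> list[str]:
        return sorted(self.batch_params)

    def pools(self) -> dict[int, list[GeneId]]:
        pools: dict[int, list[GeneId]] = {}
        for g, p in self.pool_assignment.items():
            pools.setdefault(p, []).append(g)
        return {p: sorted(m) for p, m in pools.items()}


# ---------------------------------------------------------------------------
# Ground-truth interactome with planted modules
# ---------------------------------------------------------------------------

_ORGANELLES = ("nucleus", "cytosol", "mitochondrion", "ER", "plasma_membrane",
               "golgi", "peroxisome", "lysosome")


def simulate_interactome(
    n_genes: int,
    mean_degree: float = 4.0,
    gamma: float = 2.5,
    module_count: int = 5,
    mixing: float = 0.2,
    seed: int = 0,
) -> tuple[Network, AnnotationBundle]:
    """Heavy-tailed planted-partition ground-truth interactome.

    Edge endpoints are drawn with power-law weights (target degree
    exponent ``gamma``), so degrees are heavy tailed; a fraction
    ``1 - mixing`` of edges is placed within a module.  The annotation
    bundle gives each module one shared term per namespace, assigns
    organelles and expression cell types by module, and generates
    small-scale publications within modules (plus one genome-scale
    publication covering many genes), from which per-gene publication
    counts — Zipf-like by construction — are derived.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    m_target = int(round(n_genes * mean_degree / 2.0))
    if m_target > n_genes * (n_genes - 1) // 2:
        raise ValueError("infeasible mean degree for this gene count")
    if not (0.0 <= mixing <= 1.0):
        raise ValueError("mixing must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]

    module = rng.integers(0, module_count, size=n_genes)
    # Chung-Lu style weights with P(k) ~ k^-gamma  =>  w_i ~ i^(-1/(gamma-1))
    ranks = rng.permutation(n_genes) + 1
    w = ranks.astype(float) ** (-1.0 / (gamma - 1.0))
    w /= w.sum()

    members: dict[int, np.ndarray] = {
        m: np.flatnonzero(module == m) for m in range(module_count)
    }
    mod_weight = np.array(
        [w[members[m]].sum() if len(members[m]) else 0.0 for m in range(module_count)]
    )
    mod_weight = mod_weight / mod_weight.sum()

    edges: set[tuple[int, int]] = set()
    attempts = 0
    max_attempts = 200 * m_target + 1000
    while len(edges) < m_target and attempts < max_attempts:
        attempts += 1
        if rng.random() >= mixing:
            m = int(rng.choice(module_count, p=mod_weight))
            idxs = members[m]
            if len(idxs) < 2:
                continue
            pw = w[idxs] / w[idxs].sum()
            i, j = rng.choice(idxs, size=2, replace=False, p=pw)
        else:
            i, j = rng.choice(n_genes, size=2, replace=False, p=w)
            if module[i] == module[j] and mixing < 1.0:
                continue
        e = (min(i, j), max(i, j))
        edges.add(e)
    net = Network.from_edges(
        (Pair(genes[i], genes[j]) for i, j in edges), source="truth"
    )
    for g in genes:
        net.add_node(g)

    bundle = _annotate(genes, module, module_count, sorted(net.edges), rng)
    return net, bundle


def _annotate(
    genes: list[GeneId],
    module: np.ndarray,
    module_count: int,
    edges: list[Pair],
    rng: np.random.Generator,
) -> AnnotationBundle:
    module_of = {g: int(m) for g, m in zip(genes, module)}
    gene_sets: dict[str, set[GeneId]] = {}
    for ns in ("BP", "CC", "MF", "phenotype", "complex"):
        for m in range(module_count):
            mem = {g for g in genes if module_of[g] == m}
            # each namespace covers a random ~70% slice of the module
            keep = {g for g in mem if rng.random() < 0.7}
            if keep:
                gene_sets[f"{ns}:module{m}"] = keep

    # Publications: small functional papers anchored on true interactions
    # (co-cited genes are co-studied genes), well-studied genes drawing
    # disproportionately many papers, plus one genome-scale survey that
    # exercises the large-publication filter.
    gene_pubs: dict[str, set[GeneId]] = {}
    pub_i = 0
    pop = (rng.permutation(len(genes)) + 1).astype(float) ** -1.0  # Zipf popularity
    pop_of = {g: pop[i] for i, g in enumerate(genes)}
    if edges:
        n_small = min(len(edges), max(10, int(0.6 * len(edges))))
        # papers pile up on popular genes: edge picked ~ endpoint popularity,
        # but each paper studies a distinct interaction
        ew = np.array([pop_of[e.a] + pop_of[e.b] for e in edges])
        ew /= ew.sum()
        for i in rng.choice(len(edges), size=n_small, replace=False, p=ew):
            e = edges[i]
            members_ = {e.a, e.b}
            mod_pool = [
                g for g in genes
                if module_of[g] in (module_of[e.a], module_of[e.b])
                and g not in members_
            ]
            extra = int(rng.integers(0, 4))
            if extra and mod_pool:
                take = rng.choice(len(mod_pool), size=min(extra, len(mod_pool)),
                                  replace=False)
                members_ |= {mod_pool[t] for t in take}
            gene_pubs[f"PUB{pub_i:05d}"] = members_
            pub_i += 1
    big = rng.choice(len(genes), size=len(genes), replace=False)
    gene_pubs[f"PUB{pub_i:05d}"] = {genes[i] for i in big}  # genome-scale survey

    pub_counts = {g: 0 for g in genes}
    for members_ in gene_pubs.values():
        for g in members_:
            pub_counts[g] += 1

    organelle = {
        g: _ORGANELLES[module_of[g] % len(_ORGANELLES)] for g in genes
    }

    n_celltypes = max(4, module_count)
    expr = np.zeros((len(genes), n_celltypes), dtype=int)
    for i, g in enumerate(genes):
        expr[i, module_of[g] % n_celltypes] = 1
        extra = rng.random(n_celltypes) < 0.1
        expr[i] |= extra.astype(int)
    expr_df = pd.DataFrame(
        expr, index=genes, columns=[f"celltype{c}" for c in range(n_celltypes)]
    )
    return AnnotationBundle(
        gene_sets=gene_sets,
        gene_pubs=gene_pubs,
        pub_counts=pub_counts,
        organelle=organelle,
        expr=expr_df,
        module_of=module_of,
    )


# ---------------------------------------------------------------------------
# Pooled-screen read counts
# ---------------------------------------------------------------------------

def make_screen_truth(
    net: Network,
    pool_size: int = DEFAULTS["pool_size"],
    assay_sensitivity: Mapping[str, float] | None = None,
    aa_fraction: float = DEFAULTS["aa_fraction"],
    replicates_per_version: int = DEFAULTS["replicates_per_version"],
    batch_params: BatchParams | None = None,
    aa_prey_rate: float = DEFAULTS["aa_prey_rate"],
    seed: int = 0,
) -> ScreenTruth:
    """Attach screen nuisance structure (pools, auto-activators, batches)."""
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    sens = dict(assay_sensitivity or DEFAULTS["assay_sensitivity"])
    order = rng.permutation(len(genes))
    pool_assignment = {
        genes[i]: int(pos // pool_size) for pos, i in enumerate(order)
    }
    n_aa = int(round(aa_fraction * len(genes)))
    aa = set(
        genes[i] for i in rng.choice(len(genes), size=n_aa, replace=False)
    ) if n_aa else set()
    bp = batch_params or BatchParams()
    batches = {
        f"{version}_s{r + 1}": bp
        for version in sorted(sens)
        for r in range(replicates_per_version)
    }
    return ScreenTruth(
        truth_net=net,
        autoactivators=aa,
        assay_sensitivity=sens,
        pool_assignment=pool_assignment,
        batch_params=batches,
        replicates_per_version=replicates_per_version,
        aa_prey_rate=aa_prey_rate,
    )


def simulate_pooled_screen(
    truth: ScreenTruth,
    baits: Sequence[GeneId],
    seed: int = 0,
    batches: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long read-count table for one or more screens (batches).

    One well per (bait, prey pool); each well has one AD row per pool
    ORF and one DB row for the bait (single bait per well, so the well
    DB total is the bait's own count).  A prey row is Poisson around the
    batch's signal rate when the bait–prey edge is true and detected by
    that batch's assay version, or when the bait auto-activates;
    otherwise Poisson around the background rate.
    """
    universe = truth.truth_net.nodes
    unknown = [b for b in baits if b not in universe]
    if unknown:
        raise ValueError(f"baits outside the gene universe: {unknown[:5]}")
    rng = np.random.default_rng(seed)
    pools = truth.pools()
    batch_ids = list(batches) if batches is not None else truth.batches()
    edge_set = truth.truth_net.edges

    frames = []
    for batch in batch_ids:
        if batch not in truth.batch_params:
            raise KeyError(f"unknown batch {batch!r}")
        bp = truth.batch_params[batch]
        version = batch.split("_")[0]
        sens = truth.assay_sensitivity.get(version, 1.0)
        rows_bait, rows_orf, rows_well, rows_plate = [], [], [], []
        rows_role, rows_reads = [], []
        for bait in baits:
            is_aa = bait in truth.autoactivators
            for pool_idx in sorted(pools):
                orfs = pools[pool_idx]
                well = f"{bait}:p{pool_idx}"
                true_edge = np.array(
                    [Pair(bait, o) in edge_set for o in orfs], dtype=bool
                )
                detected = true_edge & (rng.random(len(orfs)) < sens)
                signal = detected
                if is_aa:
                    # colonies picked from an auto-activator well carry a
                    # random subset of the pool at signal-level reads
                    signal = signal | (rng.random(len(orfs)) < truth.aa_prey_rate)
                lam = np.where(signal, bp.lam_sig, bp.lam_bg) * bp.depth
                x = rng.poisson(lam)
                y = int(rng.poisson(bp.lam_sig * bp.depth))
                n = len(orfs)
                rows_bait.extend([bait] * (n + 1))
                rows_orf.extend(orfs + [bait])
                rows_well.extend([well] * (n + 1))
                rows_plate.extend([pool_idx] * (n + 1))
                rows_role.extend(["AD"] * n + ["DB"])
                rows_reads.extend(list(map(int, x)) + [y])
        frames.append(
            pd.DataFrame(
                {
                    "batch": batch,
                    "plate": rows_plate,
                    "well": rows_well,
                    "bait_id": rows_bait,
                    "orf_id": rows_orf,
                    "role": rows_role,
                    "reads": rows_reads,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_screen_set(
    truth: ScreenTruth,
    baits: Sequence[GeneId] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """All configured screens (every assay version and replicate)."""
    if baits is None:
        baits = sorted(truth.truth_net.nodes - truth.autoactivators)
    return simulate_pooled_screen(truth, baits, seed=seed, batches=None)


# ---------------------------------------------------------------------------
# Pairwise retests
# ---------------------------------------------------------------------------

def simulate_retests(
    candidates: Iterable[tuple[GeneId, GeneId]],
    truth: ScreenTruth,
    seed: int = 0,
    retest_sensitivity: float = DEFAULTS["retest_sensitivity"],
    false_rate: float = DEFAULTS["retest_false_rate"],
    unscorable_rate: float = 0.0,
) -> tuple[list[RetestObservation], dict[GeneId, bool]]:
    """Quadruplicate retest observations for oriented candidate pairs.

    True pairs grow strongly on the test plate and not on CHX (missed
    with probability ``1 - retest_sensitivity``); non-pairs grow on
    neither plate except for a small spurious-growth rate; pairs whose
    bait auto-activates grow on both plates, with CHX growth strong
    enough to flag the bait in part of the replicates.  Also returns the
    AD-null control growth map (auto-activating baits grow against the
    empty prey plasmid).
    """
    rng = np.random.default_rng(seed)
    obs: list[RetestObservation] = []

    def quad(mean: float, spread: float = 0.6) -> tuple[int, int, int, int]:
        vals = np.clip(np.round(rng.normal(mean, spread, size=4)), 0, 4)
        return tuple(int(v) for v in vals)

    edge_set = truth.truth_net.edges
    baits_seen: set[GeneId] = set()
    for bait, prey in candidates:
        baits_seen.add(bait)
        pair = Pair(bait, prey)
        scorable = rng.random() >= unscorable_rate
        if bait in truth.autoactivators:
            test = quad(3.5)
            chx = quad(2.5, 0.9)  # strong CHX growth in a large fraction
        elif pair in edge_set:
            if rng.random() < retest_sensitivity:
                test = quad(3.5)
                chx = quad(0.3, 0.4)
            else:
                test = quad(0.3, 0.4)
                chx = quad(0.1, 0.3)
        else:
            if rng.random() < false_rate:
                test = quad(3.0)
                chx = quad(0.3, 0.4)
            else:
                test = quad(0.2, 0.4)
                chx = quad(0.1, 0.3)
        obs.append(
            RetestObservation(
                pair=pair, bait=bait, prey=prey,
                growth_test=test, growth_chx=chx, scorable=scorable,
            )
        )
    adnull = {b: (b in truth.autoactivators) for b in baits_seen}
    return obs, adnull


# ---------------------------------------------------------------------------
# Orthogonal validation measurements
# ---------------------------------------------------------------------------

def simulate_validation_scores(
    pairs: Sequence[Pair],
    truth_net: Network,
    mu0: float = DEFAULTS["mu0"],
    mu1: float = DEFAULTS["mu1"],
    sigma: float = DEFAULTS["sigma"],
    n_rrs: int = DEFAULTS["n_rrs"],
    n_prs: int = DEFAULTS["n_prs"],
    n_batches: int = 1,
    seed: int = 0,
    set_label: str = "screen",
) -> list[ValidationMeasurement]:
    """Validation measurement tables with per-batch RRS and PRS blocks.

    The derived pair score (fold induction over the stronger negative
    control) is log-normal: location ``mu0`` for pairs absent from the
    truth network and for the random reference set, ``mu1`` for true
    pairs and the positive reference set.  ``mu1 <= mu0`` is allowed
    (with a warning) — detection power then collapses to the FDR.
    """
    import warnings

    if mu1 <= mu0:
        warnings.warn("mu1 <= mu0: true pairs are indistinguishable from null")
    rng = np.random.default_rng(seed)
    out: list[ValidationMeasurement] = []
    base = 1000.0  # arbitrary luminescence unit scale

    def measurement(pair: Pair, batch: str, label: str, mu: float) -> ValidationMeasurement:
        score = float(rng.lognormal(mean=mu, sigma=sigma))
        # construct readings so the derived score equals the drawn one:
        # negative controls have fold induction exactly 1
        return ValidationMeasurement(
            pair=pair, batch=batch, set_label=label,
            lum_stim=(base * score, base * score),
            lum_unstim=(base, base),
            nc1_stim=(base, base), nc1_unstim=(base, base),
            nc2_stim=(base, base), nc2_unstim=(base, base),
        )

    per_batch = int(np.ceil(len(pairs) / n_batches)) if pairs else 0
    for b in range(n_batches):
        batch = f"vbatch{b + 1}"
        chunk = list(pairs[b * per_batch:(b + 1) * per_batch])
        for pair in chunk:
            mu = mu1 if pair in truth_net.edges else mu0
            out.append(measurement(pair, batch, set_label, mu))
        for i in range(n_rrs):
            rrs_pair = Pair(f"RRSA{b:02d}{i:04d}", f"RRSB{b:02d}{i:04d}")
            out.append(measurement(rrs_pair, batch, "RRS", mu0))
        for i in range(n_prs):
            prs_pair = Pair(f"PRSA{b:02d}{i:04d}", f"PRSB{b:02d}{i:04d}")
            out.append(measurement(prs_pair, batch, "PRS", mu1))
    return out


# ---------------------------------------------------------------------------
# RNAi outcomes
# ---------------------------------------------------------------------------

def simulate_rnai_outcomes(
    network_genes: set[GeneId],
    random_genes: set[GeneId],
    p_net: float = DEFAULTS["p_net"],
    p_rand: float = DEFAULTS["p_rand"],
    lines_per_gene: tuple[int, int] = (1, 5),
    seed: int = 0,
) -> list[RnaiLine]:
    """Per-line RNAi modifier outcomes for candidate and control genes.

    Network-derived genes get 1..max lines each (candidate sets are
    typically covered by several reagents), random controls one line per
    gene; each line is a modifier with its gene class's rate.
    """
    if network_genes & random_genes:
        raise ValueError("network and random gene sets must be disjoint")
    lo, hi = lines_per_gene
    if not (1 <= lo <= hi):
        raise ValueError("lines_per_gene must be a range within [1, inf)")
    rng = np.random.default_rng(seed)
    out: list[RnaiLine] = []
    for g in sorted(network_genes):
        n_lines = int(rng.integers(lo, hi + 1))
        for i in range(n_lines):
            out.append(
                RnaiLine(g, f"{g}-L{i + 1}", bool(rng.random() < p_net), "autophagy")
            )
    for g in sorted(random_genes):
        out.append(RnaiLine(g, f"{g}-L1", bool(rng.random() < p_rand), "random"))
    return out


def write_read_table(reads: pd.DataFrame, path: str, seed: int | None = None) -> None:
    """Write the long read-count TSV; the seed is recorded in a comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        reads.to_csv(fh, sep="\t", index=False)


def read_read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
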