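"""Pooled-well deconvolution scoring and pairwise-retest classification.

In a pooled yeast two-hybrid screen a single DB bait is mated against a
pool of AD prey ORFs in one well; colonies from the well are sequenced
jointly, so each candidate prey must be deconvolved from read counts.
The SWIM score of a bait–prey combination in a well is the harmonic mean
of the prey's share of AD reads and the bait's share of DB reads,

    S = 2 / ( (a + M)/x + (d + N)/y )

where x and y are the AD-ORF and DB-ORF read counts in the well, a and d
the total aligned AD and DB reads in that well, and M, N pseudo-counts
held constant within a sequencing batch.  S is 0 when either read channel
is empty (a pair absent from either channel cannot be called) and never
exceeds 1 because x <= a and y <= d.

Wells scoring at or above a per-batch cutoff yield first-pass pairs
(FiPPs), which are then retested pairwise in quadruplicate on a test
plate (selects for the interaction) and a cycloheximide plate (selects
against the prey plasmid, exposing bait auto-activation).  Growth is
recorded as ordinal 0-4 scores per replicate and classified by
median-based rules; baits that activate the reporter with an empty
"AD-null" prey are removed from the positive set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .netcore import GeneId, Pair

__all__ = [
    "WellReadSummary",
    "RetestObservation",
    "RetestCall",
    "swim_score",
    "score_wells",
    "call_fipps",
    "remove_autoactivators",
    "classify_retest",
    "remove_denovo_autoactivators",
    "positive_pairs",
    "wells_from_read_table",
]

# Default retest rule parameters (ordinal growth scores 0-4).
DELTA_DEFAULT = 2      # required median growth excess of test over CHX plate
G_MIN_DEFAULT = 2      # minimal median growth on the test plate
C_MAX_DEFAULT = 3      # CHX median at or above this flags an auto-activator
FIPP_QUANTILE_DEFAULT = 0.95  # within-batch score quantile used as cutoff


@dataclass(frozen=True)
class WellReadSummary:
    """Read-count tuple for one bait–prey candidate in one well."""

    x: int          # AD-ORF reads in well
    y: int          # DB-ORF reads in well
    a: int          # total aligned AD reads in well (>= x)
    d: int          # total aligned DB reads in well (>= y)
    M: float = 0.0  # AD pseudo-count, constant per sequencing batch
    N: float = 0.0  # DB pseudo-count, constant per sequencing batch
    batch: str = "batch0"
    well: str = "well0"
    bait: GeneId = ""
    prey: GeneId = ""

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("read counts must be non-negative")
        if self.a < self.x or self.d < self.y:
            raise ValueError("well totals cannot be smaller than member counts")
        if self.M < 0 or self.N < 0:
            raise ValueError("pseudo-counts must be non-negative")


def swim_score(w: WellReadSummary) -> float:
    """Shared-well interaction-mapping score in [0, 1].

    Harmonic mean of x/(a+M) and y/(d+N); defined as 0 in the limit
    x = 0 or y = 0.
    """
    if w.x == 0 or w.y == 0:
        return 0.0
    return 2.0 / ((w.a + w.M) / w.x + (w.d + w.N) / w.y)


def wells_from_read_table(
    reads: pd.DataFrame,
    pseudo_counts: Mapping[str, tuple[float, float]] | tuple[float, float] = (10.0, 10.0),
) -> list[WellReadSummary]:
    """Assemble per-candidate well summaries from a long read-count table.

    ``reads`` has columns ``batch plate well bait_id orf_id role reads``
    with one AD row per pool ORF and one DB row per well (single bait per
    well, so the well's DB total d equals the bait's own read count y).
    ``pseudo_counts`` maps batch -> (M, N), or is one (M, N) for all
    batches.
    """
    required = {"batch", "well", "bait_id", "orf_id", "role", "reads"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")

    def mn(batch: str) -> tuple[float, float]:
        if isinstance(pseudo_counts, Mapping):
            if batch not in pseudo_counts:
                raise KeyError(f"no pseudo-counts configured for batch {batch!r}")
            return pseudo_counts[batch]
        return pseudo_counts

    out: list[WellReadSummary] = []
    for (batch, well), grp in reads.groupby(["batch", "well"], sort=True):
        ad = grp[grp["role"] == "AD"]
        db = grp[grp["role"] == "DB"]
        a = int(ad["reads"].sum())
        d = int(db["reads"].sum())
        bait = str(grp["bait_id"].iloc[0])
        M, N = mn(str(batch))
        y = d  # single DB per well: the bait's count is the DB total
        for _, row in ad.iterrows():
            out.append(
                WellReadSummary(
                    x=int(row["reads"]), y=y, a=a, d=d, M=M, N=N,
                    batch=str(batch), well=str(well),
                    bait=bait, prey=str(row["orf_id"]),
                )
            )
    return out


def score_wells(wells: Iterable[WellReadSummary]) -> pd.DataFrame:
    """Score every well summary; returns a tidy frame with a swim_score column."""
    rows = [
        {
            "batch": w.batch, "well": w.well, "bait": w.bait, "prey": w.prey,
            "x": w.x, "y": w.y, "a": w.a, "d": w.d,
            "swim_score": swim_score(w),
        }
        for w in wells
    ]
    return pd.DataFrame(
        rows,
        columns=["batch", "well", "bait", "prey", "x", "y", "a", "d", "swim_score"],
    )


def call_fipps(
    scored_wells: pd.DataFrame,
    cutoff: float | Mapping[str, float] | None = None,
    quantile: float = FIPP_QUANTILE_DEFAULT,
) -> list[tuple[GeneId, GeneId]]:
    """Select first-pass pairs: wells with S >= the per-batch cutoff.

    ``cutoff`` may be a single number, a batch -> cutoff map, or None, in
    which case each batch's cutoff is the given quantile of its own
    *positive* score distribution (screen cutoffs varied by batch and are
    calibrated from the data at hand).  The result is deduplicated per
    (bait, prey) across wells and batches, sorted for determinism.
    """
    fipps: set[tuple[GeneId, GeneId]] = set()
    for batch, grp in scored_wells.groupby("batch", sort=True):
        if cutoff is None:
            pos = grp.loc[grp["swim_score"] > 0, "swim_score"]
            c = float(pos.quantile(quantile)) if len(pos) else math.inf
        elif isinstance(cutoff, Mapping):
            if batch not in cutoff:
                raise KeyError(f"no cutoff configured for batch {batch!r}")
            c = float(cutoff[batch])
        else:
            c = float(cutoff)
        hits = grp[grp["swim_score"] >= c]
        if c <= 0:  # score 0 means an empty read channel: never callable
            hits = hits[hits["swim_score"] > 0]
        fipps.update(zip(hits["bait"], hits["prey"]))
    return sorted(fipps)


def remove_autoactivators(
    db_orfs: Sequence[GeneId],
    growth_without_AD: Mapping[GeneId, bool],
) -> list[GeneId]:
    """Drop DB baits that grow on selective media with no AD prey present."""
    return [g for g in db_orfs if not growth_without_AD.get(g, False)]


@dataclass(frozen=True)
class RetestObservation:
    """Quadruplicate pairwise-retest growth readings for one orientation."""

    pair: Pair
    bait: GeneId
    prey: GeneId
    growth_test: tuple[int, int, int, int]   # SC-Leu-Trp-His+3AT, ordinal 0-4
    growth_chx: tuple[int, int, int, int]    # SC-Leu-His+3AT+CHX, ordinal 0-4
    scorable: bool = True

    def __post_init__(self) -> None:
        for reps in (self.growth_test, self.growth_chx):
            if len(reps) != 4:
                raise ValueError("retest growth must be quadruplicate")
            if any(not (0 <= r <= 4) for r in reps):
                raise ValueError("growth scores are ordinal 0-4")


@dataclass(frozen=True)
class RetestCall:
    pair: Pair
    bait: GeneId
    prey: GeneId
    call: str  # positive | negative | autoactivator_undetermined | NA


def classify_retest(
    obs: RetestObservation,
    delta: int = DELTA_DEFAULT,
    g_min: int = G_MIN_DEFAULT,
    c_max: int = C_MAX_DEFAULT,
) -> RetestCall:
    """Classify one pairwise retest by median replicate growth.

    Unscorable wells are NA.  Strong growth on the CHX plate (median >=
    ``c_max``) marks the bait as auto-activating and the pair as
    undetermined.  A pair is positive only with clearly more growth on
    the test plate than on CHX (median difference >= ``delta``) and real
    test-plate growth (median >= ``g_min``); anything else, including no
    growth on either plate, is negative.
    """
    if not obs.scorable:
        return RetestCall(obs.pair, obs.bait, obs.prey, "NA")
    m_test = median(obs.growth_test)
    m_chx = median(obs.growth_chx)
    if m_chx >= c_max:
        return RetestCall(obs.pair, obs.bait, obs.prey, "autoactivator_undetermined")
    if m_test - m_chx >= delta and m_test >= g_min:
        return RetestCall(obs.pair, obs.bait, obs.prey, "positive")
    return RetestCall(obs.pair, obs.bait, obs.prey, "negative")


def remove_denovo_autoactivators(
    calls: Iterable[RetestCall],
    adnull_growth: Mapping[GeneId, bool],
) -> list[RetestCall]:
    """Drop positive calls whose bait grows when mated against AD-null prey."""
    out: list[RetestCall] = []
    for c in calls:
        if c.call == "positive" and adnull_growth.get(c.bait, False):
            continue
        out.append(c)
    return out


def positive_pairs(calls: Iterable[RetestCall]) -> set[Pair]:
    """Orientation-union positives: a pair positive in either orientation."""
    return {c.pair for c in calls if c.call == "positive"}


def calls_by_pair(calls: Iterable[RetestCall]) -> dict[Pair, str]:
    """Collapse orientation-level calls to one call per pair.

    Positive in any orientation wins; otherwise negative beats
    undetermined beats NA (a pair is undetermined only if no orientation
    produced a definite answer).
    """
    rank = {"positive": 3, "negative": 2, "autoactivator_undetermined": 1, "NA": 0}
    best: dict[Pair, str] = {}
    for c in calls:
        if c.pair not in best or rank[c.call] > rank[best[c.pair]]:
            best[c.pair] = c.call
    return best


def load_retest_tsv(path: str) -> list[RetestObservation]:
    """Read a retest table ``pair_id bait prey test_r1..r4 chx_r1..r4 scorable``."""
    obs: list[RetestObservation] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "pair_id":
            raise ValueError("retest table must start with a pair_id header row")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            bait, prey = f[1], f[2]
            test = tuple(int(v) for v in f[3:7])
            chx = tuple(int(v) for v in f[7:11])
            scorable = f[11].lower() in ("1", "true", "yes") if len(f) > 11 else True
            obs.append(
                RetestObservation(
                    pair=Pair(bait, prey), bait=bait, prey=prey,
                    growth_test=test, growth_chx=chx, scorable=scorable,
                )
            )
    return obs


def swim_score_triplet(x: int, a: int, M: float, y: int, d: int, N: float) -> float:
    """Convenience scalar form of :func:`swim_score`."""
    return swim_score(WellReadSummary(x=x, y=y, a=a, d=d, M=M, N=N))


def random_valid_wells(n: int, rng: np.random.Generator) -> list[WellReadSummary]:
    """Random valid read tuples, used by property tests of the score."""
    out = []
    for _ in range(n):
        a = int(rng.integers(1, 10_000))
        d = int(rng.integers(1, 10_000))
        x = int(rng.integers(0, a + 1))
        y = int(rng.integers(0, d + 1))
        M = float(rng.uniform(0, 50))
        N = float(rng.uniform(0, 50))
        out.append(WellReadSummary(x=x, y=y, a=a, d=d, M=M, N=N))
    return out
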