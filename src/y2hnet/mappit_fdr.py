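"""Orthogonal validation scoring with empirical per-batch FDR thresholds.

Candidate interactions from a primary screen are re-tested in an
independent assay (a two-hybrid-orthogonal, mammalian-cell luciferase
readout): for each pair, replicate luminescence is read in stimulated
and unstimulated wells, together with two negative controls (bait alone
and prey alone).  The quantities derived are

* fold induction  FI = mean(stimulated) / mean(unstimulated),
* pair score      s  = FI_pair / max(FI_nc1, FI_nc2),

and a pair is called positive when its score exceeds the 99th empirical
percentile of the scores of a random reference set (RRS — random pairs
presumed non-interacting) run in the same batch, i.e. an empirical 1%
false-discovery threshold.  Pairs without a valid quantitative score
(cloning failure, no detectable bait expression) are dropped before any
rate is computed.  Recovery rate of a set is P / (P + N) with a standard
error of the proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .netcore import Pair

__all__ = [
    "ValidationMeasurement",
    "ValidationCall",
    "fold_induction",
    "mappit_score",
    "batch_threshold",
    "call_pairs",
    "recovery_rate",
    "score_measurements",
    "validate_batches",
]

RRS_MIN_DEFAULT = 20  # minimal RRS block size for a usable batch threshold


@dataclass(frozen=True)
class ValidationMeasurement:
    """One validated pair in one batch, with its two negative controls."""

    pair: Pair
    batch: str
    set_label: str  # screen | Lit-BM | Lit-BS | RRS | PRS | legacy-high | legacy-low | other
    lum_stim: tuple[float, ...]
    lum_unstim: tuple[float, ...]
    nc1_stim: tuple[float, ...]
    nc1_unstim: tuple[float, ...]
    nc2_stim: tuple[float, ...]
    nc2_unstim: tuple[float, ...]
    bait_expressed: bool = True
    cloned_ok: bool = True

    def __post_init__(self) -> None:
        if not self.batch:
            raise ValueError("batch id must be non-empty")
        for reads in (self.lum_stim, self.lum_unstim, self.nc1_stim,
                      self.nc1_unstim, self.nc2_stim, self.nc2_unstim):
            if len(reads) < 1:
                raise ValueError("at least one replicate reading required")


@dataclass(frozen=True)
class ValidationCall:
    pair: Pair
    batch: str
    set_label: str
    score: float | None
    call: str  # positive | negative | dropped


def fold_induction(stim: Sequence[float], unstim: Sequence[float]) -> float:
    """Mean stimulated signal over mean unstimulated signal."""
    stim = np.asarray(stim, dtype=float)
    unstim = np.asarray(unstim, dtype=float)
    if np.any(stim <= 0) or np.any(unstim <= 0):
        raise ValueError("luminescence readings must be positive")
    return float(stim.mean() / unstim.mean())


def mappit_score(m: ValidationMeasurement) -> float | None:
    """Pair fold induction normalized by the stronger negative control.

    None (missing) when the pair has no valid quantitative readout,
    i.e. cloning failed or bait expression was not detected.
    """
    if not (m.cloned_ok and m.bait_expressed):
        return None
    fi_pair = fold_induction(m.lum_stim, m.lum_unstim)
    fi_nc1 = fold_induction(m.nc1_stim, m.nc1_unstim)
    fi_nc2 = fold_induction(m.nc2_stim, m.nc2_unstim)
    return fi_pair / max(fi_nc1, fi_nc2)


def batch_threshold(
    rrs_scores: Sequence[float],
    q: float = 99.0,
    min_rrs: int = RRS_MIN_DEFAULT,
    method: str = "linear",
) -> float:
    """Empirical percentile of a batch's random-reference scores.

    Linear interpolation between order statistics (the default of the
    standard Python quantile routine); a batch with fewer than
    ``min_rrs`` scores cannot support an empirical threshold.
    """
    scores = np.asarray(rrs_scores, dtype=float)
    if scores.size < min_rrs:
        raise ValueError(
            f"batch has {scores.size} RRS scores; need >= {min_rrs} for a threshold"
        )
    return float(np.percentile(scores, q, method=method))


def score_measurements(
    measurements: Iterable[ValidationMeasurement],
) -> list[ValidationCall]:
    """Score every measurement; calls are provisional ('dropped' or unset)."""
    out = []
    for m in measurements:
        s = mappit_score(m)
        call = "dropped" if s is None else ""
        out.append(ValidationCall(m.pair, m.batch, m.set_label, s, call))
    return out


def call_pairs(
    scores: Iterable[ValidationCall],
    thresholds: Mapping[str, float],
) -> list[ValidationCall]:
    """Threshold scored pairs per batch: positive iff score > threshold.

    A score exactly at the threshold is negative (ties conservative).
    Pairs in a batch with no usable threshold are dropped.
    """
    out: list[ValidationCall] = []
    for s in scores:
        if s.score is None:
            out.append(ValidationCall(s.pair, s.batch, s.set_label, None, "dropped"))
            continue
        if s.batch not in thresholds:
            out.append(ValidationCall(s.pair, s.batch, s.set_label, s.score, "dropped"))
            continue
        call = "positive" if s.score > thresholds[s.batch] else "negative"
        out.append(ValidationCall(s.pair, s.batch, s.set_label, s.score, call))
    return out


def recovery_rate(calls: Iterable[ValidationCall]) -> tuple[float, float, int]:
    """Positive fraction with its standard error of the proportion.

    rate = P / (P + N), se = sqrt(rate (1 - rate) / (P + N)); dropped
    pairs are excluded from both numerator and denominator.
    """
    p = sum(1 for c in calls if c.call == "positive")
    n = sum(1 for c in calls if c.call == "negative")
    total = p + n
    if total == 0:
        raise ZeroDivisionError("no scorable pairs: recovery rate undefined")
    rate = p / total
    se = float(np.sqrt(rate * (1.0 - rate) / total))
    return rate, se, total


def validate_batches(
    measurements: Iterable[ValidationMeasurement],
    q: float = 99.0,
    min_rrs: int = RRS_MIN_DEFAULT,
) -> tuple[list[ValidationCall], dict[str, float]]:
    """Full per-batch validation: score, threshold on RRS, call.

    Returns the calls and the per-batch thresholds.  Batches whose RRS
    block is too small get no threshold and their pairs are dropped.
    """
    scored = score_measurements(list(measurements))
    thresholds: dict[str, float] = {}
    by_batch: dict[str, list[float]] = {}
    for s in scored:
        if s.set_label == "RRS" and s.score is not None:
            by_batch.setdefault(s.batch, []).append(s.score)
    for batch, rrs in sorted(by_batch.items()):
        try:
            thresholds[batch] = batch_threshold(rrs, q=q, min_rrs=min_rrs)
        except ValueError:
            pass  # flagged by absence: pairs of this batch are dropped
    return call_pairs(scored, thresholds), thresholds


def recovery_report(calls: Iterable[ValidationCall]) -> pd.DataFrame:
    """Per-set recovery rates (rate, se, n) over all batches combined."""
    calls = list(calls)
    rows = []
    for label in sorted({c.set_label for c in calls}):
        sub = [c for c in calls if c.set_label == label]
        try:
            rate, se, n = recovery_rate(sub)
        except ZeroDivisionError:
            rate, se, n = float("nan"), float("nan"), 0
        rows.append({"set_label": label, "rate": rate, "se": se, "n": n})
    return pd.DataFrame(rows, columns=["set_label", "rate", "se", "n"])
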