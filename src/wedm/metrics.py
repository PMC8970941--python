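"""Normalized error-distance scoring of detections against segments.

Each scoring segment holds one target change point (tCP).  A detection
(eCP) inside the segment is scored by its *normalized error distance*
(NED): the gap to the target divided by the distance from the target to
the segment boundary on the detection's side, so NED is in ``[0, 1]``
regardless of segment length or target placement.  The signed variant
keeps the side: negative when the eCP falls before the target (the
positive-error / NpED side), positive after it (NnED side).

Per-segment outcomes are classified hit / error / miss against a hit
radius ``hd`` around the target, and aggregate into:

* the mean weighted error distance MWED — the mean per-segment
  contribution with hit -> 0, error -> NED, miss -> 1;
* its complement MWTD = 1 - MWED;
* hit / miss / error rates and a redundant-detection count;
* frequency and weighted-error-distance (WED) distributions of the
  signed NED values over ``[-1, 1]``, where each bin's WED mass is its
  frequency times the magnitude of its NED representative.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "ScoredSegment",
    "DistributionBin",
    "EvaluationSummary",
    "compute_ned",
    "default_hit_threshold",
    "classify_segment",
    "frequency_distribution",
    "wed_distribution",
    "mwed",
    "mwtd",
    "rates",
    "normalized_times",
    "bins_to_frame",
    "scored_to_frame",
]

State = Literal["hit", "error", "miss"]
DenominatorMode = Literal["scored_events", "total_ecps"]


@dataclass(frozen=True)
class ScoredSegment:
    """Outcome of scoring one segment.

    ``ned`` equals the scoring contribution: 0 for a hit, the normalized
    error distance for an error, 1 for a miss.  ``signed_ned`` carries
    the side of the detection (misses sit at +1, hits at 0).
    """

    segment: Segment
    ecp: int | None
    state: State
    ned: float
    signed_ned: float

    @property
    def contribution(self) -> float:
        """Per-segment MWED contribution (hit -> 0, error -> NED, miss -> 1)."""
        return self.ned


@dataclass(frozen=True)
class DistributionBin:
    """One bin of the signed-NED axis over ``[-1, 1]``."""

    left: float
    right: float
    count: int
    freq: float
    wed_mass: float = 0.0

    @property
    def center(self) -> float:
        return 0.5 * (self.left + self.right)


@dataclass
class EvaluationSummary:
    """All evaluation indexes for one detector run on one sample."""

    mwed: float
    mwtd: float
    hit_rate: float
    miss_rate: float
    error_rate: float
    n_targets: int
    n_hit: int
    n_miss: int
    n_error: int
    n_redundant: int
    n_ecps: int
    compute_time: float = 0.0  # seconds; informational, hardware-dependent
    nst: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def compute_ned(segment: Segment, ecp: int) -> tuple[float, float]:
    """Normalized error distance of a detection within its segment.

    Returns ``(signed_ned, ned)``.  For a detection at or left of the
    target, ``ned = (tcp - ecp) / (tcp - start)`` and the sign is
    negative; right of the target, ``ned = (ecp - tcp) / (end - tcp)``
    and the sign is positive.  A detection exactly on the target scores
    ``(0, 0)``.

    Raises
    ------
    ValueError
        If ``ecp`` lies outside the segment, or the target coincides
        with a segment boundary (degenerate denominator).
    """
    start, end, tcp = segment.start, segment.end, segment.tcp
    if not (start <= ecp <= end):
        raise ValueError(f"eCP {ecp} not in segment [{start}, {end}]")
    if tcp <= start or tcp >= end:
        raise ValueError(
            f"degenerate segment: target {tcp} on boundary of [{start}, {end}]"
        )
    if ecp <= tcp:
        ned = (tcp - ecp) / (tcp - start)
        return -ned if ned else 0.0, ned
    ned = (ecp - tcp) / (end - tcp)
    return ned, ned


def default_hit_threshold(segment: Segment, rel: float = 0.005) -> int:
    """Hit radius as a fraction of segment length, at least one sample.

    The hit radius is not dimensioned by the framework itself, so the
    default scales with the segment: ``max(1, round(rel * len))``.
    """
    return max(1, round(rel * len(segment)))


def classify_segment(
    segment: Segment,
    ecps: Sequence[int],
    hd: int,
) -> tuple[ScoredSegment, int]:
    """Classify one segment given the detections that fell inside it.

    The detection nearest the target scores the segment (ties break to
    the smaller position); any remaining detections are redundant.
    Within the hit radius ``hd`` the segment is a hit and contributes 0;
    otherwise it is an error contributing its NED.  An empty detection
    list is a miss contributing 1 (placed at signed NED +1).

    Returns
    -------
    (scored, n_redundant)
    """
    if hd < 0:
        raise ValueError(f"hit radius must be non-negative, got {hd}")
    if not len(ecps):
        return ScoredSegment(segment, None, "miss", 1.0, 1.0), 0
    pos = np.sort(np.asarray(ecps, dtype=np.int64))
    if pos[0] < segment.start or pos[-1] > segment.end:
        raise ValueError(
            f"eCPs {pos.tolist()} not all inside segment "
            f"[{segment.start}, {segment.end}]"
        )
    # nearest to target; np.argmin takes the first (smaller position) on ties
    scoring = int(pos[np.argmin(np.abs(pos - segment.tcp))])
    n_redundant = len(pos) - 1
    if abs(scoring - segment.tcp) <= hd:
        return ScoredSegment(segment, scoring, "hit", 0.0, 0.0), n_redundant
    signed, ned = compute_ned(segment, scoring)
    return ScoredSegment(segment, scoring, "error", ned, signed), n_redundant


def frequency_distribution(
    scored: Sequence[ScoredSegment],
    n_bins: int = 201,
) -> list[DistributionBin]:
    """Bin the signed NED values of scored segments over ``[-1, 1]``.

    Hits contribute at 0, misses at +1, errors at their signed NED.
    The default odd bin count centres one bin exactly at 0 so hits carry
    no WED mass.  Frequencies sum to 1.
    """
    if not len(scored):
        raise ValueError("no scored segments to bin")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    values = np.array([s.signed_ned for s in scored], dtype=float)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    freqs = counts / counts.sum()
    bins = [
        DistributionBin(float(edges[i]), float(edges[i + 1]), int(counts[i]),
                        float(freqs[i]))
        for i in range(n_bins)
    ]
    return wed_distribution(bins)


def wed_distribution(bins: Iterable[DistributionBin]) -> list[DistributionBin]:
    """Attach WED mass to each bin: frequency times |bin centre|.

    Mass on the negative half-axis realizes the weighted positive-error
    distance (WpED), on the positive half the weighted negative-error
    distance (WnED).  Over fine bins the total mass converges to the
    mean |signed NED|.
    """
    return [
        DistributionBin(b.left, b.right, b.count, b.freq,
                        b.freq * abs(b.center))
        for b in bins
    ]


def mwed(scored: Sequence[ScoredSegment]) -> float:
    """Mean weighted error distance over all scored segments.

    The mean per-segment contribution: hits 0, errors their NED, misses
    1.  Lies in ``[0, 1]``; 0 iff every target is hit.
    """
    if not len(scored):
        raise ValueError("no scored segments")
    contrib = {"hit": 0.0, "miss": 1.0}
    return float(
        np.mean([contrib.get(s.state, s.ned) for s in scored])
    )


def mwtd(mwed_value: float) -> float:
    """Mean weighted true distance, the complement ``1 - MWED``."""
    if not 0.0 <= mwed_value <= 1.0:
        raise ValueError(f"MWED must be in [0, 1], got {mwed_value}")
    return 1.0 - mwed_value


def rates(
    scored: Sequence[ScoredSegment],
    n_redundant: int = 0,
    denominator_mode: DenominatorMode = "scored_events",
) -> tuple[float, float, float]:
    """Hit, miss and error rates of a scored run.

    With the default ``scored_events`` denominator (the number of scored
    segments) the three rates sum to 1 exactly.  The ``total_ecps`` mode
    divides instead by the total number of detections — scoring
    detections (hits and errors) plus redundant ones — in which case the
    rates need not sum to 1.
    """
    if not len(scored):
        raise ValueError("no scored segments")
    states = [s.state for s in scored]
    n_hit = states.count("hit")
    n_miss = states.count("miss")
    n_error = states.count("error")
    if denominator_mode == "scored_events":
        denom = n_hit + n_miss + n_error
    elif denominator_mode == "total_ecps":
        denom = n_hit + n_error + n_redundant
        if denom == 0:
            return 0.0, float(n_miss > 0), 0.0
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    return n_hit / denom, n_miss / denom, n_error / denom


def normalized_times(times: Mapping[str, float]) -> dict[str, float]:
    """Share of total computing time per model (NST); shares sum to 1."""
    vals = np.array(list(times.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("computing times must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("all computing times are zero")
    return {k: float(v / total) for k, v in times.items()}


# ---------------------------------------------------------------------------
# tabular export


def scored_to_frame(scored: Sequence[ScoredSegment]) -> pd.DataFrame:
    """One row per scored segment: start, end, tcp, ecp, state, NEDs."""
    return pd.DataFrame(
        {
            "start": [s.segment.start for s in scored],
            "end": [s.segment.end for s in scored],
            "tcp": [s.segment.tcp for s in scored],
            "ecp": [s.ecp if s.ecp is not None else pd.NA for s in scored],
            "state": [s.state for s in scored],
            "ned": [s.ned for s in scored],
            "signed_ned": [s.signed_ned for s in scored],
        }
    )


def bins_to_frame(bins: Sequence[DistributionBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_left": [b.left for b in bins],
            "bin_right": [b.right for b in bins],
            "count": [b.count for b in bins],
            "freq": [b.freq for b in bins],
            "wed_mass": [b.wed_mass for b in bins],
        }
    )
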