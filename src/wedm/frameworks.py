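"""Detection harnesses: single-window, fixed and random slide windows.

A detector (see :mod:`wedm.detectors`) only ever sees one window.  The
harnesses here sweep a detector over a full multi-change-point series:

* ``fsw`` — fixed slide window of length ``n_fsw``: after a detection
  at global position ``q`` the next window starts at ``q + 1``;
  otherwise the window advances by its own length (configurable
  stride).  A trailing partial window shorter than the detector's
  minimum is skipped and logged.
* ``rsw`` — random slide window: identical advance rule, but each
  window's length is drawn uniformly from ``[l_min, l_max]`` with the
  run's seeded generator, so a run is bit-reproducible given its seed.
  With ``l_min == l_max`` RSW coincides with FSW.
* ``single`` — the detector is applied once to the whole series
  (single-target samples).

``evaluate_run`` closes the loop: it segments the sample by its target
annotation, assigns every detection to the segment containing it,
classifies each segment, and returns the full evaluation summary.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .detectors import BaseDetector
from .metrics import (
    DenominatorMode,
    EvaluationSummary,
    ScoredSegment,
    classify_segment,
    default_hit_threshold,
    mwed,
    mwtd,
    rates,
)
from .segmentation import TimeSeriesSample, segment_series

__all__ = [
    "FrameworkConfig",
    "DetectionRun",
    "run_single",
    "run_fsw",
    "run_rsw",
    "run_framework",
    "score_run",
    "evaluate_run",
]


@dataclass
class FrameworkConfig:
    """How a detector is swept over a series."""

    mode: str = "fsw"  # single | fsw | rsw
    n_fsw: int = 4096
    l_min: int = 64
    l_max: int = 4096
    seed: int = 0
    stride: int | None = None  # non-detection advance; None -> window length
    endpoint_fallback: bool = False  # emit window start on non-detection

    def __post_init__(self) -> None:
        if self.mode not in ("single", "fsw", "rsw"):
            raise ValueError(f"unknown framework mode {self.mode!r}")
        if self.mode == "fsw" and self.n_fsw < 2:
            raise ValueError("n_fsw must be >= 2")
        if self.mode == "rsw" and not 2 <= self.l_min <= self.l_max:
            raise ValueError("need 2 <= l_min <= l_max")


@dataclass
class DetectionRun:
    """Outcome of one detector sweep over one sample."""

    ecps: np.ndarray  # strictly increasing global 1-based positions
    windows: list[dict[str, Any]] = field(default_factory=list)
    compute_time: float = 0.0  # summed per-window seconds
    n_evals: int = 0  # summed statistic evaluations
    detector: str = ""
    config: FrameworkConfig | None = None


def run_single(sample: TimeSeriesSample, detector: BaseDetector) -> DetectionRun:
    """Apply the detector once to a whole single-target series."""
    if sample.n_targets != 1:
        raise ValueError(
            f"single mode requires exactly one target, got {sample.n_targets}"
        )
    t0 = time.perf_counter()
    res = detector.detect(sample.values)
    dt = time.perf_counter() - t0
    ecps = (np.array([res.position], dtype=np.int64)
            if res.position is not None else np.array([], dtype=np.int64))
    log = [{"start": 1, "end": sample.n, "position": res.position,
            "n_evals": res.n_evals}]
    return DetectionRun(ecps, log, dt, res.n_evals, detector.name)


def _sweep(
    sample: TimeSeriesSample,
    detector: BaseDetector,
    next_length,
    config: FrameworkConfig,
) -> DetectionRun:
    """Shared window-advance loop; ``next_length()`` supplies each window."""
    values = sample.values
    n = sample.n
    ecps: list[int] = []
    log: list[dict[str, Any]] = []
    total_time = 0.0
    total_evals = 0
    p = 1
    while p <= n:
        length = next_length()
        end = min(p + length - 1, n)
        if end - p + 1 < detector.min_window:
            log.append({"start": p, "end": end, "skipped": True,
                        "reason": "window shorter than detector minimum"})
            p = end + 1
            continue
        t0 = time.perf_counter()
        res = detector.detect(values[p - 1 : end])
        total_time += time.perf_counter() - t0
        total_evals += res.n_evals
        q = p + res.position - 1 if res.position is not None else None
        log.append({"start": p, "end": end, "position": q,
                    "n_evals": res.n_evals})
        if q is not None:
            ecps.append(q)
            p = q + 1
        elif config.endpoint_fallback:
            ecps.append(p)
            p += length if config.stride is None else config.stride
        else:
            p += length if config.stride is None else config.stride
    return DetectionRun(np.array(ecps, dtype=np.int64), log, total_time,
                        total_evals, detector.name, config)


def run_fsw(
    sample: TimeSeriesSample,
    detector: BaseDetector,
    config: FrameworkConfig,
) -> DetectionRun:
    """Fixed slide window sweep."""
    if config.mode != "fsw":
        raise ValueError(f"config mode is {config.mode!r}, expected 'fsw'")
    if config.n_fsw > sample.n:
        raise ValueError(f"n_fsw={config.n_fsw} exceeds series length {sample.n}")
    return _sweep(sample, detector, lambda: config.n_fsw, config)


def run_rsw(
    sample: TimeSeriesSample,
    detector: BaseDetector,
    config: FrameworkConfig,
) -> DetectionRun:
    """Random slide window sweep; reproducible from ``config.seed``."""
    if config.mode != "rsw":
        raise ValueError(f"config mode is {config.mode!r}, expected 'rsw'")
    if config.l_max > sample.n:
        raise ValueError(f"l_max={config.l_max} exceeds series length {sample.n}")
    rng = np.random.default_rng(config.seed)
    return _sweep(
        sample, detector,
        lambda: int(rng.integers(config.l_min, config.l_max + 1)), config,
    )


def run_framework(
    sample: TimeSeriesSample,
    detector: BaseDetector,
    config: FrameworkConfig,
) -> DetectionRun:
    """Dispatch on ``config.mode``."""
    if config.mode == "single":
        return run_single(sample, detector)
    if config.mode == "fsw":
        return run_fsw(sample, detector, config)
    return run_rsw(sample, detector, config)


def score_run(
    sample: TimeSeriesSample,
    ecps: np.ndarray,
    hd: int | None = None,
    hd_rel: float = 0.005,
) -> tuple[list[ScoredSegment], int]:
    """Segment the sample, assign detections, classify every segment.

    ``hd`` is the absolute hit radius; when ``None`` each segment uses
    the relative default ``max(1, round(hd_rel * len(segment)))``.
    """
    segments = segment_series(sample)
    ends = np.array([s.end for s in segments])
    ecps = np.asarray(ecps, dtype=np.int64)
    owner = np.searchsorted(ends, ecps)  # segment index containing each eCP
    scored: list[ScoredSegment] = []
    n_redundant = 0
    for i, seg in enumerate(segments):
        inside = ecps[owner == i]
        radius = hd if hd is not None else default_hit_threshold(seg, hd_rel)
        s, r = classify_segment(seg, inside.tolist(), radius)
        scored.append(s)
        n_redundant += r
    return scored, n_redundant


def evaluate_run(
    sample: TimeSeriesSample,
    run: DetectionRun,
    hd: int | None = None,
    denominator_mode: DenominatorMode = "scored_events",
    hd_rel: float = 0.005,
) -> EvaluationSummary:
    """Full evaluation of one detection run against its sample."""
    scored, n_redundant = score_run(sample, run.ecps, hd=hd, hd_rel=hd_rel)
    m = mwed(scored)
    hit, miss, err = rates(scored, n_redundant, denominator_mode)
    states = [s.state for s in scored]
    return EvaluationSummary(
        mwed=m,
        mwtd=mwtd(m),
        hit_rate=hit,
        miss_rate=miss,
        error_rate=err,
        n_targets=len(scored),
        n_hit=states.count("hit"),
        n_miss=states.count("miss"),
        n_error=states.count("error"),
        n_redundant=n_redundant,
        n_ecps=int(run.ecps.size),
        compute_time=run.compute_time,
    )
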