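"""Seeded piecewise-Gaussian test-series generators.

Three study protocols are materialized, all built from Gaussian blocks:

* **exp1** — repetitive single-change-point detection: each sample is
  standard normal ``N(0, 1)`` up to the target position ``m`` and
  ``N(V, 1)`` after it, with the mean step ``V`` drawn from
  ``[1.0, 3.7]`` and the length ``N`` a power of two in ``2^10..2^15``;
  20 groups of 100 samples, one ``(N, m, V)`` draw per group.
* **exp2** — multi-change-point series for the random-slide-window
  harness: 15–30 Gaussian segments per sample, segment lengths a power
  of two in ``2^12..2^15``, means from ``[1.0, 0.1 * n_seg]`` and
  variances from ``[1.0, 2.0 * n_seg]``; 10 samples.
* **exp3** — as exp2 but with exactly 30 segments, paired with a
  fixed-slide-window sweep ``n_fsw = 2^6 .. 2^15``.

Consecutive segments are guaranteed to differ in their distribution
parameters (redrawn otherwise) so every annotated boundary is a genuine
abrupt change.  Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .frameworks import FrameworkConfig
from .segmentation import TimeSeriesSample

__all__ = [
    "Exp1Config",
    "ExpMultiConfig",
    "gen_single_cp",
    "gen_multi_cp",
    "make_experiment",
]


@dataclass
class Exp1Config:
    """Single-change-point protocol: groups of identical-parameter samples."""

    n_groups: int = 20
    samples_per_group: int = 100
    n_exp_range: tuple[int, int] = (10, 15)  # N = 2**e, e uniform in range
    v_range: tuple[float, float] = (1.0, 3.7)
    tcp_margin: int = 16  # keep both regimes detector-viable

    def __post_init__(self) -> None:
        if self.n_exp_range[0] > self.n_exp_range[1]:
            raise ValueError("invalid N exponent range")
        if self.v_range[0] > self.v_range[1] or self.v_range[0] <= 0:
            raise ValueError("invalid V range")


@dataclass
class ExpMultiConfig:
    """Multi-change-point protocol: per-segment Gaussian parameter draws.

    ``mean_factor`` and ``var_factor`` scale the upper bounds of the
    per-segment mean and variance ranges with the number of segments:
    means are drawn from ``[1.0, mean_factor * n_segments]`` and
    variances from ``[1.0, var_factor * n_segments]``.
    """

    n_segments_range: tuple[int, int] = (15, 30)
    seg_exp_range: tuple[int, int] = (12, 15)  # segment length = 2**e
    mean_factor: float = 0.1
    var_factor: float = 2.0
    length_mode: Literal["pow2", "uniform"] = "pow2"
    noiseless: bool = False  # constant segments at their means (diagnostics)
    n_samples: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.n_segments_range
        if not 2 <= lo <= hi:
            raise ValueError("need at least 2 segments to place a boundary")
        if self.seg_exp_range[0] > self.seg_exp_range[1]:
            raise ValueError("invalid segment-length exponent range")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)


def gen_single_cp(
    n: int,
    m: int,
    v: float,
    seed: int | np.random.Generator,
) -> TimeSeriesSample:
    """One two-regime Gaussian sample: ``N(0,1)`` then ``N(v,1)``.

    ``m`` (the target change point) is the last sample of the first
    regime; it must lie strictly inside the series.
    """
    if not 1 < m < n:
        raise ValueError(f"target m={m} must lie strictly inside [2, {n - 1}]")
    if v <= 0:
        raise ValueError(f"mean step v must be positive, got {v}")
    rng = _rng(seed)
    values = rng.standard_normal(n)
    values[m:] += v
    return TimeSeriesSample(
        values=values,
        target_cps=np.array([m]),
        provenance={"generator": "gen_single_cp", "n": n, "m": m, "v": v},
    )


def _draw_segment_params(
    rng: np.random.Generator, config: ExpMultiConfig, n_segments: int,
    prev: tuple[float, float] | None,
) -> tuple[float, float, int]:
    """Draw (mean, variance, length); redraw while equal to ``prev``."""
    lo_e, hi_e = config.seg_exp_range
    mean_hi = max(1.0, config.mean_factor * n_segments)
    var_hi = max(1.0, config.var_factor * n_segments)
    # in noiseless mode only the mean is observable, so consecutive
    # segments must differ in mean, not merely in (mean, variance)
    key = (lambda u, v: (u,)) if config.noiseless else (lambda u, v: (u, v))
    for _ in range(1000):
        u = float(rng.uniform(1.0, mean_hi))
        v = float(rng.uniform(1.0, var_hi))
        if prev is None or key(u, v) != key(*prev):
            break
    else:
        raise ValueError(
            "parameter ranges collapse to a point: consecutive segments "
            "cannot differ in distribution (widen mean_factor/var_factor)"
        )
    if config.length_mode == "pow2":
        length = int(2 ** rng.integers(lo_e, hi_e + 1))
    else:
        length = int(rng.integers(2**lo_e, 2**hi_e + 1))
    return u, v, length


def gen_multi_cp(
    config: ExpMultiConfig,
    seed: int | np.random.Generator,
    n_segments: int | None = None,
) -> TimeSeriesSample:
    """One multi-segment Gaussian sample with annotated boundaries.

    The targets are the cumulative segment ends (the last sample of
    each segment except the final one), so ``n_segments - 1`` targets.
    """
    rng = _rng(seed)
    if n_segments is None:
        lo, hi = config.n_segments_range
        n_segments = int(rng.integers(lo, hi + 1))
    params: list[tuple[float, float, int]] = []
    prev: tuple[float, float] | None = None
    for _ in range(n_segments):
        u, v, length = _draw_segment_params(rng, config, n_segments, prev)
        params.append((u, v, length))
        prev = (u, v)
    blocks = []
    for u, v, length in params:
        if config.noiseless:
            blocks.append(np.full(length, u))
        else:
            blocks.append(rng.normal(u, np.sqrt(v), length))
    lengths = np.array([p[2] for p in params], dtype=np.int64)
    return TimeSeriesSample(
        values=np.concatenate(blocks),
        target_cps=np.cumsum(lengths)[:-1],
        provenance={
            "generator": "gen_multi_cp",
            "n_segments": n_segments,
            "segments": [
                {"mean": u, "variance": v, "length": int(length)}
                for u, v, length in params
            ],
            "noiseless": config.noiseless,
        },
    )


def make_experiment(
    exp: Literal["exp1", "exp2", "exp3"],
    seed: int,
    overrides: dict | None = None,
) -> tuple[list[TimeSeriesSample], list[FrameworkConfig]]:
    """Materialize a full study protocol at configurable scale.

    Returns the generated samples together with the matching harness
    configuration(s): ``single`` for exp1, one random-slide-window
    config for exp2, and the fixed-window sweep (one config per
    ``n_fsw``) for exp3.  Overrides are applied to the protocol config
    dataclass fields; for exp3 ``fsw_exp_range`` bounds the sweep and
    for exp2 ``l_min``/``l_max`` bound the window draw.
    """
    overrides = dict(overrides or {})
    rng = np.random.default_rng(seed)
    if exp == "exp1":
        cfg = Exp1Config(**overrides)
        samples: list[TimeSeriesSample] = []
        for g in range(cfg.n_groups):
            n = int(2 ** rng.integers(cfg.n_exp_range[0], cfg.n_exp_range[1] + 1))
            v = float(rng.uniform(*cfg.v_range))
            m = int(rng.integers(cfg.tcp_margin, n - cfg.tcp_margin + 1))
            for _ in range(cfg.samples_per_group):
                s = gen_single_cp(n, m, v, rng)
                s.provenance["group"] = g
                samples.append(s)
        return samples, [FrameworkConfig(mode="single")]
    if exp == "exp2":
        l_min = overrides.pop("l_min", 2**9)
        l_max = overrides.pop("l_max", 2**12)
        cfg = ExpMultiConfig(**overrides)
        samples = [
            gen_multi_cp(cfg, rng) for _ in range(cfg.n_samples)
        ]
        fw = FrameworkConfig(mode="rsw", l_min=l_min, l_max=l_max, seed=seed)
        return samples, [fw]
    if exp == "exp3":
        fsw_lo, fsw_hi = overrides.pop("fsw_exp_range", (6, 15))
        overrides.setdefault("n_segments_range", (30, 30))
        cfg = ExpMultiConfig(**overrides)
        samples = [gen_multi_cp(cfg, rng) for _ in range(cfg.n_samples)]
        configs = [
            FrameworkConfig(mode="fsw", n_fsw=2**e, seed=seed)
            for e in range(fsw_lo, fsw_hi + 1)
        ]
        return samples, configs
    raise ValueError(f"unknown experiment {exp!r}")
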