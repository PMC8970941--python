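"""Ground-truth segmentation of an annotated time series.

A series with ``n`` annotated target change points (tCPs) is tiled into
``n`` disjoint scoring segments, one per target, with interior boundaries
at the floored midpoints between consecutive targets.  Every metric in
:mod:`wedm.metrics` is computed per segment, so this tiling is the unit
of account for the whole framework.

All public coordinates are 1-based inclusive sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesSample",
    "Segment",
    "segment_series",
    "read_series",
    "write_series",
    "read_annotations",
    "write_annotations",
]


class Segment(NamedTuple):
    """One scoring unit: the inclusive index range around a single target.

    ``start <= tcp <= end``; over a full segmentation the segments are
    disjoint, ordered, and tile ``[1, N]`` exactly.
    """

    start: int
    end: int
    tcp: int

    def __len__(self) -> int:  # number of samples covered
        return self.end - self.start + 1


@dataclass
class TimeSeriesSample:
    """A univariate series with its ground-truth change-point annotation.

    Parameters
    ----------
    values : array-like of float, length N >= 2
        The observed series.
    target_cps : array-like of int
        Strictly increasing 1-based target positions, each strictly
        inside ``[2, N-1]`` so both flanks of every target are non-empty.
    provenance : dict, optional
        Free-form record of how the sample was produced (generator name,
        parameters, seed).  Carried through to manifests and reports.
    """

    values: np.ndarray
    target_cps: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.target_cps = np.asarray(self.target_cps, dtype=np.int64).ravel()
        n = self.values.size
        if n < 2:
            raise ValueError(f"series must have at least 2 samples, got {n}")
        cps = self.target_cps
        if cps.size == 0:
            raise ValueError("no targets: at least one target change point required")
        if np.any(np.diff(cps) <= 0):
            raise ValueError("target_cps must be strictly increasing and unique")
        if cps[0] < 2 or cps[-1] > n - 1:
            raise ValueError(
                f"target_cps must lie strictly inside [2, {n - 1}], got "
                f"range [{cps[0]}, {cps[-1]}]"
            )

    @property
    def n(self) -> int:
        """Series length N."""
        return int(self.values.size)

    @property
    def n_targets(self) -> int:
        return int(self.target_cps.size)


def segment_series(sample: TimeSeriesSample) -> list[Segment]:
    """Tile a sample into one scoring segment per target change point.

    Interior boundaries sit at the floored midpoints
    ``m_i = floor((tCP_i + tCP_{i+1}) / 2)``; segment ``i`` is the
    inclusive range ``[m_{i-1} + 1, m_i]`` with ``m_0 = 0`` and
    ``m_n = N``.  The segments are disjoint, ordered, contain exactly one
    target each, and their lengths sum to ``N``.

    Returns
    -------
    list of :class:`Segment`, one per target, in series order.
    """
    cps = sample.target_cps
    n = sample.n
    mids = np.empty(cps.size + 1, dtype=np.int64)
    mids[0] = 0
    mids[-1] = n
    mids[1:-1] = (cps[:-1] + cps[1:]) // 2
    return [
        Segment(int(mids[i] + 1), int(mids[i + 1]), int(cps[i]))
        for i in range(cps.size)
    ]


# ---------------------------------------------------------------------------
# plain-text I/O: one value per line for the series, one integer position
# per line for the annotation sidecar


def read_series(path: str | Path) -> np.ndarray:
    """Read a series file: one numeric value per line, optional header."""
    df = pd.read_csv(path, header=None, comment="#")
    col = df.iloc[:, 0]
    if col.size and isinstance(col.iloc[0], str):  # header row present
        col = col.iloc[1:]
    return pd.to_numeric(col).to_numpy(dtype=float)


def write_series(path: str | Path, values: Sequence[float]) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.10g")


def read_annotations(path: str | Path) -> np.ndarray:
    """Read target positions: a single CSV column of 1-based integers."""
    df = pd.read_csv(path, header=None, comment="#")
    col = df.iloc[:, 0]
    if col.size and isinstance(col.iloc[0], str):
        col = col.iloc[1:]
    return pd.to_numeric(col).to_numpy(dtype=np.int64)


def write_annotations(path: str | Path, target_cps: Sequence[int]) -> None:
    np.savetxt(path, np.asarray(target_cps, dtype=np.int64), fmt="%d")


def load_sample(
    series_path: str | Path,
    annotation_path: str | Path,
    provenance: dict[str, Any] | None = None,
) -> TimeSeriesSample:
    """Assemble a :class:`TimeSeriesSample` from its two sidecar files."""
    return TimeSeriesSample(
        values=read_series(series_path),
        target_cps=read_annotations(annotation_path),
        provenance=provenance or {"source": str(series_path)},
    )
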