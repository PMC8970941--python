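"""Aggregation of evaluation summaries into benchmark report tables.

Two surfaces mirror the standard presentation of detector benchmarks:

* a *mean-analysis table* — rows MWTD, hit rate, miss rate, error
  rate, MWED, time and NST; one column per detector; each cell the
  arithmetic mean over tests, with the MWTD row enforced as the exact
  complement of the MWED row and NST the detectors' shares of total
  computing time;
* *dynamic tracks* — a long-form table ``(test_index, detector,
  metric, value)`` ready for plotting metric trajectories across tests.

Both are plain DataFrames; writing CSV/JSON is left to the CLI so
report regeneration from stored run logs stays bit-identical.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import EvaluationSummary, normalized_times

__all__ = ["mean_analysis", "dynamic_tracks"]

_TRACK_METRICS = ("hit_rate", "miss_rate", "error_rate", "mwed")


def mean_analysis(
    summaries: Mapping[str, Sequence[EvaluationSummary]],
) -> pd.DataFrame:
    """Mean of each evaluation index across tests, one column per detector."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    cols: dict[str, dict[str, float]] = {}
    times: dict[str, float] = {}
    for det, runs in summaries.items():
        if not len(runs):
            raise ValueError(f"no summaries for detector {det!r}")
        mean_mwed = float(np.mean([r.mwed for r in runs]))
        times[det] = float(np.mean([r.compute_time for r in runs]))
        cols[det] = {
            "MWTD": 1.0 - mean_mwed,
            "Hit rate": float(np.mean([r.hit_rate for r in runs])),
            "Miss rate": float(np.mean([r.miss_rate for r in runs])),
            "Error rate": float(np.mean([r.error_rate for r in runs])),
            "MWED": mean_mwed,
            "Time": times[det],
        }
    table = pd.DataFrame(cols)
    try:
        nst = normalized_times(times)
        table.loc["NST"] = [nst[det] for det in table.columns]
    except ValueError:  # all-zero times (e.g. synthetic summaries)
        table.loc["NST"] = np.nan
    return table


def dynamic_tracks(
    summaries: Mapping[str, Sequence[EvaluationSummary]],
) -> pd.DataFrame:
    """Long-form per-test metric table for trajectory plots."""
    rows = []
    for det, runs in summaries.items():
        for i, r in enumerate(runs):
            for metric in _TRACK_METRICS:
                rows.append(
                    {
                        "test_index": i,
                        "detector": det,
                        "metric": metric,
                        "value": getattr(r, metric),
                    }
                )
    return pd.DataFrame(rows, columns=["test_index", "detector", "metric",
                                       "value"])
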