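"""Trial-log validation, anticipatory-RT filtering, and normality diagnostics.

Reaction times below 200 ms are faster than perceptual processing allows
(Welford's criterion) and are treated as anticipatory guesses: they are
removed before any sequential modelling.  The boundary value is retained —
the exclusion is strictly "less than" the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DataError",
    "DegenerateSampleError",
    "FilterReport",
    "filter_rt",
    "check_normality",
    "normality_by_group",
    "rt_histogram",
]


class DataError(ValueError):
    """Raised when a trial log violates the schema or its invariants."""


class DegenerateSampleError(ValueError):
    """Raised when a sample is too short or constant for a distributional test."""


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the anticipatory-RT exclusion."""

    n_input: int
    n_removed: int
    threshold_ms: float = 200.0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    @property
    def removal_fraction(self) -> float:
        return self.n_removed / max(self.n_input, 1)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_kept": self.n_kept,
            "removal_fraction": self.removal_fraction,
            "threshold_ms": self.threshold_ms,
        }


def filter_rt(trials: pd.DataFrame, threshold_ms: float = 200.0) -> tuple[pd.DataFrame, FilterReport]:
    """Drop trials with RT strictly below ``threshold_ms``.

    Returns the surviving rows (original order, fields untouched) and a
    :class:`FilterReport`.  RTs must be positive; a nonpositive RT is a data
    error and the offending row is named.
    """
    rt = np.asarray(trials["rt_ms"], dtype=float)
    bad = np.flatnonzero(~(rt > 0))
    if bad.size:
        i = int(bad[0])
        row = trials.iloc[i]
        raise DataError(
            f"nonpositive rt_ms={row['rt_ms']!r} at row {i} "
            f"(participant {row.get('participant_id', '?')}, trial {row.get('trial_index', '?')})"
        )
    keep = rt >= threshold_ms
    kept = trials.loc[keep].reset_index(drop=True)
    report = FilterReport(n_input=len(trials), n_removed=int((~keep).sum()), threshold_ms=float(threshold_ms))
    return kept, report


def check_normality(rts, group: str | None = None) -> tuple[float, float]:
    """Shapiro-Wilk test of RT normality for one group.

    Returns (W, p).  Requires at least 3 values that are not all identical.
    """
    x = np.asarray(rts, dtype=float)
    label = f" for group {group!r}" if group else ""
    if x.size < 3:
        raise DegenerateSampleError(f"need >= 3 RTs{label}, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError(f"constant RT sample{label}: Shapiro-Wilk is undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def normality_by_group(trials: pd.DataFrame, by=("participant_id", "environment")) -> pd.DataFrame:
    """Shapiro-Wilk W and p per group, with degenerate groups flagged.

    Returned columns: the grouping keys, n, W, p, degenerate.  The study's
    grouping unit is not pinned down anywhere, so both this per-group form and
    the per-environment pooled form are exercised by the pipeline.
    """
    by = list(by)
    rows = []
    for key, grp in trials.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(by, key))
        rec["n"] = len(grp)
        try:
            w, p = check_normality(grp["rt_ms"].to_numpy(), group="/".join(map(str, key)))
            rec.update(W=w, p=p, degenerate=False)
        except DegenerateSampleError:
            rec.update(W=float("nan"), p=float("nan"), degenerate=True)
        rows.append(rec)
    return pd.DataFrame(rows, columns=by + ["n", "W", "p", "degenerate"])


def rt_histogram(rts, bins: int = 20) -> pd.DataFrame:
    """Histogram table (bin_left, bin_right, count) for visual bimodality checks."""
    x = np.asarray(rts, dtype=float)
    if x.size == 0:
        raise DataError("cannot histogram an empty RT vector")
    counts, edges = np.histogram(x, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
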