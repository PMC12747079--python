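"""Growth-curve kinetics: exponential fits and collapse detection.

Doubling times are estimated by ordinary least squares of ln(count) against
time over the best contiguous window of the series (the procedure commonly
used for batch cultures where the exponential phase must be located within
lag and stationary/collapse phases). Catastrophic collapses — sudden losses
of a large fraction of the population, here associated with lytic giant
virus infection of the culture — are flagged against the running maximum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GrowthFit:
    mu: float                  # 1/h
    doubling: float            # h, = ln2/mu
    r2: float
    window: tuple[float, float]
    n_points: int


@dataclass
class CollapseEvent:
    time: float
    drop: float                # fraction of the running maximum lost


def _validate_series(times: np.ndarray, counts: np.ndarray) -> None:
    if times.size != counts.size:
        raise ValueError("times and counts must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")


def fit_exponential(
    series: pd.DataFrame | tuple,
    min_points: int = 4,
    min_fold: float = 2.0,
    r2_min: float = 0.99,
) -> GrowthFit | None:
    """Fit exponential growth over the best window of one replicate.

    Candidate windows are all contiguous runs of at least ``min_points``
    strictly positive counts whose ln-linear slope is positive and whose
    observed fold-change (last/first count in the window) is at least
    ``min_fold``. Among candidates reaching ``r2_min`` the longest wins
    (ties: higher R^2, then earlier start); when none reaches ``r2_min``
    the highest-R^2 window is used. Preferring the longest sufficiently
    linear window avoids two failure modes of bare max-R^2 selection:
    short windows whose high R^2 is a noise fluke, and length-greedy
    scores that swallow a collapse step. Returns None when no window
    qualifies (e.g. a flat series). Zero counts exclude any window
    containing them.
    """
    if isinstance(series, pd.DataFrame):
        times = series["time_h"].to_numpy(dtype=float)
        counts = series["count"].to_numpy(dtype=float)
    else:
        times, counts = (np.asarray(x, dtype=float) for x in series)
    _validate_series(times, counts)
    n = times.size
    best: tuple | None = None
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            c = counts[i:j]
            if np.any(c <= 0):
                continue
            if c[-1] / c[0] < min_fold:
                continue
            res = sps.linregress(times[i:j], np.log(c))
            if res.slope <= 0:
                continue
            r2 = res.rvalue**2
            # linear windows sort before the fallback tier; within the
            # linear tier longest wins, otherwise highest R^2
            key = (
                (0, -(j - i), -r2, i) if r2 >= r2_min else (1, -r2, -(j - i), i)
            )
            if best is None or key < best[0]:
                fit = GrowthFit(
                    mu=float(res.slope),
                    doubling=float(np.log(2) / res.slope),
                    r2=float(r2),
                    window=(float(times[i]), float(times[j - 1])),
                    n_points=j - i,
                )
                best = (key, fit)
    return best[1] if best else None


def detect_collapse(
    series: pd.DataFrame | tuple,
    drop_frac: float = 0.5,
    horizon: int = 2,
) -> list[CollapseEvent]:
    """Flag sudden population collapses.

    An event fires at a timepoint whose count has fallen by at least
    ``drop_frac`` (inclusive) relative to the running maximum, provided the
    running maximum occurred within ``horizon`` sampling intervals — i.e.
    the loss was sudden, not a slow decline. The fractional drop is reported
    against the running maximum.
    """
    if isinstance(series, pd.DataFrame):
        times = series["time_h"].to_numpy(dtype=float)
        counts = series["count"].to_numpy(dtype=float)
    else:
        times, counts = (np.asarray(x, dtype=float) for x in series)
    _validate_series(times, counts)
    events = []
    max_val = counts[0]
    max_idx = 0
    for i in range(1, counts.size):
        if counts[i] >= max_val:
            max_val = counts[i]
            max_idx = i
            continue
        drop = 1.0 - counts[i] / max_val if max_val > 0 else 0.0
        if drop >= drop_frac and i - max_idx <= horizon:
            events.append(CollapseEvent(time=float(times[i]), drop=float(drop)))
    return events


def fit_replicates(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-replicate fits and collapse events for a long-format table
    (replicate_id, time_h, count)."""
    rows = []
    for rid, grp in table.groupby("replicate_id", sort=True):
        grp = grp.sort_values("time_h")
        fit = fit_exponential(grp, **kwargs)
        collapses = detect_collapse(grp)
        rows.append(
            {
                "replicate_id": rid,
                "mu": fit.mu if fit else np.nan,
                "doubling_h": round(fit.doubling, 1) if fit else np.nan,
                "r2": fit.r2 if fit else np.nan,
                "n_points": fit.n_points if fit else 0,
                "n_collapses": len(collapses),
                "max_drop": max((c.drop for c in collapses), default=np.nan),
            }
        )
    return pd.DataFrame(rows)
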