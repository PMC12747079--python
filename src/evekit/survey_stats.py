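"""CARD-FISH survey statistics.

Works on tables of per-sample CRY1a and total heterotrophic nanoflagellate
(HNF) counts with optional environmental covariates (``env_*`` columns).
The key derived quantity is the CRY1a percentage of the HNF community,
summarised over samples and screened for association with physicochemical
parameters. In-situ doubling times are estimated from consecutive
time-series abundance increases under exponential growth.
"""
from __future__ import annotations

import statistics
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SurveySummary:
    n: int
    n_excluded: int          # samples dropped for hnf_count == 0
    mean: float
    median: float
    sd: float | None         # None for a single sample
    min: float
    max: float
    n_above_10pct: int
    n_below_1pct: int


def cry1a_pct(samples: pd.DataFrame) -> pd.Series:
    """CRY1a as a percentage of HNF, per sample (NaN where hnf_count == 0)."""
    hnf = samples["hnf_count"].astype(float)
    pct = 100.0 * samples["cry1a_count"].astype(float) / hnf.where(hnf > 0)
    return pct


def summarize_survey(samples: pd.DataFrame) -> SurveySummary:
    """Survey-wide summary of the CRY1a percentage.

    Samples with ``hnf_count == 0`` are excluded (and counted separately,
    never imputed). The SD is the sample (n-1) standard deviation; the
    median is the lower median for even n; the abundance-category counts
    use strict inequalities (>10%, <1%).
    """
    pct = cry1a_pct(samples).dropna()
    n_excluded = len(samples) - len(pct)
    if pct.empty:
        raise ValueError("no samples with non-zero HNF counts")
    vals = pct.to_numpy()
    return SurveySummary(
        n=len(vals),
        n_excluded=n_excluded,
        mean=float(vals.mean()),
        median=float(statistics.median_low(sorted(vals.tolist()))),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else None,
        min=float(vals.min()),
        max=float(vals.max()),
        n_above_10pct=int(np.count_nonzero(vals > 10.0)),
        n_below_1pct=int(np.count_nonzero(vals < 1.0)),
    )


def correlation_screen(
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Correlation of the CRY1a percentage with each covariate.

    Both Pearson and Spearman coefficients are computed on pairwise-complete
    observations, and a covariate is flagged when either exceeds the
    threshold in absolute value (a conservative reading of an unspecified
    "r"). Constant covariates yield undefined coefficients, flagged=False,
    and a warning column entry.
    """
    pct = cry1a_pct(samples)
    if covariates is None:
        covariates = [c for c in samples.columns if c.startswith("env_")]
    rows = []
    for cov in covariates:
        pair = pd.DataFrame({"pct": pct, "x": samples[cov]}).dropna()
        warning = ""
        if len(pair) < 3:
            raise ValueError(f"covariate {cov!r} has fewer than 3 complete pairs")
        if pair["x"].nunique() == 1 or pair["pct"].nunique() == 1:
            pr = sr = np.nan
            warning = "constant input; correlation undefined"
        else:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                pr = sps.pearsonr(pair["pct"], pair["x"]).statistic
                sr = sps.spearmanr(pair["pct"], pair["x"]).statistic
        flagged = bool(
            (not np.isnan(pr) and abs(pr) > threshold)
            or (not np.isnan(sr) and abs(sr) > threshold)
        )
        rows.append(
            {
                "covariate": cov,
                "pearson_r": pr,
                "spearman_r": sr,
                "n_pairs": len(pair),
                "flagged": flagged,
                "warning": warning,
            }
        )
    return pd.DataFrame(rows)


def insitu_doubling(series: list[tuple[float, float]]) -> float | None:
    """Fastest doubling time over consecutive increasing pairs.

    For each consecutive pair with N2 > N1, doubling = (t2 - t1) * ln 2 /
    ln(N2 / N1); the minimum over pairs is the fastest in-situ doubling
    time. None when the series never increases.
    """
    if len(series) < 2:
        raise ValueError("need at least two timepoints")
    times = np.array([t for t, _ in series], dtype=float)
    abund = np.array([n for _, n in series], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(abund <= 0):
        raise ValueError("abundances must be positive")
    ratios = abund[1:] / abund[:-1]
    dts = np.diff(times)
    increasing = ratios > 1.0
    if not increasing.any():
        return None
    doubling = dts[increasing] * np.log(2) / np.log(ratios[increasing])
    return float(doubling.min())
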