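"""Plaque counts, limit-of-detection correction and clonal-expansion summaries.

Multiplying a mutation's mean read proportion by the number of plaques pooled
gives a raw estimate of how many plaques carried it.  Raw counts near one are
noisy, so they are passed through a limit-of-detection / linear calibration:
below the LOD the count collapses to a singleton (corrected count 1); above it
a fitted line maps the raw count to an integer plaque count.  A mutation with
a corrected count > 1 is treated as clonally expanded — the conservative
assumption being that identical mutations within one tissue of one animal
descend from a single event — and the proportion of expanded mutations per
group is the working proxy for mosaicism.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class ClonalityCalibration:
    """Linear map from raw (read-derived) counts to plaque counts.

    ``corrected = round(intercept + slope * raw)`` floored at 1, with raw
    counts below ``lod_count`` collapsed to singletons.
    """

    slope: float
    intercept: float
    lod_count: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.lod_count < 1:
            raise ValueError("lod_count must be >= 1")

    @classmethod
    def identity(cls, lod_count: float = 2.0) -> "ClonalityCalibration":
        return cls(slope=1.0, intercept=0.0, lod_count=lod_count)


def raw_count(mean_proportion: float, n_plaques: int) -> float:
    """Raw plaque count: mean replicate proportion x plaques pooled."""
    if not 0.0 <= mean_proportion <= 1.0:
        raise ValueError("mean_proportion must be in [0, 1]")
    return mean_proportion * n_plaques


def calibrate(observed_raw, true_counts, alpha: float = 0.05) -> ClonalityCalibration:
    """Fit the LOD/linear correction from paired (observed raw, true count) data.

    Ordinary least squares of true on observed; the LOD is the smallest
    observed raw count whose observation prediction-interval lower bound
    exceeds 1 on the calibration data itself (below it a count cannot be
    distinguished from a singleton).
    """
    import statsmodels.api as sm

    x = np.asarray(observed_raw, dtype=float)
    y = np.asarray(true_counts, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired calibration points")
    if (y < 1).any():
        raise ValueError("true counts must be >= 1")
    if np.var(x) == 0:
        raise ValueError("degenerate calibration: observed counts have no variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    lower = res.get_prediction(sm.add_constant(x)).conf_int(obs=True, alpha=alpha)[:, 0]
    qualifying = x[lower > 1.0]
    if qualifying.size:
        lod = float(qualifying.min())
    else:
        warnings.warn(
            "no calibration point has prediction-interval lower bound > 1; "
            "using the largest observed count as the LOD"
        )
        lod = float(x.max())
    return ClonalityCalibration(slope=float(slope), intercept=float(intercept),
                                lod_count=max(1.0, lod))


def correct_count(raw: float, cal: ClonalityCalibration) -> int:
    """LOD/linear corrected plaque count (integer >= 1, monotone in raw)."""
    if raw < 0:
        raise ValueError("raw count must be non-negative")
    if raw < cal.lod_count:
        return 1
    pred = cal.intercept + cal.slope * raw
    return max(1, math.floor(pred + 0.5))  # round half away from zero (pred >= 0)


def summarize_clonality(calls: pd.DataFrame, by=("tissue", "dose")) -> pd.DataFrame:
    """Singleton / clonally-expanded tallies per group.

    ``calls`` needs a ``corrected_count`` column plus the grouping columns.
    Returns one row per group with n_unique, n_singletons, n_expanded,
    proportion_expanded and total_corrected_count; an empty input yields an
    empty summary (the proportion is undefined, so no row is emitted).
    """
    by = list(by)
    cols = by + [
        "n_unique",
        "n_singletons",
        "n_expanded",
        "proportion_expanded",
        "total_corrected_count",
    ]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for key, g in calls.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        cc = g["corrected_count"].to_numpy()
        n_expanded = int((cc > 1).sum())
        rows.append(
            (*key, len(cc), len(cc) - n_expanded, n_expanded,
             n_expanded / len(cc), int(cc.sum()))
        )
    return pd.DataFrame(rows, columns=cols)
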