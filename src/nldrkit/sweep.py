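"""Threshold-adequacy sweep.

The 210-min workload boundary is the cohort's 84.1th percentile of
operative time (mean + 1 SD under a normal model).  To judge how
sensitive the discriminant's performance is to that choice, the sweep
re-dichotomizes the cohort at a grid of percentiles (default 2nd–98th,
step 1), refits the NLDR on a fixed predictor subset at each threshold
and tabulates the five hit rates, either apparent or leave-one-out
cross-validated.  Thresholds that leave fewer than two donors in either
group cannot be fitted and are recorded as skipped, never interpolated.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .cohort import Cohort, dichotomize, percentile_threshold
from .model import FitError, confusion, fit_nldr, hit_rates
from .validate import loocv_rates

MODES = ("apparent", "loocv")


def sweep_thresholds(cohort: Cohort, subset,
                     percentiles: Sequence[float] | None = None,
                     mode: str = "apparent",
                     covariance_mode: str = "pooled") -> pd.DataFrame:
    """One row per percentile: threshold, group sizes and the five rates.

    Raw minute-valued thresholds can be swept instead by passing them
    through :func:`sweep_minutes`.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if percentiles is None:
        percentiles = list(range(2, 99))
    percentiles = list(percentiles)
    if not percentiles:
        raise ValueError("percentile list is empty")
    thresholds = [percentile_threshold(cohort, q) for q in percentiles]
    out = _sweep(cohort, subset, thresholds, mode, covariance_mode)
    out.insert(0, "percentile", percentiles)
    return out


def sweep_minutes(cohort: Cohort, subset, thresholds_min: Sequence[float],
                  mode: str = "apparent",
                  covariance_mode: str = "pooled") -> pd.DataFrame:
    """Sweep explicit minute-valued thresholds instead of percentiles."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    thresholds = list(thresholds_min)
    if not thresholds:
        raise ValueError("threshold list is empty")
    return _sweep(cohort, subset, thresholds, mode, covariance_mode)


def _sweep(cohort, subset, thresholds, mode, covariance_mode) -> pd.DataFrame:
    subset = tuple(subset)
    rows = []
    for thr in thresholds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate splits recorded below
            labeled = dichotomize(cohort, thr)
        row = {"threshold_min": float(thr),
               "n_difficult": labeled.n_difficult,
               "n_easy": labeled.n_easy}
        try:
            if mode == "apparent":
                model = fit_nldr(labeled, subset, covariance_mode)
                pred = model.classify(cohort.feature_matrix(subset))
                rates = hit_rates(confusion(pred, labeled.labels))
            else:
                rates = loocv_rates(labeled, subset, covariance_mode)
        except FitError:
            row["status"] = "skipped"
            rows.append(row)
            continue
        row.update(status="ok", **rates.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
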