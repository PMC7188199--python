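"""Supporting association statistics for the workload cohort.

Univariate and multivariate OLS of operative time on the 16 candidate
predictors; Pearson/Spearman correlation screens; a Mann-Whitney /
Fisher comparison of the heaviest- vs lightest-workload extremes; and an
exact (Freeman–Halton) test of complication counts across perinephric-fat
quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, lgamma

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import Cohort
from .registry import PREDICTOR_NAMES


@dataclass(frozen=True)
class RegressionRow:
    variable: str
    coefficient: float
    p_value: float
    n: int
    mode: str  # univariate | multivariate


def regress_operative_time(cohort: Cohort) -> pd.DataFrame:
    """OLS of operative time on each predictor alone and on all 16 jointly.

    Returns one row per predictor with univariate and multivariate slope
    and two-sided t-test p-value.
    """
    y = cohort.operative_time
    x = cohort.feature_matrix()
    n, p = x.shape
    if n < p + 2:
        raise ValueError(
            f"multivariate fit needs n >= {p + 2} (16 slopes + intercept + "
            f"residual df); got n={n}"
        )
    multi = sm.OLS(y, sm.add_constant(pd.DataFrame(x, columns=PREDICTOR_NAMES))).fit()
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p + 1:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [(PREDICTOR_NAMES[i], PREDICTOR_NAMES[j])
                 for i in range(p) for j in range(i + 1, p)
                 if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear: {pairs}")
    rows = []
    for j, name in enumerate(PREDICTOR_NAMES):
        uni = sm.OLS(y, sm.add_constant(x[:, j])).fit()
        rows.append({
            "variable": name,
            "uni_coefficient": float(uni.params[1]),
            "uni_p": float(uni.pvalues[1]),
            "multi_coefficient": float(multi.params[name]),
            "multi_p": float(multi.pvalues[name]),
            "n": n,
        })
    return pd.DataFrame(rows)


def correlate(cohort: Cohort, target: str = "operative_time",
              method: str = "pearson") -> pd.DataFrame:
    """Correlation of every predictor with a target, one row per variable.

    target: ``operative_time`` or ``complication_rank`` (ordered modified
    Clavien grade).  Spearman uses average ranks for ties.  A zero-variance
    predictor yields an undefined (NaN) coefficient, flagged in the output.
    """
    if target == "operative_time":
        t = cohort.operative_time
    elif target == "complication_rank":
        t = cohort.complication_ranks().astype(float)
    else:
        raise ValueError(f"unknown target {target!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for name in PREDICTOR_NAMES:
        v = cohort.df[name].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(t) == 0:
            rows.append({"variable": name, "r": np.nan, "p": np.nan,
                         "defined": False})
            continue
        if method == "pearson":
            r, p = sps.pearsonr(v, t)
        else:
            r, p = sps.spearmanr(v, t)
        rows.append({"variable": name, "r": float(r), "p": float(p),
                     "defined": True})
    return pd.DataFrame(rows)


def compare_extremes(cohort: Cohort, high_min: float = 240.0,
                     low_min: float = 100.0,
                     extra: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Compare predictors between the longest and shortest operations.

    Groups are operative time ≥ ``high_min`` vs ≤ ``low_min``.  Continuous
    and ordinal variables are compared by two-sided Mann-Whitney U (exact
    for small tie-free groups, normal approximation with tie correction
    otherwise); binary variables by Fisher's exact test.  ``extra`` adds
    externally computed per-donor columns (e.g. a discrimination index) to
    the comparison.
    """
    time = cohort.operative_time
    hi = time >= high_min
    lo = time <= low_min
    if not hi.any() or not lo.any():
        raise ValueError(
            f"empty extreme group (>= {high_min}: {int(hi.sum())}, "
            f"<= {low_min}: {int(lo.sum())})"
        )
    columns: dict[str, np.ndarray] = {
        n: cohort.df[n].to_numpy(dtype=float) for n in PREDICTOR_NAMES
    }
    binary = {"sex_male"}
    if extra:
        columns.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    rows = []
    for name, v in columns.items():
        a, b = v[hi], v[lo]
        if name in binary:
            table = [[int(a.sum()), int(len(a) - a.sum())],
                     [int(b.sum()), int(len(b) - b.sum())]]
            _, p = sps.fisher_exact(table, alternative="two-sided")
            stat = np.nan
            test = "fisher"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            test = "mann-whitney"
        rows.append({"variable": name, "test": test, "statistic": stat,
                     "p": float(p),
                     "n_high": int(hi.sum()), "n_low": int(lo.sum()),
                     "median_high": float(np.median(a)),
                     "median_low": float(np.median(b))})
    return pd.DataFrame(rows)


# -- exact r x 2 test (Freeman–Halton extension of Fisher's exact test) -----


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _rx2_exact_p(ones: np.ndarray, sizes: np.ndarray) -> float:
    """Exact two-sided p for an r x 2 table with fixed margins.

    ``ones[i]`` successes out of ``sizes[i]`` in row i.  Enumerates every
    table with the same margins; p is the total multivariate-hypergeometric
    probability of tables no more probable than the observed one.
    """
    k_total = int(ones.sum())
    n_total = int(sizes.sum())
    log_denom = _log_comb(n_total, k_total)

    def log_prob(ks):
        return sum(_log_comb(int(n), int(k)) for n, k in zip(sizes, ks)) - log_denom

    obs = log_prob(ones)
    p = 0.0

    def recurse(row: int, remaining: int, acc: float):
        nonlocal p
        if row == len(sizes) - 1:
            if 0 <= remaining <= sizes[row]:
                lp = acc + _log_comb(int(sizes[row]), remaining) - log_denom
                if lp <= obs + 1e-9:
                    p += np.exp(lp)
            return
        tail = int(sizes[row + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(sizes[row]), remaining)
        for k in range(lo, hi + 1):
            recurse(row + 1, remaining - k, acc + _log_comb(int(sizes[row]), k))

    # acc accumulates numerator logs only; denominator applied at the leaf
    def recurse0():
        recurse(0, k_total, 0.0)

    recurse0()
    return min(p, 1.0)


def _rx2_montecarlo_p(ones: np.ndarray, sizes: np.ndarray, n_draws: int,
                      seed: int) -> float:
    """Monte-Carlo version of the r x 2 exact test (for large tables)."""
    rng = np.random.default_rng(seed)
    k_total = int(ones.sum())
    labels = np.repeat(np.arange(len(sizes)), sizes)
    log_denom = _log_comb(int(sizes.sum()), k_total)

    def log_prob(ks):
        return sum(_log_comb(int(n), int(k)) for n, k in zip(sizes, ks)) - log_denom

    obs = log_prob(ones)
    hits = 0
    for _ in range(n_draws):
        drawn = rng.choice(labels, size=k_total, replace=False)
        ks = np.bincount(drawn, minlength=len(sizes))
        if log_prob(ks) <= obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_draws + 1)


def quartile_complication_test(cohort: Cohort, variable: str = "area_pnf",
                               exact_limit: int = 10 ** 6,
                               n_draws: int = 10 ** 5, seed: int = 0):
    """Exact test of complication frequency across quartiles of a variable.

    Donors are split at the 25th/50th/75th percentiles of ``variable``
    (linear interpolation); complications (grade >= 1) are counted per
    quartile and tested against the no-association null with the
    Freeman–Halton exact test (complete enumeration when the number of
    candidate tables is below ``exact_limit``, else seeded Monte-Carlo).

    Returns ``(table, p, method)`` where ``table`` is a DataFrame with one
    row per quartile.
    """
    v = cohort.df[variable].to_numpy(dtype=float)
    has_comp = cohort.complication_ranks() >= 1
    qs = np.percentile(v, [25, 50, 75], method="linear")
    group = np.digitize(v, qs, right=True)
    sizes = np.bincount(group, minlength=4)
    ones = np.array([int(has_comp[group == g].sum()) for g in range(4)])
    table = pd.DataFrame({
        "quartile": ["Q1", "Q2", "Q3", "Q4"],
        "n": sizes,
        "complications": ones,
        "rate_pct": 100.0 * ones / np.maximum(sizes, 1),
    })
    # enumeration size: compositions of the complication total over the
    # four rows (upper-bounded by the unconstrained count)
    k_total = int(ones.sum())
    n_tables = comb(k_total + len(sizes) - 1, len(sizes) - 1)
    if n_tables <= exact_limit:
        p = _rx2_exact_p(ones, sizes)
        method = "exact"
    else:
        p = _rx2_montecarlo_p(ones, sizes, n_draws, seed)
        method = "monte-carlo"
    return table, float(p), method
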