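"""Exhaustive variable-subset search over the NLDR.

With 16 candidate predictors there are 2^16 − 1 = 65,535 non-empty
subsets — small enough to evaluate all of them.  The search computes, for
every subset, the apparent (training-data) 2x2 table and hit rates, and
reports the best-apparent tier: all subsets whose predictions yield the
same 2x2 table as the maximum-total-hit-rate subset.

The hot loop exploits two facts: (i) the group means and the shared
covariance of any subset are just slices of the full 16-variable
statistics, so the sufficient statistics are computed once; and (ii) with
a shared covariance the discrimination index is affine in x
(Ω = log π1/π0 + wᵀx − ½wᵀ(μ0+μ1), w = Σ⁻¹(μ1−μ0)), so scoring a subset
costs one small linear solve plus a mat-vec.  Subsets of equal size are
batched through numpy's stacked solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import (
    ConfusionTable,
    FitError,
    HitRates,
    confusion,
    fit_nldr,
    hit_rates,
    shared_covariance,
)
from .registry import PREDICTOR_NAMES

MAX_PREDICTORS = 24


def enumerate_subsets(p: int) -> Iterator[int]:
    """Yield all 2^p − 1 non-empty subset masks in ascending order."""
    if not 1 <= p <= MAX_PREDICTORS:
        raise ValueError(f"predictor count must be in [1, {MAX_PREDICTORS}], got {p}")
    return iter(range(1, 1 << p))


@dataclass(frozen=True)
class SubsetResult:
    """Apparent performance of one predictor subset."""

    mask: int
    names: tuple[str, ...]
    status: str  # ok | singular
    table: ConfusionTable | None = None
    apparent: HitRates | None = None


@dataclass
class SearchResult:
    """Full exhaustive-search output.

    ``best_table_tier``: masks of all subsets whose apparent predictions
    produce the identical 2x2 table as the best subset (the strict tie the
    study counts).  ``best_total_tier``: the looser tier sharing only the
    maximum total hit rate.  The representative best table is the one of
    the lowest-mask subset attaining the maximum total (deterministic).
    """

    results: list[SubsetResult]
    best_table: ConfusionTable
    best_table_tier: list[int]
    best_total_tier: list[int]

    @property
    def n_ok(self) -> int:
        return sum(r.status == "ok" for r in self.results)

    @property
    def n_singular(self) -> int:
        return sum(r.status == "singular" for r in self.results)

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            rec = {"mask": f"{r.mask:04x}", "names": "+".join(r.names),
                   "status": r.status}
            if r.table is not None:
                rec.update(zip("abcd", r.table.as_tuple()))
                rec.update(r.apparent.as_dict())
            rows.append(rec)
        return pd.DataFrame(rows)


class _SubsetScorer:
    """Scores arbitrary predictor subsets against fixed sufficient statistics.

    Holds the full-dimension group means and shared covariance for one
    train split and classifies one or more evaluation matrices on any
    subset by slicing — the core primitive behind the exhaustive search,
    leave-one-out folds and bootstrap replicates.
    """

    def __init__(self, x_train: np.ndarray, y_train: np.ndarray,
                 covariance_mode: str = "pooled"):
        n1, n0 = int(y_train.sum()), int((~y_train).sum())
        if n0 < 2 or n1 < 2:
            raise FitError(
                f"each workload group needs >= 2 members (easy={n0}, difficult={n1})"
            )
        self.n0, self.n1 = n0, n1
        self.mu0 = x_train[~y_train].mean(axis=0)
        self.mu1 = x_train[y_train].mean(axis=0)
        self.sigma = shared_covariance(x_train[~y_train], x_train[y_train],
                                       covariance_mode)
        self.log_odds = np.log(n1 / n0)

    def omega_batch(self, idx: np.ndarray, x_eval: np.ndarray) -> np.ndarray:
        """Discrimination indexes for a batch of same-size subsets.

        idx: (m, s) integer array of predictor positions; x_eval: (n, p).
        Returns (m, n) Ω values.  Raises LinAlgError if any subset's
        covariance slice is not SPD (caller falls back per subset).
        """
        sub_sigma = self.sigma[idx[:, :, None], idx[:, None, :]]  # (m, s, s)
        # cholesky up front so singular slices fail loudly, not with junk
        np.linalg.cholesky(sub_sigma)
        dmu = (self.mu1 - self.mu0)[idx]  # (m, s)
        w = np.linalg.solve(sub_sigma, dmu[..., None])[..., 0]  # (m, s)
        mid = (self.mu0 + self.mu1)[idx]  # (m, s)
        scores = np.einsum("nms,ms->mn", x_eval[:, idx], w)
        return self.log_odds + scores - 0.5 * np.einsum("ms,ms->m", mid, w)[:, None]

    def omega_single(self, positions: Sequence[int], x_eval: np.ndarray) -> np.ndarray:
        """Ω for one subset (raises LinAlgError when singular)."""
        pos = list(positions)
        sub = self.sigma[np.ix_(pos, pos)]
        np.linalg.cholesky(sub)
        w = np.linalg.solve(sub, (self.mu1 - self.mu0)[pos])
        return (self.log_odds + x_eval[:, pos] @ w
                - 0.5 * (self.mu0 + self.mu1)[pos] @ w)


def _mask_positions(mask: int, p: int) -> list[int]:
    return [i for i in range(p) if mask >> i & 1]


def apparent_rates(labeled, subset, covariance_mode: str = "pooled") -> HitRates:
    """Fit on the full labeled cohort and score the same cohort."""
    model = fit_nldr(labeled, subset, covariance_mode)
    pred = model.classify(labeled.cohort.feature_matrix(subset))
    return hit_rates(confusion(pred, labeled.labels))


def search_all(labeled, covariance_mode: str = "pooled",
               predictors: Sequence[str] = PREDICTOR_NAMES,
               batch: int = 1024) -> SearchResult:
    """Evaluate every non-empty predictor subset on the training data.

    Results are returned in ascending mask order regardless of the batched
    execution, so two runs on identical input produce identical tables.
    """
    predictors = tuple(predictors)
    p = len(predictors)
    x = labeled.cohort.feature_matrix(predictors)
    y = labeled.difficult
    scorer = _SubsetScorer(x, y, covariance_mode)

    by_size: dict[int, list[int]] = {}
    for mask in enumerate_subsets(p):
        by_size.setdefault(bin(mask).count("1"), []).append(mask)

    tables: dict[int, ConfusionTable | None] = {}
    n1 = int(y.sum())

    def record_batch(masks: list[int], omegas: np.ndarray) -> None:
        pred = omegas > 0  # (m, n)
        a = (pred & y).sum(axis=1)
        b = (pred & ~y).sum(axis=1)
        for mk, ai, bi in zip(masks, a, b):
            tables[mk] = ConfusionTable(int(ai), int(bi), int(n1 - ai),
                                        int(len(y) - n1 - (bi)))

    for size, masks in by_size.items():
        for start in range(0, len(masks), batch):
            chunk = masks[start:start + batch]
            idx = np.array([_mask_positions(m, p) for m in chunk], dtype=np.intp)
            try:
                record_batch(chunk, scorer.omega_batch(idx, x))
            except np.linalg.LinAlgError:
                # at least one singular subset in the chunk: isolate it
                for mk in chunk:
                    try:
                        omega = scorer.omega_single(_mask_positions(mk, p), x)
                    except np.linalg.LinAlgError:
                        tables[mk] = None
                    else:
                        record_batch([mk], omega[None, :])

    results: list[SubsetResult] = []
    names_of = {mask: tuple(predictors[i] for i in _mask_positions(mask, p))
                for mask in tables}
    for mask in sorted(tables):
        t = tables[mask]
        if t is None:
            results.append(SubsetResult(mask, names_of[mask], "singular"))
        else:
            results.append(SubsetResult(mask, names_of[mask], "ok",
                                        table=t, apparent=hit_rates(t)))
    ok = [r for r in results if r.status == "ok"]
    if not ok:
        raise FitError("every subset had a singular covariance")
    best_total = max(r.apparent.total for r in ok)
    total_tier = [r for r in ok if r.apparent.total == best_total]
    best_table = total_tier[0].table  # lowest mask attaining the max
    table_tier = [r.mask for r in total_tier if r.table == best_table]
    return SearchResult(
        results=results,
        best_table=best_table,
        best_table_tier=table_tier,
        best_total_tier=[r.mask for r in total_tier],
    )
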