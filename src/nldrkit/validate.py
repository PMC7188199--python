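"""True-hit-rate estimation: leave-one-out cross-validation, the .632
bootstrap estimator, and the two-stage final-model selection funnel.

The apparent hit rate — score the training data with the rule fitted to
it — is optimistic.  Two standard corrections are provided:

* Leave-one-out cross-validation: refit the NLDR n times, each time
  holding out one donor, and pool the n held-out predictions into a
  single 2x2 table.  Deterministic.

* The .632 estimator: draw B bootstrap resamples (size n, with
  replacement), fit on each, and predict only the out-of-bag donors;
  pool all out-of-bag predictions into one table to obtain r_oob, then
  combine rate-wise with the apparent rate:

      r_.632 = 0.368 · r_apparent + 0.632 · r_oob.

The selection funnel mirrors the study's procedure: exhaustively search
all subsets and keep the best-apparent tier (stage 1); cross-validate the
tier and keep subsets within a band of the best CV total (stage 2); run
the .632 estimator on the survivors and pick the subset with the highest
estimated total (stage 3), ties broken by fewer variables then lowest
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ConfusionTable,
    FitError,
    HitRates,
    NLDRModel,
    confusion,
    fit_nldr,
    hit_rates,
)
from .registry import PREDICTOR_NAMES
from .subsets import SearchResult, _mask_positions, _SubsetScorer, search_all


@dataclass(frozen=True)
class Boot632Config:
    """Settings for the .632 bootstrap.

    n_boot: number of resamples B (200 is classic practice).
    seed: RNG seed; mandatory for reproducibility.
    min_group: minimum per-class count a resample must retain; violating
        resamples are redrawn (the redraw count is recorded).
    max_redraw_factor: abort if redraws exceed this multiple of B.
    """

    n_boot: int = 200
    seed: int = 0
    min_group: int = 2
    max_redraw_factor: int = 50

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.min_group < 2:
            raise ValueError("min_group must be >= 2")


def _table_from_counts(a: int, b: int, c: int, d: int) -> ConfusionTable:
    return ConfusionTable(int(a), int(b), int(c), int(d))


def loocv_table(labeled, subset, covariance_mode: str = "pooled") -> ConfusionTable:
    """Pooled 2x2 table of the n held-out predictions."""
    subset = tuple(subset)
    x = labeled.cohort.feature_matrix(subset)
    y = labeled.difficult
    n = len(y)
    a = b = c = d = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            scorer = _SubsetScorer(x[keep], y[keep], covariance_mode)
            omega = scorer.omega_single(range(len(subset)), x[i:i + 1])[0]
        except (FitError, np.linalg.LinAlgError) as exc:
            raise FitError(f"LOOCV fold {i} (donor index {i}) unfittable: {exc}") from exc
        pred_difficult = omega > 0
        if pred_difficult and y[i]:
            a += 1
        elif pred_difficult:
            b += 1
        elif y[i]:
            c += 1
        else:
            d += 1
    return _table_from_counts(a, b, c, d)


def loocv_rates(labeled, subset, covariance_mode: str = "pooled") -> HitRates:
    """Leave-one-out cross-validated hit rates (deterministic)."""
    return hit_rates(loocv_table(labeled, subset, covariance_mode))


def _loocv_tables_multi(x, y, positions_list, covariance_mode):
    """LOOCV tables for many subsets sharing the fold structure.

    Computes each fold's full-dimension sufficient statistics once and
    slices them per subset — the same arithmetic as refitting per subset,
    orders of magnitude cheaper for large subset lists.
    """
    n = len(y)
    m = len(positions_list)
    counts = np.zeros((m, 4), dtype=int)  # a, b, c, d
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        scorer = _SubsetScorer(x[keep], y[keep], covariance_mode)
        for j, pos in enumerate(positions_list):
            omega = scorer.omega_single(pos, x[i:i + 1])[0]
            pred = omega > 0
            k = 0 if (pred and y[i]) else 1 if pred else 2 if y[i] else 3
            counts[j, k] += 1
    return [_table_from_counts(*row) for row in counts]


def _oob_tables_multi(x, y, positions_list, cfg: Boot632Config,
                      covariance_mode: str):
    """Pooled out-of-bag tables for many subsets over shared resamples."""
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    m = len(positions_list)
    counts = np.zeros((m, 4), dtype=int)
    redraws = 0
    drawn = 0
    limit = cfg.max_redraw_factor * cfg.n_boot
    while drawn < cfg.n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if (int(yb.sum()) < cfg.min_group
                or int((~yb).sum()) < cfg.min_group or not oob.any()):
            redraws += 1
            if redraws > limit:
                raise FitError(
                    "bootstrap redraw limit exceeded; the cohort is too small "
                    "or too unbalanced — enlarge it or lower min_group"
                )
            continue
        x_oob, y_oob = x[oob], y[oob]
        rep = np.zeros_like(counts)
        try:
            scorer = _SubsetScorer(x[idx], yb, covariance_mode)
            for j, pos in enumerate(positions_list):
                omega = scorer.omega_single(pos, x_oob)
                pred = omega > 0
                rep[j, 0] = int((pred & y_oob).sum())
                rep[j, 1] = int((pred & ~y_oob).sum())
                rep[j, 2] = int((~pred & y_oob).sum())
                rep[j, 3] = int((~pred & ~y_oob).sum())
        except (FitError, np.linalg.LinAlgError):
            # degenerate resample (e.g. duplicated rows make the subset
            # covariance singular): treat like a min_group violation
            redraws += 1
            if redraws > limit:
                raise FitError(
                    "bootstrap redraw limit exceeded; the cohort is too small "
                    "or too unbalanced — enlarge it or lower min_group"
                ) from None
            continue
        drawn += 1
        counts += rep
    tables = [_table_from_counts(*row) for row in counts]
    return tables, redraws


def combine_632(apparent: HitRates, oob: HitRates) -> HitRates:
    """Rate-wise convex combination 0.368·apparent + 0.632·out-of-bag."""
    def mix(app, o):
        if app is None or o is None:
            return None
        return 0.368 * app + 0.632 * o

    return HitRates(*(mix(a, o) for a, o in
                      zip(apparent.as_dict().values(), oob.as_dict().values())))


def boot632_rates(labeled, subset, cfg: Boot632Config,
                  covariance_mode: str = "pooled") -> HitRates:
    """.632-bootstrap-estimated hit rates for one subset."""
    subset = tuple(subset)
    x = labeled.cohort.feature_matrix(subset)
    y = labeled.difficult
    model = fit_nldr(labeled, subset, covariance_mode)
    apparent = hit_rates(confusion(model.classify(x), labeled.labels))
    oob_tables, _ = _oob_tables_multi(x, y, [list(range(len(subset)))],
                                      cfg, covariance_mode)
    return combine_632(apparent, hit_rates(oob_tables[0]))


@dataclass
class FunnelStageRow:
    mask: int
    names: tuple[str, ...]
    rates: HitRates


@dataclass
class FunnelReport:
    """Membership and rates of each selection stage."""

    search: SearchResult
    stage1_tier: list[int]
    predictors: tuple[str, ...] = PREDICTOR_NAMES
    stage2: list[FunnelStageRow] = field(default_factory=list)
    stage2_survivors: list[int] = field(default_factory=list)
    stage3: list[FunnelStageRow] = field(default_factory=list)
    winner_mask: int = 0
    cv_band_pp: float = 0.0

    def winner_names(self) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(self.predictors)
                     if self.winner_mask >> i & 1)

    def stage_frame(self, stage: int):
        import pandas as pd

        rows = self.stage2 if stage == 2 else self.stage3
        return pd.DataFrame(
            [{"mask": f"{r.mask:04x}", "names": "+".join(r.names),
              **r.rates.as_dict()} for r in rows]
        )


def select_final_model(labeled, cfg: Boot632Config,
                       cv_band_pp: float = 1.6,
                       covariance_mode: str = "pooled",
                       predictors: tuple[str, ...] = PREDICTOR_NAMES,
                       search: SearchResult | None = None
                       ) -> tuple[NLDRModel, FunnelReport]:
    """Run the three-stage funnel and fit the winning subset on all data.

    Stage 1: exhaustive apparent search → best-apparent tier (subsets with
    the identical best 2x2 table).  Stage 2: LOOCV on the tier; keep
    subsets whose CV total is within ``cv_band_pp`` percentage points of
    the best.  Stage 3: .632 estimator (shared resamples across survivors)
    → highest estimated total wins; ties prefer fewer variables, then the
    lower mask.  Subset masks are relative to ``predictors`` order.
    """
    predictors = tuple(predictors)
    p = len(predictors)
    x = labeled.cohort.feature_matrix(predictors)
    y = labeled.difficult
    if search is None:
        search = search_all(labeled, covariance_mode, predictors)
    tier = list(search.best_table_tier)

    def names_of(mask: int) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(predictors) if mask >> i & 1)

    report = FunnelReport(search=search, stage1_tier=tier,
                          predictors=predictors, cv_band_pp=cv_band_pp)

    positions = [_mask_positions(mk, p) for mk in tier]
    cv_tables = _loocv_tables_multi(x, y, positions, covariance_mode)
    cv_rates = [hit_rates(t) for t in cv_tables]
    report.stage2 = [FunnelStageRow(mk, names_of(mk), r)
                     for mk, r in zip(tier, cv_rates)]
    best_cv = max(r.total for r in cv_rates)
    survivors = [mk for mk, r in zip(tier, cv_rates)
                 if r.total >= best_cv - cv_band_pp]
    report.stage2_survivors = survivors

    surv_pos = [_mask_positions(mk, p) for mk in survivors]
    oob_tables, _ = _oob_tables_multi(x, y, surv_pos, cfg, covariance_mode)
    apparent_by_mask = {r.mask: r.apparent for r in search.results
                        if r.status == "ok"}
    est = [combine_632(apparent_by_mask[mk], hit_rates(t))
           for mk, t in zip(survivors, oob_tables)]
    report.stage3 = [FunnelStageRow(mk, names_of(mk), r)
                     for mk, r in zip(survivors, est)]
    winner = min(
        zip(survivors, est),
        key=lambda me: (-me[1].total, bin(me[0]).count("1"), me[0]),
    )[0]
    report.winner_mask = winner
    model = fit_nldr(labeled, names_of(winner), covariance_mode)
    return model, report
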