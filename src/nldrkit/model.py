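"""Normal-based linear discriminant rule (NLDR).

Two-class Gaussian classifier with a shared covariance matrix.  For a
feature vector x the discrimination index is

    Ω(x) = log(π1/π0) − ½ [ Δ(x; μ1, Σ) − Δ(x; μ0, Σ) ],

where Δ(x; μ, Σ) = (x−μ)ᵀ Σ⁻¹ (x−μ) is the squared Mahalanobis distance,
μ0/μ1 are the easy/difficult group means, and πi = ni/(n0+n1) are the
empirical priors.  A donor is assigned to the difficult group when Ω is
strictly positive (Ω = 0 resolves to easy — a fixed, measure-zero tie
rule).  Beyond the sign, |Ω| quantifies how strongly the donor resembles
one workload group.

Because Δ is a quadratic form with the *same* Σ for both groups, Ω is
affine in x:  Ω(x) = log(π1/π0) + wᵀx − ½ wᵀ(μ0+μ1) with w = Σ⁻¹(μ1−μ0);
the quadratic terms cancel.  Both forms are implemented and agree to
rounding error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

COVARIANCE_MODES = ("pooled", "total")

DIFFICULT = "difficult"
EASY = "easy"


class FitError(ValueError):
    """The labeled cohort cannot support an NLDR fit."""


class SingularCovarianceError(FitError):
    """The covariance matrix on the requested subset is singular."""


def mahalanobis_sq(x, mu, sigma) -> float:
    """Squared Mahalanobis distance (x−μ)ᵀ Σ⁻¹ (x−μ).

    Uses a Cholesky solve; Σ must be symmetric positive definite.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if x.shape != mu.shape or sigma.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, mu {mu.shape}, sigma {sigma.shape}"
        )
    d = x - mu
    try:
        factor = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("covariance matrix is not positive definite") from exc
    return float(d @ cho_solve(factor, d))


@dataclass
class NLDRModel:
    """A fitted NLDR: group means, shared covariance, priors, subset."""

    subset: tuple[str, ...]
    mu_easy: np.ndarray
    mu_difficult: np.ndarray
    sigma: np.ndarray
    n_easy: int
    n_difficult: int
    covariance_mode: str = "pooled"
    ridge: float = 0.0
    threshold_min: float | None = None

    @property
    def prior_easy(self) -> float:
        return self.n_easy / (self.n_easy + self.n_difficult)

    @property
    def prior_difficult(self) -> float:
        return self.n_difficult / (self.n_easy + self.n_difficult)

    @property
    def weights(self) -> np.ndarray:
        """w = Σ⁻¹ (μ1 − μ0), the linear discriminant direction."""
        factor = cho_factor(self.sigma, lower=True)
        return cho_solve(factor, self.mu_difficult - self.mu_easy)

    def _check(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = len(self.subset)
        if x.shape[-1] != p:
            raise ValueError(
                f"feature vector has {x.shape[-1]} components, model expects "
                f"{p} ({', '.join(self.subset)})"
            )
        if np.isnan(x).any():
            flat = np.atleast_2d(x)
            bad = sorted({self.subset[j] for j in np.where(np.isnan(flat))[1]})
            raise ValueError(f"missing feature value(s): {bad}")
        return x

    def discrimination_index(self, x) -> float | np.ndarray:
        """Ω(x); accepts one vector or a matrix of row vectors."""
        x = self._check(x)
        log_odds = np.log(self.prior_difficult / self.prior_easy)
        w = self.weights
        omega = log_odds + (x @ w) - 0.5 * (self.mu_easy + self.mu_difficult) @ w
        return float(omega) if np.ndim(omega) == 0 else omega

    def classify(self, x):
        """'difficult' iff Ω(x) > 0 (Ω = 0 → easy)."""
        omega = self.discrimination_index(x)
        if np.ndim(omega) == 0:
            return DIFFICULT if omega > 0 else EASY
        return np.where(omega > 0, DIFFICULT, EASY)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "mu_easy": self.mu_easy.tolist(),
            "mu_difficult": self.mu_difficult.tolist(),
            "sigma": self.sigma.tolist(),
            "n_easy": self.n_easy,
            "n_difficult": self.n_difficult,
            "covariance_mode": self.covariance_mode,
            "ridge": self.ridge,
            "threshold_min": self.threshold_min,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "NLDRModel":
        return cls(
            subset=tuple(d["subset"]),
            mu_easy=np.asarray(d["mu_easy"], dtype=float),
            mu_difficult=np.asarray(d["mu_difficult"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            n_easy=int(d["n_easy"]),
            n_difficult=int(d["n_difficult"]),
            covariance_mode=d.get("covariance_mode", "pooled"),
            ridge=float(d.get("ridge", 0.0)),
            threshold_min=d.get("threshold_min"),
        )

    @classmethod
    def load(cls, path) -> "NLDRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def shared_covariance(x0: np.ndarray, x1: np.ndarray, mode: str = "pooled") -> np.ndarray:
    """Shared covariance of the two groups.

    ``pooled``: within-group pooled estimate
    [(n0−1)S0 + (n1−1)S1]/(n0+n1−2) — the standard NLDR choice.
    ``total``: sample covariance of all vectors from both groups combined.
    """
    if mode == "pooled":
        n0, n1 = len(x0), len(x1)
        s0 = np.cov(x0, rowvar=False, ddof=1)
        s1 = np.cov(x1, rowvar=False, ddof=1)
        return ((n0 - 1) * np.atleast_2d(s0) + (n1 - 1) * np.atleast_2d(s1)) / (n0 + n1 - 2)
    if mode == "total":
        return np.atleast_2d(np.cov(np.vstack([x0, x1]), rowvar=False, ddof=1))
    raise ValueError(f"unknown covariance_mode {mode!r}; expected one of {COVARIANCE_MODES}")


def fit_nldr(labeled, subset, covariance_mode: str = "pooled",
             ridge: float = 0.0) -> NLDRModel:
    """Fit the NLDR on a labeled cohort restricted to a predictor subset.

    Both groups must have at least two members.  A singular covariance on
    the subset raises :class:`SingularCovarianceError` unless ``ridge`` > 0,
    in which case ridge·I is added (intended for degenerate synthetic tests,
    default off).
    """
    subset = tuple(subset)
    x = labeled.cohort.feature_matrix(subset)
    mask = labeled.difficult
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n0 < 2 or n1 < 2:
        raise FitError(
            f"each workload group needs >= 2 members (easy={n0}, difficult={n1})"
        )
    x0, x1 = x[~mask], x[mask]
    sigma = shared_covariance(x0, x1, covariance_mode)
    if ridge > 0:
        sigma = sigma + ridge * np.eye(len(subset))
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"singular covariance on subset {subset}; "
            "remove collinear/constant variables or set ridge > 0"
        ) from exc
    return NLDRModel(
        subset=subset,
        mu_easy=x0.mean(axis=0),
        mu_difficult=x1.mean(axis=0),
        sigma=sigma,
        n_easy=n0,
        n_difficult=n1,
        covariance_mode=covariance_mode,
        ridge=ridge,
        threshold_min=labeled.threshold_min,
    )


# -- 2x2 table and hit rates ----------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of the dichotomous prediction vs. the workload label.

    a: predicted difficult & difficult; b: predicted difficult & easy;
    c: predicted easy & difficult;      d: predicted easy & easy.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def confusion(predictions, labels) -> ConfusionTable:
    """Tally the 2x2 table from aligned prediction/label sequences."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {lab.shape}")
    pd_, ld = pred == DIFFICULT, lab == DIFFICULT
    return ConfusionTable(
        a=int((pd_ & ld).sum()),
        b=int((pd_ & ~ld).sum()),
        c=int((~pd_ & ld).sum()),
        d=int((~pd_ & ~ld).sum()),
    )


@dataclass(frozen=True)
class HitRates:
    """The five discrimination rates, as percentages.

    hrdc  — hit rate of difficult cases, A/(A+B): how often a "difficult"
            call is right.
    hrec  — hit rate of easy cases, D/(C+D): how often an "easy" call is
            right.
    sensitivity — A/(A+C); specificity — D/(B+D);
    total — (A+D)/n, the total hit rate (accuracy).

    A rate whose denominator is zero is undefined and reported as None.
    """

    hrdc: float | None
    hrec: float | None
    sensitivity: float | None
    specificity: float | None
    total: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "hrdc": self.hrdc, "hrec": self.hrec,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "total": self.total,
        }


def _pct(num: int | float, den: int | float) -> float | None:
    return 100.0 * num / den if den > 0 else None


def hit_rates(t: ConfusionTable) -> HitRates:
    """The five rates of a 2x2 workload table, in percent."""
    return HitRates(
        hrdc=_pct(t.a, t.a + t.b),
        hrec=_pct(t.d, t.c + t.d),
        sensitivity=_pct(t.a, t.a + t.c),
        specificity=_pct(t.d, t.b + t.d),
        total=_pct(t.a + t.d, t.n),
    )
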