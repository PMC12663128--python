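"""Inverse normal-rank transformation (INT) of per-cohort empirical CDFs.

Within each age cohort, raw scores are ranked (ties -> midranks), converted
to plotting-position probabilities by a configurable rank estimator, and
mapped through the normal quantile function onto the T scale (mean 50,
SD 10).  The result serves two roles: the manifest benchmark norm score
T_actual against which model predictions are judged, and the person-location
theta that the distribution-free Taylor-polynomial method regresses on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .datamodel import NormData

__all__ = ["RankConfig", "assign_cohorts", "ecdf_probability", "t_from_p", "p_from_t", "manifest_norms"]

# rank r in 1..n -> probability strictly inside (0,1)
_RANK_ESTIMATORS = {
    "rankit": lambda r, n: (r - 0.5) / n,
    "blom": lambda r, n: (r - 0.375) / (n + 0.25),
    "tukey": lambda r, n: (r - 1.0 / 3.0) / (n + 1.0 / 3.0),
    "vdw": lambda r, n: r / (n + 1.0),
}


@dataclass(frozen=True)
class RankConfig:
    rank_estimator: str = "rankit"
    tie_rule: str = "midrank"
    cohort_width: float = 1.0
    t_mean: float = 50.0
    t_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.rank_estimator not in _RANK_ESTIMATORS:
            raise ValueError(
                f"unknown rank estimator {self.rank_estimator!r}; "
                f"choose from {sorted(_RANK_ESTIMATORS)}"
            )
        if self.tie_rule != "midrank":
            raise ValueError("only the midrank tie rule is supported")
        if not self.cohort_width > 0:
            raise ValueError("cohort_width must be positive")


def assign_cohorts(ages, width: float = 1.0) -> np.ndarray:
    """Half-open cohort labels: age a -> floor(a / width), interval [k*w, (k+1)*w)."""
    if not width > 0:
        raise ValueError("cohort width must be positive")
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    return np.floor(ages / width).astype(int)


def ecdf_probability(scores, config: RankConfig = RankConfig()) -> np.ndarray:
    """Plotting-position probabilities for one cohort's scores (ties midranked)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("ecdf_probability requires a non-empty cohort")
    ranks = rankdata(scores, method="average")
    p = _RANK_ESTIMATORS[config.rank_estimator](ranks, scores.size)
    assert np.all((p > 0) & (p < 1))
    return p


def t_from_p(p, config: RankConfig = RankConfig()) -> np.ndarray:
    """T score from cumulative probability: T = t_mean + t_sd * Phi^-1(p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return config.t_mean + config.t_sd * norm.ppf(p)


def p_from_t(t, config: RankConfig = RankConfig()) -> np.ndarray:
    """Inverse of :func:`t_from_p`."""
    t = np.asarray(t, dtype=float)
    return norm.cdf((t - config.t_mean) / config.t_sd)


def manifest_norms(data: NormData, config: RankConfig = RankConfig()) -> np.ndarray:
    """Per-record manifest T scores (T_actual), aligned to record order.

    Each cohort is ranked independently; cohort processing order cannot
    affect the result.
    """
    labels = assign_cohorts(data.ages, config.cohort_width)
    out = np.empty(data.n, dtype=float)
    for lab in np.unique(labels):
        mask = labels == lab
        out[mask] = t_from_p(ecdf_probability(data.scores[mask], config), config)
    return out
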