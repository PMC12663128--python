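"""Synthetic biometric samples with known ground-truth percentiles.

Raw scores are drawn from age-varying Box–Cox (skew-normal) laws defined by
smooth polynomial trajectories L(t), M(t), S(t): a standard-normal deviate z
is mapped to a raw score through the inverse Box–Cox transform

    y = M(t) * (1 + L(t) S(t) z)^(1/L(t))        (L != 0)
    y = M(t) * exp(S(t) z)                        (L  = 0)

so every simulated person carries an exact true percentile Phi(z).  Optional
floor/ceiling censoring deliberately breaks the parametric assumption the
LMS method relies on, emulating limited-range instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial import Polynomial
from scipy.stats import norm

from .datamodel import InvariantError, NormData, norm_data_from_arrays

__all__ = [
    "TrueCurves",
    "DistortionSpec",
    "generate_sample",
    "true_percentile",
    "preset_bmi_like",
    "preset_vo2max_like",
]

# below this magnitude L(t) is treated as zero (log-normal branch); keeps the
# L -> 0 limit of the power transform numerically continuous
_L_EPS = 1e-8
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class TrueCurves:
    """Generative L(t), M(t), S(t) trajectories as low-degree polynomials."""

    L_coeffs: tuple[float, ...]
    M_coeffs: tuple[float, ...]
    S_coeffs: tuple[float, ...]
    age_min: float
    age_max: float

    def __post_init__(self) -> None:
        grid = np.linspace(self.age_min, self.age_max, 200)
        for name, vals in (("L", self.L(grid)), ("M", self.M(grid)), ("S", self.S(grid))):
            if not np.all(np.isfinite(vals)):
                raise InvariantError(f"{name}(t) not finite on the age range")
        if np.any(self.M(grid) <= 0):
            raise InvariantError("M(t) must be strictly positive on the age range")
        if np.any(self.S(grid) <= 0):
            raise InvariantError("S(t) must be strictly positive on the age range")

    def L(self, t):
        return Polynomial(self.L_coeffs)(np.asarray(t, dtype=float))

    def M(self, t):
        return Polynomial(self.M_coeffs)(np.asarray(t, dtype=float))

    def S(self, t):
        return Polynomial(self.S_coeffs)(np.asarray(t, dtype=float))


@dataclass(frozen=True)
class DistortionSpec:
    """Floor/ceiling censoring bounds applied to generated raw scores."""

    floor: Optional[float] = None
    ceiling: Optional[float] = None

    def __post_init__(self) -> None:
        if self.floor is not None and self.ceiling is not None and not self.floor < self.ceiling:
            raise InvariantError("DistortionSpec requires floor < ceiling")


def _raw_from_z(L: np.ndarray, M: np.ndarray, S: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Inverse Box–Cox map from standard-normal deviates to raw scores."""
    L = np.asarray(L, dtype=float)
    zero = np.abs(L) < _L_EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        base = 1.0 + L * S * z
        safe = np.where(~zero & (base > 0), base, 1.0)
        y = np.where(zero, M * np.exp(S * z), M * safe ** (1.0 / np.where(zero, 1.0, L)))
    return np.where(~zero & (base <= 0), np.nan, y)


def generate_sample(
    curves: TrueCurves,
    n_per_cohort: int,
    seed: int,
    distortion: Optional[DistortionSpec] = None,
) -> tuple[NormData, np.ndarray]:
    """Draw an age-cohort-structured sample from the true curves.

    One-year cohorts cover ``[age_min, age_max)``; within each cohort ages are
    uniform and z ~ N(0,1).  Deviates for which the Box–Cox power argument
    ``1 + L S z`` is non-positive are redrawn (the sample space of the
    transform is truncated there), with a cap of 100 redraws per record.

    Returns the sample and the per-record true percentile Phi(z), recorded
    *before* any floor/ceiling censoring.
    """
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    rng = np.random.default_rng(seed)
    starts = np.arange(math.floor(curves.age_min), math.ceil(curves.age_max))
    starts = starts[(starts >= curves.age_min - 1e-12) & (starts < curves.age_max)]
    ages_all, y_all, p_all = [], [], []
    for lo in starts:
        hi = min(lo + 1.0, curves.age_max)
        ages = rng.uniform(lo, hi, size=n_per_cohort)
        L, M, S = curves.L(ages), curves.M(ages), curves.S(ages)
        z = rng.standard_normal(n_per_cohort)
        y = _raw_from_z(L, M, S, z)
        for _ in range(_MAX_REDRAWS):
            bad = ~np.isfinite(y)
            if not bad.any():
                break
            z[bad] = rng.standard_normal(int(bad.sum()))
            y[bad] = _raw_from_z(L[bad], M[bad], S[bad], z[bad])
        else:
            if not np.all(np.isfinite(y)):
                raise RuntimeError(
                    "could not draw a valid Box-Cox deviate within the redraw cap; "
                    "the curves imply an extremely truncated sample space"
                )
        ages_all.append(ages)
        y_all.append(y)
        p_all.append(norm.cdf(z))
    ages = np.concatenate(ages_all)
    y = np.concatenate(y_all)
    p_true = np.concatenate(p_all)
    if distortion is not None:
        if distortion.floor is not None:
            y = np.maximum(y, distortion.floor)
        if distortion.ceiling is not None:
            y = np.minimum(y, distortion.ceiling)
    data = norm_data_from_arrays(
        ages, y, measure_name="synthetic", age_range=(curves.age_min, curves.age_max)
    )
    return data, p_true


def true_percentile(curves: TrueCurves, y, t):
    """Exact percentile of raw score ``y`` at age ``t`` under the true curves."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(y <= 0):
        raise ValueError("raw score must be strictly positive")
    L, M, S = curves.L(t), curves.M(t), curves.S(t)
    zero = np.abs(L) < _L_EPS
    with np.errstate(divide="ignore"):
        z = np.where(
            zero,
            np.log(y / M) / S,
            ((y / M) ** np.where(zero, 1.0, L) - 1.0) / (np.where(zero, 1.0, L) * S),
        )
    return norm.cdf(z)


def preset_bmi_like() -> TrueCurves:
    """Positively skewed, BMI-like truth over ages 5-19.

    Median rises from ~16 to ~21 kg/m^2, skewness L is negative (right tail),
    relative spread S grows mildly with age.  Shapes are generic pediatric-BMI
    stylizations, not estimates from any real cohort.
    """
    # expanded from M(t) = 16 + 0.1 (t-5) + 0.02 (t-5)^2 etc.
    return TrueCurves(
        L_coeffs=(-1.85, 0.05),            # L: -1.6 at age 5 -> -0.9 at 19
        M_coeffs=(16.0, -0.1, 0.02),       # M: 16.0 at 5 -> 21.3 at 19
        S_coeffs=(0.09, 0.004),            # S: 0.11 at 5 -> 0.166 at 19
        age_min=5.0,
        age_max=19.0,
    )


def preset_vo2max_like() -> TrueCurves:
    """Near-symmetric, VO2max-like truth over ages 12-19 (ml/kg/min).

    Median drifts down slowly with age; distribution close to normal (L near
    1), constant relative spread.  Not a claim about any real cohort.
    """
    return TrueCurves(
        L_coeffs=(0.8,),
        M_coeffs=(45.6, -0.3),             # 42.0 at age 12 -> 39.9 at 19
        S_coeffs=(0.18,),
        age_min=12.0,
        age_max=19.0,
    )
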