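"""Distribution-free continuous norming via two-dimensional Taylor polynomials.

Raw scores r are regressed on powers and cross-products of the person
location theta (the within-cohort normal-rank norm score, on the T scale)
and the explanatory variable a (age):

    E(r | theta, a) = sum_{i=0..k} sum_{j=0..t} c_ij theta^i a^j

with k = 5 and t = 3 by default, giving (k+1)(t+1) = 24 candidate terms.
Terms are chosen by exact best-subset least squares per model size; the
smallest model reaching the in-sample R^2 target that also passes a
coherence check (predicted raw score strictly increasing in theta over the
norm-score range, i.e. centiles cannot cross) is retained.  Norm scores for
new raw scores are recovered by numerically inverting the fitted polynomial
in theta at the person's exact age.

Theta and age are affinely standardized before powering; this leaves the
polynomial model class unchanged while keeping the design matrix
well-conditioned.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .datamodel import NormData, NormTable
from .ranking import RankConfig, manifest_norms, t_from_p

logger = logging.getLogger(__name__)

__all__ = [
    "CNormConfig",
    "CNormModel",
    "BestSubsetResult",
    "CoherenceReport",
    "build_design_matrix",
    "best_subset_fit",
    "coherence_check",
    "fit_cnorm",
    "predict_raw",
    "predict_norm",
    "norm_table_cnorm",
]

# inversion / coherence domain on the T scale: +/- 3 SD around the mean of 50
_THETA_LO, _THETA_HI = 20.0, 80.0


@dataclass(frozen=True)
class CNormConfig:
    k: int = 5                     # max power of location theta
    t_power: int = 3               # max power of age
    max_terms: int = 8             # cap on selected non-intercept terms
    r2_target: float = 0.99
    coherence_grid: tuple[int, int] = (25, 41)   # (n_ages, n_thetas)
    inversion_tol: float = 1e-6    # T-units
    theta_scale: Optional[tuple[float, float]] = None  # (center, sd); fit-time default
    age_scale: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.t_power < 0:
            raise ValueError("require k >= 1 and t_power >= 0")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")

    @property
    def n_candidates(self) -> int:
        return (self.k + 1) * (self.t_power + 1)


def term_order(k: int, t_power: int) -> list[tuple[int, int]]:
    """Fixed column order of the design matrix: (i, j) with i (theta power)
    major, j (age power) minor; (0, 0) is the intercept."""
    return [(i, j) for i in range(k + 1) for j in range(t_power + 1)]


def build_design_matrix(
    thetas, ages, config: CNormConfig = CNormConfig()
) -> np.ndarray:
    """Design matrix of standardized theta^i * age^j columns, (k+1)(t+1) wide."""
    thetas = np.asarray(thetas, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if thetas.shape != ages.shape:
        raise ValueError("thetas and ages must have the same length")
    tc, ts = config.theta_scale if config.theta_scale else (50.0, 10.0)
    ac, asd = config.age_scale if config.age_scale else (float(np.mean(ages)), float(np.std(ages)) or 1.0)
    th = (thetas - tc) / ts
    ag = (ages - ac) / asd
    cols = [th ** i * ag ** j for i, j in term_order(config.k, config.t_power)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class BestSubsetResult:
    """Best least-squares model of one size (intercept always included)."""

    size: int
    term_indices: tuple[int, ...]   # column indices into the design matrix
    coefficients: np.ndarray        # aligned with (intercept,) + term_indices
    rss: float
    r2: float


def _batched_subset_rss(
    G: np.ndarray, Xty: np.ndarray, yty: float, subsets: np.ndarray, icpt: int
) -> tuple[np.ndarray, np.ndarray]:
    """RSS and coefficients for every subset (rows of ``subsets`` are column
    indices, intercept prepended) via stacked normal-equation solves."""
    full = np.concatenate(
        [np.full((subsets.shape[0], 1), icpt, dtype=int), subsets], axis=1
    )
    A = G[full[:, :, None], full[:, None, :]]
    b = Xty[full]
    coefs = np.linalg.solve(A, b[..., None])[..., 0]
    rss = yty - np.einsum("ij,ij->i", coefs, b)
    return np.maximum(rss, 0.0), coefs


def best_subset_fit(
    design: np.ndarray,
    responses: np.ndarray,
    sizes: Sequence[int],
    intercept_index: int = 0,
) -> list[BestSubsetResult]:
    """Exact best-subset least squares: for each size s, the s non-intercept
    columns (plus the always-included intercept) minimizing the residual sum
    of squares, found by exhaustive search over all subsets.

    The search is exact (guaranteed optimum per size) for the default
    candidate counts; rank-deficient subsets are skipped with a warning.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(responses, dtype=float)
    n, p = X.shape
    if n <= max(sizes) + 1:
        raise ValueError("need more rows than the largest subset size + intercept")
    cand = [j for j in range(p) if j != intercept_index]
    G = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ybar = float(np.mean(y))
    sst = float(np.sum((y - ybar) ** 2))
    results: list[BestSubsetResult] = []
    for s in sizes:
        if s > len(cand):
            break
        best_rss, best_sub, best_coef = np.inf, None, None
        combos = itertools.combinations(range(len(cand)), s)
        cand_arr = np.asarray(cand)
        chunk = 100_000
        while True:
            block = np.fromiter(
                itertools.chain.from_iterable(itertools.islice(combos, chunk)),
                dtype=int,
            ).reshape(-1, s)
            if block.size == 0:
                break
            subs = cand_arr[block]
            try:
                rss, coefs = _batched_subset_rss(G, Xty, yty, subs, intercept_index)
            except np.linalg.LinAlgError:
                rss = np.empty(subs.shape[0])
                coefs = np.zeros((subs.shape[0], s + 1))
                for r in range(subs.shape[0]):
                    try:
                        rss_r, coef_r = _batched_subset_rss(
                            G, Xty, yty, subs[r:r + 1], intercept_index
                        )
                        rss[r], coefs[r] = rss_r[0], coef_r[0]
                    except np.linalg.LinAlgError:
                        rss[r] = np.inf
                        logger.warning("skipping rank-deficient subset %s", subs[r])
            i = int(np.argmin(rss))
            if rss[i] < best_rss:
                best_rss = float(rss[i])
                best_sub = tuple(int(c) for c in subs[i])
                best_coef = coefs[i].copy()
            if block.shape[0] < chunk:
                break
        if best_sub is None:
            continue
        r2 = 1.0 - best_rss / sst if sst > 0 else 0.0
        results.append(
            BestSubsetResult(
                size=s,
                term_indices=best_sub,
                coefficients=best_coef,
                rss=best_rss,
                r2=max(0.0, min(1.0, r2)),
            )
        )
    return results


@dataclass(frozen=True)
class CNormModel:
    """Selected Taylor-polynomial terms with coefficients.

    ``terms`` maps exponent pairs (i, j) to weights c_ij; (0, 0) is the
    intercept.  ``theta_scale`` / ``age_scale`` are the affine (center, sd)
    standardizations applied before powering.
    """

    terms: tuple[tuple[int, int], ...]
    coefficients: np.ndarray
    theta_scale: tuple[float, float]
    age_scale: tuple[float, float]
    age_range: tuple[float, float]
    score_range: tuple[float, float]
    k: int = 5
    t_power: int = 3
    coherence_passed: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for (i, j) in self.terms:
            if not (0 <= i <= self.k and 0 <= j <= self.t_power):
                raise ValueError(f"term ({i},{j}) outside the (k={self.k}, t={self.t_power}) grid")
            if (i, j) in seen:
                raise ValueError(f"term ({i},{j}) listed twice")
            seen.add((i, j))

    def to_dict(self) -> dict:
        """JSON-serializable representation (terms, scalings, diagnostics)."""
        return {
            "model": "cnorm",
            "terms": [list(t) for t in self.terms],
            "coefficients": np.asarray(self.coefficients).tolist(),
            "theta_scale": list(self.theta_scale),
            "age_scale": list(self.age_scale),
            "age_range": list(self.age_range),
            "score_range": list(self.score_range),
            "k": self.k,
            "t_power": self.t_power,
            "coherence_passed": self.coherence_passed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNormModel":
        return cls(
            terms=tuple((int(i), int(j)) for i, j in d["terms"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            theta_scale=tuple(d["theta_scale"]),
            age_scale=tuple(d["age_scale"]),
            age_range=tuple(d["age_range"]),
            score_range=tuple(d["score_range"]),
            k=int(d["k"]),
            t_power=int(d["t_power"]),
            coherence_passed=bool(d["coherence_passed"]),
        )


def predict_raw(model: CNormModel, theta, age):
    """Expected raw score at location theta (T scale) and age: the fitted
    polynomial sum c_ij theta_std^i age_std^j."""
    theta = np.asarray(theta, dtype=float)
    age = np.asarray(age, dtype=float)
    tc, ts = model.theta_scale
    ac, asd = model.age_scale
    th = (theta - tc) / ts
    ag = (age - ac) / asd
    out = np.zeros(np.broadcast(th, ag).shape)
    for (i, j), c in zip(model.terms, model.coefficients):
        out = out + c * th ** i * ag ** j
    return out if out.ndim else float(out)


def _dr_dtheta(model: CNormModel, theta, age):
    """Analytic partial derivative of the fitted polynomial w.r.t. theta."""
    theta = np.asarray(theta, dtype=float)
    age = np.asarray(age, dtype=float)
    tc, ts = model.theta_scale
    ac, asd = model.age_scale
    th = (theta - tc) / ts
    ag = (age - ac) / asd
    out = np.zeros(np.broadcast(th, ag).shape)
    for (i, j), c in zip(model.terms, model.coefficients):
        if i >= 1:
            out = out + c * i * th ** (i - 1) * ag ** j / ts
    return out


@dataclass(frozen=True)
class CoherenceReport:
    passed: bool
    min_derivative: float
    violations: tuple[tuple[float, float], ...]  # (age, theta) grid points


def coherence_check(model: CNormModel, config: CNormConfig = CNormConfig()) -> CoherenceReport:
    """Verify that the predicted raw score increases strictly with theta on a
    grid over the observed age range × theta in [20, 80] (T scale, ±3 SD);
    equivalently that extracted centile curves cannot cross."""
    n_ages, n_thetas = config.coherence_grid
    ages = np.linspace(model.age_range[0], model.age_range[1], n_ages)
    thetas = np.linspace(_THETA_LO, _THETA_HI, n_thetas)
    A, T = np.meshgrid(ages, thetas, indexing="ij")
    d = _dr_dtheta(model, T, A)
    bad = d <= 0
    violations = tuple(zip(A[bad].tolist(), T[bad].tolist()))
    return CoherenceReport(
        passed=not bad.any(),
        min_derivative=float(d.min()),
        violations=violations[:100],
    )


def fit_cnorm(
    data: NormData,
    config: CNormConfig = CNormConfig(),
    rank_config: RankConfig = RankConfig(),
) -> CNormModel:
    """Full distribution-free pipeline: cohort ranking -> theta (T scale) ->
    polynomial design -> exact best-subset fits of size 1..max_terms ->
    selection of the smallest size with R^2 >= target that passes the
    coherence check.

    Falls back to the highest-R^2 coherent model of any size; if no size is
    coherent, the best-R^2 model is returned flagged ``coherence_passed=False``
    (with a prominent warning) and cannot be inverted.
    """
    if data.n < config.max_terms + 2:
        raise ValueError(
            f"need at least max_terms + 2 = {config.max_terms + 2} records, got {data.n}"
        )
    theta = manifest_norms(data, rank_config)
    ages = data.ages
    scale_cfg = CNormConfig(
        k=config.k,
        t_power=config.t_power,
        max_terms=config.max_terms,
        r2_target=config.r2_target,
        coherence_grid=config.coherence_grid,
        inversion_tol=config.inversion_tol,
        theta_scale=config.theta_scale or (50.0, 10.0),
        age_scale=config.age_scale
        or (float(np.mean(ages)), float(np.std(ages)) or 1.0),
    )
    X = build_design_matrix(theta, ages, scale_cfg)
    order = term_order(config.k, config.t_power)
    icpt = order.index((0, 0))
    fits = best_subset_fit(X, data.scores, sizes=range(1, config.max_terms + 1), intercept_index=icpt)

    def to_model(fit: BestSubsetResult, passed: bool, diagnostics: dict) -> CNormModel:
        idx = (icpt,) + fit.term_indices
        return CNormModel(
            terms=tuple(order[c] for c in idx),
            coefficients=np.asarray(fit.coefficients, dtype=float),
            theta_scale=scale_cfg.theta_scale,
            age_scale=scale_cfg.age_scale,
            age_range=(float(ages.min()), float(ages.max())),
            score_range=(float(data.scores.min()), float(data.scores.max())),
            k=config.k,
            t_power=config.t_power,
            coherence_passed=passed,
            diagnostics=diagnostics,
        )

    r2_by_size = {f.size: f.r2 for f in fits}
    coherent: list[tuple[BestSubsetResult, CoherenceReport]] = []
    for fit in fits:  # ascending size
        model = to_model(fit, True, {})
        report = coherence_check(model, scale_cfg)
        if report.passed:
            coherent.append((fit, report))
            if fit.r2 >= config.r2_target:
                return to_model(
                    fit, True,
                    {"r2_by_size": r2_by_size, "selected_size": fit.size,
                     "selection": "smallest size meeting R2 target", "r2": fit.r2},
                )
    if coherent:
        fit, _ = max(coherent, key=lambda fr: fr[0].r2)
        return to_model(
            fit, True,
            {"r2_by_size": r2_by_size, "selected_size": fit.size,
             "selection": "best R2 among coherent sizes (target unmet)", "r2": fit.r2},
        )
    fit = max(fits, key=lambda f: f.r2)
    logger.warning(
        "no candidate model passes the coherence check; returning the best-R2 "
        "model (size %d, R2=%.4f) flagged coherence_passed=False — norm-score "
        "inversion is disabled for this model", fit.size, fit.r2,
    )
    return to_model(
        fit, False,
        {"r2_by_size": r2_by_size, "selected_size": fit.size,
         "selection": "no coherent model", "r2": fit.r2},
    )


def predict_norm(
    model: CNormModel,
    y,
    age,
    config: CNormConfig = CNormConfig(),
    return_flags: bool = False,
):
    """Invert the fitted polynomial: the theta* in [20, 80] whose predicted
    raw score equals y at the given age.

    Raw scores outside the model's range at that age are clamped to the
    boundary norm score (20 or 80) and flagged ``below`` / ``above``; if root
    bracketing fails (non-monotone numerics), a dense-grid least-squares
    search (0.01 T-unit step) is used and flagged ``fallback``.
    """
    if not model.coherence_passed:
        raise RuntimeError("model failed the coherence check; inversion refused")
    scalar_input = np.ndim(y) == 0
    y = np.atleast_1d(np.asarray(y, dtype=float))
    age = np.broadcast_to(np.asarray(age, dtype=float), y.shape).astype(float)
    out = np.empty(y.shape)
    flags = np.full(y.shape, "ok", dtype=object)
    grid = np.arange(_THETA_LO, _THETA_HI + 0.005, 0.01)
    for idx in np.ndindex(y.shape):
        f_lo = predict_raw(model, _THETA_LO, age[idx]) - y[idx]
        f_hi = predict_raw(model, _THETA_HI, age[idx]) - y[idx]
        if f_lo >= 0.0:
            out[idx], flags[idx] = _THETA_LO, ("ok" if f_lo == 0.0 else "below")
        elif f_hi <= 0.0:
            out[idx], flags[idx] = _THETA_HI, ("ok" if f_hi == 0.0 else "above")
        else:
            try:
                out[idx] = brentq(
                    lambda th: predict_raw(model, th, age[idx]) - y[idx],
                    _THETA_LO, _THETA_HI, xtol=config.inversion_tol,
                )
            except ValueError:
                vals = predict_raw(model, grid, np.full(grid.shape, age[idx]))
                out[idx] = grid[int(np.argmin((vals - y[idx]) ** 2))]
                flags[idx] = "fallback"
    if scalar_input:
        return (float(out[0]), str(flags[0])) if return_flags else float(out[0])
    if return_flags:
        return out, flags
    return out


def norm_table_cnorm(
    model: CNormModel, ages, percentiles, generated_by: str = "cnorm",
    rank_config: RankConfig = RankConfig(),
) -> NormTable:
    """Export raw-score cut-offs on an age × percentile grid from a coherent
    polynomial model (cut-off = predicted raw score at the percentile's T)."""
    if not model.coherence_passed:
        raise RuntimeError("model failed the coherence check; refusing table export")
    ages = np.asarray(ages, dtype=float)
    percentiles = np.asarray(percentiles, dtype=float)
    cutoffs = np.column_stack(
        [
            predict_raw(model, np.full(ages.shape, float(t_from_p(p, rank_config))), ages)
            for p in percentiles
        ]
    )
    return NormTable(
        ages=ages, percentiles=percentiles, cutoffs=cutoffs,
        method="CNORM", generated_by=generated_by,
    )
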