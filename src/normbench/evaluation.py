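"""Cross-validated comparison of the two norming methods.

Protocol: the benchmark norm score T_actual is computed once per dataset by
inverse normal-rank transformation of the complete sample's per-cohort
empirical CDF.  For every repetition and training size, a stratified random
split draws n cases per one-year age cohort into the training set; each
method is fitted on the training set only and predicts T scores for the
held-out test records.  Accuracy is summarized as

    RMSE = sqrt(mean((T_actual - T_predicted)^2))
    Bias = mean(T_actual - T_predicted)

plus R^2 (squared Pearson correlation), computed over the full test set and
separately in the extreme ranges: T_actual <= 30 (at or below -2 SD) and
T_actual >= 70 (at or above +2 SD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cnorm as cnorm_mod
from . import lms as lms_mod
from .datamodel import NormData
from .ranking import RankConfig, assign_cohorts, manifest_norms

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "RunResult",
    "stratified_split",
    "rmse",
    "bias",
    "r_squared",
    "region_masks",
    "run_comparison",
    "summarize",
    "results_to_frame",
]

REGIONS = ("full", "lower", "upper")


@dataclass(frozen=True)
class SplitSpec:
    """Training sizes (cases per age cohort), repetition count and seed base."""

    sizes: tuple[int, ...] = (50, 100, 150, 200)
    repetitions: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValueError("every training size must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class RunResult:
    """Metrics of one (method, size, repetition, region) cell."""

    method: str
    n_per_cohort: int
    repetition: int
    region: str
    rmse: float
    bias: float
    bias_squared: float
    r2: float
    n_test: int
    seed: int
    error: Optional[str] = None


def stratified_split(
    data: NormData, n_per_cohort: int, seed: int, cohort_width: float = 1.0
) -> tuple[NormData, NormData]:
    """Draw exactly n_per_cohort records per age cohort (without replacement)
    into the training set; the remainder is the test set.  Reproducible per
    seed; errors name any cohort too small to leave at least one test case."""
    labels = assign_cohorts(data.ages, cohort_width)
    rng = np.random.default_rng(seed)
    index = data.frame.index.to_numpy()
    train_idx = []
    for lab in np.unique(labels):
        pool = index[labels == lab]
        if pool.size <= n_per_cohort:
            raise ValueError(
                f"cohort {lab} has {pool.size} record(s); needs more than "
                f"n_per_cohort={n_per_cohort} to split"
            )
        train_idx.append(rng.choice(pool, size=n_per_cohort, replace=False))
    train_idx = np.concatenate(train_idx)
    mask = np.isin(index, train_idx)
    return data.subset(index[mask]), data.subset(index[~mask])


def _paired(actual, predicted):
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have the same length")
    return actual, predicted


def rmse(actual, predicted) -> float:
    """Root mean square error, Eq.: sqrt(mean((actual - predicted)^2))."""
    actual, predicted = _paired(actual, predicted)
    if actual.size == 0:
        return math.nan
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def bias(actual, predicted) -> float:
    """Mean signed error, actual minus predicted."""
    actual, predicted = _paired(actual, predicted)
    if actual.size == 0:
        return math.nan
    return float(np.mean(actual - predicted))


def r_squared(actual, predicted) -> float:
    """Squared Pearson correlation (affine-invariant); NaN when undefined."""
    actual, predicted = _paired(actual, predicted)
    if actual.size < 2:
        return math.nan
    if np.std(actual) == 0 or np.std(predicted) == 0:
        return math.nan
    r = np.corrcoef(actual, predicted)[0, 1]
    return float(r * r)


def region_masks(t_actual) -> dict[str, np.ndarray]:
    """Boolean masks for the full range and the inclusive ±2 SD tails on the
    T scale: lower = T <= 30, upper = T >= 70."""
    t = np.asarray(t_actual, dtype=float)
    return {
        "full": np.ones(t.shape, dtype=bool),
        "lower": t <= 30.0,
        "upper": t >= 70.0,
    }


def _metrics_for_run(
    method: str, size: int, rep: int, seed: int,
    t_actual: np.ndarray, t_pred: np.ndarray,
) -> list[RunResult]:
    rows = []
    for region, mask in region_masks(t_actual).items():
        a, p = t_actual[mask], t_pred[mask]
        b = bias(a, p)
        rows.append(
            RunResult(
                method=method, n_per_cohort=size, repetition=rep, region=region,
                rmse=rmse(a, p), bias=b,
                bias_squared=(b * b if not math.isnan(b) else math.nan),
                r2=r_squared(a, p), n_test=int(mask.sum()), seed=seed,
            )
        )
    return rows


def run_comparison(
    data: NormData,
    spec: SplitSpec,
    methods: Sequence[str] = ("lms", "cnorm"),
    lms_config: Optional["lms_mod.LMSFitConfig"] = None,
    cnorm_config: Optional["cnorm_mod.CNormConfig"] = None,
    rank_config: RankConfig = RankConfig(),
) -> list[RunResult]:
    """Run the full repeated stratified-sampling comparison.

    T_actual is derived once from the complete dataset (the manifest
    benchmark) and looked up for test records; each method sees only the
    training data.  Failed fits are recorded as rows with NaN metrics and an
    error message — the sweep never aborts.  Repetition r uses seed
    base_seed + r.
    """
    lms_config = lms_config or lms_mod.LMSFitConfig()
    cnorm_config = cnorm_config or cnorm_mod.CNormConfig()
    t_actual_all = pd.Series(manifest_norms(data, rank_config), index=data.frame.index)
    results: list[RunResult] = []
    for rep in range(spec.repetitions):
        seed = spec.base_seed + rep
        for size in spec.sizes:
            train, test = stratified_split(data, size, seed, rank_config.cohort_width)
            t_actual = t_actual_all.loc[test.frame.index].to_numpy()
            for method in methods:
                try:
                    if method.lower() == "lms":
                        model = lms_mod.fit_lms(train, lms_config)
                        t_pred = np.asarray(
                            lms_mod.predict_t_lms(model, test.scores, test.ages)
                        )
                    elif method.lower() == "cnorm":
                        cmodel = cnorm_mod.fit_cnorm(train, cnorm_config, rank_config)
                        t_pred = predict_t_cnorm(cmodel, test, cnorm_config)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                except Exception as exc:  # noqa: BLE001 — sweep must survive fit failures
                    logger.warning(
                        "run failed (method=%s size=%d rep=%d): %s", method, size, rep, exc
                    )
                    for region in REGIONS:
                        results.append(
                            RunResult(
                                method=method, n_per_cohort=size, repetition=rep,
                                region=region, rmse=math.nan, bias=math.nan,
                                bias_squared=math.nan, r2=math.nan, n_test=0,
                                seed=seed, error=str(exc),
                            )
                        )
                    continue
                results.extend(
                    _metrics_for_run(method, size, rep, seed, t_actual, t_pred)
                )
    return results


def predict_t_cnorm(
    model: "cnorm_mod.CNormModel", test: NormData, config: Optional["cnorm_mod.CNormConfig"] = None
) -> np.ndarray:
    """T-score predictions for test records from a fitted polynomial model."""
    config = config or cnorm_mod.CNormConfig()
    return np.asarray(cnorm_mod.predict_norm(model, test.scores, test.ages, config))


def results_to_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    """Flat DataFrame of run results (one row per run × region)."""
    return pd.DataFrame([vars(r) for r in results])


def summarize(results: Sequence[RunResult]) -> pd.DataFrame:
    """Mean and standard error of each metric per (method, size, region).

    NaN rows (failed fits / empty regions) are excluded per metric; the SE is
    the standard deviation across repetitions divided by sqrt(#repetitions).
    """
    frame = results_to_frame(results)
    if frame.empty:
        raise ValueError("no results to summarize")

    def _agg(g: pd.Series) -> pd.Series:
        vals = g.dropna()
        n = len(vals)
        return pd.Series(
            {
                "mean": vals.mean() if n else math.nan,
                "se": (vals.std(ddof=1) / math.sqrt(n)) if n > 1 else (0.0 if n == 1 else math.nan),
            }
        )

    out = []
    for (method, size, region), g in frame.groupby(["method", "n_per_cohort", "region"]):
        row = {"method": method, "n_per_cohort": size, "region": region,
               "n_runs": len(g), "n_failed": int(g["error"].notna().sum())}
        for metric in ("rmse", "bias", "bias_squared", "r2"):
            agg = _agg(g[metric])
            row[f"{metric}_mean"] = agg["mean"]
            row[f"{metric}_se"] = agg["se"]
        out.append(row)
    return pd.DataFrame(out).sort_values(["method", "n_per_cohort", "region"]).reset_index(drop=True)
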