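"""Shared data model, validation rules and CSV I/O.

Everything downstream (simulation, ranking, both norming methods, the
comparison harness) consumes :class:`NormData` — one row per person with a
decimal age, a raw score and an optional group label — and produces
:class:`NormTable` grids of age × percentile raw-score cut-offs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NormData",
    "NormTable",
    "Violation",
    "ConfigurationError",
    "EmptyDataError",
    "InvariantError",
    "read_norm_data",
    "write_norm_data",
    "validate_for_method",
    "write_norm_table",
    "read_norm_table",
]


class ConfigurationError(ValueError):
    """A named column or configuration value is missing or malformed."""


class EmptyDataError(ValueError):
    """No usable records remain after filtering."""


class InvariantError(ValueError):
    """A structural invariant of a data container is violated."""


@dataclass(frozen=True)
class NormData:
    """Person-level records: age in decimal years, raw score, group label.

    Parameters
    ----------
    frame
        DataFrame with columns ``age`` (decimal years, >= 0), ``score``
        (real) and ``group`` (categorical label; ``"all"`` when absent).
        The index is preserved so that subsets keep their identity across
        train/test splits.
    measure_name, score_unit
        Metadata describing the raw score (e.g. BMI in kg/m^2).
    """

    frame: pd.DataFrame
    measure_name: str = "score"
    score_unit: str = ""
    age_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        required = {"age", "score", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"NormData frame lacks columns: {sorted(missing)}")
        if len(self.frame) < 1:
            raise EmptyDataError("NormData requires at least one record")
        ages = self.frame["age"].to_numpy(dtype=float)
        scores = self.frame["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(scores)):
            raise InvariantError("NormData records must have finite age and score")
        if np.any(ages < 0):
            raise InvariantError("ages must be non-negative")
        if self.age_range is None:
            object.__setattr__(self, "age_range", (float(ages.min()), float(ages.max())))
        lo, hi = self.age_range
        if ages.min() < lo or ages.max() > hi:
            raise InvariantError(
                f"age_range {self.age_range} does not bracket observed ages "
                f"[{ages.min():g}, {ages.max():g}]"
            )

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.frame)

    def subset(self, index: Sequence) -> "NormData":
        """Return a new NormData restricted to the given frame index labels."""
        return NormData(
            frame=self.frame.loc[index],
            measure_name=self.measure_name,
            score_unit=self.score_unit,
            age_range=self.age_range,
        )


@dataclass(frozen=True)
class NormTable:
    """Grid of raw-score cut-offs: one row per age, one column per percentile."""

    ages: np.ndarray
    percentiles: np.ndarray
    cutoffs: np.ndarray
    method: str = ""
    generated_by: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        pct = np.asarray(self.percentiles, dtype=float)
        cut = np.asarray(self.cutoffs, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "percentiles", pct)
        object.__setattr__(self, "cutoffs", cut)
        if cut.shape != (ages.size, pct.size):
            raise InvariantError(
                f"cutoffs shape {cut.shape} != (n_ages={ages.size}, n_pct={pct.size})"
            )
        if np.any(pct <= 0) or np.any(pct >= 1):
            raise InvariantError("percentiles must lie strictly inside (0, 1)")
        if np.any(np.diff(pct) <= 0):
            raise InvariantError("percentile grid must be strictly increasing")
        finite = np.isfinite(cut)
        # centile non-crossing: strictly increasing along the percentile axis
        # wherever adjacent cells are both defined
        diffs = np.diff(cut, axis=1)
        both = finite[:, :-1] & finite[:, 1:]
        if np.any(diffs[both] <= 0):
            raise InvariantError("cutoffs must increase strictly with percentile (centiles cross)")


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    code: str
    message: str
    severity: str = "error"


def read_norm_data(
    path: str | Path,
    age_col: str = "age",
    score_col: str = "score",
    group_col: str | None = None,
    measure_name: str | None = None,
    score_unit: str = "",
) -> NormData:
    """Read long-format person-level CSV into a :class:`NormData`.

    Rows with non-finite age or score are dropped; the drop count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    for col in [age_col, score_col] + ([group_col] if group_col else []):
        if col not in raw.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path.name}; available: {list(raw.columns)}"
            )
    frame = pd.DataFrame(
        {
            "age": pd.to_numeric(raw[age_col], errors="coerce"),
            "score": pd.to_numeric(raw[score_col], errors="coerce"),
            "group": raw[group_col].astype(str) if group_col else "all",
        }
    )
    usable = np.isfinite(frame["age"]) & np.isfinite(frame["score"])
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("read_norm_data: dropped %d record(s) with non-finite age/score", n_dropped)
    frame = frame.loc[usable].reset_index(drop=True)
    if len(frame) == 0:
        raise EmptyDataError(f"{path.name}: no usable rows after filtering")
    return NormData(
        frame=frame,
        measure_name=measure_name or score_col,
        score_unit=score_unit,
    )


def write_norm_data(data: NormData, path: str | Path) -> None:
    """Write person-level records to CSV (age, score, group); numeric values
    keep 12 significant digits so a read round trip preserves them."""
    data.frame.to_csv(path, index=False, float_format="%.12g")


def validate_for_method(
    data: NormData, method: str, min_cohort_n: int = 20, cohort_width: float = 1.0
) -> list[Violation]:
    """Report violations that would compromise a fit with the given method.

    The parametric (LMS) route requires strictly positive raw scores — the
    Box–Cox power transform is undefined at or below zero.  Both routes warn
    about one-year age cohorts with fewer than ``min_cohort_n`` records.
    Pure: never mutates ``data``.
    """
    method = method.upper()
    if method not in {"LMS", "CNORM"}:
        raise ConfigurationError(f"unknown method {method!r}; expected 'LMS' or 'CNORM'")
    violations: list[Violation] = []
    if method == "LMS":
        bad = np.flatnonzero(data.scores <= 0)
        for i in bad:
            violations.append(
                Violation(
                    code="nonpositive_score",
                    message=(
                        f"record {data.frame.index[i]}: score {data.scores[i]:g} — "
                        "the values to be modelled have to be strictly positive (> 0)"
                    ),
                    severity="error",
                )
            )
    labels = np.floor(data.ages / cohort_width).astype(int)
    for lab, count in zip(*np.unique(labels, return_counts=True)):
        if count < min_cohort_n:
            violations.append(
                Violation(
                    code="small_cohort",
                    message=f"cohort {lab} has only {count} record(s) (< {min_cohort_n})",
                    severity="warning",
                )
            )
    return violations


def write_norm_table(table: NormTable, path: str | Path) -> None:
    """Write a norm table to CSV: one row per age, one column per percentile.

    The header encodes percentile values as ``p<percent>`` (e.g. ``p3``,
    ``p50``); a round-trip through :func:`read_norm_table` reproduces the
    cut-off matrix to at least 6 decimals.
    """
    # NormTable invariants are enforced at construction; re-validate defensively
    NormTable(table.ages, table.percentiles, table.cutoffs, table.method, table.generated_by)
    cols = {"age": table.ages}
    for j, p in enumerate(table.percentiles):
        cols[f"p{100 * p:.6g}"] = table.cutoffs[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_norm_table(path: str | Path, method: str = "") -> NormTable:
    """Read a norm table previously written by :func:`write_norm_table`."""
    frame = pd.read_csv(path)
    if "age" not in frame.columns:
        raise ConfigurationError(f"{path}: no 'age' column")
    pcols = [c for c in frame.columns if c.startswith("p")]
    percentiles = np.array([float(c[1:]) / 100.0 for c in pcols])
    return NormTable(
        ages=frame["age"].to_numpy(dtype=float),
        percentiles=percentiles,
        cutoffs=frame[pcols].to_numpy(dtype=float),
        method=method,
    )


def norm_data_from_arrays(
    ages: Iterable[float],
    scores: Iterable[float],
    groups: Iterable | None = None,
    **meta,
) -> NormData:
    """Convenience constructor from plain arrays (used by simulation and tests)."""
    ages = np.asarray(list(ages), dtype=float)
    scores = np.asarray(list(scores), dtype=float)
    frame = pd.DataFrame(
        {"age": ages, "score": scores, "group": list(groups) if groups is not None else "all"}
    )
    return NormData(frame=frame, **meta)
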