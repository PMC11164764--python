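"""Stage-based age prediction and cohort error metrics.

The classical reader rule predicts the reference-study mean age of the
assessed (stage, sex) case group.  Evaluation summarizes absolute errors
``e_i = |predicted_i - true_i|`` as MAE, SD of absolute errors, maximum
error, and 90th-percentile error, overall and per 1-year (or custom) age bin.

Conventions (both configurable):

* p90 uses linear interpolation between closest ranks (numpy's default
  ``"linear"`` method, Hyndman-Fan type 7).
* the SD of absolute errors is the sample SD (``ddof=1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .reference_model import (
    STAGE_LABELS,
    ReferenceTable,
    Sex,
    _check_stage,
)

__all__ = [
    "Cohort",
    "ErrorSummary",
    "AgeBin",
    "load_cohort",
    "load_predictions",
    "predict_age_from_stage",
    "predict_cohort_ages",
    "error_summary",
    "binned_summary",
    "compare_methods",
]

PRED_COLUMNS = ("id", "true_age", "pred_age")


@dataclass(frozen=True)
class Cohort:
    """Evaluation cohort: one row per individual.

    The underlying frame has columns ``id`` (unique, string), ``sex``
    (``'f'``/``'m'``), ``age`` (years), and optionally ``stage``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("id", "sex", "age"):
            if col not in df.columns:
                raise ValueError(f"cohort frame is missing column {col!r}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate cohort ids: {dups}")
        if (df["age"] <= 0).any():
            raise ValueError("cohort ages must be positive")
        df["sex"].map(Sex.parse)  # raises on bad codes
        if "stage" in df.columns:
            df["stage"].dropna().map(_check_stage)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_stages(self) -> bool:
        return "stage" in self.frame.columns and self.frame["stage"].notna().all()

    def with_stages(self, stages: Sequence[str]) -> "Cohort":
        df = self.frame.copy()
        df["stage"] = list(stages)
        return Cohort(df)

    def to_csv(self, path: str | Path) -> None:
        df = self.frame.rename(columns={"age": "age_years"})
        df.to_csv(path, index=False)


def load_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV with header ``id,sex,age_years[,stage]``."""
    df = pd.read_csv(path, comment="#", dtype={"id": str, "sex": str, "stage": str})
    if "age_years" not in df.columns:
        raise ValueError("cohort CSV must have an 'age_years' column")
    return Cohort(df.rename(columns={"age_years": "age"}))


def load_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV with header ``id,true_age,pred_age[,uncertainty]``."""
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    missing = set(PRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"predictions CSV is missing column(s): {', '.join(sorted(missing))}"
        )
    return df


def predict_age_from_stage(
    stage: str, sex: Sex | str, table: ReferenceTable
) -> float:
    """Classical reader prediction: the stage's reference mean age ``M(s)``."""
    return table.get(sex, stage).mean_age


def predict_cohort_ages(cohort: Cohort, table: ReferenceTable) -> pd.DataFrame:
    """Apply the stage-mean rule to a staged cohort.

    Returns a predictions frame (``id, true_age, pred_age``) suitable for
    :func:`error_summary`.
    """
    if not cohort.has_stages:
        raise ValueError("cohort has no (complete) stage assignments")
    df = cohort.frame
    pred = [
        predict_age_from_stage(stage, sex, table)
        for stage, sex in zip(df["stage"], df["sex"])
    ]
    return pd.DataFrame(
        {"id": df["id"], "true_age": df["age"], "pred_age": pred}
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ErrorSummary:
    """Absolute-error summary of a prediction set."""

    n: int
    mae: float
    sd_ae: float
    max_ae: float
    p90_ae: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "mae": self.mae,
            "sd_ae": self.sd_ae,
            "max_ae": self.max_ae,
            "p90_ae": self.p90_ae,
        }


def _summarize_errors(
    errors: np.ndarray, quantile_method: str, sd_ddof: int
) -> ErrorSummary:
    n = errors.size
    sd = float(np.std(errors, ddof=sd_ddof)) if n > sd_ddof else 0.0
    return ErrorSummary(
        n=int(n),
        mae=float(errors.mean()),
        sd_ae=sd,
        max_ae=float(errors.max()),
        p90_ae=float(np.quantile(errors, 0.9, method=quantile_method)),
    )


def error_summary(
    preds: pd.DataFrame,
    quantile_method: str = "linear",
    sd_ddof: int = 1,
) -> ErrorSummary:
    """Summarize absolute errors of a predictions frame.

    Parameters
    ----------
    preds
        Frame with columns ``true_age`` and ``pred_age``.
    quantile_method
        Quantile convention for the p90 error, any numpy quantile method
        name; default linear interpolation (type 7).
    sd_ddof
        Denominator convention for the error SD; 1 = sample SD (default).
    """
    if len(preds) == 0:
        raise ValueError("no predictions to summarize")
    errors = np.abs(
        np.asarray(preds["pred_age"], dtype=float)
        - np.asarray(preds["true_age"], dtype=float)
    )
    if not np.all(np.isfinite(errors)):
        raise ValueError("predictions contain non-finite values")
    return _summarize_errors(errors, quantile_method, sd_ddof)


@dataclass(frozen=True, order=True)
class AgeBin:
    """Left-closed right-open age interval ``[low, high)`` in years."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"invalid bin [{self.low}, {self.high})")

    def __contains__(self, age: float) -> bool:
        return self.low <= age < self.high

    def label(self) -> str:
        return f"{self.low:.1f}-<{self.high:.1f}"


def _join_by_id(preds: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    pred_ids = set(preds["id"])
    cohort_ids = set(cohort.frame["id"])
    if pred_ids != cohort_ids:
        missing = sorted(cohort_ids - pred_ids)
        extra = sorted(pred_ids - cohort_ids)
        parts = []
        if missing:
            parts.append(f"ids without predictions: {missing}")
        if extra:
            parts.append(f"predictions without cohort record: {extra}")
        raise ValueError("prediction/cohort id mismatch — " + "; ".join(parts))
    return preds.merge(cohort.frame[["id", "sex", "age"]], on="id", validate="1:1")


def binned_summary(
    preds: pd.DataFrame,
    cohort: Cohort,
    bin_width: float = 1.0,
    age_range: tuple[float, float] = (15.0, 30.0),
    quantile_method: str = "linear",
    sd_ddof: int = 1,
) -> dict[AgeBin, ErrorSummary]:
    """Per-age-bin error summaries, binned by true age.

    Bins are left-closed right-open over ``[low, high)``; the range must
    divide into whole bins.  Individuals outside the range are an error
    (balanced evaluation designs guarantee coverage); empty bins are omitted.
    """
    low, high = age_range
    n_bins = (high - low) / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9 or n_bins < 1:
        raise ValueError(
            f"range [{low}, {high}) does not divide into whole bins of "
            f"width {bin_width}"
        )
    n_bins = int(round(n_bins))
    joined = _join_by_id(preds, cohort)

    ages = np.asarray(joined["true_age"], dtype=float)
    outside = (ages < low) | (ages >= high)
    if outside.any():
        bad = joined.loc[outside, "id"].tolist()
        raise ValueError(f"true ages outside [{low}, {high}) for ids: {bad}")

    idx = np.floor((ages - low) / bin_width).astype(int)
    idx = np.minimum(idx, n_bins - 1)  # guard float edge at high - epsilon
    out: dict[AgeBin, ErrorSummary] = {}
    for k in range(n_bins):
        sub = joined[idx == k]
        if len(sub) == 0:
            continue
        b = AgeBin(low + k * bin_width, low + (k + 1) * bin_width)
        out[b] = error_summary(sub, quantile_method, sd_ddof)
    return out


def compare_methods(a: ErrorSummary, b: ErrorSummary) -> dict[str, float]:
    """Field-wise differences ``a - b`` between two error summaries."""
    da, db = a.to_dict(), b.to_dict()
    return {k: da[k] - db[k] for k in da}
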