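"""Deep-ensemble aggregation and the abstention-performance trade-off.

An ensemble regressor's point prediction is the mean of its K member
predictions; the member SD serves as the predictive uncertainty.  In an
abstention-performance trade-off the fraction of samples with the highest
uncertainty (the abstention rate) is excluded and error metrics are computed
on the retained subset — letting the model decline to answer where it is
least sure.

The rate grid defaults to per-sample granularity k/N; off-grid rates retain
ceil((1-r)*N) samples (conservative: a fractional sample is kept, not
dropped).  Uncertainty ties are broken by id so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import ErrorSummary, error_summary

__all__ = [
    "EnsemblePrediction",
    "AbstentionPoint",
    "AbstentionCurve",
    "aggregate_ensemble",
    "aggregate_ensemble_frame",
    "per_sample_rates",
    "abstention_curve",
    "threshold_crossing",
    "NEVER",
]

#: Sentinel returned by :func:`threshold_crossing` when no abstention rate
#: brings the metric below the threshold.
NEVER: Optional[float] = None

_METRICS = ("mae", "max_ae", "p90_ae")


@dataclass(frozen=True)
class EnsemblePrediction:
    """Aggregated prediction of one sample from K ensemble members."""

    id: str
    members: tuple[float, ...]
    mean_pred: float
    sd_pred: float


def aggregate_ensemble(
    members: Sequence[float], sd_ddof: int = 1
) -> tuple[float, float]:
    """Mean and SD of the member predictions for one sample.

    The mean is the ensemble's point prediction; the SD its predictive
    uncertainty.  Requires K >= 2 members (a single member has no defined
    spread).  ``sd_ddof=1`` gives the sample SD (default).
    """
    arr = np.asarray(list(members), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 ensemble members, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ensemble members must be finite")
    return float(arr.mean()), float(np.std(arr, ddof=sd_ddof))


def aggregate_ensemble_frame(wide: pd.DataFrame, sd_ddof: int = 1) -> pd.DataFrame:
    """Aggregate a wide ensemble frame ``id,true_age,member_1..member_K``.

    Returns a predictions frame ``id,true_age,pred_age,uncertainty``.
    """
    member_cols = [c for c in wide.columns if c.startswith("member_")]
    if len(member_cols) < 2:
        raise ValueError("wide ensemble frame needs >= 2 member_* columns")
    members = wide[member_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(members)):
        raise ValueError("ensemble members must be finite")
    return pd.DataFrame(
        {
            "id": wide["id"],
            "true_age": wide["true_age"],
            "pred_age": members.mean(axis=1),
            "uncertainty": np.std(members, axis=1, ddof=sd_ddof),
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class AbstentionPoint:
    """Metrics on the retained subset at one abstention rate."""

    rate: float
    retained_n: int
    summary: ErrorSummary
    retained_ids: tuple[str, ...]


@dataclass(frozen=True)
class AbstentionCurve:
    """Abstention-performance trade-off: points ordered by increasing rate."""

    points: tuple[AbstentionPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def metric(self, name: str) -> np.ndarray:
        if name not in _METRICS:
            raise ValueError(f"unknown metric {name!r}; expected one of {_METRICS}")
        return np.array([getattr(p.summary, name) for p in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([p.rate for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rate": p.rate,
                    "retained_n": p.retained_n,
                    "mae": p.summary.mae,
                    "sd_ae": p.summary.sd_ae,
                    "max_ae": p.summary.max_ae,
                    "p90_ae": p.summary.p90_ae,
                }
                for p in self.points
            ]
        )


def per_sample_rates(n: int) -> list[float]:
    """The per-sample abstention grid k/N for k = 0 .. N-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [k / n for k in range(n)]


def _retained_count(rate: float, n: int) -> int:
    k = rate * n
    if abs(k - round(k)) < 1e-9:  # exactly on the k/N grid
        return n - int(round(k))
    return math.ceil((1.0 - rate) * n)


def abstention_curve(
    preds: pd.DataFrame,
    rates: Sequence[float],
    quantile_method: str = "linear",
    sd_ddof: int = 1,
) -> AbstentionCurve:
    """Evaluate retained-subset metrics across abstention rates.

    At each rate the samples with the highest ``uncertainty`` are dropped
    and :func:`~clavage.metrics.error_summary` is computed on the rest.
    Retained sets are nested: a higher rate keeps a subset of any lower
    rate's samples.

    Parameters
    ----------
    preds
        Predictions frame with columns ``id, true_age, pred_age,
        uncertainty`` (uncertainty required for every row).
    rates
        Abstention fractions in [0, 1), strictly increasing after sorting;
        duplicates are an error, as is a rate retaining zero samples.
    """
    if "uncertainty" not in preds.columns or preds["uncertainty"].isna().any():
        raise ValueError("every prediction needs an uncertainty value")
    if (preds["uncertainty"] < 0).any():
        raise ValueError("uncertainties must be non-negative")
    rates = sorted(float(r) for r in rates)
    if len(set(rates)) != len(rates):
        raise ValueError("duplicate abstention rates")
    for r in rates:
        if not (0.0 <= r < 1.0):
            raise ValueError(f"abstention rate {r} outside [0, 1)")

    n = len(preds)
    if n == 0:
        raise ValueError("no predictions")
    # Stable ranking: lowest uncertainty first, ties broken by id.
    order = preds.sort_values(
        ["uncertainty", "id"], kind="stable"
    ).reset_index(drop=True)

    points = []
    for r in rates:
        m = _retained_count(r, n)
        if m < 1:
            raise ValueError(f"abstention rate {r} retains zero samples")
        kept = order.iloc[:m]
        points.append(
            AbstentionPoint(
                rate=r,
                retained_n=m,
                summary=error_summary(kept, quantile_method, sd_ddof),
                retained_ids=tuple(kept["id"]),
            )
        )
    return AbstentionCurve(points=tuple(points))


def threshold_crossing(
    curve: AbstentionCurve, metric: str, threshold: float
) -> Optional[float]:
    """Smallest grid rate r* with the metric strictly below *threshold* at
    every grid rate > r*.

    The curve should be computed on the per-sample grid k/N (see
    :func:`per_sample_rates`); metrics of real predictors need not be
    monotone, so the whole grid is scanned.  Returns :data:`NEVER` (``None``)
    if the metric is still at or above the threshold at the final grid rate.
    """
    if len(curve) == 0:
        raise ValueError("empty abstention curve")
    values = curve.metric(metric)
    rates = curve.rates
    bad = np.flatnonzero(values >= threshold)
    if bad.size == 0:
        return 0.0
    if bad[-1] == len(rates) - 1:
        return NEVER
    return float(rates[bad[-1]])
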