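"""Synthetic cohorts, stage assignments, and simulated ensemble predictors.

Real clavicle-CT cohorts are private clinical data, so everything the
pipeline consumes can be generated here instead:

* balanced evaluation cohorts — an equal number of individuals per sex per
  age bin (the standard design removing age/sex composition effects; the
  default emulates 10 per sex per 1-year bin over 15.0-30.0 years, 300
  individuals);
* ossification stages drawn from the stage-given-age model of a reference
  table, so staged cohorts are exactly consistent with the error-bound model;
* a simulated K-member ensemble regressor whose per-sample member spread can
  be coupled to its error, for exercising abstention analysis;
* per-(sex, stage) re-estimation of reference statistics from a staged
  cohort, for parameter-recovery studies.

All generators take a seed and are bit-reproducible; independent substreams
are derived per operation so adding one generator call never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .abstention import EnsemblePrediction
from .metrics import Cohort
from .reference_model import (
    STAGE_LABELS,
    ReferenceTable,
    Sex,
    StageReference,
    _normalized_probs,
)

__all__ = [
    "CohortDesign",
    "EnsembleSimConfig",
    "FitResult",
    "simulate_balanced_cohort",
    "simulate_stages",
    "simulate_ensemble_predictions",
    "ensemble_to_predictions",
    "ensemble_to_wide_frame",
    "fit_reference_table",
]

_PLACEMENTS = ("uniform-in-bin", "bin-midpoint")

# Substream tags so each generator draws from its own independent stream.
_STREAM_COHORT, _STREAM_STAGES, _STREAM_ENSEMBLE = 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class CohortDesign:
    """Design of a balanced evaluation cohort.

    Defaults emulate the standard balanced test design: 10 individuals per
    sex per 1-year bin over [15.0, 30.0) years — 300 in total, 150 female.
    ``age_placement`` controls where within a bin ages fall: drawn uniformly
    (default; real ages are continuous) or fixed at the bin midpoint (for
    deterministic tests).
    """

    age_low: float = 15.0
    age_high: float = 30.0
    bin_width: float = 1.0
    per_bin_per_sex: int = 10
    age_placement: str = "uniform-in-bin"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be < age_high")
        n_bins = (self.age_high - self.age_low) / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("age range must divide into whole bins")
        if self.per_bin_per_sex < 1:
            raise ValueError("per_bin_per_sex must be >= 1")
        if self.age_placement not in _PLACEMENTS:
            raise ValueError(
                f"age_placement must be one of {_PLACEMENTS}, "
                f"got {self.age_placement!r}"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.age_high - self.age_low) / self.bin_width))

    @property
    def n_total(self) -> int:
        return self.n_bins * self.per_bin_per_sex * 2


def simulate_balanced_cohort(design: CohortDesign) -> Cohort:
    """Generate a cohort with exactly ``per_bin_per_sex`` individuals of each
    sex in every age bin.

    Counts are exact, not in expectation.  Ids encode sex, bin and index
    (e.g. ``f-b03-07``) and are deterministic given the design.
    """
    rng = _rng(design.seed, _STREAM_COHORT)
    rows = []
    for sex in (Sex.FEMALE, Sex.MALE):
        for b in range(design.n_bins):
            lo = design.age_low + b * design.bin_width
            if design.age_placement == "bin-midpoint":
                ages = np.full(design.per_bin_per_sex, lo + design.bin_width / 2)
            else:
                ages = lo + design.bin_width * rng.random(design.per_bin_per_sex)
            for j, age in enumerate(ages):
                rows.append(
                    {
                        "id": f"{sex.value}-b{b:02d}-{j:02d}",
                        "sex": sex.value,
                        "age": float(age),
                    }
                )
    return Cohort(pd.DataFrame(rows))


def simulate_stages(cohort: Cohort, table: ReferenceTable, seed: int = 0) -> Cohort:
    """Assign each individual an ossification stage drawn from the
    stage-given-age model ``p_s(age, sex)`` of *table*.

    Draws are independent across individuals and deterministic given the
    seed.
    """
    rng = _rng(seed, _STREAM_STAGES)
    df = cohort.frame
    stages = []
    for sex_code, age in zip(df["sex"], df["age"]):
        sex = table.require_sex(sex_code)
        labels = table.stages_for(sex)
        p = _normalized_probs(float(age), table.means(sex), table.sds(sex))
        stages.append(labels[rng.choice(len(labels), p=p)])
    return cohort.with_stages(stages)


@dataclass(frozen=True)
class EnsembleSimConfig:
    """Generative model of a K-member ensemble regressor.

    Per individual, a latent prediction error ``eps ~ Normal(bias,
    noise_sd^2)`` is shared by all members; each member then adds its own
    ``Normal(0, s_i^2)`` deviation, where the per-sample spread

        ``s_i = (1 - c) * member_spread_sd + c * |eps|``

    interpolates (coupling ``c`` in [0, 1]) between a constant spread and a
    spread proportional to the latent error — at ``c = 1`` the ensemble SD
    is an informative uncertainty signal, at ``c = 0`` it carries no
    information about the error.  A fraction ``outlier_rate`` of individuals
    receive an extra error shift of ``outlier_shift`` years (random sign),
    emulating rare pathology-driven gross failures.

    Defaults: 20 members; ``noise_sd`` = 2.0 years so the cohort MAE of the
    ensemble mean lands near ``2.0 * sqrt(2/pi) ≈ 1.6`` years, the error
    scale reported for CT-based clavicle age regression; moderate coupling.
    """

    n_members: int = 20
    bias: float = 0.0
    noise_sd: float = 2.0
    member_spread_sd: float = 1.0
    error_uncertainty_coupling: float = 0.5
    outlier_rate: float = 0.0
    outlier_shift: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.noise_sd < 0 or self.member_spread_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.error_uncertainty_coupling <= 1.0:
            raise ValueError("error_uncertainty_coupling must be in [0, 1]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")


def simulate_ensemble_predictions(
    cohort: Cohort, config: EnsembleSimConfig
) -> list[EnsemblePrediction]:
    """Simulate per-member age predictions for every cohort individual."""
    rng = _rng(config.seed, _STREAM_ENSEMBLE)
    df = cohort.frame
    n = len(df)
    k = config.n_members

    eps = rng.normal(config.bias, config.noise_sd, size=n)
    if config.outlier_rate > 0:
        hit = rng.random(n) < config.outlier_rate
        sign = rng.choice([-1.0, 1.0], size=n)
        eps = eps + hit * sign * config.outlier_shift
    c = config.error_uncertainty_coupling
    spread = (1.0 - c) * config.member_spread_sd + c * np.abs(eps)
    members = (
        df["age"].to_numpy()[:, None]
        + eps[:, None]
        + rng.standard_normal((n, k)) * spread[:, None]
    )

    out = []
    for i, id_ in enumerate(df["id"]):
        m = members[i]
        out.append(
            EnsemblePrediction(
                id=str(id_),
                members=tuple(float(v) for v in m),
                mean_pred=float(m.mean()),
                sd_pred=float(np.std(m, ddof=1)),
            )
        )
    return out


def ensemble_to_predictions(
    ensemble: Sequence[EnsemblePrediction], cohort: Cohort
) -> pd.DataFrame:
    """Join aggregated ensemble output with true ages.

    Returns a predictions frame ``id, true_age, pred_age, uncertainty``.
    """
    agg = pd.DataFrame(
        {
            "id": [e.id for e in ensemble],
            "pred_age": [e.mean_pred for e in ensemble],
            "uncertainty": [e.sd_pred for e in ensemble],
        }
    )
    truth = cohort.frame[["id", "age"]].rename(columns={"age": "true_age"})
    merged = agg.merge(truth, on="id", validate="1:1")
    if len(merged) != len(agg):
        raise ValueError("ensemble ids do not match cohort ids")
    return merged[["id", "true_age", "pred_age", "uncertainty"]]


def ensemble_to_wide_frame(
    ensemble: Sequence[EnsemblePrediction], cohort: Cohort
) -> pd.DataFrame:
    """Wide export ``id, true_age, member_1..member_K`` of raw member outputs."""
    truth = dict(zip(cohort.frame["id"], cohort.frame["age"]))
    rows = []
    for e in ensemble:
        row = {"id": e.id, "true_age": truth[e.id]}
        row.update({f"member_{j + 1}": v for j, v in enumerate(e.members)})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FitResult:
    """Per-(sex, stage) age statistics re-estimated from a staged cohort.

    ``frame`` has one row per (sex, stage) cell with columns ``sex, stage,
    mean_age, sd_age, n, usable``; cells with fewer than 2 members are
    reported with NaN statistics, cells with zero age variance are reported
    but flagged unusable (a degenerate case group defines no density).
    """

    frame: pd.DataFrame

    @property
    def missing(self) -> list[tuple[str, str]]:
        bad = self.frame[~self.frame["usable"]]
        return list(zip(bad["sex"], bad["stage"]))

    def to_reference_table(self) -> ReferenceTable:
        """Build a ReferenceTable from the usable cells.

        Raises if any stage of a fitted sex is missing or degenerate.
        """
        good = self.frame[self.frame["usable"]]
        entries = [
            StageReference(
                stage=r.stage,
                sex=r.sex,
                mean_age=r.mean_age,
                sd_age=r.sd_age,
                n=int(r.n),
            )
            for r in good.itertuples()
        ]
        return ReferenceTable(entries)


def fit_reference_table(cohort: Cohort) -> FitResult:
    """Estimate per-(sex, stage) mean and sample SD of age from a staged
    cohort — the way reference studies derive their case-group statistics.

    Cells with < 2 members or zero variance are reported as unusable rather
    than raising: missingness is data, not failure.
    """
    if not cohort.has_stages:
        raise ValueError("cohort has no (complete) stage assignments")
    df = cohort.frame
    rows = []
    for sex_code in sorted(df["sex"].unique()):
        sub = df[df["sex"] == sex_code]
        for stage in STAGE_LABELS:
            ages = sub.loc[sub["stage"] == stage, "age"].to_numpy(dtype=float)
            n = ages.size
            if n < 2:
                rows.append(
                    {
                        "sex": sex_code,
                        "stage": stage,
                        "mean_age": np.nan,
                        "sd_age": np.nan,
                        "n": n,
                        "usable": False,
                    }
                )
                continue
            sd = float(np.std(ages, ddof=1))
            rows.append(
                {
                    "sex": sex_code,
                    "stage": stage,
                    "mean_age": float(ages.mean()),
                    "sd_age": sd,
                    "n": n,
                    "usable": sd > 0,
                }
            )
    return FitResult(pd.DataFrame(rows))
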