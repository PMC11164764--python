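"""Stage-given-age probability model and best-case reader error bound.

Reference-study age assessment assigns an individual an ossification stage of
the medial clavicular epiphyseal cartilage (ordinal stages 1, 2a-2c, 3a-3c,
4, 5) and predicts the mean age of the same-stage, same-sex case group from a
published reference study.  This module models that procedure under best-case
assumptions: the reference statistics are representative, age within each
stage is normally distributed, and staging is error-free.

For a true age ``x`` the probability of presenting stage ``s`` is the normal
density of that stage's age distribution evaluated at ``x``, normalized over
the nine stages::

    p_s(x) = phi(x; M_s, SD_s) / sum_t phi(x; M_t, SD_t)

and the expected absolute error of the stage-mean prediction rule is the
convex combination::

    AE(x) = sum_s p_s(x) * |x - M_s|

which lower-bounds what any human reader applying the reference-study method
can achieve on average at that age.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAGE_LABELS",
    "DAYS_PER_YEAR",
    "MALE_STAGE_MEANS",
    "Sex",
    "StageReference",
    "ReferenceTable",
    "StageProbabilities",
    "ReferenceTableError",
    "AgeOutsideSupportError",
    "age_from_dates",
    "load_reference_table",
    "stage_age_density",
    "stage_probabilities",
    "stage_mean_differences",
    "expected_absolute_error",
    "error_curve",
    "cohort_expected_mae",
    "min_age_probability",
]

#: Ordinal ossification stage labels of the medial clavicular epiphysis, in
#: maturation order: no ossification center (1) through complete epiphyseal
#: fusion (5), with substages of partial ossification (2a-2c) and partial
#: fusion (3a-3c).
STAGE_LABELS: tuple[str, ...] = ("1", "2a", "2b", "2c", "3a", "3b", "3c", "4", "5")

_STAGE_INDEX = {s: i for i, s in enumerate(STAGE_LABELS)}

DAYS_PER_YEAR = 365.25

#: Published male per-stage mean ages (years) of the reference-study case
#: groups.  The matching SDs are not bundled; a usable table must supply them.
MALE_STAGE_MEANS: dict[str, float] = {
    "1": 13.28,
    "2a": 17.40,
    "2b": 18.20,
    "2c": 18.60,
    "3a": 19.00,
    "3b": 21.10,
    "3c": 22.90,
    "4": 29.63,
    "5": 31.77,
}

# Beyond this many SDs from every stage mean the model has no usable support.
_MAX_Z = 10.0


class ReferenceTableError(ValueError):
    """Raised for invalid or incomplete reference tables."""


class AgeOutsideSupportError(ValueError):
    """Raised when an age is outside the representable support of a table.

    All nine stage densities underflow; normalizing would silently return a
    meaningless (near-uniform) distribution, so we refuse instead.
    """


class Sex(str, enum.Enum):
    """Binary sex as stratified by the reference studies."""

    FEMALE = "f"
    MALE = "m"

    @classmethod
    def parse(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, cls):
            return value
        v = str(value).strip().lower()
        if v in ("f", "female"):
            return cls.FEMALE
        if v in ("m", "male"):
            return cls.MALE
        raise ValueError(f"unrecognized sex {value!r}; expected 'f' or 'm'")


def _check_stage(stage: str) -> str:
    stage = str(stage).strip()
    if stage not in _STAGE_INDEX:
        raise ReferenceTableError(
            f"unknown ossification stage {stage!r}; expected one of {STAGE_LABELS}"
        )
    return stage


def age_from_dates(date_of_birth, examination_date) -> float:
    """Chronological age in years: days between birth and exam / 365.25."""
    delta = pd.Timestamp(examination_date) - pd.Timestamp(date_of_birth)
    days = delta / pd.Timedelta(days=1)
    if days <= 0:
        raise ValueError("examination date must be after date of birth")
    return days / DAYS_PER_YEAR


@dataclass(frozen=True)
class StageReference:
    """Normal age distribution of one (stage, sex) reference case group.

    Parameters
    ----------
    stage
        Ossification stage label, one of :data:`STAGE_LABELS`.
    sex
        ``Sex.FEMALE`` or ``Sex.MALE``.
    mean_age, sd_age
        Mean and standard deviation of chronological age (years) among
        reference individuals in this stage.  ``sd_age`` must be positive;
        a degenerate (zero-variance) case group cannot define a density.
    n
        Optional case-group size.
    """

    stage: str
    sex: Sex
    mean_age: float
    sd_age: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", _check_stage(self.stage))
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not (self.mean_age > 0 and math.isfinite(self.mean_age)):
            raise ReferenceTableError(
                f"mean_age must be a positive finite number, got {self.mean_age}"
            )
        if not (self.sd_age > 0 and math.isfinite(self.sd_age)):
            raise ReferenceTableError(
                f"sd_age must be a positive finite number, got {self.sd_age} "
                f"(stage {self.stage}, sex {self.sex.value})"
            )
        if self.n is not None and self.n < 1:
            raise ReferenceTableError(f"n must be >= 1 if given, got {self.n}")


class ReferenceTable:
    """Per-sex, per-stage reference age statistics.

    For every sex present all nine stages must appear exactly once; pass
    ``require_complete=False`` to build partial toy tables (fewer stages) for
    testing and exploration — the loader always enforces completeness.
    Stage means that are not strictly increasing in stage order trigger a
    warning (not an error) so that pathological user tables remain loadable
    for inspection.
    """

    def __init__(
        self, entries: Iterable[StageReference], require_complete: bool = True
    ):
        self._entries: dict[tuple[Sex, str], StageReference] = {}
        for e in entries:
            key = (e.sex, e.stage)
            if key in self._entries:
                raise ReferenceTableError(
                    f"duplicate entry for sex {e.sex.value!r}, stage {e.stage!r}"
                )
            self._entries[key] = e
        if not self._entries:
            raise ReferenceTableError("reference table has no entries")
        for sex in self.sexes:
            missing = [s for s in STAGE_LABELS if (sex, s) not in self._entries]
            if missing and require_complete:
                raise ReferenceTableError(
                    f"incomplete table for sex {sex.value!r}: "
                    f"missing stage(s) {', '.join(missing)}"
                )
            means = self.means(sex)
            if not np.all(np.diff(means) > 0):
                warnings.warn(
                    f"stage mean ages for sex {sex.value!r} are not strictly "
                    "increasing in stage order; the table is usable but likely "
                    "mis-entered",
                    stacklevel=2,
                )

    @property
    def sexes(self) -> tuple[Sex, ...]:
        return tuple(sorted({sex for sex, _ in self._entries}, key=lambda s: s.value))

    def get(self, sex: Sex | str, stage: str) -> StageReference:
        sex = Sex.parse(sex)
        stage = _check_stage(stage)
        try:
            return self._entries[(sex, stage)]
        except KeyError:
            raise ReferenceTableError(
                f"no entry for sex {sex.value!r}, stage {stage!r}"
            ) from None

    def require_sex(self, sex: Sex | str) -> Sex:
        sex = Sex.parse(sex)
        if not any(s == sex for s, _ in self._entries):
            raise ReferenceTableError(f"table has no entries for sex {sex.value!r}")
        return sex

    def stages_for(self, sex: Sex | str) -> tuple[str, ...]:
        """Stage labels present for *sex*, in maturation order."""
        sex = self.require_sex(sex)
        return tuple(s for s in STAGE_LABELS if (sex, s) in self._entries)

    def means(self, sex: Sex | str) -> np.ndarray:
        """Stage mean ages for *sex*, ordered by stage."""
        sex = self.require_sex(sex)
        return np.array(
            [self._entries[(sex, s)].mean_age for s in self.stages_for(sex)]
        )

    def sds(self, sex: Sex | str) -> np.ndarray:
        """Stage age SDs for *sex*, ordered by stage."""
        sex = self.require_sex(sex)
        return np.array(
            [self._entries[(sex, s)].sd_age for s in self.stages_for(sex)]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sex": e.sex.value,
                "stage": e.stage,
                "mean_age": e.mean_age,
                "sd_age": e.sd_age,
                "n": e.n,
            }
            for e in self._entries.values()
        ]
        df = pd.DataFrame(rows)
        df["stage_order"] = df["stage"].map(_STAGE_INDEX)
        df = df.sort_values(["sex", "stage_order"]).drop(columns="stage_order")
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceTable":
        required = {"sex", "stage", "mean_age", "sd_age"}
        missing = required - set(df.columns)
        if missing:
            raise ReferenceTableError(
                f"reference table is missing column(s): {', '.join(sorted(missing))}"
            )
        entries = []
        for _, row in df.iterrows():
            if pd.isna(row["mean_age"]) or pd.isna(row["sd_age"]):
                raise ReferenceTableError(
                    f"missing mean_age/sd_age for sex {row['sex']!r}, "
                    f"stage {row['stage']!r} (sd_age is required: reference "
                    "tables without SDs cannot define a stage-given-age model)"
                )
            n = row.get("n")
            entries.append(
                StageReference(
                    stage=row["stage"],
                    sex=row["sex"],
                    mean_age=float(row["mean_age"]),
                    sd_age=float(row["sd_age"]),
                    n=None if n is None or pd.isna(n) else int(n),
                )
            )
        return cls(entries)

    def checksum(self) -> str:
        """Deterministic content hash used to tag exported artifacts."""
        import hashlib

        payload = json.dumps(
            self.to_frame().drop(columns="n").to_dict("records"), sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceTable):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        sexes = ",".join(s.value for s in self.sexes)
        return f"ReferenceTable(sexes=[{sexes}], stages={len(STAGE_LABELS)})"


def load_reference_table(path: str | Path) -> ReferenceTable:
    """Load a reference table CSV with header ``sex,stage,mean_age,sd_age[,n]``.

    Stage labels are spelled ``1,2a,...,5`` and sex as ``f``/``m``.  Lines
    starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, comment="#", dtype={"stage": str, "sex": str})
    return ReferenceTable.from_frame(df)


@dataclass(frozen=True)
class StageProbabilities:
    """Normalized stage probabilities ``p_s(x)`` at one (age, sex)."""

    probs: Mapping[str, float]
    age: float
    sex: Sex

    def as_array(self) -> np.ndarray:
        """Probabilities ordered by stage, over the stages present."""
        return np.array(
            [self.probs[s] for s in STAGE_LABELS if s in self.probs]
        )

    def __getitem__(self, stage: str) -> float:
        return self.probs[_check_stage(stage)]


def stage_age_density(x: float, ref: StageReference) -> float:
    """Normal density of age *x* under one stage's reference distribution."""
    return float(stats.norm.pdf(x, loc=ref.mean_age, scale=ref.sd_age))


def _normalized_probs(x: float, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    # Log-space with a max shift: ages within +-10 SD of any stage stay
    # representable even when individual densities underflow a float64.
    z = (np.asarray(x, dtype=float) - means) / sds
    if np.min(np.abs(z)) > _MAX_Z:
        raise AgeOutsideSupportError(
            f"age {x} is outside the representable support of the table "
            f"(more than {_MAX_Z:g} SDs from every stage mean)"
        )
    logp = -0.5 * z**2 - np.log(sds)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def stage_probabilities(
    x: float, sex: Sex | str, table: ReferenceTable
) -> StageProbabilities:
    """Probability of presenting each ossification stage at true age *x*.

    Each stage's normal age density is evaluated at ``x`` and the nine values
    are normalized to sum to one.
    """
    sex = table.require_sex(sex)
    p = _normalized_probs(float(x), table.means(sex), table.sds(sex))
    return StageProbabilities(
        probs=dict(zip(table.stages_for(sex), p.tolist())), age=float(x), sex=sex
    )


def stage_mean_differences(
    x: float, sex: Sex | str, table: ReferenceTable
) -> dict[str, float]:
    """Absolute difference ``|x - M(s)|`` to each stage's mean age, in years."""
    sex = table.require_sex(sex)
    diffs = np.abs(float(x) - table.means(sex))
    return dict(zip(table.stages_for(sex), diffs.tolist()))


def expected_absolute_error(x: float, sex: Sex | str, table: ReferenceTable) -> float:
    """Best-case expected absolute error AE(x) of stage-mean age prediction.

    ``AE(x) = sum_s p_s(x) |x - M(s)|`` — the error a perfectly staging
    reader incurs on average by predicting the stage mean.  As a convex
    combination it lies between the smallest and largest ``|x - M(s)|``.
    """
    sex = table.require_sex(sex)
    means = table.means(sex)
    p = _normalized_probs(float(x), means, table.sds(sex))
    return float(np.sum(p * np.abs(float(x) - means)))


def error_curve(
    age_grid: Sequence[float], sex: Sex | str, table: ReferenceTable
) -> pd.DataFrame:
    """AE(x) over an age grid; columns ``age`` and ``ae_years``.

    The grid must be non-empty and strictly increasing.
    """
    grid = np.asarray(list(age_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("age grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("age grid must be strictly increasing")
    ae = [expected_absolute_error(a, sex, table) for a in grid]
    return pd.DataFrame({"age": grid, "ae_years": ae})


@dataclass(frozen=True)
class CohortExpectedError:
    """Cohort-level summary of the best-case reader error bound."""

    mae: float
    sd_ae: float
    n: int
    per_individual: np.ndarray = field(repr=False)


def cohort_expected_mae(
    ages: Sequence[float],
    sexes: Sequence[Sex | str],
    table: ReferenceTable,
    ddof: int = 1,
) -> CohortExpectedError:
    """Mean of AE(x) over a cohort, with the SD of per-individual AE values.

    ``MAE = (1/N) sum_i AE(x_i)`` over all cohort members; the returned
    ``sd_ae`` is the sample SD (``ddof=1`` by default) of the AE values.
    """
    ages = list(ages)
    sexes = list(sexes)
    if len(ages) == 0:
        raise ValueError("cohort is empty")
    if len(ages) != len(sexes):
        raise ValueError("ages and sexes differ in length")
    ae = np.array(
        [expected_absolute_error(a, s, table) for a, s in zip(ages, sexes)]
    )
    sd = float(np.std(ae, ddof=ddof)) if ae.size > ddof else 0.0
    return CohortExpectedError(
        mae=float(ae.mean()), sd_ae=sd, n=ae.size, per_individual=ae
    )


def min_age_probability(
    stage: str, sex: Sex | str, table: ReferenceTable, threshold: float
) -> float:
    """Probability that an individual in *stage* is at least *threshold* old.

    Upper tail of the stage's normal age distribution at the threshold;
    relevant to minimum-age questions such as majority at 18 years.
    """
    ref = table.get(sex, stage)
    return float(stats.norm.sf(threshold, loc=ref.mean_age, scale=ref.sd_age))
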