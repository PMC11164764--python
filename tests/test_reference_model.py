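"""Stage-given-age model: densities, normalization, and the AE(x) bound."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clavage import (
    MALE_STAGE_MEANS,
    STAGE_LABELS,
    AgeOutsideSupportError,
    ReferenceTable,
    ReferenceTableError,
    Sex,
    StageReference,
    age_from_dates,
    cohort_expected_mae,
    error_curve,
    expected_absolute_error,
    load_reference_table,
    min_age_probability,
    stage_age_density,
    stage_mean_differences,
    stage_probabilities,
)

from conftest import SYNTH_SDS, make_table, random_complete_table, two_stage_table


# ---------------------------------------------------------------- loading


def _write_table_csv(path, rows, header="sex,stage,mean_age,sd_age,n"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


def test_load_complete_male_table(tmp_path):
    rows = [f"m,{s},{m},{SYNTH_SDS[s]}," for s, m in MALE_STAGE_MEANS.items()]
    p = tmp_path / "table.csv"
    _write_table_csv(p, rows)
    table = load_reference_table(p)
    assert table.get("m", "3b").mean_age == 21.10
    assert table.get("m", "3b").sd_age == SYNTH_SDS["3b"]


def test_load_missing_stage_names_the_gap(tmp_path):
    rows = [
        f"m,{s},{m},{SYNTH_SDS[s]}," for s, m in MALE_STAGE_MEANS.items() if s != "3c"
    ]
    p = tmp_path / "table.csv"
    _write_table_csv(p, rows)
    with pytest.raises(ReferenceTableError, match="3c"):
        load_reference_table(p)


@pytest.mark.parametrize("bad_sd", ["0", "-1.0", ""])
def test_load_rejects_degenerate_sd(tmp_path, bad_sd):
    rows = [f"m,{s},{m},{SYNTH_SDS[s]}," for s, m in MALE_STAGE_MEANS.items()]
    rows[3] = f"m,2c,18.60,{bad_sd},"
    p = tmp_path / "table.csv"
    _write_table_csv(p, rows)
    with pytest.raises(ReferenceTableError):
        load_reference_table(p)


def test_load_rejects_unknown_stage(tmp_path):
    rows = [f"m,{s},{m},1.0," for s, m in MALE_STAGE_MEANS.items()]
    rows.append("m,6,33.0,1.0,")
    p = tmp_path / "table.csv"
    _write_table_csv(p, rows)
    with pytest.raises(ReferenceTableError, match="stage"):
        load_reference_table(p)


def test_bundled_means_file_requires_sds():
    """The shipped male-means CSV has no SDs and must be rejected by the loader."""
    from importlib.resources import files

    path = files("clavage").joinpath("data/male_stage_means.csv")
    with pytest.raises(ReferenceTableError, match="sd_age"):
        load_reference_table(str(path))


def test_non_monotone_means_warn_not_error():
    means = dict(MALE_STAGE_MEANS)
    means["2b"], means["2c"] = means["2c"], means["2b"]
    with pytest.warns(UserWarning, match="not strictly increasing"):
        make_table(means, SYNTH_SDS)


def test_table_roundtrip_via_frame(full_table):
    assert ReferenceTable.from_frame(full_table.to_frame()) == full_table


def test_age_from_dates_uses_julian_year():
    assert age_from_dates("2000-01-01", "2021-01-01") == pytest.approx(
        7671 / 365.25
    )
    with pytest.raises(ValueError):
        age_from_dates("2021-01-01", "2000-01-01")


# ---------------------------------------------------------------- densities


def test_density_at_mean_is_standard_normal_mode():
    ref = StageReference("3a", "m", 19.0, 1.0)
    assert stage_age_density(19.0, ref) == pytest.approx(1 / math.sqrt(2 * math.pi))


def test_density_one_sd_out():
    ref = StageReference("3a", "m", 19.0, 1.0)
    assert stage_age_density(20.0, ref) == pytest.approx(0.2420, abs=5e-5)


@given(d=st.floats(0, 20, allow_nan=False))
def test_density_symmetric_about_mean(d):
    ref = StageReference("2b", "m", 18.2, 1.3)
    assert stage_age_density(18.2 + d, ref) == pytest.approx(
        stage_age_density(18.2 - d, ref)
    )


# ----------------------------------------------------- stage probabilities


def test_identical_stages_give_uniform_probabilities():
    with pytest.warns(UserWarning):  # constant means are non-monotone
        table = make_table(
            {s: 20.0 for s in STAGE_LABELS}, {s: 1.5 for s in STAGE_LABELS}
        )
    p = stage_probabilities(23.0, "m", table)
    assert p.as_array() == pytest.approx(np.full(9, 1 / 9))


def test_equidistant_two_stage_split():
    table = two_stage_table(20.0, 22.0, 1.1, 1.1)
    p = stage_probabilities(21.0, "m", table)
    assert p["2a"] == pytest.approx(0.5)
    assert p["3a"] == pytest.approx(0.5)


def test_two_stage_unequal_distance_matches_pdf_ratio():
    # means 20 (SD 1) and 24 (SD 1) at x=21: phi(1) / (phi(1) + phi(3))
    table = two_stage_table(20.0, 24.0, 1.0, 1.0)
    p = stage_probabilities(21.0, "m", table)
    expected = stats.norm.pdf(1) / (stats.norm.pdf(1) + stats.norm.pdf(3))
    assert p["2a"] == pytest.approx(expected)
    assert expected == pytest.approx(0.982, abs=5e-4)


def test_probabilities_sum_to_one_over_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(200):
        table = random_complete_table(rng)
        x = rng.uniform(8.0, 38.0)
        total = stage_probabilities(x, "m", table).as_array().sum()
        assert abs(total - 1.0) < 1e-12


def test_extreme_age_raises_instead_of_uniform(male_table):
    with pytest.raises(AgeOutsideSupportError):
        stage_probabilities(500.0, "m", male_table)


def test_far_but_representable_age_still_normalizes(male_table):
    # Within 10 SD of the late stages even though early-stage densities underflow.
    p = stage_probabilities(45.0, "m", male_table).as_array()
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.argmax(p) == len(STAGE_LABELS) - 1


# ------------------------------------------------- differences and AE(x)


def test_stage_mean_differences_identity(male_table):
    for s in STAGE_LABELS:
        diffs = stage_mean_differences(MALE_STAGE_MEANS[s], "m", male_table)
        assert diffs[s] == pytest.approx(0.0, abs=1e-12)


def test_single_stage_table_collapses_to_distance():
    table = make_table({"3a": 19.0}, {"3a": 1.0})
    assert expected_absolute_error(21.5, "m", table) == pytest.approx(2.5)


def test_symmetric_two_stage_ae_is_half_gap():
    table = two_stage_table(20.0, 22.0, 0.9, 0.9)
    assert expected_absolute_error(21.0, "m", table) == pytest.approx(1.0)


@given(x=st.floats(10.0, 36.0), shift=st.floats(-5.0, 5.0))
@settings(max_examples=50, deadline=None)
def test_ae_convexity_bound_and_shift_equivariance(x, shift):
    """AE(x) lies between min and max |x - M(s)| and is shift-equivariant."""
    table = make_table(MALE_STAGE_MEANS, SYNTH_SDS)
    diffs = np.abs(x - np.array(list(MALE_STAGE_MEANS.values())))
    ae = expected_absolute_error(x, "m", table)
    assert diffs.min() - 1e-9 <= ae <= diffs.max() + 1e-9

    shifted = make_table(
        {s: m + shift for s, m in MALE_STAGE_MEANS.items()}, SYNTH_SDS
    )
    assert expected_absolute_error(x + shift, "m", shifted) == pytest.approx(
        ae, rel=1e-9, abs=1e-9
    )


def test_concentration_limit_picks_nearest_stage():
    tiny = {s: 0.05 for s in STAGE_LABELS}
    table = make_table(MALE_STAGE_MEANS, tiny)
    x = 20.95  # nearest mean is 21.10 (stage 3b), 3 SD away; others > 30 SD
    p = stage_probabilities(x, "m", table)
    assert p["3b"] == pytest.approx(1.0, abs=1e-9)
    assert expected_absolute_error(x, "m", table) == pytest.approx(
        abs(x - 21.10), abs=1e-6
    )


def test_ae_monte_carlo_oracle(male_table):
    """AE(x) equals the sampling estimate of E|M(S) - x| with S ~ p_s(x)."""
    rng = np.random.default_rng(7)
    means = male_table.means("m")
    for x in (16.0, 21.0, 27.5):
        p = stage_probabilities(x, "m", male_table).as_array()
        draws = rng.choice(len(means), size=100_000, p=p)
        samples = np.abs(means[draws] - x)
        se = samples.std(ddof=1) / math.sqrt(samples.size)
        assert expected_absolute_error(x, "m", male_table) == pytest.approx(
            samples.mean(), abs=3 * se
        )


# ------------------------------------------------------------- error curve


def test_error_curve_elementwise(male_table):
    curve = error_curve([21.0], "m", male_table)
    assert len(curve) == 1
    assert curve["ae_years"].iloc[0] == expected_absolute_error(21.0, "m", male_table)


def test_error_curve_validates_grid(male_table):
    with pytest.raises(ValueError):
        error_curve([], "m", male_table)
    with pytest.raises(ValueError):
        error_curve([20.0, 19.0], "m", male_table)


def test_error_curve_symmetric_for_symmetric_toy_table():
    table = two_stage_table(20.0, 24.0, 1.0, 1.0)
    grid = np.linspace(20.0, 24.0, 41)
    ae = error_curve(grid, "m", table)["ae_years"].to_numpy()
    assert ae == pytest.approx(ae[::-1], rel=1e-9)


def test_error_curve_nonnegative_dense_grid(male_table):
    ae = error_curve(np.linspace(10, 35, 251), "m", male_table)["ae_years"]
    assert (ae >= 0).all()


# ------------------------------------------------------------- cohort MAE


def test_cohort_mae_single_individual(male_table):
    res = cohort_expected_mae([21.0], ["m"], male_table)
    assert res.mae == expected_absolute_error(21.0, "m", male_table)
    assert res.n == 1


def test_cohort_mae_duplication_invariance(male_table):
    ages = [16.0, 21.0, 27.0]
    sexes = ["m"] * 3
    once = cohort_expected_mae(ages, sexes, male_table)
    twice = cohort_expected_mae(ages * 2, sexes * 2, male_table)
    assert twice.mae == pytest.approx(once.mae, rel=1e-12)


def test_cohort_mae_matches_explicit_loop(full_table, small_cohort):
    df = small_cohort.frame
    res = cohort_expected_mae(df["age"], df["sex"], full_table)
    loop = [
        expected_absolute_error(a, s, full_table)
        for a, s in zip(df["age"], df["sex"])
    ]
    assert res.mae == pytest.approx(np.mean(loop), abs=1e-12)
    assert res.sd_ae == pytest.approx(np.std(loop, ddof=1), abs=1e-12)


def test_cohort_mae_empty_errors(male_table):
    with pytest.raises(ValueError):
        cohort_expected_mae([], [], male_table)


# ------------------------------------------------------ minimum-age tails


def test_min_age_probability_examples(male_table):
    # At the stage mean the threshold is the median: probability 1/2.
    assert min_age_probability("3b", "m", male_table, 21.10) == pytest.approx(0.5)

    table = make_table({"3b": 21.10}, {"3b": 2.0})
    assert min_age_probability("3b", "m", table, 18.0) == pytest.approx(
        stats.norm.cdf(1.55)
    )
    assert stats.norm.cdf(1.55) == pytest.approx(0.9394, abs=5e-5)


def test_min_age_probability_monotone(male_table):
    probs = [
        min_age_probability(s, "m", male_table, 18.0) for s in STAGE_LABELS
    ]
    assert probs == sorted(probs)  # increasing in stage mean age
    assert min_age_probability("3b", "m", male_table, 16.0) > min_age_probability(
        "3b", "m", male_table, 20.0
    )


def test_near_zero_sd_tail_limit():
    table = make_table({"3b": 21.10}, {"3b": 1e-9})
    assert min_age_probability("3b", "m", table, 18.0) == pytest.approx(1.0)
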