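"""Time-to-event construction and proportional-hazards contrasts."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from diagtraj import (
    bonferroni_plan,
    fit_hazard_contrast,
    hazard_grid,
    identify_d1,
    make_time_to_event,
)
from diagtraj.survival import FOLLOW_UP_DAYS

from conftest import make_record

D1 = date(2002, 5, 1)


def cohort_of(records):
    return identify_d1(records)


class TestTimeToEvent:
    def test_cross_chapter_event(self, taxonomy):
        cohort = cohort_of(
            [
                make_record(event=D1, icd10="F32.1"),
                make_record(event=D1 + timedelta(days=400), icd10="F20.0"),
            ]
        )
        rows = make_time_to_event(cohort, taxonomy, "SRD", "F2")
        assert rows.iloc[0].event == 1 and rows.iloc[0].time == 400

    def test_no_followup_censored_at_ten_years(self, taxonomy):
        cohort = cohort_of([make_record(event=D1, icd10="F32.1")])
        rows = make_time_to_event(cohort, taxonomy, "SRD", "F2")
        assert rows.iloc[0].event == 0 and rows.iloc[0].time == FOLLOW_UP_DAYS

    def test_emigration_censors(self, taxonomy):
        cohort = cohort_of(
            [
                make_record(event=D1, icd10="F32.1"),
                make_record(event=D1 + timedelta(days=200),
                            event_type="EMIGRATION", icd10=""),
            ]
        )
        rows = make_time_to_event(cohort, taxonomy, "SRD", "F2")
        assert rows.iloc[0].event == 0 and rows.iloc[0].time == 200

    def test_same_chapter_needs_different_block(self, taxonomy):
        # repeat of the entry block never qualifies; a different 2-cipher
        # block in the same chapter does
        cohort = cohort_of(
            [
                make_record(event=D1, icd10="F32.1"),
                make_record(event=D1 + timedelta(days=100), icd10="F32.9"),
                make_record(event=D1 + timedelta(days=300), icd10="F33.0"),
            ]
        )
        rows = make_time_to_event(cohort, taxonomy, "SRD", "F3")
        assert rows.iloc[0].event == 1 and rows.iloc[0].time == 300

    def test_exclude_same_chapter_flag(self, taxonomy):
        cohort = cohort_of(
            [
                make_record(event=D1, icd10="F32.1"),
                make_record(event=D1 + timedelta(days=300), icd10="F33.0"),
            ]
        )
        rows = make_time_to_event(cohort, taxonomy, "SRD", "F3",
                                  exclude_same_chapter_d1=True)
        assert rows.empty

    def test_event_after_horizon_ignored(self, taxonomy):
        cohort = cohort_of(
            [
                make_record(event=D1, icd10="F32.1"),
                make_record(event=D1 + timedelta(days=FOLLOW_UP_DAYS + 10),
                            icd10="F20.0"),
            ]
        )
        rows = make_time_to_event(cohort, taxonomy, "SRD", "F2")
        assert rows.iloc[0].event == 0 and rows.iloc[0].time == FOLLOW_UP_DAYS

    def test_censoring_consistency(self, taxonomy, small_cohort):
        """A longer administrative horizon never loses events."""
        _, _, cohort = small_cohort
        short = make_time_to_event(cohort, taxonomy, "ADHD", "F8",
                                   follow_up_days=1826)
        full = make_time_to_event(cohort, taxonomy, "ADHD", "F8")
        assert full.event.sum() >= short.event.sum()


def exp_rows(n_per_arm, hr, rng, censor=5.0, rate0=0.25):
    t0 = rng.exponential(1 / rate0, n_per_arm)
    t1 = rng.exponential(1 / (rate0 * hr), n_per_arm)
    rows = []
    for exposed, times in ((0, t0), (1, t1)):
        for t in times:
            rows.append(
                {
                    "person_id": f"{exposed}-{len(rows)}",
                    "exposed": exposed,
                    "time": min(t, censor),
                    "event": int(t <= censor),
                }
            )
    return pd.DataFrame(rows)


class TestFitHazardContrast:
    def test_toy_ordering_sanity(self):
        rows = pd.DataFrame(
            {
                "person_id": list("abcd"),
                "exposed": [1, 1, 0, 0],
                "time": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
            }
        )
        res = fit_hazard_contrast(rows)
        # with perfect ordering the likelihood is monotone: the point
        # estimate still exceeds 1 and the degeneracy is flagged
        assert res.hr > 1.0
        assert res.flag in (None, "separation")

    def test_null_large_sample_ci_covers_one(self):
        rng = np.random.default_rng(17)
        res = fit_hazard_contrast(exp_rows(2000, 1.0, rng), ci_level=0.999)
        assert res.flag is None
        assert res.ci_low < 1.0 < res.ci_high
        assert res.hr == pytest.approx(1.0, abs=0.15)

    def test_twofold_hazard_recovered(self):
        rng = np.random.default_rng(23)
        res = fit_hazard_contrast(exp_rows(3000, 2.0, rng), ci_level=0.999)
        assert res.ci_low < 2.0 < res.ci_high
        assert res.hr == pytest.approx(2.0, rel=0.1)

    def test_fit_reproducible_to_six_figures(self):
        rng = np.random.default_rng(5)
        rows = exp_rows(500, 1.5, rng)
        a = fit_hazard_contrast(rows.copy())
        b = fit_hazard_contrast(rows.copy())
        assert f"{a.hr:.6g}" == f"{b.hr:.6g}"

    def test_zero_events_in_one_arm_flagged(self):
        rows = pd.DataFrame(
            {
                "person_id": list("abcd"),
                "exposed": [1, 1, 0, 0],
                "time": [1.0, 2.0, 3.0, 4.0],
                "event": [0, 0, 1, 1],
            }
        )
        res = fit_hazard_contrast(rows)
        assert res.flag == "zero_events_in_arm"
        assert np.isnan(res.hr)

    def test_empty_arm_flagged(self):
        rows = pd.DataFrame(
            {"person_id": ["a"], "exposed": [1], "time": [1.0], "event": [1]}
        )
        assert fit_hazard_contrast(rows).flag == "empty_arm"

    def test_no_events_flagged(self):
        rows = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "exposed": [1, 0],
                "time": [1.0, 1.0],
                "event": [0, 0],
            }
        )
        assert fit_hazard_contrast(rows).flag == "no_events"


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,alpha,ci",
        [(1, 0.05, 0.95), (10, 0.005, 0.995), (180, 0.05 / 180, 1 - 0.05 / 180)],
    )
    def test_plan_arithmetic(self, n, alpha, ci):
        plan = bonferroni_plan(n)
        assert plan.alpha_adjusted == pytest.approx(alpha)
        assert plan.ci_level == pytest.approx(ci)

    def test_180_tests_is_00278_percent(self):
        # 0.05/180 in percent is ~0.0278%, wider than a naive 0.026% rounding
        assert bonferroni_plan(180).alpha_adjusted * 100 == pytest.approx(
            0.0278, abs=5e-4
        )

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_plan(0)


def test_hazard_grid_shares_bonferroni_plan(small_cohort, taxonomy):
    _, _, cohort = small_cohort
    grid = hazard_grid(cohort, taxonomy, sexes=("M",), chapters=("F8", "F9"))
    assert set(grid.sex) == {"M"}
    fitted = grid[grid.flag.isna()]
    n_tests = grid.n_tests.iloc[0]
    assert n_tests >= len(fitted) > 0
    expected_level = 1 - 0.05 / n_tests
    assert np.allclose(grid.ci_level, expected_level)
    ok = fitted.dropna(subset=["hr"])
    assert ((ok.ci_low <= ok.hr) & (ok.hr <= ok.ci_high)).all()
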