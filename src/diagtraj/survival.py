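"""Time-to-subsequent-diagnosis hazard contrasts.

For each entry-diagnosis category and each 1-cipher ICD-10 chapter outcome
(F0-F9), persons are followed from their entry date until the first
qualifying diagnosis in that chapter, censoring at death, emigration, or the
10-year administrative horizon (3,652 days).  A diagnosis qualifies when its
chapter matches the outcome and its 2-cipher block differs from the entry
diagnosis's block — repeating the entry diagnosis is never a subsequent
diagnosis, but a different 2-cipher diagnosis within the entry chapter is
(an ``exclude_same_chapter_d1`` sensitivity flag drops such persons
entirely).

The exposure is binary — the target entry category versus all other entry
categories — and the contrast is a proportional-hazards model with that
single term, fitted by maximizing the partial likelihood with Efron tie
handling (via lifelines).  Confidence intervals are Wald intervals on the
log-hazard scale; with many contrasts the level is widened by a Bonferroni
plan (alpha/n_tests, e.g. 180 tests -> ~99.97% intervals, conventionally
rendered as 99.9%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .records import CohortIndex
from .taxonomy import CHAPTERS, CategoryTaxonomy

#: Administrative censoring horizon: 10 years of follow-up, in days.
FOLLOW_UP_DAYS = 3652

#: Minimum event time; same-day events get half a day of exposure.
MIN_TIME_DAYS = 0.5


def make_time_to_event(
    cohort: CohortIndex,
    taxonomy: CategoryTaxonomy,
    d1_category: str,
    outcome_chapter: str,
    sex: str | None = None,
    follow_up_days: int = FOLLOW_UP_DAYS,
    exclude_same_chapter_d1: bool = False,
) -> pd.DataFrame:
    """One row per person: exposure arm, follow-up time in days, event flag."""
    if outcome_chapter not in CHAPTERS:
        raise ValueError(f"outcome chapter must be one of {CHAPTERS}")
    rows = []
    for pid in cohort.person_ids:
        d1 = cohort.d1[pid]
        if sex is not None and d1.sex != sex:
            continue
        d1_block = taxonomy.block(d1.icd10)
        if exclude_same_chapter_d1 and d1_block[:2] == outcome_chapter:
            continue
        event_time: float | None = None
        censor_time = float(follow_up_days)
        for rec in cohort.events[pid]:
            t = (rec.event_date - d1.event_date).days
            if t < 0 or t > follow_up_days:
                continue
            if rec.event_type in ("DEATH", "EMIGRATION"):
                censor_time = min(censor_time, max(t, MIN_TIME_DAYS))
                continue
            if rec.event_date == d1.event_date and rec.icd10 == d1.icd10:
                continue
            if (
                taxonomy.chapter(rec.icd10) == outcome_chapter
                and taxonomy.block(rec.icd10) != d1_block
            ):
                event_time = max(float(t), MIN_TIME_DAYS)
                break
        if event_time is not None and event_time <= censor_time:
            time, event = event_time, 1
        else:
            time, event = censor_time, 0
        rows.append(
            {
                "person_id": pid,
                "exposed": int(taxonomy.map_code(d1.icd10) == d1_category),
                "time": time,
                "event": event,
            }
        )
    return pd.DataFrame(rows, columns=["person_id", "exposed", "time", "event"])


@dataclass
class HazardContrast:
    """Fitted exposure-versus-rest hazard contrast."""

    d1_category: str
    outcome_chapter: str
    hr: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_exposed: int
    n_unexposed: int
    n_events: int
    flag: str | None = None  # None = clean fit

    def to_dict(self) -> dict:
        return {
            "d1_category": self.d1_category,
            "outcome_chapter": self.outcome_chapter,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "n_exposed": self.n_exposed,
            "n_unexposed": self.n_unexposed,
            "n_events": self.n_events,
            "flag": self.flag,
        }


def fit_hazard_contrast(
    rows: pd.DataFrame,
    ci_level: float = 0.999,
    d1_category: str = "",
    outcome_chapter: str = "",
) -> HazardContrast:
    """Fit the binary-exposure proportional-hazards contrast.

    Degenerate inputs (an empty arm, no events, zero events in one arm, or
    non-convergence) yield a flagged result with NaN estimates rather than
    an exception.
    """
    n_exposed = int((rows["exposed"] == 1).sum())
    n_unexposed = int((rows["exposed"] == 0).sum())
    n_events = int(rows["event"].sum())

    def flagged(flag: str) -> HazardContrast:
        return HazardContrast(
            d1_category, outcome_chapter, float("nan"), float("nan"),
            float("nan"), ci_level, n_exposed, n_unexposed, n_events, flag,
        )

    if n_exposed == 0 or n_unexposed == 0:
        return flagged("empty_arm")
    if n_events == 0:
        return flagged("no_events")
    events_by_arm = rows.groupby("exposed")["event"].sum()
    if (events_by_arm == 0).any():
        return flagged("zero_events_in_arm")

    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(
                rows[["time", "event", "exposed"]],
                duration_col="time",
                event_col="event",
            )
    except (ConvergenceError, ValueError):
        return flagged("convergence")
    coef = float(fitter.params_["exposed"])
    se = float(fitter.standard_errors_["exposed"])
    if not np.isfinite(coef) or not np.isfinite(se):
        return flagged("separation")
    if se > 50:
        # monotone partial likelihood: point estimate reported, CI undefined
        return HazardContrast(
            d1_category, outcome_chapter, float(np.exp(coef)), float("nan"),
            float("nan"), ci_level, n_exposed, n_unexposed, n_events,
            "separation",
        )
    z = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    return HazardContrast(
        d1_category=d1_category,
        outcome_chapter=outcome_chapter,
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        ci_level=ci_level,
        n_exposed=n_exposed,
        n_unexposed=n_unexposed,
        n_events=n_events,
    )


@dataclass
class BonferroniPlan:
    """Multiplicity adjustment: alpha/n tests, rendered as widened CIs."""

    n_tests: int
    alpha: float = 0.05

    @property
    def alpha_adjusted(self) -> float:
        return self.alpha / self.n_tests

    @property
    def ci_level(self) -> float:
        return 1.0 - self.alpha_adjusted


def bonferroni_plan(n_tests: int, alpha: float = 0.05) -> BonferroniPlan:
    """Per-test significance level and CI level for ``n_tests`` contrasts."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return BonferroniPlan(n_tests=n_tests, alpha=alpha)


def hazard_grid(
    cohort: CohortIndex,
    taxonomy: CategoryTaxonomy | None = None,
    sexes: Iterable[str] = ("F", "M"),
    chapters: Iterable[str] = CHAPTERS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All (sex, entry category, outcome chapter) contrasts with a shared
    Bonferroni plan.

    Contrasts with zero events in both arms are skipped and reported with a
    ``skipped_no_events`` flag; the Bonferroni denominator is the number of
    contrasts actually fitted, derived from the grid at run time.
    """
    taxonomy = taxonomy or CategoryTaxonomy.default()
    jobs = []
    for sex in sexes:
        present = sorted(
            {
                taxonomy.map_code(cohort.d1[p].icd10)
                for p in cohort.person_ids
                if cohort.d1[p].sex == sex
            }
        )
        for cat in present:
            for chapter in chapters:
                rows = make_time_to_event(cohort, taxonomy, cat, chapter, sex=sex)
                if rows.empty or rows["event"].sum() == 0:
                    jobs.append((sex, cat, chapter, rows, "skipped_no_events"))
                else:
                    jobs.append((sex, cat, chapter, rows, None))
    n_tests = sum(1 for j in jobs if j[4] is None)
    plan = bonferroni_plan(max(n_tests, 1), alpha=alpha)
    out = []
    for sex, cat, chapter, rows, skip in jobs:
        if skip is not None:
            res = HazardContrast(
                cat, chapter, float("nan"), float("nan"), float("nan"),
                plan.ci_level, int((rows["exposed"] == 1).sum()) if not rows.empty else 0,
                int((rows["exposed"] == 0).sum()) if not rows.empty else 0,
                0, skip,
            )
        else:
            res = fit_hazard_contrast(
                rows, ci_level=plan.ci_level, d1_category=cat,
                outcome_chapter=chapter,
            )
        d = res.to_dict()
        d["sex"] = sex
        d["n_tests"] = n_tests
        out.append(d)
    cols = [
        "sex", "d1_category", "outcome_chapter", "hr", "ci_low", "ci_high",
        "ci_level", "n_exposed", "n_unexposed", "n_events", "flag", "n_tests",
    ]
    return pd.DataFrame(out, columns=cols)
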