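"""Synthetic registry cohort generator with known ground truth.

Real national-registry diagnostic data are not publicly available, so every
downstream stage is exercised on cohorts drawn from a generative model that
emulates the registry's statistical structure:

* per-sex mixture over the 19 entry-diagnosis categories with per-category
  mean onset ages (calibrated to the published cohort structure where
  stated; see ``data/cohort_default.yaml``),
* a per-sex discrete-time Markov transition matrix over categories, applied
  once per 12-month period, with high self-transition ("stay") probability,
* rare per-period death and emigration hazards that truncate follow-up
  (death drawn first, so death wins ties), and
* a 3-level parental-education covariate.

A person's latent 10-period state path is returned alongside the emitted
records (:class:`GroundTruth`), so sequence reconstruction, shift prevalence
and entropy summaries can be checked against exact expectations.  Identical
seeds give byte-identical record files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .records import DiagnosisRecord
from .taxonomy import CATEGORIES, DEAD, EMIGRATED, CategoryTaxonomy

N_PERIODS = 10


class ConfigError(ValueError):
    """Raised for invalid synthetic-cohort configurations."""


def _as_prob_vector(d: dict[str, float], labels: tuple[str, ...], name: str) -> np.ndarray:
    missing = [c for c in labels if c not in d]
    if missing:
        raise ConfigError(f"{name}: missing entries for {missing}")
    v = np.array([float(d[c]) for c in labels])
    total = v.sum()
    if total <= 0:
        raise ConfigError(f"{name}: non-positive total")
    # percentages are accepted and renormalized to probabilities
    v = v / total
    if abs(v.sum() - 1.0) > 1e-9:
        raise ConfigError(f"{name}: does not sum to 1")
    return v


def _stay_matrix(stay: float, k: int) -> np.ndarray:
    if not 0.0 <= stay <= 1.0:
        raise ConfigError(f"stay probability {stay} outside [0, 1]")
    off = (1.0 - stay) / (k - 1)
    m = np.full((k, k), off)
    np.fill_diagonal(m, stay)
    return m


@dataclass
class SyntheticCohortConfig:
    """Full parameterization of the generative cohort model.

    ``d1_mixture`` and ``onset_age_mean`` are per-sex dicts keyed by
    category; mixtures may be given as percentages (renormalized).
    ``transition_matrix`` is a per-sex 19x19 row-stochastic matrix in
    :data:`~diagtraj.taxonomy.CATEGORIES` order.
    """

    n_persons: int
    sex_split: float  # proportion female
    d1_mixture: dict[str, dict[str, float]]
    onset_age_mean: dict[str, dict[str, float]]
    onset_age_sd: float
    transition_matrix: dict[str, np.ndarray]
    p_death: float
    p_emigrate: float
    education_mixture: dict[str, float]
    entry_window: tuple[date, date]
    seed: int = 0
    _mix: dict[str, np.ndarray] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be positive")
        if not 0.0 <= self.sex_split <= 1.0:
            raise ConfigError("sex_split must lie in [0, 1]")
        for p, name in ((self.p_death, "p_death"), (self.p_emigrate, "p_emigrate")):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for sex in ("F", "M"):
            self._mix[sex] = _as_prob_vector(
                self.d1_mixture[sex], CATEGORIES, f"d1_mixture[{sex}]"
            )
            m = np.asarray(self.transition_matrix[sex], dtype=float)
            if m.shape != (len(CATEGORIES), len(CATEGORIES)):
                raise ConfigError(f"transition_matrix[{sex}] must be 19x19")
            if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
                raise ConfigError(f"transition_matrix[{sex}] is not row-stochastic")
            self.transition_matrix[sex] = m
            missing = [c for c in CATEGORIES if c not in self.onset_age_mean[sex]]
            if missing:
                raise ConfigError(f"onset_age_mean[{sex}]: missing {missing}")
        edu = self.education_mixture
        if abs(sum(edu.values()) - 1.0) > 1e-9:
            raise ConfigError("education_mixture must sum to 1")
        lo, hi = self.entry_window
        if hi < lo:
            raise ConfigError("entry_window end precedes start")

    # ------------------------------------------------------------------ load

    @classmethod
    def from_dict(cls, raw: dict[str, Any], **overrides: Any) -> "SyntheticCohortConfig":
        raw = dict(raw)
        raw.update(overrides)
        stay = raw.pop("stay_probability", None)
        tm = raw.pop("transition_matrix", None)
        if tm is not None:
            matrices = {s: np.asarray(tm[s], dtype=float) for s in ("F", "M")}
        elif stay is not None:
            matrices = {s: _stay_matrix(float(stay[s]), len(CATEGORIES)) for s in ("F", "M")}
        else:
            raise ConfigError("config needs transition_matrix or stay_probability")
        window = raw.pop("entry_window")
        window = tuple(
            d if isinstance(d, date) else date.fromisoformat(str(d)) for d in window
        )
        return cls(
            n_persons=int(raw["n_persons"]),
            sex_split=float(raw["sex_split"]),
            d1_mixture=raw["d1_mixture"],
            onset_age_mean=raw["onset_age_mean"],
            onset_age_sd=float(raw["onset_age_sd"]),
            transition_matrix=matrices,
            p_death=float(raw["p_death"]),
            p_emigrate=float(raw["p_emigrate"]),
            education_mixture=raw["education_mixture"],
            entry_window=window,  # type: ignore[arg-type]
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "SyntheticCohortConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh), **overrides)

    @classmethod
    def default(cls, **overrides: Any) -> "SyntheticCohortConfig":
        ref = resources.files("diagtraj.data").joinpath("cohort_default.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path, **overrides)


@dataclass
class GroundTruth:
    """Latent per-person state paths and the configured dynamics."""

    latent_paths: dict[str, tuple[str, ...]]
    d1_category: dict[str, str]
    sex: dict[str, str]
    transition_matrix: dict[str, np.ndarray]

    def expected_shift_by_sex(self) -> dict[str, float]:
        """Mixture-weighted expected probability of >= 1 shift per sex.

        Uses each person's configured stay probability; absorbing hazards
        are ignored (they truncate exposure, lowering observed prevalence
        slightly when nonzero).
        """
        out: dict[str, float] = {}
        for sex in ("F", "M"):
            pids = [p for p, s in self.sex.items() if s == sex]
            if not pids:
                continue
            idx = {c: i for i, c in enumerate(CATEGORIES)}
            stays = [
                self.transition_matrix[sex][idx[self.d1_category[p]], idx[self.d1_category[p]]]
                for p in pids
            ]
            out[sex] = float(np.mean([expected_shift_probability(s) for s in stays]))
        return out

    def to_json_dict(self) -> dict:
        return {
            "d1_category": self.d1_category,
            "sex": self.sex,
            "latent_paths": {p: list(v) for p, v in self.latent_paths.items()},
        }


def expected_shift_probability(stay: float, n_transitions: int = 9) -> float:
    """Probability of at least one category change over ``n_transitions``
    independent per-period draws with self-transition probability ``stay``."""
    if not 0.0 <= stay <= 1.0:
        raise ConfigError(f"stay probability {stay} outside [0, 1]")
    return 1.0 - stay**n_transitions


def _period_start(entry: date, k: int) -> date:
    """Start date of period k (1-based): entry + 12*(k-1) months,
    end-of-month clamped."""
    return (pd.Timestamp(entry) + pd.DateOffset(months=12 * (k - 1))).date()


def generate_cohort(
    config: SyntheticCohortConfig,
    taxonomy: CategoryTaxonomy | None = None,
) -> tuple[list[DiagnosisRecord], GroundTruth]:
    """Draw a cohort of diagnostic event records plus its ground truth.

    Per person: sex, parental education, entry category and onset age are
    sampled; the entry diagnosis record carries a code drawn uniformly from
    the category's code set.  For periods 2..10 a death draw, then an
    emigration draw, then a Markov transition decide the period's state; a
    dated record is emitted only on change (strictly inside the period).
    """
    taxonomy = taxonomy or CategoryTaxonomy.default()
    rng = np.random.default_rng(config.seed)
    cat_codes = {c: taxonomy.codes_for_category(c) for c in CATEGORIES}
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    edu_labels = tuple(config.education_mixture)
    edu_p = np.array([config.education_mixture[e] for e in edu_labels], dtype=float)
    edu_p = edu_p / edu_p.sum()
    lo, hi = config.entry_window
    window_days = (hi - lo).days

    records: list[DiagnosisRecord] = []
    paths: dict[str, tuple[str, ...]] = {}
    d1_cat: dict[str, str] = {}
    sexes: dict[str, str] = {}
    width = max(6, len(str(config.n_persons)))

    for i in range(config.n_persons):
        pid = f"P{i:0{width}d}"
        sex = "F" if rng.random() < config.sex_split else "M"
        education = str(rng.choice(edu_labels, p=edu_p))
        cat = str(rng.choice(CATEGORIES, p=config._mix[sex]))
        mean_age = float(config.onset_age_mean[sex][cat])
        age = float(rng.normal(mean_age, config.onset_age_sd))
        while not 0.5 <= age < 17.95:  # entry requires age < 18.0 years
            age = float(rng.normal(mean_age, config.onset_age_sd))
        entry = lo + timedelta(days=int(rng.integers(0, window_days + 1)))
        birth = entry - timedelta(days=int(round(age * 365.25)))

        records.append(
            DiagnosisRecord(pid, sex, birth, entry, "DIAGNOSIS",
                            str(rng.choice(cat_codes[cat])), education)
        )
        path: list[str] = [cat]
        current = cat
        row = config.transition_matrix[sex][cat_index[cat]]
        for k in range(2, N_PERIODS + 1):
            start = _period_start(entry, k)
            span = (_period_start(entry, k + 1) - start).days
            if rng.random() < config.p_death:
                when = start + timedelta(days=int(rng.integers(1, span - 1)))
                records.append(DiagnosisRecord(pid, sex, birth, when, "DEATH",
                                               "", education))
                path.extend([DEAD] * (N_PERIODS + 1 - k))
                break
            if rng.random() < config.p_emigrate:
                when = start + timedelta(days=int(rng.integers(1, span - 1)))
                records.append(DiagnosisRecord(pid, sex, birth, when, "EMIGRATION",
                                               "", education))
                path.extend([EMIGRATED] * (N_PERIODS + 1 - k))
                break
            nxt = str(rng.choice(CATEGORIES, p=row))
            if nxt != current:
                when = start + timedelta(days=int(rng.integers(1, span - 1)))
                records.append(DiagnosisRecord(pid, sex, birth, when, "DIAGNOSIS",
                                               str(rng.choice(cat_codes[nxt])), education))
                current = nxt
                row = config.transition_matrix[sex][cat_index[current]]
            path.append(current)
        paths[pid] = tuple(path)
        d1_cat[pid] = cat
        sexes[pid] = sex

    truth = GroundTruth(
        latent_paths=paths, d1_category=d1_cat, sex=sexes,
        transition_matrix=config.transition_matrix,
    )
    return records, truth
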