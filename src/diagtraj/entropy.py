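"""Normalized sequence entropy and group contrasts.

The diversity of a person's 10-period trajectory is measured by the Shannon
entropy of its state-occupancy distribution, normalized by the entropy of
the alphabet (log of the alphabet size), so h ranges from 0 (all periods in
one state) to 1 (equal time in every alphabet state, attainable when the
sequence length is a multiple of the alphabet size).  The measure depends
only on occupancy fractions, not on ordering — it quantifies diversity, not
transition structure.

By default the alphabet counts all 21 states (19 diagnostic categories plus
the two absorbing states); a 19-letter diagnostic-only alphabet is available
via ``alphabet_size=19``.  Natural logarithms are used; normalization makes
the base irrelevant.

Group contrasts follow standard practice: Welch's unequal-variance t-test
for two groups, one-way ANOVA for three or more.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import SequenceSet, StateSequence

DEFAULT_ALPHABET_SIZE = 21

_BOUND_SNAP = 1e-12  # float guard: h is mathematically confined to [0, 1]


def normalized_entropy(
    seq: StateSequence | Sequence[str],
    alphabet_size: int = DEFAULT_ALPHABET_SIZE,
) -> float:
    """Normalized Shannon entropy of a state sequence.

    With p_i the fraction of periods spent in state i,
    ``h = -(sum p_i ln p_i) / ln(alphabet_size)``; empty categories
    contribute nothing.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be at least 2")
    states = seq.states if isinstance(seq, StateSequence) else tuple(seq)
    if not states:
        raise ValueError("empty sequence")
    counts = Counter(states)
    if len(counts) > alphabet_size:
        raise ValueError(
            f"sequence uses {len(counts)} distinct states, more than the "
            f"alphabet size {alphabet_size}"
        )
    n = len(states)
    h = -math.fsum((c / n) * math.log(c / n) for c in counts.values())
    h /= math.log(alphabet_size)
    if h < _BOUND_SNAP:
        return 0.0
    if abs(h - 1.0) < _BOUND_SNAP:
        return 1.0
    return min(h, 1.0)


def entropy_by_person(
    sequences: Iterable[StateSequence],
    alphabet_size: int = DEFAULT_ALPHABET_SIZE,
) -> pd.DataFrame:
    """Per-person entropy table (person_id, h)."""
    rows = [
        {"person_id": q.person_id, "h": normalized_entropy(q, alphabet_size)}
        for q in sequences
    ]
    return pd.DataFrame(rows, columns=["person_id", "h"])


def summarize_entropy(
    sets: Iterable[SequenceSet],
    alphabet_size: int = DEFAULT_ALPHABET_SIZE,
    min_count: int = 5,
) -> pd.DataFrame:
    """Mean/sd entropy per stratum.

    Strata with fewer than ``min_count`` sequences are flagged
    ``suppressed``; renderers must not display their values, but counts are
    retained so totals stay auditable.
    """
    rows = []
    for sset in sets:
        h = np.array(
            [normalized_entropy(q, alphabet_size) for q in sset.sequences]
        )
        rows.append(
            {
                "stratum": "|".join(sset.label),
                "n": len(h),
                "mean_h": float(h.mean()),
                "sd_h": float(h.std(ddof=1)) if len(h) > 1 else 0.0,
                "suppressed": len(h) < min_count,
            }
        )
    return pd.DataFrame(
        rows, columns=["stratum", "n", "mean_h", "sd_h", "suppressed"]
    )


@dataclass
class GroupComparison:
    """Result of an entropy group contrast."""

    test: str  # "welch_t", "anova", or "insufficient_data"
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: pd.DataFrame  # name, n, mean, sd

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "groups": self.groups.to_dict(orient="records"),
        }


def compare_entropy_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Contrast mean entropy across groups.

    Two groups: Welch two-sample t-test.  Three or more: one-way ANOVA.
    Any group with fewer than two observations yields an explicit
    insufficient-data result rather than an exception.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    summary = pd.DataFrame(
        [
            {
                "name": k,
                "n": len(a),
                "mean": float(a.mean()) if len(a) else float("nan"),
                "sd": float(a.std(ddof=1)) if len(a) > 1 else float("nan"),
            }
            for k, a in arrays.items()
        ]
    )
    if any(len(a) < 2 for a in arrays.values()):
        return GroupComparison(
            "insufficient_data", float("nan"), (), float("nan"), summary
        )
    values = list(arrays.values())
    if len(values) == 2:
        res = stats.ttest_ind(values[0], values[1], equal_var=False)
        return GroupComparison(
            "welch_t", float(res.statistic), (float(res.df),),
            float(res.pvalue), summary,
        )
    res = stats.f_oneway(*values)
    k = len(values)
    n_total = sum(len(a) for a in values)
    return GroupComparison(
        "anova", float(res.statistic), (float(k - 1), float(n_total - k)),
        float(res.pvalue), summary,
    )
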