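"""ICD-10 F-chapter code mapping to the 19 analysis categories and F0-F9 chapters.

Child/adolescent psychiatric diagnoses are recorded as ICD-10 mental and
behavioural disorder codes (F00-F99).  For trajectory analysis these are
grouped into 19 clinically motivated categories (substance use, schizophrenia
spectrum, bipolar, depression, ... , a closed "other" residual).  The grouping
is rule based: block-level inclusions (e.g. F10-F19 -> SUD) with
subcode-level exceptions that take precedence (e.g. F84 -> ASD but
F84.2-F84.4 -> OTHER).  Codes claimed by no rule (F00-F09 organic disorders,
F94.0, F98.7, F85-F87, F96-F97, bare F98) map to the sentinel ``UNMAPPED``
and are excluded from sequences but reported on ingest.

The rule set ships as an editable delimited file; ``CategoryTaxonomy.default()``
loads it.  Matching is longest-prefix on the normalized (dot-stripped) code,
so a four-cipher rule always beats its parent block.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

#: The 19 diagnostic categories reachable from ICD-10 mapping.
CATEGORIES: tuple[str, ...] = (
    "SUD", "SZ", "BD", "SRD", "OMD", "AND", "OCD", "SAD", "SOM", "ED",
    "PD", "ID", "ODD", "ASD", "ADHD", "CD", "AD", "TD", "OTHER",
)

#: Absorbing sequence states; never produced by code mapping.
DEAD = "DEAD"
EMIGRATED = "EMIGRATED"
ABSORBING_STATES: tuple[str, str] = (DEAD, EMIGRATED)

#: Full 21-letter sequence alphabet.
SEQUENCE_ALPHABET: tuple[str, ...] = CATEGORIES + ABSORBING_STATES

#: Sentinel for codes claimed by no rule.
UNMAPPED = "UNMAPPED"

CHAPTERS: tuple[str, ...] = tuple(f"F{i}" for i in range(10))

_CODE_RE = re.compile(r"^F(\d{2})(?:\.(\d{1,2}))?$")


class InvalidCodeError(ValueError):
    """Raised for strings that are not syntactically valid F-chapter codes."""


def normalize_code(code: str) -> str:
    """Return the canonical form of an ICD-10 F-code (e.g. ``"F84.0"``).

    Whitespace is stripped and the string upper-cased.  Raises
    :class:`InvalidCodeError` naming the offending token otherwise.
    """
    if not isinstance(code, str):
        raise InvalidCodeError(f"ICD-10 code must be a string, got {code!r}")
    cleaned = re.sub(r"\s+", "", code).upper()
    m = _CODE_RE.match(cleaned)
    if m is None:
        raise InvalidCodeError(f"not a valid ICD-10 F-code: {code!r}")
    return cleaned


def _dotless(code: str) -> str:
    return code.replace(".", "")


def _undot(prefix: str) -> str:
    # "F840" -> "F84.0"; "F84" -> "F84"
    return prefix if len(prefix) <= 3 else prefix[:3] + "." + prefix[3:]


def _expand_rule_token(token: str) -> list[str]:
    """Expand a rule token into dotless prefixes.

    Accepts single codes ("F42", "F98.8"), block ranges ("F10-F19") and
    subcode ranges within one block ("F84.2-F84.4", "F98.0-F98.6").
    """
    token = token.strip().upper()
    if not token:
        return []
    if "-" in token:
        lo, hi = (t.strip() for t in token.split("-", 1))
        lo_m, hi_m = _CODE_RE.match(lo), _CODE_RE.match(hi)
        if lo_m is None or hi_m is None:
            raise InvalidCodeError(f"bad rule range: {token!r}")
        if lo_m.group(2) is None and hi_m.group(2) is None:
            a, b = int(lo_m.group(1)), int(hi_m.group(1))
            if b < a:
                raise InvalidCodeError(f"descending rule range: {token!r}")
            return [f"F{i:02d}" for i in range(a, b + 1)]
        if lo_m.group(1) == hi_m.group(1) and lo_m.group(2) and hi_m.group(2):
            a, b = int(lo_m.group(2)), int(hi_m.group(2))
            if b < a:
                raise InvalidCodeError(f"descending rule range: {token!r}")
            return [f"F{lo_m.group(1)}{i}" for i in range(a, b + 1)]
        raise InvalidCodeError(f"mixed-resolution rule range: {token!r}")
    return [_dotless(normalize_code(token))]


@dataclass(frozen=True)
class CategoryTaxonomy:
    """Rule set mapping ICD-10 F-codes to diagnostic categories.

    ``rules`` maps dotless code prefixes to a category label, or to ``None``
    for explicit exclusions claimed by no other category (tombstones).
    """

    rules: dict[str, str | None] = field(repr=False)
    source: str = "default"

    # ------------------------------------------------------------------ load

    @classmethod
    def from_rows(cls, rows: Iterable[dict[str, str]], source: str = "custom") -> "CategoryTaxonomy":
        includes: dict[str, str] = {}
        excludes: list[str] = []
        for row in rows:
            cat = row["category"].strip()
            for token in (row.get("include") or "").split(";"):
                for prefix in _expand_rule_token(token):
                    if prefix in includes and includes[prefix] != cat:
                        raise ValueError(
                            f"prefix {_undot(prefix)} claimed by both "
                            f"{includes[prefix]} and {cat}"
                        )
                    includes[prefix] = cat
            for token in (row.get("exclude") or "").split(";"):
                excludes.extend(_expand_rule_token(token))
        rules: dict[str, str | None] = dict(includes)
        for prefix in excludes:
            rules.setdefault(prefix, None)  # tombstone unless claimed elsewhere
        return cls(rules=rules, source=source)

    @classmethod
    def from_file(cls, path: str | Path) -> "CategoryTaxonomy":
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as fh:
            sample = fh.read(2048)
            fh.seek(0)
            delim = "\t" if "\t" in sample.splitlines()[0] else ","
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or "category" not in reader.fieldnames:
                raise ValueError(f"taxonomy file {path} lacks a 'category' column")
            return cls.from_rows(list(reader), source=str(path))

    @classmethod
    def default(cls) -> "CategoryTaxonomy":
        ref = resources.files("diagtraj.data").joinpath("taxonomy_default.csv")
        with resources.as_file(ref) as path:
            tax = cls.from_file(path)
        return cls(rules=tax.rules, source="default")

    # ------------------------------------------------------------------- map

    def map_code(self, code: str) -> str:
        """Map a code to its category label, or ``UNMAPPED``."""
        dotless = _dotless(normalize_code(code))
        for end in range(len(dotless), 2, -1):  # longest prefix first
            hit = self.rules.get(dotless[:end], "missing")
            if hit != "missing":
                return hit if hit is not None else UNMAPPED
        return UNMAPPED

    @staticmethod
    def chapter(code: str) -> str:
        """1-cipher chapter of a code: ``"F32.1" -> "F3"``."""
        return normalize_code(code)[:2]

    @staticmethod
    def block(code: str) -> str:
        """2-cipher block of a code: ``"F32.1" -> "F32"``."""
        return normalize_code(code)[:3]

    # ---------------------------------------------------------------- survey

    @property
    def categories(self) -> tuple[str, ...]:
        seen = {c for c in self.rules.values() if c is not None}
        return tuple(c for c in CATEGORIES if c in seen) + tuple(
            sorted(seen - set(CATEGORIES))
        )

    def category_count(self) -> int:
        """Number of distinct mappable categories in this rule set."""
        return len(self.categories)

    def codes_for_category(self, category: str) -> tuple[str, ...]:
        """Concrete codes of a category, for synthetic record emission.

        Block-level prefixes contribute the bare block code plus any
        single-decimal subcodes still mapping to the category (subcode-level
        exceptions are honoured); subcode prefixes contribute themselves.
        """
        codes: list[str] = []
        for prefix, cat in sorted(self.rules.items()):
            if cat != category:
                continue
            code = _undot(prefix)
            if len(prefix) == 3:
                if self.map_code(code) == category:
                    codes.append(code)
                for d in range(10):
                    sub = f"{code}.{d}"
                    if self.map_code(sub) == category:
                        codes.append(sub)
            else:
                if self.map_code(code) == category:
                    codes.append(code)
        if not codes:
            raise KeyError(f"no codes map to category {category!r}")
        return tuple(dict.fromkeys(codes))


def all_two_cipher_codes() -> tuple[str, ...]:
    """All 100 two-cipher codes F00..F99."""
    return tuple(f"F{i:02d}" for i in range(100))
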