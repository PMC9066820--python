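"""Adverse-event and drug terminologies with query expansion.

Two small dictionaries drive every query in the package:

* a MedDRA-style event dictionary mapping each Preferred Term (PT) to one
  High Level Term (HLT) and one System Organ Class (SOC), and
* an ATC-style drug dictionary mapping each active ingredient to one or more
  Anatomical Therapeutic Chemical (ATC) codes.

Queries are phrased against either dictionary (a PT or HLT label; an ATC
prefix or an explicit ingredient set) and are *expanded* to the concrete set
of PT labels or ingredient labels used for report matching.

Labels are matched case-insensitively after whitespace normalization, and
typographic apostrophes are folded to ASCII, because spontaneous-report
sources are inconsistent in both respects.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from .errors import ParseError, TermLookupError, ValidationError

__all__ = [
    "TermRecord",
    "DrugRecord",
    "TermQuery",
    "DrugQuery",
    "TermDictionary",
    "DrugDictionary",
    "normalize_label",
    "is_valid_atc_prefix",
    "expand_term_query",
    "expand_drug_query",
    "DEFAULT_ROLE_FILTER",
]

_WS = re.compile(r"\s+")

#: Drug roles on a report; purely concomitant drugs are excluded from
#: observed counts by default, per spontaneous-reporting convention.
ROLES = frozenset({"suspected", "interacting", "concomitant"})
DEFAULT_ROLE_FILTER = frozenset({"suspected", "interacting"})

# ATC codes are hierarchical: A / A02 / A02B / A02BC / A02BC01.  A prefix is
# valid iff it stops at one of those level boundaries.
_ATC_PREFIX = re.compile(r"^[A-Za-z](\d{2}([A-Za-z]([A-Za-z](\d{2})?)?)?)?$")
_ATC_FULL_LEVELS = (1, 3, 4, 5, 7)


def normalize_label(label: str) -> str:
    """Canonical form used for all label comparisons."""
    s = label.replace("’", "'").replace("‘", "'").strip()
    return _WS.sub(" ", s).casefold()


def is_valid_atc_prefix(code: str) -> bool:
    return bool(_ATC_PREFIX.match(code)) and len(code) in _ATC_FULL_LEVELS


@dataclass(frozen=True)
class TermRecord:
    """One Preferred Term with its single-path parents."""

    pt: str
    hlt: str
    soc: str

    def __post_init__(self) -> None:
        if not self.pt.strip():
            raise ValidationError("PT label must be non-empty")
        if not self.hlt.strip():
            raise ValidationError(f"PT {self.pt!r}: HLT label must be non-empty")


@dataclass(frozen=True)
class DrugRecord:
    """One active ingredient with its ATC code set."""

    ingredient: str
    atc_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.ingredient.strip():
            raise ValidationError("ingredient label must be non-empty")
        for code in self.atc_codes:
            if not is_valid_atc_prefix(code):
                raise ValidationError(
                    f"ingredient {self.ingredient!r}: invalid ATC code {code!r}"
                )


@dataclass(frozen=True)
class TermQuery:
    """An event query at PT or HLT level."""

    level: Literal["PT", "HLT"]
    label: str

    def __post_init__(self) -> None:
        if self.level not in ("PT", "HLT"):
            raise ValidationError(f"unknown term query level {self.level!r}")


@dataclass(frozen=True)
class DrugQuery:
    """A drug query by ATC prefix or explicit ingredient set.

    ``role_filter`` restricts which drug roles on a report count as a match;
    it defaults to suspected + interacting.
    """

    mode: Literal["ATC_PREFIX", "INGREDIENT_SET"]
    value: str | frozenset[str]
    role_filter: frozenset[str] = DEFAULT_ROLE_FILTER

    def __post_init__(self) -> None:
        if self.mode not in ("ATC_PREFIX", "INGREDIENT_SET"):
            raise ValidationError(f"unknown drug query mode {self.mode!r}")
        if not self.role_filter:
            raise ValidationError("role_filter must be non-empty")
        if not self.role_filter <= ROLES:
            raise ValidationError(f"unknown roles {set(self.role_filter) - ROLES}")
        if self.mode == "ATC_PREFIX":
            if not isinstance(self.value, str) or not is_valid_atc_prefix(self.value):
                raise ValidationError(f"invalid ATC prefix {self.value!r}")
        else:
            object.__setattr__(self, "value", frozenset(self.value))

    @property
    def label(self) -> str:
        if self.mode == "ATC_PREFIX":
            return str(self.value)
        return "+".join(sorted(self.value))


class TermDictionary:
    """PT -> HLT -> SOC lookup with case-insensitive resolution."""

    def __init__(self, records: Iterable[TermRecord]):
        self._by_pt: dict[str, TermRecord] = {}
        self._by_hlt: dict[str, list[str]] = {}
        for rec in records:
            key = normalize_label(rec.pt)
            if key in self._by_pt:
                raise ValidationError(f"duplicate PT {rec.pt!r}")
            self._by_pt[key] = rec
            self._by_hlt.setdefault(normalize_label(rec.hlt), []).append(rec.pt)

    # -- container protocol -------------------------------------------------
    def __contains__(self, pt: str) -> bool:
        return normalize_label(pt) in self._by_pt

    def __len__(self) -> int:
        return len(self._by_pt)

    def __iter__(self) -> Iterator[TermRecord]:
        return iter(self._by_pt.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermDictionary):
            return NotImplemented
        return self._by_pt == other._by_pt

    # -- lookups ------------------------------------------------------------
    @property
    def n_hlts(self) -> int:
        return len(self._by_hlt)

    def record(self, pt: str) -> TermRecord:
        try:
            return self._by_pt[normalize_label(pt)]
        except KeyError:
            raise TermLookupError(f"unknown PT {pt!r}") from None

    def hlt_of(self, pt: str) -> str:
        return self.record(pt).hlt

    def soc_of(self, pt: str) -> str:
        return self.record(pt).soc

    def pts_under_hlt(self, hlt: str) -> set[str]:
        try:
            return set(self._by_hlt[normalize_label(hlt)])
        except KeyError:
            raise TermLookupError(f"unknown HLT {hlt!r}") from None

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "TermDictionary":
        """Load from a `pt,hlt,soc` CSV table (UTF-8, quoted fields allowed)."""
        records = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"pt", "hlt", "soc"} <= set(
                reader.fieldnames
            ):
                raise ParseError(
                    f"{path}: expected header columns pt,hlt,soc "
                    f"(got {reader.fieldnames})",
                    line=1,
                )
            for row in reader:
                lineno = reader.line_num
                if any(row.get(c) is None for c in ("pt", "hlt", "soc")):
                    raise ParseError(f"{path}: short row", line=lineno)
                try:
                    records.append(
                        TermRecord(pt=row["pt"], hlt=row["hlt"], soc=row["soc"])
                    )
                except ValidationError as exc:
                    raise ParseError(f"{path}: {exc}", line=lineno) from exc
        return cls(records)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pt", "hlt", "soc"])
            for rec in self:
                writer.writerow([rec.pt, rec.hlt, rec.soc])


class DrugDictionary:
    """Ingredient -> ATC code set lookup with prefix expansion."""

    def __init__(self, records: Iterable[DrugRecord]):
        self._by_ingredient: dict[str, DrugRecord] = {}
        for rec in records:
            key = normalize_label(rec.ingredient)
            if key in self._by_ingredient:
                raise ValidationError(f"duplicate ingredient {rec.ingredient!r}")
            self._by_ingredient[key] = rec

    def __contains__(self, ingredient: str) -> bool:
        return normalize_label(ingredient) in self._by_ingredient

    def __len__(self) -> int:
        return len(self._by_ingredient)

    def __iter__(self) -> Iterator[DrugRecord]:
        return iter(self._by_ingredient.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DrugDictionary):
            return NotImplemented
        return self._by_ingredient == other._by_ingredient

    def record(self, ingredient: str) -> DrugRecord:
        try:
            return self._by_ingredient[normalize_label(ingredient)]
        except KeyError:
            raise TermLookupError(f"unknown ingredient {ingredient!r}") from None

    def canonical(self, ingredient: str) -> str:
        return self.record(ingredient).ingredient

    def ingredients_with_prefix(self, prefix: str) -> set[str]:
        if not is_valid_atc_prefix(prefix):
            raise ValidationError(f"invalid ATC prefix {prefix!r}")
        p = prefix.upper()
        return {
            rec.ingredient
            for rec in self
            if any(code.upper().startswith(p) for code in rec.atc_codes)
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        """Load from an `ingredient,atc_code` CSV: one row per (ingredient, code)."""
        codes: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"ingredient", "atc_code"} <= set(
                reader.fieldnames
            ):
                raise ParseError(
                    f"{path}: expected header columns ingredient,atc_code "
                    f"(got {reader.fieldnames})",
                    line=1,
                )
            for row in reader:
                lineno = reader.line_num
                ing = (row.get("ingredient") or "").strip()
                code = (row.get("atc_code") or "").strip()
                if not ing:
                    raise ParseError(f"{path}: empty ingredient", line=lineno)
                if code and not is_valid_atc_prefix(code):
                    raise ParseError(f"{path}: invalid ATC code {code!r}", line=lineno)
                key = normalize_label(ing)
                names.setdefault(key, ing)
                codes.setdefault(key, set())
                if code:
                    codes[key].add(code)
        return cls(
            DrugRecord(ingredient=names[k], atc_codes=frozenset(v))
            for k, v in codes.items()
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ingredient", "atc_code"])
            for rec in self:
                if rec.atc_codes:
                    for code in sorted(rec.atc_codes):
                        writer.writerow([rec.ingredient, code])
                else:
                    writer.writerow([rec.ingredient, ""])


def expand_term_query(query: TermQuery, dictionary: TermDictionary) -> set[str]:
    """Expand an event query to the concrete set of PT labels it matches.

    A PT-level query returns the singleton set of its (canonical) label; an
    HLT-level query returns every PT filed under that HLT.  Unresolvable
    labels raise :class:`TermLookupError`; the result is never empty.
    """
    if query.level == "PT":
        return {dictionary.record(query.label).pt}
    return dictionary.pts_under_hlt(query.label)


def expand_drug_query(query: DrugQuery, dictionary: DrugDictionary) -> set[str]:
    """Expand a drug query to the concrete set of ingredient labels it matches.

    ATC-prefix expansion may legitimately be empty (the caller decides how to
    treat an empty class); an explicit ingredient set containing an unknown
    ingredient is an error.
    """
    if query.mode == "ATC_PREFIX":
        return dictionary.ingredients_with_prefix(str(query.value))
    assert isinstance(query.value, frozenset)
    return {dictionary.canonical(ing) for ing in query.value}
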