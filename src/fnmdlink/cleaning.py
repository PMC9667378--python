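"""Field normalisation, birth-date repair and derived name/city variants.

The mortality file records identities with a number of quirks that any
comparison has to survive: birth dates with day and month set to "00" or
with day and month inverted, compound or concatenated given names,
district suffixes on big-city birth places, and accent-free text.  This
module turns raw records of either side into :class:`CleanRecord` values
whose text fields contain only lowercase unaccented letters a-z, whose
birth date is always a valid 8-digit YYYYMMDD string, and which carry the
derived first-name variants and blocking keys the matcher relies on.

First-name variants (mortality side):

* ``firstname_0`` — first hyphen/space-delimited element ("pierre" from
  "Pierre-Olivier");
* ``firstname_1`` — the whole first name, cleaned ("pierreolivier");
* ``firstname_12`` — first name concatenated with the first middle name
  ("pierreolivierchristian"); equals ``firstname_1`` when there is no
  middle name.

The local registry may record a compound given name in one cell or the
first given name only; taking the minimum distance over the three
variants absorbs both conventions.
"""

from __future__ import annotations

import calendar
import re
import unicodedata
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .records import DataError, MortalityRecord, PersonRecord

BLOCK_PREFIX_LEN = 4

# NFKD leaves a few latin ligatures intact; expand them before stripping marks
_LIGATURES = str.maketrans({"œ": "oe", "Œ": "oe", "æ": "ae", "Æ": "ae",
                            "ß": "ss", "ø": "o", "Ø": "o"})

_NON_LETTER = re.compile(r"[^a-z]")

# trailing district mention: optional punctuation, an ordinal (digits plus
# optional e/eme/er suffix), optionally the word "arrondissement" (or a
# common abbreviation), e.g. ", 13ème arrondissement", " 3e", " 1er arrdt"
_DISTRICT = re.compile(
    r"[\s,;/-]*\d+\s*(?:e|eme|ème|er)?\.?\s*(?:arrondissement|arrdt|arrt|arr)?\.?\s*$",
    re.IGNORECASE,
)

_TOKEN_SPLIT = re.compile(r"[\s/-]+")


def normalize_text(raw: str | None) -> str:
    """Lowercase, strip accents, drop every non-letter character."""
    if not raw:
        return ""
    text = raw.translate(_LIGATURES)
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return _NON_LETTER.sub("", text.lower())


_DATE_SHAPE = re.compile(r"^\s*(\d{4})\D?(\d{1,2})\D?(\d{1,2})\s*$")


def _valid_day(year: int, month: int, day: int) -> bool:
    return (1 <= month <= 12 and 1 <= day <= calendar.monthrange(year, month)[1])


def repair_birth_date(raw: str) -> str:
    """Return a valid 8-digit YYYYMMDD for a possibly broken birth date.

    Repair order: a "00" day and month becomes January 1; a "00" day alone
    becomes day 1 of the stated month; a valid date is kept; an invalid
    date is kept with day and month swapped if the swap is valid;
    otherwise January 1 of the stated year.
    """
    m = _DATE_SHAPE.match(raw or "")
    if not m:
        raise DataError(f"no extractable year in birth date {raw!r}")
    year, month, day = int(m.group(1)), int(m.group(2)), int(m.group(3))
    if month == 0 and day == 0:
        month, day = 1, 1
    elif day == 0 and 1 <= month <= 12:
        day = 1
    elif not _valid_day(year, month, day):
        if _valid_day(year, day, month):
            month, day = day, month
        else:
            month, day = 1, 1
    return f"{year:04d}{month:02d}{day:02d}"


def clean_city(raw: str | None) -> str:
    """Suppress a trailing district mention, then normalise."""
    if not raw:
        return ""
    return normalize_text(_DISTRICT.sub("", raw))


@lru_cache(maxsize=1)
def abbreviation_table() -> dict[str, str]:
    """Token → expansion map from the packaged city-abbreviation resource."""
    text = (resources.files("fnmdlink") / "data" / "abbreviations.txt").read_text(
        encoding="utf-8")
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token, expansion = line.split("\t")
        table[normalize_text(token)] = normalize_text(expansion)
    return table


def expand_city_abbrev(raw: str | None) -> str:
    """Expand abbreviation tokens (st→saint, sr→sur, ...), then normalise."""
    if not raw:
        return ""
    table = abbreviation_table()
    tokens = [t for t in _TOKEN_SPLIT.split(raw) if t]
    expanded = [table.get(normalize_text(t), t) for t in tokens]
    return normalize_text(" ".join(expanded))


def build_firstname_variants(
    first_name: str,
    first_middle_name: str | None = None,
) -> tuple[str, str, str]:
    """Return (firstname_0, firstname_1, firstname_12)."""
    head = _TOKEN_SPLIT.split(first_name.strip())[0] if first_name else ""
    firstname_0 = normalize_text(head)
    firstname_1 = normalize_text(first_name)
    if not firstname_1:
        raise DataError(f"first name {first_name!r} is empty after cleaning")
    middle = normalize_text(first_middle_name) if first_middle_name else ""
    firstname_12 = firstname_1 + middle
    return firstname_0, firstname_1, firstname_12


@dataclass(frozen=True)
class CleanRecord:
    """Normalised fields plus derived variants and blocking keys."""

    source_id: str
    side: str  # "local" | "fnmd"
    firstname_0: str
    firstname_1: str
    firstname_12: str
    surname_birth: str | None
    surname_current: str | None  # local side only
    birth_date_repaired: str  # 8-digit YYYYMMDD
    sex: str | None
    city: str | None
    city_expanded: str | None  # local side only
    country_group: str | None  # "france" | "other" | None
    block_key_date: str
    block_key_name: str
    death_date: str | None = None  # fnmd side

    @property
    def preferred_surname(self) -> str | None:
        return self.surname_birth if self.surname_birth else self.surname_current


def _block_key_name(firstname_1: str, surname: str | None) -> str:
    return firstname_1[:BLOCK_PREFIX_LEN] + (surname or "")[:BLOCK_PREFIX_LEN]


def make_clean_record(
    record: PersonRecord | MortalityRecord,
    home_country: str = "france",
) -> CleanRecord:
    """Apply every cleaning step to one raw record of either side."""
    if isinstance(record, MortalityRecord):
        middle = record.middle_names[0] if record.middle_names else None
        f0, f1, f12 = build_firstname_variants(record.first_name, middle)
        surname_birth = normalize_text(record.surname) or None
        surname_current = None
        city = clean_city(record.birth_city) or None
        city_expanded = None
        side, source_id = "fnmd", record.fnmd_id
        death_date = record.death_date
    else:
        f0, f1, f12 = build_firstname_variants(record.first_name, None)
        surname_birth = normalize_text(record.birth_surname) or None
        surname_current = normalize_text(record.current_surname) or None
        city = clean_city(record.birth_city) or None
        city_expanded = expand_city_abbrev(
            _DISTRICT.sub("", record.birth_city)) or None if record.birth_city else None
        side, source_id = "local", record.record_id
        death_date = record.death_date
    if surname_birth is None and surname_current is None:
        raise DataError(f"record {source_id!r} has no surname at all")

    country = normalize_text(record.birth_country)
    country_group = (None if not country
                     else "france" if country == normalize_text(home_country)
                     else "other")
    date8 = repair_birth_date(record.birth_date_raw)
    preferred = surname_birth if surname_birth else surname_current
    return CleanRecord(
        source_id=source_id,
        side=side,
        firstname_0=f0,
        firstname_1=f1,
        firstname_12=f12,
        surname_birth=surname_birth,
        surname_current=surname_current,
        birth_date_repaired=date8,
        sex=record.sex,
        city=city,
        city_expanded=city_expanded,
        country_group=country_group,
        block_key_date=date8,
        block_key_name=_block_key_name(f1, preferred),
        death_date=death_date,
    )
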