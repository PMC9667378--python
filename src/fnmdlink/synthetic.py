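"""Synthetic linked registries with ground truth and error injection.

Generates a local patient registry and a matching mortality file the way
a hospital extract and a national death file would relate in practice:
every deceased cohort member (minus a configurable reporting loss) has a
mortality-file counterpart whose identity fields are corrupted by an
explicit error model — clerical typos, day/month inversions, "00" days
and months, split compound given names, married-name surname changes
with the birth surname sometimes missing on the hospital side, district
suffixes on big-city birth places, and accent loss (the mortality file
is accent-free at the source).  The mortality file additionally carries
background deaths of unrelated people and, optionally, decoys that share
a blocking key with a cohort member without being them.

Ground-truth identities are generated *pairwise distinguishable at the
matcher's learned thresholds*: no two distinct synthetic persons are
within the validation envelope of one another.  Real registries violate
this (homonyms born the same day exist), so synthetic specificity is an
upper bound; the property is what makes error-free runs a clean
calibration point (perfect sensitivity and specificity by
construction).

Stratum sizes (vital status × sex × country of birth) are derived from
the requested rates by largest-remainder rounding, so requested designs
are honoured exactly and deterministically.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._pools import CITIES_FR, FEMALE_FIRST, FOREIGN, MALE_FIRST, SURNAMES
from .cleaning import make_clean_record
from .distance import dld, field_distances
from .matching import Thresholds, validate_pair
from .records import (
    ColumnMapping,
    ConfigurationError,
    DataError,
    MortalityRecord,
    PersonRecord,
)

LETTERS = "abcdefghijklmnopqrstuvwxyz"
DIGITS = "0123456789"

_BIRTH_START = _dt.date(1920, 1, 1)
_BIRTH_DAYS = (_dt.date(1995, 12, 31) - _BIRTH_START).days + 1
_DEATH_START = _dt.date(2001, 1, 1)
_DEATH_DAYS = (_dt.date(2020, 12, 31) - _DEATH_START).days + 1
_PRE_START = _dt.date(2001, 1, 1)
_PRE_DAYS = (_dt.date(2015, 12, 31) - _PRE_START).days + 1
_POST_START = _dt.date(2016, 1, 2)
_POST_DAYS = (_dt.date(2020, 12, 31) - _POST_START).days + 1


@dataclass
class ErrorModel:
    """Rates of every corruption the generator can inject.

    All rates are probabilities in [0, 1] except ``background_rate``
    (background mortality records per cohort member, ≥ 0).  The defaults
    are synthetic design choices — not measured values — picked so the
    direct strategy loses on the order of ten sensitivity points to the
    distance-based strategy.
    """

    typo_rate: float = 0.025           # per field (surname, first name, date)
    sex_error_rate: float = 0.01
    married_name_rate: float = 0.30    # women whose current ≠ birth surname
    birth_surname_missing_rate: float = 0.15  # of married women, local side
    daymonth_swap_rate: float = 0.02   # mortality side, only visible if day > 12
    missing_daymonth_rate: float = 0.01  # mortality birth date "-00-00"
    compound_name_rate: float = 0.08   # "X-Y" locally, split in mortality file
    middle_name_rate: float = 0.60     # mortality file carries middle names
    district_suffix_rate: float = 0.50  # big-city births, mortality side
    accent_rate: float = 0.80          # local side keeps accents
    missing_record_rate: float = 0.02  # death never reported to the file
    decoy_rate: float = 0.05           # blocking-key decoys per cohort member
    background_rate: float = 2.0       # unrelated deaths per cohort member
    sex_male_rate: float = 0.5
    born_outside_rate: float = 0.5
    deceased_rate: float = 0.5

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "background_rate":
                if value < 0:
                    raise ConfigurationError("background_rate must be ≥ 0")
            elif not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{f.name} must be in [0, 1]")

    @classmethod
    def zero(cls) -> "ErrorModel":
        """No corruption at all: the mortality file contains exactly the
        uncorrupted counterparts of the deceased cohort members."""
        return cls(typo_rate=0.0, sex_error_rate=0.0, married_name_rate=0.0,
                   birth_surname_missing_rate=0.0, daymonth_swap_rate=0.0,
                   missing_daymonth_rate=0.0, compound_name_rate=0.0,
                   middle_name_rate=0.0, district_suffix_rate=0.0,
                   accent_rate=0.0, missing_record_rate=0.0, decoy_rate=0.0,
                   background_rate=0.0)


@dataclass
class GoldStandard:
    """Per-record truth for scoring a linkage run."""

    truth: dict[str, str] = field(default_factory=dict)  # deceased | living
    stratum: dict[str, str] = field(default_factory=dict)  # e.g. "f_france"
    true_match: dict[str, str | None] = field(default_factory=dict)
    death_date: dict[str, str] = field(default_factory=dict)
    #: living members: encounter dates straddling the index date
    encounters: dict[str, tuple[str, str]] = field(default_factory=dict)

    def gold_mapping(self) -> dict[str, tuple[str, str]]:
        return {rid: (self.truth[rid], self.stratum[rid]) for rid in self.truth}


def corrupt_field(value: str, kind: str, rng: np.random.Generator,
                  alphabet: str = LETTERS) -> str:
    """Apply one edit of the given kind; the result is at distance 1.

    Kinds: insertion, deletion, substitution, transposition.  Raises
    :class:`DataError` when the kind is infeasible for the value (empty
    input for non-insertions, no unequal adjacent characters for a
    transposition).
    """
    if kind == "insertion":
        pos = int(rng.integers(0, len(value) + 1))
        ch = alphabet[int(rng.integers(0, len(alphabet)))]
        return value[:pos] + ch + value[pos:]
    if not value:
        raise DataError(f"cannot apply {kind} to an empty string")
    if kind == "deletion":
        pos = int(rng.integers(0, len(value)))
        return value[:pos] + value[pos + 1:]
    if kind == "substitution":
        pos = int(rng.integers(0, len(value)))
        old = value[pos]
        choices = [c for c in alphabet if c.lower() != old.lower()]
        if not choices:
            raise DataError("alphabet offers no substitute character")
        ch = choices[int(rng.integers(0, len(choices)))]
        return value[:pos] + ch + value[pos + 1:]
    if kind == "transposition":
        positions = [i for i in range(len(value) - 1)
                     if value[i].lower() != value[i + 1].lower()]
        if not positions:
            raise DataError("no unequal adjacent characters to transpose")
        pos = positions[int(rng.integers(0, len(positions)))]
        return value[:pos] + value[pos + 1] + value[pos] + value[pos + 2:]
    raise ConfigurationError(f"unknown edit kind {kind!r}")


def random_edit(value: str, rng: np.random.Generator,
                alphabet: str = LETTERS) -> str:
    """One random single edit among the kinds feasible for the value."""
    kinds = ["insertion"]
    if value:
        kinds += ["deletion", "substitution"]
        if any(value[i].lower() != value[i + 1].lower()
               for i in range(len(value) - 1)):
            kinds.append("transposition")
    kind = kinds[int(rng.integers(0, len(kinds)))]
    return corrupt_field(value, kind, rng, alphabet)


def _strip_accents(text: str) -> str:
    import unicodedata
    out = unicodedata.normalize("NFKD", text.replace("œ", "oe").replace("æ", "ae"))
    return "".join(ch for ch in out if not unicodedata.combining(ch))


def _largest_remainder(n: int, shares: Sequence[float]) -> list[int]:
    raw = [n * s for s in shares]
    counts = [int(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i),
                   reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass
class _Person:
    pid: str
    sex: str
    first: str            # possibly compound "X-Y"
    middle: str | None
    birth_surname: str
    current_surname: str
    birth_date: _dt.date
    city: str
    city_abbrev: str | None
    city_big: bool
    country: str
    origin: str           # "france" | "other"
    deceased: bool
    death_date: _dt.date | None = None
    married: bool = False
    omit_birth_surname: bool = False


_STRATA_ORDER = [
    (vital, sex, origin)
    for vital in ("deceased", "living")
    for sex in ("m", "f")
    for origin in ("france", "other")
]


def _person_records(p: _Person, keep_accents: bool) -> PersonRecord:
    def maybe_strip(t: str) -> str:
        return t if keep_accents else _strip_accents(t)
    return PersonRecord(
        record_id=p.pid,
        first_name=maybe_strip(p.first),
        birth_date_raw=p.birth_date.isoformat(),
        birth_surname=None if p.omit_birth_surname else maybe_strip(p.birth_surname),
        current_surname=maybe_strip(p.current_surname),
        sex=p.sex,
        birth_city=maybe_strip(p.city_abbrev or p.city),
        birth_country=maybe_strip(p.country),
        vital_status="deceased" if p.deceased else "alive",
        death_date=p.death_date.isoformat() if p.death_date else None,
    )


def _uncorrupted_mortality(p: _Person, fnmd_id: str) -> MortalityRecord:
    """The counterpart the mortality file would hold with no errors."""
    return MortalityRecord(
        fnmd_id=fnmd_id,
        surname=_strip_accents(p.birth_surname).upper(),
        first_name=_strip_accents(p.first),
        middle_names=(),
        birth_date_raw=p.birth_date.isoformat(),
        sex=p.sex,
        birth_city=_strip_accents(p.city),
        birth_country=_strip_accents(p.country),
        death_date=(p.death_date or _DEATH_START).isoformat(),
        death_zip=None,
    )


class _SeparationIndex:
    """Rejects new identities that the matcher could confuse with old ones.

    Indexes the cleaned identities by both blocking keys and validates
    candidate collisions with the production distance machinery, in both
    (local, mortality) orientations.
    """

    def __init__(self, thresholds: Thresholds | None = None) -> None:
        self.t = thresholds or Thresholds()
        self.by_date: dict[str, list] = {}
        self.by_name: dict[str, list] = {}

    @staticmethod
    def _clean_pair(p: _Person):
        local = make_clean_record(_person_records(p, keep_accents=False))
        # counterpart view with split compound name + middle, as the
        # mortality file would carry it
        parts = p.first.replace(" ", "-").split("-")
        middles = tuple(x for x in ([*parts[1:], p.middle] if len(parts) > 1
                                    else ([p.middle] if p.middle else [])) if x)
        fnmd = make_clean_record(MortalityRecord(
            fnmd_id=p.pid, surname=_strip_accents(p.birth_surname),
            first_name=_strip_accents(parts[0] if len(parts) > 1 else p.first),
            middle_names=tuple(_strip_accents(m) for m in middles),
            birth_date_raw=p.birth_date.isoformat(), sex=p.sex,
            birth_city=_strip_accents(p.city),
            birth_country=_strip_accents(p.country),
            death_date="2001-01-01"))
        return local, fnmd

    def collides(self, p: _Person) -> bool:
        local, fnmd = self._clean_pair(p)
        seen: set[int] = set()
        for index, key in ((self.by_date, local.block_key_date),
                           (self.by_name, local.block_key_name),
                           (self.by_name, fnmd.block_key_name)):
            for i, (other_local, other_fnmd) in index.get(key, ()):
                if i in seen:
                    continue
                seen.add(i)
                if (validate_pair(field_distances(local, other_fnmd), self.t)
                        or validate_pair(field_distances(other_local, fnmd),
                                         self.t)):
                    return True
        return False

    _n = 0

    def add(self, p: _Person) -> None:
        pair = self._clean_pair(p)
        self._n += 1
        entry = (self._n, pair)
        local, fnmd = pair
        self.by_date.setdefault(local.block_key_date, []).append(entry)
        for key in {local.block_key_name, fnmd.block_key_name}:
            self.by_name.setdefault(key, []).append(entry)


def _draw_date(rng, start: _dt.date, span: int) -> _dt.date:
    return start + _dt.timedelta(days=int(rng.integers(0, span)))


def _draw_person(rng, pid: str, sex: str, origin: str, vital: str,
                 model: ErrorModel) -> _Person:
    pool = MALE_FIRST if sex == "m" else FEMALE_FIRST
    first = pool[int(rng.integers(0, len(pool)))]
    if rng.random() < model.compound_name_rate:
        second = pool[int(rng.integers(0, len(pool)))]
        if second != first:
            first = f"{first}-{second}"
    middle = (pool[int(rng.integers(0, len(pool)))]
              if rng.random() < model.middle_name_rate else None)
    birth_surname = SURNAMES[int(rng.integers(0, len(SURNAMES)))]
    married = sex == "f" and rng.random() < model.married_name_rate
    current = (SURNAMES[int(rng.integers(0, len(SURNAMES)))]
               if married else birth_surname)
    omit = married and rng.random() < model.birth_surname_missing_rate
    if origin == "france":
        city, abbrev, big = CITIES_FR[int(rng.integers(0, len(CITIES_FR)))]
        country = "France"
    else:
        country, cities = FOREIGN[int(rng.integers(0, len(FOREIGN)))]
        city, abbrev, big = cities[int(rng.integers(0, len(cities)))], None, False
    deceased = vital == "deceased"
    return _Person(
        pid=pid, sex=sex, first=first, middle=middle,
        birth_surname=birth_surname, current_surname=current,
        birth_date=_draw_date(rng, _BIRTH_START, _BIRTH_DAYS),
        city=city, city_abbrev=abbrev, city_big=big, country=country,
        origin=origin, deceased=deceased,
        death_date=_draw_date(rng, _DEATH_START, _DEATH_DAYS) if deceased else None,
        married=married, omit_birth_surname=omit,
    )


def _corrupt_counterpart(p: _Person, fnmd_id: str, model: ErrorModel,
                         rng: np.random.Generator) -> MortalityRecord:
    surname = _strip_accents(p.birth_surname).upper()
    parts = p.first.replace(" ", "-").split("-")
    if len(parts) > 1:
        first = parts[0]
        middles = [*parts[1:]]
        if p.middle:
            middles.append(p.middle)
    else:
        first = p.first
        middles = [p.middle] if p.middle else []
    first = _strip_accents(first).upper()
    middles = [_strip_accents(m).upper() for m in middles]

    if rng.random() < model.typo_rate:
        surname = random_edit(surname, rng, LETTERS.upper())
    if rng.random() < model.typo_rate:
        first = random_edit(first, rng, LETTERS.upper())

    date = p.birth_date.isoformat()
    if rng.random() < model.missing_daymonth_rate:
        date = f"{p.birth_date.year:04d}-00-00"
    elif p.birth_date.day > 12 and rng.random() < model.daymonth_swap_rate:
        date = f"{p.birth_date.year:04d}-{p.birth_date.day:02d}-{p.birth_date.month:02d}"
    elif rng.random() < model.typo_rate:
        chars = list(date)
        digit_positions = [i for i, c in enumerate(chars) if c.isdigit() and i > 3]
        pos = digit_positions[int(rng.integers(0, len(digit_positions)))]
        chars[pos] = DIGITS[int(rng.integers(0, len(DIGITS)))]
        date = "".join(chars)

    sex = p.sex
    if rng.random() < model.sex_error_rate:
        sex = "f" if sex == "m" else "m"

    city = _strip_accents(p.city)
    if p.city_big and rng.random() < model.district_suffix_rate:
        city = f"{city}, {int(rng.integers(1, 21))}eme arrondissement"

    return MortalityRecord(
        fnmd_id=fnmd_id, surname=surname, first_name=first,
        middle_names=tuple(middles), birth_date_raw=date, sex=sex,
        birth_city=city, birth_country=_strip_accents(p.country),
        death_date=(p.death_date or _DEATH_START).isoformat(),
        death_zip=f"{int(rng.integers(1, 96)):02d}{int(rng.integers(0, 1000)):03d}",
    )


def generate_cohort(
    n: int,
    model: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[list[PersonRecord], list[MortalityRecord], GoldStandard]:
    """Generate a cohort, its mortality file, and the ground truth.

    Reproducible given the seed.  Stratum counts follow the model's
    deceased/sex/origin rates exactly (largest-remainder rounding).
    """
    if n < 1:
        raise ConfigurationError("cohort size must be ≥ 1")
    model = model or ErrorModel()
    model.validate()
    rng = np.random.default_rng(seed)

    # hierarchical rounding keeps every requested split (vital status,
    # then sex, then origin) as close to exact as integer counts allow
    by_vital = _largest_remainder(n, [model.deceased_rate,
                                      1 - model.deceased_rate])
    counts = []
    for n_vital in by_vital:
        by_sex = _largest_remainder(n_vital, [model.sex_male_rate,
                                              1 - model.sex_male_rate])
        for n_sex in by_sex:
            by_origin = _largest_remainder(
                n_sex, [1 - model.born_outside_rate, model.born_outside_rate])
            counts.extend(by_origin)

    separation = _SeparationIndex()
    persons: list[_Person] = []
    k = 0
    for (vital, sex, origin), count in zip(_STRATA_ORDER, counts):
        for _ in range(count):
            k += 1
            pid = f"L{k:06d}"
            for _attempt in range(200):
                p = _draw_person(rng, pid, sex, origin, vital, model)
                if not separation.collides(p):
                    break
            else:  # pragma: no cover - pools are large enough in practice
                raise ConfigurationError(
                    "could not draw a distinguishable identity; "
                    "pools too small for the requested cohort size")
            separation.add(p)
            persons.append(p)

    gold = GoldStandard()
    locals_: list[PersonRecord] = []
    fnmds: list[MortalityRecord] = []
    fid = 0
    for p in persons:
        keep_accents = rng.random() < model.accent_rate
        locals_.append(_person_records(p, keep_accents))
        stratum = f"{p.sex}_{p.origin}"
        gold.truth[p.pid] = "deceased" if p.deceased else "living"
        gold.stratum[p.pid] = stratum
        if p.deceased:
            gold.death_date[p.pid] = p.death_date.isoformat()
            if rng.random() < model.missing_record_rate:
                gold.true_match[p.pid] = None
            else:
                fid += 1
                fnmd_id = f"F{fid:06d}"
                fnmds.append(_corrupt_counterpart(p, fnmd_id, model, rng))
                gold.true_match[p.pid] = fnmd_id
        else:
            gold.true_match[p.pid] = None
            gold.encounters[p.pid] = (
                _draw_date(rng, _PRE_START, _PRE_DAYS).isoformat(),
                _draw_date(rng, _POST_START, _POST_DAYS).isoformat(),
            )

    # background deaths: unrelated people, still distinguishable from the
    # cohort so they cannot silently become false positives
    n_background = int(round(model.background_rate * n))
    for _ in range(n_background):
        fid += 1
        for _attempt in range(200):
            q = _draw_person(rng, f"F{fid:06d}",
                             "m" if rng.random() < model.sex_male_rate else "f",
                             "other" if rng.random() < model.born_outside_rate
                             else "france",
                             "deceased", model)
            if not separation.collides(q):
                break
        else:  # pragma: no cover
            raise ConfigurationError("background pool exhausted")
        separation.add(q)
        fnmds.append(_corrupt_counterpart(q, q.pid, model, rng))

    # decoys: share one blocking key with a cohort member, never validate
    n_decoys = int(round(model.decoy_rate * n))
    if n_decoys and persons:
        targets = rng.choice(len(persons), size=n_decoys, replace=True)
        for j, ti in enumerate(targets):
            target = persons[int(ti)]
            fid += 1
            for _attempt in range(200):
                q = _draw_person(rng, f"F{fid:06d}", target.sex, target.origin,
                                 "deceased", model)
                if j % 2 == 0:
                    q.birth_date = target.birth_date  # share the date key
                else:
                    q.birth_surname = target.birth_surname
                    q.current_surname = q.birth_surname
                    q.first = target.first  # share the 4+4 name key
                if not separation.collides(q):
                    break
            else:  # pragma: no cover
                continue
            separation.add(q)
            fnmds.append(_corrupt_counterpart(q, q.pid, model, rng))

    return locals_, fnmds, gold


# --------------------------------------------------------------------------
# file emission (used by the `simulate` CLI subcommand and file-level tests)

def default_person_mapping() -> ColumnMapping:
    return ColumnMapping(columns={
        "record_id": "record_id", "birth_surname": "birth_surname",
        "current_surname": "current_surname", "first_name": "first_name",
        "birth_date": "birth_date", "sex": "sex", "birth_city": "birth_city",
        "birth_country": "birth_country", "vital_status": "vital_status",
        "death_date": "death_date",
    })


def default_mortality_mapping() -> ColumnMapping:
    return ColumnMapping(columns={
        "record_id": "record_id", "surname": "surname",
        "first_name": "first_name", "middle_names": "middle_names",
        "birth_date": "birth_date", "sex": "sex", "birth_city": "birth_city",
        "birth_country": "birth_country", "death_date": "death_date",
        "death_zip": "death_zip",
    })


def write_cohort(outdir: str | Path,
                 locals_: Sequence[PersonRecord],
                 fnmds: Sequence[MortalityRecord],
                 gold: GoldStandard,
                 model: ErrorModel | None = None) -> dict[str, Path]:
    """Write local.csv, mortality.csv, gold.csv and the model YAML."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "local": outdir / "local.csv",
        "mortality": outdir / "mortality.csv",
        "gold": outdir / "gold.csv",
        "model": outdir / "error_model.yaml",
    }
    pd.DataFrame([{
        "record_id": r.record_id, "birth_surname": r.birth_surname or "",
        "current_surname": r.current_surname or "", "first_name": r.first_name,
        "birth_date": r.birth_date_raw, "sex": r.sex or "",
        "birth_city": r.birth_city or "", "birth_country": r.birth_country or "",
        "vital_status": r.vital_status or "", "death_date": r.death_date or "",
    } for r in locals_]).to_csv(paths["local"], index=False, lineterminator="\n")
    pd.DataFrame([{
        "record_id": r.fnmd_id, "surname": r.surname, "first_name": r.first_name,
        "middle_names": " ".join(r.middle_names), "birth_date": r.birth_date_raw,
        "sex": r.sex or "", "birth_city": r.birth_city or "",
        "birth_country": r.birth_country or "", "death_date": r.death_date,
        "death_zip": r.death_zip or "",
    } for r in fnmds]).to_csv(paths["mortality"], index=False, lineterminator="\n")
    pd.DataFrame([{
        "record_id": rid, "truth": gold.truth[rid], "stratum": gold.stratum[rid],
        "true_match": gold.true_match.get(rid) or "",
        "death_date": gold.death_date.get(rid, ""),
        "encounter_pre": gold.encounters.get(rid, ("", ""))[0],
        "encounter_post": gold.encounters.get(rid, ("", ""))[1],
    } for rid in gold.truth]).to_csv(paths["gold"], index=False,
                                     lineterminator="\n")
    if model is not None:
        with open(paths["model"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(model), fh, sort_keys=True)
    return paths
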