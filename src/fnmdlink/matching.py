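"""Pair validation, the direct-matching reference, and pair selection.

Two strategies are provided:

* ``dld`` — the distance-based strategy: blocking, per-field
  Damerau-Levenshtein distances, validation against per-field and total
  maxima, then selection of the most pertinent pair per local record.
  The default maxima (first name 2, surname 1, birth date 1, sex 1,
  total 2) are the values learned on a stratified hospital sample.
* ``direct`` — the reference: accent stripping and lowercasing only,
  then an exact join on surname (birth if present, else current), first
  name, birth date and sex.  No date repair, no variant construction.

A local record is classified deceased iff at least one of its pairs is
selected.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Iterable, Sequence

from .blocking import block_pairs
from .cleaning import CleanRecord, make_clean_record
from .distance import DistanceProfile, field_distances
from .records import ConfigurationError, MortalityRecord, PersonRecord


@dataclass(frozen=True)
class Thresholds:
    """Maximal per-field and total Damerau-Levenshtein distances."""

    max_first: int = 2
    max_surname: int = 1
    max_date: int = 1
    max_sex: int = 1
    max_total: int = 2

    def __post_init__(self) -> None:
        if min(self.max_first, self.max_surname, self.max_date,
               self.max_sex, self.max_total) < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.max_total > (self.max_first + self.max_surname
                             + self.max_date + self.max_sex):
            raise ConfigurationError(
                "max_total exceeds the sum of the per-field maxima")


@dataclass
class MatchResult:
    local_id: str
    fnmd_id: str
    profile: DistanceProfile
    selected: bool = False
    ambiguous: bool = False
    death_date: str | None = None


def validate_pair(profile: DistanceProfile, t: Thresholds) -> bool:
    """All per-field bounds and the total bound must hold simultaneously."""
    return (profile.d_first <= t.max_first
            and profile.d_surname <= t.max_surname
            and profile.d_date <= t.max_date
            and profile.d_sex <= t.max_sex
            and profile.d_total <= t.max_total)


def _minimal_clean(text: str | None) -> str | None:
    """Lowercase and strip accents only — the direct strategy's cleaning."""
    if text is None:
        return None
    out = unicodedata.normalize("NFKD", text)
    out = "".join(ch for ch in out if not unicodedata.combining(ch))
    return out.lower().strip()


def direct_match(local: PersonRecord, fnmd: MortalityRecord) -> bool:
    """Exact equality of surname, first name, birth date and sex."""
    surname = local.birth_surname if local.birth_surname else local.current_surname
    return (_minimal_clean(surname) == _minimal_clean(fnmd.surname)
            and _minimal_clean(local.first_name) == _minimal_clean(fnmd.first_name)
            and (local.birth_date_raw or "").strip() == (fnmd.birth_date_raw or "").strip()
            and local.sex == fnmd.sex)


def _city_sort_key(profile: DistanceProfile) -> int:
    # undefined city distance sorts after any defined one
    return profile.d_city if profile.d_city is not None else 10**9


def select_best(validated: Sequence[MatchResult]) -> list[MatchResult]:
    """Mark the most pertinent pair(s) among one local record's matches.

    Minimal total distance wins; ties are broken by minimal city
    distance (undefined last); remaining ties are all flagged ambiguous,
    with ``selected`` set on the first in (death_date, fnmd_id) order so
    the output stays deterministic.
    """
    if not validated:
        return []
    results = list(validated)
    if len(results) == 1:
        results[0].selected = True
        return results
    best_total = min(m.profile.d_total for m in results)
    pool = [m for m in results if m.profile.d_total == best_total]
    best_city = min(_city_sort_key(m.profile) for m in pool)
    pool = [m for m in pool if _city_sort_key(m.profile) == best_city]
    if len(pool) == 1:
        pool[0].selected = True
    else:
        pool.sort(key=lambda m: (m.death_date or "", m.fnmd_id))
        for m in pool:
            m.ambiguous = True
        pool[0].selected = True
    return results


def score_candidates(locals_: Sequence[CleanRecord],
                     fnmds: Sequence[CleanRecord],
                     t: Thresholds) -> list[MatchResult]:
    """Blocking → distances → validation, without selection."""
    local_by_id = {r.source_id: r for r in locals_}
    fnmd_by_id = {r.source_id: r for r in fnmds}
    out: list[MatchResult] = []
    for pair in block_pairs(locals_, fnmds):
        loc = local_by_id[pair.local_id]
        fn = fnmd_by_id[pair.fnmd_id]
        profile = field_distances(loc, fn)
        if validate_pair(profile, t):
            out.append(MatchResult(local_id=pair.local_id, fnmd_id=pair.fnmd_id,
                                   profile=profile, death_date=fn.death_date))
    return out


def apply_selection(validated: Iterable[MatchResult]) -> list[MatchResult]:
    """Group validated pairs per local record and run selection on each."""
    grouped: dict[str, list[MatchResult]] = {}
    for m in validated:
        grouped.setdefault(m.local_id, []).append(m)
    out: list[MatchResult] = []
    for lid in sorted(grouped):
        out.extend(select_best(grouped[lid]))
    out.sort(key=lambda m: (m.local_id, m.fnmd_id))
    return out


def run_strategy(locals_: Sequence[PersonRecord],
                 fnmds: Sequence[MortalityRecord],
                 strategy: str = "dld",
                 thresholds: Thresholds | None = None,
                 home_country: str = "france") -> list[MatchResult]:
    """Run one full strategy over raw records and return all retained pairs."""
    if strategy == "direct":
        return _run_direct(locals_, fnmds)
    if strategy != "dld":
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    t = thresholds or Thresholds()
    clean_locals = [make_clean_record(r, home_country) for r in locals_]
    clean_fnmds = [make_clean_record(r, home_country) for r in fnmds]
    return apply_selection(score_candidates(clean_locals, clean_fnmds, t))


_ZERO = DistanceProfile(0, 0, 0, 0)


def _direct_key(surname: str | None, first: str | None, date: str,
                sex: str | None) -> tuple:
    return (_minimal_clean(surname), _minimal_clean(first),
            (date or "").strip(), sex)


def _run_direct(locals_: Sequence[PersonRecord],
                fnmds: Sequence[MortalityRecord]) -> list[MatchResult]:
    """Exact-key join realisation of :func:`direct_match` over two files."""
    index: dict[tuple, list[MortalityRecord]] = {}
    for fn in fnmds:
        key = _direct_key(fn.surname, fn.first_name, fn.birth_date_raw, fn.sex)
        index.setdefault(key, []).append(fn)
    out: list[MatchResult] = []
    for loc in locals_:
        surname = loc.birth_surname if loc.birth_surname else loc.current_surname
        key = _direct_key(surname, loc.first_name, loc.birth_date_raw, loc.sex)
        hits = index.get(key, [])
        for fn in hits:
            out.append(MatchResult(local_id=loc.record_id, fnmd_id=fn.fnmd_id,
                                   profile=_ZERO, selected=True,
                                   ambiguous=len(hits) > 1,
                                   death_date=fn.death_date))
    out.sort(key=lambda m: (m.local_id, m.fnmd_id))
    return out


def deceased_ids(results: Iterable[MatchResult]) -> set[str]:
    """Local ids classified deceased: at least one selected pair."""
    return {m.local_id for m in results if m.selected}
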