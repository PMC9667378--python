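"""Damerau-Levenshtein distances between cleaned identity fields.

The edit distance used throughout is the restricted (optimal string
alignment) Damerau-Levenshtein distance: the minimum number of
single-character insertions, deletions, substitutions and transpositions
of two adjacent characters needed to turn one string into the other,
with no substring edited twice.  At the small thresholds used for
identity matching (per-field maxima of 1-2) the restricted and
unrestricted variants coincide in practice.

Per-field distances take the minimum over the name variants built during
cleaning, so that a compound given name recorded differently on the two
sides ("Marie-Claire" vs first name "Marie" + middle name "Claire")
still scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cleaning import CleanRecord
from .records import DataError


def dld(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    if a == b:
        return 0
    # two-row DP with one extra row kept for the transposition case
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            best = min(prev[j] + 1,          # deletion
                       cur[j - 1] + 1,       # insertion
                       prev[j - 1] + cost)   # substitution
            if (i > 1 and j > 1 and ai == b[j - 2] and a[i - 2] == b[j - 1]):
                best = min(best, prev2[j - 2] + 1)  # adjacent transposition
            cur[j] = best
        prev2, prev = prev, cur
    return prev[lb]


@dataclass(frozen=True)
class DistanceProfile:
    """Per-field distances for one candidate pair.

    ``d_total`` is the sum of the first-name, surname, birth-date and sex
    distances.  ``d_city`` is informative only (used to break selection
    ties) and is None when either side lacks a birth city.
    """

    d_first: int
    d_surname: int
    d_date: int
    d_sex: int
    d_city: int | None = None

    @property
    def d_total(self) -> int:
        return self.d_first + self.d_surname + self.d_date + self.d_sex


def sex_distance(a: str | None, b: str | None) -> int:
    """0 if equal or either missing, 1 if both present and different."""
    if a is None or b is None:
        return 0
    return 0 if a == b else 1


def field_distances(local: CleanRecord, fnmd: CleanRecord) -> DistanceProfile:
    """Score one (local, mortality) pair on every compared field.

    First name: minimum over the three mortality-side variants.
    Surname: minimum over the local birth and current surnames against
    the mortality surname, skipping missing ones.
    Birth date: distance between the two 8-digit repaired date strings.
    """
    lf = local.firstname_1
    d_first = min(dld(lf, fnmd.firstname_0),
                  dld(lf, fnmd.firstname_1),
                  dld(lf, fnmd.firstname_12))

    fnmd_surname = fnmd.preferred_surname or ""
    surname_candidates = [s for s in (local.surname_birth, local.surname_current)
                          if s is not None]
    if not surname_candidates:
        raise DataError(f"record {local.source_id!r}: both surnames missing")
    d_surname = min(dld(s, fnmd_surname) for s in surname_candidates)

    d_date = dld(local.birth_date_repaired, fnmd.birth_date_repaired)
    d_sex = sex_distance(local.sex, fnmd.sex)

    d_city: int | None = None
    if fnmd.city is not None:
        city_candidates = [c for c in (local.city, local.city_expanded)
                           if c is not None]
        if city_candidates:
            d_city = min(dld(c, fnmd.city) for c in city_candidates)

    return DistanceProfile(d_first=d_first, d_surname=d_surname,
                           d_date=d_date, d_sex=d_sex, d_city=d_city)
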