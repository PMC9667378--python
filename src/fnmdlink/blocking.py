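"""Candidate-pair generation by two successive simple blocking passes.

Comparing every local record against every mortality record is
quadratic and prohibitive at national scale.  Instead, two blocking
passes each restrict comparison to records agreeing exactly on one
cheap key:

1. the (repaired) birth date;
2. the concatenation of the first 4 characters of the first name and
   the first 4 characters of the surname (birth surname when present,
   current surname otherwise).

The candidate set is the union of the two passes, deduplicated: a pair
survives blocking iff at least one of the two keys agrees, i.e. a
mismatch in one key is tolerated but not in both.  Each pass is realised
as a key-partitioned join, which produces exactly the same candidate set
as the sequential pairwise description while cutting the comparison
count by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .cleaning import CleanRecord

DATE_BLOCK = "date_block"
NAME_BLOCK = "name_block"


@dataclass(frozen=True)
class CandidatePair:
    local_id: str
    fnmd_id: str
    matched_by: frozenset[str]  # nonempty subset of {date_block, name_block}


def _index_by(records: Iterable[CleanRecord], attr: str) -> dict[str, list[CleanRecord]]:
    index: dict[str, list[CleanRecord]] = {}
    for rec in records:
        key = getattr(rec, attr)
        if key:  # an empty key never blocks
            index.setdefault(key, []).append(rec)
    return index


def block_pairs(locals_: Sequence[CleanRecord],
                fnmds: Sequence[CleanRecord]) -> list[CandidatePair]:
    """Union of the two single-key blocking passes, deduplicated and sorted."""
    matched: dict[tuple[str, str], set[str]] = {}
    for attr, label in ((("block_key_date"), DATE_BLOCK),
                        (("block_key_name"), NAME_BLOCK)):
        fnmd_index = _index_by(fnmds, attr)
        for loc in locals_:
            key = getattr(loc, attr)
            for fn in fnmd_index.get(key, ()):
                matched.setdefault((loc.source_id, fn.source_id), set()).add(label)
    return [CandidatePair(local_id=lid, fnmd_id=fid,
                          matched_by=frozenset(passes))
            for (lid, fid), passes in sorted(matched.items())]
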