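"""Orchestration of full linkage runs: chunking, parallelism, determinism.

The mortality file is streamed in chunks of bounded size, each chunk is
blocked and scored against the (in-memory) local registry, and the
retained pairs — a small fraction of the candidates — are combined,
selected and written out.  Peak memory is therefore a function of the
local registry size and the chunk size, not of the mortality file size.

Chunks are independent, so they can be scored on parallel workers; the
final sort of the pair file removes every trace of scheduling order, and
the output is byte-identical for any worker count and chunk size.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence, TypeVar

from joblib import Parallel, delayed

from . import io as records_io
from .blocking import DATE_BLOCK, NAME_BLOCK, block_pairs
from .cleaning import CleanRecord, make_clean_record
from .distance import field_distances
from .matching import (
    MatchResult,
    Thresholds,
    apply_selection,
    deceased_ids,
    validate_pair,
)
from .records import ColumnMapping, ConfigurationError, MortalityRecord, PersonRecord

log = logging.getLogger("fnmdlink")

T = TypeVar("T")


def auto_workers() -> int:
    """Default worker count: available cores minus one, at least one."""
    return max(1, (os.cpu_count() or 1) - 1)


@dataclass
class RunConfig:
    local_path: str | Path
    fnmd_path: str | Path
    local_mapping: ColumnMapping
    fnmd_mapping: ColumnMapping
    out_path: str | Path
    strategy: str = "dld"
    thresholds: Thresholds = field(default_factory=Thresholds)
    workers: int | str = "auto"
    chunk_size: int = 100_000
    home_country: str = "france"

    def resolved_workers(self) -> int:
        if self.workers == "auto":
            return auto_workers()
        if not isinstance(self.workers, int) or self.workers < 1:
            raise ConfigurationError(f"invalid worker count {self.workers!r}")
        return self.workers

    def validate(self) -> None:
        if self.strategy not in ("dld", "direct"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.chunk_size < 1:
            raise ConfigurationError("chunk_size must be positive")
        self.resolved_workers()
        self.local_mapping.require(ColumnMapping.REQUIRED_PERSON)
        self.fnmd_mapping.require(ColumnMapping.REQUIRED_MORTALITY)


@dataclass
class RunSummary:
    """Counts conserved along the pipeline: validated ≤ candidates ≤ per-pass sum."""

    n_local: int = 0
    n_fnmd: int = 0
    candidates_date: int = 0
    candidates_name: int = 0
    candidates: int = 0
    validated: int = 0
    selected: int = 0
    deceased: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def partition_stream(records: Iterable[T], key: Callable[[T], object],
                     chunk_size: int = 100_000) -> Iterator[list[T]]:
    """Yield chunks such that all records sharing a key share a chunk.

    Groups are packed greedily up to chunk_size; a group larger than the
    chunk size becomes its own chunk.  Every record appears exactly once.
    """
    groups: dict[object, list[T]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)
    chunk: list[T] = []
    for k in sorted(groups, key=repr):
        group = groups[k]
        if chunk and len(chunk) + len(group) > chunk_size:
            yield chunk
            chunk = []
        chunk.extend(group)
    if chunk:
        yield chunk


def _score_chunk(clean_locals: Sequence[CleanRecord],
                 fnmd_chunk: Sequence[MortalityRecord],
                 t: Thresholds, home_country: str):
    """Block and score one mortality chunk; returns (validated, pass counts)."""
    clean_fnmds = [make_clean_record(r, home_country) for r in fnmd_chunk]
    fnmd_by_id = {r.source_id: r for r in clean_fnmds}
    local_by_id = {r.source_id: r for r in clean_locals}
    n_date = n_name = n_union = 0
    validated: list[MatchResult] = []
    for pair in block_pairs(clean_locals, clean_fnmds):
        n_union += 1
        if DATE_BLOCK in pair.matched_by:
            n_date += 1
        if NAME_BLOCK in pair.matched_by:
            n_name += 1
        profile = field_distances(local_by_id[pair.local_id],
                                  fnmd_by_id[pair.fnmd_id])
        if validate_pair(profile, t):
            fn = fnmd_by_id[pair.fnmd_id]
            validated.append(MatchResult(
                local_id=pair.local_id, fnmd_id=pair.fnmd_id,
                profile=profile, death_date=fn.death_date))
    return validated, n_date, n_name, n_union


def _direct_chunk(local_index: dict, fnmd_chunk: Sequence[MortalityRecord]):
    from .matching import _direct_key, _ZERO  # exact-key join, shared helpers
    out: list[MatchResult] = []
    for fn in fnmd_chunk:
        key = _direct_key(fn.surname, fn.first_name, fn.birth_date_raw, fn.sex)
        for lid in local_index.get(key, ()):
            out.append(MatchResult(local_id=lid, fnmd_id=fn.fnmd_id,
                                   profile=_ZERO, death_date=fn.death_date))
    return out


def run_linkage(config: RunConfig) -> RunSummary:
    """Run a full linkage and write the pair file; returns the summary."""
    config.validate()
    summary = RunSummary()

    locals_ = records_io.read_person_table(config.local_path, config.local_mapping)
    summary.n_local = len(locals_)
    log.info("read %d local records", summary.n_local)

    chunks = records_io.iter_mortality_chunks(
        config.fnmd_path, config.fnmd_mapping, config.chunk_size)
    n_jobs = config.resolved_workers()

    if config.strategy == "direct":
        from .matching import _direct_key
        local_index: dict[tuple, list[str]] = {}
        for loc in locals_:
            surname = loc.birth_surname if loc.birth_surname else loc.current_surname
            key = _direct_key(surname, loc.first_name, loc.birth_date_raw, loc.sex)
            local_index.setdefault(key, []).append(loc.record_id)
        results: list[MatchResult] = []
        for chunk in chunks:
            summary.n_fnmd += len(chunk)
            results.extend(_direct_chunk(local_index, chunk))
        grouped: dict[str, int] = {}
        for m in results:
            grouped[m.local_id] = grouped.get(m.local_id, 0) + 1
        for m in results:
            m.selected = True
            m.ambiguous = grouped[m.local_id] > 1
        results.sort(key=lambda m: (m.local_id, m.fnmd_id))
        summary.candidates = summary.validated = len(results)
    else:
        clean_locals = [make_clean_record(r, config.home_country)
                        for r in locals_]
        chunk_list = []
        for chunk in chunks:
            summary.n_fnmd += len(chunk)
            chunk_list.append(chunk)
        scored = Parallel(n_jobs=n_jobs)(
            delayed(_score_chunk)(clean_locals, chunk, config.thresholds,
                                  config.home_country)
            for chunk in chunk_list)
        validated: list[MatchResult] = []
        for chunk_validated, n_date, n_name, n_union in scored:
            validated.extend(chunk_validated)
            summary.candidates_date += n_date
            summary.candidates_name += n_name
            summary.candidates += n_union
        summary.validated = len(validated)
        results = apply_selection(validated)

    summary.selected = sum(1 for m in results if m.selected)
    summary.deceased = len(deceased_ids(results))
    records_io.write_pairs(results, config.out_path)
    log.info("wrote %d retained pairs to %s", len(results), config.out_path)
    return summary
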