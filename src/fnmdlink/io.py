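"""Reading the two registries and writing linkage outputs.

All files are delimited text with a header row; a :class:`ColumnMapping`
names the source columns, delimiter and encoding.  Dates are read as raw
text — repair and validation belong to the cleaning stage — except the
mortality file's death date, which must parse as a calendar date on
ingestion.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd
import yaml

from .records import (
    ColumnMapping,
    ConfigurationError,
    DataError,
    MortalityRecord,
    PersonRecord,
)

if TYPE_CHECKING:  # pragma: no cover
    from .matching import MatchResult

#: column order of the pair file written by :func:`write_pairs`
PAIR_COLUMNS = (
    "local_id", "fnmd_id",
    "d_first", "d_surname", "d_date", "d_sex", "d_total", "d_city",
    "selected", "ambiguous", "death_date",
)


def _read_table(path: str | Path, mapping: ColumnMapping) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=mapping.delimiter,
        encoding=mapping.encoding,
        dtype=str,
        keep_default_na=False,
    )
    missing = [src for src in mapping.columns.values() if src not in df.columns]
    if missing:
        raise ConfigurationError(
            f"mapped column(s) not found in {path}: {', '.join(missing)}"
        )
    return df


def _cell(row, mapping: ColumnMapping, canonical: str) -> str | None:
    """Missing cells and unmapped optional fields become None, never ''."""
    src = mapping.columns.get(canonical)
    if src is None:
        return None
    value = str(row[src]).strip()
    return value if value else None


def read_person_table(path: str | Path,
                      mapping: ColumnMapping) -> list[PersonRecord]:
    """Read the local registry; one record per data row, file order kept."""
    mapping.require(ColumnMapping.REQUIRED_PERSON)
    df = _read_table(path, mapping)
    records: list[PersonRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else row
        rid = _cell(row, mapping, "record_id")
        if rid is None:
            raise DataError("empty record_id encountered in local registry")
        if rid in seen:
            raise DataError(f"duplicate record_id in local registry: {rid!r}")
        seen.add(rid)
        records.append(PersonRecord(
            record_id=rid,
            first_name=_cell(row, mapping, "first_name") or "",
            birth_date_raw=_cell(row, mapping, "birth_date") or "",
            birth_surname=_cell(row, mapping, "birth_surname"),
            current_surname=_cell(row, mapping, "current_surname"),
            sex=mapping.map_sex(_cell(row, mapping, "sex")),
            birth_city=_cell(row, mapping, "birth_city"),
            birth_country=_cell(row, mapping, "birth_country"),
            vital_status=_cell(row, mapping, "vital_status"),
            death_date=_cell(row, mapping, "death_date"),
        ))
    return records


def _parse_death_date(raw: str | None, fmt: str, where: str) -> str:
    if raw is None:
        raise DataError(f"missing death date for {where}")
    try:
        return _dt.datetime.strptime(raw, fmt).date().isoformat()
    except ValueError as exc:
        raise DataError(f"unparseable death date {raw!r} for {where}") from exc


def mortality_records_from_frame(df: pd.DataFrame, mapping: ColumnMapping,
                                 start_row: int = 0,
                                 seen: set[str] | None = None
                                 ) -> list[MortalityRecord]:
    """Build MortalityRecords from one (possibly chunked) raw frame."""
    records: list[MortalityRecord] = []
    if seen is None:
        seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=start_row):
        row = row._asdict() if hasattr(row, "_asdict") else row
        rid = _cell(row, mapping, "record_id")
        if rid is None:
            raise DataError(f"empty record_id in mortality file row {i}")
        if rid in seen:
            raise DataError(f"duplicate record_id in mortality file: {rid!r}")
        seen.add(rid)
        middles = _cell(row, mapping, "middle_names")
        middle_names = tuple(
            tok for tok in (middles or "").split(mapping.middle_name_separator)
            if tok.strip()
        )
        records.append(MortalityRecord(
            fnmd_id=rid,
            surname=_cell(row, mapping, "surname") or "",
            first_name=_cell(row, mapping, "first_name") or "",
            middle_names=middle_names,
            birth_date_raw=_cell(row, mapping, "birth_date") or "",
            sex=mapping.map_sex(_cell(row, mapping, "sex")),
            birth_city=_cell(row, mapping, "birth_city"),
            birth_country=_cell(row, mapping, "birth_country"),
            death_date=_parse_death_date(
                _cell(row, mapping, "death_date"), mapping.date_format,
                f"mortality row {i} (id {rid!r})"),
            death_zip=_cell(row, mapping, "death_zip"),
        ))
    return records


def read_mortality_table(path: str | Path,
                         mapping: ColumnMapping) -> list[MortalityRecord]:
    """Read the mortality file; middle names split on the configured separator."""
    mapping.require(ColumnMapping.REQUIRED_MORTALITY)
    return mortality_records_from_frame(_read_table(path, mapping), mapping)


def iter_mortality_chunks(path: str | Path, mapping: ColumnMapping,
                          chunk_size: int):
    """Stream the mortality file as lists of records of ≤ chunk_size rows.

    Memory use is bounded by the chunk size, not the file size; duplicate
    ids are still detected across chunk boundaries.
    """
    mapping.require(ColumnMapping.REQUIRED_MORTALITY)
    seen: set[str] = set()
    start = 0
    with pd.read_csv(path, sep=mapping.delimiter, encoding=mapping.encoding,
                     dtype=str, keep_default_na=False,
                     chunksize=chunk_size) as reader:
        for df in reader:
            missing = [src for src in mapping.columns.values()
                       if src not in df.columns]
            if missing:
                raise ConfigurationError(
                    f"mapped column(s) not found in {path}: {', '.join(missing)}")
            yield mortality_records_from_frame(df, mapping, start, seen)
            start += len(df)


def write_pairs(pairs: Iterable["MatchResult"], path: str | Path) -> None:
    """Write retained pairs as CSV, sorted by (local_id, fnmd_id).

    Deterministic: rerunning with the same inputs yields a byte-identical
    file.
    """
    rows = []
    for m in pairs:
        p = m.profile
        rows.append({
            "local_id": m.local_id,
            "fnmd_id": m.fnmd_id,
            "d_first": p.d_first, "d_surname": p.d_surname,
            "d_date": p.d_date, "d_sex": p.d_sex, "d_total": p.d_total,
            "d_city": "" if p.d_city is None else p.d_city,
            "selected": int(m.selected),
            "ambiguous": int(m.ambiguous),
            "death_date": m.death_date or "",
        })
    df = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    df = df.sort_values(["local_id", "fnmd_id"], kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a pair file back as a DataFrame (round-trip of write_pairs)."""
    df = pd.read_csv(path, dtype={"local_id": str, "fnmd_id": str,
                                  "death_date": str})
    return df


def load_mapping(path: str | Path) -> dict[str, ColumnMapping]:
    """Load a YAML mapping file with one section per side (local/fnmd)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("mapping file must be a YAML mapping")
    out: dict[str, ColumnMapping] = {}
    for side, cfg in raw.items():
        if "columns" not in cfg:
            raise ConfigurationError(f"mapping section {side!r} lacks 'columns'")
        kwargs = {k: v for k, v in cfg.items()
                  if k in ("delimiter", "encoding", "date_format",
                           "middle_name_separator", "sex_values", "columns")}
        out[side] = ColumnMapping(**kwargs)
    return out
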