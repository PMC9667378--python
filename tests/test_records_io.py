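"""Delimited-file ingestion with column mappings, and pair-file output."""

from __future__ import annotations

import pytest

from fnmdlink.distance import DistanceProfile
from fnmdlink.io import (
    load_mapping,
    read_mortality_table,
    read_pairs,
    read_person_table,
    write_pairs,
)
from fnmdlink.matching import MatchResult
from fnmdlink.records import ColumnMapping, ConfigurationError, DataError

PERSON_MAP = ColumnMapping(columns={
    "record_id": "id", "first_name": "prenom", "birth_date": "ddn",
    "birth_surname": "nom_naissance", "current_surname": "nom_usage",
    "sex": "sexe",
})

MORT_MAP = ColumnMapping(columns={
    "record_id": "id", "surname": "nom", "first_name": "prenom",
    "middle_names": "autres_prenoms", "birth_date": "ddn",
    "death_date": "dcd", "sex": "sexe",
})


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


def test_read_person_table_preserves_rows_and_ids(tmp_path):
    path = _write(tmp_path, "p.csv",
                  "id,prenom,ddn,nom_naissance,nom_usage,sexe\n"
                  "a,Jean,1950-03-21,Dupont,,M\n"
                  "b,Marie,1960-01-02,Durand,Martin,2\n"
                  "c,Luc,1970-12-31,Petit,Petit,1\n")
    records = read_person_table(path, PERSON_MAP)
    assert [r.record_id for r in records] == ["a", "b", "c"]
    assert records[0].current_surname is None      # empty cell → missing
    assert records[0].sex == "m"                   # value map applied
    assert records[1].sex == "f"
    assert records[1].current_surname == "Martin"


def test_semicolon_dialect_equivalent(tmp_path):
    comma = _write(tmp_path, "a.csv",
                   "id,prenom,ddn\nx,Jean,1950-01-01\n")
    semi = _write(tmp_path, "b.csv",
                  "id;prenom;ddn\nx;Jean;1950-01-01\n")
    small = ColumnMapping(columns={"record_id": "id", "first_name": "prenom",
                                   "birth_date": "ddn"})
    small_semi = ColumnMapping(columns=dict(small.columns), delimiter=";")
    assert read_person_table(comma, small) == read_person_table(semi, small_semi)


def test_unmapped_required_column_names_the_column(tmp_path):
    path = _write(tmp_path, "p.csv", "id,prenom\na,Jean\n")
    bad = ColumnMapping(columns={"record_id": "id", "first_name": "prenom"})
    with pytest.raises(ConfigurationError, match="birth_date"):
        read_person_table(path, bad)


def test_duplicate_record_id_names_the_id(tmp_path):
    path = _write(tmp_path, "p.csv",
                  "id,prenom,ddn\na,Jean,1950-01-01\na,Luc,1951-01-01\n")
    small = ColumnMapping(columns={"record_id": "id", "first_name": "prenom",
                                   "birth_date": "ddn"})
    with pytest.raises(DataError, match="'a'"):
        read_person_table(path, small)


def test_read_mortality_middle_names_and_death_date(tmp_path):
    path = _write(tmp_path, "m.csv",
                  "id,nom,prenom,autres_prenoms,ddn,dcd,sexe\n"
                  "f1,DUPONT,Marie,Claire,1950-00-00,2010-05-01,F\n"
                  "f2,DURAND,Jean,,1951-01-01,2011-06-02,M\n"
                  "f3,PETIT,Luc,Paul Henri,1952-02-02,2012-07-03,M\n")
    records = read_mortality_table(path, MORT_MAP)
    assert records[0].middle_names == ("Claire",)
    assert records[1].middle_names == ()
    assert records[2].middle_names == ("Paul", "Henri")
    assert records[0].death_date == "2010-05-01"
    # birth dates stay raw, even invalid ones
    assert records[0].birth_date_raw == "1950-00-00"


def test_unparseable_death_date_names_the_row(tmp_path):
    path = _write(tmp_path, "m.csv",
                  "id,nom,prenom,autres_prenoms,ddn,dcd,sexe\n"
                  "f1,DUPONT,Marie,,1950-01-01,not-a-date,F\n")
    with pytest.raises(DataError, match="row 0"):
        read_mortality_table(path, MORT_MAP)


def _results():
    return [
        MatchResult("b", "F2", DistanceProfile(1, 0, 0, 0, None),
                    selected=False, death_date="2011-01-01"),
        MatchResult("a", "F1", DistanceProfile(0, 0, 0, 0, 2),
                    selected=True, death_date="2010-05-01"),
    ]


def test_write_pairs_sorted_header_and_roundtrip(tmp_path):
    out = tmp_path / "pairs.csv"
    write_pairs(_results(), out)
    df = read_pairs(out)
    assert list(df["local_id"]) == ["a", "b"]       # sorted by ids
    assert list(df["selected"]) == [1, 0]
    assert df.loc[0, "d_city"] == 2
    assert df.loc[0, "death_date"] == "2010-05-01"


def test_write_pairs_empty_and_deterministic(tmp_path):
    empty = tmp_path / "empty.csv"
    write_pairs([], empty)
    assert empty.read_text().count("\n") == 1       # header only
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_pairs(_results(), a)
    write_pairs(list(reversed(_results())), b)
    assert a.read_bytes() == b.read_bytes()


def test_load_mapping_yaml(tmp_path):
    path = _write(tmp_path, "map.yaml", """
local:
  columns: {record_id: id, first_name: prenom, birth_date: ddn}
  delimiter: ";"
fnmd:
  columns:
    record_id: id
    surname: nom
    first_name: prenom
    birth_date: ddn
    death_date: dcd
""")
    mappings = load_mapping(path)
    assert mappings["local"].delimiter == ";"
    assert mappings["fnmd"].columns["death_date"] == "dcd"
    with pytest.raises(ConfigurationError):
        load_mapping(_write(tmp_path, "bad.yaml", "local:\n  delimiter: ','\n"))
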