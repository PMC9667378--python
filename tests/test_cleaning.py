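"""Text normalisation, date repair and derived-variant construction."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnmdlink.cleaning import (
    build_firstname_variants,
    clean_city,
    expand_city_abbrev,
    make_clean_record,
    normalize_text,
    repair_birth_date,
)
from fnmdlink.records import DataError, MortalityRecord, PersonRecord


@pytest.mark.parametrize("raw, expected", [
    ("Pierre-Olivier", "pierreolivier"),
    ("Élise 2", "elise"),
    ("", ""),
    ("Jean-Noël", "jeannoel"),
    ("O'Brien", "obrien"),
    ("Œuvre", "oeuvre"),
    ("MÜLLER", "muller"),
    ("  Durand  ", "durand"),
])
def test_normalize_text(raw, expected):
    assert normalize_text(raw) == expected


@pytest.mark.parametrize("raw, expected", [
    # day and month "00" → January 1
    ("1956-00-00", "19560101"),
    # invalid month, valid after day/month inversion → inverted kept
    ("1960-31-03", "19600331"),
    # invalid both ways → January 1
    ("1959-32-33", "19590101"),
    ("1950-03-21", "19500321"),      # valid dates pass through
    ("1950-02-29", "19500101"),      # non-leap Feb 29, swap also invalid
    ("2000-02-29", "20000229"),      # leap year Feb 29 is valid
    ("1944-05-00", "19440501"),      # day-only "00" → day 1
    ("1944-00-05", "19440101"),      # month "00" with a day → fallback
    ("19441105", "19441105"),        # separator-free input accepted
])
def test_repair_birth_date(raw, expected):
    assert repair_birth_date(raw) == expected


def test_repair_birth_date_requires_year():
    with pytest.raises(DataError):
        repair_birth_date("not a date")


@settings(derandomize=True, max_examples=200)
@given(st.integers(1900, 2020), st.integers(0, 39), st.integers(0, 39))
def test_repaired_date_is_always_valid(year, month, day):
    out = repair_birth_date(f"{year:04d}-{month:02d}-{day:02d}")
    assert len(out) == 8
    dt.date(int(out[:4]), int(out[4:6]), int(out[6:]))  # must not raise
    assert int(out[:4]) == year


@pytest.mark.parametrize("raw, expected", [
    ("Paris, 13ème arrondissement", "paris"),
    ("Lyon 3e", "lyon"),
    ("Nantes", "nantes"),
    ("Marseille 1er arrondissement", "marseille"),
    ("Paris 13", "paris"),
])
def test_clean_city(raw, expected):
    assert clean_city(raw) == expected


@pytest.mark.parametrize("raw, expected", [
    ("St-Martin-sr-Ocre", "saintmartinsurocre"),
    ("Ste-Anne", "sainteanne"),
    ("bordeaux", "bordeaux"),
    ("Neuilly-ss-Clermont", "neuillysousclermont"),
])
def test_expand_city_abbrev(raw, expected):
    assert expand_city_abbrev(raw) == expected


@pytest.mark.parametrize("first, middle, expected", [
    ("Jean", None, ("jean", "jean", "jean")),
    ("Marie", "Claire", ("marie", "marie", "marieclaire")),
    ("Pierre-Olivier", "Christian",
     ("pierre", "pierreolivier", "pierreolivierchristian")),
    ("Elon-Louis", None, ("elon", "elonlouis", "elonlouis")),
])
def test_firstname_variants(first, middle, expected):
    assert build_firstname_variants(first, middle) == expected


def test_firstname_variants_prefix_containment():
    f0, f1, f12 = build_firstname_variants("Pierre-Olivier", "Christian")
    assert f1.startswith(f0)
    assert f12.startswith(f1)


def test_empty_first_name_rejected():
    with pytest.raises(DataError):
        build_firstname_variants("  2  ")


def test_make_clean_record_local_blocking_keys():
    rec = PersonRecord(record_id="p1", first_name="Jean",
                       birth_date_raw="1950-03-21", current_surname="Dupont",
                       sex="m")
    clean = make_clean_record(rec)
    assert clean.block_key_name == "jeandupo"
    assert clean.block_key_date == "19500321"
    assert clean.surname_birth is None
    assert clean.preferred_surname == "dupont"


def test_make_clean_record_short_names_use_full_prefix():
    rec = PersonRecord(record_id="p2", first_name="Ana",
                       birth_date_raw="1980-01-01", birth_surname="Li")
    assert make_clean_record(rec).block_key_name == "anali"


def test_make_clean_record_fnmd_variants_and_country():
    rec = MortalityRecord(fnmd_id="f1", surname="Dupont",
                          first_name="Elon-Louis", birth_date_raw="1935-06-29",
                          death_date="2015-05-01", birth_country="FRANCE")
    clean = make_clean_record(rec)
    assert clean.firstname_12 == "elonlouis"
    assert clean.country_group == "france"
    assert clean.death_date == "2015-05-01"


def test_make_clean_record_requires_some_surname():
    rec = PersonRecord(record_id="p3", first_name="Jean",
                       birth_date_raw="1950-01-01")
    with pytest.raises(DataError):
        make_clean_record(rec)


@settings(derandomize=True, max_examples=200)
@given(st.text(max_size=30))
def test_normalize_is_idempotent_and_letters_only(raw):
    once = normalize_text(raw)
    assert set(once) <= set("abcdefghijklmnopqrstuvwxyz")
    assert normalize_text(once) == once


def test_cleaning_is_idempotent_on_clean_record():
    rec = PersonRecord(record_id="p4", first_name="Hélène-Marie",
                       birth_date_raw="1960-31-03", birth_surname="Lefèvre",
                       birth_city="Paris, 13ème arrondissement", sex="f",
                       birth_country="France")
    clean = make_clean_record(rec)
    again = PersonRecord(record_id="p4", first_name=clean.firstname_1,
                         birth_date_raw=clean.birth_date_repaired,
                         birth_surname=clean.surname_birth,
                         birth_city=clean.city, sex="f",
                         birth_country=clean.country_group)
    clean2 = make_clean_record(again)
    assert clean2.firstname_1 == clean.firstname_1
    assert clean2.surname_birth == clean.surname_birth
    assert clean2.birth_date_repaired == clean.birth_date_repaired
    assert clean2.city == clean.city
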