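"""Core record types shared across the linkage pipeline.

Two sides are linked: a *local* patient registry (e.g. a hospital data
warehouse extract) and a national mortality file (FNMD-like).  Neither
carries a shared unique identifier, so linkage proceeds on identity
traits: names, birth date, sex, place of birth.

Missing values are represented as ``None`` throughout, never as empty
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Invalid configuration (column mapping, thresholds, weights...)."""


class DataError(ValueError):
    """Invalid data content (duplicate ids, unparseable dates...)."""


#: canonical sex codes
SEX_CODES = ("m", "f")


@dataclass(frozen=True)
class PersonRecord:
    """One row of the local registry.

    ``birth_date_raw`` is carried verbatim: date repair happens in the
    cleaning stage because the source may contain dates a parser would
    reject (day/month "00", inverted day and month).
    """

    record_id: str
    first_name: str
    birth_date_raw: str
    birth_surname: str | None = None
    current_surname: str | None = None
    sex: str | None = None  # "m" | "f" | None
    birth_city: str | None = None
    birth_country: str | None = None
    vital_status: str | None = None  # "alive" | "deceased" | None
    death_date: str | None = None  # ISO date

    @property
    def matchable(self) -> bool:
        return self.birth_surname is not None or self.current_surname is not None


@dataclass(frozen=True)
class MortalityRecord:
    """One row of the mortality file.

    The mortality file records the birth surname only, a first name and
    zero or more middle names (order preserved), and is accent-free at
    the source.
    """

    fnmd_id: str
    surname: str
    first_name: str
    birth_date_raw: str
    death_date: str  # ISO date, must parse
    middle_names: tuple[str, ...] = ()
    sex: str | None = None
    birth_city: str | None = None
    birth_country: str | None = None
    death_zip: str | None = None


# default source-value → canonical sex map; covers the common codings
DEFAULT_SEX_MAP = {
    "m": "m", "f": "f", "h": "m", "1": "m", "2": "f",
    "male": "m", "female": "f", "homme": "m", "femme": "f",
}


@dataclass
class ColumnMapping:
    """Maps canonical field names to source column names for one file.

    ``columns`` maps canonical names (``record_id``, ``first_name``,
    ``birth_date``...) to the header names actually present in the file.
    Unmapped optional fields are simply absent from the produced records.
    """

    columns: dict[str, str]
    delimiter: str = ","
    encoding: str = "utf-8"
    date_format: str = "%Y-%m-%d"
    middle_name_separator: str = " "
    sex_values: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SEX_MAP))

    REQUIRED_PERSON = ("record_id", "first_name", "birth_date")
    REQUIRED_MORTALITY = ("record_id", "surname", "first_name", "birth_date",
                          "death_date")

    def require(self, canonical: tuple[str, ...]) -> None:
        missing = [c for c in canonical if c not in self.columns]
        if missing:
            raise ConfigurationError(
                f"column mapping lacks required field(s): {', '.join(missing)}"
            )

    def map_sex(self, raw: str | None) -> str | None:
        if raw is None:
            return None
        return self.sex_values.get(raw.strip().lower())
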