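"""Registry record types, CSV round-trip I/O and strategy configuration.

Both registries are flat tables.  Dates are ISO-8601 (``YYYY-MM-DD``) in
files and ``datetime.date`` in memory; all date arithmetic elsewhere in the
package is in whole days.  Sex is serialized as ``M`` / ``F`` / ``U``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = "U"


class Urgency(str, enum.Enum):
    ELECTIVE = "elective"
    URGENT = "urgent"


class ProcedureType(str, enum.Enum):
    CABG = "CABG"
    VALVE = "valve"
    CABG_VALVE = "CABG+valve"
    OTHER = "other"


class SchemaError(ValueError):
    """A registry file does not conform to the documented column layout."""


class IntegrityError(ValueError):
    """Record identifiers are duplicated within one registry file."""


class ConfigError(ValueError):
    """A strategy configuration violates a weight-sign or value constraint."""


@dataclass(frozen=True)
class PersonIdentity:
    """Identifying fields of one person as recorded in one registry.

    Any of ``surname``, ``forename`` and ``mrn`` may be empty (the
    deidentified registry blanks them); values are stored exactly as given
    and normalization happens at comparison time.
    """

    surname: str = ""
    forename: str = ""
    mrn: str = ""
    dob: date | None = None
    sex: Sex = Sex.UNKNOWN


@dataclass(frozen=True)
class SurgeryRecord:
    """One procedure episode in the (fully identified) surgical registry.

    ``icu_dis_date`` is the discharge date of the patient's post-operative
    ICU stay as recorded by the surgical registry; it is ``None`` when the
    patient had no ICU episode, in which case any matching pass that needs
    it fails for this record.
    """

    record_id: str
    identity: PersonIdentity
    procedure_date: date
    icu_dis_date: date | None
    hosp_adm_date: date
    hosp_dis_date: date
    age: int
    urgency: Urgency
    procedure_type: ProcedureType
    risk_of_death: float

    @property
    def sex(self) -> Sex:
        return self.identity.sex

    def __post_init__(self) -> None:
        if not (self.hosp_adm_date <= self.procedure_date <= self.hosp_dis_date):
            raise ValueError(
                f"{self.record_id}: hospital stay must bracket the procedure "
                f"({self.hosp_adm_date} <= {self.procedure_date} <= {self.hosp_dis_date})"
            )
        if not 0.0 <= self.risk_of_death <= 1.0:
            raise ValueError(f"{self.record_id}: risk_of_death outside [0, 1]")


@dataclass(frozen=True)
class IcuRecord:
    """One ICU admission in the (deidentified) intensive-care registry.

    Direct identifiers may be missing; the 14-character SLK-581 survives
    deidentification and may be the only identifying handle.
    """

    record_id: str
    identity: PersonIdentity
    slk: str
    icu_adm_date: date
    icu_dis_date: date
    hosp_adm_date: date
    hosp_dis_date: date
    age: int

    @property
    def sex(self) -> Sex:
        return self.identity.sex

    def __post_init__(self) -> None:
        if self.icu_adm_date > self.icu_dis_date:
            raise ValueError(f"{self.record_id}: ICU discharge precedes admission")
        if self.hosp_adm_date > self.icu_adm_date:
            raise ValueError(f"{self.record_id}: ICU admission precedes hospital admission")
        if self.slk and len(self.slk) != 14:
            raise ValueError(f"{self.record_id}: SLK-581 must have 14 characters, got {self.slk!r}")


# Fields the probabilistic scorer may compare.  "date" is the procedure-date
# vs ICU-admission-date caliper field.
SCORE_FIELDS = ("surname", "forename", "mrn", "slk", "date")

#: Published agreement / disagreement weights for each field.
DEFAULT_WEIGHTS: dict[str, tuple[float, float]] = {
    "surname": (7.0, -3.0),
    "forename": (5.0, -2.0),
    "mrn": (15.0, -5.0),
    "slk": (10.0, -2.0),
    "date": (2.0, -40.0),
}


@dataclass(frozen=True)
class LinkConfig:
    """Field weights, calipers, tolerances and cutoff for a linkage strategy.

    Defaults are the published values: surname 7/−3, forename 5/−2,
    MRN 15/−5, SLK-581 10/−2, date 2/−40 with a 2-day caliper and a total
    score cutoff of 1.  ``fields`` selects which fields the probabilistic
    scorer compares (the full-identifier strategy uses all five; the
    SLK-only strategy uses ``("slk", "date")``).
    """

    field_weights: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    date_caliper_days: int = 2
    age_tolerance_years: int = 2
    date_tolerance_days: int = 2
    cutoff_score: float = 1.0
    fields: tuple[str, ...] = SCORE_FIELDS

    def __post_init__(self) -> None:
        for name, (agree, disagree) in self.field_weights.items():
            if not (agree > 0 > disagree):
                raise ConfigError(
                    f"field {name!r}: need agree_weight > 0 > disagree_weight, "
                    f"got ({agree}, {disagree})"
                )
        unknown = set(self.fields) - set(SCORE_FIELDS)
        if unknown:
            raise ConfigError(f"unknown score fields: {sorted(unknown)}")
        for tol in (self.date_caliper_days, self.age_tolerance_years, self.date_tolerance_days):
            if tol < 0:
                raise ConfigError("calipers and tolerances must be non-negative")

    def restricted(self, fields: Sequence[str]) -> "LinkConfig":
        """A copy comparing only *fields* (e.g. ``("slk", "date")``)."""
        return replace(self, fields=tuple(fields))


# ---------------------------------------------------------------------------
# CSV I/O

SURGERY_COLUMNS = [
    "record_id", "surname", "forename", "mrn", "dob", "sex",
    "procedure_date", "icu_dis_date", "hosp_adm_date", "hosp_dis_date", "age",
    "urgency", "procedure_type", "risk_of_death",
]
ICU_COLUMNS = [
    "record_id", "surname", "forename", "mrn", "dob", "sex", "slk",
    "icu_adm_date", "icu_dis_date", "hosp_adm_date", "hosp_dis_date", "age",
]


def _parse_date(value: str, row: int, column: str, required: bool = True) -> date | None:
    value = value.strip()
    if not value:
        if required:
            raise SchemaError(f"row {row}: missing required date {column!r}")
        return None
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise SchemaError(f"row {row}: invalid date {value!r} in column {column!r}: {exc}") from None


def _parse_sex(value: str, row: int) -> Sex:
    value = value.strip().upper()
    if not value:
        return Sex.UNKNOWN
    try:
        return Sex(value)
    except ValueError:
        raise SchemaError(f"row {row}: sex must be one of M/F/U, got {value!r}") from None


def read_registry(path: str | Path, schema: str) -> list[SurgeryRecord] | list[IcuRecord]:
    """Read a registry CSV.

    Parameters
    ----------
    path
        CSV file with the documented header for *schema*.
    schema
        ``"surgery"`` or ``"icu"``.

    Returns records in file order.  Empty cells become empty identity fields
    (ICU schema only; the surgical registry is fully identified).  Malformed
    dates and schema violations raise :class:`SchemaError` naming the row;
    duplicate ``record_id`` raises :class:`IntegrityError`.
    """
    if schema not in ("surgery", "icu"):
        raise ValueError(f"schema must be 'surgery' or 'icu', got {schema!r}")
    columns = SURGERY_COLUMNS if schema == "surgery" else ICU_COLUMNS
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in columns if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing required columns {missing}")
        records: list = []
        seen: set[str] = set()
        for lineno, raw in enumerate(reader, start=2):
            rid = (raw["record_id"] or "").strip()
            if not rid:
                raise SchemaError(f"row {lineno}: empty record_id")
            if rid in seen:
                raise IntegrityError(f"row {lineno}: duplicate record_id {rid!r}")
            seen.add(rid)
            identity = PersonIdentity(
                surname=(raw["surname"] or "").strip(),
                forename=(raw["forename"] or "").strip(),
                mrn=(raw["mrn"] or "").strip(),
                dob=_parse_date(raw["dob"] or "", lineno, "dob", required=False),
                sex=_parse_sex(raw["sex"] or "", lineno),
            )
            try:
                if schema == "surgery":
                    records.append(SurgeryRecord(
                        record_id=rid,
                        identity=identity,
                        procedure_date=_parse_date(raw["procedure_date"], lineno, "procedure_date"),
                        icu_dis_date=_parse_date(raw.get("icu_dis_date") or "", lineno,
                                                 "icu_dis_date", required=False),
                        hosp_adm_date=_parse_date(raw["hosp_adm_date"], lineno, "hosp_adm_date"),
                        hosp_dis_date=_parse_date(raw["hosp_dis_date"], lineno, "hosp_dis_date"),
                        age=int(raw["age"]),
                        urgency=Urgency(raw["urgency"].strip()),
                        procedure_type=ProcedureType(raw["procedure_type"].strip()),
                        risk_of_death=float(raw["risk_of_death"]),
                    ))
                else:
                    records.append(IcuRecord(
                        record_id=rid,
                        identity=identity,
                        slk=(raw["slk"] or "").strip(),
                        icu_adm_date=_parse_date(raw["icu_adm_date"], lineno, "icu_adm_date"),
                        icu_dis_date=_parse_date(raw["icu_dis_date"], lineno, "icu_dis_date"),
                        hosp_adm_date=_parse_date(raw["hosp_adm_date"], lineno, "hosp_adm_date"),
                        hosp_dis_date=_parse_date(raw["hosp_dis_date"], lineno, "hosp_dis_date"),
                        age=int(raw["age"]),
                    ))
            except (ValueError, KeyError) as exc:
                if isinstance(exc, (SchemaError, IntegrityError)):
                    raise
                raise SchemaError(f"row {lineno}: {exc}") from exc
    return records


def write_registry(records: Iterable[SurgeryRecord] | Iterable[IcuRecord],
                   path: str | Path) -> None:
    """Write records back to CSV in the documented column order."""
    records = list(records)
    if not records:
        raise ValueError("cannot infer schema from an empty record list")
    is_surgery = isinstance(records[0], SurgeryRecord)
    columns = SURGERY_COLUMNS if is_surgery else ICU_COLUMNS
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            ident = rec.identity
            common = [
                rec.record_id, ident.surname, ident.forename, ident.mrn,
                ident.dob.isoformat() if ident.dob else "", ident.sex.value,
            ]
            if is_surgery:
                writer.writerow(common + [
                    rec.procedure_date.isoformat(),
                    rec.icu_dis_date.isoformat() if rec.icu_dis_date else "",
                    rec.hosp_adm_date.isoformat(),
                    rec.hosp_dis_date.isoformat(),
                    rec.age, rec.urgency.value, rec.procedure_type.value,
                    f"{rec.risk_of_death:.6f}",
                ])
            else:
                writer.writerow(common + [
                    rec.slk,
                    rec.icu_adm_date.isoformat(),
                    rec.icu_dis_date.isoformat(),
                    rec.hosp_adm_date.isoformat(),
                    rec.hosp_dis_date.isoformat(),
                    rec.age,
                ])


def write_pairs(pairs: Iterable[tuple[str, str, str, object]], path: str | Path) -> None:
    """Write accepted pairs as CSV with columns surgery_id,icu_id,method,score_or_stage."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surgery_id", "icu_id", "method", "score_or_stage"])
        for row in pairs:
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Strategy configuration files
#
# Flat ``key = value`` text; '#' starts a comment.  Keys:
#   weight.<field>.agree / weight.<field>.disagree   (field in SCORE_FIELDS)
#   caliper_days, date_tolerance_days, age_tolerance_years, cutoff
#   fields = comma-separated subset of SCORE_FIELDS

def load_config(path: str | Path) -> LinkConfig:
    """Load a :class:`LinkConfig`; unspecified keys keep the published defaults."""
    weights = dict(DEFAULT_WEIGHTS)
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("weight."):
            try:
                _, fname, side = key.split(".")
            except ValueError:
                raise ConfigError(f"line {lineno}: bad weight key {key!r}") from None
            if fname not in SCORE_FIELDS or side not in ("agree", "disagree"):
                raise ConfigError(f"line {lineno}: bad weight key {key!r}")
            agree, disagree = weights[fname]
            weights[fname] = (float(value), disagree) if side == "agree" else (agree, float(value))
        elif key == "caliper_days":
            kwargs["date_caliper_days"] = int(value)
        elif key == "date_tolerance_days":
            kwargs["date_tolerance_days"] = int(value)
        elif key == "age_tolerance_years":
            kwargs["age_tolerance_years"] = int(value)
        elif key == "cutoff":
            kwargs["cutoff_score"] = float(value)
        elif key == "fields":
            kwargs["fields"] = tuple(f.strip() for f in value.split(",") if f.strip())
        else:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
    return LinkConfig(field_weights=weights, **kwargs)
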