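"""Person records: normalization, CSV input/output, parameter sets and truth sets.

A :class:`PersonRecord` holds one row of personal identifiers in normalized
form.  Missingness is represented by the explicit :data:`MISSING` sentinel
(never the empty string) because missing identifiers are a first-class
property of linkage datasets and drive much of the downstream behaviour.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Canonical identifier fields, in canonical order.
FIELDS = (
    "first_name",
    "middle_name",
    "last_name",
    "dob",
    "sex",
    "suburb",
    "address",
    "postcode",
)

#: Fields whose values are free text (names/places): punctuation is stripped,
#: internal spaces are kept (collapsed to one).
_TEXT_FIELDS = frozenset(
    {"first_name", "middle_name", "last_name", "suburb", "address"}
)


class _Missing:
    """Singleton marker for a missing field value.  Falsy; distinct from ''."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


MISSING = _Missing()

_WS_RE = re.compile(r"\s+")
_NON_ALNUM_SPACE_RE = re.compile(r"[^0-9A-Z ]+")
_NON_ALNUM_RE = re.compile(r"[^0-9A-Z]+")

# Accepted delimited date layouts, tried in order.  Ambiguous day/month
# orders are resolved in favour of day-first (matching AU source data).
_DATE_PATTERNS = (
    re.compile(r"^(?P<y>\d{4})[-/. ](?P<m>\d{1,2})[-/. ](?P<d>\d{1,2})$"),
    re.compile(r"^(?P<d>\d{1,2})[-/. ](?P<m>\d{1,2})[-/. ](?P<y>\d{4})$"),
)

# An 8-digit string is treated as already canonical (YYYYMMDD) without
# calendar validation: typo-corrupted dates are real dirty data and should
# attenuate similarity downstream rather than be blanked to MISSING.
_CANONICAL_DATE_RE = re.compile(r"^\d{8}$")


def normalize_field(raw: str, field_name: str):
    """Normalize a raw field value; return the canonical string or MISSING.

    Rules: uppercase, strip outer whitespace, collapse internal whitespace
    runs to one space; text fields additionally drop non-alphanumeric
    characters; dates are canonicalized to ``YYYYMMDD`` digits; ``sex``
    becomes a single M/F token where recognizable.  An empty result (or an
    unparseable date) maps to MISSING — normalization never aborts a load.
    """
    if raw is None or isinstance(raw, _Missing):
        return MISSING
    value = _WS_RE.sub(" ", str(raw).strip().upper())
    if not value:
        return MISSING

    if field_name == "dob":
        return _normalize_date(value)
    if field_name == "sex":
        token = _NON_ALNUM_RE.sub("", value)
        if not token:
            return MISSING
        if token in ("M", "MALE"):
            return "M"
        if token in ("F", "FEMALE"):
            return "F"
        return token
    if field_name in _TEXT_FIELDS:
        value = _WS_RE.sub(" ", _NON_ALNUM_SPACE_RE.sub("", value)).strip()
        return value if value else MISSING
    if field_name == "postcode":
        value = _NON_ALNUM_RE.sub("", value)
        return value if value else MISSING
    return value


def _normalize_date(value: str):
    if _CANONICAL_DATE_RE.match(value):
        return value
    for pat in _DATE_PATTERNS:
        m = pat.match(value)
        if m:
            y, mo, d = int(m["y"]), int(m["m"]), int(m["d"])
            if 1 <= mo <= 12 and 1 <= d <= 31:
                return f"{y:04d}{mo:02d}{d:02d}"
    logger.warning("unparseable date %r mapped to MISSING", value)
    return MISSING


@dataclass
class PersonRecord:
    """One person row: an opaque ID plus normalized identifier fields.

    ``fields`` always contains exactly the keys in :data:`FIELDS`; values are
    normalized strings or :data:`MISSING`.
    """

    record_id: str
    fields: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise DataError("record_id must be non-empty")
        full = {name: self.fields.get(name, MISSING) for name in FIELDS}
        extra = set(self.fields) - set(FIELDS)
        if extra:
            raise DataError(f"unknown fields: {sorted(extra)}")
        self.fields = full

    def get(self, name: str):
        return self.fields[name]

    def is_missing(self, name: str) -> bool:
        return isinstance(self.fields[name], _Missing)


@dataclass(frozen=True)
class ParameterSet:
    """Which identifier fields enter the CLK and how each is decomposed.

    ``per_field_gram_mode`` maps each included field to ``"unigram"`` or
    ``"bigram"``.  Defaults: bigrams for the free-text fields, unigrams for
    the short numeric/coded ones (dob, sex, postcode).
    """

    name: str
    included_fields: tuple
    per_field_gram_mode: Mapping[str, str]
    padding: bool = True

    def __post_init__(self):
        if not self.included_fields:
            raise ConfigError("parameter set must include at least one field")
        bad = [f for f in self.included_fields if f not in FIELDS]
        if bad:
            raise ConfigError(f"unknown fields in parameter set: {bad}")
        for f in self.included_fields:
            mode = self.per_field_gram_mode.get(f)
            if mode not in ("unigram", "bigram"):
                raise ConfigError(f"field {f!r} needs gram mode unigram|bigram, got {mode!r}")


DEFAULT_GRAM_MODES = {
    "first_name": "bigram",
    "middle_name": "bigram",
    "last_name": "bigram",
    "dob": "unigram",
    "sex": "unigram",
    "suburb": "bigram",
    "address": "bigram",
    "postcode": "unigram",
}

_PRESET_FIELDS = {
    "set1": ("first_name", "last_name", "dob", "sex"),
    "set2": FIELDS,
    "set3": ("first_name", "last_name", "dob", "sex", "suburb", "postcode"),
    "set4": ("first_name", "middle_name", "last_name", "dob", "sex"),
}


def parameter_set(
    name: str,
    gram_modes: Mapping[str, str] | None = None,
    padding: bool = True,
) -> ParameterSet:
    """Build one of the four preset parameter sets (``set1`` … ``set4``).

    ``gram_modes`` overrides the default per-field decomposition.
    """
    if name not in _PRESET_FIELDS:
        raise ConfigError(f"unknown parameter set {name!r}; choose from {sorted(_PRESET_FIELDS)}")
    fields_ = _PRESET_FIELDS[name]
    modes = dict(DEFAULT_GRAM_MODES)
    if gram_modes:
        modes.update(gram_modes)
    return ParameterSet(
        name=name,
        included_fields=tuple(fields_),
        per_field_gram_mode={f: modes[f] for f in fields_},
        padding=padding,
    )


@dataclass
class TruthSet:
    """Total assignment of record IDs to entity IDs (gold standard)."""

    assignment: dict

    def entity_of(self, record_id: str) -> str:
        try:
            return self.assignment[record_id]
        except KeyError:
            raise DataError(f"record {record_id!r} absent from truth set") from None

    def __len__(self) -> int:
        return len(self.assignment)


def read_records(
    path,
    column_map: Mapping[str, str],
    delimiter: str = ",",
) -> list[PersonRecord]:
    """Read a delimited file into normalized PersonRecords.

    ``column_map`` maps canonical field names (plus ``record_id``) to source
    column headers; unmapped fields load as MISSING.  Row count is preserved;
    a missing mapped column or a duplicate record ID is a hard error.
    """
    if "record_id" not in column_map:
        raise ConfigError("column_map must map 'record_id'")
    records: list[PersonRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for fname, col in column_map.items():
            if col not in header:
                raise DataError(f"mapped column {col!r} (for {fname!r}) not in header of {path}")
        for row in reader:
            rid = (row[column_map["record_id"]] or "").strip()
            if not rid:
                raise DataError(f"empty record_id in {path}")
            if rid in seen:
                raise DataError(f"duplicate record_id {rid!r} in {path}")
            seen.add(rid)
            fields_ = {
                f: normalize_field(row[column_map[f]], f)
                for f in FIELDS
                if f in column_map
            }
            records.append(PersonRecord(record_id=rid, fields=fields_))
    logger.info("read %d records from %s", len(records), path)
    return records


def write_records(records: Iterable[PersonRecord], path, delimiter: str = ",") -> None:
    """Write records to CSV with canonical headers; MISSING becomes empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(("record_id",) + FIELDS)
        for rec in records:
            writer.writerow(
                [rec.record_id]
                + ["" if rec.is_missing(f) else rec.fields[f] for f in FIELDS]
            )


def identity_column_map(include_record_id: bool = True) -> dict:
    """Column map matching the headers produced by :func:`write_records`."""
    cmap = {f: f for f in FIELDS}
    if include_record_id:
        cmap["record_id"] = "record_id"
    return cmap


def read_truth(path, delimiter: str = ",") -> TruthSet:
    """Read a two-column record_id,entity_id file into a TruthSet.

    A record listed twice with different entities is a hard error.
    """
    assignment: dict = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        first = True
        for row in reader:
            if not row:
                continue
            if first and [c.strip().lower() for c in row[:2]] == ["record_id", "entity_id"]:
                first = False
                continue
            first = False
            if len(row) < 2:
                raise DataError(f"truth row needs two columns, got {row!r}")
            rid, eid = row[0].strip(), row[1].strip()
            if rid in assignment and assignment[rid] != eid:
                raise DataError(
                    f"record {rid!r} assigned to both {assignment[rid]!r} and {eid!r}"
                )
            assignment[rid] = eid
    return TruthSet(assignment=assignment)


def write_truth(truth: TruthSet, path, delimiter: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["record_id", "entity_id"])
        for rid, eid in truth.assignment.items():
            writer.writerow([rid, eid])
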