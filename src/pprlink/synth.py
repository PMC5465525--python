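"""Synthetic person populations with known truth.

Generates clean entities from small bundled name pools, then derives
per-entity duplicate records with typographical corruption, optional
first/last name swaps, and per-field missingness profiles emulating
hospital-admission data (``nsw_public``, ``nsw_private``, ``wa`` presets).
Everything is reproducible from (n, dup_rate, model, seed).
"""

from __future__ import annotations

import datetime
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _namepools as pools
from .errors import ConfigError, DataError
from .records import FIELDS, MISSING, PersonRecord, TruthSet

_LETTERS = string.ascii_uppercase
_DIGITS = string.digits

EDIT_KINDS = ("insert", "delete", "substitute", "transpose")


@dataclass(frozen=True)
class CorruptionModel:
    """How duplicates differ from their originals, and what goes missing.

    ``per_field_missingness`` gives the marginal probability that a field is
    MISSING — applied independently to originals and duplicates alike so the
    observed rates match the profile.  ``typo_rate`` is the per-field chance
    that a duplicate's value receives exactly one edit; ``field_swap_rate``
    the chance a duplicate's first and last names are exchanged.
    """

    per_field_missingness: dict = field(default_factory=dict)
    typo_rate: float = 0.0
    edit_kinds: tuple = EDIT_KINDS
    field_swap_rate: float = 0.0

    def __post_init__(self):
        for fname, p in self.per_field_missingness.items():
            if fname not in FIELDS:
                raise ConfigError(f"unknown field in missingness map: {fname!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"missingness for {fname!r} out of [0,1]: {p}")
        for rate in (self.typo_rate, self.field_swap_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"rate out of [0,1]: {rate}")
        bad = set(self.edit_kinds) - set(EDIT_KINDS)
        if bad:
            raise ConfigError(f"unknown edit kinds: {sorted(bad)}")


# Marginal missingness presets mirroring the source datasets' published
# per-identifier rates ("<1%" is taken as 0.5%).
PROFILES: dict[str, dict] = {
    "clean": {},
    "nsw_public": {
        "first_name": 0.03, "middle_name": 0.54, "last_name": 0.005,
        "dob": 0.0, "sex": 0.005, "suburb": 0.005, "address": 0.02,
        "postcode": 0.005,
    },
    "nsw_private": {
        "first_name": 1.0, "middle_name": 1.0, "last_name": 1.0,
        "dob": 0.0, "sex": 0.005, "suburb": 0.03, "address": 0.22,
        "postcode": 0.03,
    },
    "wa": {
        "first_name": 0.005, "middle_name": 0.41, "last_name": 0.005,
        "dob": 0.005, "sex": 0.005, "suburb": 0.005, "address": 0.005,
        "postcode": 0.005,
    },
}


def corruption_model(
    profile: str = "clean",
    typo_rate: float = 0.0,
    field_swap_rate: float = 0.0,
) -> CorruptionModel:
    """A CorruptionModel with the named missingness profile."""
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    return CorruptionModel(
        per_field_missingness=dict(PROFILES[profile]),
        typo_rate=typo_rate,
        field_swap_rate=field_swap_rate,
    )


@dataclass
class SyntheticPopulation:
    """Records plus the ground-truth entity assignment that produced them."""

    records: list
    truth: TruthSet
    seed: int
    model: CorruptionModel

    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]


def generate_entities(
    n: int,
    seed: int,
    year_range: tuple[int, int] = (1920, 2005),
) -> list[PersonRecord]:
    """``n`` clean, fully populated records, one per entity, deterministic in seed.

    Entities are guaranteed gram-distinguishable: no two share first name,
    last name, sex and the digit content of the date of birth, so perfect
    data never produces colliding CLKs between different people.
    """
    if n < 0:
        raise DataError("n must be >= 0")
    rng = np.random.default_rng(seed)
    lo = datetime.date(year_range[0], 1, 1).toordinal()
    hi = datetime.date(year_range[1], 12, 31).toordinal()
    records: list[PersonRecord] = []
    seen_keys: set = set()
    i = 0
    while len(records) < n:
        first = str(rng.choice(pools.FIRST_NAMES))
        middle = str(rng.choice(pools.FIRST_NAMES))
        last = str(rng.choice(pools.LAST_NAMES))
        sex = "M" if rng.random() < 0.5 else "F"
        dob = datetime.date.fromordinal(int(rng.integers(lo, hi + 1))).strftime(
            "%Y%m%d"
        )
        key = (first, last, sex, frozenset(dob))
        if key in seen_keys:
            continue
        seen_keys.add(key)
        suburb, postcode = pools.SUBURBS[int(rng.integers(len(pools.SUBURBS)))]
        address = (
            f"{int(rng.integers(1, 300))} "
            f"{rng.choice(pools.STREET_NAMES)} {rng.choice(pools.STREET_TYPES)}"
        )
        records.append(
            PersonRecord(
                record_id=f"R{i:07d}",
                fields={
                    "first_name": first,
                    "middle_name": middle,
                    "last_name": last,
                    "dob": dob,
                    "sex": sex,
                    "suburb": suburb,
                    "address": address,
                    "postcode": postcode,
                },
            )
        )
        i += 1
    return records


def corrupt_value(value: str, kinds: Sequence[str], rng: np.random.Generator) -> str:
    """Apply exactly one typographical edit at a uniformly chosen position.

    Kinds: insert (random character), delete, substitute (to a different
    character), adjacent transpose.  Single-character values skip transpose;
    runs of equal characters fall back from transpose to substitution so the
    result always differs from the input (unless deletion empties it).
    """
    if value is MISSING or value == "":
        raise DataError("cannot corrupt a MISSING/empty value")
    alphabet = _DIGITS if value.isdigit() else _LETTERS
    usable = [k for k in kinds if k != "transpose" or len(value) >= 2]
    kind = usable[int(rng.integers(len(usable)))]
    if kind == "transpose":
        diff = [i for i in range(len(value) - 1) if value[i] != value[i + 1]]
        if not diff:
            kind = "substitute"
        else:
            i = diff[int(rng.integers(len(diff)))]
            return value[:i] + value[i + 1] + value[i] + value[i + 2 :]
    if kind == "insert":
        i = int(rng.integers(len(value) + 1))
        return value[:i] + alphabet[int(rng.integers(len(alphabet)))] + value[i:]
    if kind == "delete":
        i = int(rng.integers(len(value)))
        return value[:i] + value[i + 1 :]
    # substitute
    i = int(rng.integers(len(value)))
    choices = alphabet.replace(value[i], "") or _LETTERS.replace(value[i], "")
    return value[:i] + choices[int(rng.integers(len(choices)))] + value[i + 1 :]


def _apply_missingness(
    fields_: dict, model: CorruptionModel, rng: np.random.Generator
) -> dict:
    out = dict(fields_)
    for fname, p in model.per_field_missingness.items():
        if p > 0 and rng.random() < p:
            out[fname] = MISSING
    return out


def _corrupt_record(
    fields_: dict, model: CorruptionModel, rng: np.random.Generator
) -> dict:
    out = dict(fields_)
    if model.field_swap_rate > 0 and rng.random() < model.field_swap_rate:
        out["first_name"], out["last_name"] = out["last_name"], out["first_name"]
    if model.typo_rate > 0:
        for fname in FIELDS:
            v = out[fname]
            if v is not MISSING and v != "" and rng.random() < model.typo_rate:
                kinds = model.edit_kinds
                if fname in ("dob", "postcode"):
                    # fixed-width digit fields: keep edits length-preserving
                    kinds = tuple(
                        k for k in kinds if k in ("substitute", "transpose")
                    ) or ("substitute",)
                edited = corrupt_value(v, kinds, rng)
                out[fname] = edited if edited else MISSING
    return out


def make_duplicates(
    entities: Sequence[PersonRecord],
    dup_rate: float,
    model: CorruptionModel,
    seed: int,
    fixed_count: int | None = None,
) -> SyntheticPopulation:
    """Derive a truth-linked population: originals plus corrupted duplicates.

    Each entity receives Poisson(dup_rate) duplicates (or exactly
    ``fixed_count`` when given).  Duplicates are independently corrupted;
    missingness is applied to originals and duplicates alike so the marginal
    rates match the model.
    """
    if dup_rate < 0:
        raise DataError("dup_rate must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[PersonRecord] = []
    assignment: dict = {}
    for idx, orig in enumerate(entities):
        entity_id = f"P{idx:06d}"
        n_dups = (
            fixed_count
            if fixed_count is not None
            else int(rng.poisson(dup_rate))
        )
        base = dict(orig.fields)
        records.append(
            PersonRecord(
                record_id=orig.record_id,
                fields=_apply_missingness(base, model, rng),
            )
        )
        assignment[orig.record_id] = entity_id
        for j in range(n_dups):
            dup_fields = _apply_missingness(
                _corrupt_record(base, model, rng), model, rng
            )
            dup_id = f"{orig.record_id}.D{j}"
            records.append(PersonRecord(record_id=dup_id, fields=dup_fields))
            assignment[dup_id] = entity_id
    return SyntheticPopulation(
        records=records,
        truth=TruthSet(assignment=assignment),
        seed=seed,
        model=model,
    )


def generate_population(
    n: int,
    dup_rate: float,
    model: CorruptionModel,
    seed: int,
    year_range: tuple[int, int] = (1920, 2005),
    fixed_count: int | None = None,
) -> SyntheticPopulation:
    """Convenience: generate_entities + make_duplicates with derived seeds."""
    entities = generate_entities(n, seed, year_range=year_range)
    return make_duplicates(
        entities, dup_rate, model, seed + 1, fixed_count=fixed_count
    )
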