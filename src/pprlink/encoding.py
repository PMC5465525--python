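"""CLK encoding: q-gram decomposition and keyed hashing into one bit vector.

Every included field of a record is decomposed into unigrams or bigrams;
each gram is hashed ``k`` times with a secret-keyed digest and the resulting
positions (mod ``l``) are set in a single shared Bloom filter.  The default
scheme is full random hashing (k independent keyed digests); the classic
double-hashing construction is retained for comparability but is known to
be weaker.
"""

from __future__ import annotations

import base64
import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .records import ParameterSet, PersonRecord, _Missing

logger = logging.getLogger(__name__)

PAD = "_"  # boundary symbol for padded bigram decomposition
_SEP = "\x1f"  # joins field tag and gram; cannot occur in normalized values


@dataclass
class EncodingConfig:
    """Everything that determines the bits of a CLK except the record itself.

    The secret is required key material and is never written to any output;
    ``salt_field`` optionally names a record field whose value is mixed into
    the key per record (salting).
    """

    secret: str | bytes
    l: int = 1000
    k: int = 10
    scheme: str = "random_hashing"
    salt_field: str | None = None
    field_tagging: bool = True
    positional_unigrams: bool = False

    def __post_init__(self) -> None:
        if self.l < 1 or self.k < 1:
            raise ConfigError(f"l and k must be >= 1 (got l={self.l}, k={self.k})")
        if self.scheme not in ("random_hashing", "double_hashing"):
            raise ConfigError(f"unknown hash scheme {self.scheme!r}")
        if not self.secret:
            raise ConfigError("a non-empty secret is required")

    def __repr__(self) -> str:  # never leak the secret
        return (
            f"EncodingConfig(l={self.l}, k={self.k}, scheme={self.scheme!r}, "
            f"salt_field={self.salt_field!r}, field_tagging={self.field_tagging}, "
            f"positional_unigrams={self.positional_unigrams}, secret=***)"
        )

    def _secret_bytes(self) -> bytes:
        s = self.secret
        return s if isinstance(s, bytes) else s.encode("utf-8")


@dataclass
class CLK:
    """Cryptographic long-term key: a fixed-length bit vector for one record.

    ``bits`` is a packed big-endian uint8 array (bit 0 = MSB of byte 0) of
    ``ceil(l/8)`` bytes; trailing pad bits are always zero.  ``popcount``
    caches the number of set bits.
    """

    record_id: str
    bits: np.ndarray
    l: int
    popcount: int = field(default=-1)

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.size != (self.l + 7) // 8:
            raise DataError(
                f"CLK {self.record_id!r}: {self.bits.size} bytes for l={self.l}"
            )
        if self.popcount < 0:
            self.popcount = int(np.bitwise_count(self.bits).sum())

    def bit_positions(self) -> np.ndarray:
        """Indices of set bits, ascending."""
        return np.flatnonzero(np.unpackbits(self.bits, count=self.l))

    def as_bool(self) -> np.ndarray:
        return np.unpackbits(self.bits, count=self.l).astype(bool)

    @classmethod
    def from_positions(cls, record_id: str, positions: Iterable[int], l: int) -> "CLK":
        arr = np.zeros(l, dtype=np.uint8)
        pos = list(positions)
        if pos:
            arr[np.asarray(pos, dtype=np.intp)] = 1
        return cls(record_id=record_id, bits=np.packbits(arr), l=l)


def to_grams(
    value: str,
    mode: str,
    padding: bool,
    field: str | None = None,
    positional: bool = False,
) -> list[str]:
    """Decompose a normalized value into its ordered list of grams.

    Bigram mode yields overlapping length-2 substrings; with ``padding`` one
    boundary symbol is added at each end first.  A single character in
    unpadded bigram mode is emitted as-is (degenerate gram).  When ``field``
    is given each gram is tagged so identical substrings in different fields
    hash differently; ``positional`` prefixes unigrams with their index so
    multiplicity and order survive set semantics.
    """
    if isinstance(value, _Missing):
        raise DataError("cannot decompose a MISSING value")
    if mode == "unigram":
        grams = [f"{i}{_SEP}{c}" if positional else c for i, c in enumerate(value)]
    elif mode == "bigram":
        s = f"{PAD}{value}{PAD}" if padding else value
        if len(s) == 1:
            grams = [s]
        else:
            grams = [s[i : i + 2] for i in range(len(s) - 1)]
    else:
        raise ConfigError(f"unknown gram mode {mode!r}")
    if field is not None:
        grams = [f"{field}{_SEP}{g}" for g in grams]
    return grams


def _base_key(config: EncodingConfig, record_salt: str | None) -> bytes:
    material = config._secret_bytes()
    if record_salt is not None:
        material += b"\x1e" + record_salt.encode("utf-8")
    # Hash down to 32 bytes so appended scheme/iteration suffixes stay within
    # blake2b's 64-byte key limit regardless of secret length.
    return hashlib.blake2b(material, digest_size=32).digest()


def _digest(token: bytes, key: bytes) -> int:
    return int.from_bytes(
        hashlib.blake2b(token, key=key, digest_size=8).digest(), "big"
    )


def hash_positions(
    gram: str,
    config: EncodingConfig,
    record_salt: str | None = None,
) -> frozenset[int]:
    """Map one (already field-tagged) gram to its set of bit positions.

    random_hashing: k independent keyed digests, the iteration index mixed
    into the key, each reduced mod l.  double_hashing: positions
    ``(h1 + i*h2) mod l`` for i in 0..k-1 from two keyed digests.
    Collisions may reduce the distinct count below k.
    """
    key = _base_key(config, record_salt)
    token = gram.encode("utf-8")
    l = config.l
    if config.scheme == "random_hashing":
        return frozenset(
            _digest(token, key + i.to_bytes(4, "big")) % l for i in range(config.k)
        )
    h1 = _digest(token, key + b"\x00h1")
    h2 = _digest(token, key + b"\x00h2")
    return frozenset((h1 + i * h2) % l for i in range(config.k))


def field_grams(
    record: PersonRecord, pset: ParameterSet, config: EncodingConfig
) -> list[str]:
    """All field-tagged grams of a record under a parameter set (with duplicates)."""
    grams: list[str] = []
    for fname in pset.included_fields:
        value = record.fields[fname]
        if isinstance(value, _Missing) or value == "":
            continue
        grams.extend(
            to_grams(
                value,
                pset.per_field_gram_mode[fname],
                pset.padding,
                field=fname if config.field_tagging else None,
                positional=config.positional_unigrams,
            )
        )
    return grams


def encode_clk(
    record: PersonRecord,
    pset: ParameterSet,
    config: EncodingConfig,
    _cache: dict | None = None,
) -> CLK:
    """Encode one record into its CLK (union of all gram positions).

    MISSING fields contribute nothing; duplicate grams contribute their
    positions once.  A record whose included fields are all MISSING yields
    the all-zero CLK (with a warning) rather than an error.
    """
    salt = None
    if config.salt_field is not None:
        sv = record.fields[config.salt_field]
        salt = None if isinstance(sv, _Missing) else sv
    positions: set[int] = set()
    for gram in field_grams(record, pset, config):
        if _cache is not None and salt is None:
            cached = _cache.get(gram)
            if cached is None:
                cached = hash_positions(gram, config)
                _cache[gram] = cached
            positions.update(cached)
        else:
            positions.update(hash_positions(gram, config, record_salt=salt))
    if not positions:
        logger.warning(
            "record %r has no usable identifiers; emitting all-zero CLK",
            record.record_id,
        )
    return CLK.from_positions(record.record_id, positions, config.l)


def encode_dataset(
    records: Sequence[PersonRecord],
    pset: ParameterSet,
    config: EncodingConfig,
) -> list[CLK]:
    """Encode every record, order preserved; never drops records."""
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("record IDs must be unique within a dataset")
    cache: dict = {}
    clks = [encode_clk(rec, pset, config, _cache=cache) for rec in records]
    logger.info(
        "encoded %d records (pset=%s, l=%d, k=%d, scheme=%s)",
        len(clks), pset.name, config.l, config.k, config.scheme,
    )
    return clks


# ---------------------------------------------------------------------------
# CLK file format: line-oriented text.  Header records l, k, scheme and
# parameter-set name (never the secret); body lines are
# record_id TAB base64(big-endian packed bits) TAB popcount.
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "#pprlink-clk"


def write_clks(
    clks: Sequence[CLK],
    path,
    k: int,
    scheme: str,
    pset_name: str,
) -> None:
    if clks:
        l = clks[0].l
        if any(c.l != l for c in clks):
            raise DataError("all CLKs in a file must share one length")
    else:
        l = 0
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_PREFIX}\tl={l}\tk={k}\tscheme={scheme}\tpset={pset_name}\n")
        for clk in clks:
            b64 = base64.b64encode(clk.bits.tobytes()).decode("ascii")
            fh.write(f"{clk.record_id}\t{b64}\t{clk.popcount}\n")


def read_clks(path) -> tuple[list[CLK], dict]:
    """Read a CLK file; returns (clks, metadata dict from the header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_HEADER_PREFIX):
            raise DataError(f"{path}: not a CLK file (bad header)")
        meta: dict = {}
        for part in header.split("\t")[1:]:
            key, _, val = part.partition("=")
            meta[key] = int(val) if val.isdigit() else val
        l = int(meta["l"])
        clks: list[CLK] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                rid, b64, pop = line.split("\t")
            except ValueError:
                raise DataError(f"{path}:{lineno}: malformed CLK line") from None
            if rid in seen:
                raise DataError(f"{path}:{lineno}: duplicate record_id {rid!r}")
            seen.add(rid)
            bits = np.frombuffer(base64.b64decode(b64), dtype=np.uint8)
            clk = CLK(record_id=rid, bits=bits.copy(), l=l)
            if clk.popcount != int(pop):
                raise DataError(f"{path}:{lineno}: stored popcount disagrees with bits")
            clks.append(clk)
    return clks, meta
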