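"""Linkage engine: de-duplication, two-file linkage, and external blocking.

The engine emits raw candidate pairs above a Tanimoto threshold — no
transitive closure and no one-to-one assignment; clustering is a downstream
concern.  Per-phase record counts, comparison counters and elapsed times are
logged so runs are auditable.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import time
from dataclasses import dataclass
from typing import Sequence

from .encoding import CLK, EncodingConfig, encode_dataset
from .errors import ConfigError, DataError
from .multibit import build_tree, query_tree
from .records import ParameterSet, PersonRecord, _Missing

logger = logging.getLogger(__name__)

#: Block label for records whose blocking field is MISSING; such records are
#: compared only among themselves (cheap, but costs recall — logged).
MISSING_BLOCK = "__missing__"


@dataclass(frozen=True, order=True)
class CandidatePair:
    """Unordered candidate pair (id_a < id_b for de-duplication) with its score."""

    id_a: str
    id_b: str
    similarity: float


@dataclass(frozen=True)
class BlockingKey:
    """Named rule deriving a blocking token from a record.

    ``field`` names the source identifier and ``extractor`` how the token is
    derived from it (``year`` takes the leading 4 digits of a YYYYMMDD date,
    ``exact`` the whole value).  When a secret is supplied, tokens are stored
    only as keyed hashes so block labels leak nothing in output artifacts.
    """

    field: str
    extractor: str = "exact"
    secret: str | None = None

    _EXTRACTORS: tuple = ("exact", "year")

    def __post_init__(self):
        if self.extractor not in self._EXTRACTORS:
            raise ConfigError(f"unknown blocking extractor {self.extractor!r}")

    @classmethod
    def parse(cls, spec: str, secret: str | None = None) -> "BlockingKey":
        """Parse a ``field[:extractor]`` CLI spec, e.g. ``dob:year``."""
        field, _, extractor = spec.partition(":")
        return cls(field=field, extractor=extractor or "exact", secret=secret)

    def derive(self, record: PersonRecord) -> str:
        value = record.fields[self.field]
        if isinstance(value, _Missing):
            return MISSING_BLOCK
        token = value[:4] if self.extractor == "year" else value
        if self.secret is not None:
            token = hashlib.blake2b(
                token.encode("utf-8"),
                key=hashlib.blake2b(
                    self.secret.encode("utf-8"), digest_size=32
                ).digest(),
                digest_size=12,
            ).hexdigest()
        return token


def _check_unique_ids(clks: Sequence[CLK]) -> None:
    ids = [c.record_id for c in clks]
    if len(set(ids)) != len(ids):
        raise DataError("record IDs must be unique")


def deduplicate(
    clks: Sequence[CLK],
    threshold: float,
    leaf_limit: int = 1,
    stats: dict | None = None,
) -> list[CandidatePair]:
    """All unordered pairs (i < j) with Tanimoto >= threshold within one dataset.

    Builds one multibit tree and queries every CLK against it sequentially;
    self-matches are removed and each unordered pair is kept once.  Exact:
    equals the brute-force O(n^2) pair set.
    """
    _check_unique_ids(clks)
    t0 = time.perf_counter()
    tree = build_tree(clks, leaf_limit=leaf_limit)
    t_build = time.perf_counter() - t0
    pairs: dict[tuple[str, str], float] = {}
    t0 = time.perf_counter()
    for clk in clks:
        for rid, sim in query_tree(tree, clk, threshold, stats=stats):
            if rid == clk.record_id:
                continue
            key = (clk.record_id, rid) if clk.record_id < rid else (rid, clk.record_id)
            pairs[key] = sim
    t_query = time.perf_counter() - t0
    logger.info(
        "deduplicate: n=%d threshold=%.3f -> %d pairs (build %.2fs, query %.2fs)",
        len(clks), threshold, len(pairs), t_build, t_query,
    )
    return _sorted_pairs(pairs)


def link(
    clks_a: Sequence[CLK],
    clks_b: Sequence[CLK],
    threshold: float,
    leaf_limit: int = 1,
    stats: dict | None = None,
) -> list[CandidatePair]:
    """All cross pairs (a from A, b from B) with Tanimoto >= threshold.

    The tree is built over A; every member of B is queried sequentially.
    """
    _check_unique_ids(clks_a)
    _check_unique_ids(clks_b)
    if clks_a and clks_b and clks_a[0].l != clks_b[0].l:
        raise DataError(
            f"CLK length mismatch between datasets: {clks_a[0].l} vs {clks_b[0].l}"
        )
    t0 = time.perf_counter()
    tree = build_tree(clks_a, leaf_limit=leaf_limit)
    t_build = time.perf_counter() - t0
    pairs: dict[tuple[str, str], float] = {}
    t0 = time.perf_counter()
    for clk in clks_b:
        for rid, sim in query_tree(tree, clk, threshold, stats=stats):
            pairs[(rid, clk.record_id)] = sim
    t_query = time.perf_counter() - t0
    logger.info(
        "link: |A|=%d |B|=%d threshold=%.3f -> %d pairs (build %.2fs, query %.2fs)",
        len(clks_a), len(clks_b), threshold, len(pairs), t_build, t_query,
    )
    return _sorted_pairs(pairs)


def external_block(
    records: Sequence[PersonRecord],
    rule: BlockingKey,
) -> dict[str, list[PersonRecord]]:
    """Partition records by blocking key; a disjoint cover of the input.

    Records whose key field is MISSING form their own block.
    """
    blocks: dict[str, list[PersonRecord]] = {}
    for rec in records:
        blocks.setdefault(rule.derive(rec), []).append(rec)
    if MISSING_BLOCK in blocks:
        logger.warning(
            "%d records have a MISSING %s blocking key; they are only compared "
            "among themselves (recall cost)",
            len(blocks[MISSING_BLOCK]), rule.field,
        )
    return blocks


def run_blocked_dedup(
    records: Sequence[PersonRecord],
    rule: BlockingKey,
    pset: ParameterSet,
    config: EncodingConfig,
    threshold: float,
    leaf_limit: int = 1,
    stats: dict | None = None,
) -> list[CandidatePair]:
    """Encode and de-duplicate each block independently; concatenate pair sets.

    Equals the unblocked output restricted to within-block pairs (blocking
    never adds pairs; true pairs split across blocks are lost).
    """
    blocks = external_block(records, rule)
    all_pairs: list[CandidatePair] = []
    for key, members in sorted(blocks.items(), key=lambda kv: kv[0]):
        t0 = time.perf_counter()
        clks = encode_dataset(members, pset, config)
        pairs = deduplicate(clks, threshold, leaf_limit=leaf_limit, stats=stats)
        logger.info(
            "block %s: %d records -> %d pairs in %.2fs",
            key, len(members), len(pairs), time.perf_counter() - t0,
        )
        all_pairs.extend(pairs)
    all_pairs.sort(key=lambda p: (-p.similarity, p.id_a, p.id_b))
    return all_pairs


def _sorted_pairs(pairs: dict) -> list[CandidatePair]:
    out = [CandidatePair(a, b, s) for (a, b), s in pairs.items()]
    out.sort(key=lambda p: (-p.similarity, p.id_a, p.id_b))
    return out


def write_pairs(pairs: Sequence[CandidatePair], path) -> None:
    """Write pairs as CSV: id_a,id_b,similarity (6 decimals), sorted."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "similarity"])
        for p in pairs:
            writer.writerow([p.id_a, p.id_b, f"{p.similarity:.6f}"])


def read_pairs(path) -> list[CandidatePair]:
    pairs: list[CandidatePair] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and header[:2] != ["id_a", "id_b"]:
            fh.seek(0)
            reader = csv.reader(fh)
        for row in reader:
            if not row:
                continue
            pairs.append(CandidatePair(row[0], row[1], float(row[2])))
    return pairs


def brute_force_pairs(
    clks: Sequence[CLK],
    threshold: float,
) -> list[CandidatePair]:
    """Reference O(n^2) de-duplication by direct Jaccard of every pair.

    Kept in the library as the ground-truth oracle for the tree-based path.
    """
    from .similarity import jaccard

    _check_unique_ids(clks)
    pairs: dict[tuple[str, str], float] = {}
    for i, a in enumerate(clks):
        for b in clks[i + 1 :]:
            sim = jaccard(a, b)
            if sim >= threshold:
                key = (a.record_id, b.record_id)
                if key[0] > key[1]:
                    key = (key[1], key[0])
                pairs[key] = sim
    return _sorted_pairs(pairs)
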