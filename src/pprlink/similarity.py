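"""Bit-vector similarity measures between CLKs.

Both measures treat the all-zero/all-zero case as 0 by convention (with a
warning) so records with fully missing identifiers flow through the pipeline
as non-matches instead of crashing it.
"""

from __future__ import annotations

import logging

import numpy as np

from .encoding import CLK
from .errors import DataError

logger = logging.getLogger(__name__)


def _check(a: CLK, b: CLK) -> None:
    if a.l != b.l or a.bits.size != b.bits.size:
        raise DataError(
            f"CLK length mismatch: {a.record_id!r} has l={a.l}, {b.record_id!r} has l={b.l}"
        )


def intersection_count(a: CLK, b: CLK) -> int:
    """|A ∩ B| over set-bit positions."""
    _check(a, b)
    return int(np.bitwise_count(a.bits & b.bits).sum())


def jaccard(a: CLK, b: CLK) -> float:
    """Jaccard/Tanimoto similarity |A∩B| / |A∪B| in [0, 1]."""
    _check(a, b)
    inter = int(np.bitwise_count(a.bits & b.bits).sum())
    union = a.popcount + b.popcount - inter
    if union == 0:
        logger.warning(
            "jaccard of two all-zero CLKs (%r, %r): 0 by convention",
            a.record_id, b.record_id,
        )
        return 0.0
    return inter / union


def dice(a: CLK, b: CLK) -> float:
    """Sørensen-Dice coefficient 2|A∩B| / (|A| + |B|) in [0, 1]."""
    _check(a, b)
    denom = a.popcount + b.popcount
    if denom == 0:
        logger.warning(
            "dice of two all-zero CLKs (%r, %r): 0 by convention",
            a.record_id, b.record_id,
        )
        return 0.0
    inter = int(np.bitwise_count(a.bits & b.bits).sum())
    return 2.0 * inter / denom
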