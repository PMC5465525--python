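"""Pairwise linkage-quality evaluation against a truth set.

Metrics are pairwise (over record pairs, not clusters): precision is the
proportion of found links that are correct, recall the proportion of correct
links that were found, and the F-measure their harmonic mean.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass
from typing import Sequence

from .encoding import CLK
from .engine import CandidatePair, deduplicate
from .errors import DataError
from .records import TruthSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualityReport:
    """Confusion counts and derived metrics for one threshold."""

    threshold: float
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f_measure: float

    @classmethod
    def from_counts(
        cls, threshold: float, tp: int, fp: int, fn: int
    ) -> "QualityReport":
        if tp + fp == 0:
            logger.warning("no pairs found at threshold %.3f; precision := 1", threshold)
            precision = 1.0
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            logger.warning("no true pairs at threshold %.3f; recall := 1", threshold)
            recall = 1.0
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f_measure = 0.0
        else:
            f_measure = 2 * precision * recall / (precision + recall)
        return cls(threshold, tp, fp, fn, precision, recall, f_measure)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def true_pairs(truth: TruthSet, ids: Sequence[str]) -> set[tuple[str, str]]:
    """All unordered pairs of distinct evaluated records sharing an entity."""
    by_entity: dict[str, list[str]] = {}
    for rid in ids:
        by_entity.setdefault(truth.entity_of(rid), []).append(rid)
    pairs: set[tuple[str, str]] = set()
    for members in by_entity.values():
        members.sort()
        pairs.update(itertools.combinations(members, 2))
    return pairs


def evaluate(
    found: Sequence[CandidatePair],
    truth: TruthSet,
    ids: Sequence[str],
    threshold: float = float("nan"),
) -> QualityReport:
    """Score candidate pairs against the truth set (pairwise confusion matrix)."""
    truth_pairs = true_pairs(truth, ids)
    found_set = set()
    for p in found:
        key = (p.id_a, p.id_b) if p.id_a < p.id_b else (p.id_b, p.id_a)
        if key[0] == key[1]:
            raise DataError(f"self pair in candidate list: {key[0]!r}")
        found_set.add(key)
    tp = len(found_set & truth_pairs)
    fp = len(found_set - truth_pairs)
    fn = len(truth_pairs - found_set)
    return QualityReport.from_counts(threshold, tp, fp, fn)


def threshold_sweep(
    clks: Sequence[CLK],
    truth: TruthSet,
    thresholds: Sequence[float],
    leaf_limit: int = 1,
) -> list[QualityReport]:
    """One QualityReport per threshold from a single most-permissive run.

    Valid because candidate-pair sets nest: the run at min(thresholds) is
    filtered upward for every other threshold.
    """
    if not thresholds:
        return []
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise DataError("thresholds must lie in (0, 1]")
    ids = [c.record_id for c in clks]
    base = deduplicate(clks, min(thresholds), leaf_limit=leaf_limit)
    reports = []
    for t in thresholds:
        at_t = [p for p in base if p.similarity >= t]
        reports.append(evaluate(at_t, truth, ids, threshold=t))
    return reports


def write_sweep_csv(reports: Sequence[QualityReport], path) -> None:
    """CSV of threshold,precision,recall,f_measure (plus counts) for plotting."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["threshold", "precision", "recall", "f_measure", "tp", "fp", "fn"]
        )
        for r in reports:
            writer.writerow(
                [
                    f"{r.threshold:.6g}",
                    f"{r.precision:.6f}",
                    f"{r.recall:.6f}",
                    f"{r.f_measure:.6f}",
                    r.true_positives,
                    r.false_positives,
                    r.false_negatives,
                ]
            )
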