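"""Caller evaluation statistics: recall/precision/F1 against a validated
truth set, exact-test precision comparisons between callers, and rank-based
operating-characteristic curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import fisher_exact


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero (the convention of printed result tables)."""
    scale = 10 ** digits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass
class EvalResult:
    tp: int
    total: int
    validated: int
    recall: float
    precision: float
    f1: float

    def rounded(self, digits: int = 2) -> tuple[float, float, float]:
        return tuple(round_half_up(v, digits) for v in (self.recall, self.precision, self.f1))


def confusion_metrics(tp: int, total: int, validated: int) -> EvalResult:
    """recall = tp/validated, precision = tp/total, F1 their harmonic mean.

    With an incomplete validated list the recall is unbiased while the
    precision is a lower bound. Zero denominators yield NaN.
    """
    if tp < 0 or total < tp or validated < tp:
        raise ValueError("require 0 <= tp <= min(total, validated)")
    if total == 0 or validated == 0:
        return EvalResult(tp, total, validated, math.nan, math.nan, math.nan)
    recall = tp / validated
    precision = tp / total
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvalResult(tp, total, validated, recall, precision, f1)


def precision_fisher(tp1: int, total1: int, tp2: int, total2: int) -> float:
    """Two-sided exact test comparing two callers' precision.

    The 2x2 table has columns (true positives, total discovered candidates)
    and one row per caller; the two-sided p-value sums hypergeometric
    probabilities no larger than the observed table's.
    """
    if not (0 <= tp1 <= total1 and 0 <= tp2 <= total2):
        raise ValueError("require 0 <= tp <= total for both callers")
    table = [[tp1, total1], [tp2, total2]]
    if sum(table[0]) == 0 or sum(table[1]) == 0 or tp1 + tp2 == 0:
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def oc_curve(
    candidates: list[tuple[tuple[str, str], float]],
    truth: set[tuple[str, str]],
    ordered: bool = False,
) -> list[tuple[int, int]]:
    """Cumulative true positives per rank.

    ``candidates`` are (gene pair, score); sorted by descending score with
    ties broken lexicographically. Truth matching is unordered by default.
    Each truth entry counts once, at its best-ranked hit.
    """
    truth_keys = (
        set(truth) if ordered else {frozenset(p) for p in truth}
    )
    ranked = sorted(candidates, key=lambda x: (-x[1], x[0]))
    found: set = set()
    curve = []
    for i, (pair, _) in enumerate(ranked, start=1):
        key = pair if ordered else frozenset(pair)
        if key in truth_keys:
            found.add(key)
        curve.append((i, len(found)))
    return curve


def max_score_aggregate(
    per_sample: list[list[tuple[tuple[str, str], float]]]
) -> list[tuple[tuple[str, str], float]]:
    """Multi-sample ranking input: each fusion at its maximum score across samples."""
    best: dict[tuple[str, str], float] = {}
    for sample in per_sample:
        for pair, score in sample:
            if score > best.get(pair, -math.inf):
                best[pair] = score
    return sorted(best.items(), key=lambda x: (-x[1], x[0]))
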