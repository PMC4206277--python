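"""Accuracy/coverage evaluation of ranked contact predictions.

Predictions are judged against the native contact map within a sequence-
separation range (medium: 12-23, long: >= 24) at a top fraction of L/10,
L/5 or L/2 predictions, where L is the chain length:

    Acc = TP / (TP + FP)        Cov = TP_frac / TP_total

TP_total counts all in-range native contacts; proteins are additionally
stratified by alignment depth relative to L.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import config
from .structio import ContactMap

__all__ = [
    "EvaluationRow",
    "in_range",
    "range_filter",
    "evaluate_predictions",
    "depth_stratum",
]


@dataclass
class EvaluationRow:
    """One (range, fraction) evaluation: counts and derived rates."""

    range_name: str
    divisor: int
    n_evaluated: int
    tp: int
    fp: int
    tp_total: int
    acc: float
    cov: float | None  # None when there are no in-range native contacts


def in_range(i: int, j: int, range_name: str) -> bool:
    sep = abs(j - i)
    if range_name == "medium":
        lo, hi = config.MEDIUM_RANGE
        return lo <= sep <= hi
    if range_name == "long":
        return sep >= config.LONG_RANGE_MIN
    if range_name == "all":
        return True
    raise ValueError(f"unknown range {range_name!r}")


def range_filter(
    pairs: list[tuple[int, int]] | list[tuple[int, int, float]],
    range_name: str,
) -> list:
    """Keep pairs within the requested sequence-separation window."""
    return [p for p in pairs if in_range(p[0], p[1], range_name)]


def evaluate_predictions(
    ranked: list[tuple[int, int, float]],
    native_cm: ContactMap,
    L: int,
    divisor: int = 5,
    range_name: str = "long",
) -> EvaluationRow:
    """Score the top max(1, L // divisor) in-range predictions."""
    n = max(1, L // divisor)
    top = range_filter(ranked, range_name)[:n]
    tp = sum(1 for i, j, *_ in top if (i, j) in native_cm)
    fp = len(top) - tp
    natives = range_filter(sorted(native_cm.pairs), range_name)
    tp_total = len(natives)
    acc = tp / (tp + fp) if (tp + fp) else 0.0
    cov = tp / tp_total if tp_total else None
    return EvaluationRow(
        range_name=range_name,
        divisor=divisor,
        n_evaluated=len(top),
        tp=tp,
        fp=fp,
        tp_total=tp_total,
        acc=acc,
        cov=cov,
    )


def depth_stratum(msa_depth: int, L: int) -> str:
    """Alignment-depth stratum: '(1,1L]', '(1L,5L]' or '>5L'."""
    if msa_depth < 1:
        raise ValueError("depth must be >= 1")
    if msa_depth <= L:
        return "(1,1L]"
    if msa_depth <= 5 * L:
        return "(1L,5L]"
    return ">5L"
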