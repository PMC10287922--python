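"""Base-pair-level scoring of predicted structures against references.

A predicted pair is a true positive iff it occurs exactly in the reference
(no one-position slippage credit by default). PPV = TP/(TP+FP) and
SEN = TP/(TP+FN); the default Matthews correlation coefficient is the
sqrt(PPV*SEN) form standard in RNA structure benchmarking, with the exact
contingency MCC (true negatives counted over all candidate pairs (i, j)
with j - i >= 4, i.e. a minimal hairpin loop of 3) available on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .types import pairs_from_dotbracket


@dataclass(frozen=True)
class PredictionMetrics:
    transcript_id: str
    TP: int
    FP: int
    FN: int
    PPV: float  # NaN when TP+FP == 0
    SEN: float  # NaN when TP+FN == 0
    MCC: float


def pair_sets(dotbracket: str) -> frozenset:
    """Canonical (i, j), i < j, 1-based pair set of a dot-bracket string."""
    return pairs_from_dotbracket(dotbracket)


def _with_slippage(pred: frozenset, ref: frozenset) -> int:
    """TP count crediting pairs within one position of a reference pair."""
    credited = 0
    used: set = set()
    for i, j in sorted(pred):
        for di, dj in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)):
            cand = (i + di, j + dj)
            if cand in ref and cand not in used:
                used.add(cand)
                credited += 1
                break
    return credited


def compare(
    pred_pairs: Iterable[tuple],
    ref_pairs: Iterable[tuple],
    length: int,
    transcript_id: str = "",
    exact_mcc: bool = False,
    slippage: bool = False,
) -> PredictionMetrics:
    """Score a predicted pair set against a reference pair set.

    Degenerate conventions: PPV is NaN for an empty prediction; SEN is NaN
    for an empty reference; MCC is 0 whenever either set is empty but not
    both, and 1 when both are empty (nothing to predict, nothing predicted).
    """
    pred, ref = frozenset(pred_pairs), frozenset(ref_pairs)
    if slippage:
        tp = _with_slippage(pred, ref)
        fp, fn = len(pred) - tp, len(ref) - tp
    else:
        tp = len(pred & ref)
        fp = len(pred - ref)
        fn = len(ref - pred)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    sen = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if exact_mcc:
        candidates = (length - 4) * (length - 3) // 2 if length >= 5 else 0
        tn = candidates - tp - fp - fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    else:
        if not pred and not ref:
            mcc = 1.0
        elif not pred or not ref:
            mcc = 0.0
        else:
            mcc = math.sqrt(ppv * sen)
    return PredictionMetrics(transcript_id, tp, fp, fn, ppv, sen, mcc)


def compare_dotbrackets(
    pred: str, ref: str, transcript_id: str = "", **kwargs
) -> PredictionMetrics:
    if len(pred) != len(ref):
        raise ValueError(
            f"prediction length {len(pred)} != reference length {len(ref)}"
        )
    return compare(
        pair_sets(pred), pair_sets(ref), len(ref), transcript_id, **kwargs
    )


def aggregate(metrics: Sequence[PredictionMetrics]) -> dict:
    """Unweighted NA-skipping means of PPV, SEN, MCC over transcripts."""
    if not metrics:
        raise ValueError("aggregate requires at least one transcript")

    def na_mean(values):
        vals = [v for v in values if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else float("nan")

    return {
        "n": len(metrics),
        "PPV": na_mean([m.PPV for m in metrics]),
        "SEN": na_mean([m.SEN for m in metrics]),
        "MCC": na_mean([m.MCC for m in metrics]),
    }


def write_metrics(path, metrics: Sequence[PredictionMetrics], summary: Optional[dict] = None) -> None:
    def fmt(v: float) -> str:
        return "NA" if math.isnan(v) else f"{v:.6g}"

    with open(path, "w") as fh:
        fh.write("transcript_id\tTP\tFP\tFN\tPPV\tSEN\tMCC\n")
        for m in metrics:
            fh.write(
                f"{m.transcript_id}\t{m.TP}\t{m.FP}\t{m.FN}\t"
                f"{fmt(m.PPV)}\t{fmt(m.SEN)}\t{fmt(m.MCC)}\n"
            )
        if summary is not None:
            fh.write(
                f"__mean__\tNA\tNA\tNA\t{fmt(summary['PPV'])}\t"
                f"{fmt(summary['SEN'])}\t{fmt(summary['MCC'])}\n"
            )
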