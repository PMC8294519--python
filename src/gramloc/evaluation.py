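"""Unknown-aware multi-class evaluation.

Each localization class is scored one-vs-rest from a labeled prediction
table.  Five metrics are derived per class:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    MCC         = (TP*TN - FP*FN) /
                  sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Undefined ratios (zero denominators) are reported as NaN, never 0.

Abstentions ("Unknown" predictions) are handled by an explicit policy:

``negative`` (default)
    Unknown counts as a negative prediction for every class, so a
    true-c protein predicted Unknown is an FN for c and a TN elsewhere.
``exclude``
    rows predicted Unknown are dropped from the confusion counts (their
    abstention rate is still reported separately as ``unknown_rate``).

A multi-label truth (e.g. a cell-wall/membrane protein) makes the protein
positive for each of its classes, and a multi-label prediction counts as
positive for each predicted class.

Overall metrics are the class-size-weighted arithmetic means; classes
whose metric is undefined are excluded from that metric's average with
renormalized weights.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import METRICS_COLUMNS, TAGS, UNKNOWN, parse_tags

POLICIES = ("negative", "exclude")

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    """The five per-class metrics plus the abstention rate."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    unknown_rate: float = float("nan")


def _tag_sets(table: pd.DataFrame) -> tuple[list[frozenset], list[frozenset]]:
    truths, preds = [], []
    for t, p in zip(table["true_tags"], table["predicted_tags"]):
        ts = t if isinstance(t, frozenset) else parse_tags(t)
        ps = p if isinstance(p, frozenset) else parse_tags(p)
        if not ts:
            raise InputError("row without true tags cannot be evaluated")
        if not ps:
            raise InputError("row without predicted tags cannot be evaluated")
        truths.append(ts)
        preds.append(ps)
    return truths, preds


def confusion_all(
    table: pd.DataFrame, policy: str = "negative"
) -> dict[str, ConfusionCounts]:
    """One-vs-rest confusion counts for all five classes in one pass."""
    if policy not in POLICIES:
        raise InputError(f"unknown policy {policy!r}; allowed: {POLICIES}")
    fast = _confusion_all_fast(table, policy)
    if fast is not None:
        return fast
    truths, preds = _tag_sets(table)
    counts = {c: [0, 0, 0, 0] for c in TAGS}  # tp, fp, tn, fn
    for ts, ps in zip(truths, preds):
        if policy == "exclude" and ps == {UNKNOWN}:
            continue
        for c in TAGS:
            pos_true = c in ts
            pos_pred = c in ps  # Unknown is never a class, hence negative
            if pos_true and pos_pred:
                counts[c][0] += 1
            elif pos_pred:
                counts[c][1] += 1
            elif pos_true:
                counts[c][3] += 1
            else:
                counts[c][2] += 1
    return {c: ConfusionCounts(*counts[c]) for c in TAGS}


def _confusion_all_fast(
    table: pd.DataFrame, policy: str
) -> dict[str, ConfusionCounts] | None:
    """Vectorized path for single-tag string tables (the common case).

    Equivalent to the row loop; the equivalence is pinned by tests.
    """
    t = table["true_tags"]
    p = table["predicted_tags"]
    is_str = lambda v: isinstance(v, str)  # noqa: E731 - includes numpy str_
    if not (t.map(is_str).all() and p.map(is_str).all()):
        return None
    vocab = set(TAGS) | {UNKNOWN}
    if not (t.isin(vocab).all() and p.isin(vocab).all()):
        return None  # multi-tag cells: fall back to the row loop
    tv = t.to_numpy()
    pv = p.to_numpy()
    if policy == "exclude":
        keep = pv != UNKNOWN
        tv, pv = tv[keep], pv[keep]
    out = {}
    for c in TAGS:
        pos_true = tv == c
        pos_pred = pv == c
        tp = int(np.sum(pos_true & pos_pred))
        fp = int(np.sum(~pos_true & pos_pred))
        fn = int(np.sum(pos_true & ~pos_pred))
        tn = int(np.sum(~pos_true & ~pos_pred))
        out[c] = ConfusionCounts(tp, fp, tn, fn)
    return out


def confusion(
    table: pd.DataFrame, cls: str, policy: str = "negative"
) -> ConfusionCounts:
    """One-vs-rest confusion counts for one class."""
    if cls not in TAGS:
        raise InputError(f"unknown class {cls!r}; classes: {TAGS}")
    return confusion_all(table, policy)[cls]


def _ratio(num: float, den: float) -> float:
    return num / den if den else float("nan")


def metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Exact evaluation of the five metric formulas."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else float("nan")
    return ClassMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        accuracy=_ratio(tp + tn, counts.total),
        mcc=mcc,
    )


def overall(
    per_class: Mapping[str, ClassMetrics], sizes: Mapping[str, int]
) -> ClassMetrics:
    """Class-size-weighted average of each metric.

    Classes with an undefined (NaN) metric are excluded from that metric's
    average and the remaining weights renormalized.
    """
    if not any(sizes.get(c, 0) > 0 for c in per_class):
        raise InputError("overall metrics need at least one non-empty class")
    values = {}
    for name in METRIC_NAMES + ("unknown_rate",):
        num = den = 0.0
        for c, m in per_class.items():
            w = sizes.get(c, 0)
            v = getattr(m, name)
            if w > 0 and not math.isnan(v):
                num += w * v
                den += w
        values[name] = num / den if den else float("nan")
    return ClassMetrics(**values)


def evaluate_table(table: pd.DataFrame, policy: str = "negative") -> pd.DataFrame:
    """Full evaluation of a labeled prediction table.

    Returns the metrics table: one row per class plus an ``overall`` row,
    with class sizes (``n``, number of proteins whose truth contains the
    class) and per-class abstention rates.
    """
    truths, preds = _tag_sets(table)
    counts = confusion_all(table, policy)
    sizes = {c: sum(c in ts for ts in truths) for c in TAGS}
    per_class = {}
    for c in TAGS:
        m = metrics(counts[c])
        members = [ps for ts, ps in zip(truths, preds) if c in ts]
        unk = (
            sum(ps == {UNKNOWN} for ps in members) / len(members)
            if members
            else float("nan")
        )
        per_class[c] = ClassMetrics(
            m.sensitivity, m.specificity, m.precision, m.accuracy, m.mcc, unk
        )
    summary = overall(per_class, sizes)
    rows = []
    for c in TAGS:
        m = per_class[c]
        rows.append(
            {
                "class": c,
                "n": sizes[c],
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "accuracy": m.accuracy,
                "mcc": m.mcc,
                "unknown_rate": m.unknown_rate,
            }
        )
    rows.append(
        {
            "class": "overall",
            "n": len(table),
            "sensitivity": summary.sensitivity,
            "specificity": summary.specificity,
            "precision": summary.precision,
            "accuracy": summary.accuracy,
            "mcc": summary.mcc,
            "unknown_rate": summary.unknown_rate,
        }
    )
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
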