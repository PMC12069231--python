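"""Ground-truth scoring of feature grouping by pairwise counting.

A grouping assignment is compared with a ground truth that maps every
feature to the compound it derives from (or to a background token for
features from no known compound).  Over every unordered pair of evaluated
features:

* predicted-together — both features carry the same group index;
* truly-together — both derive from the same non-background compound.

This yields the standard pair-counting confusion matrix for clusterings,
from which FDR = FP / (FP + TP) and TPR = TP / (TP + FN) follow.
Unassigned features count as singletons, so leaving a true satellite
ungrouped costs a false negative; background-background pairs that are
kept apart count as true negatives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

from .core import ValidationError

__all__ = ["BACKGROUND", "GroundTruth", "ConfusionCounts", "pairwise_confusion", "fdr_tpr"]

#: Token marking features that derive from no known compound.
BACKGROUND = "background"


@dataclass
class GroundTruth:
    """feature id → compound identifier; :data:`BACKGROUND` marks noise features."""

    compound_of: dict[str, str]

    def is_background(self, feature_id: str) -> bool:
        return self.compound_of[feature_id] == BACKGROUND


@dataclass(frozen=True)
class ConfusionCounts:
    """Pairwise confusion counts; tp+fp+fn+tn = C(n, 2) over n features."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _c2(k: int) -> int:
    return k * (k - 1) // 2


def pairwise_confusion(
    assignment: Mapping[str, Optional[int]],
    truth: GroundTruth,
) -> ConfusionCounts:
    """Pairwise confusion matrix of a grouping against ground truth.

    ``assignment`` must cover the evaluated feature set, with ``None`` for
    unassigned (singleton) features; every feature must appear in the
    truth.  Counts are accumulated over all C(n, 2) unordered pairs using
    group-size contingency sums, which equals the exhaustive double loop.
    """
    missing = sorted(f for f in assignment if f not in truth.compound_of)
    if missing:
        raise ValidationError(f"features missing from ground truth: {missing[:20]}")

    n = len(assignment)
    total = _c2(n)
    compounds = Counter(
        truth.compound_of[f] for f in assignment if not truth.is_background(f)
    )
    true_together = sum(_c2(k) for k in compounds.values())

    groups: dict[int, list[str]] = {}
    for fid, idx in assignment.items():
        if idx is not None:
            groups.setdefault(idx, []).append(fid)
    pred_together = sum(_c2(len(m)) for m in groups.values())

    tp = 0
    for members in groups.values():
        within = Counter(
            truth.compound_of[f] for f in members if not truth.is_background(f)
        )
        tp += sum(_c2(k) for k in within.values())

    fp = pred_together - tp
    fn = true_together - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def fdr_tpr(cm: ConfusionCounts) -> tuple[float, Optional[float]]:
    """(FDR, TPR) from pairwise counts.

    FDR = FP / (FP + TP), defined as 0.0 when nothing was predicted
    together.  TPR = TP / (TP + FN); ``None`` when there are no true pairs
    (empty positive class).
    """
    fdr = 0.0 if (cm.fp + cm.tp) == 0 else cm.fp / (cm.fp + cm.tp)
    tpr = None if (cm.tp + cm.fn) == 0 else cm.tp / (cm.tp + cm.fn)
    return fdr, tpr
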