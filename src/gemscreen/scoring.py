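"""Confusion matrices and the Matthews Correlation Coefficient.

The MCC summarises binary growth/no-growth agreement between model
predictions and a reference annotation:

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

It ranges from −1 (predictions exactly opposite the reference) to +1
(perfect agreement) and makes no assumption about class frequencies.
When any factor of the denominator is zero the MCC is undefined; this
module adopts the common convention MCC = 0 in that case and logs the
event.

**Polarity.** For single-gene screens the POSITIVE class is
*non-essential* (viable): a true positive is a gene the model predicts
to grow without and that is annotated as not essential.  A gene
correctly predicted essential is therefore a true negative.

Counts are combined in exact integer arithmetic up to the final square
root, so genome-scale products cannot drift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

__all__ = [
    "ConfusionMatrix",
    "mcc",
    "overall_mcc",
    "build_confusion_single",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0
    #: Double-knockout screens only: reference pairs rejected because one
    #: of the genes is (wrongly) predicted individually essential.  Not
    #: part of the MCC.
    other_errors: int = 0
    #: Reference pairs/genes outside the model's gene set.
    out_of_scope: int = 0
    #: Context: model / medium / biomass / reference-list labels.
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN", "other_errors", "out_of_scope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_scored(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            TP=self.TP + other.TP,
            TN=self.TN + other.TN,
            FP=self.FP + other.FP,
            FN=self.FN + other.FN,
            other_errors=self.other_errors + other.other_errors,
            out_of_scope=self.out_of_scope + other.out_of_scope,
        )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews Correlation Coefficient of one confusion matrix.

    Zero-denominator convention: returns 0.0 (and logs) when any of the
    four marginal sums is zero, where the coefficient is undefined.
    """
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        logger.info("MCC undefined (zero marginal) for %s; returning 0", cm.labels)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def overall_mcc(cms: list[ConfusionMatrix]) -> float:
    """Pooled MCC across conditions.

    Computed on the element-wise sum of the matrices — NOT the mean of
    per-condition MCCs, which is a different (and generally unequal)
    number.
    """
    if not cms:
        raise ValueError("overall_mcc requires at least one confusion matrix")
    total = cms[0]
    for cm in cms[1:]:
        total = total + cm
    return mcc(total)


def build_confusion_single(
    screen,
    essential_reference: set[str],
    universe_policy: str = "intersect",
    reference_universe: set[str] | None = None,
    labels: dict[str, str] | None = None,
) -> ConfusionMatrix:
    """Score a single-deletion screen against a reference essential list.

    Positive class = viable (non-essential), per the screen polarity
    documented in the module docstring.

    ``universe_policy``:

    * ``"intersect"`` — score only genes the model contains AND the
      reference screen evaluated (``reference_universe``; defaults to the
      model's screened genes).  This mirrors benchmarking against a
      knockout-collection screen that covered a fixed gene panel.
    * ``"whole_genome"`` — score every gene the screen evaluated; genes
      not named by the reference list are annotated viable.  Suits
      database-derived whole-genome essential lists.

    Reference-essential genes outside the model are tallied in
    ``out_of_scope`` and excluded from the four counts.
    """
    predicted: dict[str, bool] = {
        rec.gene: rec.essential for rec in screen.records if rec.in_model
    }
    if universe_policy == "intersect":
        universe = set(predicted)
        if reference_universe is not None:
            universe &= set(reference_universe)
    elif universe_policy == "whole_genome":
        universe = set(predicted)
    else:
        raise ValueError(f"unknown universe_policy {universe_policy!r}")
    if not universe:
        raise ValueError("empty scoring universe")

    cm = ConfusionMatrix(labels=labels or {})
    for gene in universe:
        pred_viable = not predicted[gene]
        annot_viable = gene not in essential_reference
        if pred_viable and annot_viable:
            cm.TP += 1
        elif (not pred_viable) and (not annot_viable):
            cm.TN += 1
        elif pred_viable and not annot_viable:
            cm.FP += 1
        else:
            cm.FN += 1
    cm.out_of_scope = len(set(essential_reference) - set(predicted))
    return cm
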