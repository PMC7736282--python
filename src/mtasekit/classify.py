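"""Activity / stability / foldedness classification of enzyme variants.

Variants are grouped by three experimental axes:

* foldedness — the unfolding red-shift of the tryptophan barycentric mean;
  folded variants of the reference enzyme shift by ≈7.8 nm, a shift below
  6 nm indicates a misfolded starting state;
* stability — T_m1 more than 5 °C below the wild type is a stability
  penalty;
* activity — below 60 % of wild-type activity is an activity penalty, and
  activity indistinguishable from the knock-out control is "inactive".

Misfolded dominates every other label: a misfolded variant's loss of
activity cannot be attributed to active-site effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from mtasekit.epistasis import VariantRecord


class FitnessClass(str, Enum):
    WT_LIKE = "wt_like"
    ACTIVITY_PENALTY = "activity_penalty"
    STABILITY_PENALTY = "stability_penalty"
    ACTIVITY_AND_STABILITY_PENALTY = "activity_and_stability_penalty"
    INACTIVE_STABLE = "inactive_stable"
    INACTIVE_UNSTABLE = "inactive_unstable"
    MISFOLDED = "misfolded"


@dataclass
class ClassificationThresholds:
    """Decision thresholds; defaults are the reference study's cut-offs."""

    misfolded_red_shift: float = 6.0   # nm; red-shift strictly below → misfolded
    stability_penalty: float = 5.0     # °C below WT Tm1, strictly more → unstable
    activity_penalty: float = 0.60     # fraction of WT, strictly below → penalised

    def __post_init__(self) -> None:
        if min(self.misfolded_red_shift, self.stability_penalty,
               self.activity_penalty) <= 0:
            raise ValueError("thresholds must be positive")


class UnclassifiableError(ValueError):
    """A required measurement is missing; raised instead of a silent default."""


def classify(
    variant: VariantRecord,
    wt: VariantRecord,
    thresholds: ClassificationThresholds | None = None,
) -> FitnessClass:
    """Assign a variant exactly one fitness class.

    Decision order: (1) red-shift below the misfolded threshold → misfolded,
    regardless of the other axes; (2) below-detection activity →
    inactive_stable or inactive_unstable by the T_m1 criterion; (3) activity
    and/or stability strictly past their thresholds → the corresponding
    penalty class(es); otherwise wt_like.  All comparisons are strict
    inequalities.
    """
    th = thresholds or ClassificationThresholds()
    for label, rec in (("variant", variant), ("WT", wt)):
        if rec.red_shift is None and label == "variant":
            raise UnclassifiableError(f"{variant.name}: red_shift missing")
        if rec.tm1 is None:
            raise UnclassifiableError(f"{variant.name}: {label} Tm1 missing")
    if variant.activity is None and not variant.below_detection:
        raise UnclassifiableError(f"{variant.name}: activity missing")
    if wt.activity is None:
        raise UnclassifiableError("WT activity missing")

    unstable = (wt.tm1 - variant.tm1) > th.stability_penalty

    if variant.red_shift < th.misfolded_red_shift:
        return FitnessClass.MISFOLDED
    if variant.below_detection:
        return (
            FitnessClass.INACTIVE_UNSTABLE if unstable else FitnessClass.INACTIVE_STABLE
        )
    low_activity = variant.activity < th.activity_penalty * wt.activity
    if low_activity and unstable:
        return FitnessClass.ACTIVITY_AND_STABILITY_PENALTY
    if low_activity:
        return FitnessClass.ACTIVITY_PENALTY
    if unstable:
        return FitnessClass.STABILITY_PENALTY
    return FitnessClass.WT_LIKE
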