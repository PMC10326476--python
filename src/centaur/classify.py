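"""Tau positivity, topographic subtyping, and diagnostic metrics.

Positivity is CTRz strictly above a threshold (default 2) in a region of
interest — the meta-temporal region is the headline discriminator of AD
Ab+ from CU Ab-. Topographic subtypes form an exhaustive 2x2 partition
on mesial-temporal vs meta-temporal CTRz at the same threshold:

================  ===========  ==========
subtype           mesial > t   meta > t
================  ===========  ==========
tau_negative      no           no
limbic_predominant yes         no
hippocampal_sparing no         yes
typical           yes          yes
================  ===========  ==========

A value exactly at the threshold counts as negative everywhere (the
boundary is measure-zero; assigning it to negative keeps the rules
deterministic and matches "higher than" phrasing).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

DEFAULT_THRESHOLD = 2.0


class SubtypeLabel(str, Enum):
    """Topographic tau subtype."""

    TAU_NEGATIVE = "tau_negative"
    LIMBIC_PREDOMINANT = "limbic_predominant"
    HIPPOCAMPAL_SPARING = "hippocampal_sparing"
    TYPICAL = "typical"


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion counts and the derived proportions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def positivity(ctrz: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff CTRz is strictly above the threshold."""
    return ctrz > threshold


def subtype(mtl_ctrz: float, meta_ctrz: float,
            threshold: float = DEFAULT_THRESHOLD) -> SubtypeLabel:
    """Assign the topographic subtype from mesial- and meta-temporal CTRz."""
    mtl_pos = positivity(mtl_ctrz, threshold)
    meta_pos = positivity(meta_ctrz, threshold)
    if mtl_pos and meta_pos:
        return SubtypeLabel.TYPICAL
    if mtl_pos:
        return SubtypeLabel.LIMBIC_PREDOMINANT
    if meta_pos:
        return SubtypeLabel.HIPPOCAMPAL_SPARING
    return SubtypeLabel.TAU_NEGATIVE


def diagnostic_metrics(predicted: Sequence[bool], truth: Sequence[bool]) -> DiagnosticMetrics:
    """Confusion counts, accuracy, sensitivity and specificity.

    ``truth`` must contain at least one positive and one negative,
    otherwise sensitivity or specificity is undefined.
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError("predicted and truth must be equal-length nonempty 1-D sequences")
    if not true.any():
        raise ValueError("sensitivity undefined: truth has no positives")
    if true.all():
        raise ValueError("specificity undefined: truth has no negatives")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    tn = int((~pred & ~true).sum())
    fn = int((~pred & true).sum())
    return DiagnosticMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def prevalence(ctrz_values: Sequence[float], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of values strictly above the threshold (ties count negative)."""
    x = np.asarray(ctrz_values, dtype=float)
    if x.size == 0:
        raise ValueError("prevalence of an empty list is undefined")
    return float((x > threshold).mean())
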