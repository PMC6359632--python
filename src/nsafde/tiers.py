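"""Abundance tiers and the tier-specific significance thresholds.

Spectral-count abundance is stratified into four tiers, and each tier gets
its own p-value ceiling and NSAF-ratio cutoffs.  The rationale: spectral
counting is noisiest for scarce proteins, so low-abundance calls must clear
a stricter p-value, while abundant proteins — whose counts are stable — are
allowed a smaller fold change.

Tier boundaries on the mean spectral count (SC) are half-open:

=========  =================  ======  ========  ========
tier       mean SC            p_max   OE ratio  UE ratio
=========  =================  ======  ========  ========
very_low   0 < SC < 8         0.001   >= 2.5    <= 0.4
low        8 <= SC < 20       0.01    >= 2.5    <= 0.4
medium     20 <= SC < 80      0.05    >= 2.0    <= 0.5
high       SC >= 80           0.05    >= 1.5    <= 2/3
=========  =================  ======  ========  ========

The underexpression cutoff is always the reciprocal of the overexpression
cutoff (the high tier uses exactly 2/3, not a rounded 0.67), which makes
calls symmetric under swapping the two groups: every ratio r maps to 1/r and
every overexpressed call to underexpressed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["Tier", "TierCutoffs", "TierThresholds", "classify_abundance", "governing_tier"]


class Tier(enum.IntEnum):
    """Abundance tier; integer order makes ``max()`` the governing-tier rule."""

    ABSENT = 0
    VERY_LOW = 1
    LOW = 2
    MEDIUM = 3
    HIGH = 4

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Tier":
        try:
            return _FROM_LABEL[label.strip()]
        except KeyError:
            raise ValueError(f"unknown tier label {label!r}") from None


_LABELS = {
    Tier.ABSENT: "-",
    Tier.VERY_LOW: "VL",
    Tier.LOW: "L",
    Tier.MEDIUM: "M",
    Tier.HIGH: "H",
}
_FROM_LABEL = {v: k for k, v in _LABELS.items()}


@dataclass(frozen=True)
class TierCutoffs:
    """Significance cutoffs for one tier."""

    p_max: float
    oe_ratio_min: float
    ue_ratio_max: float


@dataclass(frozen=True)
class TierThresholds:
    """Per-tier cutoffs; defaults implement the abundance-stratified scheme."""

    cutoffs: Mapping[Tier, TierCutoffs] = field(
        default_factory=lambda: {
            Tier.VERY_LOW: TierCutoffs(0.001, 2.5, 1 / 2.5),
            Tier.LOW: TierCutoffs(0.01, 2.5, 1 / 2.5),
            Tier.MEDIUM: TierCutoffs(0.05, 2.0, 1 / 2.0),
            Tier.HIGH: TierCutoffs(0.05, 1.5, 2 / 3),
        }
    )

    def __getitem__(self, tier: Tier) -> TierCutoffs:
        return self.cutoffs[tier]


DEFAULT_THRESHOLDS = TierThresholds()


def classify_abundance(mean_sc: float) -> Tier:
    """Assign the abundance tier for a mean spectral count.

    Boundaries are half-open with the break points at 8, 20 and 80; a mean
    count of exactly 80 is high.  Zero means absent.
    """
    if mean_sc < 0:
        raise ValueError(f"negative mean spectral count {mean_sc}")
    if mean_sc == 0:
        return Tier.ABSENT
    if mean_sc < 8:
        return Tier.VERY_LOW
    if mean_sc < 20:
        return Tier.LOW
    if mean_sc < 80:
        return Tier.MEDIUM
    return Tier.HIGH


def governing_tier(tier_a: Tier, tier_b: Tier) -> Tier:
    """The tier whose cutoffs govern a two-group comparison.

    When the two groups fall in different tiers the *higher* tier governs.
    Choosing max keeps the rule symmetric in the two groups and lets a
    protein abundant in either group be judged by the cutoffs its counts can
    statistically support.
    """
    if tier_a is Tier.ABSENT or tier_b is Tier.ABSENT:
        raise ValueError("governing_tier is undefined for absent proteins; "
                         "presence/absence is resolved before tiering")
    return max(tier_a, tier_b)
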