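"""Pixel-count morphometry: the six relative lesion-area parameters.

All ratios are fractions in [0, 1] except ``dp_ra2``, which relates digital
lesions to the (disjoint) metatarsal pad and may in principle exceed 1.
Percentage formatting belongs to the report layer, never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from skimage.measure import label

from .segment import FootMasks

__all__ = ["AreaReport", "DegenerateAreaError", "measure", "per_segment_fractions"]

#: Column order used by the CSV report layer.
RATIO_COLUMNS = ("standard", "fp_ra1", "dp_ra1", "dp_ra2", "full", "rel_met")


class DegenerateAreaError(ValueError):
    """A reference area (RA1, RA2 or a segment) has zero pixels."""


@dataclass(frozen=True)
class AreaReport:
    """Pixel counts and relative-area parameters for one foot.

    standard = lesion-on-pad / pad (RA2); fp_ra1 = lesion-on-pad / foot (RA1);
    dp_ra1 = digital lesions / foot; dp_ra2 = digital lesions / pad;
    full = all lesions / foot; rel_met = pad / foot.
    """

    px_foot: int
    px_met: int
    px_lesion_met: int
    px_lesion_dig: int
    standard: float
    fp_ra1: float
    dp_ra1: float
    dp_ra2: float
    full: float
    rel_met: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "px_foot": self.px_foot,
            "px_met": self.px_met,
            "px_lesion_met": self.px_lesion_met,
            "px_lesion_dig": self.px_lesion_dig,
            "standard": self.standard,
            "fp_ra1": self.fp_ra1,
            "dp_ra1": self.dp_ra1,
            "dp_ra2": self.dp_ra2,
            "full": self.full,
            "rel_met": self.rel_met,
        }


def _attribute_lesions(lesion, met, digits):
    """Attribute each connected lesion's pixels to pad vs. digits.

    When the pad/digit boundary cuts through a discoloration and one side's
    share is a mere boundary spill (at most 20 px), the whole lesion is
    counted on the majority side — a segmentation boundary a few pixels
    off must not turn an intact pad into a scored one.  Lesions that
    straddle the boundary substantially on both sides are split by plain
    intersection, which also bounds the attribution error of a boundary
    estimate to a few tens of pixels.  The pad count is finally capped at
    the pad area (a pad alteration cannot exceed its reference).
    """
    lab, n = label(lesion, return_num=True)
    px_met = px_dig = 0
    spill_tol = 20
    for i in range(1, n + 1):
        comp = lab == i
        in_met = int((comp & met).sum())
        in_dig = int((comp & digits).sum())
        total = in_met + in_dig
        if min(in_met, in_dig) <= spill_tol:
            if in_met >= in_dig:
                px_met += total
            else:
                px_dig += total
        else:
            px_met += in_met
            px_dig += in_dig
    return px_met, min(px_dig, int(digits.sum()))


def measure(masks: FootMasks) -> AreaReport:
    """Count pixels and form the six relative-area parameters.

    ``full = fp_ra1 + dp_ra1`` holds exactly (identical denominator).
    """
    foot = masks.foot_mask.astype(bool)
    met = masks.metatarsal_mask.astype(bool)
    lesion = masks.lesion_mask.astype(bool)
    px_foot = int(foot.sum())
    px_met = int(met.sum())
    if px_foot == 0 or px_met == 0:
        raise DegenerateAreaError("degenerate reference area (RA1 or RA2 empty)")
    digit_union = np.zeros_like(foot)
    for dm in masks.digit_masks.values():
        digit_union |= dm.astype(bool)
    px_lesion_met, px_lesion_dig = _attribute_lesions(lesion, met, digit_union)
    px_lesion_met = min(px_lesion_met, px_met)
    return AreaReport(
        px_foot=px_foot,
        px_met=px_met,
        px_lesion_met=px_lesion_met,
        px_lesion_dig=px_lesion_dig,
        standard=px_lesion_met / px_met,
        fp_ra1=px_lesion_met / px_foot,
        dp_ra1=px_lesion_dig / px_foot,
        dp_ra2=px_lesion_dig / px_met,
        full=px_lesion_met / px_foot + px_lesion_dig / px_foot,
        rel_met=px_met / px_foot,
    )


def per_segment_fractions(masks: FootMasks) -> Dict[int, List[float]]:
    """Lesion fraction |lesion ∩ segment| / |segment| per digit and segment."""
    lesion = masks.lesion_mask.astype(bool)
    out: Dict[int, List[float]] = {}
    for d, segs in masks.segment_masks.items():
        fracs = []
        for s in segs:
            s = s.astype(bool)
            n = int(s.sum())
            if n == 0:
                raise DegenerateAreaError(f"degenerate reference area: digit {d} segment empty")
            fracs.append(int((lesion & s).sum()) / n)
        out[d] = fracs
    return out
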