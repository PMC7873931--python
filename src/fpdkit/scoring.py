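"""Categorical scoring rubrics for footpad dermatitis (FPD) in turkeys.

The standard European five-point FPD score grades the relative area of
brownish lesions on the metatarsal pad.  This module additionally implements
a five-point per-digit lesion score based on the lesion fraction of each
digit segment (phalanx pad), a three-point swelling grade that compares a
digit's area against the corresponding digit of the bird's unaffected
contralateral foot, the affected-digit count for digits 2-4, and a binomial
"any digit affected" flag suitable as an extension of the standard score.

All lesion fractions are dimensionless ratios in [0, 1] (a per-segment
fraction may exceed 1 when a lesion spills beyond the phalanx pad).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "ScoreRecord",
    "ScoringError",
    "NoReferenceError",
    "score_standard",
    "score_digit_lesion",
    "score_swelling",
    "assemble_record",
    "DIGITS",
    "PUNCTUAL_FRACTION",
    "SWELLING_THRESHOLDS",
]

#: Digits evaluated on a suspended foot (digit 1 is not visible in the
#: slaughter line and is never scored).
DIGITS = (2, 3, 4)

#: Default lesion fraction at or below which an alteration counts as
#: "small, punctual".  The rubric itself never quantifies "punctual";
#: this is a configurable operational choice.
PUNCTUAL_FRACTION = 0.05

#: Default (slight, distinct) area-ratio cut-offs of the swelling grade,
#: relative to the contralateral reference digit.
SWELLING_THRESHOLDS = (1.15, 1.35)


class ScoringError(ValueError):
    """Invalid input to a scoring rubric."""


class NoReferenceError(ScoringError):
    """No contralateral reference digit available; swelling grade withheld."""


@dataclass(frozen=True)
class ScoreRecord:
    """All categorical scores for a single foot.

    ``swelling_scores`` entries may be ``None`` when no reference foot was
    available; a withheld swelling grade is *missing*, never 0, and a digit
    with a missing swelling grade counts as affected only through its lesion
    score.
    """

    standard_score: int
    digit_lesion_scores: Mapping[int, int]
    swelling_scores: Mapping[int, Optional[int]] = field(
        default_factory=lambda: {d: 0 for d in DIGITS}
    )
    n_affected_digits: int = 0
    digit_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.standard_score <= 4:
            raise ScoringError(f"standard score {self.standard_score} outside 0..4")
        for d in DIGITS:
            if d not in self.digit_lesion_scores:
                raise ScoringError(f"missing lesion score for digit {d}")


def score_standard(ratio: float) -> int:
    """Grade the metatarsal-pad lesion fraction on the standard 0-4 scale.

    0: intact pad; 1: punctual alterations below 10 % of the pad;
    2: lesion up to and including 25 %; 3: above 25 % up to and including
    50 %; 4: more than 50 %.  The 10 % boundary belongs to score 2
    (score 1 is "<10 %", score 2 "≤25 %").
    """
    if not 0.0 <= ratio <= 1.0:
        raise ScoringError(f"standard lesion ratio {ratio!r} outside [0, 1]")
    if ratio == 0.0:
        return 0
    if ratio < 0.10:
        return 1
    if ratio <= 0.25:
        return 2
    if ratio <= 0.50:
        return 3
    return 4


def score_digit_lesion(
    segment_fractions: Sequence[float],
    has_hematoma: bool = False,
    punctual: float = PUNCTUAL_FRACTION,
) -> int:
    """Grade one digit's lesions from its per-segment lesion fractions.

    Each entry is |lesion ∩ segment| / |segment| for one phalanx pad of the
    digit; a value above 1 encodes a lesion larger than the phalanx pad
    itself.  Classification, with P = number of punctual segments
    (0 < f ≤ ``punctual``), M = number of intermediate segments
    (``punctual`` < f < 0.5) and L = number of large segments (f ≥ 0.5):

    * 4 — two or more large segments, or any fraction above 1;
    * 3 — exactly one large segment, or two or more intermediate segments;
    * 2 — exactly one intermediate segment, or punctual lesions on more
      than two segments;
    * 1 — punctual lesions on one or two segments, or a hematoma alone;
    * 0 — intact digit.

    The grade is non-decreasing under a pointwise increase of the fractions.
    """
    fr = [float(f) for f in segment_fractions]
    if not fr:
        raise ScoringError("no segment fractions supplied")
    if any(f < 0 for f in fr):
        raise ScoringError("negative segment lesion fraction")
    large = sum(f >= 0.5 for f in fr)
    mid = sum(punctual < f < 0.5 for f in fr)
    punct = sum(0.0 < f <= punctual for f in fr)
    if any(f > 1.0 for f in fr) or large >= 2:
        return 4
    if large == 1 or mid >= 2:
        return 3
    if mid == 1 or punct > 2:
        return 2
    if punct >= 1 or has_hematoma:
        return 1
    return 0


def score_swelling(
    digit_area: float,
    reference_area: Optional[float],
    thresholds: tuple[float, float] = SWELLING_THRESHOLDS,
) -> int:
    """Grade digit swelling against the contralateral reference digit.

    The ratio r = ``digit_area`` / ``reference_area`` maps to 0 (below the
    slight threshold), 1 (slight swelling) or 2 (distinct swelling).
    """
    if reference_area is None:
        raise NoReferenceError("no reference digit available; swelling withheld")
    if reference_area <= 0:
        raise ScoringError("degenerate reference area")
    slight, distinct = thresholds
    if not slight < distinct:
        raise ScoringError("swelling thresholds must be increasing")
    r = float(digit_area) / float(reference_area)
    if r >= distinct:
        return 2
    if r >= slight:
        return 1
    return 0


def assemble_record(
    standard_ratio: float,
    segment_fractions: Mapping[int, Sequence[float]],
    digit_areas: Optional[Mapping[int, float]] = None,
    reference_areas: Optional[Mapping[int, float]] = None,
    hematomas: Optional[Mapping[int, bool]] = None,
    punctual: float = PUNCTUAL_FRACTION,
    swelling_thresholds: tuple[float, float] = SWELLING_THRESHOLDS,
) -> ScoreRecord:
    """Build the full :class:`ScoreRecord` for one foot.

    ``segment_fractions`` maps digit (2-4) to that digit's per-segment lesion
    fractions.  Swelling is graded only for digits with both an own and a
    reference area; otherwise the grade is recorded as missing (``None``).
    A digit is *affected* when its lesion score or its swelling grade is
    positive; the binomial digit flag is set iff any digit is affected.
    """
    hematomas = hematomas or {}
    lesion = {
        d: score_digit_lesion(segment_fractions[d], hematomas.get(d, False), punctual)
        for d in DIGITS
    }
    swelling: dict[int, Optional[int]] = {}
    for d in DIGITS:
        area = (digit_areas or {}).get(d)
        ref = (reference_areas or {}).get(d)
        if area is None or ref is None:
            swelling[d] = None
        else:
            swelling[d] = score_swelling(area, ref, swelling_thresholds)
    n_affected = sum(
        1 for d in DIGITS if lesion[d] > 0 or (swelling[d] or 0) > 0
    )
    return ScoreRecord(
        standard_score=score_standard(standard_ratio),
        digit_lesion_scores=lesion,
        swelling_scores=swelling,
        n_affected_digits=n_affected,
        digit_flag=n_affected > 0,
    )
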