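"""Synthetic suspended-foot imagery with exact ground truth.

No public image set exists for slaughter-line footpad-dermatitis (FPD)
monitoring, so every downstream stage is exercised against generated feet:
a skin-colored foot on a dark background, built from a metatarsal pad
(superellipse) and digits 2-4, each a chain of elliptical phalanx pads
constricted at the joints.  Brownish lesions are grown pixel-by-pixel
inside a target region until a requested relative area is met (exact to
one pixel), so the generator's ground-truth ratios are exact by
construction.  Swelling is rendered as isotropic scaling of one digit's
segment chain; the unswollen, unlesioned contralateral foot of each pair
serves as the swelling reference, as in the visual rubric.

The module also provides cohorts stratified by target standard-score
level, noisy ordinal raters for reliability studies, and latent-normal
ordinal samples matching the model polychoric correlation assumes.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import morphometry, scoring
from .segment import FootMasks

__all__ = [
    "FootGenParams",
    "GroundTruth",
    "FootSample",
    "CohortSpec",
    "GenerationError",
    "generate_foot_pair",
    "generate_cohort",
    "simulate_raters",
    "simulate_ordinal_latent",
    "one_factor_corr",
    "LEVEL_RATIO_INTERVALS",
]


class GenerationError(ValueError):
    """Requested geometry or lesion load cannot be drawn."""


#: Standard-score level -> (low, high) interval of the metatarsal lesion
#: fraction.  Mirrors the scoring module's bins (0.10 and 0.25 belong to
#: score 2, 0.50 to score 3); level 4 is capped at 0.95 so the pad keeps a
#: visible healthy rim.
LEVEL_RATIO_INTERVALS: Dict[int, Tuple[float, float]] = {
    0: (0.0, 0.0),
    1: (0.0, 0.10),
    2: (0.10, 0.25),
    3: (0.25, 0.50),
    4: (0.50, 0.95),
}


@dataclass(frozen=True)
class FootGenParams:
    """Generative knobs for a single foot pair.

    Lesion fractions are target relative areas (lesion / reference region);
    ``digit_lesion_fracs`` maps digit number (2-4) to per-segment fractions,
    proximal to distal.  ``swelling_factors`` are area multipliers (>= 1)
    applied to the left foot's digits; the right foot is always rendered
    unswollen and unlesioned with the same base geometry.
    """

    image_size: Tuple[int, int] = (260, 200)
    background_level: int = 15
    skin_color: Tuple[int, int, int] = (210, 170, 135)
    lesion_color_range: Tuple[Tuple[int, int, int], Tuple[int, int, int]] = (
        (150, 100, 60),
        (80, 45, 25),
    )
    met_lesion_frac: float = 0.0
    digit_lesion_fracs: Mapping[int, Tuple[float, ...]] = field(
        default_factory=lambda: {2: (0.0, 0.0, 0.0), 3: (0.0, 0.0, 0.0), 4: (0.0, 0.0, 0.0)}
    )
    swelling_factors: Mapping[int, float] = field(
        default_factory=lambda: {2: 1.0, 3: 1.0, 4: 1.0}
    )
    n_segments_per_digit: int = 3
    noise_sigma: float = 2.0
    contrast_margin: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.met_lesion_frac <= 1.0:
            raise GenerationError("met_lesion_frac outside [0, 1]")
        for d, fr in self.digit_lesion_fracs.items():
            if len(fr) != self.n_segments_per_digit:
                raise GenerationError(
                    f"digit {d}: {len(fr)} fractions for "
                    f"{self.n_segments_per_digit} segments"
                )
            if any(not 0.0 <= f <= 1.0 for f in fr):
                raise GenerationError(f"digit {d} lesion fraction outside [0, 1]")
        for d, s in self.swelling_factors.items():
            if s < 1.0:
                raise GenerationError(f"digit {d} swelling factor {s} < 1")
        if self.n_segments_per_digit < 2:
            raise GenerationError("n_segments_per_digit must be >= 2")
        if self.background_level + self.contrast_margin > min(self.skin_color):
            raise GenerationError(
                "background not darker than skin by the contrast margin"
            )
        h, w = self.image_size
        if h < 120 or w < 100:
            raise GenerationError("image too small to draw requested geometry")


@dataclass
class GroundTruth:
    """Exact truth for one generated foot pair (left = evaluated foot)."""

    masks: FootMasks
    true_ratios: morphometry.AreaReport
    true_segment_fractions: Dict[int, List[float]]
    true_scores: scoring.ScoreRecord
    digit_areas: Dict[int, int]
    reference_digit_areas: Dict[int, int]
    params: FootGenParams
    latent_severity: Optional[float] = None


@dataclass
class FootSample:
    """One cohort entry: an evaluated foot, its pair reference, and truth."""

    foot_id: str
    pair_id: str
    flock: int
    side: str
    level: int
    image: np.ndarray
    reference_image: np.ndarray
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry


def _superellipse(shape, center, semi, exponent=2.5) -> np.ndarray:
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    return (
        np.abs((rr - center[0]) / semi[0]) ** exponent
        + np.abs((cc - center[1]) / semi[1]) ** exponent
    ) <= 1.0


def _ellipse(shape, center, semi) -> np.ndarray:
    return _superellipse(shape, center, semi, exponent=2.0)


def _pad_bottom_row(center, semi, exponent, dc) -> float:
    t = 1.0 - (abs(dc) / semi[1]) ** exponent
    if t <= 0:
        raise GenerationError("digit column outside the metatarsal pad")
    return center[0] + semi[0] * t ** (1.0 / exponent)


def _build_geometry(params: FootGenParams, swollen: bool):
    """Pad mask plus, per digit, the list of segment ellipse parameters."""
    h, w = params.image_size
    exponent = 2.5
    pad_center = (0.35 * h, 0.5 * w)
    pad_semi = (0.19 * h, 0.30 * w)
    pad = _superellipse((h, w), pad_center, pad_semi, exponent)

    seg_len = 0.062 * h
    seg_wid = 0.040 * w
    spacing = 1.7 * seg_len
    offsets = (-0.17 * w, 0.0, 0.17 * w)
    digits: Dict[int, List[Tuple[Tuple[float, float], Tuple[float, float]]]] = {}
    for digit, dc in zip(scoring.DIGITS, offsets):
        factor = params.swelling_factors.get(digit, 1.0) if swollen else 1.0
        s = math.sqrt(factor)
        col = pad_center[1] + dc
        attach = _pad_bottom_row(pad_center, pad_semi, exponent, dc)
        first = attach + s * seg_len - 0.4 * seg_len
        ellipses = []
        for k in range(params.n_segments_per_digit):
            cr = first + k * s * spacing
            ellipses.append(((cr, col), (s * seg_len, s * seg_wid)))
        bottom = ellipses[-1][0][0] + s * seg_len
        if bottom >= h - 1:
            raise GenerationError(
                "image too small to draw requested geometry (digit exceeds frame)"
            )
        digits[digit] = ellipses
    return pad, digits


def _digit_masks_from_geometry(shape, pad, digit_geoms):
    digit_masks: Dict[int, np.ndarray] = {}
    segment_masks: Dict[int, List[np.ndarray]] = {}
    for digit, ellipses in digit_geoms.items():
        union = np.zeros(shape, dtype=bool)
        for center, semi in ellipses:
            union |= _ellipse(shape, center, semi)
        union &= ~pad
        digit_masks[digit] = union
        centers = [c[0][0] for c in ellipses]
        cuts = [(a + b) / 2.0 for a, b in zip(centers[:-1], centers[1:])]
        bounds = [-np.inf] + cuts + [np.inf]
        segs = []
        rr = np.arange(shape[0])[:, None]
        for a, b in zip(bounds[:-1], bounds[1:]):
            band = (rr > a) & (rr <= b)
            segs.append(union & band)
        segment_masks[digit] = segs
    return digit_masks, segment_masks


# ---------------------------------------------------------------------------
# lesions


def _grow_blob(region: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Grow a connected random blob of exactly ``n_target`` pixels in ``region``.

    Randomized-Prim (Eden) growth from a random seed pixel: reachable
    neighbors enter a heap with random priorities, giving an irregular but
    compact blob with an exact pixel count.
    """
    avail = region.astype(bool)
    n_avail = int(avail.sum())
    if n_target > n_avail:
        raise GenerationError(
            f"requested lesion of {n_target} px exceeds region of {n_avail} px"
        )
    out = np.zeros_like(avail)
    if n_target == 0:
        return out
    idx = np.flatnonzero(avail)
    start = int(idx[rng.integers(len(idx))])
    h, w = avail.shape
    sr, sc = divmod(start, w)
    heap = [(0.0, sr, sc)]
    in_heap = np.zeros_like(avail)
    in_heap[sr, sc] = True
    grown = 0
    while grown < n_target and heap:
        _, r, c = heapq.heappop(heap)
        out[r, c] = True
        grown += 1
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and avail[nr, nc] and not in_heap[nr, nc]:
                in_heap[nr, nc] = True
                heapq.heappush(heap, (float(rng.random()), nr, nc))
    if grown < n_target:
        # region is disconnected; grow a further blob in what is left
        rest = _grow_blob(avail & ~out, n_target - grown, rng)
        out |= rest
    return out


def _lesion_pixels_for_fraction(region: np.ndarray, frac: float) -> int:
    n = int(region.sum())
    return int(round(frac * n))


# ---------------------------------------------------------------------------
# rendering


def _render(params, pad, digit_masks, lesion_blobs, rng) -> np.ndarray:
    h, w = params.image_size
    img = np.full((h, w, 3), params.background_level, dtype=float)
    foot = pad.copy()
    for dm in digit_masks.values():
        foot |= dm
    img[foot] = params.skin_color
    light, dark = (np.array(c, dtype=float) for c in params.lesion_color_range)
    for blob in lesion_blobs:
        t = rng.random()
        img[blob] = light + t * (dark - light)
    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# public operations


def generate_foot_pair(
    params: FootGenParams,
) -> Tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate an evaluated (left) foot, its reference foot, and ground truth.

    The left image carries the requested lesions and swellings; the right
    image shares the base geometry but is unswollen and unlesioned, serving
    as the swelling reference.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.image_size

    pad, digit_geoms = _build_geometry(params, swollen=True)
    digit_masks, segment_masks = _digit_masks_from_geometry(shape, pad, digit_geoms)
    ref_pad, ref_geoms = _build_geometry(params, swollen=False)
    ref_digit_masks, _ = _digit_masks_from_geometry(shape, ref_pad, ref_geoms)

    lesion_blobs: List[np.ndarray] = []
    n_met = _lesion_pixels_for_fraction(pad, params.met_lesion_frac)
    if n_met > 0:
        lesion_blobs.append(_grow_blob(pad, n_met, rng))
    for digit in scoring.DIGITS:
        fracs = params.digit_lesion_fracs.get(digit, ())
        for seg_mask, f in zip(segment_masks[digit], fracs):
            n = _lesion_pixels_for_fraction(seg_mask, f)
            if n > 0:
                lesion_blobs.append(_grow_blob(seg_mask, n, rng))

    lesion_mask = np.zeros(shape, dtype=bool)
    for b in lesion_blobs:
        lesion_mask |= b

    foot = pad.copy()
    for dm in digit_masks.values():
        foot |= dm
    masks = FootMasks(
        foot_mask=foot,
        metatarsal_mask=pad,
        digit_masks=digit_masks,
        segment_masks=segment_masks,
        lesion_mask=lesion_mask,
    )
    masks.validate()

    left = _render(params, pad, digit_masks, lesion_blobs, rng)
    right = _render(params, ref_pad, ref_digit_masks, [], rng)
    right = right[:, ::-1]  # mirror: contralateral foot

    true_ratios = morphometry.measure(masks)
    true_fracs = morphometry.per_segment_fractions(masks)
    digit_areas = {d: int(m.sum()) for d, m in digit_masks.items()}
    ref_areas = {d: int(m.sum()) for d, m in ref_digit_masks.items()}
    true_scores = scoring.assemble_record(
        true_ratios.standard, true_fracs, digit_areas, ref_areas
    )
    truth = GroundTruth(
        masks=masks,
        true_ratios=true_ratios,
        true_segment_fractions={d: list(v) for d, v in true_fracs.items()},
        true_scores=true_scores,
        digit_areas=digit_areas,
        reference_digit_areas=ref_areas,
        params=params,
    )
    return left, right, truth


# ---------------------------------------------------------------------------
# cohorts

#: Distribution of the number of affected digits (0-3) per standard level.
#: Emulates slaughter-line observations in which digital alterations are
#: common even on feet whose metatarsal pad is intact and barely separate
#: the upper levels.
AFFECTED_COUNT_TABLE: Dict[int, Tuple[float, ...]] = {
    0: (0.36, 0.34, 0.18, 0.12),
    1: (0.26, 0.40, 0.22, 0.12),
    2: (0.12, 0.23, 0.34, 0.31),
    3: (0.04, 0.19, 0.37, 0.40),
    4: (0.11, 0.20, 0.31, 0.38),
}

#: Lesion grade (0-4) of an affected digit, per standard level: grade 1
#: dominates at every level, with a mild shift toward higher grades.
LESION_GRADE_TABLE: Dict[int, Tuple[float, ...]] = {
    0: (0.10, 0.60, 0.15, 0.10, 0.05),
    1: (0.10, 0.60, 0.15, 0.10, 0.05),
    2: (0.08, 0.50, 0.20, 0.14, 0.08),
    3: (0.05, 0.45, 0.22, 0.18, 0.10),
    4: (0.05, 0.40, 0.22, 0.20, 0.13),
}

#: Swelling grade (0-2) of an affected digit, per standard level.
SWELLING_GRADE_TABLE: Dict[int, Tuple[float, ...]] = {
    0: (0.55, 0.35, 0.10),
    1: (0.50, 0.35, 0.15),
    2: (0.40, 0.40, 0.20),
    3: (0.35, 0.40, 0.25),
    4: (0.30, 0.40, 0.30),
}

#: Digit selection weights (digits 2, 3, 4): digit 4 is affected least,
#: digit 2 most, matching the imbalanced pressure load on a walking bird.
DIGIT_WEIGHTS = (0.40, 0.35, 0.25)


@dataclass(frozen=True)
class CohortSpec:
    """A stratified synthetic cohort: ``n_per_level`` feet per standard level.

    ``digit_concordance`` interpolates the per-level digit tables between the
    level-independent average (0: digital involvement independent of the
    standard level) and the full level-dependent tables (1).
    ``digit_model='latent'`` instead drives all six digit variables from one
    per-foot latent severity with loading ``latent_loading``, the structure a
    one-factor polychoric analysis assumes; the latent value is stored in the
    ground truth.  ``rater_error`` is the +-1-level mis-score probability
    used when simulating observers for this cohort.
    """

    n_per_level: int = 100
    levels: Tuple[int, ...] = (0, 1, 2, 3, 4)
    n_flocks: int = 16
    left_preference: bool = True
    rater_error: float = 0.2
    seed: int = 0
    digit_concordance: float = 1.0
    digit_model: str = "tabular"
    latent_loading: float = 0.7
    flock_assignment: str = "random"
    foot_params: FootGenParams = field(default_factory=FootGenParams)

    def validate(self) -> None:
        if self.n_per_level < 1:
            raise GenerationError("n_per_level must be >= 1")
        if any(level not in LEVEL_RATIO_INTERVALS for level in self.levels):
            raise GenerationError("levels must be within 0..4")
        if not 0.0 <= self.digit_concordance <= 1.0:
            raise GenerationError("digit_concordance outside [0, 1]")
        if self.digit_model not in ("tabular", "latent"):
            raise GenerationError("digit_model must be 'tabular' or 'latent'")
        if self.n_flocks < 1:
            raise GenerationError("n_flocks must be >= 1")


def _mix_table(table: Mapping[int, Tuple[float, ...]], level: int, c: float):
    probs = np.array(table[level], dtype=float)
    pooled = np.mean([np.array(v, dtype=float) for v in table.values()], axis=0)
    mixed = (1.0 - c) * pooled + c * probs
    return mixed / mixed.sum()


def _met_pixels_for_level(level: int, n_pad: int, rng) -> int:
    """Lesion pixel count whose pixel-quantized ratio scores exactly ``level``."""
    lo, hi = LEVEL_RATIO_INTERVALS[level]
    if level == 0:
        return 0
    frac = rng.uniform(lo, hi)
    n = int(round(frac * n_pad))
    n_lo = int(math.floor(lo * n_pad)) if level >= 2 else 1
    n_hi = int(math.floor(hi * n_pad))
    n = max(n_lo, min(n, n_hi))
    while scoring.score_standard(n / n_pad) != level:
        n += 1 if scoring.score_standard(n / n_pad) < level else -1
        if not 0 < n <= n_pad:
            raise GenerationError(f"cannot realize level {level} on a {n_pad}px pad")
    return n


def _fractions_for_grade(grade: int, n_segments: int, rng) -> List[float]:
    fr = [0.0] * n_segments
    if grade == 0:
        return fr
    slots = list(rng.permutation(n_segments))
    if grade == 1:
        for s in slots[: int(rng.integers(1, 3))]:
            fr[s] = rng.uniform(0.02, 0.045)
    elif grade == 2:
        if n_segments > 2 and rng.random() < 0.4:
            for s in range(n_segments):
                fr[s] = rng.uniform(0.02, 0.045)
        else:
            fr[slots[0]] = rng.uniform(0.08, 0.45)
    elif grade == 3:
        if rng.random() < 0.5:
            fr[slots[0]] = rng.uniform(0.55, 0.92)
        else:
            fr[slots[0]] = rng.uniform(0.08, 0.45)
            fr[slots[1]] = rng.uniform(0.08, 0.45)
    else:
        fr[slots[0]] = rng.uniform(0.55, 0.92)
        fr[slots[1]] = rng.uniform(0.55, 0.92)
    return fr


def _swelling_factor_for_grade(grade: int, rng) -> float:
    if grade == 0:
        return 1.0
    if grade == 1:
        return rng.uniform(1.18, 1.32)
    return rng.uniform(1.40, 1.60)


_LATENT_LESION_MARGINS = (0.35, 0.30, 0.15, 0.12, 0.08)
_LATENT_SWELLING_MARGINS = (0.55, 0.30, 0.15)


def _latent_digit_grades(z: float, loading: float, rng):
    from scipy.stats import norm

    lesion_th = norm.ppf(np.cumsum(_LATENT_LESION_MARGINS[:-1]))
    swell_th = norm.ppf(np.cumsum(_LATENT_SWELLING_MARGINS[:-1]))
    resid = math.sqrt(1.0 - loading**2)
    lesion, swelling = {}, {}
    for d in scoring.DIGITS:
        x = loading * z + resid * rng.standard_normal()
        lesion[d] = int(np.searchsorted(lesion_th, x))
        y = loading * z + resid * rng.standard_normal()
        swelling[d] = int(np.searchsorted(swell_th, y))
    return lesion, swelling


def generate_cohort(spec: CohortSpec) -> List[FootSample]:
    """Generate a pseudorandomly ordered cohort of evaluated foot pairs.

    Exactly ``spec.n_per_level`` feet per level; every foot belongs to one
    flock.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = spec.foot_params
    n_seg = base.n_segments_per_digit

    # pad size of the base geometry (levels are realized in exact pixels)
    pad, _ = _build_geometry(base, swollen=False)
    n_pad = int(pad.sum())

    samples: List[FootSample] = []
    order = [(level, i) for level in spec.levels for i in range(spec.n_per_level)]
    order = [order[k] for k in rng.permutation(len(order))]
    for idx, (level, _) in enumerate(order):
        for _attempt in range(10):
            foot_rng = np.random.default_rng(int(rng.integers(2**31)))
            sample = _realize_foot(spec, base, level, n_pad, n_seg, foot_rng, idx)
            if sample is not None:
                break
        else:
            raise GenerationError(f"cannot realize level {level} foot after 10 draws")
        if spec.flock_assignment == "round_robin":
            sample.flock = idx % spec.n_flocks
        samples.append(sample)
    return samples


def _realize_foot(spec, base, level, n_pad, n_seg, foot_rng, idx):
    """Draw one foot at the requested level.

    Returns None when the pixel-level truth lands outside the level —
    possible in rare draws where a pad lesion and a digit lesion touch
    across the boundary and merge into one discoloration — so the caller
    can redraw.
    """
    n_met = _met_pixels_for_level(level, n_pad, foot_rng)
    met_frac = n_met / n_pad

    latent = None
    lesion_grades = {d: 0 for d in scoring.DIGITS}
    swelling_grades = {d: 0 for d in scoring.DIGITS}
    if spec.digit_model == "latent":
        latent = float(foot_rng.standard_normal())
        lesion_grades, swelling_grades = _latent_digit_grades(
            latent, spec.latent_loading, foot_rng
        )
    else:
        count_probs = _mix_table(AFFECTED_COUNT_TABLE, level, spec.digit_concordance)
        n_affected = int(foot_rng.choice(4, p=count_probs))
        weights = np.array(DIGIT_WEIGHTS)
        chosen = foot_rng.choice(
            3, size=n_affected, replace=False, p=weights / weights.sum()
        )
        lesion_probs = _mix_table(LESION_GRADE_TABLE, level, spec.digit_concordance)
        swell_probs = _mix_table(SWELLING_GRADE_TABLE, level, spec.digit_concordance)
        for j in chosen:
            d = scoring.DIGITS[j]
            lesion_grades[d] = int(foot_rng.choice(5, p=lesion_probs))
            swelling_grades[d] = int(foot_rng.choice(3, p=swell_probs))
            if lesion_grades[d] == 0 and swelling_grades[d] == 0:
                lesion_grades[d] = 1

    params = replace(
        base,
        met_lesion_frac=met_frac,
        digit_lesion_fracs={
            d: tuple(_fractions_for_grade(lesion_grades[d], n_seg, foot_rng))
            for d in scoring.DIGITS
        },
        swelling_factors={
            d: _swelling_factor_for_grade(swelling_grades[d], foot_rng)
            for d in scoring.DIGITS
        },
        seed=int(foot_rng.integers(2**31)),
    )
    left, right, truth = generate_foot_pair(params)
    truth.latent_severity = latent
    if truth.true_scores.standard_score != level:
        return None
    return FootSample(
        foot_id=f"foot_{idx:04d}",
        pair_id=f"bird_{idx:04d}",
        flock=int(foot_rng.integers(spec.n_flocks)),
        side="left" if spec.left_preference else "right",
        level=level,
        image=left,
        reference_image=right,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# rater and latent-ordinal simulators


def simulate_raters(
    true_scores: Sequence[int],
    error_model: Union[float, Mapping[int, float]],
    n_raters: int = 2,
    seed: int = 0,
    categories: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Simulate noisy ordinal raters around known true scores.

    ``error_model`` is either a mapping offset -> probability (must sum to
    1) or a single float p meaning {-1: p/2, 0: 1-p, +1: p/2}.  Scores are
    clipped to the category range.  Returns a raters x items integer matrix.
    """
    truth = np.asarray(true_scores, dtype=int)
    if truth.size == 0:
        raise ValueError("empty truth sequence")
    if isinstance(error_model, Mapping):
        offsets = np.array(sorted(error_model), dtype=int)
        probs = np.array([error_model[o] for o in offsets], dtype=float)
    else:
        p = float(error_model)
        offsets = np.array([-1, 0, 1])
        probs = np.array([p / 2.0, 1.0 - p, p / 2.0])
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("error model probabilities must sum to 1")
    if categories is None:
        lo, hi = int(truth.min()), int(truth.max())
    else:
        lo, hi = int(min(categories)), int(max(categories))
    rng = np.random.default_rng(seed)
    draws = rng.choice(offsets, size=(n_raters, truth.size), p=probs)
    return np.clip(truth[None, :] + draws, lo, hi)


def one_factor_corr(loadings: Sequence[float]) -> np.ndarray:
    """Correlation matrix implied by a single-factor model."""
    lam = np.asarray(loadings, dtype=float)
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


def simulate_ordinal_latent(
    corr: np.ndarray,
    thresholds: Sequence[Sequence[float]],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Sample ordinal data from the latent-normal model.

    Latent vectors are multivariate normal with correlation ``corr``; each
    variable j is discretized at its strictly increasing ``thresholds[j]``
    (category = number of thresholds below the latent value).  This is
    exactly the data-generating model under which the polychoric estimator
    is consistent, so the generating correlation is an oracle for it.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p) or not np.allclose(corr, corr.T):
        raise ValueError("corr must be a symmetric square matrix")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is not positive definite") from e
    ths = [np.asarray(t, dtype=float) for t in thresholds]
    if len(ths) != p:
        raise ValueError("one threshold vector per variable required")
    for t in ths:
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p)) @ chol.T
    out = np.empty((n, p), dtype=int)
    for j in range(p):
        out[:, j] = np.searchsorted(ths[j], z[:, j])
    return out


def equiprobable_thresholds(n_categories: int) -> np.ndarray:
    """Normal quantile thresholds giving equal category probabilities."""
    from scipy.stats import norm

    qs = np.arange(1, n_categories) / n_categories
    return norm.ppf(qs)
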