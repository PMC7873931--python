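"""Segmentation of suspended-foot images against a dark background.

Mirrors the logic of slaughter-line camera systems for footpad-dermatitis
monitoring: the foot is found by its contrast to the dark background, the
metatarsal pad is separated from the digits using the background showing
through the interdigital spaces, each digit is split into phalanx-pad
segments at width minima, and lesions are detected as brownish, darker
pixels inside the foot.

Conventions: row-major 0-based pixel indices; digits point image-down
(hanging foot), digit 2 leftmost, digit 4 rightmost; set
``SegConfig.digits_point_down = False`` for the opposite orientation.
Areas are raw pixel counts — the downstream morphometry works in relative
areas only, so no physical calibration is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_fill_holes, binary_opening
from scipy.signal import find_peaks
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "SegConfig",
    "FootMasks",
    "SegmentationError",
    "NoFootError",
    "DigitDetectionError",
    "segment_foot",
    "partition_pads",
    "detect_lesions",
    "segment_all",
]


class SegmentationError(RuntimeError):
    """Segmentation failed in a way the caller must handle."""


class NoFootError(SegmentationError):
    """No above-threshold pixels: no foot detected."""


class DigitDetectionError(SegmentationError):
    """Fewer than three digit branches were found."""


@dataclass
class SegConfig:
    """Tunable thresholds of the segmentation stages.

    ``background_threshold`` is a gray intensity in [0, 255] separating the
    dark background from skin; ``None`` estimates it from the image border
    (assumed background) as median + a fraction of the border-to-maximum
    contrast, which stays below even dark-brown lesions.  Lesions ("brownish discolorations, light to dark")
    are defined by an HSV box: hue within ``lesion_hue_range`` (skimage hue
    units, [0, 1)) and value below ``lesion_value_cut`` — brown is darker
    than healthy skin at a similar hue.  ``opening_radius`` must lie between
    the digit half-width and the metatarsal-pad half-width; the morphological
    opening at that radius erases the digits but keeps the pad.
    """

    background_threshold: Optional[float] = None
    lesion_hue_range: Tuple[float, float] = (0.0, 0.18)
    lesion_value_cut: float = 0.72
    min_lesion_px: int = 5
    opening_radius: int = 13
    min_digit_px: int = 120
    flare_factor: float = 1.8
    curvature_window: int = 5
    n_segments: int = 3
    min_foot_px: int = 50
    digits_point_down: bool = True

    def __post_init__(self) -> None:
        if self.background_threshold is not None and not (
            0 <= self.background_threshold <= 255
        ):
            raise ValueError("background_threshold outside [0, 255]")
        if not 0.0 <= self.lesion_value_cut <= 1.0:
            raise ValueError("lesion_value_cut outside [0, 1]")
        if self.min_lesion_px < 0:
            raise ValueError("min_lesion_px must be >= 0")


@dataclass
class FootMasks:
    """Binary masks of one foot, all with the image's shape.

    ``foot_mask`` is reference area 1 (RA1, the whole visible foot);
    ``metatarsal_mask`` is reference area 2 (RA2).  ``digit_masks`` maps
    digit number (2-4) to its pad mask and ``segment_masks`` maps digit
    number to the ordered per-phalanx masks (proximal to distal), which
    partition that digit's pad.
    """

    foot_mask: np.ndarray
    metatarsal_mask: np.ndarray
    digit_masks: Dict[int, np.ndarray]
    segment_masks: Dict[int, List[np.ndarray]]
    lesion_mask: np.ndarray

    def validate(self) -> None:
        foot = self.foot_mask.astype(bool)
        met = self.metatarsal_mask.astype(bool)
        if (met & ~foot).any():
            raise SegmentationError("metatarsal mask not contained in foot mask")
        if (self.lesion_mask.astype(bool) & ~foot).any():
            raise SegmentationError("lesion mask not contained in foot mask")
        for d, dm in self.digit_masks.items():
            dm = dm.astype(bool)
            if (dm & ~foot).any():
                raise SegmentationError(f"digit {d} mask not contained in foot mask")
            if (dm & met).any():
                raise SegmentationError(f"digit {d} mask overlaps metatarsal mask")
            segs = self.segment_masks.get(d, [])
            if segs:
                union = np.zeros_like(dm)
                for s in segs:
                    s = s.astype(bool)
                    if (s & union).any():
                        raise SegmentationError(f"digit {d} segments overlap")
                    union |= s
                if (union ^ dm).any():
                    raise SegmentationError(
                        f"digit {d} segments do not partition the digit mask"
                    )
        for d1 in self.digit_masks:
            for d2 in self.digit_masks:
                if d1 < d2 and (
                    self.digit_masks[d1].astype(bool)
                    & self.digit_masks[d2].astype(bool)
                ).any():
                    raise SegmentationError(f"digits {d1} and {d2} overlap")


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop connected components with fewer than ``min_px`` pixels."""
    if min_px <= 1 or not mask.any():
        return mask
    lab, n = label(mask, return_num=True)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def _auto_threshold(lum: np.ndarray, contrast_frac: float = 0.15) -> float:
    """Background cut from the dark border: median + a contrast fraction."""
    border = np.concatenate([lum[0], lum[-1], lum[:, 0], lum[:, -1]])
    bg = float(np.median(border))
    return bg + contrast_frac * max(float(lum.max()) - bg, 1.0)


def _luminance(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    return img[..., :3].mean(axis=2)


def segment_foot(image: np.ndarray, cfg: SegConfig | None = None) -> np.ndarray:
    """Detect the foot by contrast to the dark background.

    Returns the largest connected above-threshold component with its holes
    filled.  Raises :class:`NoFootError` when nothing usable is found.
    """
    cfg = cfg or SegConfig()
    lum = _luminance(image)
    thr = cfg.background_threshold
    if thr is None:
        thr = _auto_threshold(lum)
    above = lum > thr
    if not above.any():
        raise NoFootError("no foot detected: no pixels above background threshold")
    lab = label(above)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    mask = lab == biggest
    if mask.sum() < cfg.min_foot_px:
        raise NoFootError(
            f"no foot detected: largest component has {int(mask.sum())} px"
        )
    return binary_fill_holes(mask)


def _row_widths(mask: np.ndarray) -> np.ndarray:
    return mask.sum(axis=1)


def _trim_flare(digit: np.ndarray, foot: np.ndarray, cfg: SegConfig) -> np.ndarray:
    """Reassign a digit's topmost rows to the pad where the branch width
    flares into the pad body (the "start of the curvature" boundary)."""
    widths = _row_widths(digit)
    rows = np.nonzero(widths)[0]
    if rows.size == 0:
        return digit
    body = widths[rows]
    ref = float(np.median(body))
    out = digit.copy()
    for r in rows:  # trim only a contiguous flare at the attachment end
        if widths[r] > cfg.flare_factor * ref:
            out[r] = False
        else:
            break
    return out


def partition_pads(
    foot_mask: np.ndarray, cfg: SegConfig | None = None
) -> Tuple[np.ndarray, Dict[int, np.ndarray], Dict[int, List[np.ndarray]]]:
    """Split the foot into the metatarsal pad and digits 2-4 with segments.

    The wide pad survives a morphological opening that erases the narrow
    digits; the three largest residual components are the digit branches
    (ordered left to right as digits 2, 3, 4 under the default orientation).
    The pad/digit boundary is refined where the branch width flares into the
    pad body, and each digit is split into ``cfg.n_segments`` phalanx
    segments at local width minima, falling back to equal-length division.
    """
    cfg = cfg or SegConfig()
    foot = foot_mask.astype(bool)
    if not foot.any():
        raise SegmentationError("empty foot mask")
    work = foot if cfg.digits_point_down else foot[::-1]

    pad_core = binary_opening(work, structure=disk(cfg.opening_radius))
    residual = work & ~pad_core
    residual = _remove_small(residual, 8)
    lab = label(residual)
    props = sorted(regionprops(lab), key=lambda p: p.area, reverse=True)
    cands = [p for p in props if p.area >= cfg.min_digit_px]
    if len(cands) < 3:
        raise DigitDetectionError(
            f"digit detection failed: found {len(cands)} branch(es) "
            f">= {cfg.min_digit_px} px (opening radius {cfg.opening_radius})"
        )
    cands = sorted(cands[:3], key=lambda p: p.centroid[1])
    digit_masks: Dict[int, np.ndarray] = {}
    for number, p in zip((2, 3, 4), cands):
        dm = lab == p.label
        digit_masks[number] = _trim_flare(dm, work, cfg)
    digit_union = np.zeros_like(work)
    for dm in digit_masks.values():
        digit_union |= dm
    met = work & ~digit_union

    segment_masks = {
        d: split_segments(dm, cfg.n_segments, cfg) for d, dm in digit_masks.items()
    }
    if not cfg.digits_point_down:
        met = met[::-1]
        digit_masks = {d: m[::-1] for d, m in digit_masks.items()}
        segment_masks = {
            d: [s[::-1] for s in segs] for d, segs in segment_masks.items()
        }
    return met, digit_masks, segment_masks


def split_segments(
    digit_mask: np.ndarray, n_segments: int, cfg: SegConfig | None = None
) -> List[np.ndarray]:
    """Split one digit into segments at local minima of its row-width profile.

    Digit pads are widest mid-phalanx and constricted at the joints, so the
    width profile has a local minimum at each joint.  When fewer than
    ``n_segments - 1`` interior minima are found the digit is divided into
    equal-length row bins instead.
    """
    cfg = cfg or SegConfig()
    widths = _row_widths(digit_mask)
    rows = np.nonzero(widths)[0]
    if rows.size == 0:
        return [digit_mask.copy() for _ in range(n_segments)]
    r0, r1 = rows[0], rows[-1]
    profile = widths[r0 : r1 + 1].astype(float)
    if profile.size >= 3:
        win = max(3, cfg.curvature_window) | 1
        kernel = np.ones(win) / win
        smooth = np.convolve(profile, kernel, mode="same")
    else:
        smooth = profile
    minima, _ = find_peaks(-smooth, prominence=0.5)
    minima = [m for m in minima if 0 < m < profile.size - 1]
    if len(minima) >= n_segments - 1:
        if len(minima) > n_segments - 1:
            # keep the deepest minima
            minima = sorted(
                sorted(minima, key=lambda m: smooth[m])[: n_segments - 1]
            )
        cuts = [r0 + m for m in minima]
    else:
        span = (r1 - r0 + 1) / n_segments
        cuts = [int(round(r0 + span * k)) for k in range(1, n_segments)]
    bounds = [r0] + [c + 1 for c in cuts] + [r1 + 1]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = np.zeros_like(digit_mask, dtype=bool)
        seg[a:b] = digit_mask[a:b]
        segs.append(seg)
    return segs


def detect_lesions(
    image: np.ndarray,
    foot_mask: np.ndarray,
    cfg: SegConfig | None = None,
) -> np.ndarray:
    """Detect brownish, darker lesion pixels inside the foot.

    An empty mask is a valid result (intact foot).  Speckles smaller than
    ``cfg.min_lesion_px`` are removed.
    """
    cfg = cfg or SegConfig()
    hsv = rgb2hsv(np.asarray(image, dtype=np.uint8))
    hue, val = hsv[..., 0], hsv[..., 2]
    lo, hi = cfg.lesion_hue_range
    in_hue = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi)
    lesion = foot_mask.astype(bool) & in_hue & (val < cfg.lesion_value_cut)
    return _remove_small(lesion, cfg.min_lesion_px)


def segment_all(image: np.ndarray, cfg: SegConfig | None = None) -> FootMasks:
    """Run the full segmentation chain on one image and validate the result."""
    cfg = cfg or SegConfig()
    foot = segment_foot(image, cfg)
    met, digits, segments = partition_pads(foot, cfg)
    lesions = detect_lesions(image, foot, cfg)
    masks = FootMasks(
        foot_mask=foot,
        metatarsal_mask=met,
        digit_masks=digits,
        segment_masks=segments,
        lesion_mask=lesions,
    )
    masks.validate()
    return masks
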