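"""Krippendorff's alpha for inter-observer reliability.

Implemented from the definition: the coincidence matrix of pairable values
within items, observed disagreement D_o and expected disagreement D_e under
the marginal distribution, and alpha = 1 - D_o / D_e.  Two difference
functions are provided, matching the data types of an FPD scoring study:
*ordinal* (squared cumulative-marginal distances between categories, so a
one-level disagreement weighs less than a two-level one) and *interval*
(squared value differences, for pixel-count measurements).  Missing ratings
are handled by per-item pairability — an item enters the analysis with the
ratings it has, provided there are at least two — never by imputation.

Verbal interpretation uses the Landis-Koch bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RatingMatrix",
    "AlphaResult",
    "UndefinedAlphaError",
    "krippendorff_alpha",
    "landis_koch",
]


class UndefinedAlphaError(ValueError):
    """No variation in the ratings: expected disagreement is zero."""


@dataclass
class RatingMatrix:
    """Raters x items ratings; NaN marks a missing rating.

    ``level`` selects the difference function: ``"ordinal"`` for scores,
    ``"interval"`` for metric measurements.
    """

    values: np.ndarray
    level: str = "ordinal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D raters x items array")
        if self.values.shape[0] < 2:
            raise ValueError("at least two raters required")
        if self.level not in ("ordinal", "interval"):
            raise ValueError("level must be 'ordinal' or 'interval'")

    @classmethod
    def from_csv(cls, path, level: str = "ordinal") -> "RatingMatrix":
        """Read a CSV with raters as rows and items as columns; blank = missing."""
        df = pd.read_csv(path, header=None)
        return cls(df.to_numpy(dtype=float), level=level)


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    label: str
    n_items: int
    n_pairable: int
    level: str

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "label": self.label,
            "n_items": self.n_items,
            "n_pairable": self.n_pairable,
            "level": self.level,
        }


def _coincidence(values: np.ndarray, cats: np.ndarray):
    """Coincidence matrix over categories from pairable values per item."""
    k = cats.size
    cat_index = {v: i for i, v in enumerate(cats)}
    o = np.zeros((k, k))
    n_items = 0
    for col in range(values.shape[1]):
        ratings = values[:, col]
        ratings = ratings[~np.isnan(ratings)]
        m = ratings.size
        if m < 2:
            continue
        n_items += 1
        counts = np.zeros(k)
        for v in ratings:
            counts[cat_index[v]] += 1
        # ordered pairs within the item, weighted by 1/(m-1)
        pair = np.outer(counts, counts) - np.diag(counts)
        o += pair / (m - 1)
    return o, n_items


def _delta_sq(cats: np.ndarray, margins: np.ndarray, level: str) -> np.ndarray:
    k = cats.size
    if level == "interval":
        d = cats[:, None] - cats[None, :]
        return d.astype(float) ** 2
    # ordinal: squared distance between cumulative-marginal midpoints
    delta = np.zeros((k, k))
    for c in range(k):
        for g in range(c + 1, k):
            span = margins[c : g + 1].sum() - (margins[c] + margins[g]) / 2.0
            delta[c, g] = delta[g, c] = span**2
    return delta


def krippendorff_alpha(m: RatingMatrix) -> AlphaResult:
    """Compute Krippendorff's alpha with the matrix's difference function.

    Items with fewer than two non-missing ratings are dropped.  Raises
    :class:`UndefinedAlphaError` when all pairable ratings are identical
    (expected disagreement zero), in which case no chance-corrected
    agreement is defined.
    """
    vals = m.values
    flat = vals[~np.isnan(vals)]
    cats = np.unique(flat)
    o, n_items = _coincidence(vals, cats)
    if n_items == 0:
        raise ValueError("no item has two or more ratings")
    margins = o.sum(axis=1)
    n_total = margins.sum()
    delta = _delta_sq(cats, margins, m.level)
    d_o = (o * delta).sum()
    d_e = (np.outer(margins, margins) * delta).sum() / (n_total - 1.0)
    if d_e <= 0:
        raise UndefinedAlphaError(
            "alpha undefined: no variation at all in the ratings"
        )
    alpha = 1.0 - d_o / d_e
    return AlphaResult(
        alpha=float(alpha),
        label=landis_koch(alpha),
        n_items=n_items,
        n_pairable=int(round(n_total)),
        level=m.level,
    )


#: Landis-Koch bands, closed on the printed boundaries; agreement values
#: falling in the printed gaps (e.g. 0.205 or 0.805) join the lower band.
_LANDIS_KOCH = (
    (0.21, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (np.inf, "almost perfect"),
)


def landis_koch(alpha: float) -> str:
    """Verbal label for an agreement coefficient (<0 = poor)."""
    if alpha > 1.0:
        raise ValueError("agreement coefficient cannot exceed 1")
    if alpha < 0.0:
        return "poor"
    for upper, lab in _LANDIS_KOCH:
        if alpha < upper:
            return lab
    return "almost perfect"
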