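"""End-to-end study runner: images -> masks -> morphometry -> scores -> stats.

This is the glue the numbered analysis drivers and the CLI call into; every
computational step lives in the dedicated modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import association, morphometry, scoring
from .segment import FootMasks, SegConfig, SegmentationError, segment_all
from .synth import FootSample

logger = logging.getLogger(__name__)

__all__ = ["FootResult", "score_foot_pair", "score_cohort", "analyze_scored"]

#: Ordinal digit variables used for the digital-score factor analysis.
DIGIT_VARIABLES = [
    "lesion_d2", "lesion_d3", "lesion_d4",
    "swelling_d2", "swelling_d3", "swelling_d4",
]


@dataclass
class FootResult:
    foot_id: str
    report: Optional[morphometry.AreaReport]
    record: Optional[scoring.ScoreRecord]
    masks: Optional[FootMasks]
    error: Optional[str] = None


def score_foot_pair(
    image: np.ndarray,
    reference_image: Optional[np.ndarray] = None,
    cfg: Optional[SegConfig] = None,
    punctual: float = scoring.PUNCTUAL_FRACTION,
    swelling_thresholds: Tuple[float, float] = scoring.SWELLING_THRESHOLDS,
    mirror_reference: bool = True,
) -> Tuple[morphometry.AreaReport, scoring.ScoreRecord, FootMasks]:
    """Segment, measure and score one evaluated foot.

    When a contralateral reference image is given, its digits provide the
    swelling references; ``mirror_reference`` pairs digit d of the evaluated
    foot with segmented digit 6-d of the (mirrored) reference image, the
    anatomical correspondence for a left/right pair photographed from the
    same side.  Without a reference the swelling grades are withheld.
    """
    cfg = cfg or SegConfig()
    masks = segment_all(image, cfg)
    report = morphometry.measure(masks)
    fracs = morphometry.per_segment_fractions(masks)
    digit_areas = {d: int(m.sum()) for d, m in masks.digit_masks.items()}
    reference_areas: Optional[Dict[int, int]] = None
    if reference_image is not None:
        try:
            ref_masks = segment_all(reference_image, cfg)
            ref_raw = {d: int(m.sum()) for d, m in ref_masks.digit_masks.items()}
            if mirror_reference:
                reference_areas = {d: ref_raw[6 - d] for d in scoring.DIGITS}
            else:
                reference_areas = ref_raw
        except SegmentationError as e:
            logger.warning("reference foot unusable (%s); swelling withheld", e)
    record = scoring.assemble_record(
        report.standard, fracs, digit_areas, reference_areas,
        punctual=punctual, swelling_thresholds=swelling_thresholds,
    )
    return report, record, masks


def _record_row(report: morphometry.AreaReport, record: scoring.ScoreRecord) -> dict:
    row = report.as_dict()
    row["standard_score"] = record.standard_score
    for d in scoring.DIGITS:
        row[f"lesion_d{d}"] = record.digit_lesion_scores[d]
        sw = record.swelling_scores.get(d)
        row[f"swelling_d{d}"] = np.nan if sw is None else sw
    row["n_affected_digits"] = record.n_affected_digits
    row["digit_flag"] = int(record.digit_flag)
    return row


def score_cohort(
    samples: Iterable[FootSample],
    cfg: Optional[SegConfig] = None,
    with_truth: bool = True,
) -> pd.DataFrame:
    """Run the full pipeline over a cohort; one row per foot.

    Per-foot failures are logged and flagged in the ``error`` column; the
    run continues.  With ``with_truth`` the generator's ground truth is
    joined in ``true_``-prefixed columns for recovery analyses.
    """
    rows = []
    for s in samples:
        row: dict = {
            "foot_id": s.foot_id, "pair_id": s.pair_id,
            "flock": s.flock, "side": s.side, "error": "",
        }
        try:
            report, record, _ = score_foot_pair(s.image, s.reference_image, cfg)
            row.update(_record_row(report, record))
        except (SegmentationError, morphometry.DegenerateAreaError) as e:
            logger.warning("foot %s failed: %s", s.foot_id, e)
            row["error"] = str(e)
        if with_truth:
            row["true_level"] = s.level
            tr = s.truth.true_ratios
            for name in morphometry.RATIO_COLUMNS:
                row[f"true_{name}"] = getattr(tr, name)
            ts = s.truth.true_scores
            row["true_n_affected"] = ts.n_affected_digits
            for d in scoring.DIGITS:
                row[f"true_lesion_d{d}"] = ts.digit_lesion_scores[d]
                row[f"true_swelling_d{d}"] = ts.swelling_scores[d]
            if s.truth.latent_severity is not None:
                row["latent_severity"] = s.truth.latent_severity
        rows.append(row)
    return pd.DataFrame(rows)


#: Table-5-style parameter pairs for the surface-measurement correlations.
CORRELATION_PAIRS = [
    ("standard", "fp_ra1"), ("standard", "dp_ra1"),
    ("standard", "dp_ra2"), ("standard", "full"),
    ("fp_ra1", "dp_ra1"), ("fp_ra1", "dp_ra2"), ("fp_ra1", "full"),
    ("dp_ra1", "dp_ra2"), ("dp_ra1", "full"),
]


def analyze_scored(df: pd.DataFrame, seed: int = 0) -> dict:
    """Run the study's statistics on a scored-cohort table.

    Returns a JSON-serializable dict: affected-digit distribution per
    standard level, per-digit score distributions, blocked Friedman tests
    across digits, the polychoric-PCA digital score with its association to
    the standard level, and the surface-measurement correlation table.
    """
    required = {"standard_score", "n_affected_digits"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"scored table lacks columns: {sorted(missing)}")
    ok = df[df["error"] == ""] if "error" in df.columns else df
    out: dict = {"n_feet": int(len(ok)), "n_failed": int(len(df) - len(ok))}

    dist = (
        ok.groupby("standard_score")["n_affected_digits"]
        .value_counts(normalize=True).unstack(fill_value=0.0)
    )
    out["affected_digits_by_level"] = {
        str(lv): {str(k): float(v) for k, v in row.items()}
        for lv, row in dist.iterrows()
    }
    out["pct_intact_digits"] = float((ok["n_affected_digits"] == 0).mean() * 100.0)

    for kind in ("lesion", "swelling"):
        cols = [f"{kind}_d{d}" for d in scoring.DIGITS]
        grid = ok[cols].to_numpy(dtype=float)
        try:
            fr = association.friedman_blocked(grid)
            out[f"friedman_{kind}"] = {
                "F": fr.f_statistic, "df1": fr.df1, "df2": fr.df2,
                "p": fr.p_value, "chi2": fr.chi2, "chi2_p": fr.chi2_p,
                "n_blocks": fr.n_blocks, "n_dropped": fr.n_dropped,
            }
        except ValueError as e:
            out[f"friedman_{kind}"] = {"error": str(e)}

    # polychoric-PCA digital score
    digital = None
    try:
        data = ok[DIGIT_VARIABLES].dropna().to_numpy(dtype=int)
        rho = association.polychoric_matrix(data)
        fac = association.factor_extract(rho, mineigen=1.0)
        if fac.retained:
            scores = association.factor_scores(fac, data)[:, 0]
            idx = ok[DIGIT_VARIABLES].dropna().index
            levels = ok.loc[idx, "standard_score"].to_numpy()
            rs, ps = association.correlate(scores, levels, method="spearman")
            comp = association.compare_levels(scores, levels)
            digital = {
                "first_eigenvalue": float(fac.eigenvalues[0]),
                "n_retained": fac.n_retained,
                "loadings": fac.loadings[:, 0].tolist(),
                "spearman_vs_standard": rs,
                "spearman_p": ps,
                "anova_F": comp.f_statistic,
                "anova_df": [comp.df1, comp.df2],
                "anova_p": comp.p_value,
                "significant_pairs": [
                    f"{a}-{b}"
                    for a, b, rej in zip(
                        comp.pairs["group1"], comp.pairs["group2"],
                        comp.pairs["reject"],
                    )
                    if rej
                ],
            }
        else:
            digital = {"n_retained": 0}
    except (association.DegenerateMarginError, ValueError) as e:
        digital = {"error": str(e)}
    out["digital_score"] = digital

    corr = {}
    for a, b in CORRELATION_PAIRS:
        if a in ok.columns and b in ok.columns:
            try:
                r, p = association.correlate(ok[a], ok[b], method="pearson")
                corr[f"{a}~{b}"] = {"r": r, "p": p}
            except ValueError as e:
                corr[f"{a}~{b}"] = {"error": str(e)}
    out["surface_correlations"] = corr
    return out
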