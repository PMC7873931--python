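"""Association statistics for digit scoring vs. the standard FPD score.

The centerpiece is the "digital score" construction used to condense the
six ordinal digit variables (per-digit lesion grade and swelling grade)
into one severity value per foot:

1. a polychoric correlation matrix — each pairwise coefficient is the
   latent bivariate-normal correlation estimated by the two-step maximum
   likelihood method (thresholds from the inverse-normal cumulative
   marginals, then a bounded 1-D likelihood maximization over rho);
2. principal-axis factoring of that matrix with squared-multiple-
   correlation (SMC) priors on the diagonal, retaining factors whose
   eigenvalue reaches a minimum (default 1), varimax-rotated when two or
   more are retained;
3. regression-method scoring coefficients applied to the standardized
   numeric-coded data, giving a per-foot factor score.

The module also provides the blocked Friedman test in its rank-transform
ANOVA form (treatments = digits 2-4, blocks = feet), Pearson/Spearman
correlations, and fixed-effects Tukey-Kramer pairwise level comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "PolychoricResult",
    "FactorResult",
    "FriedmanResult",
    "LevelComparison",
    "DegenerateMarginError",
    "polychoric",
    "polychoric_matrix",
    "factor_extract",
    "factor_scores",
    "friedman_blocked",
    "correlate",
    "compare_levels",
]


class DegenerateMarginError(ValueError):
    """A variable shows fewer than two observed categories."""


@dataclass(frozen=True)
class PolychoricResult:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    loglik: float
    n: int


@dataclass
class FactorResult:
    """Principal-axis factoring output.

    ``loadings`` are varimax-rotated (a single factor is rotation-invariant)
    and sign-oriented so each column sums positive.  ``scoring_coefficients``
    are the regression-method weights R^{-1} L used by
    :func:`factor_scores`.
    """

    eigenvalues: np.ndarray
    n_retained: int
    loadings: np.ndarray
    communalities: np.ndarray
    scoring_coefficients: np.ndarray
    converged: bool
    n_iter: int

    @property
    def retained(self) -> bool:
        return self.n_retained > 0


# ---------------------------------------------------------------------------
# polychoric correlation


def _thresholds_from_margins(codes: np.ndarray, n_cats: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_cats).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum)


def _bvn_rectangles(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a bivariate normal over the threshold grid."""
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))
    mvn = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
    )
    big = 8.5  # effectively infinite for the standard normal
    gx = np.clip(ax, -big, big)
    gy = np.clip(ay, -big, big)
    pts = np.array([[x, y] for x in gx for y in gy])
    cdf = mvn.cdf(pts).reshape(gx.size, gy.size)
    cells = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(cells, 1e-12, None)


def polychoric(
    x: Sequence[int],
    y: Sequence[int],
    tol: float = 1e-6,
) -> PolychoricResult:
    """Two-step maximum-likelihood polychoric correlation of two ordinal vectors.

    Thresholds come from the inverse-normal cumulative marginals; rho then
    maximizes the bivariate-normal cell-probability likelihood over (-1, 1)
    by bounded scalar optimization.  Estimates driven to the boundary are
    clamped to +-(1 - 1e-6) with a warning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    xcats, xi = np.unique(x, return_inverse=True)
    ycats, yi = np.unique(y, return_inverse=True)
    if xcats.size < 2 or ycats.size < 2:
        raise DegenerateMarginError("degenerate margin: fewer than 2 categories")
    table = np.zeros((xcats.size, ycats.size))
    np.add.at(table, (xi, yi), 1.0)
    tx = _thresholds_from_margins(xi, xcats.size)
    ty = _thresholds_from_margins(yi, ycats.size)

    mask = table > 0

    def negloglik(rho: float) -> float:
        cells = _bvn_rectangles(tx, ty, rho)
        return -float((table[mask] * np.log(cells[mask])).sum())

    bound = 1.0 - 1e-6
    res = minimize_scalar(
        negloglik, bounds=(-bound, bound), method="bounded",
        options={"xatol": tol},
    )
    rho = float(res.x)
    if abs(rho) >= bound - 1e-5:
        rho = float(np.sign(rho) * bound)
        logger.warning("polychoric estimate at the boundary; clamped to %+.6f", rho)
    return PolychoricResult(
        rho=rho, thresholds_x=tx, thresholds_y=ty,
        loglik=-float(res.fun), n=int(x.size),
    )


def polychoric_matrix(data: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Pairwise polychoric correlation matrix of an items x variables array.

    Symmetric with unit diagonal; repaired to the nearest positive
    semi-definite matrix by eigenvalue clipping (with a warning) if needed.
    """
    data = np.asarray(data)
    p = data.shape[1]
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r[i, j] = r[j, i] = polychoric(data[:, i], data[:, j], tol=tol).rho
    w = np.linalg.eigvalsh(r)
    if w.min() < -1e-10:
        logger.warning(
            "polychoric matrix not PSD (min eigenvalue %.3g); clipping", w.min()
        )
        vals, vecs = np.linalg.eigh(r)
        vals = np.clip(vals, 1e-8, None)
        r = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# principal-axis factoring


def _smc(r: np.ndarray) -> np.ndarray:
    """Squared multiple correlations from the inverse correlation matrix."""
    try:
        rinv = np.linalg.inv(r)
        smc = 1.0 - 1.0 / np.diag(rinv)
    except np.linalg.LinAlgError:
        smc = np.square(r - np.eye(r.shape[0])).max(axis=1)
    return np.clip(smc, 0.0, 1.0)


def factor_extract(
    corr: np.ndarray,
    mineigen: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FactorResult:
    """Principal-axis factoring with SMC priors and varimax rotation.

    The number of retained factors is fixed by the eigenvalues of the
    SMC-reduced matrix at the first pass (eigenvalue >= ``mineigen``);
    communalities are then iterated to convergence.  Heywood cases
    (communality above 1) are clamped with a warning.  When no eigenvalue
    reaches ``mineigen`` the result carries ``n_retained = 0`` and empty
    loadings.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    if r.shape != (p, p) or not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("corr must be a symmetric correlation matrix")
    h = _smc(r)
    r0 = r.copy()
    np.fill_diagonal(r0, h)
    eig0 = np.linalg.eigvalsh(r0)[::-1]
    k = int((eig0 >= mineigen).sum())
    if k == 0:
        return FactorResult(
            eigenvalues=eig0, n_retained=0, loadings=np.empty((p, 0)),
            communalities=h, scoring_coefficients=np.empty((p, 0)),
            converged=True, n_iter=0,
        )
    converged = False
    it = 0
    loadings = np.zeros((p, k))
    eigvals = eig0
    for it in range(1, max_iter + 1):
        rr = r.copy()
        np.fill_diagonal(rr, h)
        vals, vecs = np.linalg.eigh(rr)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        eigvals = vals
        lead = np.clip(vals[:k], 0.0, None)
        loadings = vecs[:, :k] * np.sqrt(lead)
        h_new = np.sum(loadings**2, axis=1)
        if h_new.max() > 1.0:
            logger.warning("Heywood case: communality %.4f clamped", h_new.max())
            h_new = np.clip(h_new, 0.0, 1.0 - 1e-9)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            converged = True
            break
        h = h_new
    if not converged:
        logger.warning("communalities not converged after %d iterations", max_iter)
    if k >= 2:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        loadings, _ = rotate_factors(loadings, "varimax")
    # orient each factor so its loading sum is positive
    signs = np.where(loadings.sum(axis=0) >= 0, 1.0, -1.0)
    loadings = loadings * signs
    coef = np.linalg.solve(r, loadings)
    return FactorResult(
        eigenvalues=eigvals,
        n_retained=k,
        loadings=loadings,
        communalities=np.sum(loadings**2, axis=1),
        scoring_coefficients=coef,
        converged=converged,
        n_iter=it,
    )


def factor_scores(result: FactorResult, data: np.ndarray) -> np.ndarray:
    """Per-item factor scores: standardized data times scoring coefficients.

    Rows with missing values are excluded (returned as NaN).  Raises on a
    constant variable, for which standardization is undefined.
    """
    if not result.retained:
        raise ValueError("no factor retained; no scores to compute")
    x = np.asarray(data, dtype=float)
    if x.shape[1] != result.loadings.shape[0]:
        raise ValueError("dataset variables do not match the loadings")
    ok = ~np.isnan(x).any(axis=1)
    if (~ok).any():
        logger.info("factor_scores: %d items with missing values excluded",
                    int((~ok).sum()))
    mu = x[ok].mean(axis=0)
    sd = x[ok].std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variable: standardization undefined")
    scores = np.full((x.shape[0], result.n_retained), np.nan)
    scores[ok] = (x[ok] - mu) / sd @ result.scoring_coefficients
    return scores


# ---------------------------------------------------------------------------
# blocked Friedman test


@dataclass(frozen=True)
class FriedmanResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    chi2: float
    chi2_df: int
    chi2_p: float
    n_blocks: int
    n_dropped: int


def friedman_blocked(values: np.ndarray) -> FriedmanResult:
    """Friedman test in rank-transform ANOVA form (blocks = feet, treatments = digits).

    Values are mid-ranked within each block; the F statistic for the
    treatment effect comes from a two-way fixed-effects ANOVA on the ranks
    (block sums of squares vanish for complete rank rows).  The classic
    tie-corrected Friedman chi-square is reported alongside.  Blocks with
    any missing value are dropped and counted.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 2:
        raise ValueError("values must be a blocks x treatments grid")
    keep = ~np.isnan(vals).any(axis=1)
    dropped = int((~keep).sum())
    vals = vals[keep]
    n, k = vals.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    ranks = stats.rankdata(vals, axis=1)
    grand = (k + 1) / 2.0
    col_means = ranks.mean(axis=0)
    ss_treat = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((ranks - grand) ** 2).sum())
    ss_err = ss_total - ss_treat  # block SS is identically zero on ranks
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    if ss_err <= 1e-12:
        f = 0.0 if ss_treat <= 1e-12 else np.inf
        p = 1.0 if ss_treat <= 1e-12 else 0.0
    else:
        f = (ss_treat / df1) / (ss_err / df2)
        p = float(stats.f.sf(f, df1, df2))
    # tie-corrected chi-square: SS_treat over the mean within-block variance
    denom = ss_total / (n * (k - 1))
    if denom <= 1e-12:
        chi2, chi2_p = 0.0, 1.0
    else:
        chi2 = ss_treat / denom
        chi2_p = float(stats.chi2.sf(chi2, k - 1))
    return FriedmanResult(
        f_statistic=float(f), df1=df1, df2=df2, p_value=p,
        chi2=float(chi2), chi2_df=k - 1, chi2_p=chi2_p,
        n_blocks=n, n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# correlations and level comparisons


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> Tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal length with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


@dataclass
class LevelComparison:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    pairs: pd.DataFrame
    excluded_levels: List[int] = field(default_factory=list)


def compare_levels(
    scores: Sequence[float],
    levels: Sequence[int],
    alpha: float = 0.05,
) -> LevelComparison:
    """One-way fixed-effects ANOVA over score levels plus Tukey-Kramer pairs.

    Levels with fewer than two feet are excluded (and reported).  The
    Tukey-Kramer studentized-range procedure handles unequal group sizes;
    with equal sizes it reduces to the classic Tukey HSD.
    """
    scores = np.asarray(scores, dtype=float)
    levels = np.asarray(levels)
    if scores.shape != levels.shape:
        raise ValueError("scores and levels must align")
    uniq, counts = np.unique(levels, return_counts=True)
    excluded = [int(u) for u, c in zip(uniq, counts) if c < 2]
    keep = ~np.isin(levels, excluded) & ~np.isnan(scores)
    scores, levels = scores[keep], levels[keep]
    groups = [scores[levels == u] for u in np.unique(levels)]
    if len(groups) < 2:
        raise ValueError("need at least two levels with two or more feet")
    f, p = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tk = pairwise_tukeyhsd(scores, levels, alpha=alpha)
    pairs = pd.DataFrame(
        data=tk.summary().data[1:], columns=tk.summary().data[0]
    )
    df1 = len(groups) - 1
    df2 = scores.size - len(groups)
    return LevelComparison(
        f_statistic=float(f), df1=df1, df2=df2, p_value=float(p),
        pairs=pairs, excluded_levels=excluded,
    )
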