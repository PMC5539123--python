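"""The SI₅₀ population index.

Cross-compatibility scores of a group of crosses are not normally
distributed, but their quantile plot traces a sigmoid.  The index
summarises a score set by fitting a four-parameter logistic

    Y = A + (B − A) / (1 + exp((D − x) / C))

to the quantile series, where x is the quantile coordinate, Y the
(augmented) score, A and B the lower and upper asymptotes, C a scaling
parameter and D the inflection point.  D is reported as SI₅₀ — the
quantile at which half the compatibility reactions are half-compatible —
by analogy with the LD₅₀ of toxicology.  Low SI₅₀ means a mostly
compatible group of crosses; high SI₅₀ a mostly incompatible one.

Two preprocessing steps anchor the fit: every score is incremented by one
(zero is awkward for the model), and 100 artificial points are appended on
each side of the quantile axis (x = −100…−1 at the bottom score, x =
101…200 at the top) to pin the asymptotes at A ≈ 1 and B ≈ 11.  The
reported R² uses the real points only, with the score deviations in the
denominator:  R² = 1 − Σr² / Σ(x − x̄)².  That denominator makes it a
nonstandard R² which can go negative for bad fits; it is kept as defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from sicomp.diallel import DiallelMatrix, subset_scores
from sicomp.errors import (
    NoInflectionError,
    UndefinedRSquaredError,
    ValidationError,
)

logger = logging.getLogger(__name__)

N_ANCHOR = 100  # artificial points per side


@dataclass
class QuantileSeries:
    """Sorted augmented scores on the quantile axis plus asymptote anchors.

    Real points sit at x_i = i/(n+1) with y = score + 1 ∈ [1, 11];
    artificial points sit at x = −100…−1 (y = 1) and x = 101…200 (y = 11).
    """

    x: np.ndarray
    y: np.ndarray
    is_artificial: np.ndarray

    @property
    def n_real(self) -> int:
        return int((~self.is_artificial).sum())

    @property
    def x_real(self) -> np.ndarray:
        return self.x[~self.is_artificial]

    @property
    def y_real(self) -> np.ndarray:
        return self.y[~self.is_artificial]

    @property
    def has_anchors(self) -> bool:
        art_x = self.x[self.is_artificial]
        return bool(len(art_x) and art_x.min() < 0 and art_x.max() > 100)


@dataclass
class QuantileCurveFit:
    """Four-parameter logistic fit; ``d`` (the inflection) is the SI₅₀."""

    a: float
    b: float
    c: float
    d: float
    r_squared: float
    converged: bool
    n_iterations: int

    @property
    def si50(self) -> float:
        return self.d


def logistic4(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a + (b - a) / (1.0 + np.exp(np.clip((d - x) / c, -700, 700)))


def build_quantile_series(scores) -> QuantileSeries:
    """Sort scores ascending onto the quantile grid i/(n+1) and append the
    asymptote anchors."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValidationError("need at least 2 scores to build a quantile series")
    if np.any(np.isnan(scores)) or np.any((scores < 0) | (scores > 10)):
        raise ValidationError("scores must be non-missing values in [0, 10]")
    s = np.sort(scores)
    n = len(s)
    x_real = np.arange(1, n + 1) / (n + 1)
    y_real = s + 1.0
    x_lo = np.arange(-N_ANCHOR, 0, dtype=float)
    x_hi = np.arange(101, 101 + N_ANCHOR, dtype=float)
    x = np.concatenate([x_lo, x_real, x_hi])
    y = np.concatenate([np.ones(N_ANCHOR), y_real, np.full(N_ANCHOR, 11.0)])
    art = np.concatenate(
        [np.ones(N_ANCHOR, bool), np.zeros(n, bool), np.ones(N_ANCHOR, bool)]
    )
    return QuantileSeries(x=x, y=y, is_artificial=art)


def _self_start(series: QuantileSeries) -> np.ndarray:
    xr, yr = series.x_real, series.y_real
    a0, b0 = float(series.y.min()), float(series.y.max())
    med = np.median(yr)
    d0 = float(xr[np.argmin(np.abs(yr - med))])
    c0 = float((xr.max() - xr.min()) / 4) or 0.05
    return np.array([a0, b0, c0, d0])


def fit_si50(series: QuantileSeries, max_iter: int = 200) -> QuantileCurveFit:
    """Unweighted nonlinear least squares (Levenberg–Marquardt) for the
    four-parameter logistic on an anchored quantile series.

    Non-convergence is flagged on the result rather than raised; a series
    whose real scores are all identical has no inflection and raises.
    """
    if not series.has_anchors:
        raise ValidationError("series lacks asymptote anchors; use build_quantile_series")
    if np.ptp(series.y_real) == 0:
        raise NoInflectionError("all real scores identical: no inflection to fit")

    x, y = series.x, series.y

    def resid(p):
        return logistic4(x, *p) - y

    p0 = _self_start(series)
    sol = least_squares(
        resid, p0, method="lm", xtol=1e-8, ftol=1e-8, gtol=1e-8,
        max_nfev=max_iter * 5,
    )
    a, b, c, d = sol.x
    converged = bool(sol.status > 0)
    fit = QuantileCurveFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        r_squared=np.nan, converged=converged, n_iterations=int(sol.nfev),
    )
    try:
        fit.r_squared = r_squared(fit, series)
    except UndefinedRSquaredError:
        pass
    return fit


def r_squared(fit: QuantileCurveFit, series: QuantileSeries) -> float:
    """R² over the real points only: 1 − Σr²/Σ(x − x̄)², with r the
    residuals from the fitted curve and x the cross scores."""
    yr, xr = series.y_real, series.x_real
    denom = float(np.sum((yr - yr.mean()) ** 2))
    if denom == 0:
        raise UndefinedRSquaredError("all real scores identical: R² undefined")
    res = yr - logistic4(xr, fit.a, fit.b, fit.c, fit.d)
    return 1.0 - float(np.sum(res**2)) / denom


def group_si50(
    m: DiallelMatrix,
    min_scores: int = 10,
    include_selfs: bool = False,
) -> pd.DataFrame:
    """SI₅₀ table over every ordered family pair of a diallel.

    One four-parameter logistic fit per (♀ family, ♂ family) score set
    (selfs excluded by default).  Groups below the score floor or with
    constant scores are skipped with a logged reason.  Columns:
    family_female, family_male, n, si50, a, b, c, r_squared, converged.
    """
    fams = sorted(m.family_set)
    rows = []
    for fa in fams:
        for fb in fams:
            scores = subset_scores(m, fa, fb, include_selfs=include_selfs)
            if len(scores) < min_scores:
                logger.info(
                    "si50 group (%s, %s) skipped: %d scores < floor %d",
                    fa, fb, len(scores), min_scores,
                )
                continue
            series = build_quantile_series(scores)
            try:
                fit = fit_si50(series)
            except NoInflectionError:
                logger.info(
                    "si50 group (%s, %s) skipped: constant scores", fa, fb
                )
                continue
            rows.append(
                (fa, fb, len(scores), fit.d, fit.a, fit.b, fit.c,
                 fit.r_squared, fit.converged)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family_female", "family_male", "n", "si50", "a", "b", "c",
            "r_squared", "converged",
        ],
    )
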