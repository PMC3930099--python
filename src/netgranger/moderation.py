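"""Moderated regression of executive function on network coupling.

The model is ordinary least squares

    y = b0 + b1 * x + b2 * m + b3 * (x * m) + e

with y the executive-function score, x a per-subject GPDC summary and m a
perinatal moderator (gestational age or the 0/1/2 ultrasound code; the two
are collinear, so they are analysed one at a time).  Inference on each
coefficient uses percentile bootstrap confidence intervals over subject
resamples at a Bonferroni-corrected level (alpha = .025 for the two
moderators).  Simple slopes dy/dx = b1 + b3 * m0 are reported at chosen
moderator levels with delta-method standard errors, alongside
median-split stratified refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "ModerationModel",
    "SimpleSlope",
    "fit_moderation",
    "bootstrap_ci",
    "simple_slopes",
    "stratified_slopes",
]

TERM_NAMES = ("intercept", "x", "m", "x:m")
MODERATION_ALPHA = 0.025  # .05 Bonferroni-corrected for two perinatal moderators


@dataclass(frozen=True)
class ModerationModel:
    """OLS fit of y ~ 1 + x + m + x*m with optional bootstrap CIs."""

    coefficients: np.ndarray  # (4,) in TERM_NAMES order
    standard_errors: np.ndarray
    covariance: np.ndarray = field(repr=False)
    n: int
    centered: bool = False
    n_boot: int = 0
    alpha: float = MODERATION_ALPHA
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    @property
    def terms(self) -> tuple[str, ...]:
        return TERM_NAMES

    def significant(self) -> np.ndarray:
        """Per-term flag: bootstrap CI excludes zero."""
        if self.ci_lower is None:
            raise ValueError("no bootstrap CIs attached; run bootstrap_ci first")
        return (self.ci_lower > 0) | (self.ci_upper < 0)


@dataclass(frozen=True)
class SimpleSlope:
    m_level: float
    slope: float
    standard_error: float


def _design(x: np.ndarray, m: np.ndarray, centered: bool) -> np.ndarray:
    if centered:
        x = x - x.mean()
        m = m - m.mean()
    return np.column_stack([np.ones_like(x), x, m, x * m])


def _check_design(x: np.ndarray, m: np.ndarray) -> None:
    if np.ptp(x) == 0.0:
        raise ValueError("predictor x is constant: effect unidentifiable")
    if np.ptp(m) == 0.0:
        raise ValueError("moderator m is constant: interaction unidentifiable")


def fit_moderation(
    y: np.ndarray, x: np.ndarray, m: np.ndarray, centered: bool = False
) -> ModerationModel:
    """OLS point fit with classical standard errors.

    Predictors are not mean-centred before forming the interaction unless
    ``centered=True`` (centring changes the interpretation of b1/b2 to
    effects at the mean of the other predictor; b3 is unaffected).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    if y.size != x.size or y.size != m.size:
        raise ValueError("y, x and m must have equal length")
    if y.size < 10:
        raise ValueError("need at least 10 complete observations")
    if np.any(~np.isfinite(np.concatenate([y, x, m]))):
        raise ValueError("missing or non-finite values are not allowed")
    _check_design(x, m)
    X = _design(x, m, centered)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: x, m and x:m are not jointly identifiable")
    res = sm.OLS(y, X).fit()
    return ModerationModel(
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        covariance=np.asarray(res.cov_params()),
        n=int(y.size),
        centered=centered,
    )


def bootstrap_ci(
    y: np.ndarray,
    x: np.ndarray,
    m: np.ndarray,
    n_boot: int = 1000,
    alpha: float = MODERATION_ALPHA,
    seed: int | None = None,
    centered: bool = False,
) -> ModerationModel:
    """Percentile bootstrap CIs for all four coefficients.

    Subjects are resampled with replacement ``n_boot`` times and the OLS
    refit on each resample; per-coefficient CIs take the alpha/2 and
    1 - alpha/2 percentiles.  The reported standard errors are the
    bootstrap standard deviations.  Collinear resamples are skipped and
    counted; more than 10% skips raises a warning.
    """
    point = fit_moderation(y, x, m, centered=centered)
    y = np.asarray(y, dtype=float)
    X = _design(np.asarray(x, dtype=float), np.asarray(m, dtype=float), centered)
    n = y.size
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 4))
    kept = 0
    skipped = 0
    while kept < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        # normal-equations solve; singular resample -> skip
        XtX = Xb.T @ Xb
        try:
            beta = np.linalg.solve(XtX, Xb.T @ y[idx])
        except np.linalg.LinAlgError:
            skipped += 1
            if skipped > 10 * n_boot:
                raise RuntimeError("bootstrap cannot find non-singular resamples")
            continue
        if not np.all(np.isfinite(beta)) or np.linalg.cond(XtX) > 1e12:
            skipped += 1
            continue
        draws[kept] = beta
        kept += 1
    if skipped > 0.1 * n_boot:
        warnings.warn(
            f"{skipped} collinear bootstrap resamples skipped (> 10%)", stacklevel=2
        )
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return ModerationModel(
        coefficients=point.coefficients,
        standard_errors=draws.std(axis=0, ddof=1),
        covariance=point.covariance,
        n=point.n,
        centered=centered,
        n_boot=n_boot,
        alpha=alpha,
        ci_lower=lo,
        ci_upper=hi,
    )


def simple_slopes(model: ModerationModel, m_levels: np.ndarray) -> list[SimpleSlope]:
    """Slope of y on x at given moderator levels: b1 + b3 * m0.

    The delta-method standard error is
    sqrt(var(b1) + m0^2 var(b3) + 2 m0 cov(b1, b3)) from the classical
    coefficient covariance.
    """
    b = model.coefficients
    cov = model.covariance
    out = []
    for m0 in np.atleast_1d(np.asarray(m_levels, dtype=float)):
        slope = b[1] + b[3] * m0
        var = cov[1, 1] + m0**2 * cov[3, 3] + 2 * m0 * cov[1, 3]
        out.append(SimpleSlope(float(m0), float(slope), float(np.sqrt(max(var, 0.0)))))
    return out


def stratified_slopes(
    y: np.ndarray, x: np.ndarray, m: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Median-split stratified refits: slope of y on x within each stratum.

    Returns {"low": (slope, se), "high": (slope, se)} for subjects below /
    at-or-above the moderator median.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    cut = np.median(m)
    out = {}
    for name, sel in (("low", m < cut), ("high", m >= cut)):
        if sel.sum() < 3 or np.ptp(x[sel]) == 0.0:
            raise ValueError(f"stratum {name!r} too small or degenerate for a slope")
        X = np.column_stack([np.ones(sel.sum()), x[sel]])
        res = sm.OLS(y[sel], X).fit()
        out[name] = (float(res.params[1]), float(res.bse[1]))
    return out
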