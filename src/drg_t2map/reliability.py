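"""Reliability via the intraclass correlation coefficient.

Inter-rater and test–retest reliability are both expressed as ICC(2,1):
two-way random effects, absolute agreement, single measurement, with the
F-based 95% confidence interval of McGraw & Wong and the Koo–Li qualitative
bins (poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ICCResult", "icc_two_way_agreement", "test_retest_icc", "interpret_icc"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model_descriptor: str
    n_targets: int
    n_raters: int
    interpretation: str
    small_sample_warning: bool = False


def interpret_icc(icc: float) -> str:
    """Koo–Li bins, right-open at the cut-points 0.5 / 0.75 / 0.9."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def _mean_squares(x: np.ndarray):
    """Two-way ANOVA mean squares of a complete targets × raters table."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_agreement(
    ratings, alpha: float = 0.05, model: str = "agreement"
) -> ICCResult:
    """ICC(2,1) of a complete targets × raters matrix.

    Rows with missing cells are dropped first (listwise deletion, logged).
    ``model="consistency"`` computes ICC(3,1) instead — used for diagnostics
    such as separating a constant shift between visits from true disagreement.
    """
    x = np.asarray(pd.DataFrame(ratings).dropna(), dtype=float)
    n_dropped = len(np.asarray(ratings)) - len(x)
    if n_dropped:
        log.info("ICC: dropped %d incomplete target(s)", n_dropped)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a 2D matrix with >= 2 raters")
    n, k = x.shape
    small = n < 5
    if small:
        warnings.warn("fewer than 5 targets; ICC is unstable", stacklevel=2)
    if n < 2:
        raise ValueError("need at least 2 targets")

    msr, msc, mse = _mean_squares(x)
    if np.isclose(msr, 0) and np.isclose(msc, 0) and np.isclose(mse, 0):
        raise ValueError("degenerate ratings: zero variance across targets and raters")

    if model not in ("agreement", "consistency"):
        raise ValueError("model must be 'agreement' or 'consistency'")

    with np.errstate(divide="ignore", invalid="ignore"):  # mse = 0 handled below
        if model == "consistency":
            icc = (msr - mse) / (msr + (k - 1) * mse)
            # CI for ICC(3,1) (McGraw-Wong F-based).
            f_obs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
            descriptor = "two-way mixed, consistency, single measurement"
        else:
            icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            # McGraw-Wong CI for ICC(A,1): Satterthwaite df for the lower tail.
            f3k = msc / mse if mse > 0 else np.inf
            a = n * (1 + (k - 1) * icc) - k * icc
            vn = (k - 1) * (n - 1) * (k * icc * f3k + a) ** 2
            vd = (n - 1) * k**2 * icc**2 * f3k**2 + a**2
            v = vn / vd if vd > 0 else np.inf
            f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f2u * mse) / (
                f2u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f2l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2l * msr
            )
            descriptor = "two-way random, absolute agreement, single measurement"

    # Perfect-fit degeneracy (mse = 0): the F construction collapses; pin the
    # interval to the point estimate.
    lo = lo if np.isfinite(lo) else icc
    hi = hi if np.isfinite(hi) else icc
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ICCResult(
        icc=float(icc),
        ci_low=lo,
        ci_high=hi,
        model_descriptor=descriptor,
        n_targets=n,
        n_raters=k,
        interpretation=interpret_icc(float(icc)),
        small_sample_warning=small,
    )


def test_retest_icc(visit1, visit2, alpha: float = 0.05) -> ICCResult:
    """Test–retest ICC: the two visits act as the 'raters' of each subject."""
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("visit1 and visit2 must be paired 1D arrays")
    return icc_two_way_agreement(np.column_stack([v1, v2]), alpha=alpha)
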