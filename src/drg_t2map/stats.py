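"""Cohort-level nonparametric statistics.

The battery mirrors a standard clinical-imaging analysis: Lilliefors-corrected
Kolmogorov–Smirnov normality screening, Mann–Whitney U for independent groups,
Wilcoxon signed-rank for paired contrasts (e.g. S1 vs L5 within subject),
chi-squared / Fisher's exact for categoricals, Spearman rank correlations, and
median (IQR) descriptive tables with signed percent differences.

Exact p-values are used on the small-sample, tie-free paths where enumeration
is the reference behaviour; otherwise tie- and continuity-corrected normal
approximations apply.  Each result records which path was taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TestResult",
    "ks_normality",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "categorical_test",
    "spearman_rho",
    "percent_difference",
    "build_cohort_tables",
]

#: Combined sample size at or below which tie-free rank tests use exact enumeration.
EXACT_N_MAX = 12


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method_detail: str
    flags: tuple[str, ...] = field(default_factory=tuple)


def ks_normality(values) -> TestResult:
    """One-sample KS test against a normal law with estimated mean/SD.

    Estimating the parameters from the sample makes the plain KS p-value
    anticonservative, so the Lilliefors correction is applied.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values")
    if np.std(x) == 0:
        raise ValueError("zero variance: normality test undefined")
    stat, p = lilliefors(x, dist="norm")
    return TestResult(
        "Kolmogorov-Smirnov (Lilliefors)",
        float(stat),
        float(p),
        (len(x),),
        "estimated-parameter null, Lilliefors-corrected p",
    )


def _has_ties(*groups) -> bool:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(group_a, group_b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U with midrank ties.

    Exact p by enumeration when ``n_a + n_b <= 12`` and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    exact = len(a) + len(b) <= EXACT_N_MAX and not _has_ties(a, b)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    detail = (
        "exact enumeration (no ties)"
        if exact
        else "normal approximation, tie + continuity corrections"
    )
    return TestResult(
        "Mann-Whitney U", float(res.statistic), float(res.pvalue), (len(a), len(b)), detail
    )


def wilcoxon_signed_rank(paired_a, paired_b, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank on paired samples.

    Zero differences are dropped (Wilcoxon's convention, recorded in the
    flags); exact p by exhaustive sign-flip enumeration when the retained n is
    <= 12 (enumeration is well defined under tied |differences|, where the
    tabulated null is not), else the continuity-corrected normal
    approximation.  All-zero differences are degenerate: p = 1 with a flag
    rather than an error.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n_zero = int(np.sum(d == 0))
    d_ret = d[d != 0]
    flags = tuple(f"dropped {n_zero} zero difference(s)" for _ in range(1) if n_zero)
    if len(d_ret) == 0:
        return TestResult(
            "Wilcoxon signed-rank",
            0.0,
            1.0,
            (len(a),),
            "degenerate: all differences zero",
            flags + ("degenerate",),
        )
    exact = len(d_ret) <= EXACT_N_MAX
    if exact:
        # Exhaustive sign-flip permutation: 2^n <= 4096 resamples.
        method = sps.PermutationMethod(n_resamples=2 ** len(d_ret))
        res = sps.wilcoxon(d_ret, alternative=alternative, method=method)
        detail = "exact sign-flip enumeration"
    else:
        res = sps.wilcoxon(
            d_ret,
            alternative=alternative,
            method="approx",
            correction=True,
            zero_method="wilcox",
        )
        detail = "normal approximation, continuity correction"
    return TestResult(
        "Wilcoxon signed-rank", float(res.statistic), float(res.pvalue), (len(a),), detail, flags
    )


def categorical_test(table) -> TestResult:
    """Chi-squared or Fisher's exact test of a contingency table.

    Fisher's exact (two-sided) is auto-selected for 2×2 tables with any
    expected cell below 5; otherwise Pearson chi-squared without Yates
    correction.  The rule applied is recorded in ``method_detail``.
    """
    t = np.asarray(table)
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not (np.issubdtype(t.dtype, np.floating) and np.all(t == np.floor(t)) and np.all(t >= 0)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    n_per_group = tuple(int(c) for c in t.sum(axis=1))
    expected = sps.contingency.expected_freq(t)
    if t.shape == (2, 2) and np.any(expected < 5):
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult(
            "Fisher exact",
            float(odds),
            float(p),
            n_per_group,
            "2x2 with expected cell < 5: Fisher two-sided (hypergeometric tails)",
        )
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(
        "chi-squared",
        float(chi2),
        float(p),
        n_per_group,
        f"Pearson chi-squared, no Yates correction, dof={dof}",
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation (Pearson of midranks), t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        "Spearman rho", float(rho), float(p), (len(x),), "t-approximation, n-2 df"
    )


def percent_difference(value_a: float, value_b: float) -> float:
    """Signed percent difference 100·(a − b)/b, rounded to one decimal."""
    if value_b <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (value_a - value_b) / value_b, 1)


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------


def _median_iqr(x: np.ndarray) -> str:
    # Linear-interpolation (type-7) percentiles, the numpy default.
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def build_cohort_tables(
    subjects: pd.DataFrame,
    grouping: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Stratified descriptive table with per-row hypothesis tests.

    ``grouping`` is ``"sex"`` (male vs female) or ``"mutation_class"``
    (classical vs nonclassical; VUS subjects are excluded from that
    contrast).  Continuous rows show median (IQR) per group with a
    Mann–Whitney test; categorical rows show n (%) with the auto-selected
    chi-squared / Fisher test.
    """
    if grouping == "sex":
        levels = ["male", "female"]
        df = subjects[subjects["sex"].isin(levels)]
        key = "sex"
    elif grouping == "mutation_class":
        levels = ["classical", "nonclassical"]
        df = subjects[subjects["mutation_class"].isin(levels)]
        key = "mutation_class"
    else:
        raise ValueError("grouping must be 'sex' or 'mutation_class'")
    groups = {lv: df[df[key] == lv] for lv in levels}
    for lv, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"group '{lv}' is empty")

    if continuous is None:
        skip = {"subject_id", key}
        continuous = [
            c
            for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        ]
    if categorical is None:
        categorical = [
            c
            for c in ("sex", "mutation_class")
            if c != key and c in df.columns
        ]

    rows = []
    for var in continuous:
        vals = {lv: groups[lv][var].dropna().to_numpy() for lv in levels}
        if any(len(v) == 0 for v in vals.values()):
            continue
        if all(np.all(v == next(iter(vals.values()))[0]) for v in vals.values()):
            res = TestResult("constant", np.nan, 1.0, tuple(len(v) for v in vals.values()), "no variation")
        else:
            res = mann_whitney_u(vals[levels[0]], vals[levels[1]])
        rows.append(
            {
                "variable": var,
                levels[0]: _median_iqr(vals[levels[0]]),
                levels[1]: _median_iqr(vals[levels[1]]),
                "test": res.test_name,
                "method": res.method_detail,
                "p_value": res.p_value,
            }
        )
    for var in categorical:
        cats = sorted(df[var].dropna().unique())
        for cat in cats:
            counts = [int((groups[lv][var] == cat).sum()) for lv in levels]
            others = [len(groups[lv]) - c for lv, c in zip(levels, counts)]
            table = np.array([[counts[0], others[0]], [counts[1], others[1]]])
            res = categorical_test(table)
            rows.append(
                {
                    "variable": f"{var}={cat}",
                    levels[0]: f"{counts[0]} ({100*counts[0]/len(groups[levels[0]]):.1f}%)",
                    levels[1]: f"{counts[1]} ({100*counts[1]/len(groups[levels[1]]):.1f}%)",
                    "test": res.test_name,
                    "method": res.method_detail,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
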