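"""Statistical contracts: group comparisons, viscosity regression,
orientation-distribution tests and summary reporting.

All routines wrap scipy.stats; this module fixes the conventions used
throughout the package (two-sided tests, significance at p < 0.05, exact
small-sample rank tests, the unit scale of the hematocrit–viscosity
regression).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import defaults
from .errors import DomainError

__all__ = [
    "ALPHA",
    "GroupSummary",
    "summarize_group",
    "compare_groups",
    "fit_viscosity_regression",
    "test_orientation_uniformity",
    "compare_orientation_distributions",
    "test_elongation",
]

ALPHA = 0.05

#: sample size at or below which rank tests use the exact null distribution;
#: above it the normal approximation with continuity correction is used
EXACT_N_MAX = 25


@dataclass(frozen=True)
class GroupSummary:
    """mean ± SD (and SEM = SD/√n) of one group."""

    label: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n) if self.n > 0 else math.nan


def summarize_group(values: Sequence[float], label: str = "") -> GroupSummary:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("cannot summarize an empty group")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return GroupSummary(label=label, n=int(x.size), mean=float(x.mean()), sd=sd)


def compare_groups(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U test between two independent groups.

    Exact null distribution for samples of at most 25 without ties,
    otherwise the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(x.size, y.size) <= EXACT_N_MAX and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return {
        "test": "mann-whitney",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < ALPHA),
        "method": "exact" if exact else "asymptotic",
    }


def fit_viscosity_regression(
    hematocrit: Sequence[float], eta_b_cp: Sequence[float]
) -> dict:
    """Ordinary least squares of whole-blood viscosity on hematocrit.

    The fit is done on the canonical scale — hematocrit as a fraction,
    viscosity in Pa·s — and also reported in cP per hematocrit fraction.
    Returns slope, intercept, r_squared and their standard errors.
    """
    ht = np.asarray(hematocrit, dtype=float)
    eta_pa_s = np.asarray(eta_b_cp, dtype=float) * defaults.CP_TO_PA_S
    if ht.size < 3:
        raise DomainError("regression needs at least 3 points")
    if np.ptp(ht) == 0:
        raise DomainError("hematocrit is constant; regression is degenerate")
    res = sps.linregress(ht, eta_pa_s)
    return {
        "slope_pa_s": float(res.slope),
        "intercept_pa_s": float(res.intercept),
        "slope_cp": float(res.slope / defaults.CP_TO_PA_S),
        "intercept_cp": float(res.intercept / defaults.CP_TO_PA_S),
        "r_squared": float(res.rvalue**2),
        "slope_stderr_pa_s": float(res.stderr),
        "n": int(ht.size),
    }


def test_orientation_uniformity(counts: Sequence[int]) -> dict:
    """χ² goodness-of-fit of orientation class counts against the
    equiprobable (one-third per class) null, df = len(counts) − 1."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise DomainError("total count must be positive")
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    res = sps.chisquare(counts)
    return {
        "test": "chi2-goodness-of-fit",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "df": int(counts.size - 1),
        "significant": bool(res.pvalue < ALPHA),
    }


def compare_orientation_distributions(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> dict:
    """Two-sample contingency χ² (e.g. male vs female class counts)."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    if table.sum() <= 0:
        raise DomainError("total count must be positive")
    stat, p, df, _ = sps.chi2_contingency(table)
    return {
        "test": "chi2-contingency",
        "statistic": float(stat),
        "p_value": float(p),
        "df": int(df),
        "significant": bool(p < ALPHA),
    }


def test_elongation(elongations: Sequence[float], null_value: float = 1.0) -> dict:
    """Two-sided one-sample Wilcoxon signed-rank test of nucleus elongation
    against 1 (a circular nucleus).

    Exact null distribution for n ≤ 25, normal approximation with
    continuity correction above. If every value equals the null exactly
    the statistic is undefined; the result is reported as non-significant
    (p = 1) with a warning.
    """
    e = np.asarray(elongations, dtype=float)
    if e.size == 0:
        raise DomainError("need at least one elongation value")
    diffs = e - null_value
    if np.all(diffs == 0):
        warnings.warn(
            "all elongations equal the null value; Wilcoxon statistic is "
            "undefined — reporting p = 1",
            stacklevel=2,
        )
        return {
            "test": "wilcoxon-signed-rank",
            "statistic": math.nan,
            "p_value": 1.0,
            "significant": False,
            "method": "degenerate",
        }
    method = "exact" if e.size <= EXACT_N_MAX else "approx"
    res = sps.wilcoxon(
        diffs, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return {
        "test": "wilcoxon-signed-rank",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < ALPHA),
        "method": method,
    }
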