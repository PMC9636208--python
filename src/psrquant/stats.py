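"""Validation statistics: Spearman correlation, Fisher z, comparison of two
dependent correlations sharing a reference variable, and OLS regression.

The central question these statistics answer: does image-based CPA track liver
fibrosis at least as well as the biochemical hydroxyproline (HYP) assay, taking
the histopathological stage as the reference?  Because CPA and HYP are measured
on the *same* animals, the two correlations (stage-vs-CPA and stage-vs-HYP) are
dependent, and the default comparison is Steiger's Z for dependent correlations
— it corrects the Fisher-z difference for the CPA-HYP correlation ``r23``.  The
naive independent-samples Fisher Z is exposed as an explicit variant for
comparison; applied to Spearman coefficients, both follow common practice for
rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import SYSTEM_NAMES, get_system

__all__ = [
    "CorrelationResult", "DependentCorrelationComparison", "RegressionResult",
    "spearman", "fisher_z", "compare_dependent_correlations", "linreg_r2",
    "correlation_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    method: str
    p_two_sided: float


@dataclass(frozen=True)
class DependentCorrelationComparison:
    """Comparison of r12 (reference vs A) and r13 (reference vs B) on one sample.

    ``r23`` is the A-B correlation; ``variant`` records whether the dependence
    correction (Steiger) or the naive independent-samples statistic was used.
    """

    r12: float
    r13: float
    r23: float
    n: int
    z_stat: float
    p_one_sided: float
    variant: str
    alternative: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def _clean_pairs(x, y):
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mean ranks for ties.

    Pairs with missing values are removed; p is the two-sided t approximation
    ``t = r * sqrt((n-2) / (1-r^2))``.  Constant inputs raise ``ValueError``.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    return CorrelationResult(r=float(res.statistic), n=n, method="spearman",
                             p_two_sided=float(res.pvalue))


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform ``z = atanh(r) = 0.5 ln((1+r)/(1-r))``."""
    r = float(r)
    if not abs(r) < 1.0:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return float(np.arctanh(r))


def compare_dependent_correlations(r12: float, r13: float, r23: float, n: int,
                                   alternative: str = "greater",
                                   variant: str = "steiger_dependent",
                                   ) -> DependentCorrelationComparison:
    """Test r12 vs r13, correlations sharing variable 1 on the same n subjects.

    Default ``steiger_dependent``:

        z = (z12 - z13) * sqrt((n-3) / (2 (1 - s)))

    with ``s = psi / (1 - rbar^2)^2``, ``psi = r23 (1 - 2 rbar^2)
    - rbar^2 (1 - 2 rbar^2 - r23^2) / 2`` and ``rbar = (r12 + r13)/2``.
    ``fisher_independent`` ignores the dependence:
    ``z = (z12 - z13) / sqrt(2/(n-3))``.

    ``alternative='greater'`` gives the upper-tail one-sided p for r12 > r13.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not abs(r) < 1.0:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    dz = fisher_z(r12) - fisher_z(r13)
    if variant == "steiger_dependent":
        rbar = (r12 + r13) / 2.0
        psi = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
        s = psi / (1.0 - rbar**2) ** 2
        z = dz * np.sqrt((n - 3.0) / (2.0 * (1.0 - s)))
    elif variant == "fisher_independent":
        z = dz / np.sqrt(2.0 / (n - 3.0))
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return DependentCorrelationComparison(r12=r12, r13=r13, r23=r23, n=int(n),
                                          z_stat=float(z), p_one_sided=p,
                                          variant=variant, alternative=alternative)


def linreg_r2(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; r² is the squared Pearson correlation."""
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]):
        raise ValueError("regression undefined for constant x")
    if np.all(y == y[0]):  # flat response: zero slope, nothing explained
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=n)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), n=n)


def correlation_report(cohort: pd.DataFrame,
                       cpa_col: str = "mean_cpa",
                       hyp_col: str = "hyp_ug_per_g",
                       substage_coding: str = "collapse",
                       alternative: str = "greater",
                       variant: str = "steiger_dependent",
                       ) -> Dict[str, object]:
    """Full validation report for an animal-level cohort table.

    For every staging-system column present (``ishak``, ``ishak_modified``,
    ``nash_crn``): Spearman r of stage-vs-CPA and stage-vs-HYP, the CPA-vs-HYP
    r23, and the dependent-correlation Z with its one-sided p (stage as the
    reference).  Also reports the overall CPA-vs-HYP correlation, and the
    20X-on-40X OLS regression when ``cpa_20x``/``cpa_40x`` columns are present.

    Returns ``{"per_system": DataFrame[system, r_CPA, r_HYP, r23, n, Z,
    p_one_sided], "cpa_vs_hyp": CorrelationResult, "regression_20x_40x":
    RegressionResult | None}``.
    """
    if len(cohort) < 4:
        raise ValueError(f"need at least 4 animals, got {len(cohort)}")
    if cpa_col not in cohort or hyp_col not in cohort:
        raise ValueError(f"cohort table must contain {cpa_col!r} and {hyp_col!r}")

    cpa = cohort[cpa_col].to_numpy(float)
    hyp = cohort[hyp_col].to_numpy(float)
    cpa_hyp = spearman(cpa, hyp)

    rows = []
    for system in SYSTEM_NAMES:
        if system not in cohort.columns:
            continue
        sysobj = get_system(system, substage_coding)
        score = np.array([sysobj.encode(lab) for lab in cohort[system].astype(str)])
        r12 = spearman(score, cpa)
        r13 = spearman(score, hyp)
        n = min(r12.n, r13.n)
        if max(abs(r12.r), abs(r13.r), abs(cpa_hyp.r)) >= 1.0:
            # perfect correlation: Fisher z diverges, comparison undefined
            z_stat, p = float("nan"), float("nan")
        else:
            comp = compare_dependent_correlations(r12.r, r13.r, cpa_hyp.r, n,
                                                  alternative=alternative, variant=variant)
            z_stat, p = comp.z_stat, comp.p_one_sided
        rows.append({"system": system, "r_CPA": r12.r, "r_HYP": r13.r,
                     "r23": cpa_hyp.r, "n": n, "Z": z_stat,
                     "p_one_sided": p})
    per_system = pd.DataFrame(rows, columns=["system", "r_CPA", "r_HYP", "r23",
                                             "n", "Z", "p_one_sided"])

    regression = None
    if "cpa_20x" in cohort.columns and "cpa_40x" in cohort.columns:
        regression = linreg_r2(cohort["cpa_40x"].to_numpy(float),
                               cohort["cpa_20x"].to_numpy(float))
    return {"per_system": per_system, "cpa_vs_hyp": cpa_hyp,
            "regression_20x_40x": regression}
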