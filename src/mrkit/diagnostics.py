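"""Heterogeneity, pleiotropy and influence diagnostics, plus FDR.

* Cochran's Q about the IVW fit (df = J−1) and Rücker's Q′ about the Egger
  fit (df = J−2) quantify between-instrument heterogeneity of the Wald
  ratios; large values indicate pleiotropy or other model violations.
* The MR-Egger intercept test detects *directional* (unbalanced)
  pleiotropy.
* Leave-one-out re-estimation detects single variants that drive the
  pooled estimate; a configurable influence rule turns the visual check
  into a reproducible flag.
* Benjamini–Hochberg q-values adjust the family of primary tests for
  multiple testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate, RatioEstimate, ivw
from .harmonize import HarmonizedSet

logger = logging.getLogger("mrkit")

#: Default influence rule: flag a variant when omitting it moves the IVW
#: estimate by more than this many full-sample SEs.
DEFAULT_FLAG_RULE = 1.0


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "IVW" or "Egger"
    Q: float
    df: int
    pvalue: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("heterogeneity test needs df >= 1")


@dataclass(frozen=True)
class InterceptTest:
    """MR-Egger intercept (log-odds units), its SE and two-sided p-value."""

    intercept: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Per-omitted-variant IVW re-estimates plus the all-variant estimate."""

    table: pd.DataFrame  # columns: variant_id, beta, se, ci_low, ci_high
    full: MREstimate


@dataclass(frozen=True)
class OutlierFlags:
    by_delta: tuple[str, ...]   # |beta_-v − beta_full| > rule × se_full
    by_ci: tuple[str, ...]      # omission changes whether the 95% CI excludes 0
    flagged: tuple[str, ...]    # union, sorted


def cochran_q(hset: HarmonizedSet, ivw_beta: float) -> HeterogeneityResult:
    """Q = Σ w_j (Γ̂_j − β γ̂_j)², w_j = 1/σ_Yj²; chi-square with J−1 df."""
    J = len(hset)
    if J < 2:
        raise ValueError("Cochran's Q requires >=2 instruments")
    g = np.array([i.gamma for i in hset.instruments])
    G = np.array([i.Gamma for i in hset.instruments])
    w = 1.0 / np.array([i.sigma_y for i in hset.instruments]) ** 2
    Q = float(np.sum(w * (G - ivw_beta * g) ** 2))
    df = J - 1
    return HeterogeneityResult("IVW", Q, df, float(stats.chi2.sf(Q, df)) or 5e-324)


def rucker_q(hset: HarmonizedSet, egger_fit: MREstimate) -> HeterogeneityResult:
    """Q′ about the Egger line (intercept + slope); chi-square with J−2 df.

    Uses the Q′ already computed by the Egger fit when available, so the
    statistic always refers to the same oriented instruments the fit used.
    """
    J = len(hset)
    if J < 3:
        raise ValueError("Rucker's Q' requires >=3 instruments")
    if egger_fit.n_variants != J:
        raise ValueError("egger_fit was computed on a different instrument set")
    Qp = float(egger_fit.extras["Q_prime"])
    df = J - 2
    return HeterogeneityResult("Egger", Qp, df, float(stats.chi2.sf(Qp, df)) or 5e-324)


def intercept_test(egger_fit: MREstimate) -> InterceptTest:
    ex = egger_fit.extras
    return InterceptTest(
        intercept=float(ex["intercept"]),
        se=float(ex["intercept_se"]),
        pvalue=float(ex["intercept_p"]),
    )


def leave_one_out(hset: HarmonizedSet, estimator=ivw, **estimator_kwargs) -> LeaveOneOutResult:
    """Re-estimate J times, each omitting one instrument (IVW by default).

    Rows are ordered by variant_id for deterministic output.
    """
    J = len(hset)
    if J < 3:
        raise ValueError("leave-one-out requires >=3 instruments")
    full = estimator(hset, **estimator_kwargs)
    rows = []
    for vid in sorted(i.variant_id for i in hset.instruments):
        est = estimator(hset.without([vid]), **estimator_kwargs)
        rows.append(
            {
                "variant_id": vid,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return LeaveOneOutResult(table=pd.DataFrame(rows), full=full)


def flag_outliers(loo: LeaveOneOutResult, rule: float = DEFAULT_FLAG_RULE) -> OutlierFlags:
    """Flag influential variants from a leave-one-out analysis.

    Two criteria, reported separately and combined: (1) omitting the
    variant shifts the estimate by more than ``rule`` × the full-sample SE;
    (2) omitting it changes whether the 95% CI excludes zero.

    The influence scale in (1) is the full fit's *fixed-effect* SE (its
    instrument precision).  A random-effects SE would itself be inflated
    by the heterogeneity the outliers create, letting strong outliers mask
    their own influence.
    """
    beta_full = loo.full.beta
    se_full = float(loo.full.extras.get("se_fixed", loo.full.se))
    excl_full = loo.full.ci_low > 0 or loo.full.ci_high < 0
    by_delta, by_ci = [], []
    for r in loo.table.itertuples(index=False):
        if abs(r.beta - beta_full) > rule * se_full:
            by_delta.append(r.variant_id)
        if (r.ci_low > 0 or r.ci_high < 0) != excl_full:
            by_ci.append(r.variant_id)
    flagged = tuple(sorted(set(by_delta) | set(by_ci)))
    if flagged:
        logger.info("flag_outliers: %s", ", ".join(flagged))
    return OutlierFlags(tuple(by_delta), tuple(by_ci), flagged)


@dataclass(frozen=True)
class FunnelData:
    """Plot-ready funnel data: per-variant ratio vs precision, with the
    pooled estimates as vertical reference lines."""

    points: pd.DataFrame       # variant_id, ratio, precision
    references: pd.DataFrame   # method, beta

    def to_frame(self) -> pd.DataFrame:
        refs = pd.DataFrame(
            {
                "variant_id": "ref:" + self.references["method"],
                "ratio": self.references["beta"],
                "precision": np.nan,
            }
        )
        return pd.concat([self.points, refs], ignore_index=True)


def funnel_data(
    ratios: list[RatioEstimate], reference_betas: dict[str, float] | None = None
) -> FunnelData:
    """One (ratio, precision = 1/ratio_se) row per variant; no rendering."""
    if not ratios:
        raise ValueError("funnel_data requires at least one ratio")
    points = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "precision": [1.0 / r.ratio_se for r in ratios],
        }
    )
    refs = pd.DataFrame(
        list((reference_betas or {}).items()), columns=["method", "beta"]
    )
    return FunnelData(points=points, references=refs)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values for one family of tests."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_adjust requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
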