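"""Causal-effect estimators for two-sample Mendelian randomisation.

Given harmonized per-variant pairs (γ̂_j, σ_Xj, Γ̂_j, σ_Yj), each estimator
returns the causal log-odds ratio per SD of the exposure:

* ``ivw`` — inverse-variance-weighted estimate, equivalent to weighted
  least squares of Γ̂ on γ̂ through the origin with weights 1/σ_Yj²; under
  the multiplicative random-effects model the SE is inflated by
  max(1, sqrt(Q/(J−1))).
* ``egger`` — weighted regression of Γ̂ on γ̂ *with* an intercept, the
  intercept estimating the average directional pleiotropy; instruments are
  oriented γ̂_j ≥ 0 first, inference uses the t distribution with J−2 df
  and multiplicative SE inflation by max(1, sqrt(Q′/(J−2))).
* ``weighted_median`` — the 50% point of the inverse-variance-weighted
  empirical distribution of the per-variant Wald ratios; consistent when
  less than half the weight comes from invalid instruments; SE by seeded
  parametric bootstrap.
* ``weighted_mode`` — the maximum of a weighted normal-kernel density of
  the Wald ratios (bandwidth = phi × a modified Silverman rule using the
  median absolute deviation); consistent when the largest cluster of
  instruments is valid; SE by seeded parametric bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet, orient_positive

logger = logging.getLogger("mrkit")

#: Instruments with |γ̂_j| below this floor are excluded from ratio-based
#: computation (they would produce unbounded Wald ratios).
WEAK_GAMMA_FLOOR = 1e-6

#: Grid resolution for the mode estimator's density argmax.
MODE_GRID_SIZE = 10_000

_TINY_P = 5e-324  # smallest subnormal double; keeps p-values in (0, 1]


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio β̂_j = Γ̂_j/γ̂_j with first-order SE σ_Yj/|γ̂_j|."""

    variant_id: str
    ratio: float
    ratio_se: float

    @property
    def weight(self) -> float:
        return 1.0 / self.ratio_se**2


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds-per-SD scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


def _arrays(hset: HarmonizedSet, min_gamma: float = WEAK_GAMMA_FLOOR):
    g = np.array([i.gamma for i in hset.instruments], dtype=float)
    sx = np.array([i.sigma_x for i in hset.instruments], dtype=float)
    G = np.array([i.Gamma for i in hset.instruments], dtype=float)
    sy = np.array([i.sigma_y for i in hset.instruments], dtype=float)
    ids = np.array([i.variant_id for i in hset.instruments])
    keep = np.abs(g) >= min_gamma
    n_weak = int((~keep).sum())
    if n_weak:
        logger.warning(
            "excluding %d instrument(s) with |gamma| < %g: %s",
            n_weak,
            min_gamma,
            ", ".join(ids[~keep]),
        )
    return ids[keep], g[keep], sx[keep], G[keep], sy[keep]


def wald_ratios(hset: HarmonizedSet, min_gamma: float = WEAK_GAMMA_FLOOR) -> list[RatioEstimate]:
    """Per-variant causal-effect ratios; weak instruments are excluded."""
    ids, g, _, G, sy = _arrays(hset, min_gamma)
    return [
        RatioEstimate(variant_id=v, ratio=G_j / g_j, ratio_se=sy_j / abs(g_j))
        for v, g_j, G_j, sy_j in zip(ids, g, G, sy)
    ]


def _two_sided_normal_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (WLS of Γ̂ on γ̂ through the origin).

    ``model='fixed'`` needs J ≥ 1 and uses SE = 1/sqrt(Σ w_j γ̂_j²);
    ``model='multiplicative_random'`` (default) needs J ≥ 2 and inflates
    that SE by max(1, sqrt(Q/(J−1))) where Q is Cochran's statistic.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    _, g, _, G, sy = _arrays(hset)
    J = len(g)
    min_J = 1 if model == "fixed" else 2
    if J < min_J:
        raise ValueError(f"IVW ({model}) requires at least {min_J} instrument(s), got {J}")
    w = 1.0 / sy**2
    denom = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = 1.0 / math.sqrt(denom)
    Q = float(np.sum(w * (G - beta * g) ** 2))
    inflation = 1.0
    if model == "multiplicative_random":
        inflation = max(1.0, math.sqrt(Q / (J - 1)))
    se = se_fixed * inflation
    z = stats.norm.ppf(0.975)
    return MREstimate(
        method="IVW",
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pvalue=_two_sided_normal_p(beta / se),
        n_variants=J,
        extras={"Q": Q, "inflation": inflation, "model": model, "se_fixed": se_fixed},
    )


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: slope is the causal estimate, intercept the
    average directional pleiotropy.  Requires J ≥ 3."""
    oriented = orient_positive(hset)
    _, g, _, G, sy = _arrays(oriented)
    J = len(g)
    if J <= 2:
        raise ValueError("Egger requires >=3 instruments")
    w = 1.0 / sy**2
    sw, swx = float(np.sum(w)), float(np.sum(w * g))
    swx2, swy = float(np.sum(w * g * g)), float(np.sum(w * G))
    swxy = float(np.sum(w * g * G))
    det = sw * swx2 - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    resid = G - intercept - slope * g
    Qp = float(np.sum(w * resid**2))
    df = J - 2
    inflation = max(1.0, math.sqrt(Qp / df))
    # (X'WX)^{-1} diagonal for [1, gamma] design
    se_int = math.sqrt(swx2 / det) * inflation
    se_slope = math.sqrt(sw / det) * inflation
    tq = stats.t.ppf(0.975, df)
    p_slope = max(2.0 * stats.t.sf(abs(slope / se_slope), df), _TINY_P)
    p_int = max(2.0 * stats.t.sf(abs(intercept / se_int), df), _TINY_P)
    return MREstimate(
        method="Egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pvalue=p_slope,
        n_variants=J,
        extras={
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_p": p_int,
            "intercept_ci_low": intercept - tq * se_int,
            "intercept_ci_high": intercept + tq * se_int,
            "Q_prime": Qp,
            "inflation": inflation,
            "df": df,
        },
    )


# ---------------------------------------------------------------------------
# weighted median


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical ratio distribution.

    With ratios sorted ascending, the standardized cumulative weight of the
    j-th ratio is s_j = (Σ_{k≤j} w_k − w_j/2) / Σ w_k; the estimate is the
    linear interpolation of the sorted ratios at s = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    b = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


def _bootstrap_draws(hset, n_boot, seed, min_gamma=WEAK_GAMMA_FLOOR):
    """Parametric bootstrap of (ratio, weight) pairs; one row per replicate."""
    _, g, sx, G, sy = _arrays(hset, min_gamma)
    rng = np.random.default_rng(seed)
    gb = rng.normal(g, sx, size=(n_boot, len(g)))
    Gb = rng.normal(G, sy, size=(n_boot, len(g)))
    gb = np.where(np.abs(gb) < min_gamma, np.sign(gb) * min_gamma + (gb == 0) * min_gamma, gb)
    ratios = Gb / gb
    weights = (gb / sy) ** 2
    return ratios, weights


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE (seeded)."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    _, g, _, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise ValueError("weighted_median requires >=3 instruments")
    beta = weighted_median_point(G / g, (g / sy) ** 2)
    rb, wb = _bootstrap_draws(hset, n_boot, seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = weighted_median_point(rb[i], wb[i])
    se = float(np.std(boots, ddof=1))
    z = stats.norm.ppf(0.975)
    return MREstimate(
        method="WeightedMedian",
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pvalue=_two_sided_normal_p(beta / se),
        n_variants=J,
        extras={"n_boot": n_boot, "seed": seed},
    )


# ---------------------------------------------------------------------------
# weighted mode


def mode_bandwidth(ratios: np.ndarray, phi: float = 1.0) -> float:
    """phi × modified Silverman bandwidth with a MAD-based robust spread."""
    b = np.asarray(ratios, dtype=float)
    mad = 1.4826 * float(np.median(np.abs(b - np.median(b))))
    sd = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * len(b) ** (-0.2)


def weighted_mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    phi: float = 1.0,
    grid_size: int = MODE_GRID_SIZE,
) -> float:
    """Argmax of the weighted normal-kernel density of the ratios.

    The argmax is located on a ``grid_size``-point grid spanning
    [min − h, max + h]; ties at the maximum resolve to the smallest grid
    value.  Zero bandwidth (all ratios identical) returns the common ratio.
    """
    b = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / np.sum(w)
    h = mode_bandwidth(b, phi)
    if h <= 0 or not np.isfinite(h):
        return float(b[0]) if np.ptp(b) == 0 else float(np.median(b))
    x = np.linspace(b.min() - h, b.max() + h, grid_size)
    dens = np.exp(-0.5 * ((x[None, :] - b[:, None]) / h) ** 2).T @ w
    return float(x[np.argmax(dens)])


def weighted_mode(
    hset: HarmonizedSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    grid_size: int = MODE_GRID_SIZE,
) -> MREstimate:
    """Weighted-mode estimator with parametric-bootstrap SE (seeded)."""
    if phi <= 0:
        raise ValueError("phi must be > 0")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if seed is None:
        raise ValueError("weighted_mode requires an explicit seed for the bootstrap")
    _, g, _, G, sy = _arrays(hset)
    J = len(g)
    if J < 3:
        raise ValueError("weighted_mode requires >=3 instruments")
    beta = weighted_mode_point(G / g, (g / sy) ** 2, phi, grid_size)
    rb, wb = _bootstrap_draws(hset, n_boot, seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = weighted_mode_point(rb[i], wb[i], phi, grid_size)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = _TINY_P  # degenerate: all ratios identical in every replicate
    z = stats.norm.ppf(0.975)
    return MREstimate(
        method="WeightedMode",
        beta=beta,
        se=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pvalue=_two_sided_normal_p(beta / se),
        n_variants=J,
        extras={"phi": phi, "n_boot": n_boot, "seed": seed, "grid_size": grid_size},
    )
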