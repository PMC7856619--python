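"""Statistical power for Mendelian randomisation with a binary outcome.

For a two-sample MR analysis whose instruments explain a fraction
ρ_GX² of the exposure's variance, and an outcome GWAS of N subjects with
case fraction ℙ(Y=1), the smallest causal log-odds ratio per SD detectable
with power 1−β₂ at two-sided level α is

    β = (Φ⁻¹(power) + z_{1−α/2}) / (ρ_GX · sqrt(N · ℙ(Y=1) · ℙ(Y=0)))

where Φ⁻¹ is the standard-normal quantile function.  At the defaults
(power 0.8, α 0.05) the numerator is Φ⁻¹(0.8) + 1.96.  The inverse
direction — the power achieved for a given effect — is

    power = Φ(|β| · ρ_GX · sqrt(N · ℙ(Y=1) · ℙ(Y=0)) − z_{1−α/2}).

Presets bundle the instrument strengths of the four lifestyle exposures
(BMI 7.0%, lifetime smoking 1.3%, accelerometer physical activity 0.2%,
alcohol drinks/week 0.6%) with the two COVID-19 outcome GWAS sample sizes
(severe respiratory: 2972 cases / 284,472 controls; hospitalization:
6492 cases / 1,012,809 controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats


@dataclass(frozen=True)
class PowerParameters:
    rho2_gx: float       # variance of exposure explained by the instruments
    n_total: int         # outcome GWAS sample size N
    p_case: float        # P(Y = 1)
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.rho2_gx < 1.0):
            raise ValueError("rho2_gx must lie in (0, 1)")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0.0 < self.p_case < 1.0):
            raise ValueError("p_case must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")

    @property
    def p_control(self) -> float:
        return 1.0 - self.p_case

    @classmethod
    def from_counts(
        cls, rho2_gx: float, n_cases: int, n_controls: int, alpha: float = 0.05, power: float = 0.8
    ) -> "PowerParameters":
        n = n_cases + n_controls
        return cls(rho2_gx=rho2_gx, n_total=n, p_case=n_cases / n, alpha=alpha, power=power)


#: Variance explained by the genome-wide significant instruments of each
#: exposure (fractions as reported for the source GWAS).
EXPOSURE_RHO2 = {
    "bmi": 0.070,
    "smoking": 0.013,
    "physical_activity": 0.002,
    "alcohol": 0.006,
}

#: Outcome GWAS case/control counts.
OUTCOME_COUNTS = {
    "severe_respiratory": (2972, 284_472),
    "hospitalization": (6492, 1_012_809),
}

_OUTCOME_ALIASES = {"severe": "severe_respiratory", "hosp": "hospitalization"}


def preset(exposure: str, outcome: str, alpha: float = 0.05, power: float = 0.8) -> PowerParameters:
    """Named exposure × outcome parameter preset, e.g. ``preset('bmi', 'severe')``."""
    exp = exposure.lower()
    out = _OUTCOME_ALIASES.get(outcome.lower(), outcome.lower())
    if exp not in EXPOSURE_RHO2:
        raise KeyError(f"unknown exposure {exposure!r}; choose from {sorted(EXPOSURE_RHO2)}")
    if out not in OUTCOME_COUNTS:
        raise KeyError(f"unknown outcome {outcome!r}; choose from {sorted(OUTCOME_COUNTS)}")
    cases, controls = OUTCOME_COUNTS[out]
    return PowerParameters.from_counts(EXPOSURE_RHO2[exp], cases, controls, alpha, power)


def _noncentrality_scale(params: PowerParameters) -> float:
    return math.sqrt(params.rho2_gx) * math.sqrt(
        params.n_total * params.p_case * params.p_control
    )


def detectable_effect(params: PowerParameters) -> tuple[float, float]:
    """Smallest detectable causal effect: (log-OR per SD, OR per SD)."""
    z_alpha = stats.norm.ppf(1.0 - params.alpha / 2.0)
    z_power = stats.norm.ppf(params.power)
    beta = (z_power + z_alpha) / _noncentrality_scale(params)
    return beta, math.exp(beta)


def power_at_effect(beta: float, params: PowerParameters) -> float:
    """Power achieved for a causal log-OR ``beta`` at ``params.alpha``."""
    if beta == 0:
        raise ValueError("beta must be nonzero")
    z_alpha = stats.norm.ppf(1.0 - params.alpha / 2.0)
    return float(stats.norm.cdf(abs(beta) * _noncentrality_scale(params) - z_alpha))
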