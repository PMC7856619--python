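"""Synthetic two-sample GWAS summary statistics.

The generator draws summary statistics directly (no individual-level
genotypes), matching the regime the estimators operate in:

* per variant j, a minor-allele frequency p_j ~ Uniform(maf_range) and a
  true per-allele exposure effect γ_j (half-normal, so the effect allele
  is the exposure-increasing one), deterministically rescaled so that
  Σ 2p_j(1−p_j)γ_j² equals the target variance explained ρ²_GX on the
  standardized-exposure scale;
* a pleiotropic outcome effect α_j for a configurable fraction of invalid
  instruments: balanced (mean 0) or directional (mean μ_α), drawn
  independently of γ (InSIDE satisfied) or correlated with it
  (``inside=False``);
* the true outcome effect Γ_j = β·γ_j + α_j on the log-odds scale;
* two-sample sampling noise on both betas with the standard per-allele
  GWAS approximations σ_Xj = 1/sqrt(2p_j q_j n_exp) and
  σ_Yj = 1/sqrt(2p_j q_j n_eff), where n_eff = n_cases·n_controls/N is the
  effective sample size of the case-control outcome GWAS;
* optionally, ``n_planted`` large pleiotropic effects of size
  ``planted_alpha`` placed on the strongest instruments, emulating a
  single-locus outlier episode such as the large-effect alcohol loci.

All randomness flows from one seed through named child streams, so adding
a new quantity or preset never perturbs existing output, and identical
seeds give bit-identical studies.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import CANONICAL_COLUMNS, write_sumstats

logger = logging.getLogger("mrkit")

#: Non-palindromic allele pairs assigned cyclically to simulated variants.
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    J: int = 150
    beta_true: float = 0.0
    rho2_gx: float = 0.013
    n_exposure: int = 462_690
    n_outcome_cases: int = 6492
    n_outcome_controls: int = 1_012_809
    tau: float = 0.0            # SD of the pleiotropy among invalid instruments
    mu_alpha: float = 0.0       # mean (directional) pleiotropy
    frac_invalid: float = 0.0   # fraction of instruments receiving pleiotropy
    inside: bool = True         # pleiotropy independent of instrument strength
    inside_corr: float = 0.5    # corr(α, γ) among invalid when inside=False
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_planted: int = 0          # planted outliers on the strongest instruments
    planted_alpha: float = 0.0  # their pleiotropic effect, log-odds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1 or self.n_exposure < 1 or self.n_outcome_cases < 1 or self.n_outcome_controls < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 < self.rho2_gx < 1.0):
            raise ValueError("rho2_gx must lie in (0, 1)")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ValueError("frac_invalid must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_planted > self.J:
            raise ValueError("cannot plant more outliers than instruments")


@dataclass
class SimulatedStudy:
    """Exposure and outcome tables (same rsIDs) plus the generating truth."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    truth: dict


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG: deterministic in (seed, name), independent across names."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic two-sample study under ``config``."""
    J = config.J
    lo, hi = config.maf_range
    maf = _stream(config.seed, "maf").uniform(lo, hi, J)
    het = 2.0 * maf * (1.0 - maf)

    gamma_raw = np.abs(_stream(config.seed, "gamma").standard_normal(J))
    gamma_raw = np.maximum(gamma_raw, 1e-3)  # avoid pathological null instruments
    denom = float(np.sum(het * gamma_raw**2))
    if denom <= 0:
        raise ValueError(
            f"rho2_gx = {config.rho2_gx} unreachable: zero heterozygosity-weighted "
            f"effect mass for J = {J} and maf_range = {config.maf_range}"
        )
    gamma = gamma_raw * np.sqrt(config.rho2_gx / denom)

    valid = np.ones(J, dtype=bool)
    n_invalid = int(round(config.frac_invalid * J))
    if n_invalid:
        idx = _stream(config.seed, "validity").choice(J, size=n_invalid, replace=False)
        valid[idx] = False
    alpha = np.zeros(J)
    if n_invalid:
        z = _stream(config.seed, "alpha").standard_normal(n_invalid)
        inv = ~valid
        if config.inside:
            shock = z
        else:
            gs = gamma[inv]
            gstd = (gs - gs.mean()) / gs.std() if gs.std() > 0 else np.zeros_like(gs)
            r = config.inside_corr
            shock = r * gstd + np.sqrt(1.0 - r**2) * z
        alpha[inv] = config.mu_alpha + config.tau * shock

    planted_ids: list[str] = []
    if config.n_planted:
        strongest = np.argsort(-np.abs(gamma), kind="stable")[: config.n_planted]
        alpha[strongest] += config.planted_alpha
        valid[strongest] = False
        planted_ids = [f"rs{i + 1:07d}" for i in sorted(strongest)]

    Gamma = config.beta_true * gamma + alpha

    n_out = config.n_outcome_cases + config.n_outcome_controls
    n_eff = config.n_outcome_cases * config.n_outcome_controls / n_out
    sx = 1.0 / np.sqrt(het * config.n_exposure)
    sy = 1.0 / np.sqrt(het * n_eff)

    beta_x = gamma + sx * _stream(config.seed, "noise_x").standard_normal(J)
    beta_y = Gamma + sy * _stream(config.seed, "noise_y").standard_normal(J)
    p_x = np.maximum(2.0 * stats.norm.sf(np.abs(beta_x / sx)), 5e-324)
    p_y = np.maximum(2.0 * stats.norm.sf(np.abs(beta_y / sy)), 5e-324)

    ids = [f"rs{i + 1:07d}" for i in range(J)]
    ea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(J)]
    oa = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(J)]

    def _table(beta, se, pval, n):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pvalue": pval,
                "n": float(n),
            },
            columns=CANONICAL_COLUMNS,
        )

    truth = {
        "config": asdict(config),
        "beta_true": config.beta_true,
        "variant_id": ids,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "valid": valid.tolist(),
        "maf": maf.tolist(),
        "planted": planted_ids,
        "n_effective_outcome": n_eff,
        "realized_rho2": float(np.sum(het * gamma**2)),
    }
    return SimulatedStudy(
        exposure=_table(beta_x, sx, p_x, config.n_exposure),
        outcome=_table(beta_y, sy, p_y, n_out),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fixture presets mirroring the four exposures x two COVID-19 outcomes

FIXTURE_PRESETS: dict[str, SimulationConfig] = {
    # 656 BMI instruments (rho2 ~ 7.0%) against severe respiratory disease
    "bmi_severe_like": SimulationConfig(
        J=656, beta_true=0.65, rho2_gx=0.070, n_exposure=681_275,
        n_outcome_cases=2972, n_outcome_controls=284_472,
    ),
    # 126 lifetime-smoking instruments (rho2 = 1.3%) against hospitalization
    "smoking_hosp_like": SimulationConfig(
        J=126, beta_true=0.77, rho2_gx=0.013, n_exposure=462_690,
        n_outcome_cases=6492, n_outcome_controls=1_012_809,
    ),
    # 5 accelerometer physical-activity instruments (rho2 ~ 0.2%)
    "physical_activity_severe_like": SimulationConfig(
        J=5, beta_true=-1.66, rho2_gx=0.002, n_exposure=91_105,
        n_outcome_cases=2972, n_outcome_controls=284_472,
    ),
    # 80 drinks-per-week instruments (rho2 ~ 0.6%) with two large
    # pleiotropic effects planted on the strongest loci
    "alcohol_with_planted_outliers": SimulationConfig(
        J=80, beta_true=0.0, rho2_gx=0.006, n_exposure=941_280,
        n_outcome_cases=2972, n_outcome_controls=284_472,
        n_planted=2, planted_alpha=0.5,
    ),
}


def make_fixture(
    preset: str, out_dir: str | Path | None = None, seed: int = 2020
) -> SimulatedStudy:
    """Generate a named fixture study; optionally write TSVs + truth JSON.

    Each preset derives its own child seed from ``seed`` and the preset
    name, so adding presets never changes existing fixtures.
    """
    if preset not in FIXTURE_PRESETS:
        raise KeyError(
            f"unknown preset {preset!r}; available: {', '.join(sorted(FIXTURE_PRESETS))}"
        )
    child = int(
        np.random.SeedSequence([seed, zlib.crc32(preset.encode())]).generate_state(1)[0]
        % (2**31)
    )
    config = FIXTURE_PRESETS[preset]
    config = SimulationConfig(**{**asdict(config), "seed": child})
    study = simulate_two_sample(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sumstats(study.exposure, out / f"{preset}.exposure.tsv")
        write_sumstats(study.outcome, out / f"{preset}.outcome.tsv")
        (out / f"{preset}.truth.json").write_text(
            json.dumps(study.truth, indent=1, sort_keys=True)
        )
        logger.info("make_fixture(%s): wrote tables to %s", preset, out)
    return study
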