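# Methods

## The estimation problem

Two-sample Mendelian randomisation treats genetic variants as
instrumental variables for a modifiable exposure. Each instrument *j*
contributes a pair of association estimates from two independent GWAS:
γ̂\_j ± σ\_Xj on the exposure (per SD) and Γ̂\_j ± σ\_Yj on a binary
outcome (log-odds). Under the instrumental-variable assumptions
(association with the exposure; independence from confounders; no effect
on the outcome except through the exposure), Γ\_j = β γ\_j, and β — the
causal log-odds ratio per SD — is identified from the per-variant Wald
ratios Γ̂\_j/γ̂\_j. All estimators here act on summary statistics only
and treat γ̂\_j as fixed (the standard NO Measurement Error
approximation, accurate when instruments are genome-wide significant).

## Harmonization

Outcome records are aligned to the exposure's effect allele before
estimation. Four reconcilable configurations exist — identical labels,
swapped labels (negate the outcome beta, complement its EAF), strand
complement, and strand complement plus swap — and anything else drops
the variant as an allele mismatch. Palindromic variants (A/T, C/G) are
strand-ambiguous; the default policy infers orientation from the effect
allele frequencies when both lie outside 0.5 ± 0.08 and drops the
variant otherwise. The window of 0.08 is a conservative, auditable
default for a step GWAS pipelines rarely document; `keep` and `drop`
policies are available. Each harmonized record carries an `action` tag
so the applied transformation is auditable.

MR-Egger is the one estimator whose result depends on instrument
orientation: its intercept is only meaningful with every γ̂\_j ≥ 0, so
the Egger fit re-orients pairs internally. IVW, median and mode are
invariant to per-instrument sign flips and consume pairs as harmonized.

## Estimators and inference

- **IVW**: β̂ = Σ w\_j γ̂\_j Γ̂\_j / Σ w\_j γ̂\_j², w\_j = 1/σ\_Yj².
  Default inference is the multiplicative random-effects model: the
  fixed-effect SE 1/√(Σ w\_j γ̂\_j²) scaled by max(1, √(Q/(J−1))). The
  floor at 1 never lets observed under-dispersion shrink the SE. Normal
  reference distribution.
- **MR-Egger**: weighted regression with intercept; SEs from
  (XᵀWX)⁻¹ scaled by max(1, √(Q′/(J−2))); t reference with J−2 df for
  slope and intercept. The intercept estimates the average directional
  pleiotropy (log-odds units); its test is the directional-pleiotropy
  diagnostic.
- **Weighted median**: ratios sorted ascending; standardized cumulative
  weights s\_j = (Σ\_{k≤j} w\_k − w\_j/2)/Σ w\_k with ratio weights
  γ̂\_j²/σ\_Yj²; linear interpolation at s = 0.5. SE by seeded parametric
  bootstrap (γ̂\*, Γ̂\* redrawn from normals at their SEs, estimator
  recomputed; default 1000 replicates), normal inference.
- **Weighted mode**: argmax of the weighted normal-kernel density of the
  ratios. Bandwidth = φ × 0.9·min(sd, 1.4826·MAD)·J^(−1/5) (a
  modified-Silverman rule with a MAD-based robust spread; φ defaults
  to 1). The argmax is located on a 10,000-point grid spanning
  [min − h, max + h]; ties resolve to the smallest grid value, making
  the estimate deterministic. All-identical ratios short-circuit to the
  common value. SE by the same seeded bootstrap.

Weak instruments with |γ̂\_j| < 10⁻⁶ (configurable) are excluded before
any ratio is formed, so division by zero cannot occur. P-values are
floored at the smallest positive double so they remain in (0, 1].

## Diagnostics

Cochran's Q about the IVW fit (df J−1) and Rücker's Q′ about the Egger
fit (df J−2) are referred to chi-square upper tails. Q ≥ Q′ always holds
on the oriented instruments, since the Egger model nests the
through-origin one.

Leave-one-out re-runs IVW once per omitted instrument (rows ordered by
variant id). A variant is flagged as influential when either
(1) |β̂\_{−j} − β̂\_full| exceeds `rule` (default 1.0) times the full
fit's **fixed-effect** SE, or (2) omitting it changes whether the 95% CI
excludes zero. The fixed-effect SE is deliberate: strong outliers
inflate the heterogeneity-scaled random-effects SE and would thereby
mask their own influence; the fixed-effect SE measures instrument
precision alone and is immune to that feedback. The pipeline removes all
flagged variants and re-runs the full estimator and diagnostic suite
exactly once — never iteratively — mirroring the single
remove-and-refit step used in practice when leave-one-out plots identify
outlying loci.

Benjamini–Hochberg q-values (via statsmodels) are computed across the
plan's primary all-variant IVW tests only; sensitivity estimators are
reported unadjusted.

## Power for a binary outcome

The smallest detectable causal effect at two-sided level α and target
power is β = (Φ⁻¹(power) + z\_{1−α/2}) / (ρ\_GX √(N P(Y=1) P(Y=0))); at
the defaults (0.8, 0.05) the numerator is the familiar Φ⁻¹(0.8) + 1.96.
Writing the α-quantile instead of the literal 1.96 makes the function
reusable at other levels without changing the default numbers. The
inverse, power = Φ(|β| ρ\_GX √(N P(Y=1) P(Y=0)) − z\_{1−α/2}), ignores
the far-tail rejection region, which is negligible whenever power
exceeds ~0.1; the Monte-Carlo test verifies agreement to 0.01 in that
regime. Presets pair the four exposures' instrument strengths
(ρ² = 0.070, 0.013, 0.002, 0.006) with the two outcome GWAS sizes
(2972/284,472 and 6492/1,012,809). The ρ² values for physical activity
and alcohol are order-of-magnitude figures rounded to one significant
digit, so their detectable ORs are reproducible only to about ±0.06;
BMI and smoking reproduce to the printed two decimals.

## Synthetic data

The generator works entirely at the summary level — no individual
genotypes — matching the regime the estimators see and keeping a
500-replicate operating-characteristic run in seconds. Per variant: MAF
uniform on (0.05, 0.5) by default; true γ\_j half-normal (the effect
allele is taken as the exposure-increasing one, the convention the
Egger orientation step would impose anyway) and rescaled so the
heterozygosity-weighted sum Σ 2p\_j q\_j γ\_j² equals the target ρ²\_GX
exactly; pleiotropy α\_j = μ\_α + τ·shock for a chosen fraction of
invalid instruments, with the shock either independent of γ (InSIDE
holds) or correlated with it at a configurable level; observed betas
drawn around truth with the per-allele approximations
σ\_Xj = 1/√(2p\_j q\_j n\_exp) and σ\_Yj = 1/√(2p\_j q\_j n\_eff),
where n\_eff = n\_cases·n\_controls/N is the effective size of the
case-control outcome GWAS (an approximation that slightly understates
the SE at extreme case fractions). One master seed feeds named child
streams, so adding a new random quantity or preset never perturbs
existing draws, and identical seeds give bit-identical studies.

Planted outliers (the `alcohol_with_planted_outliers` preset) add a
large pleiotropic effect (0.5 log-odds) to the **strongest** instruments.
This mirrors the empirical situation the preset emulates — the outlying
alcohol loci are the largest-effect variants for that trait — and it is
also what makes a ≥95% recovery guarantee achievable at this instrument
strength: a pleiotropic effect on a near-null instrument has
vanishing leverage on the pooled estimate and is undetectable from
leave-one-out shifts in principle.

What the generator does *not* emulate: linkage disequilibrium between
instruments (the analyses use independent sentinel variants), sample
overlap between the two GWAS, allele-frequency differences between
cohorts, strand errors, and winner's-curse inflation of γ̂. Passing
tests therefore certify the statistical machinery under the stated
two-sample model, not robustness to those real-data pathologies.

## Simulation study sizes and conditions

The operating-characteristic suites use: J = 150 instruments at the
lifetime-smoking preset sample sizes for IVW bias (500 replicates per
true effect in {0, 0.2, 0.6}) and null-calibration runs (500
replicates, Kolmogorov–Smirnov at the 1% level); J = 100 with balanced
pleiotropy τ = 0.01 for the Egger intercept type-I-error run (1000
replicates) — τ is set small relative to the outcome sampling SEs
(≈0.02–0.04) so the multiplicative-overdispersion model the estimator
assumes is close to correctly specified; 30% directional-invalid
instruments (μ\_α = 0.03) for the median-versus-IVW robustness ordering
(200 replicates); and the 80-instrument planted-outlier preset for
influence-rule recovery (200 replicates). These sizes give Monte-Carlo
standard errors comfortably inside the asserted margins while keeping
the default test run around half a minute.

## Numerical choices and edge cases

- Write precision is `%.17g`, and reads use pandas' round-trip float
  parser, so a write/read cycle is bit-exact.
- Proxy substitution keeps the sentinel's exposure statistics under the
  proxy's rsID (candidates filtered to r² ≥ 0.8, the highest r² wins,
  lexicographic tie-break); a sentinel with no usable proxy is dropped
  and counted.
- Estimator preconditions (J ≥ 2 for random-effects IVW, J ≥ 3 for
  Egger/median/mode) abort a pipeline pair with a recorded failure
  without stopping the other pairs; the CLI then exits nonzero.
- Reported tables print ORs and CIs to two decimals and p-values in
  scientific notation below 0.01, with full-precision log-scale columns
  alongside; provenance (config hash, seed, package version, variant
  accounting) is written without timestamps so identical runs are
  byte-identical.

## Known limitations

No LD-aware proxy discovery (proxies are consumed from a precomputed
table); rsID-only variant identity (no chr:pos matching or liftover);
no MR-PRESSO-style outlier search, Steiger filtering or multivariable
MR; power formulas ignore weak-instrument bias and winner's curse; the
bootstrap SEs for median and mode assume approximately normal sampling
of the per-variant effects.
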