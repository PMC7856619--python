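# mrkit

Two-sample Mendelian randomisation (MR) on GWAS summary statistics, built
around the design of recent analyses of modifiable lifestyle exposures
(body mass index, lifetime smoking, accelerometer-measured physical
activity, alcohol consumption) against severe COVID-19 outcomes. It is a
library plus a small `mrkit` command-line tool for epidemiologists who
want the full pipeline — instrument selection, LD-proxy substitution,
allele harmonization, estimation, pleiotropy diagnostics, outlier
handling, FDR and power — as tested, reusable, deterministic code.

## The model

For each genetic instrument *j* we observe the variant's effect on the
exposure, γ̂\_j (per SD, with SE σ\_Xj), and on the binary outcome,
Γ̂\_j (log-odds, with SE σ\_Yj), from two separate GWAS. If the variant
is a valid instrument, Γ\_j = β·γ\_j, where β is the causal log-odds
ratio per SD of the exposure. The package implements:

- **Wald ratios** β̂\_j = Γ̂\_j/γ̂\_j with SE σ\_Yj/|γ̂\_j|;
- **IVW**: weighted least squares of Γ̂ on γ̂ through the origin with
  weights 1/σ\_Yj²; under the default multiplicative random-effects
  model the SE is inflated by max(1, √(Q/(J−1))), Q = Cochran's
  statistic;
- **MR-Egger**: the same regression with a free intercept on instruments
  oriented γ̂\_j ≥ 0; the intercept estimates average directional
  pleiotropy, inference uses t with J−2 df and Rücker's Q′;
- **weighted median**: the 50% point of the inverse-variance-weighted
  ratio distribution — consistent with up to 50% invalid weight;
- **weighted mode**: the peak of a weighted normal-kernel density of the
  ratios (MAD-based modified-Silverman bandwidth × φ) — consistent when
  the largest cluster of instruments is valid;
- **diagnostics**: Cochran's Q (df J−1), Rücker's Q′ (df J−2), the Egger
  intercept test, leave-one-out IVW with a reproducible influence rule,
  funnel-plot data, and Benjamini–Hochberg FDR over the plan's primary
  IVW tests;
- **power**: the binary-outcome detectable effect
  β = (Φ⁻¹(power) + z\_{1−α/2}) / (ρ\_GX √(N·P(Y=1)·P(Y=0))),
  where ρ\_GX² is the exposure variance explained by the instruments and
  N the outcome GWAS size, plus its inverse (power at a given effect);
- **simulation**: a seeded generator of two-sample summary statistics
  with configurable causal effect, instrument strength, sample sizes,
  balanced/directional pleiotropy, InSIDE violations and planted
  outliers, used by the test suite and usable for study design.

## Worked example

Generate two synthetic studies (one mimicking the 126-instrument lifetime
smoking set against a 6492-case hospitalization GWAS, one mimicking the
80-instrument alcohol set with two large planted pleiotropic loci) and
run a two-pair plan:

```python
from pathlib import Path
import yaml
from mrkit import simulate, pipeline

simulate.make_fixture("smoking_hosp_like", out_dir="fixtures")
simulate.make_fixture("alcohol_with_planted_outliers", out_dir="fixtures")
plan = {
    "seed": 1, "output_dir": "results",
    "options": {"p_threshold": 5e-8, "n_boot": 1000},
    "pairs": [
        {"name": "smoking_hosp",
         "exposure": "fixtures/smoking_hosp_like.exposure.tsv",
         "outcome": "fixtures/smoking_hosp_like.outcome.tsv"},
        {"name": "alcohol_severe",
         "exposure": "fixtures/alcohol_with_planted_outliers.exposure.tsv",
         "outcome": "fixtures/alcohol_with_planted_outliers.outcome.tsv"},
    ],
}
Path("plan.yaml").write_text(yaml.safe_dump(plan))
report = pipeline.run_plan(pipeline.load_plan("plan.yaml"))
print(report.pairs["alcohol_severe"].estimates.iloc[:, :7].to_string(index=False))
```

which prints (ORs per SD of the exposure, 95% CI, two-sided P):

```
        method           subset  n_variants      OR ci_low   ci_high       P
           IVW     all_variants          37    9.56   1.45     62.90    0.02
         Egger     all_variants          37 2758.71  25.40 299588.25 1.6e-03
WeightedMedian     all_variants          37    1.70   0.81      3.56    0.16
  WeightedMode     all_variants          37    1.64   0.59      4.54    0.34
           IVW outliers_removed          34    0.93   0.55      1.58    0.79
         Egger outliers_removed          34    3.34   0.75     14.82    0.11
WeightedMedian outliers_removed          34    1.43   0.69      2.95    0.34
  WeightedMode outliers_removed          34    1.67   0.63      4.44    0.30
```

The story the numbers tell: 37 of the 80 simulated alcohol instruments
reach genome-wide significance; two planted pleiotropic loci drag the
all-variant IVW OR to 9.56, the leave-one-out influence rule flags them
(plus one borderline variant), and after the single removal-and-refit
pass the estimate collapses to the simulated null (OR 0.93, P = 0.79) —
the robust median and mode estimators were never fooled. For the clean
smoking-like pair the four estimators agree (IVW OR 2.11, 95% CI
1.66–2.67, P = 7.4×10⁻¹⁰ against a simulated true OR of 2.16), and
`results/fdr.tsv` carries the Benjamini–Hochberg q-values over the two
primary IVW tests. Every table under `results/` is byte-identical when
the plan is re-run with the same seed.

The same steps are available from the shell: `mrkit simulate`,
`mrkit harmonize`, `mrkit estimate`, `mrkit diagnose`, `mrkit power`,
`mrkit run --plan plan.yaml`.

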