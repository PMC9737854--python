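# plusqol

Hierarchical fuzzy-logic scoring of personal life satisfaction from
clinimetric questionnaires, with longitudinal monitoring for the early
detection of deterioration.

`plusqol` is aimed at mental-health informatics work — occupational-health
screening, remote monitoring pipelines, computational psychometrics — where
several validated questionnaires must be fused into one interpretable
number per person per assessment, and where a *decline* in that number over
repeated assessments is the signal of interest (emerging burnout,
depressive drift).

## The model

Four instruments feed the composite, each reduced to its total or subscale
scores:

| scale | range | higher means |
|---|---|---|
| PSS10 (Perceived Stress Scale) | 0–40 | more stress |
| SWLS (Satisfaction with Life Scale) | 5–35 | better life satisfaction |
| NMQ (Nordic Musculoskeletal Questionnaire, complaint count) | 0–40 | more complaints |
| MBI emotional exhaustion / depersonalization / personal accomplishment | 0–54 / 0–30 / 0–48 | worse / worse / **better** |

The PLUS ("personal living usual satisfaction") score is produced by a
three-tier hierarchy of Mamdani fuzzy systems:

1. **Normalization.** Each raw score x is fuzzified against a Ruspini
   partition of its scale into trapezoidal sets *low / medium / high*
   (membership functions sum to 1 everywhere), and mapped by three rules
   onto an output partition Y of [0, 1] — direction-reversed for the four
   "higher is worse" scales — giving a normalized value e ∈ [0, 1] with the
   uniform reading "the higher, the better".
2. **Context modules.** Mental state aggregates normalized PSS10 and SWLS;
   physical condition is the normalized NMQ passed through unchanged;
   burnout aggregates the three normalized MBI subscales through the
   8-rule base `o = O(1 + #high)` (all-low → O₁, one high → O₂, two high →
   O₃, all high → O₄) over two-valued input partitions μ_L(x) = 1 − x,
   μ_H(x) = x.
3. **Final aggregation.** The three module outputs — deliberately of equal
   importance — pass through a system with the same structure as the
   burnout module, yielding PLUS ∈ [0, 1].

All tiers use **PROD** premise aggregation, **MIN** implication, **MAX**
accumulation and **centre-of-gravity** defuzzification. COG is evaluated in
closed form on the exact piecewise-linear envelope of the clipped
consequents; boundary output sets are extended symmetrically beyond [0, 1]
(e.g. Y₁ = (−0.5, 0, 0, 0.5), Y₃ = (0.5, 1, 1, 1.5)) so that the extremes
defuzzify to exactly 0 and exactly 1.

On top of the model, `plusqol.monitoring` computes per-step deltas,
classifies trajectories (deteriorating / improving / stable / mixed), flags
any decline of at least a configurable threshold (default 0.05), summarizes
groups (sum, min, Q1, median, Q3, max, mean, SD) and correlates changes in
PLUS against changes in the raw scales (Spearman ρ). `plusqol.synthetic`
generates seeded cohorts with the evaluation-study design — two
occupational groups × three timepoints — for end-to-end testing without
access to the (unpublished) original data.

## Worked example

```python
from plusqol import ScoreVector, evaluate_plus

scores = ScoreVector(pss10=31, swls=12, nmq=1, mbi_ee=34, mbi_dp=16, mbi_pa=25)
result = evaluate_plus(scores)
for name, value in result.flat_values().items():
    print(f"{name}: {value:.4f}")
```

prints

```
norm_pss10: 0.3081
norm_swls: 0.3326
norm_nmq: 0.9510
norm_mbi_ee: 0.3510
norm_mbi_dp: 0.4190
norm_mbi_pa: 0.3825
module_mental: 0.2731
module_physical: 0.9510
module_burnout: 0.3099
plus_score: 0.4799
```

A stressed, exhausted but physically healthy subject: all six normalized
values read "higher is better", so elevated stress (31/40) and low life
satisfaction (12/35) pull the mental module down to 0.27 and the burnout
module to 0.31, while a single musculoskeletal complaint leaves the
physical module at 0.95; the final aggregation of the three balances out
at a PLUS of 0.48 on the 0–1 satisfaction axis.

The same is available from a shell:

```
plus trace 31 12 1 34 16 25            # full JSON trace of one evaluation
plus simulate --preset group1-like --n 20 --seed 1 --out cohort.csv
plus score cohort.csv --out scored.csv
plus monitor cohort.csv --threshold 0.05
plus validate-model
```

`plus monitor` prints one deterioration report per subject (deltas, trend,
flag) and a per-group, per-timepoint summary table.

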