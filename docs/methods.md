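# Methods

## Inference engine

Every stage of the hierarchy is a single-output Mamdani system over
trapezoidal fuzzy sets T = (l, k1, k2, r): membership 0 outside [l, r],
1 on the kernel [k1, k2], linear on the ramps. Degenerate shoulders
(l = k1 or k2 = r) follow the jump convention — the kernel point keeps
membership 1 — which is required for a raw score of exactly 0 to belong
fully to a set like (0, 0, 0, 14).

Operators are fixed: premise aggregation by product, implication by
minimum (clipping), accumulation by pointwise maximum, defuzzification by
centre of gravity. The engine rejects any other configuration rather than
silently accepting untested algebra.

The accumulated consequent is represented exactly: each clipped trapezoid
is a piecewise-linear curve, and the max envelope is built by merging all
breakpoints and inserting every pairwise crossing, between which the
maximum is linear. COG is then integrated in closed form per linear
segment. Two numerical choices matter:

* the moment is taken about the midpoint of the envelope's positive
  support, so mirror-symmetric envelopes defuzzify to their symmetry point
  with zero floating-point residue — this is what makes the boundary
  outputs *exactly* 0.0 and 1.0 rather than 1 ± 1e-16;
* a grid-based integrator (`fuzzy.numeric_centroid`, even 1e-4 grid plus
  nodes at the curve's breakpoints) is kept alongside purely as a
  verification oracle; inference never runs off a grid.

The model layer clamps its outputs to [0, 1]; the centroids of these
systems lie in [0, 1] mathematically, so this only removes sub-1e-15
floating-point residue at the endpoints.

## Partitions and rules

The six input partitions are the published ones and are Ruspini partitions
of their scales (memberships sum to 1 everywhere — property-tested on
dense grids). The personal-accomplishment partition reaches 49 on a 0–48
scale; the parameters are kept verbatim rather than "fixed", with the
documented consequence that a perfect accomplishment score normalizes to
≈ 0.933 and the best achievable composite is ≈ 0.985, not 1.

Output partitions: three levels Y over [0, 1] for tier 1 (breakpoints at
0.5), four levels O for the three-input modules (breakpoints at exact
thirds — the decimal values 0.333/0.667 in the source are evident
roundings, and exact thirds preserve both the Ruspini property and mirror
symmetry). Boundary sets are extended symmetrically (Y₁ = (−0.5, 0, 0,
0.5), Y₃ = (0.5, 1, 1, 1.5); O₁, O₄ analogously by thirds) and the
defuzzification interval extends with them ([−0.5, 1.5] and [−1/3, 4/3]).
The source states the extension for the tier-1 output only; it is applied
at every tier here, for consistency with its stated purpose (reaching
exactly 0 and 1) and because the final tier is defined to share the
three-input module's structure. Without the extension the edge triangles
defuzzify to ≈ 0.167 and ≈ 0.833 (unit-tested via `extended=False`).

The two-input (mental) module's rule base was not published; the one used
— LL → low, LH/HL → medium, HH → high over μ_L(x) = 1 − x, μ_H(x) = x —
is the minimal two-input analogue of the published three-input base and is
the unique choice preserving mirror symmetry f(1−a, 1−b) = 1 − f(a, b).
It should be read as a reconstruction.

Consequences that are property-tested rather than assumed: composite in
[0, 1] on exhaustive grids, non-decreasing response to improvement along
any single axis, mirror symmetry of the three-input modules to 1e-9, and
bit-identical passthrough of the normalized NMQ as the physical module.

## Monitoring conventions

Deltas are consecutive-assessment differences. The deterioration flag
requires an actual decline of at least the threshold (a flat trajectory is
never flagged, even at threshold 0). The default threshold of 0.05 on the
PLUS scale has no published decision rule behind it; it is the value that
separates the reference cohort's clearly declining group (mean per-step
changes −0.060, −0.113) from its stable group (−0.044, +0.035), and it is
configurable everywhere it appears.

Group summaries use quartiles by linear interpolation at position
(n − 1)·p and the sample (n − 1) standard deviation — both conventions
pinned by reproducing the reference cohort's printed summary rows from its
printed per-subject outcomes. One published cell (the declining group's
second-assessment median) is inconsistent with its own per-subject values
under this convention and matches the upper middle order statistic
instead; the test suite documents the discrepancy rather than hiding it in
a loose tolerance.

Change-vs-change association uses Spearman's ρ with midranks for ties
(scipy), two-sided p from the t approximation by default (matching common
statistics packages at the study's n = 20) with an optional permutation
p-value, and a significance flag at 0.05.

## Synthetic cohorts

`plusqol.synthetic` generates the evaluation-study design: two
occupational groups, twenty subjects by default, three timepoints (before
the pandemic, during its second year, during the war in the neighboring
country). Per scale and timepoint, scores are drawn from a normal
distribution, rounded to the instruments' integer granularity and clamped
to the legal interval; a shared per-subject offset (SD = half the
cross-sectional SD by default) induces within-subject correlation across
timepoints. A configuration whose mean/SD places most of the mass outside
the legal range triggers a warning.

Preset provenance. The published record reports group-level means and SDs
for PSS10, SWLS, NMQ and an MBI aggregate only, and parts of it are
internally inconsistent, so the presets are a documented reconstruction:

* group1-like: PSS10 and SWLS means/SDs as published; NMQ drifts upward
  (0.55 → 0.70 → 0.85), following the published direction-of-change table
  (the per-timepoint NMQ means printed elsewhere in the record move the
  other way and were set aside); the MBI aggregate (48.75 → 56.75 → 63.50)
  is split into exhaustion/depersonalization at shares 0.55/0.25 with
  accomplishment anti-drifting via PA = 48·(1 − total/132).
* group2-like: PSS10 as published; the published group-2 life-satisfaction
  column exceeds the SWLS legal range and is rescaled by 1/2.5 into range
  (21.4 → 25.0 → 22.4); complaints stay flat (0.45 → 0.50 → 0.50); burnout
  worsens transiently at the second assessment and recovers past baseline
  (EE 9.5 → 13.0 → 8.9, DP 4.3 → 5.9 → 4.0, PA 41.7 → 39.5 → 42.3),
  consistent with the published composite outcomes, which dip at the
  second assessment, and with overall endpoint improvement.

What the generator does *not* emulate: item-level response processes,
floor/ceiling clustering beyond truncation, dropout, measurement error
correlated across instruments, or the original per-subject outcomes (the
raw data behind them were never published). Passing end-to-end tests
therefore demonstrate that the pipeline reproduces the study's qualitative
group trajectories — monotone decline for group 1, dip-then-recovery for
group 2 — under plausible inputs, not that it reproduces the original
cohort numerically; the synthetic cohorts' absolute PLUS levels sit higher
than the published ones.

Problem sizes used in the checked properties: dense membership grids of
10,001 points; 1,000 random envelopes for the COG cross-check; 500 triples
for mirror symmetry; the full 5⁶ = 15,625-point factorial grid for global
bounds (per-value memoization makes this cheap — the grid touches only 30
distinct tier-1 inferences); synthetic cohorts of n = 200 per group for
direction fidelity.

## Known limitations

* The composite is only as valid as its inputs; the model encodes the
  published partitions, not a fitted or calibrated instrument, and no
  facility is provided to fit set parameters to data (out of scope by
  design).
* The best achievable composite is ≈ 0.985 (the PA partition overshoot
  above); rank order is unaffected.
* Monotonicity is verified along single axes from the kernel midpoint;
  Mamdani/COG systems do not guarantee joint monotonicity in general.
* The deterioration rule is a threshold on observed deltas — it does not
  model measurement error in the questionnaires, so very small thresholds
  will flag noise.
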