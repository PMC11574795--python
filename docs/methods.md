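# Methods

## Analysis model

All statistics operate on the Fisher-z scale. For a T×R table of ROI time
series, FC is `z' = arctanh(clip(r, ±(1 − 1e-7)))` of the Pearson
correlation between each ROI pair; the clip keeps degenerate (perfectly
correlated) inputs finite and deterministic. Edges are enumerated row-major
over the upper triangle — (0,1), (0,2), …, (1,2), … — and this ordering is
written into every output header. The two task runs are averaged
element-wise **on the z' scale** (not on back-transformed r; the two
conventions differ and a regression test asserts the z-scale path). The
reconfiguration statistic is the edge-wise absolute difference
`|z'_rest − z'_task|`.

Optional temporal filtering uses order-4 Butterworth filters applied
forward–backward (zero phase), because phase lags introduced by causal
filtering would bias the inter-regional correlations. Defaults: 0.008–0.08
Hz band-pass for rest, 0.01 Hz high-pass for task (preserving task-driven
fluctuations at higher frequencies). Filtering is off by default in the
pipeline — ROI tables are frequently exported already filtered — and the
filters are available for raw inputs. Forward–backward filtering has edge
transients; correlation estimation is insensitive to them at the series
lengths involved (T ≈ 300), and validation of the frequency response is
done on interior samples.

### Group statistics

- Edge-wise contrasts: two-sided independent-samples t-tests (pooled
  variance by default, Welch optional), sign convention A − B, corrected
  over the E-edge family with Benjamini–Hochberg step-up FDR at q = 0.05.
  Edges with zero pooled variance are flagged and excluded from the FDR
  family with a warning. The reject flag is `adjusted p < q`.
- Distribution contrasts treat the E group-averaged edge values of two
  samples as exchangeable observations and compare them with the Wilcoxon
  rank-sum test and the two-sample Kolmogorov–Smirnov test. Edges of one
  connectome are *not* independent, so these p-values faithfully reproduce
  an analysis convention rather than a calibrated error rate; the per-edge
  t-tests above are the calibrated route. The rank-sum z is the tie- and
  continuity-corrected normal deviate of the Mann–Whitney U, positive when
  the first sample is larger; for pooled samples ≤ 10 without ties the
  p-value switches to the exact permutation null. Underflowed asymptotic
  p-values are floored at the smallest positive float so they remain valid
  FDR inputs.
- Each results table is its own FDR family (the 120 edges of one contrast;
  the rank-sum rows of the distribution table; the rows of each permutation
  table; the behavioral contrast table), mirroring table-level correction.

### Similarity, typicality, permutation tests

The n×E edge table of a state yields an n×n inter-subject matrix of
Fisher-z pattern correlations (diagonal excluded). Similarity is the mean
z-correlation to same-group subjects (self excluded); typicality is the
mean z-correlation to the typically-developing reference group, with
reference members contributing their leave-one-out within-reference mean as
the baseline the other group is compared against. Scores are reported on
the Fisher-z scale and never back-transformed.

Group differences use label permutation: the observed statistic is Cohen's
d (pooled-SD denominator, n₁+n₂−2) between the two groups' per-subject
scores; the null shuffles group labels (sizes preserved) and re-derives the
scores *from the fixed inter-subject matrix* — pattern correlations are
never recomputed, which makes B = 10,000 permutations cheap and exact
enumeration automatic whenever C(n, n₁) ≤ 20,000. The two-sided Monte-Carlo
p is (1 + #{|d_perm| ≥ |d_obs|})/(B + 1), which respects the 1/(B+1) floor.
Choosing d (rather than a raw mean difference) as the permuted statistic,
and the leave-one-out baseline for the typicality contrast, are
interpretation choices; both are recorded in the output metadata.

### Subgrouping and brain–behavior analysis

Composite accuracy is the unweighted mean of the single-word and
abstract-word accuracies. Clinical-group subjects at or above the 0.90
cutoff are typically-performing (TP), below it lower-performing (LP);
control subjects below the cutoff are excluded from the trimmed comparison
subgroup. The boundary value counts as typical-performing (the cutoff
semantics are "at typical levels"); both the cutoff and the choice of
composite are configurable.

Behavioral measures (accuracy and reaction-time composites, executive
composite, language score) are correlated with each edge's reconfiguration
after residualizing **both** sides on an intercept, age (years) and head
motion (RMSD, mm; mean of rest and task by default, either alone by
config). Missing behavioral values are dropped pairwise per measure, never
listwise, and the per-measure n is recorded. The object of interest is the
distribution of the E coefficients per group; group contrasts use the
rank-sum test. Summary tables report the median and, as a descriptive
spread, the SD of the E coefficients.

## Synthetic-cohort generator

The generator emulates the study conditions the pipeline targets: 30 + 23
subjects (clinical/control), 16 ROIs (120 edges), TR 1.25 s, one rest scan
and two task runs, and phenotypes with the published group means/SDs
(accuracy mixes 0.95 ± 0.03 / 0.83 ± 0.05 for the two clinical subgroups
and 0.96 ± 0.02 with a small 0.86 ± 0.03 tail for controls; RMSD ≈ 0.06–0.07
± 0.02–0.03 mm; executive composite 65.7 ± 7.4 vs 46.4 ± 8.0; language
score 35.2 ± 4.2 vs 36.0 ± 2.4; ages uniform on 11–21 years). Default
planted FC medians are 0.41/0.40 (clinical rest/task) and 0.30/0.30
(control); default reconfiguration targets 0.11 and 0.09.

Generative model on the z scale, per group g and subject s:

```
rest_se  = T_g,e              + a_se + ε_se
task_se  = T_g,e + (m_task − m_rest) + a_se + δ_s u_se + ε'_se   (two runs)
```

- **Template** T_g: Gaussian draw with the planted median and spread
  (default spread 0.20, matching the printed spread of the edge
  distributions), recentred so its empirical median equals the planted
  value exactly. Without recentring, the median of 120 draws wobbles by
  ~0.20·1.25/√120 ≈ 0.023 across seeds — larger than the ±0.02 recovery
  tolerance the generator is validated against, i.e. pure order-statistic
  noise would dominate the quantity being validated. The task template is
  the rest template plus the scalar planted median difference (an
  independent redraw would inject ~√2·spread of spurious per-edge
  "reconfiguration").
- **Idiosyncrasy** a_s: per-subject Gaussian edge deviation (SD 0.15
  clinical, 0.08 control), fixed per subject and shared across states.
  These SDs are this package's choice: they produce clearly separated
  inter-subject similarity in the planted direction (clinical less similar)
  at the defaults. Because a real cohort has shared nuisance variability
  the generator omits, the resulting similarity effect sizes are much
  larger than empirical ones; passing tests demonstrate recovery of planted
  structure, not realism of effect magnitudes.
- **Task shift** δ_s·u_s: u_s is a random ±1 pattern over edges (fixed per
  subject, shared by both runs), and δ_s = δ·(1 + 0.5·q_i) uses stratified
  standard-normal quantiles q_i assigned by seeded permutation, truncated
  at 0. The coefficient of variation 0.5 makes reconfiguration genuinely
  heterogeneous across subjects — each edge's reconfiguration then
  correlates ~0.9 with the subject mean, which is what lets a planted
  behavior coupling ρ reappear as a median edge coefficient near ρ. The
  stratified (rather than iid) design pins the cohort-mean scale at δ,
  whose sampling wobble (~0.5·δ/√n ≈ 0.01) would otherwise exhaust the
  ±0.01 recovery tolerance on the reconfiguration median. Consequence: the
  δ_s assignment depends on cohort size, while all other per-subject
  streams are stable under cohort growth.
- **Noise** ε: per-run Gaussian (SD 0.02 in matrix mode). The rest-minus-
  averaged-task noise difference has SD √1.5·0.02, giving a closed-form
  noise floor (median |Δ| = 0.674·√1.5·noise_sd at δ = 0) that the tests
  check.
- **Calibration**: δ is found by bisection against a Monte-Carlo simulation
  of the generative model with common random numbers, measuring exactly
  what the pipeline reports — the median over edges of the per-edge
  group-mean |Δ| (tolerance 0.001). Targets below the floor measured at
  δ = 0 raise an error reporting the floor.
- **Behavioral coupling**: each measure is linear in the subject's true
  mean reconfiguration with configured per-group ρ, using an
  exact-sample-correlation construction (noise orthogonalized against the
  standardized reconfiguration). ρ defaults couple the clinical group only
  (accuracy −0.3, RT +0.3, executive composite −0.3, language +0.3),
  emulating group differences in coupling distributions. For accuracy, the
  subgroup-mix variance attenuates the realized correlation below ρ.
  A configurable number of executive-composite scores (default 7) is
  blanked to emulate questionnaire non-return.

**Time-series mode** maps each state's true edge vector through tanh,
repairs it to the nearest correlation matrix, and samples T multivariate-
Gaussian timepoints, so estimation noise arises naturally (per-run SD floor
≈ 1/√(T−3) on the z scale). At R = 16 and spread 0.20 the unconstrained
tanh image is essentially never positive semi-definite, so the repair uses
Higham (2002) alternating projections with an eigenvalue floor of 1e-6 —
a one-shot eigenvalue clip followed by diagonal rescaling shrinks all
planted edges by several hundredths, whereas the nearest-matrix projection
perturbs the planted median by ~0.01. Because the repair partially absorbs
the high-rank shift pattern, time-series mode calibrates δ against the full
generative path (repair → sampling → Pearson → z → run averaging) rather
than the matrix-mode closed-noise model. Matrix mode is the primary
validation path; time-series mode exercises the estimation and filtering
front end. The Gaussian sampler is white in time — no hemodynamic
autocorrelation, no motion artifacts — so temporal-df effects of real BOLD
are not emulated.

All randomness flows from one master seed through named `SeedSequence`
substreams (per purpose, per subject, per state); cohorts are byte-identical
for identical (config, seed).

## Validation problem sizes

The test suite validates planted-median recovery on cohorts of n = 15–30
(matrix mode), statistical calibration with 500 simulated edge-test
datasets, 2000 permutation-test null simulations at B = 999 (Monte-Carlo SE
~0.005 against the ±0.015 band), 1000 simulated 120-edge FDR families with
30 planted effects (so expected false-discovery proportion is strictly
below q and the bound is testable), idiosyncrasy monotonicity over
{0.05, 0.1, 0.2, 0.4} × 20 seeds at n = 30, behavior-coupling recovery at
n = 200, and mode agreement at T = 2000 with n = 12. The full suite runs in
well under a minute on one CPU.

## Known limitations

- Distribution-level tests over edges inherit the edge-dependence caveat
  above; they are reproduction-faithful, not calibrated.
- The generator's idiosyncrasy model is additive Gaussian on edges; it has
  no spatial structure, no shared nuisance sources, and no subgroup-specific
  reconfiguration by default (subgroup contrasts are validated on separately
  configured cohorts).
- Typicality's baseline (reference leave-one-out) and the permuted
  statistic (Cohen's d) are interpretation choices among defensible
  alternatives; both are flagged in output metadata.
- The 90% cutoff uses the SW+AW composite; whether the inhibition condition
  should enter the composite is configurable but defaults off.
- Volumetric ingestion (NIfTI + label mask) is a convenience helper outside
  the validated path.
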