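# Methods

## Problem and data model

Glaucomatous damage to the retinal nerve fiber layer (RNFL) is usually
asymmetric between a patient's two eyes, while healthy eyes are close to
mirror images of each other. The pipeline therefore works on *paired*
peripapillary OCT measurements: for each patient, each eye contributes
the mean RNFL thickness (µm) of the six TSNIT sectors — temporal-superior
(TS), temporal (T), temporal-inferior (TI), nasal-superior (NS), nasal
(N), nasal-inferior (NI) — plus the global 360° mean G. T and N span 90°,
the other four sectors 45°; when a device-reported G is absent it is
derived as the angle-weighted sector mean `G = Σ_S extent_S · w_S / 360`.
Device-reported G values are kept verbatim when present, because devices
average per A-scan and can differ from the sector-mean combination by a
few hundredths of a micrometre.

Each patient carries one diagnosis label (healthy / glaucoma) valid for
both eyes; cohorts with discordant per-eye diagnoses are out of scope and
the CSV reader rejects unpaired or mixed-label rows.

## Asymmetry metrics

All metrics start from the per-sector inter-eye difference
`δ_{S,i} = w^r_{S,i} − w^l_{S,i}` (µm) and differ in normalisation:

| id | definition | range |
|----|-----------|-------|
| `delta`, `abs_delta` | δ, \|δ\| | µm |
| `Delta`, `abs_Delta` | δ / (w^r + w^l) per patient and sector | [−1, 1], [0, 1] |
| `Delta_bar`, `abs_Delta_bar` | δ / (w̄^r_S + w̄^l_S), cohort sector means | [−1, 1], [0, 1] |
| `Delta_dbar`, `abs_Delta_dbar` | δ / (w^r_G + w^l_G), patient's global sum | [−1, 1], [0, 1] |
| `sqrt_abs_Delta` | √\|Delta\| (gamma compression) | [0, 1] |

The cohort reference means are computed over the *pooled* cohort (both
diagnosis groups), matching how the reference summaries were produced; an
externally supplied reference can be passed instead. Because the
cohort-referenced variants divide every patient by the same constant, any
linear group statistic (mean, SD) of `Delta_bar` equals the corresponding
`delta` statistic divided by that constant — the identity the acceptance
script exploits. At the G column, `Delta_dbar` coincides with `Delta`
exactly.

Gamma compression (the square root) is applied only to `abs_Delta`: its
values are non-negative and bounded by 1, so the concave power law
spreads the mass near zero apart and increases the separation between the
healthy and glaucoma distributions without reordering them.

## Statistical characterization

Signed metrics are zero-centred in both groups (the subtraction direction
is arbitrary); disease shows up as *variance*, and taking magnitudes
converts that variance into a mean shift: if δ ~ N(0, σ²), then
E|δ| = σ·√(2/π) (half-normal mean law).

Group comparison defaults to the two-sided Wilcoxon rank-sum
(Mann–Whitney U): group sizes are unequal (160 vs 47) and the magnitude
metrics are markedly non-normal. The implementation uses the exact U null
distribution when the combined sample size is ≤ 25 and the tie-corrected
normal approximation otherwise; Welch's t is available as an option.
Degenerate all-tied input returns p = 1 with a warning. Sample SDs use
the n−1 denominator. Box-plot summaries use linear-interpolation
quantiles, 1.5·IQR whisker fences, and a median notch of half-width
1.57·IQR/√n (the standard 5 %-level median-comparison convention).

## Classification tree

The screening model is a from-scratch binary CART over the 7 asymmetry
features of one metric:

- **Impurity**: weighted Gini, `1 − p_h² − p_g²`, on per-class weight
  sums. Each observation carries its class weight (w_h, w_g), normalised
  to sum to one over the training set.
- **Split search**: exhaustive over all features; candidate thresholds
  are midpoints between consecutive distinct sorted values; ties broken
  by lowest feature index, then smallest threshold. The rule is
  `value < threshold → left`; exact equality goes right.
- **Growth**: best-first under a split budget ξ — at each step the leaf
  whose best split yields the largest *global* impurity decrease (local
  decrease × leaf weight share) is split; growth stops at ξ splits or
  when no leaf improves. ξ therefore bounds the number of internal
  nodes, not the depth.
- **Leaves** predict the class with the larger weighted proportion; an
  exact tie predicts glaucoma (the positive class — a screening tool
  should fail toward sensitivity).
- **No pruning**, no minimum leaf size, no surrogate splits: complexity
  is controlled only by ξ.
- **Model selection**: stratified 5-fold cross-validated classification
  loss — within each class, a seeded shuffle deals patients round-robin
  into folds; the loss is the summed weight of misclassified held-out
  observations, with weights normalised over the full dataset so it lies
  in [0, 1]. By default the loss uses the class weights
  (`loss_weighted=True`); a plain-count variant is exposed because either
  convention is defensible.

A known, and here deliberate, limitation: greedy best-first growth is
not globally optimal. On label patterns with interaction structure
(XOR-like arrangements), *no* greedy CART — including the reference
implementations this design mirrors — attains the loss of the best tree
found by exhaustive enumeration; on small random-label instances this
occurs in roughly 3 % of cases, always with budget ≥ 2. The test suite
therefore validates the split search by exact gain-equality against an
independent reference implementation and by enumeration equality for
single-split trees, and documents the structural greedy/optimal gap
rather than hiding it.

## Screening evaluation

Glaucoma is the positive class. From TP/FP/TN/FN: accuracy, sensitivity
(TPR), specificity (TNR), precision (PPV). Ratios are exact; rounding
(half away from zero, 4 decimals) happens only in reports. Undefined
ratios (zero denominator) are reported as missing rather than 0.
`reconstruct_confusion` inverts published sensitivity/specificity to
integer counts via `TP = round(TPR·n_g)`, `TN = round(TNR·n_h)`, which
lets printed rate tables be checked for internal consistency; comparisons
against printed values use a 1e−4 tolerance to absorb occasional
truncation in publication.

## Synthetic cohort generator

No patient-level data are available, so the generator draws cohorts whose
summary statistics match the published reference cohort by construction:

- **Group sizes** 160 healthy / 47 glaucoma (defaults).
- **Per patient**: a bilateral level `b_S = base_S + u`, with `base_S`
  the midpoint of the published right/left sector means and
  `u ~ N(0, between_patient_sd²)` shared by both eyes; a 6-vector of
  inter-eye differences δ from a multivariate normal with the published
  per-sector, per-group means and SDs and an exchangeable cross-sector
  correlation ρ. Eyes are `w^r = b + δ/2`, `w^l = b − δ/2`, so the
  difference distribution and the per-eye mean levels are both hit
  exactly. Patients with any non-positive thickness are redrawn
  (rejection is negligible at these scales; > 1000 rejections raises).
- **ρ calibration**: the global difference is the angle-weighted
  combination `δ_G = Σ a_S δ_S` (`a_S = extent_S/360`), so
  `var(δ_G) = Σ a_S²σ_S² + ρ Σ_{S≠S'} a_S a_{S'} σ_S σ_{S'}` is linear in
  ρ and inverted in closed form against the published global-difference
  SD. With the defaults this gives ρ ≈ 0.073 (healthy) and ρ ≈ 0.564
  (glaucoma). G is always computed from the sectors, never drawn, keeping
  the global-sum normalisers internally consistent.
- **between_patient_sd** defaults to 10 µm: level heterogeneity is not
  reported in the reference summaries, this is a modelling choice at a
  scale typical of normative RNFL databases, and no asymmetry metric is
  sensitive to it (it cancels in δ).
- Age and sex are drawn from the published group marginals for realism
  but carry no signal and are not features.

What passing tests on this generator do **not** show: the generator has
no cross-sector correlation of *levels*, no measurement/segmentation
error, no floor effect of advanced atrophy, and normal (not skewed)
difference distributions — real-cohort performance of the tree is
therefore not predicted by the synthetic accuracy bands, which only check
that the pipeline's behaviour is qualitatively right (global asymmetry
dominates the root split; accuracy in a plausible screening range).

## Problem sizes and numerics

Default analyses run on 207-patient cohorts (seconds). Monte-Carlo
checks use 10⁵ draws for the half-normal law (≈1 % accuracy) and 10⁵
multivariate draws for the ρ calibration (2 %). The end-to-end band uses
20 cohort seeds. The brute-force tree oracle is limited to n ≤ 8, two
features and budget ≤ 2, where exhaustive enumeration is cheap.

All randomness flows through `numpy.random.default_rng` seeds; the two
simulated groups consume independent spawned child seeds so one group's
size does not perturb the other's draws, and identical seeds reproduce
cohort CSVs byte-for-byte.
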