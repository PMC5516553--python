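# Methods

## The analysis being modeled

The pipeline reproduces a data-driven subtyping workflow for early-stage
Parkinson's disease (Hoehn & Yahr I–III, complete cases): derive nine
clinical variables per patient, z-standardize them, cluster with k-means
over k = 2..5, choose k by local peaks of the cubic clustering criterion,
then profile the resulting subgroups — PD-MCI by the MDS Level-1 rule,
comorbid symptoms by questionnaire cutoffs, and held-out variables by a
normality-gated test battery.

## Derived variables

* **Progression rate** = total MDS-UPDRS I–III / disease duration (years).
  Durations are floored at 0.25 y inside the quotient; the floor only guards
  degenerate synthetic inputs (the shortest subgroup mean duration is
  ~2.1 y), preventing unbounded rates.
* **Motor phenotype score** = mean(tremor items) / mean(non-tremor items),
  each lateralized item contributing its higher left/right score.  A zero
  denominator with non-zero tremor maps to 5.0 (keeps the standardized
  column finite; 5.0 exceeds any plausible subgroup mean), 0/0 maps to 0.
  Which raw score names belong to the tremor set, the non-tremor set and
  the left/right pairs is site-dependent configuration (`ItemMap`), not
  code; the default uses a flattened numbering dialect (tremor: 23, the
  54/55 pair, 59; non-tremor: 28–44 with 33–37 lateralized).
* **Dopaminergic therapy ordinal**: 0 = no L-dopa/agonist; 1 = L-dopa
  < 1000 mg/day (± agonist) or agonist monotherapy; 2 = ≥ 1000 mg/day.  The
  boundary dose 1000 mg/day is assigned to the higher-exposure class.
* **Standardization** uses the sample SD (n − 1).  Constant columns map to
  zeros with a logged warning instead of erroring.

## PD-MCI and symptom classifiers

Level-1 PD-MCI requires ≥ 2 impaired tests in an 8-test battery (MMSE,
TMT-A/B, digit span, LM-I/II, COWAT FAS/animals — configurable) **and** a
subjective complaint (MDS-UPDRS item 1.1 ≥ 1).  "Impaired" is
operationalized on the normative z-scale relative to the premorbid estimate:
premorbid z = (NART-R IQ − 100)/15, and a test is impaired iff
z ≤ premorbid z − 1.5.  This is the only reading that uses the NART-R as a
premorbid level and SD units consistently.

All cutoffs are inclusive at the first abnormal value (BDI-II 13/14 → ≥ 14;
ESS ≥ 10; SCOPA-S DS 4/5 → ≥ 5; NS 6/7 → ≥ 7; RBDSQ ≥ 5; FOG-Q item 3 ≥ 1;
hallucination = SCOPA-PC item 1 ≥ 1 AND MDS-UPDRS item 1.2 ≥ 1).

**Percentage rounding.** Printed percentages use a two-stage convention:
round to one decimal, then to the nearest integer (half away from zero).
This is the convention that reproduces the reference cohort composition
(93/209 = 44.498 % → 44.5 → 45 %) as well as every frequency-table entry;
single-stage rounding differs only in the [x.45, x.50) band.

## Cluster engine

Lloyd k-means with k-means++ initialization, best of `restarts` (default
50) random starts, at most 300 iterations, convergence on unchanged
assignments.  Empty clusters are repaired by reseeding to the point
farthest from its current centroid (deterministic).  WSS is asserted
non-increasing across iterations.  All randomness flows from one integer
seed; per-k seeds in a scan are spawned from it.

The **cubic clustering criterion** follows Sarle's 1983 derivation
(SAS Technical Report A-108): with s₁ ≥ … ≥ s_p the square roots of the
eigenvalues of the covariance of the (centered) clustered matrix, an initial
cut c = (∏s_j / q)^{1/p} fixes the effective dimensionality
p* = min(#{s_j/c ≥ 1}, q − 1); c is then recomputed over the top p* values,
u_j = s_j/c, and

E(R²) = 1 − [(Σ_{j≤p*} 1/(n+u_j) + Σ_{j>p*} u_j²/(n+u_j)) / Σ u_j²] ·
        [(n−q)²/n] · (1 + 4/n),
CCC   = ln[(1−E(R²))/(1−R²)] · √(n·p*/2) / (0.001 + E(R²))^{1.2}.

Model selection takes the k whose CCC exceeds both neighbors (largest CCC
among several peaks, ties to smaller k); a monotone curve yields the curve
maximum flagged as `boundary_max`.  Four-cluster solutions are named by
centroid evidence: TD = highest motor-phenotype mean, RDP = highest
progression rate among the rest, YO = lowest onset age among the remainder,
NTD = last; other k get generic names.

### CCC behavior worth knowing

Verified properties of this implementation: CCC = 0 exactly when
R² = E(R²); sharp interior peak at the true k on well-separated equal-size
blobs; negative, decreasing values on a single Gaussian and on uniform
data (the classical signature of unclustered data).  Two caveats:

* Under the uniform null the criterion is *conservative*, not centered:
  E(R²) is an analytic approximation for idealized hyperbox partitions and
  exceeds what Lloyd k-means attains on uniform data, and the gap is
  amplified by √(n·p*/2) — at n = 5000, p = 9 the null CCC runs from about
  −5 (k=2) to −30 (k=5) rather than hovering near 0.
* On mixtures of overlapping Gaussians, splitting a Gaussian-tailed cluster
  keeps earning more R² than the uniform null expects, so the CCC curve can
  rise monotonically past the latent k.  On the default synthetic cohorts
  (below) this is the typical outcome: the curve rises through k = 5 and
  the boundary maximum is reported, even though a 4-cluster fit recovers
  the latent subgroups well above chance.  Interior peaks at the latent k
  appear only when separation is much larger than the default profiles
  encode.

## Group statistics

Normality is checked per subgroup with a Lilliefors-style KS test
(parameters estimated from the sample; constant samples are degenerate and
reported non-normal).  A variable goes parametric only if every subgroup
passes at α = 0.05.  Parametric route: one-way ANOVA then pooled-variance
unpaired t-tests (Welch behind a flag).  Nonparametric: tie-corrected
Kruskal–Wallis then Mann–Whitney U with midranks; U is reported as
min(U₁, U₂).  The Mann–Whitney p is exact (full enumeration of
C(n₁+n₂, n₁) rank assignments) when n₁+n₂ ≤ 12, otherwise a tie-corrected
normal approximation *without* continuity correction — this makes the
two-sample Kruskal–Wallis χ²(1) p coincide with the Mann–Whitney p in the
absence of ties, a property the test suite asserts.  All tests are
two-tailed at α ≤ 0.05 with no multiple-testing correction; reports carry
an explicit uncorrected-α annotation.

## Synthetic cohort generator

The generator emulates the *statistical shape* of a 209-patient early-PD
cohort with four latent subgroups mixed at 45/12/23/21 % (renormalized from
printed percentages summing to 101 %).  Per subgroup it encodes marginal
means/SDs for twelve continuous variables (onset age, duration, progression
rate, motor ratio, NART-R, MMSE, LM-II z, TMT-B z, BDI-II, LEDD, H&Y,
PDQ-39 cognition) and prevalences for six binary symptoms plus PD-MCI.

Design choices:

* **Truncated normals via rejection** (resample until inside the instrument
  range), never clipping: clipping would create boundary atoms.  Note that
  rejection at a hard floor shifts realized means upward for near-floor
  variables (e.g., a nominal motor-ratio mean of 0.43 realizes ≈ 0.54);
  this is inherent to parameterizing the pre-truncation normal with the
  reported moments.
* **Within-subgroup independence**: only marginal moments are encoded; no
  correlation structure is imposed.  Real clinical variables correlate, and
  real subgroups defined by a k-means partition occupy disjoint regions of
  feature space — resampled overlapping normals are strictly more diffuse.
  Passing tests on these cohorts therefore demonstrate the machinery, not
  real-data effect sizes, and the monotone-CCC behavior above is partly a
  consequence of this diffuseness.
* **Score back-filling**: binary symptom draws are written into the
  questionnaire scores (positive → at/above the cutoff, negative → below),
  so classifier output reproduces the drawn state exactly.  MDS-UPDRS items
  are back-filled so the derived motor ratio equals its sampled target
  exactly (tremor/non-tremor items share common means in the target ratio,
  integers except one fractional correction item per set) and part totals
  sum exactly to rate × duration; when the natural item scores exceed that
  budget they are scaled down ratio-preservingly, and in the rare case of a
  tiny budget the totals are distributed proportionally at the cost of
  item/total coherence.  Rate is sampled jointly with duration so the
  implied total never exceeds the instrument maximum (236).
* **Two MCI modes**: `profile` lets PD-MCI emerge from the sampled
  neuropsychological scores (subjective-complaint probability set to the
  subgroup MCI prevalence + 0.2, complaints being more common than the
  diagnosis); `prevalence` draws PD-MCI Bernoulli at the subgroup
  prevalence and constructs the battery to reproduce it exactly —
  marginal tables over-determine the joint distribution, so both views are
  needed.  In `prevalence` mode the forced LM-II/TMT-B z-scores override
  their subgroup means.
* **BDI-II integers by flooring** the continuous draw, which preserves
  P(score ≥ cutoff) of the continuous model exactly.
* Untested niceties kept realistic: sex ratio 144:69 M:F, agonist flag at
  29 %, age = onset + duration, auxiliary battery tests centered between
  the LM-II and TMT-B subgroup means with unit SD.  MMSE enters twice (raw
  for clustering, a separately sampled normative z in the battery); the two
  are deliberately not linked deterministically, as normative z depends on
  age/education norms not modeled here.

What the generator does **not** emulate: longitudinal change, missingness
(complete cases only), within-subgroup correlations, sex-specific profiles,
untreated patients (LEDD rejection sampling leaves no mass at 0 mg/day).

`make_count_fixture` builds deterministic cohorts in which exactly the
requested number of records per subgroup classify positive for one named
feature — used for count-exact frequency tables.

## Problem sizes and determinism

Default analyses run at the emulated study scale (n = 209, k = 2..5, 50
restarts; ≈ 0.3 s).  Distributional checks in the test suite use 20,000
generated patients (moment recovery, depression prevalence) and 10,000 per
subgroup (classifier prevalence recovery, binomial SE ≈ 0.5 points).  Every
stochastic component — generator, k-means starts, scan — is driven by a
single integer seed, and identical seeds reproduce cohorts, partitions and
reports bit-for-bit.

## Known limitations

* The CCC/k-means model-selection behavior on diffuse Gaussian synthetic
  mixtures differs qualitatively from what hard-partitioned clinical data
  can show (monotone curves vs interior peaks); see above.
* Exact Mann–Whitney enumeration is limited to combined n ≤ 12 (C(12,6) =
  924 arrangements); beyond that the tie-corrected normal approximation is
  used.
* The Lilliefors p-value uses the table approximation from statsmodels,
  accurate near conventional α but truncated in the extreme tails.
* LEDD is consumed directly as the L-dopa dose for the therapy ordinal;
  computing LEDD from a medication list is out of scope.
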