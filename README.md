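# pdsubtypes

Data-driven subtyping of early Parkinson's disease (PD) cohorts, packaged as
a tested, reusable pipeline with a synthetic-cohort generator.

PD is clinically heterogeneous: age at onset, the balance of tremor vs
non-tremor motor signs, and the pace of progression vary widely, and mild
cognitive impairment (PD-MCI) is distributed unevenly across the spectrum.
This package re-creates a classic data-driven approach to that heterogeneity
for biostatisticians and clinical researchers who want to run, probe or
extend it:

1. **Feature derivation** — nine clinical variables per patient: motor
   phenotype score (ratio of mean tremor-item to mean non-tremor-item
   severity on the MDS-UPDRS, lateralized items contributing their higher
   side), age of disease onset, rate of disease progression
   (total MDS-UPDRS I–III / disease duration in years), NART-R estimated IQ,
   MMSE, Logical Memory II *z*, Trail Making Test B *z*, BDI-II, and a 0–2
   dopaminergic-therapy ordinal — then column-wise *z*-standardization.
2. **Cluster engine** — Lloyd k-means (k-means++ starts, best of *r*
   restarts, deterministic given a seed) over k = 2..5, scored with Sarle's
   cubic clustering criterion

   CCC = ln[(1 − E(R²))/(1 − R²)] · √(n·p*/2) / (0.001 + E(R²))^1.2,

   where E(R²) is the expected variance explained under a uniform-hyperbox
   null and p* the effective between-cluster dimensionality; the number of
   clusters is chosen at a local CCC peak (curve maximum if the curve is
   monotone). Four-cluster solutions are named clinically: **TD** (tremor
   dominant), **RDP** (rapid disease progression), **YO** (younger onset),
   **NTD** (non-tremor dominant).
3. **Phenotype classifiers** — MDS Task Force Level-1 PD-MCI (≥2
   neuropsychological tests at least 1.5 SD below the NART-R-estimated
   premorbid level, plus a subjective complaint on MDS-UPDRS item 1.1), and
   questionnaire cutoffs for depression (BDI-II ≥ 14), excessive daytime
   sleepiness (ESS ≥ 10), sleep disturbances (SCOPA-S DS ≥ 5, NS ≥ 7),
   probable RBD (RBDSQ ≥ 5), freezing of gait (FOG-Q item 3 ≥ 1) and
   hallucinations (SCOPA-PC item 1 ≥ 1 confirmed by MDS-UPDRS item 1.2 ≥ 1).
4. **Group statistics** — Lilliefors normality gate routing each held-out
   variable (age, disease duration, H&Y stage, PDQ-39 cognition dimension)
   to ANOVA + unpaired t-tests or Kruskal–Wallis + Mann–Whitney U
   (exact enumeration at small n), two-tailed, α = 0.05, uncorrected.
5. **Synthetic cohorts** — since no patient-level data are distributed, a
   seeded generator emulates a 209-patient cohort with four latent
   subgroups (weights 45/12/23/21 %), truncated-normal marginals inside
   instrument ranges, Bernoulli comorbid symptoms written back into
   questionnaire scores, and MDS-UPDRS items back-filled so derived scores
   reproduce their sampled targets. Count-exact fixtures support
   deterministic frequency tables.

## Worked example

```python
from pdsubtypes import CohortSpec, generate_cohort, build_feature_matrix, run_cluster_scan
from pdsubtypes.cluster import label_clusters

cohort = generate_cohort(CohortSpec(n=209, seed=2))
features = build_feature_matrix(cohort)
solutions, profile = run_cluster_scan(features, restarts=50, seed=2)
for s in solutions:
    print(f"k={s.k}: R2={s.r2:.3f}  CCC={s.ccc:+.2f}")
names, evidence = label_clusters(next(s for s in solutions if s.k == 4), features)
print(evidence.round(2))
```

prints

```
k=2: R2=0.156  CCC=-1.74
k=3: R2=0.258  CCC=-1.92
k=4: R2=0.337  CCC=-0.54
k=5: R2=0.392  CCC=+0.59
           motor_phenotype  progression_rate  age_onset label
cluster_0             0.57              5.47      60.19   NTD
cluster_1             0.75              5.65      55.16    YO
cluster_2             1.73              9.12      62.76    TD
cluster_3             0.75              20.06     69.90   RDP
```

R² grows with k; the CCC weighs that growth against the uniform null.  The
named 4-cluster solution shows the expected clinical pattern: one cluster
with a tremor-dominant motor ratio (1.73), one progressing at 20 UPDRS
points/year with the oldest onset, one with the youngest onset, and a
non-tremor-dominant remainder.  On these synthetic cohorts the CCC curve is
typically monotone over 2..5 (see `docs/methods.md` for why), so the
boundary maximum k=5 is reported rather than an interior peak.

A deterministic frequency table (`examples/04_mci_and_symptoms.py`):

```
per-subgroup frequencies (%):
                                 YO  TD NTD RDP
PD-MCI                           24  42  54  25
...
```

i.e., with subgroup sizes 93/24/48/44 and PD-MCI counts 22/10/26/11, mild
cognitive impairment concentrates in the non-tremor-dominant subgroup (54 %).

The `examples/` directory holds one short narrative script per capability;
a thin CLI (`pdsubtypes simulate|run|fixture`) wraps the same functions for
shell use.

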