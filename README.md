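# neurotyp

Typicality of brain activity under naturalistic stimulation, and its
association with personality traits.

## The problem

When subjects watch the same movies in the scanner, their evoked BOLD
responses are partly shared and partly idiosyncratic. Because free viewing
has no task regressors, a general linear model cannot summarise how
"stimulus-driven" a subject is. A simple alternative is *typicality*: how
closely a subject's multivariate time series (ICA component or atlas-ROI
time courses) follows the group-average response. Individual differences in
that one number can then be related to stable psychological traits — here,
the 12 scores of two standard personality inventories (NEO-FFI: N, E, O, A,
C; TCI: NS, HA, RD, Pe, SD, Co, ST).

## The statistic

For K signals observed over T volumes (TR = 2.5 s, band-pass filtered
0.009–0.1 Hz with a zero-phase second-order Butterworth filter), the
*typical time series* of signal k is the subject average
x̄ₖ(t) = (1/n) Σₛ x₍ₛ,ₖ₎(t). Subject s's *similarity profile* is the
vector of Pearson correlations

  rₛₖ = corr( x₍ₛ,ₖ₎ , x̄ₖ ),  k = 1…K,

and their *typicality index* is the plain mean τₛ = (1/K) Σₖ rₛₖ.
Subjects with τₛ more than 1.5 interquartile ranges outside the quartiles
are removed and everything is recomputed once. A leave-one-out variant
excludes subject s from x̄ₖ, removing the include-self upward bias.

Downstream, the 12 trait scores are reduced by correlation-matrix PCA;
typicality is related to the first principal components (and to individual
traits, and per-signal similarity indices) by Spearman rank correlation
with Benjamini–Hochberg FDR control within each analysis family, by
canonical correlation analysis with sequential Wilks-Λ / Rao-F tests, and
— for the functional-connectivity variant — by partial Spearman
correlations controlling for age. Anderson–Darling normality tests justify
the rank-based choices. A synthetic-cohort generator with a known
trait–coupling ground truth makes every stage testable end to end.

## Worked example

Simulate a cohort at the study's scale (82 subjects, 39 components, 714
volumes across three video segments, 3 planted pure-noise subjects) and run
the full battery:

```bash
neurotyp simulate --out demo/cohort --seed 7
neurotyp run-all --cohort demo/cohort/manifest.csv \
                 --personality demo/cohort/personality.csv --out demo/results
# n=79 after outlier removal (removed ['sub-007', 'sub-026', 'sub-045']); ...
```

The three removed subjects are exactly the planted pure-noise subjects
(see `demo/cohort/ground_truth.json`). `demo/results/` then contains the
typicality indices, similarity profiles, PCA loadings/scores (first two
components explain 43.8% + 30.1% of trait variance for this seed), the
primary association family — e.g. this replicate estimates
Spearman ρ = 0.096 (q = 0.418) between typicality and PC1 over all
stimuli, a draw from the sampling distribution around the planted
population value ρ ≈ 0.30 at n ≈ 80 (SD ≈ 0.11) — the per-trait and
per-signal tables, and the CCA report
(first canonical r = 0.884, F(468, 364) = 0.904, p = 0.848: with 12 and 39
variables at n = 79, high canonical correlations arise even without any
true multivariate association).

The same operations are available as a library:

```python
from neurotyp import (SyntheticCohortConfig, generate_cohort,
                      filter_cohort, compute_typicality)
cohort, personality, covariates, truth = generate_cohort(SyntheticCohortConfig(seed=7))
result = compute_typicality(filter_cohort(cohort))
result.indices, result.removed_subjects
```

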