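# Methods

This note records the statistical model behind each stage, the defaults that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions adopted where the design was genuinely open.

## Bipartite modularity biclustering

The case-only patient×comorbidity incidence matrix `A` defines a bipartite
graph with patient degrees `k_i`, comorbidity degrees `d_j` and `m = Σ A_ij`
edges. For a joint labelling `g` of both node families, Barber's bipartite
modularity is

    Q = (1/m) Σ_{i,j} (A_ij − k_i d_j / m) · δ(g_i, g_j),

the within-bicluster edge fraction minus its expectation under a
degree-preserving random bipartite null. `Q = 0` for the one-cluster
partition on any graph, and `Q = 1 − 1/K` for K equal, fully dense, disjoint
biclusters — both used as exact regression anchors in the tests, together
with an exhaustive-partition oracle on graphs of ≤ 9 nodes.

**Optimisation.** BRIM-style alternating sweeps: fixing comorbidity labels,
each patient's optimal label maximises its modularity contribution
(a single `(n×L)` matrix product), then the roles swap; a fixed point is a
local optimum. We run `restarts` seeded random comorbidity labellings
(default 20) plus an agglomerative warm start — average-linkage Jaccard
clustering of comorbidity columns cut at every K in 2..min(d,12) — and keep
the best Q. Connected components are optimised independently (labels stay
disjoint); K is whatever survives at the optimum. Ties in the argmax break
toward the lowest label, making the fit deterministic given the seed. A
`max_sweeps` cap (200) guards non-convergence; hitting it logs a warning and
returns best-so-far.

**Significance.** No closed-form variance of an optimised Q exists, so
significance is a permutation test: each of `n_perm` permutations rewires the
graph by double-edge swaps (attempt budget 10·m) preserving *both* degree
sequences — degree heterogeneity would otherwise inflate z — and re-runs the
optimiser with a reduced restart budget (default 4) so the null reflects the
same search procedure as the observed statistic. A cruder row-shuffle null
(`null_model="shuffle"`, patient degrees only) is available as a switch.
Reported are z = (Q_obs − mean)/sd of the null, the normal-tail P, and the
empirical P = (1 + #{Q_null ≥ Q_obs})/(n_perm + 1), which can never be zero.
`n_perm < 20` is refused (unstable sd). Full-scale analyses use
n_perm = 1000; the test suite and acceptance script use 49–200 to keep a
single-CPU run in minutes — problem sizes are stated with every reported
number.

**Replication.** The two cohort halves share comorbidities but not patients,
so replication is judged on the comorbidity labellings only: the Rand index
(concordant pair fraction) between the training-half and replication-half
labellings, against a null that shuffles the replication labels over
comorbidities. Same z and empirical-P conventions.

## Feature screening

1:1 exact matching of controls to cases within joint demographic strata
(age band, sex, race, Medicaid eligibility), controls drawn uniformly without
replacement, seeded; unmatched cases are returned, never silently dropped.
Comorbidities with pooled matched-set prevalence < 1% are removed (exact
ties at the threshold are retained). Each remaining comorbidity gets a 2×2
case/control × exposed/unexposed odds ratio with Wald CI and two-sided P
(equivalent to univariable logistic regression; verified against a
statsmodels oracle to machine precision); zero cells get the
Haldane–Anscombe +0.5 correction and a degeneracy flag that excludes the
comorbidity from survival. Survival requires P < α/d_tested in *both*
halves, with d_tested the post-prevalence-filter count (filtering precedes
testing). The matched-pair structure is deliberately not conditioned on in
the univariable tests — plain unconditional ORs are what gets displayed on
the network — and the Wald statistic was chosen where likelihood-ratio or
score tests would also have been defensible. Patients with none of the
surviving comorbidities are dropped (count logged) before graph building.

## Subgroup classification

Multinomial logistic regression on the selected comorbidities, fitted with a
small L2 penalty (default strength 1e-2, recorded; an unpenalised switch
exists) because planted or near-separable cohorts make unpenalised maximum
likelihood diverge. Hard assignment takes the highest membership
probability; exact ties break toward the lowest subgroup index and raise a
per-patient flag; the full probability vector is always kept alongside,
since the hard label discards membership strength. Internal validation
refits on `n_splits` seeded 75/25 splits (default 1000; 100 in the
acceptance run), resampling any split whose training fold misses a subgroup,
and summarises both folds' accuracies as percent quantiles
(2.5/25/50/75/97.5), mean, SD, range. Subgroup risk is the case fraction
among patients classified into the subgroup — undefined (never zero) for
empty subgroups — and IS = membership probability × risk ranks subgroups per
patient with a stable descending sort.

## Readmission prediction

Binary logistic models fitted by maximum likelihood (statsmodels); the
hierarchical model adds K−1 subgroup indicators with the lowest label as
reference — a single integer code would impose a spurious ordering.
Separation or non-convergence triggers a recorded L2 refit rather than a
failure. Arbitrary variable lists are accepted, so published-model variable
sets can be emulated. On the held-out fold (default 25%):

- **Discrimination**: C = P(score_case > score_control) + ½P(tie), computed
  from midranks and checked against exhaustive pair counting; variance and
  CI from DeLong structural components. The standard-vs-hierarchical
  contrast uses the paired DeLong z with z² reported as a 1-df chi-squared —
  the natural reading of "a chi-squared test comparing C-statistics" when
  both models score the same patients. Identical score vectors return
  chi2 = 0, P = 1 exactly.
- **Calibration**: slope = coefficient of the linear predictor in a logistic
  refit of the outcome on it; calibration-in-the-large = intercept of a
  refit with the linear predictor as fixed offset (ideals 1 and 0).
- **Reclassification**: continuous NRI counts any directional risk change,
  categorical NRI counts cutpoint crossings; cutpoints are configurable and
  default to tertiles of the standard model's pooled predicted risk, echoed
  into the result because no canonical category set exists for readmission.
  IDI is the change in mean risk separation between events and non-events.
  Both use the standard large-sample normal variances; degenerate (zero-SE)
  cases return z = 0, P = 1.

## Synthetic cohorts

Each patient draws a subgroup (uniform by default, weights configurable),
carries each comorbidity of their subgroup's contiguous block with
probability `p_in` (default 0.4) and every other with `p_out` (default 0.05)
— remainder comorbidities go to the last block — and is readmitted with the
subgroup's risk (defaults 0.12/0.15/0.17/0.20, the spread observed in
elderly readmission cohorts). Demographics are sampled independently of
subgroup so that demographic matching removes no subgroup signal; a
confounding switch tilts the first demographic by subgroup for stress tests.
Exact case/control quotas are met by oversampling and truncation, so matched
designs get exact 1:1 sets; `sample_patients` exposes the untruncated draw,
under which the per-subgroup case fraction converges to the subgroup risk
(verified at n = 20,000 within ±0.02).

With subgroup-only risks in the 12–20% band, univariable comorbidity ORs are
necessarily mild (≈0.8–1.2), which real cohorts do not show; an optional
`comorbidity_log_or` vector therefore adds direct per-comorbidity log-odds,
with the per-subgroup intercept solved numerically so the mean subgroup risk
stays on target. The pipeline's demo default cycles 0.4/0.7/1.0 (ORs ≈
1.5–3), which is what lets Bonferroni screening retain most comorbidities at
desk scale. The generator emulates block co-occurrence, matched demographic
structure and subgroup-graded risk; it does not emulate correlated
comorbidity cascades, age-graded prevalence, coding noise, or temporal
structure — so passing tests certify the algorithms and their inferential
calibration, not performance on real claims data.

## Pipeline and reproducibility

One master seed spawns per-stage seeds through `numpy.random.SeedSequence`
(all < 2^31, logged), so any stage is independently reproducible; the
summary JSON is byte-identical across reruns of the same config. Stages
communicate through plain files (CSV tables, GraphML, SVG, JSON) and the CLI
refuses to run a stage whose prerequisites are missing or any stochastic
stage without a seed. Matched controls for the replication half are drawn
from the pool *after* removing the training half's controls, keeping the
halves' control sets disjoint.

## Known limitations

- BRIM sweeps find local optima; multi-restart plus the agglomerative warm
  start recovers planted structure reliably at the tested scales but carries
  no global-optimality guarantee beyond the exhaustively checked toy graphs.
- The permutation null re-optimises with fewer restarts than the observed
  fit, a mild anti-conservatism that is invisible at the tested effect sizes
  (type-I control holds at ≤ 2/20 in the null suite) but worth remembering
  near the significance boundary.
- Subgroup labels are identifiable only up to permutation; comparisons with
  planted truth use the adjusted Rand index or a majority-vote mapping.
- Bicluster membership enters prediction as a hard label; membership-
  probability-weighted hierarchical models are deliberately out of scope.
- No alternative biclustering backends (e.g. nonnegative matrix
  factorisation), no subgroup-specific prediction models with separate
  slopes, and no probability calibration of the multinomial classifier.
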