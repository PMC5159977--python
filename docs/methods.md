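# Methods

This note documents the models, numerical choices and known limitations of
`phenoclust`. It describes what the code computes; every empirical number
mentioned here is produced by the test suite or `scripts/acceptance.py`.

## Synthetic cohort model

The generator emulates a four-phenotype adult asthma cohort of 156
subjects (28/44/49/35 per phenotype) followed at baseline and 3, 6 and 12
months. Within each phenotype the nine clustering variables, sputum
differentials and demographics are drawn independently:

* normal variables (spirometry, reversibility, ACQ-7, AQLQ, sputum
  neutrophils, demographics) from the phenotype's mean and SD;
* right-skewed biomarkers (FENO, blood eosinophils, PC20, sputum
  eosinophils) log-normally, from the geometric mean and multiplicative
  geometric SD. A printed asymmetric interval `GM +u/−l` determines the
  GSD via `GSD = (GM+u)/GM = GM/(GM−l)`.

Physically impossible draws (ACQ-7 outside [0, 6], AQLQ outside [1, 7],
FEV1/FVC above 1.2, percentages outside [0, 100]) are **resampled, not
clipped**, preserving distribution shape inside the admissible range.
Resampling shifts the realized mean of strongly truncated variables
(e.g. a phenotype with ACQ-7 0.5 ± 0.5 realizes ≈ 0.65); tests therefore
validate sample means against the truncated-normal expectation, not the
raw location parameter.

Longitudinal dynamics: each subject's latent z-scores follow an AR(1)
process with autocorrelation 0.8 per visit (default), and at each
follow-up visit the subject switches, with probability 0.10, to a
uniformly chosen different phenotype whose distributions generate its
values from then on. The switch probability was set once so that the
majority of subjects keep a stable assignment over four visits while
follow-up discordance clearly exceeds the baseline misclassification
rate, matching the qualitative longitudinal behavior the pipeline is
meant to exercise; there is no subject-level longitudinal model to
calibrate against, so these dynamics are a stand-in, not an inference.

Methacholine PC20 is masked whenever the same visit's FEV1 falls below
60 %predicted (the challenge is not performed in that case), so PC20
missingness is exactly the event FEV1 < 60. Squamous-cell contamination of
sputum samples is drawn from Beta(2.5, 7.5) scaled to percent (mean 25%,
roughly a third of samples failing the ≤ 30% cytospin QC rule), so the QC
filter has real work to do on synthetic data.

Seeding: one master seed; each subject owns a `SeedSequence` spawned from
it by subject index, so subsetting the cohort never shifts another
subject's draws.

**What the generator does not emulate.** Variables are independent within
phenotype (no within-cluster correlation is available to parameterize; an
off-diagonal hook is deliberately absent from the defaults). Real clinical
variables are correlated, and empirical phenotypes derived from a
partitioning algorithm are crisper than a parametric mixture with the same
marginal spreads. Consequences are discussed under *Limitations*.

## Preprocessing

PC20 and FENO enter on the natural-log scale (any log base is equivalent
after rescaling); blood eosinophils stay as absolute counts. Each variable
is centered at its observed mean and divided by its mean absolute
deviation `s = mean(|x − mean|)` computed over observed cells only;
variables with zero spread are dropped with a warning. Mean centering was
chosen where the convention was ambiguous (median centering would also be
defensible); the choice is irrelevant to distances up to a constant shift
per variable. Scaling parameters are stored and re-applied verbatim to
validation cohorts and classifier inputs, so training and application
always share one coordinate system. Missing squamous content is treated
as a QC failure (conservative). Screening/baseline visit pairs merge by
arithmetic mean for differential cell counts and geometric mean for
analyte measurements; single-visit subjects pass through.

## Fuzzy c-medoids

Distances: `d(i,j) = sqrt(p/p_obs(i,j) · Σ_shared (z_i − z_j)²)` — the
Gower-style completion that rescales by the fraction of variables observed
in both subjects. A pair sharing no observed variable is an error rather
than an imputation.

The optimizer alternates the exact membership update
`u_iv ∝ d(i, medoid_v)^(−1/(m−1))` (membership 1 when a subject coincides
with a medoid) and the exact per-cluster medoid update
`argmin_x Σ_i u_iv^m d(i,x)`. Medoid distinctness is enforced greedily in
cluster order; if that constraint blocks the exact update and the
objective would rise, iteration stops at the best state seen. Convergence
is declared when the medoid set repeats; the objective is asserted
non-increasing at every unconstrained step. Defaults: fuzzifier 1.1,
50 random restarts, 200 iteration cap. Hard assignments break argmax ties
toward the lowest cluster index (deterministic).

Validity indices follow the classical partition-coefficient definitions
(`F`, `Fc`, `D`, `Dc` as in the README). Their analytic anchors — hard
partition ⇒ (Fc, Dc) = (1, 0); uniform memberships ⇒ (0, 1) — are the
contract, verified exactly. `select_k` maximizes Fc and warns when Dc's
minimizer disagrees.

The perturbation suite removes either the k medoid subjects or an entire
severity arm, re-clusters, aligns labels by Hungarian matching on the
confusion matrix, and reports changed assignments.

## Classification

The elastic-net multinomial fit is delegated to scikit-learn
(`LogisticRegression`; lbfgs for the pure-L2 corner, saga otherwise), with
`C = 1/(n·λ)` aligning scikit-learn's unaveraged likelihood with the
averaged-likelihood parameterization the penalty is stated in. (α, λ) are
tuned by leave-one-out cross-validated accuracy by default — accuracy
rather than deviance, a documented choice; an integer `cv` requests
stratified k-fold instead. CV fits reuse one warm-started estimator per
grid point (adjacent folds differ by one row) at tolerance 1e−3; the final
refit uses 1e−4. Ties in CV accuracy prefer the stronger penalty, then
the smaller α. Library default grids are α ∈ {0, 0.25, 0.5, 0.75, 1} ×
30 log-spaced λ in [1e−4, 10]; the simulation studies in the test suite
and acceptance script use the compact grid α ∈ {0, 0.5, 1} ×
λ ∈ {1e−3, 1e−2, 1e−1}, which pilots showed selects the same models on
these cohorts at a fraction of the cost.

The saga solver leaves the (unpenalized) intercept essentially at zero
when λ is extremely large; the pure-L2/lbfgs path realizes the
infinite-penalty limit (probabilities → class frequencies) exactly, and
the test suite checks the limit there while checking coefficient
shrinkage on the saga path.

The calculator export folds the stored scaling into the coefficients
(`b_m/s_m` slopes, intercept shifted by `Σ b_m c_m/s_m`) and writes full
float precision, so file → memory round trips reproduce probabilities
bit-identically; the export is kept C-contiguous so BLAS uses the same
kernel on both paths.

## Stability

Model B (no PC20, no blood eosinophils) classifies every subject-visit
with complete data; a subject missing a model variable at one visit is
excluded at that visit only. Discordance is the fraction of classified
subjects whose call differs from their baseline assignment. The
per-baseline-phenotype Pearson contingency coefficient is computed from
that stratum's (follow-up visit × classified phenotype) count table —
the stratified-table construction is a documented design choice, as the
coefficient can be defined over several table layouts. Subjects with no
classifiable follow-up are counted and reported, never silently dropped.

## Biomarkers and expression support

Granulocyte classes partition the (sputum eosinophil %, neutrophil %)
plane with inclusive cuts at 3% and 60%. FENO ≥ 35 ppb and blood
eosinophils ≥ 300/µL are inclusive threshold flags with OR semantics over
observed inputs.

The limit of reliable quantification for log2 intensities is estimated two
ways — the 90th percentile of nonspecific-probe mean intensities, and the
mean intensity at the maximum of a moving-average-smoothed SD-vs-mean
curve — with the consensus defaulting to their maximum; explicit
platform-specific overrides short-circuit both. Probes are quantifiable
when their per-cohort mean exceeds the threshold in at least one cohort.

The signature enrichment score is a mean-normalized-rank statistic:
`ES = 2·(mean((rank − 0.5)/N over signature genes) − 0.5)` per sample,
in [−1, 1], equal to `(N − |S|)/N` when the signature occupies the top
|S| ranks, and invariant under any monotone per-sample transformation.
It is deliberately not a kernel-density random-walk enrichment method:
the downstream T2 dichotomy only uses a percentile cut of a monotone
per-sample statistic, and those are the properties preserved and tested.
Users supply their own gene lists (GMT); no reference signature ships
with the package.

T2-high calls cut at the empirical 95th percentile (linear-interpolation
quantile) of the healthy reference by default, with the healthy-maximum
rule available; "beyond" is strict, so a value exactly at the threshold is
low. Under exchangeability the rule flags ~5% by construction, verified by
simulation.

## Summary statistics

The one-way F-test is computed from per-group (n, mean, SD):
`SSB = Σ n_g(m_g − m̄)²`, `SSW = Σ (n_g − 1)SD_g²`, F on (G−1, N−G)
degrees of freedom — algebraically identical to the raw-data ANOVA when
the summaries are exact, which the tests verify to 1e−10. Variables
summarized geometrically are tested on the log scale (the standard
reading when geometric means are reported). Pearson χ² uses no continuity
correction; zero-margin rows/columns are dropped with a warning.
Percentage-to-count reconstruction rounds half away from zero and flags
groups whose reconstructed counts do not sum to n rather than repairing
them. P-values are reported per row without multiplicity adjustment,
matching the table style being reproduced; a Benjamini–Hochberg option is
intentionally out of the default path.

## Problem sizes

The simulation studies run at the cohort's native size (n = 156, four
visits). The test suite uses 50 seeds for the cluster-count selection
study, 20 seeds for the Model A/B comparison, 200 cohort replicates for
the generator's Monte-Carlo check, 100 random instances for the
enumeration oracle, and 20 × 1000 draws for the T2 null calibration; the
acceptance script uses 20, 8, 1 (plus a perturbation run), 100 and
20 × 1000 respectively. These sizes were chosen once to give stable
Monte-Carlo estimates at interactive runtimes.

## Limitations

* **Cluster-count selection on parametric resimulations.** Because the
  generator draws variables independently within phenotype with the
  published marginal spreads — and the skewed biomarkers carry geometric
  SDs up to ~5 — the four-group structure of the original correlated data
  is substantially blurred. The Bayes-optimal classifier on the true
  generative mixture still reaches ~93% accuracy, but the equal-weight
  Euclidean medoid geometry recovers the truth labels at ~77% and the
  Fc-maximizing cluster count is unstable across 2–5, selecting k = 4 in
  only a minority of seeds. This is a property of the resimulation design,
  not of the optimizer (exhaustive-enumeration checks confirm the
  optimizer finds global optima on small instances). Passing clustering
  tests on this generator therefore demonstrate algorithmic correctness,
  not that marginal summary statistics suffice to re-derive a published
  cluster structure.
* The exact fuzzy objective of the original clustering software is not
  public; the fuzzy c-medoid objective implemented here is one reasonable
  reading, anchored by the partition-coefficient contracts.
* LOOCV tuning optimizes accuracy; deviance-based tuning can select
  different (α, λ) on small cohorts.
* The AR(1)-plus-switching longitudinal model is a plumbing assumption;
  gradual drift, seasonal triggers and treatment changes are not modeled.
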