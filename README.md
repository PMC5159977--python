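# phenoclust

Clinical phenotyping of asthma cohorts by fuzzy partition-around-medoids
clustering, with penalized multinomial re-classification, longitudinal
stability assessment, rule-based inflammatory biomarker calls, and the
association statistics that accompany per-phenotype summary tables.

The package is aimed at biostatisticians and respiratory researchers who
want to reproduce, stress-test or extend this style of phenotyping analysis
without access to subject-level trial data: a synthetic-cohort generator
with known ground-truth phenotype labels drives every stage end to end.

## The method

**Clustering.** Nine routinely measured variables — pre-bronchodilator
FEV1 %predicted, FVC %predicted, FEV1/FVC, bronchodilator reversibility (%),
ACQ-7, AQLQ, FENO (ppb, log), blood eosinophils (×1000/µL) and methacholine
PC20 (mg/mL, log) — are centered at their means and scaled by the mean
absolute deviation. Subjects are compared by a missing-tolerant Euclidean
distance (pairs are compared on shared observed variables, rescaled by the
fraction observed), which lets PC20 stay in the analysis even though the
challenge is skipped when FEV1 < 60 %predicted. Fuzzy c-medoids with
fuzzifier m = 1.1 minimizes

    J = Σ_i Σ_v u_iv^m · d(i, medoid_v),   u_iv ∝ d(i, medoid_v)^(−1/(m−1)),

alternating exact membership and medoid updates (J is non-increasing; best
of many random restarts). The cluster count is chosen by partition
coefficients: maximize the normalized Dunn coefficient
Fc(U) = (k·F(U) − 1)/(k − 1) with F(U) = (1/n)ΣΣ u², and report the
normalized Kaufman distance coefficient Dc(U) (0 for a hard partition,
1 for uniform memberships).

**Classification.** Phenotype labels from the partition train multinomial
logistic models with an elastic-net penalty
λ[(1−α)/2‖β‖² + α‖β‖₁], tuned by leave-one-out cross-validated accuracy.
Model A uses 8 variables (no PC20); Model B uses 7 (also no blood
eosinophils) and serves follow-up visits. For subject *i*,
f(k,i) = Σ_m β_{m,k} X_{m,i} (X₀ = 1) and
Pr(Y_i = c) = e^{f(c,i)} / Σ_k e^{f(k,i)}. A self-contained CSV
"calculator" exports the coefficients on the raw variable scale.

**Stability and biomarkers.** Follow-up visits are re-classified with
Model B; per-visit discordance against the baseline assignment,
transition tables and per-phenotype Pearson contingency coefficients
C = √(χ²/(χ² + n)) summarize stability. Sputum granulocyte classes cut at
3% eosinophils / 60% neutrophils; FENO ≥ 35 ppb and blood eosinophils
≥ 300/µL flag type-2 biomarker highs; a rank-based single-sample signature
enrichment score and a healthy-95th-percentile rule call airway T2-high
status. One-way F-tests computable directly from printed per-group
(n, mean, SD) summaries and Pearson χ² tests reproduce table statistics.

## Worked example

```python
import numpy as np
from phenoclust import cohort, preprocess, fuzzy_pam, classify

spec = cohort.default_cohort_spec(seed=42)        # 4 phenotypes, n = 156
records = cohort.generate_cohort(spec)
baseline = records[records.visit == "baseline"].reset_index(drop=True)

fm = preprocess.mad_scale(preprocess.transform_variables(baseline))
D = fuzzy_pam.pairwise_distance(fm)
sel = fuzzy_pam.select_k(D, range(2, 6), m=1.1, restarts=50, seed=42)
print(sel.table.round(3).to_string(index=False))
print("selected k =", sel.best_k)

part = sel.partitions[4]
labels = np.array([f"C{v+1}" for v in part.hard_labels])
model = classify.train_classifier(
    fm, labels, variant="A", alpha_grid=(0.0, 0.5, 1.0),
    lambda_grid=(1e-3, 1e-2, 1e-1), cv="loo", seed=42)
print(f"model A: loocv_accuracy={model.cv_accuracy:.3f} "
      f"training_concordance={model.training_concordance:.3f}")
```

prints

```
 k     F    Fc     D    Dc  objective
 2 0.804 0.607 0.069 0.139    546.257
 3 0.841 0.762 0.053 0.080    508.477
 4 0.732 0.643 0.097 0.129    482.322
 5 0.725 0.657 0.111 0.138    458.308
selected k = 3
model A: loocv_accuracy=0.897 training_concordance=0.917
```

Fc rises from k = 2 to its maximum and Dc falls; on this synthetic draw the
crispest partition has three clusters — the generator draws each variable
independently within phenotype, which blurs the four-group structure that
correlated clinical data exhibit (see `docs/methods.md` on this
limitation). Forcing k = 4 and training the 8-variable Model A on the
resulting labels still reproduces them at 92% concordance, with each
subject receiving an explicit softmax probability over the four phenotypes.

A command-line interface wraps the same stages:

```bash
phenoclust simulate --out cohort.csv --seed 1
phenoclust cluster  --input cohort.csv --k 2:5 --fuzzifier 1.1 --seed 1 --out partition.json
phenoclust train    --input cohort.csv --labels partition.json --variant A --out model.json
phenoclust classify --model model.json --input cohort.csv --out calls.csv
phenoclust report   --input cohort.csv --partition partition.json --out report/
phenoclust run      --config config.yaml    # full pipeline with manifest
```

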