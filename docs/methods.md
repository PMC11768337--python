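# Methods

This note documents the models, conventions and numerical choices behind
qsarkit, a toolkit for ligand-based QSAR (quantitative structure–activity
relationship) regression of inhibitor potency.

## The modelling problem

Given a table of compounds with measured IC50 values, the pipeline learns a
map from computed molecular descriptors to potency on the pIC50 scale
(pIC50 = −log10 IC50, IC50 in mol/L), validates it internally and
externally, and applies it to prioritize new candidates from a screening
library. The prototypical application is inhibition of a kinase target
(e.g., FLT3 in acute myeloid leukemia), but nothing in the code is specific
to one target.

## Data curation

* Concentrations are held internally in mol/L; readers require an explicit
  unit (nM, µM, mM, M, pM), either as a column or as a header suffix
  (`ic50_nM`). This removes silent factor-of-1000 unit errors.
* Structures are canonicalized with RDKit; rows whose SMILES do not parse
  are rejected (`INVALID_SMILES`). No salt stripping or tautomer
  normalization is attempted beyond canonicalization.
* The potency filter keeps compounds with IC50 strictly below 10 µM
  (equivalently pIC50 > 5), concentrating the model on the actives regime.
* Duplicates are keyed on the canonical SMILES string. Replicate potencies
  are merged as the median of the pIC50s, which at two replicates equals
  the geometric mean of the IC50s — the standard way to pool replicate
  dose–response measurements, since errors are roughly log-normal. Every
  merged or rejected row is logged with a machine-readable reason, and
  |records| + |rejects| always equals the number of input rows.
* Train/test splitting is shuffle-then-partition with a single integer
  seed (default 11) and |test| = round(fraction·n); at the conventional
  n = 1350 and fraction 0.2 this gives the familiar 1080/270 split. The
  seed is recorded in every downstream artifact.

## Descriptor matrices

Descriptors come from a pluggable backend registry; the built-in backend
computes RDKit's full 2D descriptor set (~210 columns). Curation drops any
column with a missing value for at least one compound and any column that
is constant, so every compound ends with the same complete descriptor
vector; the dropped log records each removal. The exact surviving column
inventory is backend- and version-dependent — the toolkit guarantees the
curation *rules*, not a particular column list.

Standardization (zero mean, unit variance with the population
n-denominator, matching scikit-learn's `StandardScaler`) is fitted on
training rows only and applied with those frozen parameters to the test
block, so no information flows from test data into preprocessing. Scaling
is applied only to scale-sensitive regressors (kernel ridge, Gaussian
process, support-vector, neural network); tree ensembles are
scale-invariant and consume raw descriptors.

## Diversity analysis

MACCS structural keys (166 informative bits; RDKit's bit 0 placeholder is
dropped) are clustered by Butina sphere exclusion at a Tanimoto *distance*
threshold, default 0.3 — members of a cluster are therefore at least 0.7
similar to their centroid. The implementation builds neighbor lists at
distance ≤ threshold, then repeatedly promotes the unassigned compound
with the most unassigned neighbors to centroid, assigning those neighbors
to it; singletons become their own clusters. Ties on neighbor count break
to the lower input index, making output deterministic. Two all-zero
fingerprints are defined as identical (similarity 1) to avoid 0/0, and are
flagged in the clustering result. The test suite checks this native
implementation against an independent brute-force restatement of the same
rule on hundreds of random instances, and checks that raising the distance
threshold never increases the cluster count.

Note that MACCS bit order differs slightly between cheminformatics
toolkits; cluster identities are reproducible only within one backend.

## Regressor registry and metrics

The registry holds random forest (RFR), gradient boosting (GBR), kernel
ridge (KRR), Gaussian process (GPR), bagging over random forests (BRF) and
support-vector (SVM) regressors at library defaults with a fixed seed
(default 11) where the estimator accepts one. Because library defaults
drift across versions, every resolved hyperparameter is recorded in the
bundle provenance. An optional neural-network entry (dense 500 → 5 → 1,
ReLU hidden layers, linear output, batch size 10, 100 epochs) can be added
with `include_ann=True`; it is excluded from the default benchmark because
its training cost and variance are out of proportion to the default suite.

Metrics: R² = 1 − SSres/SStot; MAE = mean |e|; RMSE = √(mean e²); SD =
population standard deviation of the residuals. These satisfy the identity
RMSE² = SD² + mean(e)², which the suite asserts to 1e−9. R² on constant
observations is undefined and raises rather than returning a sentinel.

## Feature selection

Selection is two-stage:

1. **Univariate ranking.** For each descriptor, a fresh default random
   forest is fitted on the training block of that single column and scored
   by R² on the test block; descriptors are sorted by that score. Using a
   held-out score rather than a correlation coefficient credits nonlinear
   single-descriptor relationships. All fits share one seed so the ranking
   is reproducible.
2. **Greedy inclusion with a correlation prune.** The top of the ranking
   (default pool 100) is visited in order. A candidate whose absolute
   Pearson correlation with any already-included descriptor is ≥ 0.90 is
   skipped, with the blocking pair logged; correlations are computed on
   training rows only, so inclusion decisions never see test data.
   Otherwise the candidate is included, the model refitted (same seed),
   and the test R² appended to the R²-vs-k curve.

The final k is the smallest k whose curve value is within ε (default
0.001) of the curve maximum — a plateau rule that automates the
by-inspection choice usually made on such curves; an explicit override is
available. The selected set by construction contains no pair at |r| ≥
0.90.

## Internal validation

Q² is computed from pooled out-of-sample predictions:
Q² = 1 − Σ(yᵢ − ŷ₋ᵢ)² / Σ(yᵢ − ȳ)², with ȳ the mean of *all* observed
targets. This is the dominant QSAR convention; it also makes k = n fold
cross-validation coincide exactly with leave-one-out, which the suite
asserts to 1e−12. Closed forms anchor the implementation: a mean-only
model has LOO residuals (n/(n−1))(yᵢ − ȳ), so its LOO Q² at n = 10 is
1 − (10/9)² ≈ −0.2346. k-fold CV uses shuffled, seeded folds and pools
out-of-fold predictions rather than averaging per-fold R², which is more
stable at small fold sizes.

## Virtual screening

References default to the 100 most potent curated compounds (ties broken
by id). Candidates stream from a .smi file (optionally gzipped) and are
retained when their maximum MACCS Tanimoto similarity to any reference
reaches the gate (default 0.90); the gate doubles as an
applicability-domain filter, restricting predictions to candidates near
the training chemotypes. Gated candidates whose canonical structure is
already in the known set (by default the curated training table; an extra
exclusion list is accepted) are removed, the remainder predicted with the
persisted model, and hits ranked by predicted pIC50 (similarity, then name
break ties, so shuffling the candidate file cannot change ranks). Public
similarity services use proprietary fingerprints; a local screen with
MACCS keys at the same numeric threshold will retain a different — though
similarly composed — candidate set, and no concordance with any hosted
screen is claimed.

## Model persistence

A trained model is saved as a directory: `metadata.json` (selected
descriptor names in order, scaler parameters, seed, split, resolved
hyperparameters, train/test metrics) plus `model.joblib` (the estimator).
The JSON stays human-diffable even if the blob format changes. Prediction
recomputes exactly the stored descriptor names in stored order, applies
the stored scaler if present, and reports pIC50 together with IC50 in
mol/L and nM. Invalid SMILES in a batch produce error rows, never abort.

## Synthetic data

Two generator tiers stand in for proprietary activity datasets:

* **Planted matrices** (`make_planted_matrix`): k informative columns, a
  configurable number of exact duplicate columns, and independent noise
  columns; the target is a linear combination of the informative columns
  plus a mild interaction, standardized to unit spread, plus Gaussian
  noise (default sd 0.3). The informative columns share a latent factor
  (pairwise r = 0.5 — far below the 0.90 prune threshold) while remaining
  marginally standard normal. Real descriptor panels are collinear in
  exactly this way, and the shared factor gives every informative column
  enough univariate signal for a single-descriptor ranking to surface the
  whole family; with fully independent informative columns, each column's
  marginal R² (~1/k) is too weak for a single-column forest to separate
  from 200 noise columns at n = 300, which is not the regime the ranking
  stage is designed for.
* **Synthetic SMILES libraries** (`make_synthetic_library`): generic
  drug-like scaffolds (benzamides, quinoxalines, benzimidazoles,
  thiazoles…) enumerated with small substituents; ~400 valid, unique
  compounds by default. Activities come from a smooth rule on cheap
  computed properties (logP, TPSA, H-bond counts, molecular weight) mapped
  into pIC50 ∈ [5, 10] plus Normal(0, 0.15) noise — 0.15 log units is at
  the low end of inter-assay reproducibility, making this a low-noise,
  learnable benchmark. The screening candidate list plants one one-carbon
  homolog of the top active (novel, but MACCS-similar at ≥ 0.93), ten
  structurally unrelated decoys far below any gate, and the library
  compounds themselves.

What the generators do *not* emulate: activity cliffs, assay
heterogeneity and censored measurements, scaffold-specific SAR,
target-specific chemotypes, and the heavy-tailed cluster-size
distributions of real mined datasets. Passing tests on synthetic data
therefore demonstrate the correctness of the machinery (no leakage,
correct algorithms, reproducibility), not field performance on any real
target.

## Problem sizes and determinism

The default verification runs use: 100 random fingerprint sets (n ≤ 25)
for the clustering oracle; 1000 random vector pairs for the metric
identities; a 300 × 200 planted matrix (5 informative, 10 duplicates) for
selection recovery; and a ~400-compound synthetic library for the
end-to-end pipeline, whose leave-one-out loop over the 320-compound
training block dominates runtime. Every stochastic step — generators,
splits, folds, forests — is driven by explicit integer seeds, and reruns
at a fixed seed are bit-identical for deterministic estimators.

## Known limitations

* Descriptor inventories, MACCS bit semantics and estimator defaults are
  tied to the installed RDKit/scikit-learn versions; provenance records
  them but cross-version numeric identity is not guaranteed.
* The plateau rule for choosing k assumes a roughly saturating R² curve;
  on non-monotone curves the explicit override should be used.
* The similarity gate uses a single fingerprint scheme per screen; hit
  sets are not comparable across schemes.
* No applicability-domain measure beyond the similarity gate is provided,
  and no y-randomization or bootstrap validation is implemented.
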