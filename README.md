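# qsarkit

A toolkit for **ligand-based QSAR modelling of inhibitor potency**: from a
raw table of SMILES strings and IC50 measurements to a validated,
persisted regression model and a similarity-gated virtual screen of new
candidates.

It is written for computational and medicinal chemists who assemble
bioactivity datasets (e.g., kinase-inhibitor IC50s mined from public
databases), need a reproducible pipeline around the standard modelling
steps, and want every filtering and selection decision logged and
auditable.

## What it does

Potency is modelled on the pIC50 scale, pIC50 = −log₁₀ IC50 (mol/L), as a
function of computed molecular descriptors **x**:

*  **Curation** — canonicalize structures, merge replicate measurements
   (geometric-mean IC50), apply a strict IC50 < 10 µM potency filter, and
   log every rejected row with a machine-readable reason.
*  **Descriptors** — compounds × descriptors matrix from a pluggable
   backend (RDKit 2D set built in), curated by dropping failed and
   constant columns; standardization (train-fitted, population SD) is
   applied only to scale-sensitive models.
*  **Diversity** — MACCS-key fingerprints clustered by a native Butina
   sphere-exclusion implementation at Tanimoto distance 0.3, with a
   cluster-size report.
*  **Benchmarking** — RFR, GBR, KRR, GPR, BRF and SVM regressors at fixed
   seeds on one 80:20 split, scored by R², MAE, SD, RMSE (with
   RMSE² = SD² + mean(e)² holding exactly).
*  **Feature selection** — rank every descriptor by single-column test R²
   under a random forest, then greedily include down the ranking, skipping
   any candidate with train-set |Pearson r| ≥ 0.90 against the included
   set, and choose k at the plateau of the R²-vs-k curve.
*  **Validation** — Q² from leave-one-out and 10-fold cross-validation,
   Q² = 1 − PRESS/TSS over pooled out-of-sample predictions.
*  **Screening** — gate a candidate library at MACCS Tanimoto ≥ 0.90
   against the top-100 most potent references, exclude known compounds,
   predict pIC50 with the persisted model, rank.

Because real mined datasets cannot ship with a library, `qsarkit.fixtures`
generates seeded synthetic inputs with known ground truth (planted
descriptor signals, enumerated scaffold libraries with planted screening
candidates) that every stage is tested against.

## Worked example

```python
from qsarkit import (SplitSpec, compute_matrix, curate, curate_matrix,
                     greedy_select, make_synthetic_library, predict,
                     rank_univariate, screen, select_references, train_final)

lib = make_synthetic_library(n_scaffolds=2, n_variants=40, seed=7)
table = curate(lib.activity_rows())
matrix = curate_matrix(compute_matrix(table.records))
targets = {r.compound_id: r.pic50 for r in table.records}
spec = SplitSpec(0.2, 11)

ranked = rank_univariate(matrix, targets, spec)
trace = greedy_select(ranked, matrix, targets, spec, top_pool=40, max_k=10)
bundle = train_final(matrix, targets, trace.selected(), split_spec=spec)
print(bundle.provenance["metrics"])

refs = select_references(table, n=100)
hits = screen(bundle, lib.candidates, refs, threshold=0.90, top_n=5,
              known_smiles=[r.smiles_canonical for r in table.records])
print(hits[["rank", "name", "pic50_pred", "max_tanimoto"]])
```

Output (abridged):

```
trained on 5 descriptors: R2_train = 0.970, R2_test = 0.874
 rank         name  pic50_pred  max_tanimoto
    1 near_dup_top       9.578          0.97
```

The model explains 87% of held-out potency variance on the 80-compound
synthetic library, and the screen's top hit is the planted near-twin of
the most potent training compound: it clears the 0.90 similarity gate
(Tanimoto 0.97), is not itself a known compound, and receives the highest
predicted pIC50 (9.58, i.e. sub-nanomolar predicted IC50). Decoys never
reach the gate and every known compound is excluded. The scripts in
`examples/` walk through each capability the same way.

## Command line

The same pipeline is available as subcommands, each writing a
`manifest.json` with the resolved configuration and SHA-256 hashes of its
inputs and outputs:

```bash
qsarkit curate    --in raw.csv --out run/cur
qsarkit featurize --in run/cur/curated.csv --out run/feat
qsarkit cluster   --in run/cur/curated.csv --out run/clus
qsarkit benchmark --matrix run/feat/matrix.csv --activities run/cur/curated.csv --out run/bench
qsarkit select    --matrix run/feat/matrix.csv --activities run/cur/curated.csv --out run/sel
qsarkit validate  --matrix run/feat/matrix.csv --activities run/cur/curated.csv \
                  --selection run/sel/selection.json --out run/val
qsarkit train     --matrix run/feat/matrix.csv --activities run/cur/curated.csv \
                  --selection run/sel/selection.json --out run/bundle
qsarkit predict   --in new.smi --model run/bundle --out predictions.csv
qsarkit screen    --model run/bundle --candidates library.smi.gz \
                  --activities run/cur/curated.csv --out run/screen
```

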