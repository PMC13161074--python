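# dtakit

Cold-start drug–target affinity (DTA) regression with masked
cross-attention, plus everything needed to evaluate such a model honestly:
entity-disjoint and similarity-controlled splits, cross-split leakage
audits, rank-aware metrics, perturbation/SHAP/attention interpretability,
and virtual-screening refinement.

## Who this is for

DTA models predict a continuous binding strength y (pKd, where
pKd = −log₁₀ Kd[M], or a unified KIBA-style score) from a drug's SMILES
string and a protein's amino-acid sequence.  Benchmark numbers on random
("warm") splits routinely overstate real-world performance, because in
practice the compounds and targets being screened were never in the
training set.  `dtakit` is for researchers who need the full cold-start
workflow: build splits in which test drugs/proteins (or whole similarity
clusters of them) never appear in training, audit what residual similarity
leaks across the boundary, train and evaluate an interaction-aware
regressor under those splits, and interrogate *why* it predicts what it
predicts.

## The model

An encode–interact–predict architecture:

1. tokenize SMILES (≤256 tokens) and protein sequence (≤1024 residues),
   each with a binary validity mask m;
2. encode each modality into per-token hidden states H ∈ R^{L×h}
   (pluggable backends; trainable conv encoders ship by default);
3. project both into a shared latent space, Z = HW + b, of width d_model;
4. masked multi-head cross-attention,
   softmax(QWᵠ(KWᵏ)ᵀ/√d_k + M)VWᵛ, where the additive mask M puts −∞ on
   padded keys (their attention weight is exactly 0); bidirectionally,
   drug queries interrogate protein context and vice versa — or
   unidirectionally, or bypassed (the ablation modes);
5. mask-aware mean pooling Pool(Z, m) = Σᵢ mᵢzᵢ / Σᵢ mᵢ, concatenation
   r = v_d ∥ v_p, and an MLP head ŷ = f_θ(r), trained by MSE.

Training uses AdamW (decoupled weight decay 1e−4) with differential
learning rates for the encoder backbone vs newly initialised modules,
ReduceLROnPlateau on validation RMSE (×0.5 after 3 stagnant epochs) and
early stopping (patience 10).  Evaluation reports RMSE, Pearson R,
Spearman ρ and concordance index (CI) over repeated seeded splits.

The network runs on a compact NumPy autodiff engine included in the
package (`dtakit.nn`), so everything works on a single CPU with no deep
learning framework.  A synthetic benchmark generator produces
Davis/KIBA-shaped datasets with a known mechanism — a planted drug
"warhead" fragment and protein motif whose co-occurrence raises affinity
by γ — so every claim the package makes is checkable against ground truth.

## Worked example

```python
from dtakit import DTAModel, SyntheticSpec, generate_benchmark, make_warm_split
from dtakit.presets import desk_scale_model_config, desk_scale_training_config

records, dicts, truth = generate_benchmark(SyntheticSpec(seed=7))
split = make_warm_split(records, seed=7)
model = DTAModel(records, dicts, split, desk_scale_model_config(7))
results = model.fit(desk_scale_training_config(7))
print(results.summary())
```

prints (about a minute on one CPU):

```
Drug-target affinity regression results
=======================================================
records: 800   split: warm/pair seed=7
subsets: train=640 val=80 test=80
architecture: d_model=32 heads=4 interaction=bidirectional
encoders: drug=conv protein=conv
trained epochs: 30 (best epoch 30, val RMSE 0.1992)
-------------------------------------------------------
subset      RMSE   Pearson  Spearman      CI      n
train     0.1794    0.9785    0.7393  0.7720    640
val       0.1992    0.9743    0.7428  0.7804     80
test      0.1999    0.9753    0.8072  0.8006     80
```

Test RMSE 0.20 approaches the generator's noise floor (σ = 0.1), and test
Pearson 0.98 / CI 0.80 say the model recovered the planted
warhead×motif mechanism on held-out pairs — the CI ceiling of the
generating mechanism itself is ≈0.89 here, because many pair differences
are pure noise.  Single pairs score directly:

```python
results.predict(dicts.drugs["D0000"], dicts.proteins["P0000"])  # -> 5.366
```

Interpretability and screening hang off the same results object:
`results.occlusion(...)`, `results.shap(...)`, `results.attention_map(...)`,
`results.screen(targets, library)`.

## Command line

Every step is also a subcommand (`dtakit --help`): `simulate`, `split`,
`audit`, `train`, `evaluate`, `explain`, `screen`.  Each
artifact-producing run writes a `manifest.json` with the merged config,
seeds and input digests, so results are reproducible from the manifest
alone.

```bash
dtakit simulate --out data/ --seed 3
dtakit split --pairs data/pairs.tsv --out split.json --mode cold --axis drug --seed 3
dtakit train --pairs data/pairs.tsv --drugs data/drugs.tsv \
       --proteins data/proteins.fasta --split split.json --out ckpt/ --seed 3
dtakit evaluate --ckpt ckpt/ --pairs data/pairs.tsv --drugs data/drugs.tsv \
       --proteins data/proteins.fasta --split split.json
```

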