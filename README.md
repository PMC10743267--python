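# fedtab

Federated-learning simulation for tabular breast-cancer diagnosis.

Hospitals rarely share patient-level records, yet diagnostic classifiers
benefit from multi-institution data. `fedtab` simulates the standard
workaround on cytology tables of the Wisconsin Diagnostic type (30
cell-nucleus morphology features, benign/malignant label): each simulated
clinic trains a neural classifier on its own shard, and a server combines
the clients into one global model — either by summing their predicted class
probabilities and taking the argmax (soft voting), or by federated
averaging (FedAvg) of the network weights. It is aimed at researchers who
want a reproducible, fully-tested reference for this protocol, including
its data-preparation stages and its pitfalls (the default protocol is
deliberately leak-prone; a leak-safe mode is built in).

## What it computes

The pipeline, end to end:

1. **Cleaning** — missing/duplicate handling, then per-feature Tukey-fence
   outlier removal: a record is dropped when it breaches
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` on at least `min_violations` features.
2. **Augmentation** — each class grown to a target count by appending copies
   of originals with elementwise `Uniform(−0.01, 0.01)` noise, then **SMOTE**
   to parity: synthetic minority points `x + u·(nn − x)`, `u ~ U(0,1)`, `nn`
   a k-nearest minority neighbour.
3. **Feature selection** — L1-penalised logistic regression,
   `J(θ,b) = −(1/m) Σᵢ [yᵢ log h(θᵀxᵢ+b) + (1−yᵢ) log(1−h(θᵀxᵢ+b))] + λ‖θ‖₁`,
   minimised by proximal gradient (ISTA) with soft-thresholding; λ tuned by
   the one-standard-error rule on a validation grid; non-zero-weight
   features survive.
4. **Federation** — IID sharding to clients, per-client 70:15:15 split,
   local training of a dense network (ReLU hidden layers 64/32/16, dense 8,
   2-unit softmax head; Adam, batch 32, early stopping with patience 10),
   then server aggregation, for a configurable number of rounds.
5. **Metrics** — confusion counts with malignant positive; accuracy,
   precision, recall/sensitivity, F1, FPR, specificity, FNR; undefined
   ratios reported as such, never as 0.

A synthetic generator emulates the cytology table's per-feature marginals
(truncated normals matched to packaged mean/std/min/max summaries, tunable
class separation), so everything runs without downloads; the bundled
real table (569 records, 357 benign / 212 malignant) is sourced from
scikit-learn's packaged copy.

## Worked example

```sh
fedtab run --seed 1 --out demo_run
```

prints

```
round 0: accuracy 0.9886, recall 0.9877, f1 0.9887  (n_test=966)
round 1: accuracy 0.9917, recall 0.9940, f1 0.9920  (n_test=966)
round 2: accuracy 0.9938, recall 0.9917, f1 0.9938  (n_test=966)
manifest written to demo_run/manifest.json
```

Reading this: the bundled 569-record table was cleaned to 536 records
(outlier stage), augmented to 5742, SMOTE-balanced to 6424 (3212 per
class), and reduced to 23 features at λ ≈ 3.2e-4 — the manifest's
`stage_counts` records this chain. Two clients then trained for three
rounds; each round's global model was evaluated on the union of the client
test splits (966 records). Final-round accuracy 99.38% means 960 of 966
held-out records were classified correctly; recall 99.17% is the fraction
of malignant cases caught. These figures are optimistic by construction —
augmentation runs before splitting, so test records include noisy copies of
training sources; rerun with `--leak-safe` for honest generalisation
estimates. `demo_run/` contains the manifest (stage counts, resolved
config, per-round metrics), per-round report CSVs and the client model
archives.

The same run in Python:

```python
from fedtab import PipelineConfig, run_pipeline
manifest, results, model = run_pipeline(PipelineConfig(seed=1))
print(manifest.stage_counts)   # {'loaded': 569, ..., 'balanced': 6424, ...}
print(results[-1].report.accuracy)
```

Other entry points: `fedtab synth` (generate a synthetic table),
`fedtab preprocess`, `fedtab select-features`, `fedtab report`.

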