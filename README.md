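# delblocks

Building-block-level analysis of DNA-encoded library (DEL) selection data.

A three-cycle DEL member — a *trisynthon* — is assembled from three
building blocks (position 1 nearest the DNA tag, position 3 furthest) and
carries a DNA barcode whose post-selection sequencing read count is the raw
binding signal. For screeners the practical questions are: which building
blocks are productive, how do they combine, and can a prior screen predict
whether *new* compounds — including ones containing untested building
blocks — will bind the target? `delblocks` answers these with a small set
of interpretable statistics and models:

- **Binder calling.** A compound is a binder when its read count is
  inconsistent with a Poisson background: the smallest k with
  P(X ≥ k | λ₀) < α (default α = 0.05) is the calling threshold.
- **Productivity.** For building block x at position i, over the N
  trisynthons containing it, P(bind) = (1/N) Σₖ Iₖ, where Iₖ indicates that
  the k-th such compound binds. Building blocks bin into width-0.2 P(bind)
  intervals; compatibility counts the distinct partners a block forms
  binders with; joint tables give binder fractions for pairs of bins or
  clusters, flagging never-observed combinations.
- **Chemical space.** All-by-all building-block similarity (2D Morgan
  Tanimoto by default, rescaled to the [0, 2] combo-score convention; a 3D
  shape+color backend plugs into the same contract) is transformed to
  distances (2 − score, symmetrized), embedded to 2D with UMAP, and
  clustered with HDBSCAN, whose hyperparameters minimize
  L = n_noise/n + ICD/d_max over a grid. New building blocks project into
  the fitted space and inherit clusters deterministically.
- **Prediction.** A decision tree over the three per-position P(bind)
  features (depth chosen by 5-fold CV on precision-recall AUC) classifies
  binders. For untested building blocks, P(bind) is first imputed from the
  assigned cluster (median, mean, random member, or nearest member).
  Evaluation reports precision, recall, and PR-AUC against the hit-rate
  baseline, under either a leakage-controlled random 90/10 split or a
  building-block holdout (5% of blocks per position removed with all their
  compounds).

A fully seeded synthetic generator (`delblocks.synthdel`) emulates the
statistical structure this pipeline assumes — latent building-block
clusters, spatially smooth productivity, noisy-OR position effects with a
dominant position 3, Poisson read counts — so the entire workflow runs and
is tested without any proprietary screening data.

## Worked example

Generate a synthetic selection (with SMILES decoration so the CSV ingest
path runs), curate and label it, and inspect productivity:

```bash
delblocks synth --scenario figure2_like --seed 1 --smiles --out synth/
delblocks curate --input synth/selection.csv --lambda0 1.0 --out curated/
delblocks pbind --records curated/records.csv --out pbind/
delblocks joint --records curated/records.csv --positions 1,3 --out joint/
delblocks predict --records curated/records.csv --split random --seed 0 --out pred/
```

which prints (numbers from this exact invocation):

```
wrote 128000 records to synth
128000/128000 rows kept; 8188 binders at threshold 4
wrote P(bind) tables to pbind
2 cells, 0 never observed
precision=0.193 recall=0.607 pr_auc=0.402 baseline=0.0629
```

Reading it: 128,000 trisynthons (40 × 40 × 80 full factorial) survive
curation untouched; with a Poisson background rate of 1, read counts of 4
or more are binder calls (6.3% hit rate). In this right-skewed regime
every position-1 building block sits in the lowest P(bind) bin while
position 3 spans up to the high bins, so the 1-vs-3 joint table collapses
to 2 occupied cells — the position-3 bin carries all the signal. On a
random 10% test split — every test compound a new combination of
already-tested building blocks — the P(bind)-only decision tree reaches
PR-AUC 0.402 against a random-guessing baseline of 0.063, a 6.4× lift;
binding in this synthetic regime is intentionally stochastic (most binding
probabilities are far from 0 or 1), which caps attainable precision well
below what near-deterministic real selections allow. (The building-block
*holdout* protocol, where test compounds contain untested blocks and
P(bind) must be imputed from clusters, is exercised by
`delblocks predict --split holdout` and the acceptance script below.)

Library usage mirrors the CLI; estimator-style classes carry the fitted
state:

```python
from delblocks import ChemSpace, BinderClassifier, scenario, generate, label_binders

ds = generate(scenario("smooth_space", seed=0))
records = label_binders(ds.records)
space = ChemSpace(random_state=42).fit(ds.distance_matrices[3])
space.n_clusters_, space.best_params_
```

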