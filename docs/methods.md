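# Methods

`delblocks` analyzes DNA-encoded library (DEL) selection data at the
building-block level. This note records the statistical model behind each
stage, the parameters that matter, what the synthetic benchmark does and
does not emulate, and the numerical choices made where the design was open.

## Data model and binder calling

The unit of data is the **trisynthon**: a library member assembled from
three building blocks, with position 1 closest to the DNA tag and position 3
furthest. The raw input is one CSV row per trisynthon — compound SMILES,
NGS read count, and the three building-block SMILES.

Curation drops null and duplicate rows, strips the protecting groups left in
some exports (Fmoc and Boc carbamates to the free amine, methyl and ethyl
esters to the acid; SMIRKS applied exhaustively in list order), removes
boron-containing building blocks (untreatable by the conformer force fields
used for 3D scoring, and irrelevant for 2D scoring consistency), and — when
the same building-block skeleton appears both with and without specified
stereochemistry — removes the compounds carrying the unspecified form.
Stereo duplicates are detected by comparing stereo-stripped canonical
SMILES. Building-block IDs are the rank of the canonical SMILES in sorted
order within each position, so joins are reproducible across runs.

A compound is a **binder** when its read count is inconsistent with a
Poisson background: the threshold k\* is the smallest integer with
P(X ≥ k\* | λ₀) < α, default α = 0.05. The background rate λ₀ is the open
parameter: with a literal zero-rate null every nonzero count would be
significant, so when no rate is supplied the library-wide mean read count is
used as a conservative dataset-intrinsic estimate (documented as an
approximation; pass the true sequencing background when known). In the
limit λ₀ → 0 the threshold is 1. Labeling is monotone in the count, in λ₀,
and in α. A threshold-sweep table reports how the binder/nonbinder split
moves with the cutoff, for targets where the delineation is less clean.

An optional post-labeling subsample (top-N binders by read count plus a
random draw of nonbinders) reproduces the dataset-size management used for
very large screens; it is off by default because it changes dataset
composition, not any statistic's definition.

## Building-block statistics

**P(bind)** of building block x at position i is the fraction of binders
among the trisynthons containing x at i. Estimates from 30 or fewer
compounds carry a small-sample flag but are never dropped. Bins over
P(bind) are left-closed width-1/B intervals with a closed top bin
(B = 5 by default: bin 1 is [0.0, 0.2), bin 5 is [0.8, 1.0]); the bin count
can be overridden per position when one position spans a wider range.

**Compatibility** counts, for a building block at one position, the number
of distinct partners at another position that co-occur with it in at least
one binder. **Joint probability tables** give the binder fraction for every
pair of groups (bins or clusters) at two positions — adjacent or not — and
flag never-observed combinations explicitly (`observed=False`, probability
undefined) rather than reporting zero: a gap in the design space is
different from a measured low probability.

## Similarity, embedding, clustering

Similarity backends score building-block pairs on a common [0, 2] scale,
the convention of combined shape+pharmacophore ("combo") scores whose two
components each range 0–1. The default backend is 2D Morgan-fingerprint
Tanimoto (radius 3, 2048 bits) rescaled ×2 onto that range; it runs
anywhere RDKit does. A 3D multiconformer backend (shape + color) can be
registered under the same contract; multiconformer and stereoisomer
handling then live behind that plug-in boundary. Distances are
`2 − score`, symmetrized by averaging with the transpose and zeroing the
diagonal, because score matrices from conformer-overlay tools are only
approximately symmetric. Every downstream result depends on the backend
only through this distance matrix — which is also what lets the synthetic
benchmark substitute latent-geometry distances for chemistry.

Each position's building blocks are embedded to 2D with UMAP in
precomputed-distance mode (default seed 42, recorded on the model;
`n_neighbors` capped at n−1; at least 4 points required). HDBSCAN clusters
the coordinates; its two hyperparameters are grid-searched
(`min_cluster_size` ∈ {5, 10, 15, 25}, `min_samples` ∈ {1, 5, 10} by
default) minimizing

    L = w_noise · n_noise / n  +  w_icd · ICD / d_max

where `n_noise` is the number of noise-labeled points, ICD the mean
pairwise distance over all within-cluster pairs, and `d_max` the maximum
pairwise distance in the embedding (normalizer making the term
dimensionless). The two terms penalize the two degenerate solutions —
labeling everything noise, and merging everything into diffuse clusters.
Both weights default to 1 and are configurable. Ties are broken by fewer
noise points, then grid order. All grid evaluations are returned for audit,
and the selected optimum is asserted to be their minimum. If every grid
point labels every point noise, the fit fails loudly with the grid trace.

**Out-of-sample projection.** A new building block, described by its
distances to all training building blocks, is placed by inverse-distance
weighted interpolation over its 5 nearest training points. The neighbor
count is deliberately small: with many neighbors the placement collapses
toward cluster centroids and local structure is lost. A new point at
distance exactly zero from a training point lands exactly on it, so
training members re-project to their stored coordinates. Cluster
assignment gives the new point the cluster of its nearest clustered
training point, unless that distance exceeds `assign_factor` (default 2)
times the cluster's reach (its largest member-to-nearest-member spacing) —
then it is noise. Because 2D interpolation always lands inside the convex
hull, remoteness is checked in the *input* metric: a point further than
`assign_factor` times the largest training nearest-neighbor distance from
every training point is noise regardless of where it interpolates.

**Cluster-quality checks.** The full width at half maximum (fwhm) of each
cluster's P(bind) histogram (10 bins over the sample range, half-maximum
crossings linearly interpolated; constant samples have width 0) is compared
with size-matched random clusters obtained by permuting the labels; smaller
real-cluster fwhm means clusters group building blocks of similar
productivity. Singleton clusters have undefined width and are excluded and
counted. A second check compares embedding distances among the top-10
building blocks by P(bind) against distances from those to randomly chosen
others (excluding the top set); a ratio above 1 means productive building
blocks concentrate geometrically.

## Binder prediction

Two splits answer two questions. The **random compound split** (default
10% test) asks whether per-position P(bind) predicts binding for new
combinations of already-tested building blocks; test rows containing a
building block absent from training are moved into training (counted, and
warned about if the achieved fraction drifts more than 1% from target), so
every test trisynthon is strictly a new combination of tested blocks. The
**building-block holdout** removes 5% of building blocks per position and
every trisynthon containing any of them, emulating a proposed follow-up
library of untested building blocks.

For held-out building blocks, P(bind) is imputed from the cluster the
projected point lands in: the cluster **median**, cluster **mean**, a
seeded uniformly **random** member's value, or the **nearest** member's
value. "Most similar" is metric-ambiguous; the workflow measures it in the
raw similarity-derived distance by default, with embedding Euclidean
distance (the space in which the clusters are defined) as the alternative.
The raw metric is preferred because the 2D embedding is a lossy summary:
nearest-neighbor identification through it compounds two projection
errors, and the occasional cross-boundary neighbor it produces puts
high-variance mistakes at the top of the ranking, which the
precision-recall AUC of a rare-positive problem punishes hardest.
Noise-assigned building blocks receive the global training median,
flagged.

The classifier is a decision tree over the three per-position P(bind)
features (cluster IDs can be appended as features; both sets are
supported). Maximum depth is chosen by stratified 5-fold cross-validation
maximizing mean precision–recall AUC over depths 1–10, ties to the
shallower tree, then refit on the full training set. Class weights are
balanced by default because binders are a percent-level minority; the
evaluation metrics are precision, recall, and PR-AUC (average precision:
the step-wise sum over unique score thresholds), whose random-guessing
baseline equals the hit rate. The fitted tree serializes to JSON (feature,
threshold, children, leaf class counts).

The end-to-end holdout workflow repeats, per trial: split, compute
training P(bind), fit one chemical space per position on training
building blocks, project and assign held-out ones, train the tree on
training features, and evaluate each imputation strategy on the holdout
set; it reports per-trial and mean PR-AUC per strategy with the mean
holdout hit rate as baseline.

## The synthetic benchmark

The generator emulates the *statistical* structure the analysis relies on,
not chemistry. Each position's building blocks live at latent 2D
coordinates around cluster centers (rejection-sampled to a minimum
separation, default 5 cluster standard deviations, so the premise "clusters
exist" holds); latent productivity q is the cluster's base level (Beta
prior) plus an optional within-cluster spatial gradient (optionally scaled
by the base level, so productive families are internally graded while
unproductive ones stay flat), optional localized Gaussian "hotspots", and
independent jitter, clipped to [0, 1]. A trisynthon binds with probability
1 − Π(1 − wᵢqᵢ) (noisy-OR; a thresholded weighted sum is available), which
reproduces the rescue phenomenon: one strong building block at a heavily
weighted position dominates. Read counts are Poisson at λ_signal = 100 for
true binders and λ_background = 1 otherwise — a regime in which the
Poisson binder call is essentially clean, matching selections where the
lowest binder count is far above background. Distance matrices are latent
Euclidean distances rescaled to [0, 2], so the embedding/clustering stage
runs identically to the chemical case. Optional SMILES decoration (simple
unique alkyl/amine/ether chains) exercises the CSV ingest and curation path
end to end.

Defaults (20 × 20 × 50 building blocks, full factorial; weights
w = (0.35, 0.5, 0.75); cluster-mean productivity Beta(0.6, 1.8); gradient
0.6; jitter 0.05) give a moderate-signal, well-conditioned regime for
parameter-recovery validation: position 3 dominates (its weight is
largest, mirroring the empirical picture that the position furthest from
the DNA tag matters most) and empirical P(bind) tracks latent q tightly.
Named presets reproduce specific regimes: `figure2_like` (right-skewed
productivity, >95% of building blocks below P(bind) 0.2 at every position,
with one small promoted family at position 3 spanning the widest range),
`monotone_compat` (percent-level hit rate with unsaturated
compatibility–productivity monotonicity), `smooth_space` (spatially smooth
productivity with a percent-level hit rate and graded productive families
at position 3 — the regime for cluster imputation and the holdout
workflow), and `null` (zero weights; no signal).

What the generator does **not** emulate: synthesis truncates and yield
variation, DNA-barcode sequencing errors, replicate selections and
singleton reconciliation, target-specific chemistry, and any real
structure–activity landscape. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure of the assumed form — not
that any particular chemical conclusion transfers to a given screen.

## Numerical choices and edge cases

- Poisson threshold: computed from the survival function, starting near the
  analytic inverse; α ≥ 1 returns threshold 0 (everything passes); an
  all-zero count column with the automatic background estimate uses the
  vanishing-background limit (threshold 1).
- Unobserved joint cells report probability as NaN with `observed=False`,
  never 0.
- Distance matrices must be symmetric to 1e−9 with zero diagonal, entries
  in [0, 2]; `to_distance` enforces and repairs within tolerance, and
  rejects scores above the backend maximum plus 1e−6.
- Embedding determinism: UMAP is run with a fixed recorded seed
  (single-threaded under a set random state), so coordinates are
  reproducible bit-for-bit for a given input.
- Grid-search ties: smallest noise count, then grid order — deterministic.
- PR-AUC: sklearn's average precision (step-wise interpolation), chosen for
  bit-exact reproducibility across runs; curves with a single class in the
  truth are reported as NaN.
- Splits: the random split satisfies its leakage constraint by moving
  violating rows into training (single ordered pass; moving rows only adds
  training coverage, so one pass reaches a fixed point); building blocks
  occurring once can never appear in test.
- fwhm: bins span the sample range, so the statistic discriminates tight
  clusters whose spread is far below any fixed global bin width.

## Problem sizes used in validation

The validation suite runs entirely on synthetic data: brute-force oracle
comparisons on a 1000-record subsampled library; parameter recovery on the
default 20 × 20 × 50 full factorial (20,000 trisynthons); the holdout
workflow and imputation comparisons on the `smooth_space` preset at 20
resampled holdout trials. These sizes were chosen so the full suite
exercises every stage, including 60+ UMAP fits, at interactive runtimes on
a single CPU while keeping per-building-block occupancy (hundreds of
compounds per block) high enough that P(bind) estimates are tight.

## Known limitations

- The objective L weighs its two terms equally after normalization; the
  appropriate weighting is data-dependent and exposed as configuration.
- Out-of-sample projection is interpolation: a genuinely novel building
  block far from all training data cannot be placed meaningfully and is
  labeled noise; its P(bind) falls back to the global median.
- The background rate default (mean read count) overestimates λ₀ whenever
  true binders are present, biasing the threshold conservative (fewer
  binder calls).
- Curation canonicalizes stereo as given; enumerating stereoisomers and
  picking the most representative one is delegated to 3D backends.
- With very small libraries the CV depth selection is noisy; the depth grid
  and fold count are configurable.
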