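# Methods

## Model and assumptions

The package treats drug repurposing as link prediction on a typed
knowledge graph. Three assumptions shape the design:

1. **Edges are trustworthy, non-edges are not.** The triple set is
   assumed correct but incomplete, so absent (drug, disease) pairs are
   only weak negatives. Positives therefore carry a higher
   cross-entropy weight (default: the negative:positive count ratio, 30,
   so the two classes contribute equally in aggregate), and a weighted
   batch sampler over-samples positives to an expected 1:1.5
   positive:negative ratio per minibatch. The per-pair sampling weights
   follow from expectation algebra: positives share probability mass
   1/(1+1.5), negatives 1.5/(1+1.5), independent of the global 1:30
   imbalance.

2. **Structure is captured before training.** The symmetric-normalized
   adjacency Ã = D^(−1/2)AD^(−1/2) is applied to the pretrained
   400-dimensional entity embeddings K times up front
   ([X, ÃX, …, Ã^K X]); the encoder is then a plain feed-forward map
   and training touches no graph. Compound-treats-disease edges are
   removed from A before normalization so the features cannot leak the
   labels being predicted. All relation types are merged into a single
   unweighted adjacency; relation-typed convolutions are out of scope.
   Isolated nodes get all-zero rows (a zero D^(−1/2) convention) rather
   than NaNs, since type-filtering can strand entities. No self-loops
   are added before normalization.

3. **Scores are only comparable within a disease.** Per-disease
   z-scoring (population σ, ddof 0; zero-spread rows zeroed with a
   warning) removes disease-level score inflation before any
   aggregation. All aggregation rankings are invariant to positive
   rescaling of the standardized matrix.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| K | 2 | highest adjacency power in the feature stack (two-hop context) |
| hidden_dim | 128 | width of each per-power encoder map |
| out_dim | 250 | node embedding dimension fed to the decoder |
| neg_per_pos | 30 | sampled non-edges per treats edge |
| target_ratio | 1.5 | expected negatives per positive inside a batch |
| epochs / lr / weight decay | 25 / 1e-5 / 1e-2 | Adam training schedule at full (DRKG) scale |
| r | 100 | length of the final candidate ranking |
| ℓ | 2 | per-drug outlier scores dropped by the outlier-mean strategy |
| disease k | 3 (also 8) | k-means disease clusters; 3 matches the PCA diagnostic |
| drug k | 250 (also 500) | k-means drug clusters for the drug-clusters-mean strategy |

The learning rate 1e-5 is calibrated to a multi-million-edge graph with
large batches. On the small synthetic graphs (hundreds of entities,
a few hundred positives) 25 epochs at 1e-5 move the parameters by only
~1e-2 in total, so the synthetic-recovery experiments keep the
optimizer, schedule length and weight decay but scale the learning rate
to 1e-3. Two further numerical choices stabilize small-scale training:
decoder weights are initialized at 1/10 Glorot scale so initial logits
start near zero instead of saturated (the bilinear form y_v·W·y_u has
logit standard deviation of several units at full Glorot scale), and
the binary cross-entropy is computed in the standard log1p(exp(−|z|))
stable form. Adam uses coupled weight decay (decay added to the
gradient). Gradients of the full forward pass are hand-derived and
verified against central finite differences at 1e-7 tolerance in the
test suite.

## Aggregation conventions

Several reductions are underdetermined by their verbal description;
the package fixes them deterministically:

* **Ties** everywhere break by ascending drug index after descending
  score; the biclique prefix index takes the smallest maximizer.
* **Union of top-x lists**: x grows from 1 until the union of per-row
  top-x sets reaches r unique drugs; the merge walks rank positions
  1..x, rows in order, keeps first occurrences, truncates to r. This
  preserves "best rank anywhere first" semantics.
* **Biclique sums** use signed standardized scores. Clipping negatives
  to zero is applied only where required — the Louvain bipartite graph,
  whose edges are max(ŝ, 0) with zero-weight edges omitted.
* **Louvain** runs on the disease+drug bipartite graph (networkx
  implementation, seeded, resolution 1.0); communities containing no
  disease carry no label; an all-negative matrix collapses to a single
  cluster with a warning.
* **k-means** uses 10 restarts with a fixed seed. The per-cluster
  disease-subset enumeration in the biclique strategies is bounded at
  20 diseases per cluster; beyond that the strategy aborts and suggests
  more clusters.
* **Single-disease median** is an evaluation baseline (the median of
  per-disease hit counts; even counts average the middle two), not a
  ranking strategy: a median of counts cannot emit one drug list.
* **Drug similarity** is true cosine (L2-normalized columns); zero-norm
  columns get similarity 0 with a warning. A raw dot-product mode is
  retained behind a flag for sensitivity checks.

## Synthetic data: what it emulates and what it does not

`gen_kg` emulates the *shape* of the real substrate: four entity types,
a sparse typed edge set, treats edges drawn from a latent-factor model
(probability sigmoid(scale·z_c·z_d/√m + bias)), and embeddings that are
a fixed random linear lift of the latent vectors plus Gaussian noise.
The lift is linear on purpose: it guarantees the link signal is
recoverable from the embeddings by the encoder-decoder, so recovery
tests measure the training loop rather than an unlearnable task. Default
sizes (50 genes, 100 compounds, 5 anatomy, 10 diseases) keep a full
train-and-evaluate cycle around twenty seconds on one CPU.

`gen_score_matrix` emulates the *output* structure: 33 diseases × 8070
drugs by default, diseases in 3 contiguous clusters, 20 planted hit
drugs each boosted by δ = 2 (noise σ = 1) on the diseases of a random
non-empty cluster subset. An optional `cluster_effect` adds a shared
per-cluster score signature across all drugs; it defaults to 0 (hit
columns are then the only cluster signal) and is used by tests that
probe cluster-geometry recovery (k-means ARI, PCA silhouette), which is
otherwise information-theoretically out of reach on small matrices.

Neither generator matches real degree distributions, relation
inventories, name vocabularies, or the correlated noise of a trained
model's scores. Passing tests therefore demonstrate that the
implementation is correct and that the strategies behave as designed
under known structure — not that any particular hit count on the real
DRKG/clinical-trials data is reproduced. Full-scale DRKG counts (69,036
entities; 4,885,854 edges; 8,070 drugs; 33 COVID-19 diseases; a
250-name truth list) require the real downloads; the tests exercise the
same restriction and selection rules on a dialect fixture with counts
known by construction instead.

## Degenerate inputs

* Zero-degree nodes: zero feature rows, never NaN.
* Zero-spread score rows: z-scores zeroed, warning.
* r larger than the drug count: all drugs returned, warning.
* Training sets without both labels: sampler warns and degrades to
  uniform sampling; training-set construction with no positives is
  fatal.
* Negative demand above the non-edge universe (tiny graphs): sampling
  with replacement proceeds with a warning.
* Non-finite propagated features or training loss: fatal with the
  offending power / epoch.

## Known limitations

* The trainer is plain numpy on one CPU; it is sized for the synthetic
  study conditions and for moderate graphs, not for multi-million-edge
  training runs.
* No exact maximum-edge-biclique solver: only the prefix heuristic plus
  subset enumeration inside small clusters (the unrestricted problem is
  NP-hard).
* Name matching is exact after trimming and case-folding; no synonym or
  fuzzy resolution, by design, so hit counts are reproducible.
* Negative sampling corrupts both sides of the pair (uniform over
  drug×disease non-edges); single-side corruption variants are not
  implemented.
* The aggregation stage operates in memory (a 33×8070 matrix is ~2 MB);
  no out-of-core backend.
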