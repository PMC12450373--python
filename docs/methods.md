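# Methods

## The encoder and its adapters

`plmtune` treats a protein encoder as a contract: a token sequence of
length L goes in, an L × d matrix of residue vectors (last hidden layer)
and an L × V matrix of vocabulary logits come out. The bundled reference
encoder is a pre-norm transformer with learned positional embeddings,
multi-head self-attention, a ReLU feed-forward block, and a tied-width
logit head. It is deliberately tiny (defaults: d = 32, 2 layers, 4 heads)
and fully deterministic given its seed; it exists so that adapter
mechanics, objectives, and benchmarks can be exercised end to end on one
CPU. Any encoder exposing the same contract — including large pretrained
models — can be substituted. Forward and backward passes run on a small
reverse-mode automatic-differentiation engine over numpy arrays written
for this package; its gradients are validated against central finite
differences in the test suite.

LoRA adapters attach a factor pair (A: r × d, B: d × r) to each of the
attention query/key/value projections. A is initialised to small seeded
Gaussian noise, B to zeros, so the adapted forward pass equals the base
forward pass exactly before training — an identity the tests check
bitwise. The update is scaled by α/r with α defaulting to r (net factor
1), matching common practice; α is configurable because published work
does not agree on a value. `merge_lora` folds `(α/r)·AᵀBᵀ` into the stored
weights and is verified to reproduce the adapted forward pass within 1e−5
relative tolerance. The base weights are hashed before and after training;
only the factors and the task head may change.

## Objectives

All three losses follow the negative-log-likelihood forms stated in the
README. Decisions worth recording:

* **Masking.** `round(0.15·L)` distinct residue positions (at least one)
  are selected uniformly; each is replaced by the mask token with
  probability 0.8 (configurable to 1.0). Selected-but-unreplaced positions
  keep their original token and are still scored — no random-token
  substitution, since only a masking probability is specified in the
  training regimes this mirrors.
* **Contrastive loss.** The hybrid cosine/MSE pair loss has two modes. The
  default "similarity-target" mode penalises the cosine's distance from a
  target (1 for positives, 0 for negatives) under both an absolute and a
  squared term; this is the only reading that is self-consistent for
  triplets. The literal "vector-mse" mode (α·(1−cos) + (1−α)·mean
  elementwise squared difference) is retained but valid only for positive
  pairs — applied to a negative pair it would pull the vectors together.
  The weight α defaults to 0.5 and is always logged.
* **Reduction.** The equations are written as sums; the optimizer path
  averages within a batch for step-size stability, and the mode is
  recorded in the training manifest.
* **Learning rate.** The recorded full-scale default is 1e−9; on the tiny
  reference encoder that produces no measurable update, so desk-scale runs
  and tests use 1e−3. Both are explicit `TrainConfig` values, never
  implicit.
* **Epoch seeding.** Each epoch re-derives its sampling stream (shuffles,
  masks, triplets) from `config.seed` alone, so a zero-learning-rate run
  has a bitwise-constant loss trajectory — a cheap and strong determinism
  check. At desk scale (a handful of epochs) the repetition of masks
  across epochs is harmless; a long-horizon training run would want
  per-epoch streams instead.
* **Held-out evaluation.** Test loss for the contrastive objective uses
  held-out anchors with positives and negatives drawn from the full set,
  because a 90:10 stratified split of 12-member groups leaves a single
  test member per group — no within-test positives exist.

Triplets are sampled with a uniform anchor over sequences whose group has
two or more members, a uniform positive among the anchor's group mates,
and a uniform negative over all other groups' sequences.

## Synthetic ortholog families

The generator emulates what an orthologous-group database provides —
labelled families of homologous sequences with alignments — while owning
its ground truth:

* Each family descends from a random ancestor (default 120 residues,
  uniform residue frequencies, configurable).
* Conserved motif blocks (default three 12-residue blocks) are copied
  verbatim into every member, optionally with a small flip rate.
* Every non-conserved position diverges by point substitution (default
  rate 0.25). The column is re-sampled, seeded, until it genuinely fails
  the conserved-column criteria; without this the ground truth would be
  only approximate, because a 12-row column at 25% substitution passes the
  ≥70%-majority test by chance a few percent of the time. The escalating
  re-sampling slightly raises the realised substitution rate in the
  affected columns; the trade — exact truth labels over an exact marginal
  rate — is deliberate.
* Indels (default off) fall only outside conserved blocks, so conserved
  columns stay fully occupied. Insertions occupy member-private alignment
  columns; the true alignment is therefore maintained by construction, and
  stripping gaps from any row reproduces the member's sequence exactly.
* With `shared_motif_seed` set, all families carry the same motif residues
  in their conserved blocks. Sequences from different families are then
  remote homologs — identical in ~30% of positions, unrelated elsewhere —
  which is the regime the soft-alignment benchmark probes.

What the generator does **not** emulate: realistic amino-acid exchange
matrices (substitutions are uniform over the other 19 residues),
position-dependent rate variation, fragmentary sequences, or annotation
noise in group labels. Passing benchmarks on these families therefore
demonstrates mechanical and statistical correctness of the pipeline and
the expected qualitative response to fine-tuning, not performance on real
proteomes.

## Benchmarks: conventions and numerical choices

* **Group filter.** "More than 10 members" is strict (≥11 kept). The
  stratified split assigns `max(1, round(0.1·n))` members per group to the
  test set, ties rounding half-up; every group appears in both subsets.
* **Conserved columns.** Gap characters count as unknown alongside `X`
  and are excluded from the type and majority counts; "fewer than 5%" is
  strict, "at most four" and "at least 70%" are inclusive. Coordinates are
  0-based; the similarity benchmarks map alignment columns to ungapped
  residue indices through per-row column maps.
* **Site sampling.** Conserved-site comparisons iterate families, columns,
  and row pairs in sorted order and truncate deterministically at the
  comparison cap (default 10⁶). Random-site sampling sweeps row pairs in
  sorted order, one accepted draw per pair per sweep, rejecting draws that
  violate `p_i ≠ p_j`, `|p_i − p_j| > 20`, or the conserved-column
  exclusion, with a 100-retry cap per draw; families where no pair can
  satisfy the separation constraint are skipped with a logged warning.
* **Clustering.** HDBSCAN is delegated to scikit-learn with parameters
  passed through verbatim. Noise points (label −1) are excluded from the
  silhouette; singleton clusters score 0; iterations with fewer than two
  clusters have no defined silhouette and are excluded from the best-case
  maximum (recorded as skipped). Distances are Euclidean. When the
  selection epsilon exceeds every dendrogram merge distance scikit-learn's
  epsilon search fails; the package returns the single root cluster in
  that case, which the silhouette stage then reports as undefined.
* **Soft alignment.** Candidate matches are mutual nearest neighbours of
  the residue cosine matrix (argmax ties toward the smallest index) with
  similarity ≥ τ (default 0, i.e. mutual-NN alone gates matches, since no
  published threshold exists for this construction). The path is the
  longest strictly-increasing chain of candidates, computed by an O(k²)
  dynamic program that returns the lexicographically smallest optimum; it
  is tested against exhaustive search over all monotone candidate subsets.
  The match rule is pluggable so a different published soft-alignment
  procedure can be swapped in. The >18 path-length and <1,024
  sequence-length filters are strict inequalities.
* **MSA metrics.** Mutual information uses log base 2 (bits), empirical
  frequencies without pseudocounts, and pairwise-complete rows (a column
  pair is skipped when fewer than 2 shared non-gap rows remain). "Mean MI"
  averages all unordered column pairs, with a deterministic ordered cap
  for wide alignments. Occupancy is the per-column non-gap fraction.

## The directional experiment

The package's end-to-end claim — contrastive LoRA fine-tuning improves
embedding quality — is tested at fixed desk-scale study conditions: 30
shared-motif families × 12 members, the d = 32 reference encoder, 200 Adam
steps at lr 1e−3, seed 0, with a 0.2 held-out fraction (the smallest that
leaves two test members per group). Against the untrained encoder, three
quantities are compared: the held-out anchor-positive minus anchor-negative
cosine gap, the best-case bootstrap silhouette over 50 iterations of 20
sampled families (selection epsilon 0 — an absolute epsilon calibrated for
2,560-dimensional embeddings merges everything at d = 32, so the
clustering parameters are re-tuned to the encoder scale, as one does per
model suite), and the mean soft-alignment path length over cross-family
remote-homolog pairs. The run takes roughly half a minute on one CPU;
problem sizes were chosen so the whole suite stays comfortably inside an
interactive budget.

## Known limitations

* The reference encoder is not pretrained; "untrained" baselines reflect a
  random (though deterministic) encoder, which is the correct null for the
  directional comparison but not a stand-in for a pretrained model's
  behaviour.
* The autodiff engine supports exactly the operations this architecture
  needs; it is not a general training framework and keeps everything in
  float64 on one CPU.
* The soft-alignment construction is this package's declared procedure;
  published embedding-based aligners differ in match gating and gap
  handling, and absolute path lengths are not comparable across
  constructions.
* Silhouette handling of density-based noise points follows the common
  exclude-noise convention; including noise as a pseudo-cluster would
  shift scores systematically.
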