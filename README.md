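# plmtune

Parameter-efficient fine-tuning of per-residue protein encoders, with a
benchmark suite that measures whether fine-tuning actually improved the
embeddings.

Protein language models map each residue of a protein to a vector; pooled
(mean) vectors represent whole sequences. For proteins from
under-represented clades — viral proteins especially — these embeddings are
often poorly calibrated: unrelated sequences score nearly as similar as true
orthologs. `plmtune` implements the standard remedy and its evaluation at a
scale that runs on a laptop CPU:

* **LoRA fine-tuning.** The base encoder weights `W` stay frozen; each
  attention projection (Wq, Wk, Wv) gains a trainable rank-r update, so the
  adapted projection computes

  ```
  h = W·x + (α/r)·B·A·x ,   A ∈ R^{r×d},  B ∈ R^{d×r},  B = 0 at init
  ```

  Zero-initialising `B` makes the adapted model exactly equal to the base
  model before training, and the learned update `(α/r)·BA` can be merged
  back into `W` afterwards. Default rank r = 8 on Wq/Wk/Wv.

* **Three training objectives** on ortholog-labelled sequences, optimised
  with Adam:
  - masked-token (MLM): `Loss = −Σᵢ log P(true_tokenᵢ | context)`, with
    15% of residues selected and replaced by the mask token with
    probability 0.8;
  - group classification (CLS): `Loss = −Σᵢ log P(true_groupᵢ | xᵢ)` from
    an affine head on the pooled embedding;
  - contrastive triplets (CON): for anchor/positive/negative sequences,
    each pair contributes `α·|t − cos(A,B)| + (1−α)·(cos(A,B) − t)²` with
    target t = 1 (anchor–positive) or t = 0 (anchor–negative).

* **Benchmarks** mirroring the three standard views of embedding quality:
  - pooled within-group pairwise cosine similarity, and residue-level
    similarity at conserved versus random well-separated MSA sites
    (conserved column: <5% unknowns, ≤4 residue types, ≥70% majority);
  - bootstrap HDBSCAN clustering of pooled embeddings scored by the
    silhouette coefficient `S(i) = (b(i) − a(i)) / max(a(i), b(i))`, with
    the best case (max over iterations) as summary;
  - embedding-based pairwise soft alignment: mutual-nearest-neighbour
    residue matches chained by a longest-increasing-subsequence dynamic
    program; the path length (longest homologous residue path, kept when
    >18 for sequences <1,024 residues) measures alignment quality; plus
    MSA mutual information (bits) and column occupancy.

* **A synthetic ortholog-family generator** with exact ground truth:
  families descend from random ancestors, keep conserved motif blocks, and
  diverge by point substitution and optional indels. True alignments and
  true conserved columns are known by construction, so every benchmark can
  be validated against ground truth. No external database is required.

The tiny built-in transformer encoder (a few thousand LoRA parameters)
stands in for billion-parameter encoders behind the same
tokens-in/vectors-out contract; external encoders can be plugged in through
that contract.

## Worked example

```python
from plmtune import DirectionalBenchmarkConfig, directional_benchmark

result = directional_benchmark(DirectionalBenchmarkConfig())
for phase in ("untrained", "trained"):
    r = result[phase]
    print(phase, round(r["cosine_gap"], 3), round(r["max_silhouette"], 3),
          round(r["mean_path_length"], 1))
```

This simulates 30 families × 12 members (120-residue sequences sharing
conserved motif blocks across families), fine-tunes the 32-dimensional
reference encoder contrastively for 200 Adam steps at lr 1e−3, and
re-evaluates. It prints:

```
untrained 0.004 0.17 51.6
trained 0.191 0.331 51.8
```

Reading: before training, held-out orthologs are barely more similar than
non-orthologs (cosine gap 0.004); after training the gap is 0.191. The
best-case clustering silhouette rises from 0.17 to 0.33, and the mean
longest homologous residue path over cross-family remote-homolog pairs
rises from 51.6 to 51.8 — the three views all move in the direction
fine-tuning is supposed to move them.

The same pipeline is scriptable from the shell:

```bash
plmtune simulate --out data --n-groups 30 --members 12 --seed 0
plmtune finetune --data data --out model --objective con --lr 1e-3 --steps 200
plmtune embed --data data --model model --out emb
plmtune bench-pairwise --data data --embeddings emb --out bench/pw
plmtune bench-cluster  --data data --embeddings emb --out bench/cl --epsilon 0
plmtune bench-align    --data data --embeddings emb --out bench/al
plmtune report --runs bench/pw --runs bench/cl --runs bench/al --out report.json
```

Every command writes a `manifest.json` echoing its resolved configuration
and seeds, so each numerical report is reproducible from its manifest.

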