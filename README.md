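# enhancerkit

A self-contained toolkit for DNA "word"-based enhancer identification:

* **Word segmentation** of DNA sequences — overlapped 3-grams, non-overlapped
  3-grams (three start offsets; 4 + 16 + 64 = 84-word dictionary),
  non-overlapped 2-grams, and a **statistics-based segmenter** that learns a
  150-word unigram dictionary (BPE seeding → EM over the full segmentation
  lattice → loss-ranked pruning) and segments by maximum-probability path
  (Viterbi).
* **Skip-gram embeddings** with negative sampling for DNA words, and
  per-sequence embedding matrices (vertically stacked word vectors).
* **Sequence GAN augmentation** — a GRU token generator trained by policy
  gradient with Monte-Carlo rollout rewards from a convolutional
  discriminator, class-conditional generation, and a greedy sequence-identity
  redundancy filter (internal CD-HIT stand-in, 80% cutoff).
* **A two-layer CNN classifier** (multi-width convolutions 2/3/4 × N, 128
  kernels each → max pooling → 384-d feature vector → softmax): layer 1
  calls enhancer vs non-enhancer, layer 2 grades called enhancers strong vs
  weak.
* **Evaluation** — Acc/Sn/Sp/MCC, leakage-audited stratified 10-fold
  cross-validation (generated sequences may join training folds only), and
  real-vs-generated analytics (nucleotide composition and trinucleotide
  physicochemical profiles).
* **Synthetic data** — benchmark-shaped simulator (AT-biased negatives,
  near-uniform positives, strength encoded as planted-motif dosage) so every
  stage is testable without external downloads.

Everything is NumPy: all gradients (skip-gram, CNN, GRU/BPTT, policy
gradient) are hand-written and verified against finite-difference and
enumeration oracles in the test suite.

## CLI

One entry point with per-stage subcommands:

```bash
enhancerkit simulate --preset benchmark --scale 0.05 --seed 1 --out data/
enhancerkit tokenize --scheme ov3 --in data/strong_enhancers.fasta --out strong.words
enhancerkit lexicon-train --in data/strong_enhancers.fasta --size 150 --out dict.tsv
enhancerkit lexicon-segment --dict dict.tsv --in data/strong_enhancers.fasta --out strong.stat.words
enhancerkit embed-train --words strong.words --scheme ov3 --dim 300 --window 4 --neg 10 --seed 1 --out sg.model
enhancerkit gan-train --in data/strong_enhancers.fasta --class-tag strong --seed 1 --out g_strong.model
enhancerkit gan-generate --model g_strong.model -n 1000 --filter 0.8 --out aug_strong.fasta
enhancerkit train --layer 1 --data-dir data/ --out models/l1
enhancerkit train --layer 2 --data-dir data/ --out models/l2
enhancerkit predict --model1 models/l1 --model2 models/l2 --in query.fasta --out pred.tsv
enhancerkit cv --data-dir data/ --layer 1 --k 10 --seed 1 --out cv.tsv
enhancerkit compare --real data/strong_enhancers.fasta --generated aug_strong.fasta --out cmp.tsv
enhancerkit run --config config.json --out artifacts/   # end-to-end + manifest
```

Expected per-class FASTA layout for a dataset directory:
`non_enhancers.fasta`, `strong_enhancers.fasta`, `weak_enhancers.fasta`
(plus an optional `labels.tsv`: `id<TAB>enhancer_label<TAB>strength_label`).
Sequences must be plain A/C/G/T; ambiguity codes are rejected.

The `run` command takes a JSON config, e.g.

```json
{
  "seed": 1,
  "scheme": "ov3",
  "embed_dim": 16,
  "augment": true,
  "gan": {"n_generate": 200, "pretrain_epochs": 2, "adv_rounds": 1},
  "simulate": {"n_non": 100, "n_strong": 50, "n_weak": 50, "length": 200}
}
```

and writes every stage artifact plus `manifest.json` with content hashes;
reruns with the same config are deterministic.

## Notes

* The published 200-bp enhancer benchmark (1484 enhancers / 1484
  non-enhancers train, 200/200 test) has no public accession; to reproduce
  paper-scale experiments, place the per-class FASTA files in a directory
  and use `cv`/`train`/`predict` directly. All shipped tests and the
  acceptance suite run on synthetic data at desk scale.
* The bundled trinucleotide property table
  (`src/enhancerkit/data/trinucleotide_properties.tsv`) is a documented
  stand-in (nearest-neighbor duplex thermodynamics + composition fractions);
  replace it with any 64-row, 5-column TSV via
  `PropertyTable.from_tsv`.
* `redundancy_filter(..., engine="cdhit")` shells out to `cd-hit-est` when
  that binary is available; the default internal filter is self-contained.
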