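# Methods

## Scope and model

`mnporigin` classifies the kingdom of origin (Animalia / Bacteria / Fungi)
of a compound from its structure and removes Animalia annotations that are
structurally microbial — the signature of host–microbe symbiosis
misannotation. The design assumption throughout is asymmetric label trust:
microbial labels are treated as reliable (direct isolation evidence),
Animalia labels as fallible (host attribution). Cleaning therefore only
ever flags or removes label-0 records and never reassigns a compound to a
specific microbial kingdom.

## Encoder

The molecular encoder is a directed message-passing network on the bond
graph. Each bond contributes two directed edges; atom features are one-hot
element (C, N, O, S, P, F, Cl, Br, I, B, other), degree (0–5), formal
charge (−2…+2), total H count (0–4), aromaticity and ring membership
(29 dims); bond features are order, conjugation and ring membership
(6 dims). With `h0_vw = relu(W_i [x_v ; e_vw])`, messages update as

```
h_vw(t) = relu(h0_vw + W_h · Σ_{k∈N(v)\w} h_kv(t−1)),   t = 1 … T−1
```

excluding the reverse edge from the aggregation so information does not
echo straight back. Atom states are `h_v = relu(W_o [x_v ; Σ_k h_kv])`, and
the molecule vector is the **sum** over atom states (the MPN
representation). A feed-forward head (default one hidden layer) produces
three-class logits; its final hidden activation is the **last_FFN**
representation used as the primary structural fingerprint downstream.

Implementation is plain NumPy (float64) with hand-derived gradients
(verified against central finite differences to ~1e-6 relative error) and
Adam. This keeps the model dependency-light, single-process and exactly
reproducible: atom/edge ordering is derived from the canonical SMILES
parse, so any SMILES writing of a molecule yields a bit-identical graph,
embedding and prediction.

### Hyperparameters

| parameter | default | notes |
|---|---|---|
| `hidden_dim` | 1100 | full-scale embedding width; all tests and the shipped study run at 64 |
| `ffn_hidden_dim` | = `hidden_dim` | the head width is a separate knob |
| `message_steps` T | 3 | number of edge-state levels |
| `dropout` | 0.0 | inverted dropout on the last FFN activation when > 0 |
| optimizer | Adam, lr 1e-3 | |
| `epochs` / `batch_size` | 30 / 50 | |

Training is two-stage. **Pretraining** draws a seeded uniform microbial
sample equal in size to the Animalia set (whole pool with a warning if
smaller) and trains encoder + head jointly with 3-class cross-entropy; the
sampled ids are recorded on the model. **Fine-tuning** freezes the encoder
— the returned model shares the encoder arrays, so the freeze contract is
bit-exact by construction and witnessed by a SHA-256 checksum — and re-fits
only the head.

The `map4like` fingerprint is a MinHashed atom-pair descriptor built
in-package: for every atom pair, shingles combine the two atoms' canonical
circular-environment SMILES at radius 1 and 2 with their topological
distance; the shingle set is min-hashed into 1024 slots with fixed-seed
universal hashing (single-atom molecules hash singleton shingles). It is a
deterministic, rewriting-invariant baseline in the same spirit as MinHashed
atom-pair fingerprints from the literature, not a bit-compatible clone of
any of them.

## Synthetic data generator

The generator emulates the three chemotypes that make structure-based
origin classification plausible in the first place:

* **class 0** — saturated fused/bridged carbocycles (decalin,
  perhydrophenanthrene, spiro and steroid-flavoured tetracyclic cores)
  decorated with alkyl/hydroxyl substituents;
* **class 1** — aromatic nitrogen heterocycles (pyridine, pyrimidine,
  indole, quinoline, quinoxaline, imidazole, pyrrole) with amide/amine
  decoration;
* **class 2** — lactones and ester/ketone-rich chains with acyl/ester
  decoration (polyketide flavour).

Molecules are assembled by attaching 1–3 substituents to template cores at
carbons with free valence, sanitizing after every attachment, so all SMILES
are valid by construction; duplicates are rejected and generation raises an
actionable error if the grammar cannot supply the requested number of
distinct structures. The default study conditions are 200/100/100
train compounds, a disjoint 60/30/30 test draw, and an 8% one-way
microbial→Animalia flip rate — a deliberately strong but not overwhelming
noise level for a screening method whose premise is that most labels are
correct.

What the generator does **not** emulate: real MNP property distributions,
scaffold overlap between kingdoms, stereochemical subtlety, or compounds
near class boundaries. The three classes are nearly linearly separable
(5-fold fingerprint-classifier accuracy ≥ 0.9 is a construction
requirement). Consequently the shipped study measures whether the
machinery is *correct* — that screening recovers exactly the planted
flips, that filtering matches its brute-force definition — not what
precision/recall the method would achieve on CMNPD-scale data, where
boundaries blur and both numbers will drop.

## Cross-prediction screening

Each of `cycles` (default 10) rounds trains a fresh model on a seeded
random `subset_fraction` (default 0.5 — a balance between per-cycle
training representation and OOF coverage; unspecified upstream) of the
Animalia compounds plus **all** microbial compounds, then predicts the
held-out Animalia compounds. Out-of-fold probability vectors are averaged
per compound across cycles; a compound is flagged iff the argmax of the
mean vector is not class 0. Averaging probabilities (rather than majority
voting per-cycle argmaxes) uses the models' confidence; argmax ties break
toward class 0, i.e. conservatively toward keeping the label.

Coverage is `strict` by default: every Animalia id is assigned one
mandatory hold-out cycle (seeded round-robin over a permutation) before
training subsets are drawn, guaranteeing ≥ 1 OOF appearance whenever
`(1 − subset_fraction) · cycles ≥ 1`; otherwise the error names the minimal
feasible cycle count. `independent` mode draws cycles independently
instead. The trainer is a pluggable contract (dataset, seed → predictor),
which is how the tests substitute a truth-table oracle for the network.

## Neighborhood filter

After retraining on step-1 survivors (pipeline ordering enforces this),
Animalia compounds whose last_FFN embedding lies strictly within Euclidean
radius of any microbial embedding are removed. The KD-tree is an
implementation detail; the semantics are the O(n²) predicate, and the test
suite asserts equality on random instances. The default radius 5.0 is
scale-dependent (embeddings are unnormalized), so `radius="auto"` sets it
to the 1% quantile of the pairwise-distance distribution — the
distribution-based choice that a fixed 5.0 presumes.

## Evaluation

Balanced accuracy is computed exactly as the unweighted mean of per-class
recalls TPᵢ/(TPᵢ+FNᵢ) — no chance correction. Report tables row-normalize
the confusion matrix and round half-up to two decimals, so each kingdom's
accuracy plus its two misclassification rates sums to 100.00 ± 0.02 by
construction. Downstream heads are an RBF-kernel SVM and a
gradient-boosted-tree classifier (200 trees, depth 6; hyperparameters are
package defaults, recorded in run logs) fitted on last_FFN embeddings.

## MCTS rationales

States are connected subgraphs of the parent molecule. The only action is
deleting a non-ring (bridge) bond of the current subgraph; both resulting
components become children. This removes peripheral chains atom-group by
atom-group and whole terminal rings via their linker bond, while ring
systems are never fragmented. Node value is the scorer's probability for
the target class on the substructure SMILES; selection maximizes
`Q + c_puct · score · √N_parent/(1+N_child)` with deterministic, ordered
tie-breaks, so the search is reproducible without randomness. All visited
states within `[min_atoms, max_atoms]` scoring ≥ `prop_delta` are returned,
which makes the returned set monotone non-increasing in `prop_delta`; on
small molecules a few hundred rollouts enumerate the entire reachable
space, which is how the tests compare against brute-force subgraph
enumeration. Scorer failures prune the branch with a logged warning.
Aggregation groups rationales by exact canonical SMILES (reproducible by
construction) and ranks by count, then mean score.

## Pipeline and numerical choices

`run_pipeline` executes simulate → profile → pretrain → fine-tune →
two-step clean → retrain → evaluate → interpret. Every stage seed is
derived deterministically from the global seed; run directories are
content-addressed by a config hash and never overwritten; a stage failure
aborts with the stage name while keeping earlier artifacts. The shipped
configuration runs the whole workflow on 400 synthetic molecules at
`hidden_dim` 64 in well under a minute on one CPU.

Degenerate inputs handled explicitly: single-atom molecules have zero
directed edges (atom-only readout still works); acyclic molecules have an
empty Murcko scaffold and are excluded from top-N scaffold tables (a
"no-ring" pseudo-scaffold carries no origin signal); K-means with more
clusters than points raises with a suggested `k = ⌊n/2⌋` (or `k="auto"` to
clamp); the Morgan environment radius defaults to 6 but is an explicit
knob, since typical ECFP work uses 2–3.

## Known limitations

* The synthetic chemotypes are far more separable than real MNP chemistry;
  recovery metrics here are upper bounds, not forecasts.
* Cleaning can only *remove* suspect Animalia records; it neither corrects
  labels to a specific microbial kingdom nor questions microbial labels.
* The fixed neighborhood radius is meaningless across embedding scales;
  use `auto` unless embeddings are known to share a scale.
* Rationale "clustering" is exact-SMILES grouping; structurally similar
  but non-identical rationales remain separate rows (an optional
  similarity merge is deliberately not the default, for reproducibility).
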