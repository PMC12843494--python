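# mnporigin

Structure-based origin classification and symbiosis-misannotation cleaning
for marine natural products.

## The problem

Marine natural products (MNPs) carry a biological-origin annotation —
here mapped to kingdom level as **0 = Animalia, 1 = Bacteria, 2 = Fungi**.
Many compounds credited to a marine invertebrate are actually biosynthesized
by its microbial symbionts, and because public databases compile origins
from the literature, these host-attribution errors propagate. The bias is
asymmetric: microbial labels usually rest on direct isolation and culture,
while animal labels are often host-based inference. For anyone training
structure→origin models, mining biosynthetic gene clusters, or choosing
isolation targets, this label noise is a first-order problem.

`mnporigin` is a pipeline for (a) classifying a compound's kingdom of
origin from its structure alone and (b) detecting and removing
Animalia-labeled compounds that are structurally microbial. It ships a
synthetic-data generator that emulates the three chemotypes (saturated
fused carbocycles for animal-derived compounds, aromatic N-heterocycles
for bacterial, ester/polyketide-flavoured structures for fungal) with a
planted, one-way microbial→Animalia noise mechanism, so the entire
workflow is testable without any proprietary database export.

## The method

**Encoder.** Molecules are encoded with a directed message-passing neural
network (D-MPNN) over the bond graph: messages live on directed edges, and
the update for edge *v→w* aggregates incoming messages *k→v* excluding the
reverse edge, for *T* = 3 steps; a sum readout over atom states yields the
molecule embedding (the *MPN* representation), and a feed-forward head maps
it to three kingdom logits. The activation of the head's final hidden layer
(*last_FFN*) is the primary structural fingerprint. A MinHashed atom-pair
fingerprint (`map4like`) is provided as a model-free baseline
representation. The network is implemented in NumPy with hand-derived
gradients and Adam, so runs are exactly reproducible on one CPU.

**Training scheme.** Stage 1 pretrains encoder + head jointly on all
Animalia compounds plus an equal-sized seeded sample of microbial
compounds (3-class cross-entropy). Stage 2 freezes the encoder —
bit-identical before and after — and fits only the head on the full
training set. SVM and gradient-boosted-tree heads can additionally be
trained on the extracted last_FFN embeddings.

**Two-step cleaning.**

1. *Cross-prediction screening* — over 10 cycles, a random half of the
   Animalia compounds plus all microbial compounds trains a fresh model;
   the held-out Animalia compounds receive out-of-fold probability
   vectors. Per compound the vectors are averaged across cycles and the
   compound is flagged iff argmax of the mean is microbial.
2. *Neighborhood filtering* — after retraining on the step-1 survivors,
   Animalia compounds whose last_FFN embedding lies within a Euclidean
   radius of any microbial compound are removed (KD-tree accelerated;
   radius 5.0 or the 1% quantile of the pairwise-distance distribution
   with `radius="auto"`).

**Evaluation.** Confusion matrices, per-kingdom report tables, and balanced
accuracy

&nbsp;&nbsp;&nbsp;&nbsp;BA = (1/N) Σᵢ TPᵢ / (TPᵢ + FNᵢ),&nbsp;&nbsp;N = 3,

i.e. the unweighted mean of per-class recalls, reported in percent.

**Interpretability.** Monte Carlo tree search over peripheral-fragment
deletions (ring systems are never fragmented) finds minimal connected
substructures whose classifier score for a target kingdom stays above a
threshold; rationales are aggregated by canonical SMILES.

## Worked example

Plant 8% microbial→Animalia label flips into a 400-compound synthetic
dataset and recover them with the cross-prediction screen (64-dim encoder,
10 cycles; ~30 s on one CPU):

```python
from mnporigin import (SyntheticSpec, generate_dataset, inject_label_noise,
                       EncoderConfig, cross_prediction_screen)
from mnporigin.cleaning import model_trainer

ds = generate_dataset(SyntheticSpec(n_per_class={0: 200, 1: 100, 2: 100}, seed=7))
noisy, planted = inject_label_noise(ds, rate=0.08, seed=7)
trainer = model_trainer(EncoderConfig(hidden_dim=64, seed=7))
log, flagged = cross_prediction_screen(noisy, trainer, cycles=10,
                                       subset_fraction=0.5, seed=7)
print(f"planted flips : {len(planted)}")
print(f"flagged       : {len(flagged)}")
print(f"true positives: {len(flagged & planted)}")
```

Output:

```
planted flips : 16
flagged       : 16
true positives: 16
```

All 16 planted misannotations are flagged with no false positives: the
screen's averaged out-of-fold predictions contradict the corrupted
Animalia labels exactly on the structurally microbial compounds. On real
database exports, where class boundaries are far blurrier, precision and
recall will be lower — see `docs/methods.md` for what the synthetic
conditions do and do not demonstrate.

The same workflow is available from the shell:

```bash
mnporigin simulate --n-animalia 200 --n-bacteria 100 --n-fungi 100 \
    --noise-rate 0.08 --seed 7 --out ds.csv
mnporigin clean --in ds.csv --cycles 10 --subset-fraction 0.5 \
    --radius auto --seed 7 --out-dir cleaned/
mnporigin run-all --seed 7 --out-dir runs/
```

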