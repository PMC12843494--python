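"""Two-step misannotation cleaning for Animalia-labeled compounds.

Historic origin annotations trust isolation evidence asymmetrically:
microbial labels usually stem from direct culture, while animal labels are
often host-based inference that a symbiont actually deserves.  Cleaning
therefore only ever questions label 0 (Animalia):

Step 1 — cross-prediction screening.  Over several cycles, a random subset
of Animalia compounds plus *all* microbial compounds trains a fresh
classifier; the held-out Animalia compounds receive out-of-fold (OOF)
probability vectors.  Per compound the OOF vectors are averaged across
cycles; a compound whose averaged prediction is microbial is flagged.

Step 2 — embedding-neighborhood filtering.  On a model retrained after
step 1, Animalia compounds whose last_FFN embedding lies within a Euclidean
radius of any microbial compound are removed (KD-tree accelerated, defined
by the brute-force predicate "∃ microbial j with d(i,j) < r").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chem_io import CompoundRecord, LabeledDataset, MICROBIAL_LABELS
from .encoder import EmbeddingTable, EncoderConfig, OriginModel, train_from_scratch

# A trainer builds a fresh model from a cycle's training set and returns a
# predictor mapping compound records to an (n, 3) class-probability matrix.
Predictor = Callable[[Sequence[CompoundRecord]], np.ndarray]
Trainer = Callable[[LabeledDataset, int], Predictor]


def model_trainer(config: EncoderConfig) -> Trainer:
    """Trainer backed by the D-MPNN model (fresh joint training per cycle)."""

    def trainer(train_ds: LabeledDataset, seed: int) -> Predictor:
        from dataclasses import replace

        model = train_from_scratch(train_ds, replace(config, seed=seed))

        def predict(records: Sequence[CompoundRecord]) -> np.ndarray:
            return model.predict_proba([r.smiles for r in records])

        return predict

    return trainer


@dataclass
class OOFLog:
    """Per-Animalia-compound out-of-fold prediction log."""

    entries: dict[str, list[tuple[int, np.ndarray]]] = field(default_factory=dict)

    def add(self, cid: str, cycle: int, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (3,) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"OOF entry for {cid!r} is not a probability simplex")
        self.entries.setdefault(cid, []).append((cycle, probs))

    def appearance_count(self, cid: str) -> int:
        return len(self.entries.get(cid, []))

    def mean_probs(self) -> dict[str, np.ndarray]:
        return {
            cid: np.mean([p for _, p in rows], axis=0)
            for cid, rows in self.entries.items()
        }

    def to_rows(self) -> list[dict]:
        out = []
        for cid, rows in self.entries.items():
            for cycle, p in rows:
                out.append({"id": cid, "cycle": cycle,
                            "p0": p[0], "p1": p[1], "p2": p[2]})
        return out


@dataclass
class CleaningReport:
    """Outcome of the two-step workflow plus the settings that produced it."""

    step1_flagged: set[str] = field(default_factory=set)
    step2_removed: set[str] = field(default_factory=set)
    cycles: int = 0
    subset_fraction: float = 0.5
    radius: float = 5.0
    seed: int = 0
    mean_confidence: dict[str, list[float]] = field(default_factory=dict)

    @property
    def removed_ids(self) -> set[str]:
        return self.step1_flagged | self.step2_removed

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "step1_flagged": sorted(self.step1_flagged),
            "step2_removed": sorted(self.step2_removed),
            "cycles": self.cycles,
            "subset_fraction": self.subset_fraction,
            "radius": self.radius,
            "seed": self.seed,
            "mean_confidence": self.mean_confidence,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CleaningReport":
        d = json.loads(Path(path).read_text())
        return cls(
            set(d["step1_flagged"]), set(d["step2_removed"]), d["cycles"],
            d["subset_fraction"], d["radius"], d["seed"], d["mean_confidence"],
        )


def cross_prediction_screen(
    ds: LabeledDataset,
    trainer: Trainer,
    cycles: int = 10,
    subset_fraction: float = 0.5,
    seed: int = 0,
    coverage: str = "strict",
) -> tuple[OOFLog, set[str]]:
    """Flag Animalia compounds whose averaged OOF prediction is microbial.

    Each cycle trains on a seeded random ``subset_fraction`` of the Animalia
    compounds plus all microbial compounds, and predicts the held-out
    Animalia compounds.  With ``coverage="strict"`` (default) every Animalia
    compound is guaranteed at least one OOF appearance: each id is assigned
    one mandatory hold-out cycle before the per-cycle training subsets are
    drawn.  ``coverage="independent"`` draws cycles independently.

    A compound is flagged iff the argmax of its cycle-averaged probability
    vector is not class 0, with argmax ties resolved toward class 0 (no
    flag).  Microbial compounds are never candidates.  Deterministic for a
    given seed.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if not 0.0 < subset_fraction < 1.0:
        raise ValueError("subset_fraction must lie strictly between 0 and 1")
    counts = ds.counts
    if min(counts.values()) == 0:
        raise ValueError("screening requires all three kingdom labels present")
    animalia = [r for r in ds if r.label == 0]
    microbial = [r for r in ds if r.label in MICROBIAL_LABELS]
    n0 = len(animalia)
    train_size = round(subset_fraction * n0)
    holdout_per_cycle = n0 - train_size
    if holdout_per_cycle == 0:
        raise ValueError(
            "subset_fraction leaves no held-out Animalia compounds; lower it"
        )
    if coverage == "strict" and holdout_per_cycle * cycles < n0:
        min_cycles = math.ceil(n0 / holdout_per_cycle)
        raise ValueError(
            f"coverage impossible: {cycles} cycles × {holdout_per_cycle} "
            f"held out < {n0} Animalia compounds; need at least "
            f"{min_cycles} cycles"
        )
    if coverage not in ("strict", "independent"):
        raise ValueError(f"coverage must be 'strict' or 'independent'; got {coverage!r}")

    rng = np.random.default_rng(seed)
    ani_ids = [r.id for r in animalia]
    mandatory_cycle: dict[str, int] = {}
    if coverage == "strict":
        perm = rng.permutation(n0)
        for pos, idx in enumerate(perm):
            mandatory_cycle[ani_ids[idx]] = pos % cycles

    log = OOFLog()
    by_id = {r.id: r for r in animalia}
    for cycle in range(cycles):
        available = [cid for cid in ani_ids if mandatory_cycle.get(cid) != cycle]
        chosen = rng.choice(available, size=min(train_size, len(available)),
                            replace=False).tolist()
        train_records = [by_id[cid] for cid in chosen] + microbial
        heldout = [by_id[cid] for cid in ani_ids if cid not in set(chosen)]
        predict = trainer(LabeledDataset(train_records), seed * 1000 + cycle)
        probs = np.asarray(predict(heldout), dtype=float)
        for rec, p in zip(heldout, probs):
            log.add(rec.id, cycle, p)

    flagged = set()
    for cid, mean in log.mean_probs().items():
        if max(mean[1], mean[2]) > mean[0]:  # argmax tie keeps the Animalia label
            flagged.add(cid)
    return log, flagged


def neighborhood_filter(
    emb: EmbeddingTable, labels: dict[str, int], radius: float = 5.0
) -> set[str]:
    """Animalia ids lying strictly within ``radius`` of any microbial point.

    Computed with a KD-tree but defined by the brute-force predicate
    ``label(i)=0 and ∃ j microbial with ‖x_i − x_j‖ < radius`` (strict
    inequality, so radius 0 removes nothing).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if len(emb.ids) == 0 or radius == 0:
        return set()
    vecs = {cid: v for cid, v in zip(emb.ids, emb.vectors)}
    micro = [cid for cid in emb.ids if labels[cid] in MICROBIAL_LABELS]
    ani = [cid for cid in emb.ids if labels[cid] == 0]
    if not micro or not ani:
        return set()
    micro_X = np.vstack([vecs[c] for c in micro])
    tree = cKDTree(micro_X)
    removed = set()
    for cid in ani:
        idx = tree.query_ball_point(vecs[cid], r=radius)
        if any(np.linalg.norm(vecs[cid] - micro_X[j]) < radius for j in idx):
            removed.add(cid)
    return removed


def auto_radius(emb: EmbeddingTable, quantile: float = 0.01, seed: int = 0,
                max_points: int = 2000) -> float:
    """Radius from the embedding's pairwise-distance distribution.

    Returns the given quantile (default 1%) of pairwise Euclidean distances;
    for large tables a seeded subsample of ``max_points`` is used.
    """
    X = emb.vectors
    if len(X) < 2:
        raise ValueError("need at least two points to estimate a radius")
    if len(X) > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=max_points, replace=False)]
    from scipy.spatial.distance import pdist

    return float(np.quantile(pdist(X), quantile))


def apply_cleaning(ds: LabeledDataset, report: CleaningReport) -> LabeledDataset:
    """Drop the union of flagged and neighborhood-removed ids.

    Microbial records are never touched; an id in the report that is absent
    from the dataset raises.
    """
    removed = report.removed_ids
    unknown = removed - set(ds.ids)
    if unknown:
        raise KeyError(f"report references unknown ids: {sorted(unknown)[:5]}")
    microbial_hit = {cid for cid in removed if ds[cid].label in MICROBIAL_LABELS}
    if microbial_hit:
        raise ValueError(
            f"cleaning report targets microbial records: {sorted(microbial_hit)[:5]}"
        )
    return ds.without(removed)
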