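"""Downstream heads, confusion matrices, balanced accuracy, report tables.

Balanced accuracy is the unweighted mean of per-class recalls,

    BA = (1/N) Σ_i TP_i / (TP_i + FN_i),   N = 3 kingdoms,

reported as a percentage.  Report tables mirror the per-class layout used
for origin classification: each kingdom's accuracy plus its two
misclassification rates, row-normalized so the three percentages sum to
100 within rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .chem_io import LABEL_NAMES, LABELS
from .encoder import EmbeddingTable


@dataclass
class ConfusionMatrix:
    """3×3 counts; rows = true kingdom, columns = predicted kingdom."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix; got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return 3

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i].sum() - self.counts[i, i])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Exact 3×3 confusion counts from parallel label sequences."""
    t = np.asarray(list(true_labels))
    p = np.asarray(list(predicted_labels))
    if len(t) != len(p):
        raise ValueError(f"label sequences differ in length ({len(t)} vs {len(p)})")
    counts = np.zeros((3, 3), dtype=np.int64)
    for ti, pi in zip(t, p):
        counts[int(ti), int(pi)] += 1
    return ConfusionMatrix(counts)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class recalls, as a percentage."""
    recalls = []
    for i in LABELS:
        denom = cm.tp(i) + cm.fn(i)
        if denom == 0:
            raise ValueError(
                f"class {i} ({LABEL_NAMES[i]}) has no evaluated samples; "
                "balanced accuracy undefined"
            )
        recalls.append(cm.tp(i) / denom)
    return float(np.mean(recalls)) * 100.0


def balanced_accuracy_from_recalls(recalls_pct) -> float:
    """Balanced accuracy (%) from already-computed per-class accuracies (%)."""
    recalls = list(recalls_pct)
    if len(recalls) != 3:
        raise ValueError("expected three per-class accuracies")
    return float(np.mean(recalls))


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (presentation convention for tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PerClassReport:
    """Per-kingdom accuracy and misclassification rates (%, 2 decimals).

    ``rows[i]`` maps target class j → percentage of true-class-i compounds
    predicted as j; the diagonal entry is the class accuracy.
    """

    rows: dict[int, dict[int, float]]
    balanced_accuracy: float

    def as_dict(self) -> dict:
        named = {}
        for i, row in self.rows.items():
            ni = LABEL_NAMES[i][:3]
            named[f"{ni} Acc"] = row[i]
            for j in LABELS:
                if j != i:
                    named[f"{ni} to {LABEL_NAMES[j][:3]}"] = row[j]
        return {"Balanced Acc": self.balanced_accuracy, **named}


def table_report(cm: ConfusionMatrix) -> PerClassReport:
    """Row-normalized percentages with half-up 2-decimal rounding."""
    rows: dict[int, dict[int, float]] = {}
    for i in LABELS:
        row_total = cm.counts[i].sum()
        if row_total == 0:
            rows[i] = {j: 0.0 for j in LABELS}
            continue
        rows[i] = {
            j: round2(100.0 * cm.counts[i, j] / row_total) for j in LABELS
        }
    ba = round2(balanced_accuracy(cm))
    return PerClassReport(rows, ba)


def train_head(emb: EmbeddingTable, labels: dict[str, int], kind: str, seed: int = 0):
    """Fit a classical head (SVM or gradient-boosted trees) on embeddings.

    ``kind`` ∈ {"svm", "gbt"}.  Returns a fitted scikit-learn-style
    classifier exposing ``predict`` and ``predict_proba``; deterministic
    for a fixed seed.  Raises on single-class input.
    """
    y = np.array([labels[cid] for cid in emb.ids])
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; nothing to separate")
    X = emb.vectors
    if kind == "svm":
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
    elif kind == "gbt":
        clf = XGBClassifier(
            n_estimators=200, max_depth=6, random_state=seed, n_jobs=1,
            verbosity=0, use_label_encoder=False, eval_metric="mlogloss",
        )
    else:
        raise ValueError(f"kind must be 'svm' or 'gbt'; got {kind!r}")
    clf.fit(X, y)
    return clf


def project_2d(emb: EmbeddingTable, method: str = "pca", seed: int = 0) -> np.ndarray:
    """Seeded 2-D projection of an embedding table (PCA or t-SNE)."""
    X = emb.vectors
    if len(X) < 3:
        raise ValueError("projection needs at least 3 points")
    if method == "pca":
        return PCA(n_components=2, random_state=seed).fit_transform(X)
    if method == "tsne":
        perplexity = min(30.0, (len(X) - 1) / 3.0)
        return TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(X)
    raise ValueError(f"method must be 'pca' or 'tsne'; got {method!r}")
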