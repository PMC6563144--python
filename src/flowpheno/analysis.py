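"""Downstream characterization of the learned latent space.

Operates on the matrix of posterior means (one 10-vector per crop):
unsupervised k-means classification scored against ground truth by the
accuracy-maximising cluster-to-label assignment, few-shot SVM
classification from a handful of annotated examples per species,
Euclidean nearest-neighbour queries, a seeded t-SNE 2-D visualisation,
and latent-space interpolation decoded back to images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .vae import decode


@dataclass
class LatentMatrix:
    """Rows = crops, columns = latent posterior means; optionally labelled."""

    values: np.ndarray                       # (n, latent_dim)
    ids: np.ndarray | None = None            # crop ids aligned to rows
    labels: np.ndarray | None = None         # ground-truth species per row

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValueError("latent matrix contains non-finite entries")
        if self.ids is None:
            self.ids = np.arange(len(self.values))
        self.ids = np.asarray(self.ids)
        if len(self.ids) != len(self.values):
            raise ValueError("ids not aligned to rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.values):
                raise ValueError("labels not aligned to rows")


@dataclass
class ClassificationReport:
    predicted: np.ndarray
    accuracy: float
    confusion: np.ndarray                    # rows true, cols predicted, row %
    class_names: list
    misclassified_ids: np.ndarray
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "class_names": list(self.class_names),
                "confusion_percent": self.confusion.tolist(),
                "misclassified_ids": self.misclassified_ids.tolist()}


def _confusion_percent(true_idx, pred_idx, k):
    counts = np.zeros((k, k), dtype=np.float64)
    for t, p in zip(true_idx, pred_idx):
        counts[t, p] += 1
    rows = counts.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1
    return 100.0 * counts / rows


def map_clusters_to_labels(clusters: np.ndarray, true_idx: np.ndarray,
                           k: int) -> np.ndarray:
    """Accuracy-maximising bijection cluster -> label (Hungarian assignment).

    For k = 2 this equals brute force over both permutations.
    """
    agree = np.zeros((k, k), dtype=np.int64)
    for c, t in zip(clusters, true_idx):
        agree[c, t] += 1
    row, col = linear_sum_assignment(-agree)
    mapping = np.empty(k, dtype=int)
    mapping[row] = col
    return mapping


def kmeans_classify(latents: LatentMatrix, k: int = 2,
                    seed: int = 0, n_init: int = 10) -> ClassificationReport:
    """Unsupervised species classification: k-means on the latent space,
    clusters mapped to ground-truth labels by the best bijection."""
    if latents.labels is None:
        raise ValueError("ground-truth labels required for scoring")
    x = latents.values
    if len(np.unique(x, axis=0)) < k:
        raise ValueError("k exceeds the number of distinct points")
    names = sorted(np.unique(latents.labels).tolist())
    if len(names) != k:
        raise ValueError(f"found {len(names)} labels for k={k}")
    true_idx = np.array([names.index(l) for l in latents.labels])
    clusters = KMeans(n_clusters=k, n_init=n_init,
                      random_state=seed).fit_predict(x)
    mapping = map_clusters_to_labels(clusters, true_idx, k)
    pred_idx = mapping[clusters]
    acc = float(np.mean(pred_idx == true_idx))
    report = ClassificationReport(
        predicted=np.array([names[i] for i in pred_idx]),
        accuracy=acc,
        confusion=_confusion_percent(true_idx, pred_idx, k),
        class_names=names,
        misclassified_ids=latents.ids[pred_idx != true_idx])
    return report


def fewshot_svm(latents: LatentMatrix, n_per_class: int = 10, seed: int = 0,
                kernel: str = "linear", C: float = 1.0,
                selection: str = "representative"):
    """Few-shot species classification: linear SVM on ``n_per_class``
    annotated examples per species, scored on the held-out remainder.

    ``selection="representative"`` (default) annotates the examples nearest
    each class medoid in latent space — emulating an expert picking typical
    exemplars of each species — which makes the result deterministic given
    the latents.  ``selection="random"`` is a seeded stratified draw.
    Returns (report, fitted classifier); the evaluation set never overlaps
    the training set.
    """
    if latents.labels is None:
        raise ValueError("labels required")
    if selection not in ("representative", "random"):
        raise ValueError("selection must be 'representative' or 'random'")
    names = sorted(np.unique(latents.labels).tolist())
    true_idx = np.array([names.index(l) for l in latents.labels])
    rng = np.random.default_rng(seed)
    train_rows = []
    for c in range(len(names)):
        rows = np.where(true_idx == c)[0]
        if len(rows) < n_per_class + 1:
            raise ValueError(f"class {names[c]!r} has only {len(rows)} examples")
        if selection == "representative":
            medoid = np.median(latents.values[rows], axis=0)
            dist = np.linalg.norm(latents.values[rows] - medoid, axis=1)
            train_rows.extend(rows[np.argsort(dist)[:n_per_class]])
        else:
            train_rows.extend(rng.choice(rows, n_per_class, replace=False))
    train_rows = np.array(sorted(train_rows))
    test_rows = np.setdiff1d(np.arange(len(true_idx)), train_rows)
    clf = SVC(kernel=kernel, C=C)
    clf.fit(latents.values[train_rows], true_idx[train_rows])
    pred = clf.predict(latents.values[test_rows])
    acc = float(np.mean(pred == true_idx[test_rows]))
    report = ClassificationReport(
        predicted=np.array([names[i] for i in pred]),
        accuracy=acc,
        confusion=_confusion_percent(true_idx[test_rows], pred, len(names)),
        class_names=names,
        misclassified_ids=latents.ids[test_rows[pred != true_idx[test_rows]]],
        extras={"train_ids": latents.ids[train_rows].tolist()})
    return report, clf


def nearest_neighbors(latents: LatentMatrix, query_id, k: int = 4) -> np.ndarray:
    """The ``k`` ids nearest the query in Euclidean latent distance,
    ascending, query excluded; exact ties broken by id."""
    rows = np.where(latents.ids == query_id)[0]
    if len(rows) == 0:
        raise ValueError(f"query id {query_id!r} not present")
    if k >= len(latents.values):
        raise ValueError("k must be smaller than the number of points")
    q = latents.values[rows[0]]
    mask = np.arange(len(latents.values)) != rows[0]
    d = np.linalg.norm(latents.values[mask] - q, axis=1)
    ids = latents.ids[mask]
    order = np.lexsort((ids, d))
    return ids[order[:k]]


def tsne_embed(latents: LatentMatrix, seed: int = 0,
               perplexity: float | None = None) -> np.ndarray:
    """Seeded 2-D t-SNE of the latent matrix (visualisation only).

    Perplexity defaults to 30, reduced to (n - 1) / 3 for small n.
    """
    n = len(latents.values)
    if n < 5:
        raise ValueError("need at least 5 points")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
              init="pca")
    return ts.fit_transform(latents.values).astype(np.float64)


def latent_interpolate(model, z_a: np.ndarray, z_b: np.ndarray,
                       steps: int = 8) -> np.ndarray:
    """Decode the straight latent path (1 - t) z_a + t z_b at ``steps``
    equally spaced t in [0, 1]; endpoints decode exactly z_a and z_b."""
    if steps < 2:
        raise ValueError("steps must be >= 2")
    z_a = np.asarray(z_a, dtype=np.float64)
    z_b = np.asarray(z_b, dtype=np.float64)
    if z_a.shape != z_b.shape or z_a.ndim != 1:
        raise ValueError("z_a and z_b must be 1-D of equal length")
    ts = np.linspace(0.0, 1.0, steps)
    # decode one latent at a time so each frame is bit-identical to a
    # standalone decode of the same vector (batch matmuls may reorder
    # float reductions)
    return np.stack([decode(model, (1 - t) * z_a + t * z_b) for t in ts])
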