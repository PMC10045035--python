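"""Mislabeled-negative elimination via image flattening, PCA and k-means.

Candidates called by upstream callers but absent from the truth set are
labeled negative; some of those are real variants the truth set simply lacks,
and training on them teaches the classifier to discard true calls. To purge
them, every image is flattened column-wise into one integer feature vector

    ArrE[i][j] = sum_k ( R[k][j] * omega^2 + G[k][j] * omega + B[k][j] )

(the sum runs over image rows, so the feature is invariant to where in the
stack a fragment was drawn), the matrix is PCA-reduced, rows are k-means
clustered, and negatives sitting in predominantly positive clusters are
removed. Positives are never removed, and labels are never flipped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .encoder import EncodedImage

DEFAULT_OMEGA = 256
DEFAULT_N_CLUSTERS = 8
DEFAULT_PURITY = 0.5
DEFAULT_PCA_COMPONENTS = 10
# per-type caps used to balance positive/negative counts before training
DEFAULT_BALANCE_CAPS = {"INS": 5000, "DEL": 5000, "INV": 10000, "DUP": 10000}


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n_samples, n_features)
    labels: list[str]  # per-row: positive | negative
    ids: list[str]
    reduced: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.values.shape[0] or len(self.ids) != self.values.shape[0]:
            raise ValueError("labels/ids length must equal row count")

    @property
    def active(self) -> np.ndarray:
        return self.reduced if self.reduced is not None else self.values


@dataclass
class ClusterPartition:
    assignments: np.ndarray  # (n_samples,) cluster index
    n_clusters: int


def flatten_images(
    images: Sequence[EncodedImage] | Sequence[np.ndarray],
    labels: Sequence[str],
    ids: Sequence[str],
    omega: int = DEFAULT_OMEGA,
) -> FeatureMatrix:
    """Column-wise integer flattening of fixed-size RGB images (exact arithmetic)."""
    if omega < 2:
        raise ValueError("omega must be >= 2")
    arrays = [im.pixels if isinstance(im, EncodedImage) else im for im in images]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"images have mixed shapes: {sorted(shapes)}")
    rows = []
    for a in arrays:
        a = a.astype(np.int64)
        r, g, b = a[..., 0], a[..., 1], a[..., 2]
        rows.append((r * omega * omega + g * omega + b).sum(axis=0))
    return FeatureMatrix(np.asarray(rows, dtype=np.int64), list(labels), list(ids))


def reduce_features(
    matrix: FeatureMatrix, n_components: int = DEFAULT_PCA_COMPONENTS, seed: int = 0
) -> FeatureMatrix:
    """Project onto the top principal components (deterministic sign convention)."""
    X = matrix.values.astype(np.float64)
    if X.shape[0] < 2 or not np.any(X.std(axis=0) > 0):
        raise ValueError("zero variance: feature matrix is constant, PCA undefined")
    n_components = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    Z = pca.fit_transform(X)
    # fix signs: largest-|loading| coordinate of each component made positive
    for k in range(pca.components_.shape[0]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            Z[:, k] *= -1
    matrix.reduced = Z
    return matrix


def cluster_rows(
    matrix: FeatureMatrix, n_clusters: int = DEFAULT_N_CLUSTERS, seed: int = 0
) -> ClusterPartition:
    """Seeded k-means over the (reduced) feature rows."""
    X = matrix.active.astype(np.float64)
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if X.shape[0] < n_clusters:
        raise ValueError(f"{X.shape[0]} rows < {n_clusters} clusters")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return ClusterPartition(km.fit_predict(X), n_clusters)


def remove_mislabeled(
    partition: ClusterPartition,
    matrix: FeatureMatrix,
    purity_threshold: float = DEFAULT_PURITY,
) -> tuple[list[str], list[str], dict[int, float]]:
    """Drop negatives whose cluster is predominantly positive.

    For each cluster the positive fraction ``p`` is computed; negatives in
    clusters with ``p >= purity_threshold`` are removed. Returns
    (surviving ids, removed ids, per-cluster positive fraction).
    """
    labels = np.asarray([1 if l == "positive" else 0 for l in matrix.labels])
    purity: dict[int, float] = {}
    removed_mask = np.zeros(len(labels), dtype=bool)
    for cl in range(partition.n_clusters):
        members = partition.assignments == cl
        if not members.any():
            purity[cl] = 0.0
            continue
        p = float(labels[members].mean())
        purity[cl] = p
        if p >= purity_threshold:
            removed_mask |= members & (labels == 0)
    kept = [i for i, m in zip(matrix.ids, removed_mask) if not m]
    removed = [i for i, m in zip(matrix.ids, removed_mask) if m]
    return kept, removed, purity


def eliminate_mislabeled_per_type(
    images_by_type: dict[str, list[EncodedImage]],
    labels_by_type: dict[str, list[str]],
    omega: int = DEFAULT_OMEGA,
    n_components: int = DEFAULT_PCA_COMPONENTS,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    purity_threshold: float = DEFAULT_PURITY,
    seed: int = 0,
    audit_path: str | Path | None = None,
) -> dict[str, list[str]]:
    """Run the elimination pipeline independently per SV type.

    Returns surviving candidate ids per type; optionally writes an audit TSV
    of removed ids (id, svtype, cluster, cluster positive fraction).
    """
    kept_by_type: dict[str, list[str]] = {}
    audit_rows: list[tuple[str, str, int, float]] = []
    for svtype, images in images_by_type.items():
        labels = labels_by_type[svtype]
        ids = [im.candidate_id for im in images]
        if len(images) < max(n_clusters, 2) or len(set(labels)) < 2:
            kept_by_type[svtype] = list(ids)
            continue
        fm = flatten_images(images, labels, ids, omega)
        try:
            reduce_features(fm, n_components, seed)
        except ValueError:
            kept_by_type[svtype] = list(ids)
            continue
        part = cluster_rows(fm, n_clusters, seed)
        kept, removed, purity = remove_mislabeled(part, fm, purity_threshold)
        kept_by_type[svtype] = kept
        cluster_of = dict(zip(fm.ids, part.assignments))
        audit_rows.extend(
            (rid, svtype, int(cluster_of[rid]), purity[int(cluster_of[rid])])
            for rid in removed
        )
    if audit_path is not None:
        with open(audit_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "svtype", "cluster", "cluster_positive_fraction"])
            for row in sorted(audit_rows):
                w.writerow([row[0], row[1], row[2], f"{row[3]:.4f}"])
    return kept_by_type


def balance_classes(
    samples: Sequence[tuple[str, str, str]],
    caps: dict[str, int] | None = None,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Per-type, per-class seeded down-sampling to the configured caps.

    ``samples`` are (id, svtype, label) triples. Each class within each SV
    type is down-sampled uniformly at random to ``min(cap, class size)``.
    Types where one class is empty are skipped (they cannot train a binary
    model) with a warning.
    """
    import warnings

    caps = dict(DEFAULT_BALANCE_CAPS, **(caps or {}))
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, str]] = []
    types = sorted({s[1] for s in samples})
    for svtype in types:
        cap = caps.get(svtype, max(caps.values()))
        pos = sorted(s for s in samples if s[1] == svtype and s[2] == "positive")
        neg = sorted(s for s in samples if s[1] == svtype and s[2] == "negative")
        if not pos or not neg:
            warnings.warn(f"type {svtype} has an empty class; skipped for training")
            continue
        for cls in (pos, neg):
            if len(cls) > cap:
                idx = rng.choice(len(cls), size=cap, replace=False)
                out.extend(cls[i] for i in sorted(idx))
            else:
                out.extend(cls)
    return out
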