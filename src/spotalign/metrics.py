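"""Evaluation metrics for slice alignment and integration.

Matching-based metrics judge the hard spot correspondence: *alignment
accuracy* is the fraction of matched spot pairs whose annotations agree, and
*label-transfer ARI* (LTARI) is the adjusted Rand index between a slice's own
annotations and the annotations transferred through the correspondence
``pi``.  Embedding-based metrics judge the common latent space following
single-cell integration benchmarking conventions: kNN *batch entropy*
(normalized to [0,1]; 1 = batches perfectly mixed), *batch ASW* (silhouette
on batch labels within each cell-type group, rescaled so 1 = well mixed) and
*cell-type ASW* (silhouette on cell-type labels, rescaled to [0,1];
1 = well separated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .gat import Embedding
from .uot import Matching, UNMATCHED

__all__ = ["MetricsReport", "alignment_accuracy", "label_transfer_ari",
           "batch_entropy", "silhouette_scores", "evaluate"]

SENTINEL = float("nan")


@dataclass
class MetricsReport:
    alignment_accuracy: float
    ltari: float
    batch_entropy: float
    batch_asw: float
    celltype_asw: float
    n_matched: int

    def to_dict(self) -> dict:
        return asdict(self)


def _matched(matching: Matching) -> tuple[np.ndarray, np.ndarray]:
    rows = np.nonzero(matching.pi != UNMATCHED)[0]
    return rows, matching.pi[rows]


def alignment_accuracy(matching: Matching, labels_x: np.ndarray,
                       labels_y: np.ndarray) -> float:
    """Fraction of matched pairs with equal annotations.

    Unmatched source spots are excluded from the denominator; if nothing is
    matched the metric is undefined and NaN is returned with a warning.
    """
    rows, cols = _matched(matching)
    if rows.size == 0:
        warnings.warn("no matched pairs; alignment accuracy undefined")
        return SENTINEL
    lx = np.asarray(labels_x)[rows]
    ly = np.asarray(labels_y)[cols]
    return float(np.mean(lx == ly))


def label_transfer_ari(matching: Matching, labels_x: np.ndarray,
                       labels_y: np.ndarray) -> float:
    """ARI between source annotations and annotations transferred via pi.

    Restricted to matched spots.  When both partitions are single clusters
    the ARI is undefined by convention; identical one-cluster partitions
    return 1.0.
    """
    rows, cols = _matched(matching)
    if rows.size == 0:
        warnings.warn("no matched pairs; LTARI undefined")
        return SENTINEL
    lx = np.asarray(labels_x)[rows]
    transferred = np.asarray(labels_y)[cols]
    if len(set(lx)) == 1 and len(set(transferred)) == 1:
        return 1.0
    return float(adjusted_rand_score(lx, transferred))


def batch_entropy(embedding: Embedding | np.ndarray, batch_ids: np.ndarray,
                  k_neighbors: int = 50) -> float:
    """Mean kNN batch-composition entropy, normalized to [0, 1].

    For each spot, the entropy of the batch proportions among its
    ``k_neighbors`` nearest neighbors in the embedding, averaged over spots
    and divided by ``log(n_batches)``.
    """
    z = embedding.z if isinstance(embedding, Embedding) else np.asarray(embedding)
    batch_ids = np.asarray(batch_ids)
    batches, codes = np.unique(batch_ids, return_inverse=True)
    if batches.size < 2:
        raise ValueError("batch entropy needs at least two batches")
    n = z.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    idx = nn.kneighbors(z, return_distance=False)[:, 1:]  # drop self
    neigh_codes = codes[idx]
    ent = np.zeros(n)
    for b in range(batches.size):
        p = (neigh_codes == b).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent -= np.where(p > 0, p * np.log(p), 0.0)
    return float(ent.mean() / np.log(batches.size))


def silhouette_scores(embedding: Embedding | np.ndarray, labels: np.ndarray,
                      batch_ids: np.ndarray | None = None
                      ) -> tuple[float, float]:
    """(cell-type ASW, batch ASW), both rescaled to [0, 1].

    Cell-type ASW: ``(mean silhouette over labels + 1) / 2`` — separation of
    annotated types.  Batch ASW: within each label group containing >= 2
    batches, ``1 - |mean silhouette over batch ids|``; averaged over groups
    and clipped to [0, 1] — closeness of batches within a type.  Groups too
    small to score are excluded with a warning.
    """
    z = embedding.z if isinstance(embedding, Embedding) else np.asarray(embedding)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two label groups")
    sil = silhouette_samples(z, labels)
    celltype_asw = float((sil.mean() + 1.0) / 2.0)

    batch_asw = SENTINEL
    if batch_ids is not None:
        batch_ids = np.asarray(batch_ids)
        per_group = []
        for lab in np.unique(labels):
            sel = labels == lab
            group_batches = np.unique(batch_ids[sel])
            if group_batches.size < 2 or sel.sum() <= group_batches.size:
                warnings.warn(
                    f"label group {lab!r} too small/single-batch; excluded "
                    "from batch ASW")
                continue
            s = silhouette_samples(z[sel], batch_ids[sel])
            per_group.append(1.0 - abs(float(s.mean())))
        if per_group:
            batch_asw = float(np.clip(np.mean(per_group), 0.0, 1.0))
    return celltype_asw, batch_asw


def evaluate(matching: Matching, embedding: Embedding | np.ndarray,
             labels_x: np.ndarray, labels_y: np.ndarray,
             batch_ids: np.ndarray, k_neighbors: int = 50) -> MetricsReport:
    """Full report over one aligned slice pair.

    ``labels_x``/``labels_y`` annotate the two slices in matching order;
    the embedding rows are the concatenation of both slices with
    ``batch_ids`` marking the slice of origin.
    """
    labels_all = np.concatenate([np.asarray(labels_x), np.asarray(labels_y)])
    ct_asw, b_asw = silhouette_scores(embedding, labels_all, batch_ids)
    return MetricsReport(
        alignment_accuracy=alignment_accuracy(matching, labels_x, labels_y),
        ltari=label_transfer_ari(matching, labels_x, labels_y),
        batch_entropy=batch_entropy(embedding, batch_ids, k_neighbors),
        batch_asw=b_asw,
        celltype_asw=ct_asw,
        n_matched=matching.n_matched,
    )
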