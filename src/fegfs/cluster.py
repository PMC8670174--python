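"""Agglomerative cell clustering and partition-agreement metrics.

Clustering is bottom-up agglomerative merging under Euclidean distance in
the feature space, with Ward linkage by default (the natural pairing for
Euclidean distances).  Agreement between a predicted clustering and
reference labels is measured four ways:

* ARI — the Hubert-Arabie adjusted Rand index from pair counts,
* NMI — 2 I(F, G) / (H(F) + H(G)) from the contingency table,
* HOM / COM — matching-based homogeneity and completeness: each predicted
  cluster is matched to a reference class (majority vote by default,
  optimal assignment optionally) and the correctly classified fraction is
  averaged over cluster sizes (HOM) or matched class sizes (COM).

HOM/COM here are the matched-fraction variants, not the entropy-based
V-measure scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering

from .features import FeatureMatrix

LINKAGES = ("ward", "average", "complete", "single")


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    linkage: str
    cell_ids: list[str] | None = None


@dataclass
class MetricReport:
    ari: float
    nmi: float
    hom: float
    com: float

    def as_dict(self) -> dict[str, float]:
        return {"ARI": self.ari, "NMI": self.nmi,
                "HOM": self.hom, "COM": self.com}


def agglomerative(features: FeatureMatrix | np.ndarray, k: int,
                  linkage: str = "ward") -> ClusteringResult:
    """Cluster cells into ``k`` groups by agglomerative merging."""
    if isinstance(features, FeatureMatrix):
        X, cell_ids = features.values, features.cell_ids
    else:
        X, cell_ids = np.asarray(features, dtype=float), None
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage,
                                    metric="euclidean")
    labels = model.fit_predict(X)
    return ClusteringResult(labels=labels, k=k, linkage=linkage,
                            cell_ids=cell_ids)


def _check_pair(truth: Sequence, pred: Sequence) -> tuple[np.ndarray, np.ndarray]:
    t, p = np.asarray(truth), np.asarray(pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    return t, p


def contingency(truth: Sequence, pred: Sequence) -> np.ndarray:
    """Classes x clusters contingency table (rows: truth, cols: pred)."""
    t, p = _check_pair(truth, pred)
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=int)
    np.add.at(table, (ti, pi), 1)
    return table


def ari(truth: Sequence, pred: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index in [-1, 1]."""
    table = contingency(truth, pred)
    n = int(table.sum())
    sum_ij = sum(comb(int(x), 2) for x in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        # both partitions trivial (all-singletons or single cluster): treat
        # exact agreement as 1, consistent with the identical-partition case
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def nmi(truth: Sequence, pred: Sequence) -> float:
    """Normalized mutual information 2 I / (H(F) + H(G)) in [0, 1]."""
    table = contingency(truth, pred)
    n = table.sum()
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    mask = pij > 0
    mi = float((pij[mask] * np.log(
        pij[mask] / (pi[:, None] * pj[None, :])[mask])).sum())
    h_f = float(-(pi[pi > 0] * np.log(pi[pi > 0])).sum())
    h_g = float(-(pj[pj > 0] * np.log(pj[pj > 0])).sum())
    if h_f + h_g == 0.0:
        return 1.0  # both partitions trivial and identical
    return max(0.0, 2.0 * mi / (h_f + h_g))


def hom_com(truth: Sequence, pred: Sequence,
            matching: str = "majority") -> tuple[float, float]:
    """Matching-based homogeneity and completeness scores.

    Every predicted cluster i is matched to a reference class — its
    majority class (ties to the smallest class index), or with
    ``matching="hungarian"`` the globally optimal one-to-one assignment.
    With N(F_i, G_i) the matched-class cells inside cluster i,

        HOM = mean_i N(F_i, G_i) / |cluster i|
        COM = mean_i N(F_i, G_i) / |matched class of i|

    averaged over the k predicted clusters.
    """
    table = contingency(truth, pred)  # classes x clusters
    n_classes, k = table.shape
    class_sizes = table.sum(axis=1)
    cluster_sizes = table.sum(axis=0)

    if matching == "majority":
        matched = np.argmax(table, axis=0)  # argmax ties -> smallest index
    elif matching == "hungarian":
        # pad to square so every cluster receives some class
        size = max(n_classes, k)
        cost = np.zeros((size, size))
        cost[:n_classes, :k] = -table
        rows, cols = linear_sum_assignment(cost)
        matched = np.empty(k, dtype=int)
        for r, c in zip(rows, cols):
            if c < k:
                matched[c] = r if r < n_classes else int(np.argmax(table[:, c]))
    else:
        raise ValueError(f"unknown matching {matching!r}")

    correct = table[matched, np.arange(k)]
    hom = float(np.mean(correct / cluster_sizes))
    com = float(np.mean(correct / class_sizes[matched]))
    return hom, com


def evaluate(truth: Sequence, pred: Sequence,
             matching: str = "majority") -> MetricReport:
    """All four agreement scores between reference and predicted labels."""
    hom, com = hom_com(truth, pred, matching=matching)
    return MetricReport(ari=ari(truth, pred), nmi=nmi(truth, pred),
                        hom=hom, com=com)


def read_labels(path) -> tuple[list[str], np.ndarray]:
    """Read a two-column TSV (cell_id, label)."""
    ids, labels = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cid, lab = line.rstrip("\n").split("\t")[:2]
            ids.append(cid)
            labels.append(lab)
    return ids, np.asarray(labels)


def write_labels(cell_ids: Sequence[str], labels: Sequence, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, lab in zip(cell_ids, labels):
            fh.write(f"{cid}\t{lab}\n")
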