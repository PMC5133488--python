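"""Stage 3a: local ancestry within a region from its common variants.

In a recently admixed cohort the common variants of a genomic window carry
enough frequency differentiation to separate the ancestral origins of that
window.  We take the leading principal components of the region's common-variant
dosages and cluster subjects with k-means (defaults: 3 PCs, k = 3 for a
three-way admixed population).  The resulting labels are an anonymous
partition — no identity is claimed across regions and no cluster is mapped to
a named ancestral population.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .containers import MISSING, LocalAncestry, ValidationError

logger = logging.getLogger(__name__)

ANCESTRY_UNASSIGNABLE = "ancestry_unassignable"
CLUSTER_FALLBACK = "cluster_fallback"


class LocalAncestryKMeans(BaseEstimator, ClusterMixin):
    """PCA + k-means local-ancestry clustering for one region.

    Parameters
    ----------
    n_pcs : int
        Leading principal components of the common-variant dosages to cluster
        on (default 3).
    n_clusters : int
        Target number of ancestry clusters k (default 3).
    n_restarts : int
        k-means++ restarts; the best fit by within-cluster sum of squares wins.
    random_state : int
        Seed for the k-means initializations (deterministic given the seed).
    scaling : {"standardize", "patterson"}
        Per-SNV scaling before the PCA, matching the global-PCA convention.
    weight_by_eigenvalue : bool
        If True, scale each PC score column by sqrt(eigenvalue) weight before
        clustering; default False (unweighted scores).

    Fitted attributes: ``labels_`` (1..J), ``n_clusters_`` (realized J),
    ``cluster_sizes_``, ``pc_scores_``, ``flags_``.
    """

    def __init__(
        self,
        n_pcs: int = 3,
        n_clusters: int = 3,
        n_restarts: int = 10,
        random_state: int = 0,
        scaling: str = "standardize",
        weight_by_eigenvalue: bool = False,
    ):
        self.n_pcs = n_pcs
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.scaling = scaling
        self.weight_by_eigenvalue = weight_by_eigenvalue

    def fit(self, X: np.ndarray, y=None) -> "LocalAncestryKMeans":
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValidationError("expected a subjects × common-SNVs dosage matrix")
        if (X == MISSING).any():
            raise ValidationError("local-ancestry input contains missing dosages; impute first")
        n = X.shape[0]

        Xf = X.astype(np.float64)
        var = Xf.var(axis=0)
        poly = var > 0
        if int(poly.sum()) < self.n_pcs:
            # Too little common-variant information to place subjects: the
            # region is flagged and everyone falls into a single cluster.
            self.labels_ = np.ones(n, dtype=int)
            self.n_clusters_ = 1
            self.cluster_sizes_ = np.array([n])
            self.pc_scores_ = np.zeros((n, 0))
            self.flags_ = frozenset({ANCESTRY_UNASSIGNABLE})
            return self

        Xf = Xf[:, poly]
        if self.scaling == "patterson":
            p = Xf.mean(axis=0) / 2.0
            scale = np.sqrt(p * (1.0 - p))
        else:
            scale = np.sqrt(var[poly])
        Z = (Xf - Xf.mean(axis=0)) / scale
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        rank = int((s > s[0] * max(Z.shape) * np.finfo(float).eps).sum())
        n_use = min(self.n_pcs, rank)
        # sign convention: largest-magnitude loading positive, so the scores
        # (hence the k-means++ draws) do not depend on SNV column order
        signs = np.sign(Vt[np.arange(n_use), np.abs(Vt[:n_use]).argmax(axis=1)])
        signs[signs == 0] = 1.0
        scores = U[:, :n_use] * s[:n_use] * signs
        if self.weight_by_eigenvalue:
            ev = (s[:n_use] ** 2) / max(n - 1, 1)
            scores = scores * np.sqrt(ev / ev.max())

        n_distinct = np.unique(np.round(scores, 12), axis=0).shape[0]
        k = min(self.n_clusters, n_distinct, n)
        flags = set()
        if k < self.n_clusters:
            flags.add(CLUSTER_FALLBACK)
            logger.info("local ancestry: only %d distinct score rows; using k=%d", n_distinct, k)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=int(self.random_state) % (2**32),
        ).fit(scores)
        raw = km.labels_
        # relabel realized clusters to 1..J by first occurrence: deterministic
        # and independent of sklearn's internal label assignment
        order: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, lab in enumerate(raw):
            if lab not in order:
                order[lab] = len(order) + 1
            labels[i] = order[lab]
        J = len(order)
        if J < k:
            flags.add(CLUSTER_FALLBACK)
        self.labels_ = labels
        self.n_clusters_ = J
        self.cluster_sizes_ = np.bincount(labels, minlength=J + 1)[1:]
        self.pc_scores_ = scores
        self.flags_ = frozenset(flags)
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def infer_local_ancestry(
    g_common: np.ndarray,
    n_pcs: int = 3,
    k: int = 3,
    n_restarts: int = 10,
    seed: int = 0,
    scaling: str = "standardize",
) -> LocalAncestry:
    """Cluster a region's subjects by ancestral origin (thin estimator wrapper)."""
    est = LocalAncestryKMeans(
        n_pcs=n_pcs, n_clusters=k, n_restarts=n_restarts, random_state=seed, scaling=scaling
    ).fit(g_common)
    return LocalAncestry(
        labels=est.labels_,
        n_clusters=est.n_clusters_,
        cluster_sizes=est.cluster_sizes_,
        pc_scores=est.pc_scores_,
        flags=est.flags_,
    )


def local_ancestry_frame(la: LocalAncestry, subject_ids=None):
    """Per-subject diagnostics table: cluster label and the PC scores used."""
    import pandas as pd

    df = pd.DataFrame({"label": la.labels})
    for k in range(la.pc_scores.shape[1]):
        df[f"PC{k + 1}"] = la.pc_scores[:, k]
    if subject_ids is not None:
        df.insert(0, "id", list(subject_ids))
    return df
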