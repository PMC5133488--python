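"""Principal-component scores on dosage matrices, and their bootstrap stability.

The first PC of a genome-wide standardized dosage matrix is the usual
single-axis summary of global ancestry in an admixed sample; its per-subject
score enters the trait adjustment.  The decomposition is computed exactly via
the subjects × subjects Gram matrix, accumulated over SNV chunks, so very wide
matrices never need a dense standardized copy in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .containers import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GlobalPCScores:
    """Per-subject PC scores (columns ordered by decreasing explained variance)."""

    scores: np.ndarray
    explained_variance: np.ndarray


class GlobalPCA(BaseEstimator):
    """Exact PCA of a subjects × SNVs dosage matrix.

    Monomorphic SNVs are dropped (with a logged count); the remaining columns
    are mean-centered and scaled.  The sign of each component is fixed so that
    its largest-magnitude SNV loading is positive, making scores reproducible
    across column reorderings up to that convention.

    Parameters
    ----------
    n_components : int
        Number of leading components to retain.
    scaling : {"standardize", "patterson"}
        ``standardize`` divides each SNV by its sample standard deviation (the
        common GWAS convention, making rare and common SNVs commensurate);
        ``patterson`` divides by sqrt(p(1-p)) with p the sample allele
        frequency.
    chunk_size : int
        SNV columns per block in the Gram accumulation.
    """

    def __init__(self, n_components: int = 1, scaling: str = "standardize", chunk_size: int = 20_000):
        self.n_components = n_components
        self.scaling = scaling
        self.chunk_size = chunk_size

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "GlobalPCA":
        X = self._validate(X)
        n, m = X.shape
        mean = np.empty(m)
        var = np.empty(m)
        for sl in self._chunks(m):
            block = X[:, sl].astype(np.float64)
            mean[sl] = block.mean(axis=0)
            var[sl] = block.var(axis=0)
        keep = var > 0
        n_dropped = int(m - keep.sum())
        if n_dropped:
            logger.info("GlobalPCA: dropping %d monomorphic SNVs of %d", n_dropped, m)
        if not keep.any():
            raise ValidationError("all SNVs are monomorphic; PCA is undefined")
        if self.scaling == "standardize":
            scale = np.sqrt(var)
        elif self.scaling == "patterson":
            p = mean / 2.0
            scale = np.sqrt(p * (1.0 - p))
        else:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        scale[~keep] = 1.0  # dropped anyway

        m_kept = int(keep.sum())
        n_comp = min(self.n_components, n, m_kept)
        if n <= m_kept:
            # wide matrix: n × n Gram, accumulated over SNV chunks
            G = np.zeros((n, n))
            for sl in self._chunks(m):
                k = keep[sl]
                if not k.any():
                    continue
                block = (X[:, sl].astype(np.float64)[:, k] - mean[sl][k]) / scale[sl][k]
                G += block @ block.T
            evals, evecs = np.linalg.eigh(G)
            order = np.argsort(evals)[::-1]
            evals = np.clip(evals[order], 0.0, None)
            sv = np.sqrt(evals[:n_comp])
            U = evecs[:, order][:, :n_comp]
            scores = U * sv
            # One more pass for the SNV loadings of the retained components;
            # they set the sign convention and let transform() project.
            V = np.zeros((m_kept, n_comp))
            col = 0
            safe_sv = np.where(sv > 0, sv, 1.0)
            for sl in self._chunks(m):
                k = keep[sl]
                if not k.any():
                    continue
                block = (X[:, sl].astype(np.float64)[:, k] - mean[sl][k]) / scale[sl][k]
                V[col : col + block.shape[1]] = block.T @ (U / safe_sv)
                col += block.shape[1]
        else:
            # tall matrix: m × m scatter, accumulated over subject chunks
            M = np.zeros((m_kept, m_kept))
            step = max(self.chunk_size // max(m_kept, 1), 1) * 64
            for lo in range(0, n, step):
                rows = X[lo : lo + step].astype(np.float64)[:, keep]
                rows = (rows - mean[keep]) / scale[keep]
                M += rows.T @ rows
            evals, evecs = np.linalg.eigh(M)
            order = np.argsort(evals)[::-1]
            evals = np.clip(evals[order], 0.0, None)
            sv = np.sqrt(evals[:n_comp])
            V = evecs[:, order][:, :n_comp]
            scores = np.zeros((n, n_comp))
            for lo in range(0, n, step):
                rows = X[lo : lo + step].astype(np.float64)[:, keep]
                rows = (rows - mean[keep]) / scale[keep]
                scores[lo : lo + rows.shape[0]] = rows @ V
        signs = np.sign(V[np.abs(V).argmax(axis=0), np.arange(n_comp)])
        signs[signs == 0] = 1.0
        V *= signs
        scores = scores * signs

        self.n_snvs_in_ = m
        self.keep_mask_ = keep
        self.n_dropped_monomorphic_ = n_dropped
        self.mean_ = mean
        self.scale_ = scale
        self.components_ = V.T  # (n_components, n_kept_snvs)
        self.singular_values_ = sv
        self.explained_variance_ = evals[:n_comp] / max(n - 1, 1)
        self.scores_ = scores
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (possibly new) subjects onto the fitted components."""
        X = self._validate(X)
        if X.shape[1] != self.n_snvs_in_:
            raise ValidationError(
                f"transform expects {self.n_snvs_in_} SNVs, got {X.shape[1]}"
            )
        out = np.zeros((X.shape[0], self.components_.shape[0]))
        col = 0
        for sl in self._chunks(self.n_snvs_in_):
            k = self.keep_mask_[sl]
            if not k.any():
                continue
            block = (X[:, sl].astype(np.float64)[:, k] - self.mean_[sl][k]) / self.scale_[sl][k]
            out += block @ self.components_[:, col : col + block.shape[1]].T
            col += block.shape[1]
        return out

    # -- helpers -----------------------------------------------------------
    def _chunks(self, m: int):
        step = max(int(self.chunk_size), 1)
        for lo in range(0, m, step):
            yield slice(lo, min(lo + step, m))

    @staticmethod
    def _validate(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("PCA needs a 2-D matrix with at least 2 subjects")
        if (X == MISSING).any():
            raise ValidationError("PCA input contains missing dosages; impute first")
        return X


def compute_global_pcs(g: GenotypeMatrix, n_components: int = 1, scaling: str = "standardize") -> GlobalPCScores:
    """Global-ancestry PC scores of a genotype matrix (thin estimator wrapper)."""
    pca = GlobalPCA(n_components=n_components, scaling=scaling).fit(g.dosages)
    return GlobalPCScores(pca.scores_, pca.explained_variance_)


def bootstrap_pc_stability(
    g: GenotypeMatrix | np.ndarray,
    n_snvs_per_rep: int,
    n_reps: int,
    n_components: int,
    seed: int,
    scaling: str = "standardize",
    tsv_path=None,
) -> np.ndarray:
    """Bootstrap stability of PC subject scores.

    For each replicate, SNV columns are resampled with replacement, the PCA is
    recomputed, and each component's subject scores are correlated (absolute
    Pearson, handling sign indeterminacy) with the full-data component.
    Returns the mean absolute correlation per component; a stable axis of
    structure (e.g. genuine ancestry on PC1) stays near 1 while noise axes
    decorrelate.
    """
    X = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)
    if n_snvs_per_rep < 2:
        raise ValidationError("n_snvs_per_rep must be ≥ 2")
    full = GlobalPCA(n_components=n_components, scaling=scaling).fit(X).scores_
    rng = np.random.default_rng(seed)
    corr = np.full((n_reps, full.shape[1]), np.nan)
    for rep in range(n_reps):
        idx = rng.integers(0, X.shape[1], size=n_snvs_per_rep)
        sub = GlobalPCA(n_components=n_components, scaling=scaling).fit(X[:, idx]).scores_
        for c in range(min(sub.shape[1], full.shape[1])):
            a, b = full[:, c], sub[:, c]
            if a.std() == 0 or b.std() == 0:
                continue
            corr[rep, c] = abs(np.corrcoef(a, b)[0, 1])
    stability = np.nanmean(corr, axis=0)
    if tsv_path is not None:
        import pandas as pd

        pd.DataFrame(
            {"component": np.arange(1, len(stability) + 1),
             "mean_abs_correlation": stability}
        ).to_csv(tsv_path, sep="\t", index=False)
    return stability
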