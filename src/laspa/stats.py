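"""Stage 3b: the summation-partition statistics I1 and IA for a region.

For a region with K rare variants and adjusted phenotype Y with overall mean
Ȳ, the marginal summation-partition statistic is

    I1 = Σ_{i=1..K} n_i² (Ȳ_i − Ȳ)²

where n_i is the number of carriers of rare variant i (subjects with at least
one minor allele) and Ȳ_i is the mean adjusted phenotype over those carriers.
The local-ancestry variant partitions each carrier set by the subject's
ancestry cluster j ∈ 1..J for the region:

    IA = Σ_{j=1..J} Σ_{i=1..K} n_{i,j}² (Ȳ_{i,j} − Ȳ)²

with n_{i,j} = carriers of variant i in cluster j and Ȳ_{i,j} their mean
phenotype.  Ȳ is always the *overall* sample mean, never a per-cluster mean.
Zero-carrier terms contribute exactly 0 (the n² = 0 weight), so monomorphic
rare columns are harmless.  With J = 1 the outer sum collapses and IA = I1.

``n_i`` is the carrier count by default; an experimental ``allele`` mode
weights by the minor-allele count instead (carrier means are unchanged).
"""

from __future__ import annotations

import numpy as np

from .containers import MISSING, CarrierStructure, LocalAncestry, RegionStatistics, ValidationError


class NoRareVariantsError(ValueError):
    """Raised when a statistic is requested for a region with K = 0."""


def build_carriers(g_rare: np.ndarray) -> CarrierStructure:
    """Carrier structure of a region's rare-variant dosage submatrix.

    A carrier is a subject with dosage ≥ 1; a homozygote counts once.  A
    region with no rare variants yields an empty (flaggable) structure.
    """
    g_rare = np.asarray(g_rare)
    if g_rare.ndim != 2:
        raise ValidationError("expected a subjects × rare-SNVs dosage matrix")
    if (g_rare == MISSING).any():
        raise ValidationError("carrier structure requires imputed dosages")
    return CarrierStructure(carriers=g_rare >= 1, dosages=g_rare.astype(np.int8))


def _weights(c: CarrierStructure, mode: str) -> np.ndarray:
    if mode == "carrier":
        return c.carriers.sum(axis=0).astype(np.float64)
    if mode == "allele":
        return c.dosages.astype(np.float64).sum(axis=0)
    raise ValueError(f"unknown carrier mode {mode!r}; use 'carrier' or 'allele'")


def compute_I1(y: np.ndarray, c: CarrierStructure, mode: str = "carrier") -> float:
    """Marginal summation-partition statistic I1 = Σ n_i² (Ȳ_i − Ȳ)²."""
    y = np.asarray(y, dtype=np.float64)
    if c.K == 0:
        raise NoRareVariantsError("region has no rare variants; I1 is undefined")
    ybar = y.mean()
    C = c.carriers.astype(np.float64)
    counts = C.sum(axis=0)
    w = _weights(c, mode)
    sums = y @ C
    nz = counts > 0
    means = np.zeros_like(sums)
    means[nz] = sums[nz] / counts[nz]
    return float((w[nz] ** 2 * (means[nz] - ybar) ** 2).sum())


def compute_IA(
    y: np.ndarray, c: CarrierStructure, la: LocalAncestry, mode: str = "carrier"
) -> RegionStatistics:
    """Local-ancestry statistic IA and its per-cluster decomposition."""
    y = np.asarray(y, dtype=np.float64)
    if c.K == 0:
        raise NoRareVariantsError("region has no rare variants; IA is undefined")
    if len(la.labels) != len(y):
        raise ValidationError("ancestry labels are not aligned with the phenotype")
    ybar = y.mean()
    per_cluster = np.zeros(la.n_clusters)
    for j in range(1, la.n_clusters + 1):
        mask = la.labels == j
        Cj = c.carriers[mask].astype(np.float64)
        counts = Cj.sum(axis=0)
        if mode == "carrier":
            w = counts
        else:
            w = c.dosages[mask].astype(np.float64).sum(axis=0)
        sums = y[mask] @ Cj
        nz = counts > 0
        means = np.zeros_like(sums)
        means[nz] = sums[nz] / counts[nz]
        per_cluster[j - 1] = float((w[nz] ** 2 * (means[nz] - ybar) ** 2).sum())
    return RegionStatistics(
        I1=compute_I1(y, c, mode=mode), IA=float(per_cluster.sum()), per_cluster=per_cluster
    )
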