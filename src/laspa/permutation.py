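"""Stage 4: permutation p-values for each region and the full genome scan loop.

Three add-one Monte-Carlo p-values are produced per region, all holding the
carrier sets and ancestry labels fixed and permuting only the adjusted
phenotype Y:

* ``global_p_IA`` — IA against B unrestricted permutations of Y (a *global*
  null: the phenotype is independent of both the rare variants and the
  ancestry composition of the region);
* ``local_p_IA`` — IA against B permutations of Y *within* each ancestry
  cluster (a *local* null: any phenotype–ancestry association is preserved,
  only the within-cluster phenotype–genotype association is broken);
* ``p_I1`` — I1 against unrestricted permutations.

Each p-value is (1 + #{permuted ≥ observed}) / (B + 1); ties count as
exceedances and the estimator can never return 0.  The three schemes use
independent random streams spawned deterministically from
(master seed, region index, scheme), so results do not depend on the order in
which regions are processed.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    AdjustedPhenotype,
    CarrierStructure,
    LocalAncestry,
    Region,
    RegionResult,
)
from .stats import compute_I1, compute_IA

logger = logging.getLogger(__name__)

NO_RARE_VARIANTS = "no_rare_variants"

# stream identifiers for the spawned generators
_SCHEME_GLOBAL_IA = 1
_SCHEME_LOCAL_IA = 2
_SCHEME_I1 = 3


def _rng(seed: int, region_index: int, scheme: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(int(region_index), int(scheme)))
    )


def permute_global(y: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """One uniform random permutation of y across all subjects."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.permutation(np.asarray(y, dtype=np.float64))


def permute_local(
    y: np.ndarray, la: LocalAncestry, seed: int | np.random.Generator
) -> np.ndarray:
    """Permute y independently within each ancestry cluster.

    Cluster-wise multisets are conserved, so any phenotype–ancestry
    association survives while within-cluster phenotype–genotype association
    is destroyed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=np.float64).copy()
    for j in range(1, la.n_clusters + 1):
        idx = np.flatnonzero(la.labels == j)
        y[idx] = y[idx][rng.permutation(idx.size)]
    return y


def _perm_matrix_global(y: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """(n, B) matrix whose columns are independent unrestricted permutations."""
    Yb = np.tile(y, (B, 1))
    Yb = rng.permuted(Yb, axis=1)
    return Yb.T

def _perm_matrix_local(
    y: np.ndarray, la: LocalAncestry, B: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, B) matrix of independent within-cluster permutations."""
    Yb = np.tile(y, (B, 1))
    for j in range(1, la.n_clusters + 1):
        idx = np.flatnonzero(la.labels == j)
        if idx.size > 1:
            Yb[:, idx] = rng.permuted(Yb[:, idx], axis=1)
    return Yb.T


def _batch_I1(Y: np.ndarray, c: CarrierStructure, ybar: float, mode: str) -> np.ndarray:
    """I1 for every phenotype column of Y (n × B) with fixed carriers."""
    C = c.carriers.astype(np.float64)
    counts = C.sum(axis=0)
    w = counts if mode == "carrier" else c.dosages.astype(np.float64).sum(axis=0)
    nz = counts > 0
    S = C[:, nz].T @ Y  # (K_nz, B) carrier phenotype sums
    M = S / counts[nz][:, None]
    return ((w[nz][:, None] ** 2) * (M - ybar) ** 2).sum(axis=0)


def _batch_IA(
    Y: np.ndarray, c: CarrierStructure, la: LocalAncestry, ybar: float, mode: str
) -> np.ndarray:
    """IA for every phenotype column of Y (n × B) with fixed carriers/labels."""
    vals = np.zeros(Y.shape[1])
    for j in range(1, la.n_clusters + 1):
        mask = la.labels == j
        Cj = c.carriers[mask].astype(np.float64)
        counts = Cj.sum(axis=0)
        w = counts if mode == "carrier" else c.dosages[mask].astype(np.float64).sum(axis=0)
        nz = counts > 0
        if not nz.any():
            continue
        S = Cj[:, nz].T @ Y[mask]
        M = S / counts[nz][:, None]
        vals += ((w[nz][:, None] ** 2) * (M - ybar) ** 2).sum(axis=0)
    return vals


def _pvalue(perm_vals: np.ndarray, observed: float) -> float:
    B = perm_vals.size
    return float((1 + (perm_vals >= observed).sum()) / (B + 1))


def region_pvalues(
    y: AdjustedPhenotype | np.ndarray,
    c: CarrierStructure,
    la: LocalAncestry,
    B: int = 10_000,
    seed: int = 0,
    region: Region | None = None,
    region_index: int = 0,
    mode: str = "carrier",
    batch_size: int = 2_000,
) -> RegionResult:
    """Observed statistics and the three permutation p-values for one region."""
    if B < 1:
        raise ValueError("B must be ≥ 1")
    yv = np.asarray(y.y if isinstance(y, AdjustedPhenotype) else y, dtype=np.float64)
    flags = set(la.flags)
    if c.K == 0:
        flags.add(NO_RARE_VARIANTS)
        logger.info("region %d: no rare variants; statistics reported as NA", region_index)
        return RegionResult(
            region=region,
            n_rare=0,
            I1_obs=np.nan,
            IA_obs=np.nan,
            global_p_IA=np.nan,
            local_p_IA=np.nan,
            p_I1=np.nan,
            n_permutations=B,
            flags=frozenset(flags),
        )
    ybar = yv.mean()
    obs = compute_IA(yv, c, la, mode=mode)

    def scheme_pvalue(scheme: int, observed: float, use_ia: bool, local: bool) -> float:
        rng = _rng(seed, region_index, scheme)
        count = 0
        done = 0
        while done < B:
            b = min(batch_size, B - done)
            if local:
                Y = _perm_matrix_local(yv, la, b, rng)
            else:
                Y = _perm_matrix_global(yv, b, rng)
            vals = _batch_IA(Y, c, la, ybar, mode) if use_ia else _batch_I1(Y, c, ybar, mode)
            count += int((vals >= observed).sum())
            done += b
        return float((1 + count) / (B + 1))

    return RegionResult(
        region=region,
        n_rare=c.K,
        I1_obs=obs.I1,
        IA_obs=obs.IA,
        global_p_IA=scheme_pvalue(_SCHEME_GLOBAL_IA, obs.IA, use_ia=True, local=False),
        local_p_IA=scheme_pvalue(_SCHEME_LOCAL_IA, obs.IA, use_ia=True, local=True),
        p_I1=scheme_pvalue(_SCHEME_I1, obs.I1, use_ia=False, local=False),
        n_permutations=B,
        flags=frozenset(flags),
    )
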