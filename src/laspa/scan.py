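"""The four-stage genome scan, packaged as a fit-shaped estimator.

Stage 1 residualizes the trait on covariates and the leading global-ancestry
PC score(s); Stage 2 partitions SNVs into fixed-size chromosome-contiguous
regions split into rare/common sets by MAF; Stage 3 infers each region's
local ancestry from its common variants (PCA + k-means) and evaluates the
summation-partition statistics I1 and IA on its rare variants; Stage 4
attaches three permutation p-values per region.

A single master seed (``random_state``) spawns every random stream the scan
uses — imputation, per-region clustering, and the three permutation schemes
per region — via ``np.random.SeedSequence`` spawn keys, so a rerun with the
same seed is bit-identical and independent of region processing order.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io
from .adjust import TraitAdjuster
from .ancestry import infer_local_ancestry
from .containers import GenotypeMatrix, PhenotypeTable, RegionResult
from .pca import GlobalPCA
from .permutation import region_pvalues
from .regions import partition_regions
from .stats import build_carriers

logger = logging.getLogger(__name__)

# spawn-key namespaces under the master seed
_STREAM_IMPUTE = 0
_STREAM_ANCESTRY = 1


class LASPAScan(BaseEstimator):
    """Region-based rare-variant scan with local-ancestry partitioning.

    Parameters mirror the method's defaults: 500-SNV regions, MAF cutoff
    0.05, one global PC in the adjustment, 3 local PCs clustered with k = 3,
    and 10,000 permutations per region.

    After ``fit(genotypes, phenotypes)``:

    Attributes
    ----------
    results_ : list of RegionResult, sorted by chromosome then position
    results_table_ : pandas.DataFrame view of ``results_``
    adjusted_ : AdjustedPhenotype (Stage-1 residuals and model R²)
    global_scores_ : per-subject global PC scores used in the adjustment
    regions_ : list of Region
    """

    def __init__(
        self,
        region_size: int = 500,
        maf_cutoff: float = 0.05,
        n_pcs_global: int = 1,
        n_pcs_local: int = 3,
        k_clusters: int = 3,
        n_restarts: int = 10,
        n_permutations: int = 10_000,
        random_state: int = 0,
        scaling: str = "standardize",
        carrier_mode: str = "carrier",
        adjust: bool = True,
    ):
        self.region_size = region_size
        self.maf_cutoff = maf_cutoff
        self.n_pcs_global = n_pcs_global
        self.n_pcs_local = n_pcs_local
        self.k_clusters = k_clusters
        self.n_restarts = n_restarts
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.scaling = scaling
        self.carrier_mode = carrier_mode
        self.adjust = adjust

    def fit(self, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable) -> "LASPAScan":
        t0 = time.time()
        pheno = phenotypes.aligned_to(genotypes)

        impute_seed = np.random.SeedSequence(
            int(self.random_state), spawn_key=(_STREAM_IMPUTE,)
        ).generate_state(1)[0] % (2**31)
        g = io.impute_missing(genotypes, seed=int(impute_seed))
        logger.info("stage 0: imputation done (%.1fs)", time.time() - t0)

        if self.adjust:
            pca = GlobalPCA(n_components=self.n_pcs_global, scaling=self.scaling).fit(g.dosages)
            self.global_scores_ = pca.scores_
            adj = TraitAdjuster().fit(pheno, self.global_scores_)
            self.adjusted_ = adj.adjusted()
            logger.info(
                "stage 1: global PCs + covariate adjustment, R²=%.3f (%.1fs)",
                self.adjusted_.r_squared,
                time.time() - t0,
            )
        else:
            from .containers import AdjustedPhenotype

            y = pheno.table["trait"].to_numpy(dtype=float)
            self.global_scores_ = np.zeros((len(y), 0))
            self.adjusted_ = AdjustedPhenotype(y - y.mean(), 0.0)

        self.regions_ = partition_regions(g, self.region_size, self.maf_cutoff)
        logger.info("stage 2: %d regions of ≤%d SNVs", len(self.regions_), self.region_size)

        results: list[RegionResult] = []
        for r_idx, region in enumerate(self.regions_):
            anc_seed = np.random.SeedSequence(
                int(self.random_state), spawn_key=(_STREAM_ANCESTRY, r_idx)
            ).generate_state(1)[0] % (2**31)
            la = infer_local_ancestry(
                g.dosages[:, region.common_idx],
                n_pcs=self.n_pcs_local,
                k=self.k_clusters,
                n_restarts=self.n_restarts,
                seed=int(anc_seed),
                scaling=self.scaling,
            )
            carriers = build_carriers(g.dosages[:, region.rare_idx])
            results.append(
                region_pvalues(
                    self.adjusted_,
                    carriers,
                    la,
                    B=self.n_permutations,
                    seed=int(self.random_state),
                    region=region,
                    region_index=r_idx,
                    mode=self.carrier_mode,
                )
            )
        logger.info("stage 3-4: statistics + permutations done (%.1fs)", time.time() - t0)

        flagged = [(i, sorted(r.flags)) for i, r in enumerate(results) if r.flags]
        if flagged:
            logger.info("flagged regions: %s", flagged)
        self.results_ = results
        self.results_table_ = io.results_frame(results)
        return self

    def write_results(self, path) -> None:
        self._check_fitted()
        io.write_results(self.results_, path)

    def _check_fitted(self) -> None:
        if not hasattr(self, "results_"):
            raise RuntimeError("scan has not been fitted; call fit() first")


def run_scan(
    g: GenotypeMatrix, p: PhenotypeTable, **config
) -> list[RegionResult]:
    """Run the full four-stage scan; thin wrapper over :class:`LASPAScan`."""
    return LASPAScan(**config).fit(g, p).results_


def results_frame(results: list[RegionResult]) -> pd.DataFrame:
    return io.results_frame(results)
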