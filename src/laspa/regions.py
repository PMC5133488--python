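"""Stage 2: fixed-size chromosome-contiguous regions, stratified by MAF.

Consecutive SNVs (canonical file order) are grouped into windows of
``region_size`` within each chromosome; a trailing partial window becomes its
own (flagged) region.  Within each region SNVs are split into a *rare* set
(MAF strictly below the cutoff) and a *common* set (MAF ≥ cutoff — a MAF
exactly at the boundary is classed common, keeping the rare set strictly
rare).  Defaults: windows of 500 SNVs, cutoff 0.05.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix, Region, ValidationError


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Folded minor-allele frequency per SNV: min(f, 1 - f) of the dosage mean/2.

    Requires a fully observed (imputed) matrix.
    """
    if g.has_missing:
        raise ValidationError("compute_maf requires imputed genotypes (missing present)")
    f = g.dosages.astype(np.float64).sum(axis=0) / (2.0 * g.n_subjects)
    return np.minimum(f, 1.0 - f)


def partition_regions(
    g: GenotypeMatrix, region_size: int = 500, maf_cutoff: float = 0.05
) -> list[Region]:
    """Split SNVs into chromosome-contiguous windows of ``region_size``."""
    if region_size < 2:
        raise ValidationError(f"region_size must be ≥ 2, got {region_size}")
    if not (0.0 < maf_cutoff < 0.5):
        raise ValidationError(f"maf_cutoff must lie in (0, 0.5), got {maf_cutoff}")
    maf = compute_maf(g)
    chrom = g.snv_meta["chrom"].to_numpy(dtype=object)
    pos = g.snv_meta["pos"].to_numpy()

    regions: list[Region] = []
    # chromosome boundaries = changes in the (contiguous) chromosome labels
    boundaries = [0] + (np.flatnonzero(chrom[1:] != chrom[:-1]) + 1).tolist() + [g.n_snvs]
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        for start in range(lo, hi, region_size):
            stop = min(start + region_size, hi)
            idx = np.arange(start, stop)
            m = maf[idx]
            rare = idx[m < maf_cutoff]
            common = idx[m >= maf_cutoff]
            regions.append(
                Region(
                    chromosome=chrom[start],
                    start=start,
                    stop=stop,
                    maf=m,
                    rare_idx=rare,
                    common_idx=common,
                    pos_first=int(pos[start]),
                    pos_last=int(pos[stop - 1]),
                    is_partial=(stop - start) < region_size,
                )
            )
    return regions


def regions_to_bed(regions: list[Region], path) -> None:
    """Export region boundaries as BED (0-based half-open positions)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chromosome}\t{r.pos_first - 1}\t{r.pos_last}\tregion_{i}\n")
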