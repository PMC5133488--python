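"""Core in-memory containers shared across the scan pipeline.

Genotypes are held as a dense subjects × SNVs minor-allele dosage matrix
(``int8``; values 0/1/2 plus the out-of-band :data:`MISSING` sentinel) with a
per-SNV metadata frame. File order is the canonical SNV index everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Out-of-band sentinel for a missing genotype.  Deliberately not 0, so that
#: imputation can never silently treat a missing call as homozygous reference.
MISSING: int = -1


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class GenotypeMatrix:
    """Subjects × SNVs minor-allele dosage matrix with SNV metadata.

    Parameters
    ----------
    dosages
        ``(n_subjects, n_snvs)`` integer array with values in {0, 1, 2} or
        :data:`MISSING`.
    snv_meta
        One row per SNV, columns ``chrom`` (label), ``pos`` (1-based bp
        position) and optionally ``snv_id``.  Row order is the canonical SNV
        index (file order).
    subject_ids
        Unique subject identifiers aligned row-wise with ``dosages``.
    """

    dosages: np.ndarray
    snv_meta: pd.DataFrame
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D subjects × SNVs array")
        values = np.unique(self.dosages)
        bad = values[~np.isin(values, (MISSING, 0, 1, 2))]
        if bad.size:
            raise ValidationError(
                f"dosages contain values outside {{0,1,2,{MISSING}}}: {bad[:5].tolist()}"
            )
        if len(self.subject_ids) != self.dosages.shape[0]:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {self.dosages.shape[0]} rows"
            )
        ids, counts = np.unique(self.subject_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            raise ValidationError(
                f"duplicate subject ids: {ids[counts > 1][:5].tolist()}"
            )
        if not {"chrom", "pos"}.issubset(self.snv_meta.columns):
            raise ValidationError("snv_meta requires 'chrom' and 'pos' columns")
        if len(self.snv_meta) != self.dosages.shape[1]:
            raise ValidationError(
                f"{len(self.snv_meta)} metadata rows for {self.dosages.shape[1]} SNVs"
            )
        # Within each chromosome (taken as contiguous runs in file order)
        # positions must be non-decreasing: file order is the canonical index.
        pos = self.snv_meta["pos"].to_numpy()
        chrom = self.snv_meta["chrom"].to_numpy(dtype=object)
        if len(pos) > 1:
            same = chrom[1:] == chrom[:-1]
            if np.any(same & (np.diff(pos) < 0)):
                raise ValidationError("SNVs are not position-sorted within chromosome")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def chromosomes(self) -> list:
        """Chromosome labels in canonical (file) order."""
        out: list = []
        for c in self.snv_meta["chrom"]:
            if not out or out[-1] != c:
                out.append(c)
        return out


@dataclass
class PhenotypeTable:
    """Per-subject quantitative trait and covariates.

    ``table`` has one row per subject with columns ``id``, ``trait`` (e.g.
    systolic blood pressure, mmHg), ``age`` (years), ``sex`` (binary
    category) and ``medication`` (≤3-level category; an unknown status is its
    own level, not a missing value).
    """

    table: pd.DataFrame

    REQUIRED = ("id", "trait", "age", "sex", "medication")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"phenotype table lacks columns: {missing}")
        ids = self.table["id"].astype(str)
        if ids.duplicated().any():
            raise ValidationError(
                f"duplicate phenotype ids: {ids[ids.duplicated()].tolist()[:5]}"
            )
        med_levels = self.table["medication"].astype(str).nunique()
        if med_levels > 3:
            raise ValidationError(
                f"medication has {med_levels} levels; at most 3 are allowed"
            )
        sex_levels = self.table["sex"].astype(str).nunique()
        if sex_levels > 2:
            raise ValidationError(f"sex has {sex_levels} levels; expected ≤2")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeTable":
        """Return a copy row-ordered to match ``genotypes.subject_ids``.

        Alignment is always by id, never by row order.
        """
        tab = self.table.copy()
        tab.index = tab["id"].astype(str)
        want = [str(s) for s in genotypes.subject_ids]
        absent = [s for s in want if s not in tab.index]
        if absent:
            raise ValidationError(
                f"subjects present in genotypes but absent from phenotypes: {absent[:10]}"
            )
        return PhenotypeTable(tab.loc[want].reset_index(drop=True))


@dataclass
class AdjustedPhenotype:
    """Residual trait after covariate + global-ancestry regression."""

    y: np.ndarray
    r_squared: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)


@dataclass
class Region:
    """One chromosome-contiguous window of SNVs.

    ``start``/``stop`` are a 0-based half-open range into the canonical SNV
    index; ``rare_idx``/``common_idx`` are absolute canonical indices
    partitioning it by MAF.
    """

    chromosome: object
    start: int
    stop: int
    maf: np.ndarray
    rare_idx: np.ndarray
    common_idx: np.ndarray
    pos_first: int
    pos_last: int
    is_partial: bool = False

    @property
    def size(self) -> int:
        return self.stop - self.start

    @property
    def snv_indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class LocalAncestry:
    """Per-subject ancestry cluster labels for one region.

    Labels are anonymous integers in ``1..J`` — a partition, with no identity
    claimed across regions and no mapping to named ancestral populations.
    """

    labels: np.ndarray
    n_clusters: int
    cluster_sizes: np.ndarray
    pc_scores: np.ndarray
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.n_clusters:
            raise ValidationError("ancestry labels must lie in 1..J")
        if int(self.cluster_sizes.sum()) != len(self.labels):
            raise ValidationError("cluster sizes must sum to n_subjects")


@dataclass
class CarrierStructure:
    """Rare-variant carrier sets for one region.

    ``carriers`` is an ``(n_subjects, K)`` boolean matrix; a carrier is a
    subject with dosage ≥ 1 at that variant (a homozygote counts once).
    ``dosages`` retains the 0/1/2 values for the experimental allele-count
    weighting.
    """

    carriers: np.ndarray
    dosages: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.carriers.shape[0]

    @property
    def K(self) -> int:
        return self.carriers.shape[1]

    @property
    def n_i(self) -> np.ndarray:
        """Carrier count per variant."""
        return self.carriers.sum(axis=0)

    def carrier_sets(self) -> list:
        return [np.flatnonzero(self.carriers[:, i]) for i in range(self.K)]


@dataclass
class RegionStatistics:
    """The two summation-partition statistics for one region."""

    I1: float
    IA: float
    per_cluster: np.ndarray  # length-J decomposition of IA


@dataclass
class RegionResult:
    """Scan output for one region: statistics and three permutation p-values."""

    region: Region
    n_rare: int
    I1_obs: float
    IA_obs: float
    global_p_IA: float
    local_p_IA: float
    p_I1: float
    n_permutations: int
    flags: frozenset = field(default_factory=frozenset)
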