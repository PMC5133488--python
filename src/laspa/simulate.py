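"""Synthetic admixed cohorts with known global/local ancestry and trait effects.

The generator emulates the structure the scan is designed for: a recently
admixed cohort (default three ancestral populations, Balding–Nichols
differentiated) in which each subject's genome is a mosaic of region-sized
ancestry blocks, ~80 % of SNVs per region are rare, covariates (age, sex,
3-level medication status) and global ancestry move the trait, and an
optional planted region carries ancestry-specific rare-variant effects.

Allele frequencies: each SNV gets an ancestral frequency — common sites
Uniform(maf_cutoff, 0.5), rare sites a Beta(0.5, 80) truncated to
(1e-4, maf_cutoff), a heavily zero-skewed law calibrated (together with a
2 % inflation of the rare-site share) so the post-admixture *sample* rare
fraction lands on the target — and
per-ancestry frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around it.  Local
ancestry is assigned per region block: each subject draws a diploid ancestry
pair from its Dirichlet admixture proportions once per region, and genotypes
are two Bernoulli draws at the corresponding haplotype frequencies.  Truth
labels record the first haplotype's draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .containers import MISSING, GenotypeMatrix, PhenotypeTable, ValidationError


@dataclass
class CausalRegion:
    """A planted association: per-ancestry effects on rare-variant carriers.

    ``selection`` picks which of the region's rare variants are causal:
    ``"random"`` draws them uniformly (carrier counts then vary a lot between
    replicates, since most rare variants have a handful of carriers);
    ``"most_carried"`` takes the ``n_causal`` rare variants with the most
    carriers, giving a stable, reproducible planted signal for power studies.
    """

    region_index: int
    effects: tuple  # one additive effect per ancestry, applied per carried causal variant
    n_causal: int = 20
    selection: str = "random"


@dataclass
class SimulationConfig:
    """Cohort-generation settings.

    Defaults describe the study conditions the scan targets: a cohort of
    1,851 subjects admixed from three ancestral populations with realistic
    Mexican-American-like admixture (Dirichlet mean ≈ 0.50/0.45/0.05 for the
    European/Native-American/African-like components), per-ancestry
    Balding–Nichols F of 0.10/0.15/0.25, 500-SNV ancestry blocks, an ~80 %
    rare fraction at MAF cutoff 0.05, and covariate + global-ancestry effect
    sizes chosen so the Stage-1 adjustment model explains roughly a quarter
    of the trait variance (systolic-blood-pressure-like scale, mmHg).
    """

    n_subjects: int = 1851
    n_chromosomes: int = 3
    snvs_per_chromosome: int = 2000
    n_ancestries: int = 3
    fst: float | tuple = (0.10, 0.25, 0.15)
    admixture_alpha: tuple | None = None  # default (5.0, 4.5, 0.5) for 3 ancestries
    region_size: int = 500
    target_rare_fraction: float = 0.8
    maf_cutoff: float = 0.05
    # trait model (mmHg scale)
    intercept: float = 118.0
    beta_age: float = 0.4
    beta_sex: float = 3.0
    beta_medication: tuple = (0.0, 5.0, 2.0)  # (none, on, unknown)
    global_ancestry_effect: float = 20.0
    causal_region: CausalRegion | None = None
    noise_sd: float = 14.0
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_rare_fraction < 1.0):
            raise ValidationError("target_rare_fraction must lie strictly in (0, 1)")
        fst = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_ancestries,))
        if ((fst <= 0) | (fst >= 1)).any():
            raise ValidationError(f"fst values must lie in (0, 1): {fst.tolist()}")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValidationError("missing_rate must lie in [0, 1]")
        if self.admixture_alpha is not None and len(self.admixture_alpha) != self.n_ancestries:
            raise ValidationError("admixture_alpha length must equal n_ancestries")
        if self.region_size < 2:
            raise ValidationError("region_size must be ≥ 2")

    @property
    def fst_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_ancestries,)).copy()

    @property
    def alpha(self) -> np.ndarray:
        if self.admixture_alpha is not None:
            return np.asarray(self.admixture_alpha, dtype=float)
        if self.n_ancestries == 3:
            return np.array([5.0, 4.5, 0.5])
        return np.ones(self.n_ancestries)

    @property
    def n_snvs(self) -> int:
        return self.n_chromosomes * self.snvs_per_chromosome

    def region_blocks(self) -> list[tuple[int, int]]:
        """(start, stop) canonical-index ranges matching the scan's partition."""
        blocks = []
        for c in range(self.n_chromosomes):
            lo = c * self.snvs_per_chromosome
            hi = lo + self.snvs_per_chromosome
            for start in range(lo, hi, self.region_size):
                blocks.append((start, min(start + self.region_size, hi)))
        return blocks


@dataclass
class SimulatedTruth:
    """Ground truth emitted alongside a simulated cohort."""

    local_ancestry: np.ndarray  # (n_subjects, n_regions), 0-based ancestry of haplotype 1
    local_ancestry_hap2: np.ndarray
    global_proportions: np.ndarray  # (n_subjects, n_ancestries)
    causal_variant_indices: np.ndarray | None = None
    genetic_effects: np.ndarray | None = None


def simulate_ancestral_freqs(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-ancestry, per-SNV allele frequencies under Balding–Nichols.

    Returns an ``(n_ancestries, n_snvs)`` array.  A ``target_rare_fraction``
    share of sites draws its ancestral frequency from the truncated rare law,
    the rest from Uniform(maf_cutoff, 0.5).
    """
    m = config.n_snvs
    # Balding–Nichols jitter pushes a few ancestrally-rare sites over the MAF
    # cutoff in the admixed sample; a 2 % inflation of the designated rare
    # share compensates, so the realized rare fraction matches the target.
    rare_site = rng.random(m) < min(config.target_rare_fraction * 1.02, 1.0)
    p = np.empty(m)
    p[~rare_site] = rng.uniform(config.maf_cutoff, 0.5, size=int((~rare_site).sum()))
    # truncated Beta(0.5, 80) on (1e-4, maf_cutoff) via inverse-CDF
    a, b = 0.5, 80.0
    lo, hi = beta_dist.cdf(1e-4, a, b), beta_dist.cdf(config.maf_cutoff, a, b)
    u = rng.uniform(lo, hi, size=int(rare_site.sum()))
    p[rare_site] = beta_dist.ppf(u, a, b)

    fst = config.fst_vector
    freqs = np.empty((config.n_ancestries, m))
    for anc in range(config.n_ancestries):
        F = fst[anc]
        shape = (1.0 - F) / F
        freqs[anc] = rng.beta(p * shape, (1.0 - p) * shape)
    return freqs


def _draw_ancestry(proportions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per subject from its own admixture proportions."""
    cum = np.cumsum(proportions, axis=1)
    u = rng.random(proportions.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def simulate_genotypes(
    config: SimulationConfig, freqs: np.ndarray, rng: np.random.Generator
) -> tuple[GenotypeMatrix, SimulatedTruth]:
    """Block-wise admixed genotypes plus ground-truth ancestry."""
    n, m = config.n_subjects, config.n_snvs
    proportions = rng.dirichlet(config.alpha, size=n)
    blocks = config.region_blocks()
    dosages = np.empty((n, m), dtype=np.int8)
    anc1 = np.empty((n, len(blocks)), dtype=np.int64)
    anc2 = np.empty((n, len(blocks)), dtype=np.int64)
    for r, (start, stop) in enumerate(blocks):
        a1 = _draw_ancestry(proportions, rng)
        a2 = _draw_ancestry(proportions, rng)
        anc1[:, r] = a1
        anc2[:, r] = a2
        f1 = freqs[a1][:, start:stop]
        f2 = freqs[a2][:, start:stop]
        dosages[:, start:stop] = rng.binomial(1, f1) + rng.binomial(1, f2)
    if config.missing_rate > 0:
        holes = rng.random(dosages.shape) < config.missing_rate
        dosages[holes] = MISSING

    chrom = np.repeat(
        [f"chr{c + 1}" for c in range(config.n_chromosomes)], config.snvs_per_chromosome
    )
    pos = np.concatenate(
        [
            np.cumsum(rng.integers(200, 3000, size=config.snvs_per_chromosome))
            for _ in range(config.n_chromosomes)
        ]
    )
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "snv_id": [f"snv{i:07d}" for i in range(m)],
        }
    )
    subject_ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    g = GenotypeMatrix(dosages, meta, subject_ids)
    truth = SimulatedTruth(anc1, anc2, proportions)
    return g, truth


def simulate_phenotype(
    config: SimulationConfig,
    g: GenotypeMatrix,
    truth: SimulatedTruth,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Trait + covariates under the configured linear model.

    trait = intercept + β_age·age + β_sex·1[male] + β_med[level]
          + γ·(first admixture proportion) + planted rare-variant effects
          + Normal(0, noise_sd).

    A planted :class:`CausalRegion` adds, for each carried causal rare
    variant, the effect corresponding to the subject's *true* local ancestry
    at that region — ancestry-specific (e.g. opposite-sign) effects are the
    scenario the local-ancestry partition is designed to detect.
    """
    n = g.n_subjects
    age = rng.uniform(20.0, 80.0, size=n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    med_levels = np.array(["none", "on", "unknown"], dtype=object)
    med = med_levels[rng.choice(3, size=n, p=[0.7, 0.2, 0.1])]
    med_effect = np.asarray(config.beta_medication, dtype=float)[
        np.searchsorted(med_levels, med)
    ]

    genetic = np.zeros(n)
    if config.causal_region is not None:
        cr = config.causal_region
        blocks = config.region_blocks()
        if not (0 <= cr.region_index < len(blocks)):
            raise ValidationError(
                f"causal_region index {cr.region_index} out of range (0..{len(blocks) - 1})"
            )
        if len(cr.effects) != config.n_ancestries:
            raise ValidationError("causal_region.effects must have one entry per ancestry")
        start, stop = blocks[cr.region_index]
        block = g.dosages[:, start:stop]
        obs = block != MISSING
        with np.errstate(invalid="ignore"):
            f = np.where(obs, block, 0).sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)
        maf = np.minimum(f, 1.0 - f)
        carriers_any = ((block >= 1) & obs).any(axis=0)
        eligible = np.flatnonzero((maf < config.maf_cutoff) & carriers_any)
        if eligible.size == 0:
            raise ValidationError("causal region has no carried rare variants to plant on")
        if cr.selection == "most_carried":
            n_carriers = ((block[:, eligible] >= 1) & obs[:, eligible]).sum(axis=0)
            chosen = eligible[np.argsort(n_carriers)[::-1][: cr.n_causal]]
        elif cr.selection == "random":
            chosen = rng.choice(eligible, size=min(cr.n_causal, eligible.size), replace=False)
        else:
            raise ValidationError(f"unknown causal-variant selection {cr.selection!r}")
        chosen.sort()
        anc = truth.local_ancestry[:, cr.region_index]
        per_subject_effect = np.asarray(cr.effects, dtype=float)[anc]
        carrier = (block[:, chosen] >= 1) & obs[:, chosen]
        genetic = per_subject_effect * carrier.sum(axis=1)
        truth.causal_variant_indices = start + chosen
    truth.genetic_effects = genetic

    trait = (
        config.intercept
        + config.beta_age * age
        + config.beta_sex * (sex == "M")
        + med_effect
        + config.global_ancestry_effect * truth.global_proportions[:, 0]
        + genetic
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    return PhenotypeTable(
        pd.DataFrame(
            {
                "id": g.subject_ids,
                "trait": trait,
                "age": age,
                "sex": sex,
                "medication": med,
            }
        )
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, SimulatedTruth]:
    """Generate a full (genotypes, phenotypes, truth) cohort from one seed."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_ancestral_freqs(config, rng)
    g, truth = simulate_genotypes(config, freqs, rng)
    pheno = simulate_phenotype(config, g, truth, rng)
    return g, pheno, truth


def write_cohort(
    outdir,
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    truth: SimulatedTruth | None = None,
    prefix: str = "cohort",
) -> dict:
    """Write the cohort in the matrix-TSV dialect (+ truth TSV if given)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / f"{prefix}.geno.tsv",
        "snvs": outdir / f"{prefix}.geno.snvs.tsv",
        "phenotypes": outdir / f"{prefix}.pheno.tsv",
    }
    geno = pd.DataFrame(
        g.dosages, index=g.subject_ids, columns=g.snv_meta["snv_id"].tolist()
    ).replace(MISSING, "NA")
    geno.index.name = "id"
    geno.to_csv(paths["genotypes"], sep="\t")
    g.snv_meta[["snv_id", "chrom", "pos"]].to_csv(paths["snvs"], sep="\t", index=False)
    pheno.table.to_csv(paths["phenotypes"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = outdir / f"{prefix}.truth.tsv"
        t = pd.DataFrame(
            truth.local_ancestry,
            index=g.subject_ids,
            columns=[f"region{r}" for r in range(truth.local_ancestry.shape[1])],
        )
        for a in range(truth.global_proportions.shape[1]):
            t[f"prop{a}"] = truth.global_proportions[:, a]
        t.index.name = "id"
        t.to_csv(paths["truth"], sep="\t")
    return paths
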