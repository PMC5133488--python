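# Methods

`laspa` implements a region-based genome scan for quantitative traits in
recently admixed cohorts. It combines two ideas: *admixture mapping* — the
ancestral origin of a genomic segment may itself be associated with the
trait — and *rare-variant collapsing* — individually uninformative rare
variants can be aggregated over a region into a single test. The scan
proceeds in four stages; this note records the model, the defaults and the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The model and the four stages

**Stage 1 — global adjustment.** The trait (e.g. systolic blood pressure,
mmHg) is regressed by OLS on an intercept, age, a sex indicator, dummy-coded
medication status (three levels: on / not on / unknown, reference = not on),
and the subject scores of the leading principal component(s) of the
genome-wide standardized dosage matrix. PC1 of such a matrix is the usual
one-dimensional summary of global ancestry in an admixed sample. The
residual vector Y is the working phenotype for everything downstream; its
overall mean Ȳ is the centering constant of both statistics. Only PC1 is
used by default; `n_pcs_global` is configurable. The bootstrap stability
diagnostic (resample SNV columns with replacement, recompute scores,
correlate with the full-data scores) supports this choice empirically: on
structured cohorts PC1 scores correlate near 1 across resamples while higher
PCs decorrelate.

**Stage 2 — regions.** SNVs are grouped, in file order and within
chromosome, into consecutive windows of `region_size` (default 500; a
trailing partial window is kept and flagged). Within each window, SNVs with
sample MAF strictly below `maf_cutoff` (default 0.05) form the *rare* set
and the rest the *common* set. A MAF exactly at the cutoff is classed
common, keeping the rare set strictly rare. At the default settings and the
generator's defaults roughly 80 % of a region's SNVs are rare, leaving on
the order of 100 common SNVs for ancestry inference.

**Stage 3 — local ancestry and the statistics.** The common variants of a
region carry its ancestry signal: the subjects' scores on the first
`n_pcs_local` (default 3) principal components of the region's common-variant
matrix are clustered by k-means (default k = 3 for a three-way admixed
population; k-means++ with `n_restarts` = 10, best fit by within-cluster sum
of squares). Labels are an anonymous partition 1..J — no identity is claimed
across regions and no cluster is mapped to a named population. For the
region's K rare variants, with n_i the number of carriers of variant i
(dosage ≥ 1; homozygotes count once) and Ȳ_i their mean working phenotype,

    I1 = Σ_{i=1..K} n_i² (Ȳ_i − Ȳ)²

and, partitioning each carrier set by the ancestry cluster,

    IA = Σ_{j=1..J} Σ_{i=1..K} n_{i,j}² (Ȳ_{i,j} − Ȳ)².

Ȳ is always the overall sample mean, also inside IA — deliberately not the
per-cluster mean, so a cluster whose carriers sit far from the cohort mean
contributes signal. Zero-carrier terms contribute exactly 0. With J = 1 the
two statistics coincide. The partition matters when a variant's carriers
straddle clusters with opposite trait deviations: the marginal mean can
cancel to near Ȳ while the per-cluster means do not, which is precisely the
ancestry-heterogeneous signal the scan is designed to catch.

*Carrier versus allele weighting.* n_i is the carrier count, because the
carrier mean Ȳ_i is a mean over subjects; weighting the squared deviation of
that mean by anything other than the size of the set it is computed over
mixes scales. An `allele` mode (n_i = minor-allele count, carrier means
unchanged) is exposed as an experimental option.

**Stage 4 — permutation p-values.** Three add-one Monte-Carlo p-values per
region, all with carriers and ancestry labels held fixed (ancestry is a
property of the genome, not of the phenotype) and only Y permuted:

* *global* IA p-value — unrestricted permutations of Y: the null is that the
  phenotype is independent of both the region's rare variants and its
  ancestry composition;
* *local* IA p-value — permutations within each ancestry cluster: any
  phenotype–ancestry association is preserved, so only the within-cluster
  rare-variant signal is tested;
* I1 p-value — unrestricted permutations of the marginal statistic.

Each p-value is (1 + #{permuted ≥ observed}) / (B + 1) with B = 10,000 by
default; ties count as exceedances (conservative) and the estimator never
returns 0. Raw p-values are reported; Bonferroni/BH columns are deliberately
not applied by default.

The "global vs local" pairing is one reading of a two-level permutation
scheme (between- vs within-ancestry rearrangement); it is the reading this
package implements and documents, chosen because it gives the two p-values
distinct, well-defined nulls.

## Randomness and determinism

A single master seed drives everything. Imputation, each region's k-means,
and each region's three permutation schemes draw from independent streams
spawned as `SeedSequence(master, spawn_key=(namespace, region, scheme))`, so
results are bit-reproducible and independent of region processing order.
Missing genotypes are imputed per SNV by sampling uniformly from that SNV's
observed dosages (a SNV with no observed genotype is an error).

## Numerical choices

* PCA standardization: per-SNV mean-centering and unit-variance scaling by
  default (the common GWAS convention; makes rare and common SNVs
  commensurate); Patterson's √(p(1−p)) scaling is a config option.
  Monomorphic SNVs are dropped with a logged count.
* The PCA is an exact eigendecomposition of whichever of the Gram
  (subjects × subjects) or scatter (SNVs × SNVs) matrix is smaller,
  accumulated over chunks so a genome-wide dosage matrix is never
  standardized densely in memory. Component signs follow the
  largest-|loading|-positive convention, making scores invariant to SNV
  column order.
* k-means degeneracies: a region with fewer polymorphic common SNVs than
  `n_pcs_local` is flagged `ancestry_unassignable` and falls back to J = 1
  (its local permutation then coincides with the global one); fewer distinct
  score rows than k triggers a logged `cluster_fallback` to the realized
  number of clusters. Realized clusters are relabeled 1..J by first
  occurrence, so labels are deterministic.
* Regions with K = 0 rare variants report NA statistics and p-values with a
  `no_rare_variants` flag and are excluded from plots.
* Permutation statistics are evaluated for whole batches of permuted
  phenotype columns at once via carrier-indicator matrix products; the
  batched values equal per-permutation recomputation to 1e-10 relative
  (tested), and ~500 subjects × ~400 rare variants × 1,000 permutations ×
  3 schemes costs a fraction of a second per region on one core.
* OLS rank problems name the offending design column (constant covariate, or
  QR-pivot-identified collinear columns).

## The synthetic-data generator

The generator produces the structure the scan assumes, with known truth:

* **Frequencies.** Each SNV has an ancestral frequency — common sites
  Uniform(cutoff, 0.5); rare sites Beta(0.5, 80) truncated to (1e-4, cutoff).
  Per-ancestry frequencies are Balding–Nichols draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) with per-ancestry F defaulting to
  (0.10, 0.25, 0.15) — differentiation of the order seen among European,
  African and Native-American-like continental ancestries. Because the
  Balding–Nichols jitter pushes a few ancestrally rare sites above the MAF
  cutoff in the admixed sample, the designated rare share is inflated by 2 %;
  with these two calibrations the realized per-region rare fraction averages
  0.80 at the defaults (the pair (Beta(0.5, 50), no inflation) realizes
  ≈ 0.77).
* **Ancestry.** Subjects draw admixture proportions from a Dirichlet with
  α = (5.0, 4.5, 0.5) — mean ≈ 0.50/0.45/0.05 with realistic between-subject
  spread for a Mexican-American-like cohort. Local ancestry is assigned per
  region block: each subject draws a diploid ancestry pair per region from
  its own proportions, and each haplotype's genotype is a Bernoulli draw at
  that ancestry's frequency. Truth labels record the first haplotype's draw;
  heterozygous-ancestry blocks therefore make the recorded truth itself
  noisy, which is documented behavior, not an error. Block-wise assignment
  matches the analysis window exactly, so method-level tests are clean; it
  does not emulate recombination-scale tract-length variation.
* **Phenotype.** trait = 118 + 0.4·age + 3·1[male] + medication effect
  (0/5/2 mmHg for none/on/unknown, drawn 0.7/0.2/0.1) + 20·(first admixture
  proportion) + planted effects + N(0, 14²), with age ~ Uniform(20, 80) and
  sex ~ Bernoulli(1/2). These sizes put the Stage-1 adjustment model at
  R² ≈ 0.25 of the trait variance at the defaults (age ≈ 48 mmHg² of
  explained variance, ancestry ≈ 9, medication ≈ 4, sex ≈ 2.25, against
  196 mmHg² of noise).
* **Planted effects.** A `CausalRegion` adds, per carried causal rare
  variant, an effect chosen by the subject's true local ancestry at that
  region — opposite-sign effects in two ancestries being the scenario where
  partitioning by ancestry is designed to beat the marginal statistic.
  Causal variants are drawn at random among the region's carried rare
  variants, or deterministically as the most-carried ones
  (`selection="most_carried"`), which stabilizes the planted signal across
  replicates for power studies.
* **Missingness** is masked uniformly at rate 0.01 by default (missing calls
  are uncommon in the intended inputs).

What passing tests on this generator do *not* show: robustness to LD within
regions beyond ancestry-induced correlation, to recombination-scale ancestry
tracts crossing region boundaries, to relatedness/kinship, or to genotyping
artifacts — none of which the generator emulates.

## Problem sizes used in the checks

The statistics are verified against an independent brute-force double-loop
oracle on 1,000 random micro-regions (n ≤ 50, K ≤ 10, J ≤ 3) at 1e-10
relative tolerance. Null calibration uses 500 regions of 500 SNVs at
n = 500 subjects and B = 999 permutations; the planted-effect power study
uses 100 replicates of a six-region cohort (n = 500, B = 999) with
±3 mmHg per-variant opposite-sign effects on the 20 most-carried rare
variants of one region, an effect size chosen by pilot simulation to put the
region-ranking power near or above 0.8 while keeping the IA and I1 p-values
off the permutation floor so their medians remain comparable. Ancestry
recovery uses unadmixed three-population cohorts (ARI against truth at
F = 0.05/0.15/0.3); PC stability uses 100 bootstrap replicates of 1,000
SNVs on a two-population cohort of 200 subjects. `scripts/acceptance.py`
re-runs the same computations at comparable sizes (200 calibration regions,
60 power replicates) from a single seed.

## Known limitations

* The local-ancestry clusters are anonymous; mapping them to named ancestral
  populations (e.g. with reference panels) is out of scope, as are
  HMM/haplotype local-ancestry callers, phasing, kinship adjustment,
  analytic null distributions, gene-based region definitions, and
  multi-allelic sites (rejected at parse time).
* With B permutations the smallest attainable p-value is 1/(B+1); regions at
  the floor cannot be ranked further apart.
* Very sparse regions (few carried rare variants) carry little information
  and large between-replicate variance; the statistics are exact but weak
  there.
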