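"""Reading genotype/phenotype inputs, missing-genotype imputation, results I/O.

Two genotype dialects are supported:

* VCF (v4.x, GT field only, biallelic sites).  Dosage is the count of the
  *minor* allele, the allele with sample frequency ≤ 0.5 at that site (ties
  break to ALT).
* A plain matrix TSV: rows = subjects, columns = SNVs, first column = subject
  id, header row = SNV ids, entries 0/1/2 (allele coded "1") or ``NA``/``.``
  for missing — plus a companion SNV-metadata TSV with columns
  ``snv_id``, ``chrom``, ``pos``.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PhenotypeTable, RegionResult, ValidationError

RESULT_COLUMNS = [
    "chromosome",
    "pos_first",
    "pos_last",
    "n_rare",
    "global_p_IA",
    "local_p_IA",
    "p_I1",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed under its declared format."""


def _orient_minor(dosages: np.ndarray) -> np.ndarray:
    """Flip each SNV so dosage counts the minor allele (freq ≤ 0.5, tie kept)."""
    d = dosages.astype(np.int8, copy=True)
    obs = d != MISSING
    with np.errstate(invalid="ignore"):
        n_obs = obs.sum(axis=0)
        alt_sum = np.where(obs, d, 0).sum(axis=0)
    freq = np.divide(alt_sum, 2.0 * n_obs, out=np.zeros(d.shape[1]), where=n_obs > 0)
    flip = freq > 0.5  # strict: a tie keeps the ALT / "1"-coded allele
    if flip.any():
        cols = d[:, flip]
        cols = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        d[:, flip] = cols
    return d


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic VCF into a minor-allele dosage matrix.

    Multi-allelic records are rejected (no decomposition is attempted); a
    half-called or fully missing GT becomes the missing sentinel.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc
    subjects = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ValidationError(
                f"{path}: record {var.CHROM}:{var.POS} is not biallelic "
                f"(ALT={var.ALT}); multi-allelic sites are rejected"
            )
        alts = np.zeros(len(subjects), dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            a = gt[:-1]  # last element is the phase flag
            if len(a) != 2 or min(a) < 0:
                alts[s] = MISSING
            else:
                alts[s] = int(a[0] != 0) + int(a[1] != 0)
        rows.append(alts)
        meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}"))
    if not rows:
        raise ParseError(f"{path}: VCF contains no records")
    dosages = _orient_minor(np.stack(rows, axis=1))
    snv_meta = pd.DataFrame(meta, columns=["chrom", "pos", "snv_id"])
    return GenotypeMatrix(dosages, snv_meta, np.asarray(subjects, dtype=object))


def default_meta_path(genotype_path: str | os.PathLike) -> Path:
    """Sidecar SNV-metadata path for a matrix TSV: ``<stem>.snvs.tsv``."""
    p = Path(genotype_path)
    return p.with_name(p.stem + ".snvs.tsv")


def read_matrix_tsv(
    path: str | os.PathLike, meta_path: str | os.PathLike | None = None
) -> GenotypeMatrix:
    """Read the matrix-TSV dialect (see module docstring)."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else default_meta_path(path)
    try:
        tab = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    raw = tab.replace({"NA": str(MISSING), ".": str(MISSING), "": str(MISSING)})
    try:
        dosages = raw.to_numpy(dtype=np.int8)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer dosage entry ({exc})") from exc
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    if "snv_id" not in meta.columns:
        raise ParseError(f"{meta_path}: metadata requires an 'snv_id' column")
    meta = meta.set_index("snv_id").loc[[str(c) for c in tab.columns]].reset_index()
    dosages = _orient_minor(dosages)
    return GenotypeMatrix(
        dosages,
        meta[["chrom", "pos", "snv_id"]],
        tab.index.to_numpy(dtype=object),
    )


def read_genotypes(
    path: str | os.PathLike,
    format: str = "vcf",
    meta_path: str | os.PathLike | None = None,
) -> GenotypeMatrix:
    """Read genotypes from ``vcf`` or ``matrix_tsv`` input."""
    if format == "vcf":
        return read_vcf(path)
    if format == "matrix_tsv":
        return read_matrix_tsv(path, meta_path)
    raise ValueError(f"unknown genotype format {format!r}; use 'vcf' or 'matrix_tsv'")


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read a tab- or comma-delimited phenotype/covariate table.

    Requires header columns ``id``, ``trait``, ``age``, ``sex``,
    ``medication`` (case-insensitive).
    """
    try:
        tab = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    tab.columns = [str(c).strip().lower() for c in tab.columns]
    return PhenotypeTable(tab)


def impute_missing(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Impute missing dosages by sampling uniformly from the SNV's observed ones.

    Each missing entry at SNV *i* is replaced by a uniform draw from the
    multiset of non-missing dosages observed at SNV *i*; non-missing entries
    are untouched.  Deterministic given ``seed``; a fully observed matrix is
    returned unchanged (same object).
    """
    if not g.has_missing:
        return g
    rng = np.random.default_rng(seed)
    d = g.dosages.copy()
    miss_cols = np.flatnonzero((d == MISSING).any(axis=0))
    for j in miss_cols:
        col = d[:, j]
        observed = col[col != MISSING]
        if observed.size == 0:
            snv = g.snv_meta.iloc[j]
            raise ValidationError(
                f"SNV {snv.get('snv_id', j)} ({snv['chrom']}:{snv['pos']}) "
                "has no observed genotypes to impute from"
            )
        holes = col == MISSING
        col[holes] = rng.choice(observed, size=int(holes.sum()), replace=True)
        d[:, j] = col
    return GenotypeMatrix(d, g.snv_meta, g.subject_ids)


def results_frame(results: list[RegionResult]) -> pd.DataFrame:
    """Tabulate scan results, one row per region."""
    rows = []
    for r in results:
        rows.append(
            {
                "chromosome": r.region.chromosome,
                "pos_first": r.region.pos_first,
                "pos_last": r.region.pos_last,
                "n_rare": r.n_rare,
                "global_p_IA": r.global_p_IA,
                "local_p_IA": r.local_p_IA,
                "p_I1": r.p_I1,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def add_multiple_testing(df: pd.DataFrame) -> pd.DataFrame:
    """Append Bonferroni and Benjamini–Hochberg columns for each p-value series.

    NA p-values (flagged regions) are excluded from the correction and stay NA.
    """
    from scipy.stats import false_discovery_control

    df = df.copy()
    for c in ("global_p_IA", "local_p_IA", "p_I1"):
        p = df[c].to_numpy(dtype=float)
        ok = np.isfinite(p)
        bonf = np.full_like(p, np.nan)
        bh = np.full_like(p, np.nan)
        if ok.any():
            bonf[ok] = np.minimum(p[ok] * int(ok.sum()), 1.0)
            bh[ok] = false_discovery_control(p[ok], method="bh")
        df[f"{c}_bonferroni"] = bonf
        df[f"{c}_bh"] = bh
    return df


def write_results(
    results: list[RegionResult], path: str | os.PathLike, multiple_testing: bool = False
) -> None:
    """Write the result table as TSV (p-values at 6 significant digits).

    Raw p-values are the default, as region screens are usually ranked;
    ``multiple_testing=True`` appends Bonferroni/BH-adjusted columns.
    """
    if not results:
        raise ValidationError("cannot write an empty result list")
    df = results_frame(results)
    if multiple_testing:
        df = add_multiple_testing(df)
    for c in df.columns:
        if c.endswith(("p_IA", "p_I1", "bonferroni", "_bh")):
            df[c] = df[c].map(lambda v: "NA" if _isna(v) else f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chromosome": str})


def _isna(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))
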