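"""Stage 1: residualize the trait on covariates and global-ancestry PC scores.

The adjusted phenotype Y is the vector of OLS residuals from regressing the
trait on an intercept, age, a sex indicator, dummy-coded medication status
(reference = not-on-medication) and the leading global PC score(s).  Y is what
all downstream region statistics see; its sample mean Ȳ is the centering
constant of both summation-partition statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator

from .containers import AdjustedPhenotype, PhenotypeTable, ValidationError

# medication labels recognized as the "not on medication" reference level
_REFERENCE_MED = {"none", "not-on", "not_on", "no", "off", "0", "false"}


def build_design(pheno: PhenotypeTable, pc_scores: np.ndarray) -> pd.DataFrame:
    """Covariate design matrix: intercept, age, sex, medication dummies, PCs."""
    tab = pheno.table
    n = len(tab)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    cols["age"] = tab["age"].to_numpy(dtype=float)

    sex = tab["sex"].astype(str)
    sex_levels = sorted(sex.unique())
    if len(sex_levels) == 2:
        cols[f"sex[{sex_levels[1]}]"] = (sex == sex_levels[1]).to_numpy(dtype=float)
    # a single observed sex level carries no information: omitted (constant)

    med = tab["medication"].astype(str)
    levels = sorted(med.unique())
    ref = next((l for l in levels if l.lower() in _REFERENCE_MED), levels[0])
    for lev in levels:
        if lev != ref:
            cols[f"medication[{lev}]"] = (med == lev).to_numpy(dtype=float)

    pc = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if pc.shape[0] != n:
        pc = pc.T
    if pc.shape[0] != n:
        raise ValidationError("pc_scores are not aligned with the phenotype table")
    for k in range(pc.shape[1]):
        cols[f"PC{k + 1}"] = pc[:, k]
    return pd.DataFrame(cols)


class TraitAdjuster(BaseEstimator):
    """OLS covariate adjustment exposing residuals as the working phenotype.

    Fitted attributes
    -----------------
    coef_ : per-column regression coefficients
    residuals_ : the adjusted phenotype Y
    r_squared_ : fraction of trait variance explained by the adjustment model
    design_columns_ : names of the design columns actually used
    """

    def fit(self, pheno: PhenotypeTable, pc_scores: np.ndarray) -> "TraitAdjuster":
        design = build_design(pheno, pc_scores)
        X = design.to_numpy(dtype=float)
        y = pheno.table["trait"].to_numpy(dtype=float)
        self._check_rank(design, X)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        resid = y - fitted
        sst = float(((y - y.mean()) ** 2).sum())
        ssr = float((resid**2).sum())
        self.coef_ = coef
        self.design_columns_ = list(design.columns)
        self.residuals_ = resid
        self.r_squared_ = 1.0 - ssr / sst if sst > 0 else 0.0
        return self

    def adjusted(self) -> AdjustedPhenotype:
        return AdjustedPhenotype(self.residuals_, self.r_squared_)

    @staticmethod
    def _check_rank(design: pd.DataFrame, X: np.ndarray) -> None:
        for name in design.columns:
            if name != "intercept" and design[name].nunique() == 1:
                raise ValidationError(f"covariate column {name!r} is constant")
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            bad = [design.columns[j] for j in piv[rank:]]
            raise ValidationError(f"design matrix is rank-deficient; dependent columns: {bad}")


def adjust_phenotype(pheno: PhenotypeTable, pc_scores: np.ndarray) -> AdjustedPhenotype:
    """Residualize the trait on covariates + global PC score(s)."""
    return TraitAdjuster().fit(pheno, pc_scores).adjusted()
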