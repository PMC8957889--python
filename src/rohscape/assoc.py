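"""Allele frequencies, derived-allele orientation, and SNP association.

The association model is the single-SNP additive linear model

    y = mu + beta * dosage + gamma_age * age + batch effects + e

with the genotype coded 0/1/2 as copies of a designated *effect allele*
(``allele2`` by default; for a derived/ancestral design, count the derived
allele).  Batch is dummy-encoded by default; a numeric-covariates
compatibility mode treats every covariate as a single numeric column, as
some genotype-analysis tools do.  Fitting is ordinary least squares
(complete cases only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import MISSING, GenotypeMatrix


@dataclass
class AssocResult:
    marker_id: str
    trait: str
    n_used: int
    beta: float
    se: float
    t_stat: float
    p_two_sided: float
    effect_allele: str
    genotype_means: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "marker_id": self.marker_id,
            "trait": self.trait,
            "n_used": self.n_used,
            "beta": self.beta,
            "se": self.se,
            "t_stat": self.t_stat,
            "p_two_sided": self.p_two_sided,
            "effect_allele": self.effect_allele,
        }
        for code in (0, 1, 2):
            d[f"mean_geno{code}"] = self.genotype_means.get(code, np.nan)
        return pd.DataFrame([d])


def allele_freq(
    matrix: GenotypeMatrix,
    by_population: bool = True,
    derived_allele: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-marker allele2 frequency, optionally per population.

    ``derived_allele`` maps marker_id to the allele label designated derived
    (from an outgroup comparison); when given, a ``daf`` column reports the
    derived-allele frequency.  Markers with no calls in a stratum report NaN.
    """
    groups = (
        matrix.by_population().items() if by_population else [("all", matrix)]
    )
    frames = []
    for pop, sub in groups:
        freq = sub.allele2_freq()
        nm = (sub.calls != MISSING).sum(axis=0)
        frame = sub.markers[["marker_id", "chrom", "pos_bp", "allele1", "allele2"]].copy()
        frame["population"] = pop
        frame["n_nonmissing"] = nm
        frame["freq_allele2"] = freq
        if derived_allele is not None:
            des = frame["marker_id"].map(derived_allele)
            daf = np.where(
                des == frame["allele2"],
                freq,
                np.where(des == frame["allele1"], 1.0 - freq, np.nan),
            )
            frame["derived_allele"] = des
            frame["daf"] = daf
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending column."""


def linear_assoc(
    matrix: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    marker_id: str,
    covariates: Sequence[str] = ("age", "batch"),
    *,
    trait: str = "trait",
    effect_allele: str = "allele2",
    numeric_covariates: bool = False,
) -> AssocResult:
    """OLS of a trait on the additive dosage of one SNP plus covariates.

    Samples missing the genotype, trait, or any covariate are dropped
    (complete-case).  ``effect_allele`` selects which allele the 0/1/2 code
    counts; flipping it flips beta's sign only.  ``numeric_covariates=True``
    treats categorical covariates (batch) as numeric codes instead of
    dummies, reproducing the behavior of numeric-only association tools.
    """
    hits = np.flatnonzero((matrix.markers["marker_id"] == marker_id).to_numpy())
    if hits.size == 0:
        raise KeyError(f"marker {marker_id!r} not in matrix")
    j = int(hits[0])
    if effect_allele not in ("allele1", "allele2"):
        raise ValueError("effect_allele must be 'allele1' or 'allele2'")
    code = matrix.calls[:, j].astype(float)
    code[code == MISSING] = np.nan
    if effect_allele == "allele1":
        code = 2.0 - code

    data = pd.DataFrame(
        {"sample_id": matrix.sample_ids.astype(str), "dosage": code}
    ).merge(phenotypes.astype({"sample_id": str}), on="sample_id", how="inner")
    need = ["dosage", trait, *covariates]
    data = data.dropna(subset=[c for c in need if c in data.columns])
    missing_cols = [c for c in need if c not in data.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks columns {missing_cols}")

    y = data[trait].astype(float).to_numpy()
    design = pd.DataFrame({"dosage": data["dosage"].to_numpy()})
    for cov in covariates:
        col = data[cov]
        if numeric_covariates or pd.api.types.is_numeric_dtype(col):
            design[cov] = pd.to_numeric(col).to_numpy()
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                design[dcol] = dummies[dcol].to_numpy()
    X = sm.add_constant(design, has_constant="add")
    if len(data) < X.shape[1] + 1:
        raise ValueError(
            f"only {len(data)} complete cases for {X.shape[1]} design columns"
        )
    for col in X.columns:
        if col != "const" and np.std(X[col].to_numpy()) == 0:
            raise CollinearityError(f"design column {col!r} is constant")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns (collinear covariates)"
        )

    fit = sm.OLS(y, X).fit()
    geno_means = {
        int(g): float(data.loc[data["dosage"] == g, trait].mean())
        for g in (0, 1, 2)
        if (data["dosage"] == g).any()
    }
    allele = matrix.markers[effect_allele].iat[j]
    return AssocResult(
        marker_id=marker_id,
        trait=trait,
        n_used=int(fit.nobs),
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        t_stat=float(fit.tvalues["dosage"]),
        p_two_sided=float(fit.pvalues["dosage"]),
        effect_allele=str(allele),
        genotype_means=geno_means,
    )


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values (for multi-SNP runs)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)
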