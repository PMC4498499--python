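"""Dosage transforms, SNP QC, and sex-stratified trait residualization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genio import GenotypeMatrix


class ZeroVarianceError(ValueError):
    """Raised when a trait has no residual variance within a stratum."""


def compute_dosage(probs) -> np.ndarray | float:
    """Expected allele-B count: 0*P_AA + 1*P_AB + 2*P_BB.

    `probs` is a length-3 triple or an (..., 3) array; triples must be
    non-negative and sum to 1 within 1e-6.
    """
    arr = np.asarray(probs, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("genotype probabilities must have 3 components")
    if (arr < 0).any():
        raise ValueError("negative genotype probability")
    sums = arr.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("genotype probabilities must sum to 1 within 1e-6")
    dose = arr[..., 1] + 2.0 * arr[..., 2]
    return float(dose) if dose.ndim == 0 else dose


def flip_effect_allele(dosage):
    """Swap the counted allele: d -> 2 - d (an involution on [0, 2])."""
    arr = np.asarray(dosage, dtype=float)
    with np.errstate(invalid="ignore"):
        if ((arr < 0) | (arr > 2)).any():
            raise ValueError("dosage outside [0, 2]")
    out = 2.0 - arr
    return float(out) if out.ndim == 0 else out


def hwe_chi2_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square HWE test on hard-call genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return np.nan
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = expected > 0
    stat = ((observed[nz] - expected[nz]) ** 2 / expected[nz]).sum()
    return float(chi2.sf(stat, df=1))


def qc_filter_snps(
    gm: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Drop SNPs failing MAF >= maf_min or HWE p > hwe_p_min.

    Soft dosages are rounded to hard calls for the HWE test only.  Returns
    the filtered matrix and a {snp_id: reason} map for dropped SNPs.
    """
    reasons: dict[str, str] = {}
    maf = gm.maf()
    keep = []
    for j, snp in enumerate(gm.snp_ids):
        col = gm.dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            reasons[snp] = "all_missing"
            continue
        if not (maf[j] >= maf_min):
            reasons[snp] = "maf"
            continue
        hard = np.round(obs).astype(int)
        pval = hwe_chi2_pvalue(
            int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())
        )
        if not (pval > hwe_p_min):
            reasons[snp] = "hwe"
            continue
        keep.append(snp)
    if not keep:
        import warnings

        warnings.warn("qc_filter_snps removed every SNP")
    return gm.subset_snps(keep), reasons


@dataclass
class ResidualizedTrait:
    """Standardized sex-stratified residuals of a single trait."""

    values: pd.Series  # aligned to input index; NaN = missing or excluded
    strata: pd.Series
    n_excluded_outliers: int


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd < 1e-12:
        raise ZeroVarianceError("zero-variance residuals within stratum")
    return (x - x.mean()) / sd


def prepare_trait(
    trait: pd.Series,
    sex: pd.Series,
    covariates: pd.DataFrame | None,
    mode: str = "exclude",
    log_transform: bool = False,
) -> ResidualizedTrait:
    """Residualize a trait on covariates within each sex stratum.

    Steps per stratum: optional natural-log transform, OLS residuals on an
    intercept plus the covariate columns, then outlier handling —
    mode="exclude" drops |z| > 4 values and re-standardizes, mode="winsorize"
    clamps residuals to mean +/- 4 SD before standardizing.  Output residuals
    have mean 0 and unit SD within each stratum; samples with missing trait
    or covariates stay missing.
    """
    if mode not in ("exclude", "winsorize"):
        raise ValueError("mode must be 'exclude' or 'winsorize'")
    trait = pd.Series(trait, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=trait.index)
    covariates = covariates.astype(float)

    out = pd.Series(np.nan, index=trait.index)
    n_excluded = 0
    usable = trait.notna() & sex.notna() & covariates.notna().all(axis=1)
    for level in sorted(pd.unique(sex.dropna())):
        idx = usable & (sex == level)
        y = trait[idx].to_numpy()
        if log_transform:
            if (y <= 0).any():
                raise ValueError("log transform requires strictly positive values")
            y = np.log(y)
        X = np.column_stack([np.ones(idx.sum()), covariates.loc[idx].to_numpy()])
        if len(y) < X.shape[1] + 2:
            raise ValueError(f"stratum {level!r} too small for covariate set")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            raise ZeroVarianceError("zero-variance residuals within stratum")
        if mode == "exclude":
            z = (resid - resid.mean()) / sd
            keep = np.abs(z) <= 4.0
            n_excluded += int((~keep).sum())
            sub_index = trait.index[idx][keep]
            out.loc[sub_index] = _standardize(resid[keep])
        else:
            clamped = np.clip(resid, resid.mean() - 4 * sd, resid.mean() + 4 * sd)
            out.loc[trait.index[idx]] = _standardize(clamped)
    return ResidualizedTrait(values=out, strata=sex.copy(), n_excluded_outliers=n_excluded)


def biomarker_covariates(pheno: pd.DataFrame, include_time: bool = True) -> pd.DataFrame:
    """Age, squared age, and (optionally) time-of-sampling dummy columns.

    Time of sampling enters as two indicators against the first category.
    """
    cov = pd.DataFrame(index=pheno.index)
    cov["age"] = pheno["age"]
    cov["age_squared"] = (
        pheno["age_squared"] if "age_squared" in pheno.columns else pheno["age"] ** 2
    )
    if include_time:
        tos = pheno["time_of_sampling"]
        cov["tos_2"] = (tos == 2).astype(float).where(tos.notna())
        cov["tos_3"] = (tos == 3).astype(float).where(tos.notna())
    return cov


def prepare_phenotypes(
    pheno: pd.DataFrame,
    biomarkers: tuple[str, ...],
    outcomes: tuple[str, ...] = (),
    mode: str = "winsorize",
    log_traits: tuple[str, ...] = (),
    time_for_biomarkers: bool = True,
) -> pd.DataFrame:
    """Residualize a set of traits; biomarkers also adjust for sampling time.

    Returns a table of standardized residuals (one column per trait) aligned
    to `pheno`'s index.
    """
    out = pd.DataFrame(index=pheno.index)
    cov_bio = biomarker_covariates(pheno, include_time=time_for_biomarkers)
    cov_out = biomarker_covariates(pheno, include_time=False)
    for trait in biomarkers:
        rt = prepare_trait(
            pheno[trait], pheno["sex"], cov_bio, mode=mode, log_transform=trait in log_traits
        )
        out[trait] = rt.values
    for trait in outcomes:
        rt = prepare_trait(pheno[trait], pheno["sex"], cov_out, mode=mode)
        out[trait] = rt.values
    return out
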