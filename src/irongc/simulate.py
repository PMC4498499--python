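"""Synthetic genotype/phenotype generator with known variance-component truth.

Genotypes are unlinked biallelic SNPs in Hardy-Weinberg proportions; an
optional block of full-sibling pairs is built from explicit parental gametes
so that expected genomic relationships are correct.  Multi-trait phenotypes
are the sum of causal-SNP genetic values (effects drawn multivariate-normal
across traits on the standardized-genotype scale), multivariate-normal
residuals, fixed SNP effects on the dosage scale, and covariate effects.
Binary traits are produced by thresholding a standardized liability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genio import GenotypeMatrix

#: default proportions for the three time-of-sampling categories
TIME_OF_SAMPLING_PROPS = (0.21, 0.64, 0.15)

LIPID_COLUMNS = ("TC", "LDL", "HDL", "TGC")

#: trait roster used by the cohort-style convenience configuration
NBS_TRAITS = (
    "hepcidin",
    "ferritin",
    "hepcidin_ferritin_ratio",
    "hepcidin_TS_ratio",
    "iron",
    "TIBC",
    "TS",
    "plaque",
    "IMT",
    "ABI_rest",
    "ABI_exercise",
)


@dataclass
class SimulationConfig:
    n_samples: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 1
    genetic_cov: np.ndarray | None = None
    residual_cov: np.ndarray | None = None
    causal_fraction: float = 1.0
    fixed_effects: list[tuple[str, int, float]] = field(default_factory=list)
    binary_traits: list[tuple[int, float]] = field(default_factory=list)
    n_sib_pairs: int = 0
    outcome_subset_fraction: float = 1.0
    outcome_traits: tuple[int, ...] | None = None
    trait_names: tuple[str, ...] | None = None
    covariate_effects: dict | None = None
    add_lipids: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_snps < 1:
            raise ValueError("non-positive simulation dimensions")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in (0, 1]")
        if 2 * self.n_sib_pairs > self.n_samples:
            raise ValueError("more sib-pair samples than n_samples")
        if self.genetic_cov is None:
            self.genetic_cov = 0.5 * np.eye(self.n_traits)
        if self.residual_cov is None:
            self.residual_cov = 0.5 * np.eye(self.n_traits)
        self.genetic_cov = np.asarray(self.genetic_cov, dtype=float)
        self.residual_cov = np.asarray(self.residual_cov, dtype=float)
        for name, mat in (("genetic_cov", self.genetic_cov), ("residual_cov", self.residual_cov)):
            if mat.shape != (self.n_traits, self.n_traits):
                raise ValueError(f"{name} does not conform to n_traits")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} is not symmetric")
            if np.linalg.eigvalsh(mat).min() < -1e-8:
                raise ValueError(f"{name} is not positive semidefinite")
        total = np.diag(self.genetic_cov) + np.diag(self.residual_cov)
        if (total <= 0).any():
            raise ValueError("per-trait genetic + residual variance must be > 0")
        for t, prev in self.binary_traits:
            if not (0.0 < prev < 1.0):
                raise ValueError("prevalence must lie in (0, 1)")
            if not (0 <= t < self.n_traits):
                raise ValueError("binary trait index out of range")
        if not (0.0 < self.outcome_subset_fraction <= 1.0):
            raise ValueError("outcome_subset_fraction must lie in (0, 1]")
        if self.trait_names is None:
            self.trait_names = tuple(f"trait_{t + 1}" for t in range(self.n_traits))
        if len(self.trait_names) != self.n_traits:
            raise ValueError("trait_names does not conform to n_traits")
        if self.outcome_traits is None:
            self.outcome_traits = tuple(t for t, _ in self.binary_traits)
        if self.covariate_effects is None:
            # nonzero age/sex defaults so residualization matters downstream
            self.covariate_effects = {"age": 0.2, "sex": 0.5, "time": (0.0, 0.1, 0.2)}

    def implied_rg(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.genetic_cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            rg = self.genetic_cov / np.outer(d, d)
        return rg

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "n_snps": self.n_snps,
            "maf_range": list(self.maf_range),
            "n_traits": self.n_traits,
            "genetic_cov": self.genetic_cov.tolist(),
            "residual_cov": self.residual_cov.tolist(),
            "causal_fraction": self.causal_fraction,
            "fixed_effects": [list(fx) for fx in self.fixed_effects],
            "binary_traits": [list(bt) for bt in self.binary_traits],
            "n_sib_pairs": self.n_sib_pairs,
            "outcome_subset_fraction": self.outcome_subset_fraction,
            "outcome_traits": list(self.outcome_traits),
            "trait_names": list(self.trait_names),
            "covariate_effects": {
                k: (list(v) if isinstance(v, (list, tuple)) else v)
                for k, v in self.covariate_effects.items()
            },
            "add_lipids": self.add_lipids,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["maf_range"] = tuple(payload["maf_range"])
        payload["fixed_effects"] = [tuple(fx) for fx in payload.get("fixed_effects", [])]
        payload["binary_traits"] = [tuple(bt) for bt in payload.get("binary_traits", [])]
        for key in ("outcome_traits", "trait_names"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        payload["genetic_cov"] = np.asarray(payload["genetic_cov"])
        payload["residual_cov"] = np.asarray(payload["residual_cov"])
        return cls(**payload)


@dataclass
class SimulationTruth:
    """Ground truth recorded next to a simulated phenotype table."""

    true_genetic_cov: np.ndarray
    true_residual_cov: np.ndarray
    true_rg: np.ndarray
    causal_snp_ids: np.ndarray
    snp_effects: np.ndarray  # causal SNPs x traits, standardized-genotype scale
    genetic_values: np.ndarray  # samples x traits
    liability_thresholds: dict

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "true_genetic_cov": self.true_genetic_cov.tolist(),
            "true_residual_cov": self.true_residual_cov.tolist(),
            "true_rg": self.true_rg.tolist(),
            "causal_snp_ids": [str(s) for s in self.causal_snp_ids],
            "snp_effects": self.snp_effects.tolist(),
            "liability_thresholds": {int(k): float(v) for k, v in self.liability_thresholds.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload))


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """MVN draws that tolerate singular covariance matrices."""
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((size, cov.shape[0])) @ factor.T


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes; the last 2*n_sib_pairs samples form sibling pairs.

    Each sibling inherits one allele per SNP from each of two shared parents,
    so the expected genomic relationship between sibs is 0.5.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, m, k = config.n_samples, config.n_snps, config.n_sib_pairs
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)

    n_unrel = n - 2 * k
    geno = np.empty((n, m), dtype=np.float64)
    geno[:n_unrel] = rng.binomial(2, p, size=(n_unrel, m))
    if k:
        mother = rng.binomial(2, p, size=(k, m)).astype(float)
        father = rng.binomial(2, p, size=(k, m)).astype(float)
        for s in range(2):
            child = rng.binomial(1, mother / 2.0) + rng.binomial(1, father / 2.0)
            geno[n_unrel + s * k : n_unrel + (s + 1) * k] = child
    # sib pairs are (n_unrel + i, n_unrel + k + i) for i in range(k)

    return GenotypeMatrix(
        sample_ids=np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp_{j + 1}" for j in range(m)], dtype=object),
        dosages=geno,
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        allele_a=np.array(["A"] * m, dtype=object),
        allele_b=np.array(["B"] * m, dtype=object),
    )


def sib_pair_indices(config: SimulationConfig) -> list[tuple[int, int]]:
    n_unrel = config.n_samples - 2 * config.n_sib_pairs
    return [(n_unrel + i, n_unrel + config.n_sib_pairs + i) for i in range(config.n_sib_pairs)]


def simulate_genotype_probabilities(genotypes: np.ndarray, certainty: float) -> np.ndarray:
    """Expand hard genotypes into (P_AA, P_AB, P_BB) triples.

    Mass `certainty` sits on the true genotype; the remainder is split evenly
    over the other two classes.
    """
    if not (1.0 / 3.0 < certainty <= 1.0):
        raise ValueError("certainty must lie in (1/3, 1]")
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be hard calls in {0,1,2}")
    rest = (1.0 - certainty) / 2.0
    probs = np.full(g.shape + (3,), rest)
    idx = np.indices(g.shape)
    probs[(*idx, g.astype(int))] = certainty
    return probs


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Build the phenotype+covariate table and its ground truth.

    Causal effects are drawn per SNP from N(0, genetic_cov / n_causal) on the
    standardized-genotype scale, so trait-pair genetic covariances equal
    genetic_cov in expectation regardless of the MAF spectrum.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, m, T = genotypes.n_samples, genotypes.n_snps, config.n_traits

    # --- genetic values on the standardized-genotype scale
    p = genotypes.allele_b_freq()
    poly = (p > 0) & (p < 1)
    poly_idx = np.flatnonzero(poly)
    n_causal = max(1, int(round(config.causal_fraction * len(poly_idx))))
    causal = np.sort(rng.choice(poly_idx, size=n_causal, replace=False))
    W = (genotypes.dosages[:, causal] - 2 * p[causal]) / np.sqrt(
        2 * p[causal] * (1 - p[causal])
    )
    effects = _mvn(rng, config.genetic_cov / n_causal, n_causal)
    g = W @ effects

    e = _mvn(rng, config.residual_cov, n)
    y = g + e

    # --- fixed SNP effects on the effect-allele dosage scale
    snp_pos = {s: j for j, s in enumerate(genotypes.snp_ids)}
    for snp_id, trait, beta in config.fixed_effects:
        y[:, trait] += beta * genotypes.dosages[:, snp_pos[snp_id]]

    # --- covariates
    age = rng.uniform(42.0, 76.0, size=n)
    sex = rng.integers(1, 3, size=n)  # 1 = men, 2 = women
    props = np.asarray(TIME_OF_SAMPLING_PROPS) / sum(TIME_OF_SAMPLING_PROPS)
    time_cat = rng.choice([1, 2, 3], size=n, p=props)
    eff = config.covariate_effects
    t_eff = np.asarray(eff.get("time", (0.0, 0.0, 0.0)))
    cov_shift = (
        eff.get("age", 0.0) * (age - 59.0) / 10.0
        + eff.get("sex", 0.0) * (sex - 1)
        + t_eff[time_cat - 1]
    )
    y += cov_shift[:, None]

    # --- binary traits via liability thresholding
    from scipy.stats import norm

    thresholds: dict = {}
    for t, prev in config.binary_traits:
        liab = (y[:, t] - y[:, t].mean()) / y[:, t].std()
        thr = norm.ppf(1.0 - prev)
        thresholds[t] = thr
        y[:, t] = (liab > thr).astype(float)

    pheno = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "age_squared": age**2,
            "time_of_sampling": time_cat,
        },
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )
    for t, name in enumerate(config.trait_names):
        pheno[name] = y[:, t]

    # --- outcome traits observed only on a random subset
    if config.outcome_traits and config.outcome_subset_fraction < 1.0:
        n_sub = int(round(config.outcome_subset_fraction * n))
        keep = rng.choice(n, size=n_sub, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[keep] = False
        for t in config.outcome_traits:
            pheno.loc[mask, config.trait_names[t]] = np.nan

    if config.add_lipids:
        for col in LIPID_COLUMNS:
            pheno[col] = rng.standard_normal(n)

    truth = SimulationTruth(
        true_genetic_cov=config.genetic_cov.copy(),
        true_residual_cov=config.residual_cov.copy(),
        true_rg=config.implied_rg(),
        causal_snp_ids=genotypes.snp_ids[causal],
        snp_effects=effects,
        genetic_values=g,
        liability_thresholds=thresholds,
    )
    return pheno, truth


def nbs_like_config(
    n_samples: int = 1819,
    n_snps: int = 5000,
    outcome_subset_fraction: float = 549 / 1819,
    seed: int = 0,
    h2: float = 0.3,
    rg: float = 0.0,
    **overrides,
) -> SimulationConfig:
    """Cohort-style configuration: 7 biomarkers + 4 outcome traits.

    All traits share heritability `h2` and pairwise genetic correlation `rg`;
    plaque is binary with prevalence 0.42 and the four outcome traits are
    observed only on a subsample.
    """
    T = len(NBS_TRAITS)
    gcov = h2 * (rg * np.ones((T, T)) + (1 - rg) * np.eye(T))
    rcov = (1 - h2) * np.eye(T)
    kwargs = dict(
        n_samples=n_samples,
        n_snps=n_snps,
        n_traits=T,
        genetic_cov=gcov,
        residual_cov=rcov,
        causal_fraction=0.2,
        binary_traits=[(NBS_TRAITS.index("plaque"), 0.42)],
        outcome_subset_fraction=outcome_subset_fraction,
        outcome_traits=tuple(
            NBS_TRAITS.index(t) for t in ("plaque", "IMT", "ABI_rest", "ABI_exercise")
        ),
        trait_names=NBS_TRAITS,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
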