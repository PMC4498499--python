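"""Single-SNP and multi-SNP-score association models and the direction-
consistency evaluation of the iron hypothesis.

Linear fits are ordinary least squares with Wald 95% intervals
(effect +/- 1.96 SE); logistic fits use iteratively reweighted least squares.
Quartile contrasts are expressed against Q1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genio import GenotypeMatrix
from .preprocess import flip_effect_allele

OUTCOME_TRAITS = ("plaque", "IMT", "ABI_rest", "ABI_exercise")
BIOMARKER_TRAITS = (
    "hepcidin",
    "ferritin",
    "hepcidin_ferritin_ratio",
    "hepcidin_TS_ratio",
    "iron",
    "TIBC",
    "TS",
)
LIPID_COVARIATES = ("TC", "LDL", "HDL", "TGC")

#: the 4 exposure SNPs left out of the multi-SNP score (unknown direction)
SCORE_EXCLUDED_SNPS = ("rs8177240", "rs4921915", "rs6486121", "rs174577")

_Z95 = 1.959963984540054


@dataclass
class SNPAnnotation:
    """Per-SNP effect allele, published betas, and hypothesized direction.

    `hypothesized_direction` refers to atherosclerosis risk for the effect
    allele: "+" risk-increasing, "-" risk-decreasing, "unknown" when the
    published iron-trait effects do not map onto the hypothesis.
    """

    snp_id: str
    effect_allele: str
    hypothesized_direction: str = "unknown"
    published_betas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hypothesized_direction not in ("+", "-", "unknown"):
            raise ValueError("hypothesized_direction must be '+', '-' or 'unknown'")


def load_snp_annotations(path: str | Path) -> list[SNPAnnotation]:
    """Read a YAML list of {snp_id, effect_allele, hypothesized_direction, betas}."""
    raw = yaml.safe_load(Path(path).read_text())
    return [
        SNPAnnotation(
            snp_id=rec["snp_id"],
            effect_allele=rec["effect_allele"],
            hypothesized_direction=rec.get("hypothesized_direction", "unknown"),
            published_betas=rec.get("betas", {}),
        )
        for rec in raw
    ]


def write_snp_annotations(annotations: list[SNPAnnotation], path: str | Path) -> None:
    payload = [
        {
            "snp_id": a.snp_id,
            "effect_allele": a.effect_allele,
            "hypothesized_direction": a.hypothesized_direction,
            "betas": a.published_betas,
        }
        for a in annotations
    ]
    Path(path).write_text(yaml.safe_dump(payload))


@dataclass
class AssociationResult:
    predictor: str
    outcome: str
    effect: float  # beta, or log-OR for logistic
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model: str  # "linear" | "logistic"
    covariates: tuple[str, ...] = ()
    stratum: str = "all"
    status: str = "ok"

    @property
    def odds_ratio(self) -> float:
        if self.model != "logistic":
            raise ValueError("odds ratio only defined for logistic fits")
        return float(np.exp(self.effect))

    def to_row(self) -> dict:
        row = {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "model": self.model,
            "stratum": self.stratum,
            "effect": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "status": self.status,
        }
        if self.model == "logistic":
            with np.errstate(over="ignore"):
                row["odds_ratio"] = self.odds_ratio
                row["or_ci_low"] = float(np.exp(self.ci_low))
                row["or_ci_high"] = float(np.exp(self.ci_high))
        return row


@dataclass
class MultiSNPScore:
    sample_ids: np.ndarray
    score: pd.Series  # sum of 8 oriented dosages in [0, 16]; NaN = missing
    quartile: pd.Series  # labels "Q1".."Q4"


def orient_dosages(
    gm: GenotypeMatrix, annotations: list[SNPAnnotation], to_risk_increasing: bool = True
) -> pd.DataFrame:
    """Per-SNP dosage columns, flipped so the counted allele is risk-increasing."""
    dose = gm.dosage_frame()
    out = pd.DataFrame(index=dose.index)
    for ann in annotations:
        if ann.snp_id not in dose.columns:
            raise KeyError(f"SNP {ann.snp_id} missing from genotype matrix")
        col = dose[ann.snp_id]
        if to_risk_increasing and ann.hypothesized_direction == "-":
            col = pd.Series(flip_effect_allele(col.to_numpy()), index=col.index)
        out[ann.snp_id] = col
    return out


def build_multi_snp_score(oriented: pd.DataFrame, annotations: list[SNPAnnotation]) -> MultiSNPScore:
    """Sum of 8 risk-oriented dosages; samples missing any dosage get NaN."""
    if oriented.shape[1] != 8:
        raise ValueError("multi-SNP score requires exactly 8 SNPs")
    by_id = {a.snp_id: a for a in annotations}
    for snp in oriented.columns:
        ann = by_id.get(snp)
        if ann is None or ann.hypothesized_direction == "unknown":
            raise ValueError(f"SNP {snp} has unknown hypothesized direction")
    score = oriented.sum(axis=1, skipna=False)
    try:
        quart = assign_quartiles(score)
    except ValueError:
        # constant or near-empty score: quartiles undefined
        quart = pd.Series(np.nan, index=score.index)
    return MultiSNPScore(sample_ids=oriented.index.to_numpy(), score=score, quartile=quart)


def assign_quartiles(scores: pd.Series) -> pd.Series:
    """Empirical-quartile labels Q1..Q4; boundary ties fall to the lower quartile."""
    obs = scores.dropna()
    if len(obs) < 8:
        raise ValueError("need >= 8 non-missing scores for quartiles")
    if obs.nunique() == 1:
        raise ValueError("cannot form quartiles of a constant score")
    q25, q50, q75 = np.quantile(obs.to_numpy(), [0.25, 0.50, 0.75])
    rank = (
        (scores > q25).astype(int) + (scores > q50).astype(int) + (scores > q75).astype(int)
    )
    labels = rank.map({0: "Q1", 1: "Q2", 2: "Q3", 3: "Q4"})
    return labels.where(scores.notna())


def fit_linear(
    y: pd.Series | np.ndarray,
    predictor: pd.Series | np.ndarray | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    predictor_label: str = "x",
    outcome_label: str = "y",
    stratum: str = "all",
) -> AssociationResult | list[AssociationResult]:
    """OLS with intercept; Wald CI and two-sided normal p for the predictor.

    A DataFrame predictor (e.g. quartile indicators) yields one result per
    column.
    """
    y, P, C, n = _align(y, predictor, covariates)
    k = P.shape[1]
    X = np.column_stack([np.ones(n), P, C])
    if n <= X.shape[1] + 1:
        raise ValueError("too few observations for model size")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    results = []
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    labels = (
        list(predictor.columns) if isinstance(predictor, pd.DataFrame) else [predictor_label]
    )
    for j, lab in enumerate(labels, start=1):
        b, s = float(beta[j]), float(se[j])
        z = np.inf if s == 0 and b != 0 else (0.0 if s == 0 else b / s)
        from scipy.stats import norm

        p = 0.0 if np.isinf(z) else float(2 * norm.sf(abs(z)))
        results.append(
            AssociationResult(
                predictor=lab,
                outcome=outcome_label,
                effect=b,
                ci_low=b - _Z95 * s,
                ci_high=b + _Z95 * s,
                p_value=p,
                n_used=n,
                model="linear",
                covariates=cov_names,
                stratum=stratum,
            )
        )
    return results if isinstance(predictor, pd.DataFrame) else results[0]


def fit_logistic(
    y: pd.Series | np.ndarray,
    predictor: pd.Series | np.ndarray | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    predictor_label: str = "x",
    outcome_label: str = "y",
    stratum: str = "all",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AssociationResult | list[AssociationResult]:
    """Maximum-likelihood logistic regression via IRLS.

    Separation is flagged (status="separation") when any coefficient diverges
    beyond |log-OR| > 15; non-convergence within `max_iter` is flagged too.
    """
    y, P, C, n = _align(y, predictor, covariates)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("binary outcome must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("outcome has a single class")
    X = np.column_stack([np.ones(n), P, C])
    if n <= X.shape[1] + 1:
        raise ValueError("too few observations for model size")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    status = "not_converged"
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        XtW = X.T * w
        H = XtW @ X
        try:
            step = np.linalg.solve(H, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            status = "separation"
            break
        beta = beta + step
        if np.abs(beta[1:]).max(initial=0.0) > 15.0:
            status = "separation"
            break
        if abs(ll - ll_old) < tol:
            status = "ok"
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv((X.T * w) @ X)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    from scipy.stats import norm

    cov_names = tuple(covariates.columns) if covariates is not None else ()
    labels = (
        list(predictor.columns) if isinstance(predictor, pd.DataFrame) else [predictor_label]
    )
    results = []
    for j, lab in enumerate(labels, start=1):
        b, s = float(beta[j]), float(se[j])
        p = float(2 * norm.sf(abs(b / s))) if s > 0 else (0.0 if b != 0 else 1.0)
        results.append(
            AssociationResult(
                predictor=lab,
                outcome=outcome_label,
                effect=b,
                ci_low=b - _Z95 * s,
                ci_high=b + _Z95 * s,
                p_value=p,
                n_used=n,
                model="logistic",
                covariates=cov_names,
                stratum=stratum,
                status=status,
            )
        )
    return results if isinstance(predictor, pd.DataFrame) else results[0]


def _align(y, predictor, covariates):
    """Row-align outcome, predictor(s) and covariates; drop incomplete rows."""
    y = pd.Series(y, dtype=float) if not isinstance(y, pd.Series) else y.astype(float)
    if isinstance(predictor, pd.DataFrame):
        P = predictor.astype(float)
    else:
        P = pd.DataFrame({"__x__": pd.Series(predictor, index=y.index)}).astype(float)
    C = (
        covariates.astype(float)
        if covariates is not None
        else pd.DataFrame(index=y.index)
    )
    mask = y.notna() & P.notna().all(axis=1) & C.notna().all(axis=1)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no complete observations")
    return (
        y[mask].to_numpy(),
        P.loc[mask].to_numpy(),
        C.loc[mask].to_numpy() if C.shape[1] else np.empty((n, 0)),
        n,
    )


def quartile_indicators(quartile: pd.Series) -> pd.DataFrame:
    """Q2/Q3/Q4 indicator columns against the Q1 reference."""
    out = pd.DataFrame(index=quartile.index)
    for q in ("Q2", "Q3", "Q4"):
        out[q] = (quartile == q).astype(float).where(quartile.notna())
    return out


def run_mr_suite(
    gm: GenotypeMatrix,
    pheno: pd.DataFrame,
    annotations: list[SNPAnnotation],
    outcomes: tuple[str, ...] = OUTCOME_TRAITS,
    binary_outcomes: tuple[str, ...] = ("plaque",),
    strata: tuple[str, ...] = ("all", "men", "women"),
    adjustments: tuple[bool, ...] = (False, True),
    score_quartiles_on_subset: bool = True,
) -> pd.DataFrame:
    """Single-SNP and score-quartile models against the outcome traits.

    Produces one row per (predictor, outcome, stratum, adjustment): every
    annotated SNP on its published effect allele plus Q2-Q4 contrasts of the
    8-SNP risk score, each fitted unadjusted and lipid-adjusted, in the full
    sample and per sex.
    """
    present = [o for o in outcomes if o in pheno.columns and pheno[o].notna().any()]
    if len(present) < len(outcomes):
        raise ValueError("outcome subset is empty for at least one trait")

    dose = gm.dosage_frame().reindex(pheno.index)
    score_anns = [a for a in annotations if a.hypothesized_direction != "unknown"]
    oriented = orient_dosages(gm, score_anns).reindex(pheno.index)
    score_scores = oriented.sum(axis=1, skipna=False)
    if score_quartiles_on_subset:
        nima_mask = pheno[list(outcomes)].notna().any(axis=1)
        quart = assign_quartiles(score_scores.where(nima_mask))
    else:
        quart = assign_quartiles(score_scores)
    qind = quartile_indicators(quart)

    rows = []
    for stratum in strata:
        sub = _stratum_mask(pheno, stratum)
        for adjusted in adjustments:
            cov = pd.DataFrame(index=pheno.index)
            cov["age"] = pheno["age"]
            cov["age_squared"] = pheno["age"] ** 2
            if stratum == "all":
                cov["sex"] = pheno["sex"]
            if adjusted:
                for lip in LIPID_COVARIATES:
                    cov[lip] = pheno[lip]
            for outcome in outcomes:
                fitter = fit_logistic if outcome in binary_outcomes else fit_linear
                for ann in annotations:
                    res = fitter(
                        pheno.loc[sub, outcome],
                        dose.loc[sub, ann.snp_id],
                        cov.loc[sub],
                        predictor_label=ann.snp_id,
                        outcome_label=outcome,
                        stratum=stratum,
                    )
                    rows.append({**res.to_row(), "adjusted": adjusted, "predictor_type": "snp"})
                qres = fitter(
                    pheno.loc[sub, outcome],
                    qind.loc[sub],
                    cov.loc[sub],
                    outcome_label=outcome,
                    stratum=stratum,
                )
                for r in qres:
                    rows.append(
                        {**r.to_row(), "adjusted": adjusted, "predictor_type": "score_quartile"}
                    )
    return pd.DataFrame(rows)


def _stratum_mask(pheno: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=pheno.index)
    if stratum == "men":
        return pheno["sex"] == 1
    if stratum == "women":
        return pheno["sex"] == 2
    raise ValueError(f"unknown stratum {stratum!r}")


def run_cross_trait(
    gm: GenotypeMatrix,
    annotations: list[SNPAnnotation],
    biomarker_residuals: pd.DataFrame,
) -> pd.DataFrame:
    """Outcome-SNP x biomarker linear models on standardized residuals."""
    dose = gm.dosage_frame().reindex(biomarker_residuals.index)
    rows = []
    for ann in annotations:
        for trait in biomarker_residuals.columns:
            res = fit_linear(
                biomarker_residuals[trait],
                dose[ann.snp_id],
                covariates=None,
                predictor_label=ann.snp_id,
                outcome_label=trait,
            )
            rows.append(res.to_row())
    return pd.DataFrame(rows)


#: required effect signs on (plaque OR, IMT, ABI rest, ABI exercise) when the
#: predictor's counted allele is hypothesized risk-increasing
_CONSISTENT_SIGNS = {"plaque": 1, "IMT": 1, "ABI_rest": -1, "ABI_exercise": -1}


def evaluate_direction_consistency(
    results: pd.DataFrame, annotations: list[SNPAnnotation]
) -> pd.DataFrame:
    """Score each predictor's 4-outcome effect pattern against its hypothesis.

    Strict inequalities on point estimates; unknown-direction SNPs are
    reported unscored.  `results` must contain one row per (predictor,
    outcome) with columns effect/model.
    """
    rows = []
    for ann in annotations:
        sub = results[results["predictor"] == ann.snp_id]
        checks = {}
        for outcome, sign in _CONSISTENT_SIGNS.items():
            hit = sub[sub["outcome"] == outcome]
            if hit.empty:
                raise ValueError(f"missing result for {ann.snp_id} on {outcome}")
            rec = hit.iloc[0]
            eff = rec["effect"]  # log-OR for logistic, so >0 means OR>1
            checks[outcome] = float(eff) * sign
        if ann.hypothesized_direction == "unknown":
            consistent = None
        else:
            want = 1.0 if ann.hypothesized_direction == "+" else -1.0
            consistent = all(v * want > 0 for v in checks.values())
        rows.append(
            {
                "predictor": ann.snp_id,
                "hypothesized_direction": ann.hypothesized_direction,
                "consistent": consistent,
                **{f"signed_{k}": v for k, v in checks.items()},
            }
        )
    return pd.DataFrame(rows)
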