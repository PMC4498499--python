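"""Bayesian multivariate genomic model on scaled GRM eigenvectors.

The model regresses T standardized traits on Z = U sqrt(D) (so Z Z' equals
the GRM).  Cross-trait genetic covariance is carried by latent genetic
factors with lower-triangular loadings; each trait keeps its own residual
genetic term, giving implied genetic covariance
G0 = L_g diag(tau) L_g' + diag(s2_g).  Residual covariance is modelled the
same way with its own factors (an "unstructured" option uses a full set of
residual factors).  Variance parameters carry bounded-uniform priors,
sampled from their truncated scaled-inverse-chi-square full conditionals;
free loadings are N(0,1).  Missing trait values are imputed by data
augmentation each sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invgamma, norm

from .grm import EigenGRM

_LOG2PI = float(np.log(2 * np.pi))
_VAR_UPPER = 10.0  # vacuous for standardized traits
_VAR_LOWER = 1e-6


@dataclass
class LatentFactorModel:
    """Chain and structure settings for the Gibbs sampler."""

    n_genetic_factors: int = 1
    n_residual_factors: int = 1
    sweeps: int = 30_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int = 0
    residual_structure: str = "latent"  # "latent" | "unstructured"

    def __post_init__(self) -> None:
        if self.residual_structure not in ("latent", "unstructured"):
            raise ValueError("residual_structure must be 'latent' or 'unstructured'")
        if self.sweeps <= self.burn_in:
            raise ValueError("sweeps must exceed burn_in")


@dataclass
class PosteriorSummary:
    trait_names: tuple[str, ...]
    rg_mean: np.ndarray
    rg_sd: np.ndarray
    h2_mean: np.ndarray
    h2_sd: np.ndarray
    dic: float
    p_d: float
    n_retained: int
    ess_rg: np.ndarray
    rg_samples: np.ndarray  # retained x T x T
    param_table: pd.DataFrame


def _marginal_deviance(Y: np.ndarray, ZtY: np.ndarray, d: np.ndarray, G0: np.ndarray, E0: np.ndarray) -> float:
    """-2 log N(Y; 0, A x G0 + I x E0) via the GRM eigenbasis.

    `ZtY` is Z'Y with Z = U sqrt(d); coordinates in the dropped null space of
    A contribute with covariance E0 alone, recovered through Y'Y - ytil'ytil.
    """
    n, T = Y.shape
    ytil = ZtY / np.sqrt(d)[:, None]
    Sig = d[:, None, None] * G0[None] + E0[None]
    sign, logdets = np.linalg.slogdet(Sig)
    if (sign <= 0).any():
        raise FloatingPointError("non-PD covariance block in deviance")
    sols = np.linalg.solve(Sig, ytil[:, :, None])[:, :, 0]
    dev = float(logdets.sum() + (ytil * sols).sum())
    n_null = n - len(d)
    if n_null > 0:
        M = Y.T @ Y - ytil.T @ ytil
        sign_e, logdet_e = np.linalg.slogdet(E0)
        if sign_e <= 0:
            raise FloatingPointError("non-PD residual covariance in deviance")
        dev += n_null * logdet_e + float(np.trace(np.linalg.solve(E0, M)))
    return dev + n * T * _LOG2PI


def dic_from_deviances(deviance_samples: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC = D_bar + p_D with p_D = D_bar - D(theta_bar); returns (DIC, p_D)."""
    d_bar = float(np.mean(deviance_samples))
    if not np.isfinite(d_bar) or not np.isfinite(deviance_at_mean):
        raise ValueError("non-finite deviance")
    p_d = d_bar - float(deviance_at_mean)
    return d_bar + p_d, p_d


def build_design(eig: EigenGRM, tol: float = 1e-10) -> np.ndarray:
    """Z = U sqrt(D); columns with eigenvalue < tol are dropped; Z Z' = A."""
    d = eig.values
    if (d < -tol).any():
        raise ValueError("negative eigenvalue beyond tolerance")
    keep = d >= tol
    return eig.vectors[:, keep] * np.sqrt(d[keep])


def _draw_truncated_variance(rng, ss: float, k: float) -> float:
    """Draw from p(s2) ~ invgamma(k/2 - 1, ss/2) restricted to the prior box."""
    a = k / 2.0 - 1.0
    if a <= 0:
        a = 0.5
    scale = max(ss / 2.0, 1e-300)
    lo = invgamma.cdf(_VAR_LOWER, a, scale=scale)
    hi = invgamma.cdf(_VAR_UPPER, a, scale=scale)
    if hi <= lo:
        return _VAR_UPPER if lo >= 1.0 else _VAR_LOWER
    u = lo + rng.uniform() * (hi - lo)
    val = float(invgamma.ppf(u, a, scale=scale))
    return float(np.clip(val, _VAR_LOWER, _VAR_UPPER))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(np.clip(n / (1.0 + 2.0 * s), 1.0, n))


class _GibbsState:
    def __init__(self, Y, Z, Lg, Le, rng):
        n, T = Y.shape
        q = Z.shape[1]
        self.alpha = np.zeros((q, Lg))  # genetic factor scores
        self.lam = np.zeros((T, Lg))  # genetic loadings (lower-tri)
        self.tau = np.full(Lg, 0.1)  # genetic factor variances
        self.beta = np.zeros((q, T))  # trait-specific genetic effects
        self.s2g = np.full(T, 0.1)
        self.R = np.zeros((n, Le)) if Le else np.zeros((n, 0))
        self.psi = np.zeros((T, Le))  # residual loadings (lower-tri)
        self.tau_e = np.full(Le, 0.1)
        self.s2e = np.full(T, 0.5)
        for f in range(Lg):
            self.lam[f:, f] = 0.1
        for h in range(Le):
            self.psi[h:, h] = 0.1


def run_gibbs(
    Y: np.ndarray | pd.DataFrame,
    Z: np.ndarray,
    model: LatentFactorModel,
    trait_names: tuple[str, ...] | None = None,
) -> PosteriorSummary:
    """Gibbs-sample the latent-factor genomic model and summarize rG.

    `Y` is n x T standardized trait residuals; NaN entries are treated as
    missing and data-augmented.  Identical (data, model, seed) inputs yield
    bit-identical chains.
    """
    if isinstance(Y, pd.DataFrame):
        trait_names = trait_names or tuple(Y.columns)
        Y = Y.to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    if trait_names is None:
        trait_names = tuple(f"trait_{t + 1}" for t in range(T))
    if T > 8:
        raise ValueError("at most 8 traits per model")
    Lg = model.n_genetic_factors
    Le = T if model.residual_structure == "unstructured" else model.n_residual_factors
    if Lg > T or Le > T:
        raise ValueError("more latent factors than traits")
    q = Z.shape[1]
    d = np.einsum("ij,ij->j", Z, Z)  # Z'Z diagonal (orthogonal columns)

    rng = np.random.default_rng(model.seed)
    obs = ~np.isnan(Y)
    Ycur = Y.copy()
    col_mean = np.nanmean(Y, axis=0)
    for t in range(T):
        Ycur[~obs[:, t], t] = col_mean[t]

    st = _GibbsState(Ycur, Z, Lg, Le, rng)
    # residual matrix given current effects
    fitted = Z @ (st.alpha @ st.lam.T + st.beta) + st.R @ st.psi.T
    res = Ycur - fitted

    n_keep = (model.sweeps - model.burn_in) // model.thin
    if n_keep < 100:
        raise ValueError("fewer than 100 retained samples; lengthen the chain")
    rg_samples = np.empty((n_keep, T, T))
    h2_samples = np.empty((n_keep, T))
    dev_samples = np.empty(n_keep)
    g0_sum = np.zeros((T, T))
    e0_sum = np.zeros((T, T))
    y_sum = np.zeros((n, T))
    kept = 0

    for sweep in range(model.sweeps):
        # --- genetic factor scores and loadings
        for f in range(Lg):
            res += np.outer(Z @ st.alpha[:, f], st.lam[:, f])  # factor f out of the fit
            wts = st.lam[:, f] / st.s2e
            prec = d * float(st.lam[:, f] @ wts) + 1.0 / st.tau[f]
            mean = (Z.T @ (res @ wts)) / prec
            st.alpha[:, f] = mean + rng.standard_normal(q) / np.sqrt(prec)
            s = Z @ st.alpha[:, f]
            ss_s = float(s @ s)
            for t in range(f, T):  # loadings above the diagonal stay 0
                prec_l = ss_s / st.s2e[t] + 1.0
                mean_l = float(s @ res[:, t]) / st.s2e[t] / prec_l
                sd_l = 1.0 / np.sqrt(prec_l)
                if t == f:
                    # diagonal loading constrained non-negative
                    u = rng.uniform()
                    lo = norm.cdf(0.0, loc=mean_l, scale=sd_l)
                    st.lam[t, f] = norm.ppf(lo + u * (1.0 - lo), loc=mean_l, scale=sd_l)
                    if not np.isfinite(st.lam[t, f]):
                        st.lam[t, f] = max(mean_l, 0.0)
                else:
                    st.lam[t, f] = mean_l + sd_l * rng.standard_normal()
            res -= np.outer(s, st.lam[:, f])
            st.tau[f] = _draw_truncated_variance(rng, float(st.alpha[:, f] @ st.alpha[:, f]), q)

        # --- trait-specific genetic effects
        for t in range(T):
            zb = Z @ st.beta[:, t]
            res[:, t] += zb
            prec = d / st.s2e[t] + 1.0 / st.s2g[t]
            mean = (Z.T @ res[:, t]) / st.s2e[t] / prec
            st.beta[:, t] = mean + rng.standard_normal(q) / np.sqrt(prec)
            res[:, t] -= Z @ st.beta[:, t]
            st.s2g[t] = _draw_truncated_variance(rng, float(st.beta[:, t] @ st.beta[:, t]), q)

        # --- residual factors
        for h in range(Le):
            res += np.outer(st.R[:, h], st.psi[:, h])
            wts = st.psi[:, h] / st.s2e
            prec = float(st.psi[:, h] @ wts) + 1.0 / st.tau_e[h]
            mean = (res @ wts) / prec
            st.R[:, h] = mean + rng.standard_normal(n) / np.sqrt(prec)
            r = st.R[:, h]
            ss_r = float(r @ r)
            for t in range(h, T):
                prec_l = ss_r / st.s2e[t] + 1.0
                mean_l = float(r @ res[:, t]) / st.s2e[t] / prec_l
                sd_l = 1.0 / np.sqrt(prec_l)
                if t == h:
                    u = rng.uniform()
                    lo = norm.cdf(0.0, loc=mean_l, scale=sd_l)
                    st.psi[t, h] = norm.ppf(lo + u * (1.0 - lo), loc=mean_l, scale=sd_l)
                    if not np.isfinite(st.psi[t, h]):
                        st.psi[t, h] = max(mean_l, 0.0)
                else:
                    st.psi[t, h] = mean_l + sd_l * rng.standard_normal()
            res -= np.outer(r, st.psi[:, h])
            st.tau_e[h] = _draw_truncated_variance(rng, ss_r, n)

        # --- iid residual variances
        for t in range(T):
            st.s2e[t] = _draw_truncated_variance(rng, float(res[:, t] @ res[:, t]), n)

        # --- data augmentation for missing values
        fitted = Ycur - res
        for t in range(T):
            miss = ~obs[:, t]
            if miss.any():
                newvals = fitted[miss, t] + np.sqrt(st.s2e[t]) * rng.standard_normal(miss.sum())
                Ycur[miss, t] = newvals
                res[miss, t] = newvals - fitted[miss, t]

        if not np.isfinite(res).all():
            raise FloatingPointError("chain diverged to non-finite state")

        if sweep >= model.burn_in and (sweep - model.burn_in) % model.thin == 0 and kept < n_keep:
            G0 = st.lam * st.tau @ st.lam.T + np.diag(st.s2g)
            E0 = st.psi * st.tau_e @ st.psi.T + np.diag(st.s2e)
            dg = np.sqrt(np.diag(G0))
            rg_samples[kept] = G0 / np.outer(dg, dg)
            h2_samples[kept] = np.diag(G0) / (np.diag(G0) + np.diag(E0))
            # deviance marginal over the random effects, on the augmented data
            dev_samples[kept] = _marginal_deviance(Ycur, Z.T @ Ycur, d, G0, E0)
            g0_sum += G0
            e0_sum += E0
            y_sum += Ycur
            kept += 1

    rg_samples = rg_samples[:kept]
    h2_samples = h2_samples[:kept]
    dev_samples = dev_samples[:kept]
    if kept < 100:
        raise RuntimeError("fewer than 100 retained samples")

    # DIC: mean deviance + p_D, with D(theta_bar) at the posterior means
    y_bar = y_sum / kept
    dev_bar_theta = _marginal_deviance(y_bar, Z.T @ y_bar, d, g0_sum / kept, e0_sum / kept)
    dic, p_d = dic_from_deviances(dev_samples, dev_bar_theta)

    iu = np.triu_indices(T, k=1)
    ess = np.zeros((T, T))
    for a, b in zip(*iu):
        ess[a, b] = ess[b, a] = _ess(rg_samples[:, a, b])

    param_rows = []
    for t in range(T):
        param_rows.append(
            {
                "parameter": f"h2[{trait_names[t]}]",
                "mean": float(h2_samples[:, t].mean()),
                "sd": float(h2_samples[:, t].std(ddof=1)),
                "ess": _ess(h2_samples[:, t]),
            }
        )
    for a, b in zip(*iu):
        param_rows.append(
            {
                "parameter": f"rG[{trait_names[a]},{trait_names[b]}]",
                "mean": float(rg_samples[:, a, b].mean()),
                "sd": float(rg_samples[:, a, b].std(ddof=1)),
                "ess": ess[a, b],
            }
        )

    return PosteriorSummary(
        trait_names=trait_names,
        rg_mean=rg_samples.mean(axis=0),
        rg_sd=rg_samples.std(axis=0, ddof=1),
        h2_mean=h2_samples.mean(axis=0),
        h2_sd=h2_samples.std(axis=0, ddof=1),
        dic=float(dic),
        p_d=float(p_d),
        n_retained=kept,
        ess_rg=ess,
        rg_samples=rg_samples,
        param_table=pd.DataFrame(param_rows),
    )


def compute_dic(summary: PosteriorSummary) -> float:
    return summary.dic


def select_n_latent(
    Y,
    Z: np.ndarray,
    candidates=(1, 2),
    model: LatentFactorModel | None = None,
    trait_names=None,
):
    """Fit each candidate factor count with a common seed; argmin-DIC wins."""
    model = model or LatentFactorModel()
    table = []
    fits = {}
    for L in candidates:
        cfg = LatentFactorModel(
            n_genetic_factors=L,
            n_residual_factors=model.n_residual_factors,
            sweeps=model.sweeps,
            burn_in=model.burn_in,
            thin=model.thin,
            seed=model.seed,
            residual_structure=model.residual_structure,
        )
        fit = run_gibbs(Y, Z, cfg, trait_names=trait_names)
        fits[L] = fit
        table.append({"n_latent": L, "dic": fit.dic, "p_d": fit.p_d})
    table = pd.DataFrame(table)
    best = int(table.loc[table["dic"].idxmin(), "n_latent"])
    return best, table, fits


# --- the four-model suite ---------------------------------------------------

#: ratio traits and their components; a roster may not contain a ratio
#: together with both of its components
RATIO_COMPONENTS = {
    "hepcidin_ferritin_ratio": ("hepcidin", "ferritin"),
    "hepcidin_TS_ratio": ("hepcidin", "TS"),
    "TS": ("iron", "TIBC"),
}

NIMA_TRAITS = ("plaque", "IMT", "ABI_rest", "ABI_exercise")

DEFAULT_MODEL_ROSTERS = {
    1: ("hepcidin", "ferritin", "iron", "TIBC") + NIMA_TRAITS,
    2: ("hepcidin_ferritin_ratio", "iron", "TIBC") + NIMA_TRAITS,
    3: ("hepcidin_TS_ratio", "ferritin") + NIMA_TRAITS,
    4: ("hepcidin", "ferritin", "TS") + NIMA_TRAITS,
}

#: which model sources each biomarker row of the merged report
DEFAULT_ROW_SOURCE = {
    "hepcidin": 1,
    "ferritin": 1,
    "iron": 1,
    "TIBC": 1,
    "hepcidin_ferritin_ratio": 2,
    "hepcidin_TS_ratio": 3,
    "TS": 4,
}


@dataclass
class ModelSuiteConfig:
    rosters: dict = field(default_factory=lambda: dict(DEFAULT_MODEL_ROSTERS))
    row_source: dict = field(default_factory=lambda: dict(DEFAULT_ROW_SOURCE))
    nima: tuple[str, ...] = NIMA_TRAITS

    def validate(self) -> None:
        for mid, roster in self.rosters.items():
            for ratio, (c1, c2) in RATIO_COMPONENTS.items():
                if ratio in roster and c1 in roster and c2 in roster:
                    raise ValueError(
                        f"model {mid}: ratio trait {ratio} together with both components"
                    )
        for row, mid in self.row_source.items():
            if mid not in self.rosters:
                raise ValueError(f"row {row} sourced from unknown model {mid}")
            if row not in self.rosters[mid]:
                raise ValueError(f"row {row} absent from model {mid} roster")


def run_model_suite(
    residuals: pd.DataFrame,
    Z: np.ndarray,
    suite: ModelSuiteConfig | None = None,
    model: LatentFactorModel | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Fit the four trait rosters and merge a biomarker x NIMA rG report.

    Returns ({model_id: PosteriorSummary}, report) where the report has one
    row per (biomarker, NIMA) with posterior mean and SD sourced from the
    configured model.
    """
    suite = suite or ModelSuiteConfig()
    suite.validate()
    model = model or LatentFactorModel()
    summaries = {}
    for mid, roster in suite.rosters.items():
        missing = [t for t in roster if t not in residuals.columns]
        if missing:
            raise KeyError(f"model {mid} traits missing from residual table: {missing}")
        summaries[mid] = run_gibbs(
            residuals[list(roster)], Z, model, trait_names=tuple(roster)
        )

    rows = []
    for biomarker, mid in suite.row_source.items():
        summ = summaries[mid]
        names = summ.trait_names
        bi = names.index(biomarker)
        for outcome in suite.nima:
            oi = names.index(outcome)
            rows.append(
                {
                    "biomarker": biomarker,
                    "nima": outcome,
                    "rg_mean": float(summ.rg_mean[bi, oi]),
                    "rg_sd": float(summ.rg_sd[bi, oi]),
                    "source_model": mid,
                }
            )
    return summaries, pd.DataFrame(rows)
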