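"""Univariate and bivariate REML variance components on a GRM.

The restricted likelihood of y ~ N(Xb, G (x) A + E (x) I) is maximized with
average-information (AI) updates plus step-halving fallback when an AI step
is inadmissible or decreases the likelihood.  With complete trait overlap the
problem block-diagonalizes in the GRM eigenbasis (one 2x2 block per
eigenvalue), giving O(n) iterations; with partial overlap a dense-matrix path
is used.  Fixed effects are per-trait intercepts (traits arrive
pre-residualized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import EigenGRM

_VAR_FLOOR = 1e-8
_MAX_ITER = 200
_LL_TOL = 1e-6
_PAR_TOL = 1e-4


@dataclass
class VarianceComponents:
    sigma2_g: np.ndarray  # per-trait genetic variance
    sigma2_e: np.ndarray  # per-trait residual variance
    sigma_g12: float | None  # genetic covariance (bivariate)
    sigma_e12: float | None  # residual covariance on the overlap
    rg: float | None
    se: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    status: str = "converged"  # converged | boundary | failed
    n_iter: int = 0

    @property
    def heritability(self) -> np.ndarray:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _admissible(theta: np.ndarray, bivariate: bool) -> np.ndarray:
    """Project parameters onto the admissible region (PSD 2x2 blocks)."""
    th = theta.copy()
    if bivariate:
        g11, g12, g22, e11, e12, e22 = th
        g11, g22 = max(g11, _VAR_FLOOR), max(g22, _VAR_FLOOR)
        e11, e22 = max(e11, _VAR_FLOOR), max(e22, _VAR_FLOOR)
        gbound = np.sqrt(g11 * g22)
        g12 = np.clip(g12, -gbound, gbound)
        ebound = np.sqrt(e11 * e22) * (1 - 1e-10)
        e12 = np.clip(e12, -ebound, ebound)
        return np.array([g11, g12, g22, e11, e12, e22])
    th[0] = max(th[0], _VAR_FLOOR)
    th[1] = max(th[1], _VAR_FLOOR)
    return th


def _strictly_admissible(theta: np.ndarray, bivariate: bool) -> bool:
    if bivariate:
        g11, g12, g22, e11, e12, e22 = theta
        return (
            g11 > 0
            and g22 > 0
            and e11 > 0
            and e22 > 0
            and g12**2 <= g11 * g22
            and e12**2 < e11 * e22
        )
    return theta[0] > 0 and theta[1] > 0


class _EigenREML:
    """Fast REML engine for complete-overlap traits in the GRM eigenbasis."""

    def __init__(self, Y: np.ndarray, eig: EigenGRM):
        # Y: n x T (T in {1, 2}), no missing values
        self.T = Y.shape[1]
        self.d = eig.values
        U = eig.vectors
        self.Z = U.T @ Y  # rotated traits
        self.c = U.T @ np.ones(Y.shape[0])
        self.n = Y.shape[0]

    # --- parameter layout: univariate [g, e]; bivariate [g11,g12,g22,e11,e12,e22]

    def _blocks(self, theta):
        d = self.d
        if self.T == 1:
            g, e = theta
            return g * d + e
        g11, g12, g22, e11, e12, e22 = theta
        return (d * g11 + e11, d * g12 + e12, d * g22 + e22)

    def loglik(self, theta) -> float:
        c = self.c
        if self.T == 1:
            s = self._blocks(theta)
            if (s <= 0).any():
                return -np.inf
            z = self.Z[:, 0]
            M = float(np.sum(c * c / s))
            b = float(np.sum(c * z / s))
            quad = float(np.sum(z * z / s))
            return -0.5 * (np.log(s).sum() + np.log(M) + quad - b * b / M)
        a, b_, cc = self._blocks(theta)
        det = a * cc - b_ * b_
        if (det <= 0).any() or (a <= 0).any():
            return -np.inf
        ia, ib, ic = cc / det, -b_ / det, a / det
        z1, z2 = self.Z[:, 0], self.Z[:, 1]
        M = np.array(
            [
                [np.sum(c * c * ia), np.sum(c * c * ib)],
                [np.sum(c * c * ib), np.sum(c * c * ic)],
            ]
        )
        bv = np.array(
            [np.sum(c * (ia * z1 + ib * z2)), np.sum(c * (ib * z1 + ic * z2))]
        )
        quad = float(np.sum(ia * z1 * z1 + 2 * ib * z1 * z2 + ic * z2 * z2))
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        return -0.5 * (
            np.log(det).sum() + logdetM + quad - float(bv @ np.linalg.solve(M, bv))
        )

    def score_ai(self, theta):
        """Gradient and average-information matrix at theta."""
        c, d = self.c, self.d
        if self.T == 1:
            s = self._blocks(theta)
            z = self.Z[:, 0]
            inv = 1.0 / s
            M = float(np.sum(c * c * inv))
            bv = float(np.sum(c * z * inv))
            alpha = bv / M
            w = inv * (z - c * alpha)  # P y
            derivs = [d, np.ones_like(d)]
            score = np.empty(2)
            u = []
            for i, D in enumerate(derivs):
                trPV = float(np.sum(inv * D)) - float(np.sum(c * c * inv * D * inv)) / M
                yPVPy = float(np.sum(w * D * w))
                score[i] = -0.5 * (trPV - yPVPy)
                u.append(D * w)
            AI = np.empty((2, 2))
            for i in range(2):
                for j in range(2):
                    gj = float(np.sum(c * inv * u[j]))
                    Pu_j = inv * (u[j] - c * gj / M)
                    AI[i, j] = 0.5 * float(np.sum(u[i] * Pu_j))
            return score, AI

        a, b_, cc = self._blocks(theta)
        det = a * cc - b_ * b_
        ia, ib, ic = cc / det, -b_ / det, a / det
        z1, z2 = self.Z[:, 0], self.Z[:, 1]
        M = np.array(
            [
                [np.sum(c * c * ia), np.sum(c * c * ib)],
                [np.sum(c * c * ib), np.sum(c * c * ic)],
            ]
        )
        Minv = np.linalg.inv(M)
        bv = np.array(
            [np.sum(c * (ia * z1 + ib * z2)), np.sum(c * (ib * z1 + ic * z2))]
        )
        alpha = Minv @ bv
        r1, r2 = z1 - c * alpha[0], z2 - c * alpha[1]
        w1, w2 = ia * r1 + ib * r2, ib * r1 + ic * r2  # P y per block

        # structure matrices: (scale, [[.,.],[.,.]]) with scale d_k or 1
        structs = [
            (d, (1.0, 0.0, 0.0)),
            (d, (0.0, 1.0, 0.0)),
            (d, (0.0, 0.0, 1.0)),
            (np.ones_like(d), (1.0, 0.0, 0.0)),
            (np.ones_like(d), (0.0, 1.0, 0.0)),
            (np.ones_like(d), (0.0, 0.0, 1.0)),
        ]

        def apply_D(scale, sh, v1, v2):
            s11, s12, s22 = sh
            return scale * (s11 * v1 + s12 * v2), scale * (s12 * v1 + s22 * v2)

        def sigma_inv(v1, v2):
            return ia * v1 + ib * v2, ib * v1 + ic * v2

        score = np.empty(6)
        u_list = []
        for i, (scale, sh) in enumerate(structs):
            s11, s12, s22 = sh
            # tr(V^-1 D) = sum scale * tr(Sigma^-1 Dsh)
            trVinvD = float(np.sum(scale * (ia * s11 + 2 * ib * s12 + ic * s22)))
            # correction tr(Minv * S_i), S_i = sum c^2 Sigma^-1 Dsh Sigma^-1
            # Sigma^-1 Dsh Sigma^-1 entries:
            q11 = ia * s11 * ia + 2 * ia * s12 * ib + ib * s22 * ib
            q12 = ia * s11 * ib + s12 * (ia * ic + ib * ib) + ib * s22 * ic
            q22 = ib * s11 * ib + 2 * ib * s12 * ic + ic * s22 * ic
            S11 = float(np.sum(c * c * scale * q11))
            S12 = float(np.sum(c * c * scale * q12))
            S22 = float(np.sum(c * c * scale * q22))
            trPV = trVinvD - (
                Minv[0, 0] * S11 + 2 * Minv[0, 1] * S12 + Minv[1, 1] * S22
            )
            u1, u2 = apply_D(scale, sh, w1, w2)
            yPVPy = float(np.sum(w1 * u1 + w2 * u2))
            score[i] = -0.5 * (trPV - yPVPy)
            u_list.append((u1, u2))

        AI = np.empty((6, 6))
        Pu = []
        for u1, u2 in u_list:
            t1, t2 = sigma_inv(u1, u2)
            g = np.array([np.sum(c * t1), np.sum(c * t2)])
            h = Minv @ g
            p1, p2 = sigma_inv(u1 - c * h[0], u2 - c * h[1])
            Pu.append((p1, p2))
        for i in range(6):
            for j in range(6):
                AI[i, j] = 0.5 * float(
                    np.sum(u_list[i][0] * Pu[j][0] + u_list[i][1] * Pu[j][1])
                )
        return score, AI


class _DenseREML:
    """Reference REML engine on explicit covariance matrices.

    Handles partial trait overlap; O(n^3) per evaluation, intended for
    moderate n and as the oracle for the eigenbasis fast path.
    """

    def __init__(self, y1: np.ndarray, y2: np.ndarray | None, A: np.ndarray):
        self.univariate = y2 is None
        if self.univariate:
            obs1 = ~np.isnan(y1)
            self.y = y1[obs1]
            self.A11 = A[np.ix_(obs1, obs1)]
            n1 = obs1.sum()
            self.X = np.ones((n1, 1))
            self.parts = None
        else:
            obs1, obs2 = ~np.isnan(y1), ~np.isnan(y2)
            i1, i2 = np.flatnonzero(obs1), np.flatnonzero(obs2)
            self.y = np.concatenate([y1[i1], y2[i2]])
            n1, n2 = len(i1), len(i2)
            self.A11 = A[np.ix_(i1, i1)]
            self.A12 = A[np.ix_(i1, i2)]
            self.A22 = A[np.ix_(i2, i2)]
            # residual covariance applies where the same sample carries both traits
            self.J12 = (i1[:, None] == i2[None, :]).astype(float)
            self.X = np.zeros((n1 + n2, 2))
            self.X[:n1, 0] = 1.0
            self.X[n1:, 1] = 1.0
            self.n1, self.n2 = n1, n2

    def _V(self, theta):
        if self.univariate:
            g, e = theta
            return g * self.A11 + e * np.eye(self.A11.shape[0])
        g11, g12, g22, e11, e12, e22 = theta
        n1, n2 = self.n1, self.n2
        V = np.empty((n1 + n2, n1 + n2))
        V[:n1, :n1] = g11 * self.A11 + e11 * np.eye(n1)
        V[:n1, n1:] = g12 * self.A12 + e12 * self.J12
        V[n1:, :n1] = V[:n1, n1:].T
        V[n1:, n1:] = g22 * self.A22 + e22 * np.eye(n2)
        return V

    def _structs(self):
        if self.univariate:
            n1 = self.A11.shape[0]
            return [self.A11, np.eye(n1)]
        n1, n2 = self.n1, self.n2
        mats = []
        for blk11, blk12, blk22 in [
            (self.A11, None, None),
            (None, self.A12, None),
            (None, None, self.A22),
            (np.eye(n1), None, None),
            (None, self.J12, None),
            (None, None, np.eye(n2)),
        ]:
            M = np.zeros((n1 + n2, n1 + n2))
            if blk11 is not None:
                M[:n1, :n1] = blk11
            if blk12 is not None:
                M[:n1, n1:] = blk12
                M[n1:, :n1] = blk12.T
            if blk22 is not None:
                M[n1:, n1:] = blk22
            mats.append(M)
        return mats

    def loglik(self, theta) -> float:
        V = self._V(theta)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, self.y)
        Vi_X = np.linalg.solve(V, self.X)
        M = self.X.T @ Vi_X
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        bv = self.X.T @ Vi_y
        quad = float(self.y @ Vi_y) - float(bv @ np.linalg.solve(M, bv))
        return -0.5 * (logdetV + logdetM + quad)

    def score_ai(self, theta):
        V = self._V(theta)
        Vi = np.linalg.inv(V)
        M = self.X.T @ Vi @ self.X
        Minv = np.linalg.inv(M)
        P = Vi - Vi @ self.X @ Minv @ self.X.T @ Vi
        Py = P @ self.y
        structs = self._structs()
        k = len(structs)
        score = np.empty(k)
        u = [D @ Py for D in structs]
        for i, D in enumerate(structs):
            score[i] = -0.5 * (float(np.trace(P @ D)) - float(Py @ D @ Py))
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                AI[i, j] = 0.5 * float(u[i] @ P @ u[j])
        return score, AI


def _maximize(engine, theta0: np.ndarray, bivariate: bool) -> tuple[np.ndarray, float, str, int, np.ndarray]:
    theta = _admissible(theta0, bivariate)
    ll = engine.loglik(theta)
    status = "failed"
    AI = np.eye(len(theta))
    it = 0
    for it in range(1, _MAX_ITER + 1):
        score, AI = engine.score_ai(theta)
        ridge = 1e-8 * max(np.abs(np.diag(AI)).max(), 1.0)
        try:
            delta = np.linalg.solve(AI + ridge * np.eye(len(theta)), score)
        except np.linalg.LinAlgError:
            delta = score / max(1.0, np.abs(score).max())
        # keep ill-conditioned AI from proposing astronomical jumps
        cap = 10.0 * (np.abs(theta).sum() + 1.0)
        norm = np.abs(delta).max()
        if norm > cap:
            delta = delta * (cap / norm)
        # AI step with step-halving fallback (EM-flavoured damping)
        accepted = False
        for trial in (delta, score / max(1.0, np.abs(score).max())):
            scale = 1.0
            for _ in range(30):
                cand = _admissible(theta + scale * trial, bivariate)
                ll_new = engine.loglik(cand)
                if np.isfinite(ll_new) and ll_new >= ll + 1e-12:
                    accepted = True
                    break
                scale *= 0.5
            if accepted:
                break
        if not accepted:
            status = "converged"  # no ascent direction left: local optimum
            break
        rel = np.abs(cand - theta) / np.maximum(np.abs(theta), 1e-4)
        dll = ll_new - ll
        theta, ll = cand, ll_new
        if dll < _LL_TOL and rel.max() < _PAR_TOL:
            status = "converged"
            break
    else:
        status = "failed"
    return theta, ll, status, it, AI


def _rg_and_se(theta: np.ndarray, AI: np.ndarray) -> tuple[float, dict]:
    g11, g12, g22 = theta[0], theta[1], theta[2]
    se: dict = {}
    try:
        cov = np.linalg.inv(AI + 1e-12 * np.eye(len(theta)))
        diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = {
            "sigma2_g1": diag[0],
            "sigma_g12": diag[1],
            "sigma2_g2": diag[2],
            "sigma2_e1": diag[3],
            "sigma_e12": diag[4],
            "sigma2_e2": diag[5],
        }
    except np.linalg.LinAlgError:
        cov = None
    if g11 <= 1e-6 or g22 <= 1e-6:
        return np.nan, se
    rg = g12 / np.sqrt(g11 * g22)
    rg = float(np.clip(rg, -1.0, 1.0))
    if cov is not None:
        grad = np.zeros(len(theta))
        grad[0] = -rg / (2 * g11)
        grad[1] = 1.0 / np.sqrt(g11 * g22)
        grad[2] = -rg / (2 * g22)
        var_rg = float(grad @ cov @ grad)
        se["rg"] = float(np.sqrt(max(var_rg, 0.0)))
    return rg, se


def fit_univariate_greml(
    y: np.ndarray, eig: EigenGRM, min_n: int = 50
) -> VarianceComponents:
    """REML fit of y ~ N(mu, s2_g A + s2_e I) in the GRM eigenbasis."""
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("univariate fit expects complete trait values")
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} samples")
    if np.ptp(eig.values) < 1e-10:
        return VarianceComponents(
            sigma2_g=np.array([np.nan]),
            sigma2_e=np.array([np.nan]),
            sigma_g12=None,
            sigma_e12=None,
            rg=None,
            status="failed",
        )
    engine = _EigenREML(y[:, None], eig)
    vp = float(np.var(y, ddof=1))
    theta0 = np.array([0.5 * vp, 0.5 * vp])
    theta, ll, status, it, AI = _maximize(engine, theta0, bivariate=False)
    boundary = theta[0] <= 2 * _VAR_FLOOR or theta[1] <= 2 * _VAR_FLOOR
    if status == "converged" and boundary:
        status = "boundary"
    se = {}
    try:
        cov = np.linalg.inv(AI + 1e-12 * np.eye(2))
        se = {
            "sigma2_g": float(np.sqrt(max(cov[0, 0], 0.0))),
            "sigma2_e": float(np.sqrt(max(cov[1, 1], 0.0))),
        }
    except np.linalg.LinAlgError:
        pass
    return VarianceComponents(
        sigma2_g=np.array([theta[0]]),
        sigma2_e=np.array([theta[1]]),
        sigma_g12=None,
        sigma_e12=None,
        rg=None,
        se=se,
        log_likelihood=ll,
        status=status,
        n_iter=it,
    )


def fit_bivariate_greml(
    y1: np.ndarray,
    y2: np.ndarray,
    eig: EigenGRM,
    fix_cov_zero: bool = False,
) -> VarianceComponents:
    """Bivariate REML; NaN entries encode the partial-overlap pattern.

    With complete overlap the eigenbasis fast path is used; otherwise the
    dense engine.  rG and its SE come from the point estimates and the
    delta method on the inverse average-information matrix.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if len(y1) != len(y2) or len(y1) != len(eig.sample_ids):
        raise ValueError("traits must align with the GRM samples")
    complete = not (np.isnan(y1).any() or np.isnan(y2).any())
    if complete:
        engine = _EigenREML(np.column_stack([y1, y2]), eig)
    else:
        A = (eig.vectors * eig.values) @ eig.vectors.T
        engine = _DenseREML(y1, y2, A)

    v1 = float(np.nanvar(y1, ddof=1))
    v2 = float(np.nanvar(y2, ddof=1))
    theta0 = np.array([0.5 * v1, 0.0, 0.5 * v2, 0.5 * v1, 0.0, 0.5 * v2])

    if fix_cov_zero:
        engine = _FixedCovEngine(engine)
    theta, ll, status, it, AI = _maximize(engine, theta0, bivariate=True)
    if fix_cov_zero:
        theta = theta.copy()
        theta[1] = 0.0
        theta[4] = 0.0

    rg, se = _rg_and_se(theta, AI)
    boundary = (
        theta[0] <= 2 * _VAR_FLOOR
        or theta[2] <= 2 * _VAR_FLOOR
        or theta[3] <= 2 * _VAR_FLOOR
        or theta[5] <= 2 * _VAR_FLOOR
        or (np.isfinite(rg) and abs(rg) >= 1.0 - 1e-6)
    )
    if status == "converged" and boundary:
        status = "boundary"
    return VarianceComponents(
        sigma2_g=np.array([theta[0], theta[2]]),
        sigma2_e=np.array([theta[3], theta[5]]),
        sigma_g12=float(theta[1]),
        sigma_e12=float(theta[4]),
        rg=rg,
        se=se,
        log_likelihood=ll,
        status=status,
        n_iter=it,
    )


class _FixedCovEngine:
    """Wraps a bivariate engine, pinning both covariance parameters at 0."""

    def __init__(self, engine):
        self.engine = engine

    @staticmethod
    def _pin(theta):
        th = np.asarray(theta, dtype=float).copy()
        th[1] = 0.0
        th[4] = 0.0
        return th

    def loglik(self, theta):
        return self.engine.loglik(self._pin(theta))

    def score_ai(self, theta):
        score, AI = self.engine.score_ai(self._pin(theta))
        score = score.copy()
        AI = AI.copy()
        for idx in (1, 4):
            score[idx] = 0.0
            AI[idx, :] = 0.0
            AI[:, idx] = 0.0
            AI[idx, idx] = 1.0
        return score, AI


def small_sample_behavior_report(
    sample_sizes=(300, 600, 1000),
    n_snps: int = 2000,
    h2: float = 0.5,
    rg: float = 0.3,
    n_reps: int = 50,
    seed: int = 0,
    n_genotype_sets: int = 5,
):
    """Replicate grid of bivariate fits: empirical SD of rG and boundary rates.

    Returns a pandas DataFrame with one row per sample size; the empirical SE
    of rG should shrink (weakly) with n.
    """
    import pandas as pd

    from .grm import compute_grm, eigendecompose
    from .simulate import SimulationConfig, simulate_genotypes, simulate_phenotypes

    gcov = np.array([[h2, rg * h2], [rg * h2, h2]])
    rcov = np.array([[1 - h2, 0.0], [0.0, 1 - h2]])
    rows = []
    for n in sample_sizes:
        estimates, boundary = [], 0
        per_set = max(1, n_reps // n_genotype_sets)
        rep = 0
        for gset in range(n_genotype_sets):
            cfg = SimulationConfig(
                n_samples=n,
                n_snps=n_snps,
                n_traits=2,
                genetic_cov=gcov,
                residual_cov=rcov,
                covariate_effects={},
                add_lipids=False,
                seed=seed * 10_000 + n * 100 + gset,
            )
            gm = simulate_genotypes(cfg)
            eig = eigendecompose(compute_grm(gm))
            for r in range(per_set):
                if rep >= n_reps:
                    break
                cfg_r = SimulationConfig(
                    n_samples=n,
                    n_snps=n_snps,
                    n_traits=2,
                    genetic_cov=gcov,
                    residual_cov=rcov,
                    covariate_effects={},
                    add_lipids=False,
                    seed=seed * 10_000 + n * 100 + gset * 97 + r + 7,
                )
                pheno, _ = simulate_phenotypes(gm, cfg_r)
                fit = fit_bivariate_greml(
                    pheno["trait_1"].to_numpy(), pheno["trait_2"].to_numpy(), eig
                )
                if fit.rg is not None and np.isfinite(fit.rg):
                    estimates.append(fit.rg)
                if fit.status in ("boundary", "failed"):
                    boundary += 1
                rep += 1
        rows.append(
            {
                "n": n,
                "n_reps": rep,
                "mean_rg": float(np.mean(estimates)) if estimates else np.nan,
                "sd_rg": float(np.std(estimates, ddof=1)) if len(estimates) > 1 else np.nan,
                "boundary_fraction": boundary / rep,
            }
        )
    return pd.DataFrame(rows)
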