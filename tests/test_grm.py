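import itertools

import numpy as np
import pytest

from irongc import grm as grm_mod
from irongc import simulate as sim
from irongc.grm import GRMatrix

from conftest import make_genotype_matrix


def brute_force_grm(dosages):
    """Double-loop GCTA formula oracle."""
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    p = X.mean(axis=0) / 2
    A = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc = 0.0
            for i in range(m):
                acc += (X[j, i] - 2 * p[i]) * (X[k, i] - 2 * p[i]) / (2 * p[i] * (1 - p[i]))
            A[j, k] = acc / m
    return A


class TestComputeGRM:
    def test_single_snp_diagonal(self):
        # p = 0.5; sample with x = 2 has diagonal (2-1)^2 / (2*0.5*0.5) = 2
        gm = make_genotype_matrix(np.array([[2.0], [0.0], [1.0], [1.0]]))
        A = grm_mod.compute_grm(gm).matrix
        assert A[0, 0] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.binomial(2, p, 20) for p in rng.uniform(0.1, 0.5, 50)])
        gm = make_genotype_matrix(X)
        A = grm_mod.compute_grm(gm).matrix
        assert np.abs(A - brute_force_grm(X)).max() < 1e-10

    def test_identical_twins(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.binomial(2, 0.3, 10) for _ in range(40)])
        X[1] = X[0]
        A = grm_mod.compute_grm(make_genotype_matrix(X)).matrix
        assert A[0, 1] == pytest.approx(A[0, 0])
        assert A[0, 1] == pytest.approx(A[1, 1])

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.binomial(2, p, 30) for p in rng.uniform(0.1, 0.5, 25)])
        A1 = grm_mod.compute_grm(make_genotype_matrix(X)).matrix
        X2 = X.copy()
        X2[:, ::2] = 2 - X2[:, ::2]
        A2 = grm_mod.compute_grm(make_genotype_matrix(X2)).matrix
        assert np.abs(A1 - A2).max() < 1e-12

    def test_monomorphic_rejected(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.random.default_rng(3).binomial(2, 0.4, 10)
        with pytest.raises(ValueError, match="monomorphic"):
            grm_mod.compute_grm(make_genotype_matrix(X))

    def test_missing_mean_imputed(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.binomial(2, 0.4, 20).astype(float) for _ in range(10)])
        Xm = X.copy()
        Xm[0, 0] = np.nan
        A = grm_mod.compute_grm(make_genotype_matrix(Xm)).matrix
        # sample 0's missing SNP contributes exactly 0 to its cross-products
        p0 = np.nanmean(Xm[:, 0]) / 2
        Xfill = Xm.copy()
        Xfill[0, 0] = 2 * p0
        assert np.allclose(A, grm_mod.compute_grm(make_genotype_matrix(Xfill)).matrix)

    def test_diag_near_one_and_sib_offdiag(self):
        cfg = sim.SimulationConfig(
            n_samples=120,
            n_snps=5000,
            n_sib_pairs=40,
            maf_range=(0.1, 0.5),
            covariate_effects={},
            add_lipids=False,
            seed=5,
        )
        gm = sim.simulate_genotypes(cfg)
        A = grm_mod.compute_grm(gm).matrix
        assert 0.95 < A.diagonal().mean() < 1.05
        sib = [A[i, j] for i, j in sim.sib_pair_indices(cfg)]
        assert 0.4 < np.mean(sib) < 0.6


def brute_force_prune(X, r2_max):
    """All-pairs keep-first pruning oracle (no windowing)."""
    m = X.shape[1]
    removed = np.zeros(m, dtype=bool)
    corr = np.corrcoef(X, rowvar=False) ** 2
    for a in range(m):
        if removed[a]:
            continue
        for b in range(a + 1, m):
            if not removed[b] and corr[a, b] > r2_max:
                removed[b] = True
    return [j for j in range(m) if not removed[j]]


class TestLDPrune:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, 100).astype(float)
        y = rng.binomial(2, 0.3, 100).astype(float)
        gm = make_genotype_matrix(np.column_stack([x, x, y]))
        kept = grm_mod.ld_prune(gm)
        assert kept == ["snp0", "snp2"]

    def test_independent_snps_kept(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.binomial(2, p, 300) for p in rng.uniform(0.1, 0.5, 500)])
        kept = grm_mod.ld_prune(make_genotype_matrix(X))
        # null r^2 ~ 1/n scale; crossing 0.98 is essentially impossible
        assert len(kept) == 500

    def test_triple_matches_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.4, 80).astype(float)
        c = rng.binomial(2, 0.3, 80).astype(float)
        gm = make_genotype_matrix(np.column_stack([a, a, c]))
        kept = grm_mod.ld_prune(gm, window=50)
        oracle = brute_force_prune(gm.dosages, 0.98)
        assert kept == [f"snp{j}" for j in oracle]
        assert "snp2" in kept and ("snp0" in kept) != ("snp1" in kept)

    def test_windowed_matches_oracle_when_window_covers_all(self):
        rng = np.random.default_rng(3)
        cols = []
        for j in range(40):
            base = rng.binomial(2, 0.4, 60).astype(float)
            cols.append(base)
            if j % 5 == 0:  # inject near-duplicates
                cols.append(base.copy())
        X = np.column_stack(cols)
        gm = make_genotype_matrix(X)
        kept = grm_mod.ld_prune(gm, window=X.shape[1], step=5)
        oracle = brute_force_prune(X, 0.98)
        assert kept == [f"snp{j}" for j in oracle]

    def test_window_validation(self):
        gm = make_genotype_matrix(np.random.default_rng(4).binomial(2, 0.4, (20, 5)).astype(float))
        with pytest.raises(ValueError):
            grm_mod.ld_prune(gm, window=1)

    def test_monomorphic_rejected(self):
        X = np.column_stack([np.ones(20), np.random.default_rng(5).binomial(2, 0.4, 20)])
        with pytest.raises(ValueError, match="variance"):
            grm_mod.ld_prune(make_genotype_matrix(X))


def _grm_from(A):
    return GRMatrix(
        sample_ids=np.array([f"S{i}" for i in range(A.shape[0])], dtype=object),
        matrix=A,
        n_snps_used=1,
    )


class TestFilterRelatedness:
    def test_no_pairs_above_cutoff(self):
        A = np.eye(5) + 0.01
        kept = grm_mod.filter_relatedness(_grm_from(A))
        assert len(kept) == 5

    def test_sib_pair_drops_one(self):
        A = np.eye(4) * 1.0
        A[0, 1] = A[1, 0] = 0.5
        kept = grm_mod.filter_relatedness(_grm_from(A))
        assert len(kept) == 3
        assert ("S0" in kept) != ("S1" in kept)

    def test_chain_removes_middle(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.3
        A[1, 2] = A[2, 1] = 0.3
        kept = list(grm_mod.filter_relatedness(_grm_from(A)))
        assert kept == ["S0", "S2"]

    def test_matches_minimal_removal_on_small_cases(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 8
            A = np.eye(n)
            for i, j in itertools.combinations(range(n), 2):
                if rng.uniform() < 0.25:
                    A[i, j] = A[j, i] = 0.1
            kept = grm_mod.filter_relatedness(_grm_from(A))
            idx = [int(s[1:]) for s in kept]
            sub = A[np.ix_(idx, idx)]
            off = sub[~np.eye(len(idx), dtype=bool)]
            assert (off < 0.025).all()  # validity
            # oracle: maximum independent set by exhaustive search
            best = 0
            for r in range(n, 0, -1):
                for combo in itertools.combinations(range(n), r):
                    sub = A[np.ix_(combo, combo)]
                    if (sub[~np.eye(r, dtype=bool)] < 0.025).all():
                        best = r
                        break
                if best:
                    break
            assert len(kept) >= best - 1  # greedy is near-optimal, never invalid


class TestEigendecompose:
    def test_identity(self):
        eig = grm_mod.eigendecompose(_grm_from(np.eye(6)))
        assert np.allclose(eig.values, 1.0)

    def test_rank_one(self):
        v = np.array([1.0, 2.0, 3.0])
        eig = grm_mod.eigendecompose(_grm_from(np.outer(v, v)))
        assert eig.values[0] == pytest.approx(v @ v)
        assert np.abs(eig.values[1:]).max() < 1e-10

    def test_reconstruction(self):
        rng = np.random.default_rng(7)
        B = rng.standard_normal((50, 30))
        A = B @ B.T / 30
        eig = grm_mod.eigendecompose(_grm_from(A))
        recon = (eig.vectors * eig.values) @ eig.vectors.T
        assert np.abs(recon - A).max() < 1e-8
        assert np.abs(eig.vectors.T @ eig.vectors - np.eye(50)).max() < 1e-10
        assert (np.diff(eig.values) <= 1e-12).all()

    def test_non_symmetric_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValueError):
            GRMatrix(
                sample_ids=np.array(["a", "b", "c"], dtype=object), matrix=A, n_snps_used=1
            )
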