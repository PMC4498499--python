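"""LD pruning, GRM construction, relatedness filtering, eigendecomposition."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genio import GenotypeMatrix


@dataclass
class GRMatrix:
    sample_ids: np.ndarray
    matrix: np.ndarray  # symmetric n x n
    n_snps_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            # symmetrize tiny float asymmetry; reject genuine asymmetry
            if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
                raise ValueError("GRM must be symmetric")
            self.matrix = 0.5 * (self.matrix + self.matrix.T)


@dataclass
class EigenGRM:
    values: np.ndarray  # descending, >= 0 after clipping
    vectors: np.ndarray  # orthonormal columns
    sample_ids: np.ndarray
    n_clipped: int = 0


def ld_prune(
    gm: GenotypeMatrix, window: int = 100, step: int = 5, r2_max: float = 0.98
) -> list[str]:
    """Sliding-window pairwise pruning of highly correlated dosage columns.

    Within each window of `window` SNPs (advanced by `step`), any pair with
    squared Pearson correlation > r2_max loses its later member (bim order is
    kept).  Deterministic; requires polymorphic SNPs.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    X = gm.dosages
    m = gm.n_snps
    col_means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_means, X)
    if (X.std(axis=0) == 0).any():
        raise ValueError("ld_prune requires per-SNP variance > 0")

    removed = np.zeros(m, dtype=bool)
    start = 0
    while start < m:
        stop = min(start + window, m)
        idx = np.arange(start, stop)
        live = idx[~removed[idx]]
        if len(live) >= 2:
            sub = X[:, live]
            corr = np.corrcoef(sub, rowvar=False)
            r2 = corr**2
            for a in range(len(live)):
                if removed[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if removed[live[b]]:
                        continue
                    if r2[a, b] > r2_max:
                        removed[live[b]] = True
        if stop == m:
            break
        start += step
    return [s for s, r in zip(gm.snp_ids, removed) if not r]


def compute_grm(gm: GenotypeMatrix) -> GRMatrix:
    """GCTA-style GRM: A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i)).

    p_i is the sample allele-B frequency.  Missing dosages are mean-imputed
    per SNP (zero contribution after centering).  Monomorphic SNPs are
    rejected.
    """
    if gm.n_samples < 2:
        raise ValueError("GRM needs >= 2 samples")
    p = gm.allele_b_freq()
    if np.isnan(p).any() or ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic or all-missing SNP present; QC first")
    X = gm.dosages
    W = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    W = np.where(np.isnan(W), 0.0, W)
    m = gm.n_snps
    A = (W @ W.T) / m
    A = 0.5 * (A + A.T)
    return GRMatrix(sample_ids=gm.sample_ids.copy(), matrix=A, n_snps_used=m)


def filter_relatedness(grm: GRMatrix, cutoff: float = 0.025) -> np.ndarray:
    """Retain a subset with all pairwise relationships below `cutoff`.

    Iteratively drops the individual carrying the most relationships >=
    cutoff (ties: lowest index) until no offending pair remains.
    """
    A = grm.matrix
    n = A.shape[0]
    adj = A >= cutoff
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        active[int(np.argmax(deg))] = False  # argmax takes lowest index on ties
    return grm.sample_ids[active]


def eigendecompose(grm: GRMatrix) -> EigenGRM:
    """Full spectral decomposition; slightly negative eigenvalues clip to 0."""
    A = grm.matrix
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("eigendecompose requires a symmetric matrix")
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_clipped = int((vals < -1e-8).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} eigenvalues below -1e-8 clipped to 0")
    vals = np.clip(vals, 0.0, None)
    return EigenGRM(values=vals, vectors=vecs, sample_ids=grm.sample_ids.copy(), n_clipped=n_clipped)
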