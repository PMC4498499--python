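"""Genotype containers and file formats (PLINK bed/bim/fam, GCTA GRM, TSV).

Dosages are stored sample-major (n_samples x n_snps) as float64 with NaN for
missing calls.  Allele B is the counted/effect allele throughout; in PLINK
files it maps onto the bim A1 allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_BED_MAGIC = b"\x6c\x1b\x01"

# 2-bit PLINK codes -> counted-allele (A1) dosage
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def _bed_lut() -> np.ndarray:
    """256 x 4 lookup table: byte value -> four dosages."""
    lut = np.empty((256, 4), dtype=np.float64)
    for byte in range(256):
        for k in range(4):
            lut[byte, k] = _CODE_TO_DOSAGE[(byte >> (2 * k)) & 0b11]
    return lut


_LUT = _bed_lut()


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Attributes
    ----------
    sample_ids : array of str, unique
    snp_ids : array of str, unique
    dosages : (n, m) float array, values in [0, 2], NaN = missing
    chrom, pos : per-SNP chromosome label and 1-based position
    allele_a, allele_b : other / effect allele per SNP
    imputation_quality : optional per-SNP info score in [0, 1]
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    imputation_quality: np.ndarray | None = None
    build: str = "b37"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("dosage shape inconsistent with id vectors")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_b_freq(self) -> np.ndarray:
        """Counted-allele frequency per SNP; NaN for all-missing SNPs."""
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Folded minor allele frequency in [0, 0.5]; NaN for all-missing SNPs."""
        p = self.allele_b_freq()
        return np.minimum(p, 1.0 - p)

    def all_missing_snps(self) -> np.ndarray:
        return self.snp_ids[np.isnan(self.dosages).all(axis=0)]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        cols = np.array([idx[s] for s in snp_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[cols],
            dosages=self.dosages[:, cols],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
            allele_a=self.allele_a[cols],
            allele_b=self.allele_b[cols],
            imputation_quality=None
            if self.imputation_quality is None
            else self.imputation_quality[cols],
            build=self.build,
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([idx[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[rows],
            snp_ids=self.snp_ids,
            dosages=self.dosages[rows],
            chrom=self.chrom,
            pos=self.pos,
            allele_a=self.allele_a,
            allele_b=self.allele_b,
            imputation_quality=self.imputation_quality,
            build=self.build,
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write hard-called genotypes as PLINK bed/bim/fam (SNP-major bed)."""
    prefix = Path(prefix)
    rounded = np.round(gm.dosages)
    ok = np.isnan(gm.dosages) | (np.abs(gm.dosages - rounded) <= 1e-6)
    if not ok.all():
        raise ValueError("bed output requires hard-called dosages in {0,1,2}")

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in gm.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(gm.n_snps):
            fh.write(
                f"{gm.chrom[j]}\t{gm.snp_ids[j]}\t0\t{gm.pos[j]}"
                f"\t{gm.allele_b[j]}\t{gm.allele_a[j]}\n"
            )

    n = gm.n_samples
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(gm.n_snps):
            col = rounded[:, j]
            row = bytearray(nbytes)
            for i in range(n):
                code = 0b01 if np.isnan(col[i]) else _DOSAGE_TO_CODE[int(col[i])]
                row[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(row))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam trio; the bim A1 allele becomes allele B."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    if fam["iid"].duplicated().any():
        raise ValueError("duplicate sample ids in fam file")
    if bim["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in bim file")

    n, m = len(fam), len(bim)
    nbytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("malformed bed magic bytes (expect SNP-major v1.00)")
    body = raw[3:]
    if body.size != m * nbytes:
        raise ValueError("bed size inconsistent with fam/bim dimensions")
    dosages = _LUT[body.reshape(m, nbytes)].reshape(m, nbytes * 4)[:, :n].T.copy()

    return GenotypeMatrix(
        sample_ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp"].to_numpy(dtype=object),
        dosages=dosages,
        chrom=bim["chrom"].to_numpy(dtype=object),
        pos=bim["pos"].to_numpy(),
        allele_a=bim["a2"].to_numpy(dtype=object),
        allele_b=bim["a1"].to_numpy(dtype=object),
    )


def write_grm_gcta(matrix: np.ndarray, sample_ids, n_snps: int, prefix: str | Path) -> None:
    """Write a GRM in GCTA binary format (grm.bin / grm.N.bin / grm.id)."""
    prefix = Path(prefix)
    n = matrix.shape[0]
    tri = matrix[np.tril_indices(n)].astype(np.float32)
    tri.tofile(str(prefix) + ".grm.bin")
    np.full(tri.shape, n_snps, dtype=np.float32).tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA binary GRM; returns (matrix, sample_ids, n_snps)."""
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None)[1].to_numpy(dtype=object)
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32)
    if tri.size != n * (n + 1) // 2:
        raise ValueError("grm.bin size inconsistent with grm.id")
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    nsnp = int(np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)[0])
    return mat, ids, nsnp


def write_grm_tsv(matrix: np.ndarray, sample_ids, path: str | Path) -> None:
    pd.DataFrame(matrix, index=sample_ids, columns=sample_ids).to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table must carry a sample_id column")
    return df.set_index("sample_id")


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id", na_rep="NA")
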