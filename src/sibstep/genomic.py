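"""Genomic relationship matrix G and the single-step H inverse.

G follows VanRaden's first method: gene contents are centred by twice the
allele frequency and cross-products are scaled by sum(2 p (1-p)).  Because
a G built from a few hundred animals is singular or near-singular, it is
blended with the pedigree block A22 before inversion.  The single-step
inverse then never forms H itself:

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

with the correction confined to the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.linalg import splu

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "allele_frequencies",
    "build_G",
    "blend_G",
    "HInverseParts",
    "build_H_inverse",
    "sparse_logdet",
]

#: canonical missing-genotype sentinel for integer gene-content storage
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNP gene-content matrix.

    ``values`` holds 0/1/2 gene content; missing cells are :data:`MISSING`
    in integer storage or NaN in float storage (after expectation-based
    imputation gene content may be fractional).
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    values: np.ndarray
    p_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating):
            return np.isnan(self.values)
        return self.values == MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids.copy(), self.snp_ids.copy(), self.values.copy())

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        idx = np.asarray([pos[s] for s in snp_ids], dtype=np.int64)
        return GenotypeMatrix(self.sample_ids.copy(), self.snp_ids[idx], self.values[:, idx])


def allele_frequencies(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-SNP allele frequency p = mean(gene content)/2 over non-missing cells.

    SNPs with every cell missing get NaN (flagged, excluded downstream).
    """
    if isinstance(genotypes, GenotypeMatrix):
        vals = genotypes.values
        miss = genotypes.missing_mask()
    else:
        vals = np.asarray(genotypes)
        miss = np.isnan(vals) if np.issubdtype(vals.dtype, np.floating) else vals == MISSING
    m = np.where(miss, np.nan, vals.astype(float))
    with np.errstate(invalid="ignore"):
        p = np.nanmean(m, axis=0) / 2.0
    if isinstance(genotypes, GenotypeMatrix):
        genotypes.p_ = p
    return p


def monomorphic_mask(p: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """SNPs unusable for G: fixed (p at 0 or 1) or entirely missing."""
    return ~np.isfinite(p) | (p <= tol) | (p >= 1.0 - tol)


def centred_scores(genotypes: GenotypeMatrix, p: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Centred gene-content matrix Z = M - 2p over usable SNPs.

    Missing cells are replaced by their expectation 2p (centred value 0).
    Returns (Z, keep_mask, denom) with denom = sum over kept SNPs of
    2 p (1 - p).
    """
    if p is None:
        p = allele_frequencies(genotypes)
    keep = ~monomorphic_mask(p)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic or missing; G is undefined")
    vals = genotypes.values[:, keep].astype(float)
    miss = genotypes.missing_mask()[:, keep]
    pk = p[keep]
    Z = vals - 2.0 * pk
    Z[miss] = 0.0
    denom = float(np.sum(2.0 * pk * (1.0 - pk)))
    return Z, keep, denom


def build_G(genotypes: GenotypeMatrix, p: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix ZZ'/sum 2p(1-p)."""
    Z, _, denom = centred_scores(genotypes, p)
    if denom <= 0:
        raise ValueError("zero scaling denominator: no polymorphic SNPs")
    return (Z @ Z.T) / denom


def blend_G(G: np.ndarray, A22: np.ndarray, tau: float = 0.95, omega: float = 0.05) -> np.ndarray:
    """G* = tau G + omega A22, the standard invertibility blend."""
    if G.shape != A22.shape:
        raise ValueError(f"G {G.shape} and A22 {A22.shape} are not conformable")
    if tau <= 0 or abs(tau + omega - 1.0) > 1e-8:
        raise ValueError("blending weights must satisfy tau > 0 and tau + omega = 1")
    return tau * G + omega * A22


@dataclass
class HInverseParts:
    """H^-1 held as sparse A^-1 plus a dense genotyped-block correction.

    ``geno_index`` are 0-based positions of the genotyped animals in the
    pedigree order.  ``logdet_H`` is log|H| = log|A| + log|G*| - log|A22|,
    needed by the REML likelihood.
    """

    a_inv: sparse.csr_matrix
    correction: np.ndarray  # G*^-1 - A22^-1
    geno_index: np.ndarray
    tau: float = 0.95
    omega: float = 0.05
    logdet_H: float | None = None

    @property
    def n(self) -> int:
        return self.a_inv.shape[0]

    def to_sparse(self) -> sparse.csr_matrix:
        """Assemble H^-1 as one sparse matrix (dense block embedded)."""
        g = self.geno_index
        if len(g) == 0:
            return self.a_inv.copy()
        rows = np.repeat(g, len(g))
        cols = np.tile(g, len(g))
        corr = sparse.coo_matrix(
            (self.correction.ravel(), (rows, cols)), shape=self.a_inv.shape
        )
        return (self.a_inv + corr.tocsr()).tocsr()

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.a_inv @ v
        g = self.geno_index
        if len(g):
            out[g] += self.correction @ v[g]
        return out


def sparse_logdet(M: sparse.spmatrix) -> float:
    """log|M| for a symmetric positive-definite sparse matrix via LU."""
    lu = splu(sparse.csc_matrix(M))
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _chol_inv_logdet(M: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    try:
        c, low = linalg.cho_factor(M, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"{what} is singular or not positive definite; "
            "increase the blending weight omega on A22"
        ) from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv = linalg.cho_solve((c, low), np.eye(M.shape[0]))
    return inv, logdet


def build_H_inverse(
    a_inv: sparse.spmatrix,
    G_star: np.ndarray,
    A22: np.ndarray,
    geno_index: np.ndarray,
    tau: float = 0.95,
    omega: float = 0.05,
) -> HInverseParts:
    """Assemble the single-step H^-1 parts from A^-1, blended G* and A22.

    With no genotyped animals the correction block is empty and H^-1 is
    exactly A^-1.
    """
    a_inv = sparse.csr_matrix(a_inv)
    geno_index = np.asarray(geno_index, dtype=np.int64)
    logdet_A = -sparse_logdet(a_inv)
    if len(geno_index) == 0:
        return HInverseParts(a_inv, np.zeros((0, 0)), geno_index, tau, omega, logdet_A)
    G_star = np.asarray(G_star, float)
    A22 = np.asarray(A22, float)
    if G_star.shape != (len(geno_index),) * 2 or A22.shape != G_star.shape:
        raise ValueError("G*, A22 and genotyped index have inconsistent dimensions")
    G_inv, logdet_G = _chol_inv_logdet(G_star, "blended G*")
    A22_inv, logdet_A22 = _chol_inv_logdet(A22, "A22")
    corr = G_inv - A22_inv
    corr = (corr + corr.T) / 2.0
    return HInverseParts(
        a_inv, corr, geno_index, tau, omega, logdet_A + logdet_G - logdet_A22
    )
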