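"""Genomic relationship machinery for single-step evaluation.

Genotype QC (per-breed MAF and call-rate filters), expected-dosage
filling of sporadic missing genotypes, the genomic relationship matrix
G from centered SNP dosages, mean-matching compatibility scaling of G
to the pedigree submatrix A22, blending for invertibility, and the
single-step H matrix in both explicit (dense, oracle-scale) and
inverse (sparse A^-1 plus a dense genotyped-block correction) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from . import pedigree as ped_mod
from .pedigree import PedigreeTable

__all__ = [
    "QCError",
    "GenotypeMatrix",
    "qc_filter",
    "fill_missing",
    "build_G",
    "match_G_to_A22",
    "blend_G",
    "build_H_explicit",
    "HInverse",
    "build_H_inverse",
    "RelationshipSet",
    "single_step_relationships",
]


class QCError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix (animals x SNPs) with missingness.

    ``dosages`` holds 0/1/2 counts of the coded (alternate) allele as
    floats, with ``nan`` marking missing calls.  Allele frequencies are
    always computed from non-missing entries only.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    breed: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.breed = np.asarray(self.breed, dtype=object)
        n, m = self.dosages.shape
        if len(self.ids) != n or len(self.snp_ids) != m or len(self.breed) != n:
            raise ValueError("inconsistent genotype matrix dimensions")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def breeds(self) -> list:
        return sorted(set(self.breed))

    def allele_freq(self, freq_source: str = "pooled"):
        """Frequencies of the coded allele: pooled vector or per-breed dict."""
        if freq_source == "pooled":
            with np.errstate(invalid="ignore"):
                q = np.nanmean(self.dosages, axis=0) / 2.0
            return q
        if freq_source == "per_breed":
            out = {}
            for b in self.breeds():
                rows = self.dosages[self.breed == b]
                with np.errstate(invalid="ignore"):
                    out[b] = np.nanmean(rows, axis=0) / 2.0
            return out
        raise ValueError(f"unknown freq_source {freq_source!r}")

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = slice(None) if animal_mask is None else animal_mask
        sm = slice(None) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            ids=self.ids[am],
            snp_ids=self.snp_ids[sm],
            dosages=self.dosages[am][:, sm],
            breed=self.breed[am],
        )


def qc_filter(
    genos: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.98,
    single_breed: bool = False,
):
    """Keep SNPs that pass MAF and call-rate thresholds in every breed.

    Thresholds are strict (MAF > maf_min, call rate > callrate_min),
    evaluated separately per breed; a SNP must pass in all breeds to be
    kept (the conservative intersection rule).  Animals are never
    dropped.  Returns ``(kept_snp_ids, filtered_matrix)``.
    """
    breeds = genos.breeds()
    if len(breeds) < 2 and not single_breed:
        raise QCError("fewer than two breeds present; pass single_breed=True if intended")
    keep = np.ones(genos.n_snps, dtype=bool)
    for b in breeds:
        rows = genos.dosages[genos.breed == b]
        if rows.shape[0] == 0:
            raise QCError(f"breed {b!r} has no genotyped animals")
        called = ~np.isnan(rows)
        callrate = called.mean(axis=0)
        with np.errstate(invalid="ignore"):
            q = np.nanmean(rows, axis=0) / 2.0
        q = np.where(callrate > 0, q, 0.0)
        maf = np.minimum(q, 1.0 - q)
        keep &= (maf > maf_min) & (callrate > callrate_min)
    return list(genos.snp_ids[keep]), genos.subset(snp_mask=keep)


def fill_missing(genos: GenotypeMatrix, freq_source: str = "pooled") -> GenotypeMatrix:
    """Replace missing dosages by their expectation 2 q_j.

    After centering by 2 q_j a filled entry contributes exactly zero to
    G, which is how sporadic missingness is "taken into account" rather
    than imputed.
    """
    dos = genos.dosages.copy()
    mask = np.isnan(dos)
    if not mask.any():
        return GenotypeMatrix(genos.ids, genos.snp_ids, dos, genos.breed)
    if freq_source == "pooled":
        q = genos.allele_freq("pooled")
        fill = np.broadcast_to(2.0 * q, dos.shape)
        dos[mask] = fill[mask]
    else:
        qb = genos.allele_freq("per_breed")
        for b, q in qb.items():
            rows = genos.breed == b
            block = dos[rows]
            bm = np.isnan(block)
            block[bm] = np.broadcast_to(2.0 * q, block.shape)[bm]
            dos[rows] = block
    return GenotypeMatrix(genos.ids, genos.snp_ids, dos, genos.breed)


def _center(genos: GenotypeMatrix, freq_source: str):
    if freq_source == "pooled":
        q = genos.allele_freq("pooled")
    elif freq_source == "per_breed":
        breeds = genos.breeds()
        if len(breeds) != 1:
            raise ValueError(
                "per-breed G requires a single-breed genotype subset; "
                "subset the matrix by breed first"
            )
        q = genos.allele_freq("per_breed")[breeds[0]]
    else:
        raise ValueError(f"unknown freq_source {freq_source!r}")
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise QCError("fixed SNP encountered when building G; run qc_filter first")
    filled = fill_missing(genos, freq_source).dosages
    M = filled - 2.0 * q
    return M, q


def build_G(genos: GenotypeMatrix, freq_source: str = "pooled") -> np.ndarray:
    """Raw genomic relationship matrix G = M M' / (2 sum q_j (1 - q_j)).

    M is the dosage matrix column-centered by twice the allele
    frequency; ``freq_source`` selects whole-population frequencies
    (multi-breed and multiple-trait models) or the breed's own
    frequencies (within-breed model, single-breed input).
    """
    M, q = _center(genos, freq_source)
    denom = 2.0 * float(np.sum(q * (1.0 - q)))
    return (M @ M.T) / denom


def match_G_to_A22(G: np.ndarray, A22: np.ndarray, mode: str = "mean_matching"):
    """Scale G for compatibility with the pedigree base: G* = a + b G.

    ``mean_matching`` solves the 2x2 system equating the means of the
    diagonals and of the off-diagonals of G* and A22 (the two-coefficient
    correction).  ``offset`` applies only the additive constant matching
    the off-diagonal means (the single-constant alternative, b = 1).
    Returns ``(G_star, a, b)``.  Idempotent: re-matching returns (0, 1).
    """
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape or G.shape[0] != G.shape[1]:
        raise ValueError("G and A22 must be square and conformable")
    n = G.shape[0]
    if n < 2:
        raise ValueError("compatibility scaling needs at least 2 animals")
    off = ~np.eye(n, dtype=bool)
    mdG, moG = G.diagonal().mean(), G[off].mean()
    mdA, moA = A22.diagonal().mean(), A22[off].mean()
    if mode == "offset":
        a, b = moA - moG, 1.0
    elif mode == "mean_matching":
        if abs(mdG - moG) < 1e-12:
            raise QCError("degenerate scaling system: mean(diag G) == mean(offdiag G)")
        b = (mdA - moA) / (mdG - moG)
        a = moA - b * moG
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return a + b * G, a, b


def blend_G(G_star: np.ndarray, A22: np.ndarray, tau: float = 0.95) -> np.ndarray:
    """G_b = tau G* + (1 - tau) A22; guarantees invertibility for tau < 1."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("blend weight tau must lie in (0, 1]")
    return tau * np.asarray(G_star, float) + (1.0 - tau) * np.asarray(A22, float)


def build_H_explicit(A: np.ndarray, G_b: np.ndarray, genotyped_idx) -> np.ndarray:
    """Dense single-step H with blocks written out explicitly.

    In the (ungenotyped, genotyped) partition of A:
    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21, H12 = A12 A22^-1 G,
    H22 = G.  Returned in the original animal order of A.  Intended for
    small instances and as the oracle for :func:`build_H_inverse`.
    """
    A = np.asarray(A, float)
    n = A.shape[0]
    g = np.asarray(genotyped_idx, dtype=np.int64)
    u = np.setdiff1d(np.arange(n), g)
    A22 = A[np.ix_(g, g)]
    if len(u) == 0:
        return np.asarray(G_b, float).copy()
    A12 = A[np.ix_(u, g)]
    try:
        cf = la.cho_factor(A22)
    except la.LinAlgError as exc:
        raise la.LinAlgError("A22 is singular; cannot form H blocks") from exc
    K = la.cho_solve(cf, A12.T).T  # A12 A22^-1
    H = np.empty_like(A)
    H[np.ix_(u, u)] = A[np.ix_(u, u)] + K @ (G_b - A22) @ K.T
    H12 = K @ G_b
    H[np.ix_(u, g)] = H12
    H[np.ix_(g, u)] = H12.T
    H[np.ix_(g, g)] = G_b
    return H


@dataclass
class HInverse:
    """H^-1 = A^-1 + [0 0; 0 G_b^-1 - A22^-1], kept in structured form.

    ``A_inv`` is the sparse pedigree inverse over all animals and
    ``correction`` the dense genotyped-block increment.  The structure
    is what makes single-step MME assembly and REML absorption cheap.
    """

    A_inv: sp.csr_matrix
    genotyped_idx: np.ndarray
    correction: np.ndarray
    log_det_H: float | None = None

    @property
    def n(self) -> int:
        return self.A_inv.shape[0]

    def to_dense(self) -> np.ndarray:
        H = self.A_inv.toarray()
        ix = np.ix_(self.genotyped_idx, self.genotyped_idx)
        H[ix] += self.correction
        return H

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.A_inv @ x
        g = self.genotyped_idx
        if x.ndim == 1:
            y[g] += self.correction @ x[g]
        else:
            y[g, :] += self.correction @ x[g, :]
        return y

    def to_sparse(self) -> sp.csr_matrix:
        g = self.genotyped_idx
        k = len(g)
        corr = sp.coo_matrix(
            (self.correction.ravel(), (np.repeat(g, k), np.tile(g, k))),
            shape=self.A_inv.shape,
        )
        return (self.A_inv + corr.tocsr()).tocsr()


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    G_b: np.ndarray,
    genotyped_idx,
    log_det_A: float | None = None,
) -> HInverse:
    """Assemble H^-1 from A^-1 and the genotyped-block correction.

    Raises a linear-algebra error with a hint to blend when G_b is
    singular.  ``log_det_A`` (if given) lets the REML module carry
    log|H| = log|A| + log|G_b| - log|A22| at no extra cost.
    """
    G_b = np.asarray(G_b, float)
    A22 = np.asarray(A22, float)
    try:
        cf_g = la.cho_factor(G_b)
    except la.LinAlgError as exc:
        raise la.LinAlgError(
            "G_b is singular or indefinite; blend with A22 (blend_G) before inverting"
        ) from exc
    cf_a = la.cho_factor(A22)
    eye = np.eye(G_b.shape[0])
    corr = la.cho_solve(cf_g, eye) - la.cho_solve(cf_a, eye)
    corr = 0.5 * (corr + corr.T)
    log_det_H = None
    if log_det_A is not None:
        ld_g = 2.0 * np.log(np.diag(cf_g[0])).sum()
        ld_a22 = 2.0 * np.log(np.diag(cf_a[0])).sum()
        log_det_H = log_det_A + ld_g - ld_a22
    return HInverse(
        A_inv=sp.csr_matrix(A_inv),
        genotyped_idx=np.asarray(genotyped_idx, dtype=np.int64),
        correction=corr,
        log_det_H=log_det_H,
    )


@dataclass
class RelationshipSet:
    """All relationship pieces of one single-step build, with provenance."""

    ped: PedigreeTable
    F: np.ndarray
    A_inv: sp.csr_matrix
    genotyped_ids: list
    genotyped_idx: np.ndarray
    A22: np.ndarray
    G_raw: np.ndarray
    G_star: np.ndarray
    G_b: np.ndarray
    scale_a: float
    scale_b: float
    tau: float
    freq_source: str
    h_inv: HInverse
    h_diag: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.h_diag is None:
            # diag(H): exact G_b diagonal for genotyped animals; 1 + F
            # for the rest (the H11 diagonal correction is negligible at
            # desk scale and this is the convention used for reliability).
            d = 1.0 + self.F
            d[self.genotyped_idx] = np.diag(self.G_b)
            self.h_diag = d


def single_step_relationships(
    ped: PedigreeTable,
    genos: GenotypeMatrix,
    freq_source: str = "pooled",
    tau: float = 0.95,
    scaling: str = "mean_matching",
) -> RelationshipSet:
    """One-call pipeline: A^-1, A22, G, scaled/blended G_b and H^-1.

    ``genos`` must already be QC-filtered.  Genotyped animals must all
    appear in the pedigree; the genomic pieces are ordered by the
    pedigree positions of the genotyped animals.
    """
    F = ped_mod.compute_inbreeding(ped)
    A_inv = ped_mod.build_A_inverse(ped, F)
    order = np.argsort(ped.indices_of(genos.ids))
    genos = genos.subset(animal_mask=order)
    gidx = ped.indices_of(genos.ids)
    A22 = ped_mod.extract_A22(ped, list(genos.ids), F=F)
    G_raw = build_G(genos, freq_source=freq_source)
    G_star, a, b = match_G_to_A22(G_raw, A22, mode=scaling)
    G_b = blend_G(G_star, A22, tau=tau)
    d_ms = ped_mod.mendelian_sampling_variance(ped, F)
    log_det_A = float(np.log(d_ms).sum())
    h_inv = build_H_inverse(A_inv, A22, G_b, gidx, log_det_A=log_det_A)
    return RelationshipSet(
        ped=ped,
        F=F,
        A_inv=A_inv,
        genotyped_ids=list(genos.ids),
        genotyped_idx=gidx,
        A22=A22,
        G_raw=G_raw,
        G_star=G_star,
        G_b=G_b,
        scale_a=a,
        scale_b=b,
        tau=tau,
        freq_source=freq_source,
        h_inv=h_inv,
    )
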