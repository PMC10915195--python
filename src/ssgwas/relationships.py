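"""Relationship matrices of the single-step method.

Builds Wright's numerator relationship matrix A from the pedigree (tabular
method), the genomic relationship matrix G22 = ZZ'/(2 sum p_j (1 - p_j))
among genotyped animals with 2p-centered allele-2 dosages, the scaled and
blended G* (diagonal/off-diagonal means matched to A22, then
G* = alpha G_scaled + beta A22), and the genomic-polygenic matrix H with its
inverse H^-1 = A^-1 + [0, 0; 0, tau G*^-1 - omega A22^-1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataError, GenotypeMatrix, PedigreeTable


@dataclass
class BlendParams:
    """Weights of the blending/scaling step; defaults are the customary
    single-step ones (tau=1, alpha=0.95, beta=0.05, gamma=delta=0, omega=1).
    gamma and delta are accepted but inert (reserved)."""

    tau: float = 1.0
    alpha: float = 0.95
    beta: float = 0.05
    gamma: float = 0.0
    delta: float = 0.0
    omega: float = 1.0

    def __post_init__(self):
        if self.alpha + self.beta > 1 + 1e-9:
            raise DataError("alpha + beta must not exceed 1")


def build_A(ped: PedigreeTable) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Processing animals in topological order,
    a_ij = 0.5 (a_{sire(i),j} + a_{dam(i),j}) for j < i and
    a_ii = 1 + 0.5 a_{sire(i),dam(i)}; unknown parents contribute zero.
    """
    n = len(ped)
    parents = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def build_G22(g: GenotypeMatrix, allele_freqs: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Genomic relationship matrix among the genotyped animals.

    Z carries allele-2 dosages centered by 2 p_j (codes 0/1/2 map to
    -2p, 1-2p, 2-2p); the divisor is 2 sum_j p_j (1 - p_j).  Frequencies
    default to the observed ones in the genotyped animals.  Returns
    (G22_raw, p).
    """
    if g.n_animals < 2:
        raise DataError("need at least two genotyped animals for G")
    codes = np.asarray(g.codes, dtype=float)
    if np.isnan(codes).any():
        raise DataError("genotypes must be imputed (no missing codes) before G")
    p = g.allele_frequencies() if allele_freqs is None else np.asarray(allele_freqs, float)
    s = 2.0 * float(np.sum(p * (1.0 - p)))
    if s <= 0.0:
        raise DataError("all markers are monomorphic; G divisor is zero")
    Z = codes - 2.0 * p
    G = (Z @ Z.T) / s
    return G, p


def center_Z(g: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    """The 2p-centered dosage matrix used for G and for SNP back-solving."""
    return np.asarray(g.codes, dtype=float) - 2.0 * np.asarray(p, dtype=float)


def scaling_divisor(p: np.ndarray) -> float:
    return 2.0 * float(np.sum(p * (1.0 - p)))


def blend_and_scale(G22_raw: np.ndarray, A22: np.ndarray,
                    params: BlendParams | None = None) -> np.ndarray:
    """Scale G to match A22's diagonal and off-diagonal means, then blend.

    The scaling G_scaled = a G + b J solves the 2x2 linear system that
    equates mean(diag) and mean(offdiag) with those of A22; the blend is
    G* = alpha G_scaled + beta A22.
    """
    params = params or BlendParams()
    G = np.asarray(G22_raw, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape or G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise DataError("G and A22 must be square and of equal size")
    n = G.shape[0]
    if n < 2:
        raise DataError("scaling needs at least two genotyped animals")
    off = ~np.eye(n, dtype=bool)
    gd, go = G.diagonal().mean(), G[off].mean()
    ad, ao = A22.diagonal().mean(), A22[off].mean()
    det = gd - go
    if abs(det) < 1e-12:
        raise DataError("G has equal diagonal and off-diagonal means; "
                        "scaling system is singular")
    a = (ad - ao) / det
    b = ad - a * gd
    G_scaled = a * G + b
    return params.alpha * G_scaled + params.beta * A22


@dataclass
class RelationshipSet:
    """All matrices of one single-step run, aligned to the pedigree order."""

    animal_ids: list[str]
    genotyped_ids: list[str]
    genotyped_idx: np.ndarray
    A: np.ndarray
    A22: np.ndarray
    G22_raw: np.ndarray | None
    G22_star: np.ndarray | None
    H: np.ndarray
    H_inverse: np.ndarray
    allele_freqs: np.ndarray | None
    divisor: float | None
    params: BlendParams = field(default_factory=BlendParams)


def _safe_inv(M: np.ndarray, name: str) -> np.ndarray:
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise DataError(f"{name} is numerically singular (condition number {cond:.3g})")
    return np.linalg.inv(M)


def build_H_inverse(A: np.ndarray, genotyped_idx: np.ndarray,
                    G22_star: np.ndarray | None,
                    params: BlendParams | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Dense H and H^-1 over the full pedigree.

    H^-1 adds tau G*^-1 - omega A22^-1 on the genotyped block of A^-1; the
    dense H comes from the textbook four-block formula
    [A11 + A12 A22^-1 (G - A22) A22^-1 A21,  A12 A22^-1 G;
     G A22^-1 A21,                           G].
    With no genotyped animals (or G* = A22) both reduce to A and A^-1.
    """
    params = params or BlendParams()
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    Ainv = _safe_inv(A, "A")
    gi = np.asarray(genotyped_idx, dtype=int)
    if gi.size == 0 or G22_star is None:
        return A.copy(), Ainv
    A22 = A[np.ix_(gi, gi)]
    A22inv = _safe_inv(A22, "A22")
    Gs = np.asarray(G22_star, dtype=float)
    Gsinv = _safe_inv(Gs, "G*")
    Hinv = Ainv.copy()
    Hinv[np.ix_(gi, gi)] += params.tau * Gsinv - params.omega * A22inv
    ngi = np.setdiff1d(np.arange(n), gi)
    H = np.empty_like(A)
    A12 = A[np.ix_(ngi, gi)]
    T = A12 @ A22inv
    H[np.ix_(ngi, ngi)] = A[np.ix_(ngi, ngi)] + T @ (Gs - A22) @ T.T
    H[np.ix_(ngi, gi)] = T @ Gs
    H[np.ix_(gi, ngi)] = H[np.ix_(ngi, gi)].T
    H[np.ix_(gi, gi)] = Gs
    return H, Hinv


def build_relationships(ped: PedigreeTable, genotypes: GenotypeMatrix | None = None,
                        params: BlendParams | None = None,
                        allele_freqs: np.ndarray | None = None) -> RelationshipSet:
    """One call from pedigree (+ optional genotypes) to the full set."""
    params = params or BlendParams()
    A = build_A(ped)
    if genotypes is None:
        n = len(ped)
        return RelationshipSet(list(ped.animals), [], np.empty(0, dtype=int), A,
                               np.empty((0, 0)), None, None, A.copy(),
                               _safe_inv(A, "A"), None, None, params)
    missing = [a for a in genotypes.animal_ids if a not in set(ped.animals)]
    if missing:
        raise DataError(f"genotyped animals absent from pedigree: {missing[:5]}")
    gi = np.array([ped.index_of(a) for a in genotypes.animal_ids], dtype=int)
    G_raw, p = build_G22(genotypes, allele_freqs)
    A22 = A[np.ix_(gi, gi)]
    G_star = blend_and_scale(G_raw, A22, params)
    H, Hinv = build_H_inverse(A, gi, G_star, params)
    return RelationshipSet(list(ped.animals), list(genotypes.animal_ids), gi, A,
                           A22, G_raw, G_star, H, Hinv, p, scaling_divisor(p), params)


def matrix_to_frame(M: np.ndarray, ids: list[str]) -> pd.DataFrame:
    """Dense matrix with row/column ids, for the debug TSV dumps."""
    df = pd.DataFrame(M, columns=ids)
    df.insert(0, "animal", ids)
    return df
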