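"""Pedigree and genomic relationship algebra.

Implements the numerator relationship matrix A by the tabular method,
inbreeding coefficients, Henderson's direct rules for A^-1 (with
inbreeding-adjusted Mendelian-sampling variances), the VanRaden genomic
relationship matrix G = M M' / (2 sum p_k (1 - p_k)) with columns centered
by 2 p_k, convex G/A22 blending, and the single-step H matrix in both its
explicit four-block form and its sparse-friendly inverse form

    H^-1 = A^-1 + [0 0; 0  G^-1 - A22^-1]

where block 2 indexes the genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

UNKNOWN = "0"


def topological_order(ped: pd.DataFrame) -> pd.DataFrame:
    """Reorder the pedigree so every parent precedes its offspring; raise on cycles."""
    ids = list(ped["animal"])
    idx = {a: i for i, a in enumerate(ids)}
    if len(idx) != len(ids):
        raise ValueError("duplicated animal in pedigree")
    placed = [False] * len(ids)
    order = []
    remaining = set(range(len(ids)))
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    while remaining:
        progressed = False
        for i in sorted(remaining):
            ok = True
            for p in (sires[i], dams[i]):
                if p != UNKNOWN and p in idx and not placed[idx[p]]:
                    ok = False
                    break
            if ok:
                order.append(i)
                placed[i] = True
                remaining.discard(i)
                progressed = True
        if not progressed:
            raise ValueError("pedigree contains a cycle")
    return ped.iloc[order].reset_index(drop=True)


def _parent_indices(ped: pd.DataFrame):
    idx = {a: i for i, a in enumerate(ped["animal"])}
    n = len(ped)
    si = np.full(n, -1, dtype=int)
    di = np.full(n, -1, dtype=int)
    for i, (s, d) in enumerate(zip(ped["sire"], ped["dam"])):
        if s != UNKNOWN:
            si[i] = idx.get(s, -1)
        if d != UNKNOWN:
            di[i] = idx.get(d, -1)
    return si, di


def a_matrix(ped: pd.DataFrame):
    """Numerator relationship matrix by the tabular method.

    Returns (A, animal_ids) with animals in topological order.  A parent
    referenced but absent from the table is treated as unknown (founder).
    """
    ped = topological_order(ped)
    si, di = _parent_indices(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        if s >= 0 and d >= 0:
            if i > 0:
                A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            if i > 0:
                A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A, list(ped["animal"])


def inbreeding(ped: pd.DataFrame):
    """Per-animal inbreeding coefficients F (diag(A) - 1). Returns (F, ids)."""
    A, ids = a_matrix(ped)
    return np.diag(A) - 1.0, ids


def a_inverse(ped: pd.DataFrame):
    """A^-1 by Henderson's rules with inbreeding-adjusted Mendelian variances.

    Returns (A_inv, animal_ids) in the same topological order as a_matrix.
    """
    ped = topological_order(ped)
    F, ids = inbreeding(ped)
    si, di = _parent_indices(ped)
    n = len(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        if s >= 0 and d >= 0:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            dvar = 0.75 - 0.25 * F[p]
        else:
            dvar = 1.0
        alpha = 1.0 / dvar
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2.0
                Ainv[p, i] -= alpha / 2.0
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += alpha / 4.0
    return Ainv, ids


def a22(A: np.ndarray, ids, genotyped_ids):
    """Sub-block of A restricted to the genotyped animals (in genotyped_ids order)."""
    pos = {a: i for i, a in enumerate(ids)}
    gi = np.array([pos[a] for a in genotyped_ids])
    return A[np.ix_(gi, gi)]


def vanraden_g(dosages: np.ndarray, freqs=None) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Columns of the dosage matrix are centered by twice the coded-allele
    frequency and the cross-product is scaled by 2 sum p_k (1 - p_k).  If
    ``freqs`` is None the frequencies are the observed column means / 2
    (centering is invariant to which allele is coded).
    """
    M = np.asarray(dosages, dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing dosages; impute before building G")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        j = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        raise ValueError(f"monomorphic SNP at column {j} (p in {{0,1}}); remove in QC")
    Z = M - 2.0 * p[None, :]
    denom = 2.0 * float((p * (1 - p)).sum())
    G = Z @ Z.T / denom
    return (G + G.T) / 2.0


def blend_g(G_raw: np.ndarray, A22_mat: np.ndarray, weight: float = 0.05) -> np.ndarray:
    """G_blend = (1 - w) G + w A22; w > 0 guarantees invertibility when A22 is PD."""
    if not (0 <= weight < 1):
        raise ValueError("blending weight must be in [0, 1)")
    if G_raw.shape != A22_mat.shape:
        raise ValueError("shape mismatch between G and A22")
    return (1 - weight) * G_raw + weight * A22_mat


def _spd_inverse(M: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(M)
        return linalg.cho_solve((c, low), np.eye(M.shape[0]))
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"{what} is singular or not positive definite; "
            "use a blending weight > 0"
        ) from err


def h_inverse(A_inv: np.ndarray, G_blend: np.ndarray, A22_mat: np.ndarray,
              genotyped_idx) -> np.ndarray:
    """H^-1 = A^-1 + (G^-1 - A22^-1) on the genotyped block.

    ``genotyped_idx`` gives the positions of the genotyped animals in the
    global animal ordering of A_inv, aligned with the rows of G_blend/A22.
    """
    gi = np.asarray(genotyped_idx, dtype=int)
    H_inv = A_inv.copy()
    if gi.size:
        Ginv = _spd_inverse(G_blend, "blended G")
        A22inv = _spd_inverse(A22_mat, "A22")
        H_inv[np.ix_(gi, gi)] += Ginv - A22inv
    return (H_inv + H_inv.T) / 2.0


def h_matrix_explicit(A: np.ndarray, G_blend: np.ndarray, ids, genotyped_ids) -> np.ndarray:
    """Explicit H from its four-block definition.

    With 1 = non-genotyped, 2 = genotyped:
        H11 = A11 - A12 A22^-1 A21 + A12 A22^-1 G A22^-1 A21
        H12 = A12 A22^-1 G ;  H21 = H12' ;  H22 = G
    Returned in the ordering of ``ids``.
    """
    pos = {a: i for i, a in enumerate(ids)}
    gi = np.array([pos[a] for a in genotyped_ids], dtype=int)
    if gi.size == 0:
        return A.copy()
    ni = np.array([i for i in range(len(ids)) if i not in set(gi)], dtype=int)
    A22_mat = A[np.ix_(gi, gi)]
    A22inv = _spd_inverse(A22_mat, "A22")
    H = np.zeros_like(A)
    H[np.ix_(gi, gi)] = G_blend
    if ni.size:
        A12 = A[np.ix_(ni, gi)]
        P = A12 @ A22inv                       # A12 A22^-1
        H[np.ix_(ni, ni)] = A[np.ix_(ni, ni)] - P @ A12.T + P @ G_blend @ P.T
        H12 = P @ G_blend
        H[np.ix_(ni, gi)] = H12
        H[np.ix_(gi, ni)] = H12.T
    return (H + H.T) / 2.0


@dataclass
class RelationshipSet:
    """All relationship matrices for one evaluation, on one animal ordering."""

    ids: list
    genotyped_ids: list
    A: np.ndarray
    F: np.ndarray
    A_inv: np.ndarray
    A22: np.ndarray
    G_raw: np.ndarray
    G_blend: np.ndarray
    H_inv: np.ndarray

    def genotyped_positions(self) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        return np.array([pos[a] for a in self.genotyped_ids], dtype=int)


def build_relationships(ped: pd.DataFrame, dosages: np.ndarray, genotyped_ids,
                        blend_weight: float = 0.05, freqs=None) -> RelationshipSet:
    """Assemble A, A^-1, A22, G and H^-1 for a pedigree plus a genotyped subset.

    ``dosages`` rows must align with ``genotyped_ids``.  Allele frequencies
    for G-centering default to the observed combined genotyped pool.
    """
    A, ids = a_matrix(ped)
    A_inv, _ = a_inverse(ped)
    A22_mat = a22(A, ids, genotyped_ids)
    G_raw = vanraden_g(dosages, freqs)
    Gb = blend_g(G_raw, A22_mat, blend_weight)
    pos = {a: i for i, a in enumerate(ids)}
    gi = np.array([pos[a] for a in genotyped_ids], dtype=int)
    H_inv = h_inverse(A_inv, Gb, A22_mat, gi)
    return RelationshipSet(ids=ids, genotyped_ids=list(genotyped_ids), A=A,
                           F=np.diag(A) - 1.0, A_inv=A_inv, A22=A22_mat,
                           G_raw=G_raw, G_blend=Gb, H_inv=H_inv)


def export_matrix_tsv(M: np.ndarray, ids, path, triplet: bool = True) -> None:
    """Write a matrix as (row_id, col_id, value) triplets or as dense CSV."""
    if triplet:
        rows = []
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if j >= i:
                    rows.append((a, b, M[i, j]))
        pd.DataFrame(rows, columns=["row_id", "col_id", "value"]).to_csv(
            path, sep="\t", index=False)
    else:
        pd.DataFrame(M, index=ids, columns=ids).to_csv(path)
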