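"""Pedigree (A) and genomic (G) relationship matrices.

A is built by the tabular method and inverted via the classic
Henderson/Quaas rules (which account for parental inbreeding through the
Mendelian-sampling variance); G follows VanRaden's first method,
G = Z Z' / sum_j 2 p_j (1 - p_j) with Z the 2p-centered genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popsim import Pedigree


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str                      # "numerator" | "genomic"
    inbreeding: np.ndarray | None = None   # F_i, numerator kind only

    @property
    def n(self) -> int:
        return self.values.shape[0]


def numerator_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + A(sire, dam)/2; A_ij = (A(j, sire_i) + A(j, dam_i))/2 for
    earlier j, with unknown parents contributing zero.
    """
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(A, "numerator", np.diag(A) - 1.0)


def numerator_relationship_inverse(pedigree: Pedigree,
                                   inbreeding: np.ndarray | None = None) -> np.ndarray:
    """A^-1 assembled directly from the pedigree (Henderson's rules with
    inbreeding via the Mendelian-sampling variance d_i)."""
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    if inbreeding is None:
        inbreeding = numerator_relationship(pedigree).inbreeding
    F = np.concatenate([inbreeding, [0.0]])  # F[-1] reads as 0 for unknown
    Ainv = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        n_known = (si >= 0) + (di >= 0)
        di_var = 1.0 - 0.25 * ((1 + F[si]) if si >= 0 else 0.0) \
                     - 0.25 * ((1 + F[di]) if di >= 0 else 0.0)
        w = 1.0 / di_var
        Ainv[i, i] += w
        for p in (si, di):
            if p >= 0:
                Ainv[i, p] -= 0.5 * w
                Ainv[p, i] -= 0.5 * w
        for p in (si, di):
            for q in (si, di):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += 0.25 * w
    return Ainv


def genomic_relationship(X: np.ndarray, allele_freqs: np.ndarray | None = None,
                         ridge: float = 1e-6) -> RelationshipMatrix:
    """VanRaden method-1 G from a 0/1/2 genotype matrix.

    Frequencies default to those observed in ``X``; a small ridge keeps G
    invertible when individuals outnumber the matrix rank.
    """
    X = np.asarray(X, dtype=float)
    if allele_freqs is None:
        p = X.mean(axis=0) / 2.0
    else:
        p = np.asarray(allele_freqs, dtype=float)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all SNPs monomorphic: G denominator is zero")
    Z = X - 2.0 * p
    G = (Z @ Z.T) / denom
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return RelationshipMatrix(G, "genomic")
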