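"""Pedigree (numerator) and genomic relationship matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wgspred.errors import DegenerateInputError, IntegrityError
from wgspred.simpop import GenotypeMatrix, Pedigree


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered id list."""

    individual_ids: np.ndarray
    values: np.ndarray
    kind: str  # "pedigree_A" | "genomic_K"

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise IntegrityError("relationship matrix shape mismatch")

    def index_of(self, ids) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        return np.array([pos[i] for i in ids], dtype=np.int64)

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.values[np.ix_(idx, idx)]


def pedigree_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    a(i, j) = (a(sire_i, j) + a(dam_i, j)) / 2 for j preceding i, and
    a(i, i) = 1 + a(sire_i, dam_i) / 2; unknown parents contribute 0.
    """
    pedigree.validate()
    n = pedigree.n
    sire, dam = pedigree.parent_indices()
    order = np.argsort(
        pedigree.table["generation"].to_numpy(), kind="stable"
    )
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    if ((sire >= 0) & (rank[sire] >= rank)).any() or (
        (dam >= 0) & (rank[dam] >= rank)
    ).any():  # pragma: no cover - validate() already rejects this
        raise IntegrityError("pedigree is not parent-before-child orderable")

    A = np.zeros((n, n))
    for r in range(n):
        i = order[r]
        prev = order[:r]
        s, d = sire[i], dam[i]
        row = np.zeros(r)
        if s >= 0:
            row += A[s, prev]
        if d >= 0:
            row += A[d, prev]
        row *= 0.5
        A[i, prev] = row
        A[prev, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(pedigree.ids.copy(), A, kind="pedigree_A")


def genomic_K(
    genotypes: GenotypeMatrix, variant_mask: np.ndarray | None = None
) -> RelationshipMatrix:
    """Genomic relationship matrix (VanRaden method 1, observed frequencies).

    K = Z Z' / c with Z the dosage matrix centered by twice the observed
    allele frequency and c = sum of 2 p (1 - p) over masked variants.
    Missing dosages are mean-imputed per variant before centering.
    """
    dosages = genotypes.dosages
    if variant_mask is not None:
        dosages = dosages[:, np.asarray(variant_mask)]
    dosages = np.asarray(dosages, dtype=np.float64)
    col_mean = np.nanmean(dosages, axis=0)
    if np.isnan(dosages).any():
        dosages = np.where(np.isnan(dosages), col_mean[None, :], dosages)
    p = col_mean / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0.0:
        raise DegenerateInputError(
            "all masked variants are monomorphic; K undefined"
        )
    Z = dosages - 2.0 * p
    K = (Z @ Z.T) / c
    K = (K + K.T) / 2.0  # exact symmetry despite BLAS rounding
    return RelationshipMatrix(
        genotypes.individual_ids.copy(), K, kind="genomic_K"
    )
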