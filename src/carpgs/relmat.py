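"""Additive relationship matrices: pedigree numerator A and genomic G.

A is built by the tabular method (diagonal 1 + F); G by VanRaden's first
method, G = ZZ' / (2 * sum p_j (1 - p_j)) with Z the dosage matrix centered
by twice the allele frequency and missing dosages mean-imputed per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree


@dataclass
class RelationshipMatrix:
    """Dense symmetric additive relationship matrix with an id index."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # "pedigree_A" | "genomic_G"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.values.shape != (self.ids.size, self.ids.size):
            raise ValueError("relationship matrix shape does not match id index")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.ids.size

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in relationship matrix") from None

    def subset(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], np.asarray(ids, dtype=object),
                                  self.kind, dict(self.provenance))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "genomic_G") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(dtype=object), kind)


def pedigree_numerator_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    Individuals are processed parents-before-offspring; unknown parents
    contribute zero relationship.  Diagonals are 1 + F (half the parents'
    relationship); the result's index follows the pedigree table order.
    """
    order = pedigree.topological_order()  # raises on cycles
    ped = pedigree.table
    ids = pedigree.ids
    pos_sorted = {ped["id"].iloc[i]: k for k, i in enumerate(order)}
    n = len(ids)
    a = np.zeros((n, n))
    sire_k = np.full(n, -1)
    dam_k = np.full(n, -1)
    for k, i in enumerate(order):
        s, d = ped["sire"].iloc[i], ped["dam"].iloc[i]
        sire_k[k] = pos_sorted.get(s, -1) if s != UNKNOWN else -1
        dam_k[k] = pos_sorted.get(d, -1) if d != UNKNOWN else -1

    for k in range(n):
        s, d = sire_k[k], dam_k[k]
        a_sd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[k, k] = 1.0 + 0.5 * a_sd
        if k:
            contrib = np.zeros(k)
            if s >= 0:
                contrib += a[:k, s]
            if d >= 0:
                contrib += a[:k, d]
            a[:k, k] = a[k, :k] = 0.5 * contrib

    # back to pedigree table order
    perm = np.array([pos_sorted[i] for i in ids])
    a = a[np.ix_(perm, perm)]
    return RelationshipMatrix(a, ids, "pedigree_A")


def vanraden_grm(g: GenotypeMatrix, freqs="observed") -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``freqs`` is either "observed" (allele frequencies computed from all
    genotyped animals in ``g``) or a per-locus frequency array of the
    counted allele.  Missing dosages are mean-imputed (2p per locus), which
    zeroes their centered contribution; monomorphic loci add nothing to
    numerator or denominator.
    """
    d = g.dosage_float()
    if isinstance(freqs, str):
        if freqs != "observed":
            raise ValueError("freqs must be 'observed' or an array")
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (g.n_loci,):
            raise ValueError("frequency array length does not match loci")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all loci monomorphic: VanRaden denominator is zero")
    z = d - 2.0 * p
    z[np.isnan(z)] = 0.0  # mean imputation
    values = (z @ z.T) / denom
    values = (values + values.T) / 2.0
    return RelationshipMatrix(values, g.samples.copy(), "genomic_G",
                              provenance={"freqs": "observed" if isinstance(freqs, str) else "supplied",
                                          "n_markers": g.n_loci})


def condition_matrix(m: RelationshipMatrix, alpha: float = 0.01) -> RelationshipMatrix:
    """Blend with the identity, G* = (1 - alpha) G + alpha I.

    Guarantees positive definiteness (hence invertibility in the mixed-model
    equations) whenever the input is positive semidefinite and alpha > 0.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if alpha == 0:
        return m
    values = (1.0 - alpha) * m.values + alpha * np.eye(m.n)
    prov = dict(m.provenance)
    prov["blend_alpha"] = alpha
    return RelationshipMatrix(values, m.ids.copy(), m.kind, prov)
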