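"""Pedigree (NRM) and genomic (GRM) relationship matrices.

The numerator relationship matrix is built by the tabular method; the
genomic relationship matrix follows VanRaden's first method,
G = ZZ' / (2 * sum_i p_i (1 - p_i)) with Z the allele dosages centred at
twice the allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import UNKNOWN

__all__ = ["RelationshipMatrix", "build_nrm", "build_grm", "nrm_inverse"]


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str                       # "NRM" | "GRM"
    freqs: np.ndarray | None = None
    diagonal_boost: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def stabilized(self, boost: float = 0.01) -> "RelationshipMatrix":
        """Copy with `boost` added to the diagonal (guards inversion when
        near-identical genotypes make G singular)."""
        v = self.values.copy()
        v[np.diag_indices_from(v)] += boost
        return RelationshipMatrix(values=v, kind=self.kind, freqs=self.freqs,
                                  diagonal_boost=self.diagonal_boost + boost)

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.tril_indices(self.n)
        return pd.DataFrame({"i": i, "j": j, "value": self.values[i, j]})


def build_nrm(sire: np.ndarray, dam: np.ndarray) -> RelationshipMatrix:
    """Tabular-method NRM; parents must precede offspring (UNKNOWN = founder)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = sire.shape[0]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN and p >= i:
                raise ValueError(f"individual {i} listed before parent {p}")
    # row/col n is a zero-filled slot standing in for unknown parents
    A = np.zeros((n + 1, n + 1))
    s = np.where(sire == UNKNOWN, n, sire)
    d = np.where(dam == UNKNOWN, n, dam)
    for i in range(n):
        A[i, :i] = A[:i, i] = 0.5 * (A[s[i], :i] + A[d[i], :i])
        A[i, i] = 1.0 + 0.5 * A[s[i], d[i]]
    return RelationshipMatrix(values=A[:n, :n], kind="NRM")


def build_grm(dosages: np.ndarray,
              freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden method-1 GRM from an (individuals x SNPs) dosage matrix.

    Frequencies default to those observed in the genotyped set itself.
    Monomorphic loci contribute nothing to Z but would also not contribute to
    the denominator; an all-monomorphic panel is an error.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    if freqs is None:
        freqs = dosages.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=np.float64)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("SNP panel is monomorphic: GRM denominator is zero")
    Z = dosages - 2.0 * freqs
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(values=G, kind="GRM", freqs=freqs)


def nrm_inverse(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """A-inverse by Henderson's rules with inbreeding.

    Uses Mendelian-sampling variances from the tabular A diagonal; kept dense
    (population sizes here stay in the low thousands).
    """
    A = build_nrm(sire, dam).values
    F = np.diag(A) - 1.0
    n = A.shape[0]
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        # Mendelian sampling variance: 1 - 0.25(1+Fs) - 0.25(1+Fd), with the
        # 0.25 terms dropped for unknown parents
        m = 1.0
        if s != UNKNOWN:
            m -= 0.25 * (1.0 + F[s])
        if d != UNKNOWN:
            m -= 0.25 * (1.0 + F[d])
        k = 1.0 / m
        Ainv[i, i] += k
        for p in (s, d):
            if p != UNKNOWN:
                Ainv[i, p] -= 0.5 * k
                Ainv[p, i] -= 0.5 * k
        for p in (s, d):
            for q in (s, d):
                if p != UNKNOWN and q != UNKNOWN:
                    Ainv[p, q] += 0.25 * k
    return Ainv
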