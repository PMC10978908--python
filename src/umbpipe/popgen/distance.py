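"""Kimura 2-parameter distances over concatenated SNP pseudo-sequences."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..snpcall import MISSING, GenotypeMatrix

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(base_a: str, base_b: str) -> bool:
    return (base_a in _PURINES and base_b in _PURINES) or (
        base_a in _PYRIMIDINES and base_b in _PYRIMIDINES
    )


def k2p_from_proportions(p: float, q: float) -> float:
    """Kimura 2-parameter distance from transition (p) and transversion (q)
    proportions:

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    Returns NaN for saturated pairs (non-positive log arguments).
    """
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return math.nan
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    model: str = "K2P"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        sym = finite & finite.T
        if not np.allclose(self.values[sym], self.values.T[sym], atol=1e-12):
            raise ValueError("matrix must be symmetric within 1e-12")

    @property
    def complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out


def k2p_distance(
    matrix: GenotypeMatrix, loci_idx: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise K2P distances between accessions from a genotype matrix.

    For each accession pair the concatenated SNP-allele pseudo-sequence is
    restricted to loci observed in both; the transition/transversion class
    of a disagreeing locus is fixed by its ref/alt base pair.  Pairs with
    no shared loci or with saturated distances are NaN (reported absent).
    """
    calls = matrix.calls
    loci = matrix.loci
    if loci_idx is not None:
        calls = calls[loci_idx]
        loci = [loci[i] for i in np.asarray(loci_idx)]
    ts = np.array([is_transition(ref, alt) for (_t, _p, ref, alt) in loci])
    obs = calls != MISSING
    n = calls.shape[1]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[:, i] & obs[:, j]
            m = int(shared.sum())
            if m == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            diff = shared & (calls[:, i] != calls[:, j])
            p = float((diff & ts).sum()) / m
            q = float((diff & ~ts).sum()) / m
            d = k2p_from_proportions(p, q)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(matrix.accessions), values, model="K2P")
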