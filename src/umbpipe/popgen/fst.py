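"""Weir–Cockerham F_ST variance-components estimator for haploid-coded data.

With one allele copy per accession the ANOVA has two strata: among
populations and among copies within populations.  Per locus with ``r``
populations, ``n_i`` observed copies in population ``i`` (total ``n``) and
alternative-allele frequencies ``p_i``:

    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
    MSG = sum_i n_i p_i (1 - p_i) / (n - r)
    n_c = (n - sum_i n_i^2 / n) / (r - 1)

    a = (MSP - MSG) / n_c        (among-population component)
    b = MSG                      (within-population component)

The multi-locus estimate is sum(a) / sum(a + b) over loci.  Populations
fixed for alternate alleles at every locus give exactly 1.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..snpcall import MISSING, GenotypeMatrix
from .admixture import LineageAssignment


def _groups_from_assignment(
    matrix: GenotypeMatrix, assignment: LineageAssignment | Mapping[str, object]
) -> dict[object, list[int]]:
    labels = (
        assignment.assigned()
        if isinstance(assignment, LineageAssignment)
        else {a: g for a, g in assignment.items() if g is not None}
    )
    groups: dict[object, list[int]] = {}
    col = {acc: j for j, acc in enumerate(matrix.accessions)}
    for acc, lineage in labels.items():
        if acc in col:
            groups.setdefault(lineage, []).append(col[acc])
    return groups


def _pair_components(
    calls: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (a, a+b) variance components for one population pair."""
    r = 2
    sums_a = np.empty(calls.shape[0])
    parts = []
    for idx in (idx_a, idx_b):
        sub = calls[:, idx]
        obs = sub != MISSING
        n_i = obs.sum(axis=1).astype(float)
        alt = ((sub == 1) & obs).sum(axis=1).astype(float)
        parts.append((n_i, alt))
    n1, alt1 = parts[0]
    n2, alt2 = parts[1]
    n = n1 + n2
    valid = (n1 >= 1) & (n2 >= 1) & (n > r)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, alt1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, alt2 / np.maximum(n2, 1), 0.0)
        pbar = (alt1 + alt2) / np.maximum(n, 1)
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / np.maximum(n - r, 1)
        nc = (n - (n1**2 + n2**2) / np.maximum(n, 1)) / (r - 1)
        a = np.where(valid & (nc > 0), (msp - msg) / np.maximum(nc, 1e-300), 0.0)
        b = np.where(valid, msg, 0.0)
    a[~valid] = 0.0
    return a, a + b


def fst_weir_cockerham(
    matrix: GenotypeMatrix,
    assignment: LineageAssignment | Mapping[str, object],
) -> pd.DataFrame:
    """Pairwise multi-locus Weir–Cockerham F_ST over assigned groups.

    Unassigned accessions are excluded.  Pairs whose shared loci are all
    monomorphic have an undefined estimate and come back as NaN.
    Returns a table with columns ``pop_a``, ``pop_b``, ``fst``, ``n_loci``.
    """
    groups = _groups_from_assignment(matrix, assignment)
    names = sorted(groups, key=str)
    if len(names) < 2:
        raise ValueError("need at least two assigned groups")
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 accessions")
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            a, denom = _pair_components(matrix.calls, groups[ga], groups[gb])
            informative = denom != 0
            total = denom[informative].sum()
            fst = float(a[informative].sum() / total) if total > 0 else np.nan
            rows.append(
                {
                    "pop_a": ga,
                    "pop_b": gb,
                    "fst": fst,
                    "n_loci": int(informative.sum()),
                }
            )
    return pd.DataFrame(rows)
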