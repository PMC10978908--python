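"""Gibbs-sampled admixture model, K selection, run alignment, and lineage calls.

The model is the classic admixture model with independent (uncorrelated)
cluster allele frequencies: per accession ``i`` a membership simplex
``q_i`` (symmetric Dirichlet prior), per cluster/locus an allele frequency
``p_kl`` (Beta(1,1) prior), and per observed allele copy a latent origin
indicator ``z_il``.  Accessions are haploid-coded (one allele copy per
locus), consistent with homozygous-only calling in a selfing species.

The log marginal likelihood for a run, ln P(X|K), is estimated from the
recorded log-likelihood trace as mean(lnL) - var(lnL)/2, the estimator
documented for the standard clustering tool this module re-implements.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..snpcall import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QMatrix:
    """Accession x K membership proportions with a log-likelihood trace."""

    memberships: np.ndarray  # (n_accessions, K)
    accessions: list[str]
    K: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    def __post_init__(self):
        self.memberships = np.asarray(self.memberships, dtype=float)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.memberships.shape != (len(self.accessions), self.K):
            raise ValueError("membership shape does not match accessions x K")
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("membership rows must sum to 1 within 1e-6")

    def ln_p_x_k(self) -> float:
        """Estimate ln P(X|K) as mean(lnL) - var(lnL)/2 over the trace."""
        trace = self.loglik_trace
        if trace.size == 0:
            raise ValueError("empty log-likelihood trace")
        return float(trace.mean() - trace.var() / 2.0)


@dataclass
class StructureRunSet:
    """Replicate runs for one K with their ln P(X|K) estimates."""

    K: int
    runs: list[QMatrix]
    lnpk: list[float]

    def __post_init__(self):
        if any(run.K != self.K for run in self.runs):
            raise ValueError("all runs in a set must share K")
        if len(self.lnpk) != len(self.runs):
            raise ValueError("one lnPK per run required")


def _genotypes(matrix: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, GenotypeMatrix):
        g = matrix.calls.T.astype(np.int8)  # accessions x loci
        return g, list(matrix.accessions)
    g = np.asarray(matrix, dtype=np.int8)
    return g, [f"acc{i}" for i in range(g.shape[0])]


def admixture_gibbs(
    matrix: GenotypeMatrix | np.ndarray,
    K: int,
    n_sweeps: int = 2000,
    burnin: int = 500,
    thin: int = 1,
    alpha: float = 1.0,
    seed: int | None = None,
) -> QMatrix:
    """Run the Gibbs sampler and return posterior-mean memberships.

    ``matrix`` is a biallelic haploid-coded genotype matrix (or a raw
    accessions x loci array coded 0/1 with -1 missing); missing cells are
    skipped in the likelihood.  ``n_sweeps`` counts total sweeps including
    ``burnin``; every ``thin``-th post-burn-in sweep is recorded.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 <= burnin < n_sweeps:
        raise ValueError("need 0 <= burnin < n_sweeps")
    g, accessions = _genotypes(matrix)
    n, L = g.shape
    obs = g != MISSING
    poly = np.array(
        [len(np.unique(g[obs[:, l], l])) > 1 for l in range(L)]
    )
    if L == 0 or not poly.any():
        raise ValueError("genotype matrix has zero polymorphic loci")

    rng = np.random.default_rng(seed)
    # (n, L, K) layout keeps the per-cell cluster scan on the contiguous axis
    gf = (g == 1).astype(np.float32)[:, :, None]  # (n, L, 1); masked via obs
    is_alt = (g == 1) & obs

    q = np.full((n, K), 1.0 / K, dtype=np.float32)
    # seed cluster frequencies from mutually distant accessions (smoothed,
    # farthest-point greedy); the posterior is unchanged but merged-cluster
    # modes are rarely visited
    if K <= n:
        seeds = [int(rng.integers(n))]
        while len(seeds) < K:
            dmin = np.full(n, np.inf)
            for s in seeds:
                shared = obs & obs[s]
                diff = ((g != g[s]) & shared).sum(axis=1)
                with np.errstate(invalid="ignore"):
                    dmin = np.minimum(
                        dmin, diff / np.maximum(shared.sum(axis=1), 1)
                    )
            dmin[seeds] = -1.0
            seeds.append(int(np.argmax(dmin + 1e-6 * rng.random(n))))
        p = np.where(g[seeds].T == 1, 0.75, 0.25).astype(np.float32)  # (L, K)
        p[~obs[seeds].T] = 0.5
    else:
        p = rng.uniform(0.2, 0.8, size=(L, K)).astype(np.float32)

    keep = np.zeros((n, K))
    n_kept = 0
    trace: list[float] = []
    n_tot = np.empty((L, K))
    n_alt = np.empty((L, K))
    c = np.empty((n, K))
    for sweep in range(n_sweeps):
        record = sweep >= burnin and (sweep - burnin) % thin == 0
        # per-cell joint weight of each cluster: q * (p if alt else 1-p)
        w = (1.0 - p)[None, :, :] + gf * (2.0 * p - 1.0)[None, :, :]
        w *= q[:, None, :]  # (n, L, K)
        np.cumsum(w, axis=2, out=w)
        wsum = w[:, :, -1]  # (n, L)
        if record:
            with np.errstate(divide="ignore"):
                ll = np.log(np.maximum(wsum[obs], 1e-30), dtype=float)
            trace.append(float(ll.sum()))
        # sample origin indicators z by inverse CDF over the cumulative weights
        u = (rng.random((n, L), dtype=np.float32) * wsum)[:, :, None]
        z = (w < u).sum(axis=2)  # (n, L) in [0, K)
        for k in range(K):
            mask = z == k
            mask &= obs
            n_tot[:, k] = mask.sum(axis=0)
            n_alt[:, k] = (mask & is_alt).sum(axis=0)
            c[:, k] = mask.sum(axis=1)
        # cluster allele frequencies, Beta(1,1) prior
        p = rng.beta(1.0 + n_alt, 1.0 + n_tot - n_alt).astype(np.float32)
        # memberships, Dirichlet(alpha) prior
        gam = rng.gamma(alpha + c)
        q = (gam / gam.sum(axis=1, keepdims=True)).astype(np.float32)
        if record:
            keep += q
            n_kept += 1
    memberships = keep / n_kept
    memberships /= memberships.sum(axis=1, keepdims=True)
    return QMatrix(memberships, accessions, K, np.array(trace), seed=seed)


def run_structure(
    matrix: GenotypeMatrix | np.ndarray,
    k_values: Sequence[int],
    n_runs: int = 10,
    n_sweeps: int = 2000,
    burnin: int = 500,
    thin: int = 1,
    alpha: float = 1.0,
    seed: int | None = None,
) -> dict[int, StructureRunSet]:
    """Replicate :func:`admixture_gibbs` over a K range; one run-set per K."""
    ss = np.random.SeedSequence(seed)
    out: dict[int, StructureRunSet] = {}
    for K in k_values:
        runs: list[QMatrix] = []
        for child in ss.spawn(n_runs):
            run_seed = int(child.generate_state(1)[0])
            runs.append(
                admixture_gibbs(
                    matrix, K, n_sweeps=n_sweeps, burnin=burnin, thin=thin,
                    alpha=alpha, seed=run_seed,
                )
            )
        out[K] = StructureRunSet(K, runs, [r.ln_p_x_k() for r in runs])
    return out


def evanno_delta_k(runsets: Mapping[int, StructureRunSet]) -> pd.DataFrame:
    """Second-difference statistic of ln P(X|K) across K.

    Returns a table indexed by K with columns ``mean_lnpk``, ``sd_lnpk``
    and ``delta_k``; the endpoints of the K range have no defined delta_k
    (NaN).  Requires at least three consecutive K values with >= 2 runs
    each (for the between-run standard deviation).
    """
    ks = sorted(runsets)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    lnpk = {k: np.asarray(runsets[k].lnpk, dtype=float) for k in ks}
    if any(v.size < 2 for v in lnpk.values()):
        raise ValueError("need >= 2 runs per K for the sd")
    rows = []
    for k in ks:
        mean = lnpk[k].mean()
        sd = lnpk[k].std(ddof=1)
        delta = np.nan
        if k - 1 in lnpk and k + 1 in lnpk:
            lo, mid, hi = lnpk[k - 1], lnpk[k], lnpk[k + 1]
            if lo.size == mid.size == hi.size:
                second = np.abs(hi - 2.0 * mid + lo).mean()
            else:  # unequal run counts: fall back to means
                second = abs(hi.mean() - 2.0 * mid.mean() + lo.mean())
            if sd == 0:
                warnings.warn(f"zero sd of lnPK at K={k}; delta_k is infinite")
                delta = np.inf
            else:
                delta = second / sd
        rows.append({"K": k, "mean_lnpk": mean, "sd_lnpk": sd, "delta_k": delta})
    return pd.DataFrame(rows).set_index("K")


def align_runs(runs: Sequence[QMatrix | np.ndarray]) -> QMatrix:
    """Align replicate runs by cluster-label permutation and average them.

    Each run's columns are permuted to minimize the Frobenius distance to
    the first run (exhaustive over K! permutations, bounded at K <= 6);
    the consensus is the element-wise mean, renormalized per row.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    mats = [
        r.memberships if isinstance(r, QMatrix) else np.asarray(r, dtype=float)
        for r in runs
    ]
    K = mats[0].shape[1]
    if any(m.shape != mats[0].shape for m in mats):
        raise ValueError("all runs must share data dimensions")
    if K > 6:
        raise ValueError(
            "exhaustive label alignment is bounded at K <= 6; use a heuristic "
            "aligner for larger K"
        )
    ref = mats[0]
    total = ref.copy()
    for m in mats[1:]:
        best_perm = min(
            itertools.permutations(range(K)),
            key=lambda perm: float(((m[:, perm] - ref) ** 2).sum()),
        )
        total += m[:, best_perm]
    consensus = total / len(mats)
    consensus /= consensus.sum(axis=1, keepdims=True)
    accessions = (
        list(runs[0].accessions)
        if isinstance(runs[0], QMatrix)
        else [f"acc{i}" for i in range(ref.shape[0])]
    )
    return QMatrix(consensus, accessions, K)


@dataclass
class LineageAssignment:
    """Accession -> cluster index (or None for intermediates)."""

    labels: dict[str, int | None]
    threshold: float

    def assigned(self) -> dict[str, int]:
        return {a: k for a, k in self.labels.items() if k is not None}

    def unassigned(self) -> list[str]:
        return [a for a, k in self.labels.items() if k is None]


def assign_lineages(
    consensus: QMatrix, threshold: float = 0.8
) -> LineageAssignment:
    """Assign each accession to its argmax cluster iff membership > threshold.

    The inequality is strict: a membership exactly equal to the threshold
    leaves the accession unassigned (intermediate).
    """
    if not (1.0 / consensus.K < threshold <= 1.0):
        raise ValueError("threshold must be in (1/K, 1]")
    labels: dict[str, int | None] = {}
    for acc, row in zip(consensus.accessions, consensus.memberships):
        k = int(np.argmax(row))
        labels[acc] = k if row[k] > threshold else None
    return LineageAssignment(labels, threshold)
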