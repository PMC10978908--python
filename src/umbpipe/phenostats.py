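"""Phenotype statistics.

Unit-variance scaling, EM-based probabilistic-PCA imputation of missing
values, PCA with per-component contributions, Ward clustering of trait
loadings, a conjugate Gibbs sampler for the lineage x season normal linear
mixed model with split-chain Rhat diagnostics, and the per-season
flowering dendrogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# scaling / PCA / imputation
# --------------------------------------------------------------------------


def scale_uv(data: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to zero mean and unit variance (sample sd, ddof=1).

    Missing cells stay missing.  A zero-variance column is an error naming
    the offending trait.
    """
    out = data.copy().astype(float)
    for col in out.columns:
        values = out[col]
        if values.notna().sum() < 2:
            raise ValueError(f"trait {col!r} has fewer than 2 non-missing values")
        sd = values.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"trait {col!r} has zero variance")
        out[col] = (values - values.mean()) / sd
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    contributions: np.ndarray  # percent variance per component
    eigenvalues: np.ndarray

    def __post_init__(self):
        if (self.contributions < -1e-9).any():
            raise ValueError("contributions must be nonnegative")
        if self.contributions.sum() > 100 + 1e-6:
            raise ValueError("contributions exceed 100%")


def pca(data: pd.DataFrame | np.ndarray) -> PCAResult:
    """PCA by eigendecomposition of the column covariance.

    Columns are centered; contributions are eigenvalue shares x 100.  The
    sign convention fixes each component so its largest-magnitude loading
    is positive.
    """
    frame = isinstance(data, pd.DataFrame)
    X = np.asarray(data, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix must be complete; impute missing values first")
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    loadings = vt.T
    # fix signs: largest-|loading| positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    scores = u * s
    total = eig.sum()
    contributions = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    comp_names = [f"PC{j + 1}" for j in range(len(eig))]
    if frame:
        scores_df = pd.DataFrame(scores, index=data.index, columns=comp_names)
        loadings_df = pd.DataFrame(loadings, index=data.columns, columns=comp_names)
    else:
        scores_df = pd.DataFrame(scores, columns=comp_names)
        loadings_df = pd.DataFrame(loadings, columns=comp_names)
    return PCAResult(scores_df, loadings_df, contributions, eig)


@dataclass
class BPCAResult:
    completed: pd.DataFrame | np.ndarray
    loglik_trace: np.ndarray
    n_components: int


def bpca_impute(
    data: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
    n_steps: int = 100,
    seed: int = 0,
    full_output: bool = False,
):
    """Impute missing cells with an EM-fitted probabilistic PCA model.

    Latent scores and missing entries are the hidden variables of the
    E-step; ``n_steps`` EM iterations are run (default 100).  Observed
    cells are returned unchanged; only missing cells are filled with their
    posterior expectations.  Deterministic under a fixed seed (used only
    for the loading initialization).

    With ``full_output=True`` returns a :class:`BPCAResult` carrying the
    observed-data log-likelihood trace (non-decreasing, the EM guarantee).
    """
    frame = isinstance(data, pd.DataFrame)
    X = np.asarray(data, dtype=float).copy()
    n, d = X.shape
    obs = ~np.isnan(X)
    if (~obs).all(axis=0).any() or (~obs).all(axis=1).any():
        raise ValueError("matrix has an all-missing row or column")
    if n_components is None:
        n_components = min(d - 1, n - 1, 10)
    q = n_components
    if q >= min(n, d):
        raise ValueError("n_components must be < min(n_samples, n_variables)")
    del seed  # the fit is fully deterministic; kept for interface stability

    sigma_floor = 1e-12
    mu = np.nanmean(X, axis=0)
    Xexp = np.where(obs, X, mu)

    def _ppca_from_cov(S: np.ndarray) -> tuple[np.ndarray, float]:
        # closed-form PPCA maximum likelihood given a covariance matrix
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        s2 = float(np.clip(evals[q:].mean() if q < d else 0.0, sigma_floor, None))
        scale = np.sqrt(np.clip(evals[:q] - s2, 0.0, None))
        return evecs[:, :q] * scale, s2

    S0 = np.cov(Xexp, rowvar=False, bias=True)
    W, sigma2 = _ppca_from_cov(np.atleast_2d(S0))

    trace = np.empty(n_steps)
    Iq = np.eye(q)
    for step in range(n_steps):
        # E-step over the missing cells (and the latent scores implicitly):
        # x_m | x_o is Gaussian under the current PPCA model.
        Ssum = np.zeros((d, d))
        loglik = 0.0
        for i in range(n):
            o = obs[i]
            m = ~o
            Wo = W[o]
            xo = X[i, o] - mu[o]
            M = Wo.T @ Wo + sigma2 * Iq
            Minv = np.linalg.inv(M)
            proj = Minv @ (Wo.T @ xo)  # posterior mean of z
            if m.any():
                Wm = W[m]
                Xexp[i, m] = mu[m] + Wm @ proj
                cov_mm = sigma2 * (Wm @ Minv @ Wm.T + np.eye(int(m.sum())))
                Ssum[np.ix_(m, m)] += cov_mm
            # observed-data log-likelihood via the determinant lemma / Woodbury
            do = int(o.sum())
            sign, logdetM = np.linalg.slogdet(M / sigma2)
            logdet = logdetM + do * np.log(sigma2)
            quad = (xo @ xo - xo @ Wo @ proj) / sigma2
            loglik += -0.5 * (do * np.log(2 * np.pi) + logdet + quad)
        trace[step] = loglik
        # M-step: exact ML over (mu, W, sigma2) given expected sufficient stats
        mu = Xexp.mean(axis=0)
        Xc = Xexp - mu
        S = (Xc.T @ Xc + Ssum) / n
        W, sigma2 = _ppca_from_cov(S)

    completed = np.where(obs, X, Xexp)
    if frame:
        completed = pd.DataFrame(completed, index=data.index, columns=data.columns)
    if full_output:
        return BPCAResult(completed, trace, q)
    return completed


def cluster_traits(
    loadings: pd.DataFrame,
    n_components_used: int | None = None,
    method: str = "ward",
) -> "Dendrogram":
    """Ward-cluster traits by Euclidean distance between loading vectors."""
    if loadings.shape[0] < 2:
        raise ValueError("need at least 2 traits")
    L = loadings.iloc[:, :n_components_used] if n_components_used else loadings
    Z = hierarchy.linkage(L.to_numpy(), method=method, metric="euclidean")
    return Dendrogram(Z, list(loadings.index))


@dataclass
class Dendrogram:
    linkage: np.ndarray
    labels: list[str]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )

    def cut(self, n_clusters: int) -> dict[str, int]:
        assignments = hierarchy.fcluster(
            self.linkage, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.left, node.right
            dl = node.dist - left.dist
            dr = node.dist - right.dist
            return f"({rec(left)}:{dl:.6g},{rec(right)}:{dr:.6g})"

        return rec(tree) + ";"


# --------------------------------------------------------------------------
# Rhat and the Bayesian linear mixed model
# --------------------------------------------------------------------------


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws); each chain is split in half before
    computing sqrt(((n-1)/n * W + B/n) / W).  Zero within-chain variance is
    defined as 1 with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains of equal length >= 4")
    half = chains.shape[1] // 2
    split = np.concatenate(
        [chains[:, :half], chains[:, half : 2 * half]], axis=0
    )
    n = split.shape[1]
    within = split.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0:
        if split.mean(axis=1).var() > 0:
            warnings.warn("zero within-chain variance with differing means")
        return 1.0
    B = n * split.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


@dataclass
class PosteriorSummary:
    """Posterior summaries for a fitted mixed model."""

    table: pd.DataFrame  # index: parameter; columns: mean, q2.5, q97.5, rhat
    chains: int
    draws: int  # retained draws across chains
    converged: bool
    draws_by_param: dict[str, np.ndarray] = field(default_factory=dict)
    # (chains, kept) per parameter

    def __post_init__(self):
        bad = self.table[
            (self.table["q2.5"] > self.table["mean"] + 1e-9)
            | (self.table["q97.5"] < self.table["mean"] - 1e-9)
        ]
        if len(bad):
            raise ValueError("credible interval does not bracket the mean")

    def contrast(self, param_a: str, param_b: str) -> dict[str, float]:
        """Posterior mean and 95% CI of ``param_a - param_b``."""
        diff = (self.draws_by_param[param_a] - self.draws_by_param[param_b]).ravel()
        lo, hi = np.percentile(diff, [2.5, 97.5])
        return {"mean": float(diff.mean()), "q2.5": float(lo), "q97.5": float(hi)}


def _design_matrix(
    lineage: pd.Series, season: pd.Series
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effect design: intercept, lineage, season,
    and lineage x season interaction, reference level = first sorted level."""
    lin_levels = sorted(lineage.unique())
    sea_levels = sorted(season.unique())
    cols = [np.ones(len(lineage))]
    names = ["(Intercept)"]
    for lv in lin_levels[1:]:
        cols.append((lineage == lv).to_numpy(float))
        names.append(f"lineage[{lv}]")
    for sv in sea_levels[1:]:
        cols.append((season == sv).to_numpy(float))
        names.append(f"season[{sv}]")
    for lv in lin_levels[1:]:
        for sv in sea_levels[1:]:
            cols.append(
                ((lineage == lv) & (season == sv)).to_numpy(float)
            )
            names.append(f"lineage[{lv}]:season[{sv}]")
    return np.column_stack(cols), names


def fit_glmm(
    data: pd.DataFrame,
    value_col: str = "value",
    lineage_col: str = "lineage",
    season_col: str = "season",
    accession_col: str = "accession",
    chains: int = 4,
    iterations: int = 5000,
    burnin: int = 1000,
    seed: int = 0,
    prior_beta_var: float = 1e6,
    prior_shape: float = 0.01,
    prior_rate: float = 0.01,
    shared_variance: bool = False,
    rhat_limit: float = 1.1,
) -> PosteriorSummary:
    """Gibbs sampler for the lineage x season normal linear mixed model.

    Model: y = X beta + gamma_accession + eps with gamma ~ N(0, sigma_g^2)
    and eps ~ N(0, sigma_e^2); fixed effects are the intercept, lineage,
    season, and their interaction under treatment coding.  Priors are
    beta ~ N(0, ``prior_beta_var``) and Inverse-Gamma(shape, rate) on both
    variances, giving exact conjugate updates.  ``shared_variance=True``
    forces a single variance for both strata (the literal reading of a
    model printed with one delta^2 for both).

    Retained draws number ``chains * (iterations - burnin)``.  A fit with
    any parameter's split-Rhat >= ``rhat_limit`` is flagged (``converged``
    False) but never suppressed.
    """
    df = data.dropna(subset=[value_col]).reset_index(drop=True)
    if df[lineage_col].nunique() < 2 or df[season_col].nunique() < 2:
        raise ValueError("need >= 2 lineages and >= 2 seasons")
    y = df[value_col].to_numpy(float)
    X, names = _design_matrix(df[lineage_col], df[season_col])
    n, p = X.shape
    acc_codes, acc_levels = pd.factorize(df[accession_col])
    A = len(acc_levels)

    XtX = X.T @ X
    kept = iterations - burnin
    if kept <= 0:
        raise ValueError("burnin must be < iterations")

    beta_draws = np.empty((chains, kept, p))
    sg_draws = np.empty((chains, kept))
    se_draws = np.empty((chains, kept))
    root = np.random.SeedSequence(seed)
    for c, child in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(child)
        beta = np.zeros(p)
        gamma = np.zeros(A)
        sigma_g2 = 1.0
        sigma_e2 = 1.0
        for it in range(iterations):
            # beta | rest
            resid = y - gamma[acc_codes]
            prec = XtX / sigma_e2 + np.eye(p) / prior_beta_var
            cov = np.linalg.inv(prec)
            mean = cov @ (X.T @ resid) / sigma_e2
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            # gamma | rest
            r = y - X @ beta
            sums = np.bincount(acc_codes, weights=r, minlength=A)
            counts = np.bincount(acc_codes, minlength=A)
            g_prec = counts / sigma_e2 + 1.0 / sigma_g2
            g_mean = (sums / sigma_e2) / g_prec
            gamma = g_mean + rng.standard_normal(A) / np.sqrt(g_prec)
            # variances | rest
            sse = float(((r - gamma[acc_codes]) ** 2).sum())
            ssg = float((gamma**2).sum())
            if shared_variance:
                shape = prior_shape + (n + A) / 2.0
                rate = prior_rate + (sse + ssg) / 2.0
                shared = rate / rng.gamma(shape)
                sigma_e2 = sigma_g2 = float(shared)
            else:
                sigma_e2 = float(
                    (prior_rate + sse / 2.0) / rng.gamma(prior_shape + n / 2.0)
                )
                sigma_g2 = float(
                    (prior_rate + ssg / 2.0) / rng.gamma(prior_shape + A / 2.0)
                )
            if it >= burnin:
                j = it - burnin
                beta_draws[c, j] = beta
                sg_draws[c, j] = np.sqrt(sigma_g2)
                se_draws[c, j] = np.sqrt(sigma_e2)

    params: dict[str, np.ndarray] = {
        name: beta_draws[:, :, i] for i, name in enumerate(names)
    }
    params["sigma_gamma"] = sg_draws
    params["sigma_eps"] = se_draws
    rows = []
    for name, draws in params.items():
        flat = draws.ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "rhat": rhat(draws),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    converged = bool((table["rhat"] < rhat_limit).all())
    if not converged:
        logger.warning(
            "mixed model flagged non-converged: max Rhat = %.3f",
            table["rhat"].max(),
        )
    return PosteriorSummary(
        table=table,
        chains=chains,
        draws=chains * kept,
        converged=converged,
        draws_by_param=params,
    )


# --------------------------------------------------------------------------
# flowering dendrogram
# --------------------------------------------------------------------------


def flowering_dendrogram(values: pd.DataFrame) -> Dendrogram:
    """Ward dendrogram of accessions from per-season flowering values.

    ``values`` is accessions x seasons.  Each season column is z-normalized
    (ddof=1); Euclidean distances are computed over season vectors, with
    missing seasons pairwise-excluded and the squared distance rescaled by
    (total seasons / shared seasons).  Accessions missing every season are
    excluded with a warning.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    keep = values.notna().any(axis=1)
    if not keep.all():
        dropped = list(values.index[~keep])
        warnings.warn(f"excluding accessions with no seasons: {dropped}")
        values = values.loc[keep]
    Z = values.copy().astype(float)
    for col in Z.columns:
        sd = Z[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"season {col!r} has zero variance")
        Z[col] = (Z[col] - Z[col].mean()) / sd
    arr = Z.to_numpy()
    obs = ~np.isnan(arr)
    n, s = arr.shape
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"accessions {Z.index[i]!r} and {Z.index[j]!r} share no seasons"
                )
            sq = float(((arr[i, shared] - arr[j, shared]) ** 2).sum())
            dist[i, j] = dist[j, i] = np.sqrt(sq * s / m)
    link = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return Dendrogram(link, [str(i) for i in Z.index])
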