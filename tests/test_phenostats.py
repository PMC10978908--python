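import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from umbpipe.phenostats import (
    Dendrogram,
    bpca_impute,
    cluster_traits,
    fit_glmm,
    flowering_dendrogram,
    pca,
    rhat,
    scale_uv,
)
from umbpipe.synthdata import GLMMSpec, gen_phenotypes, make_design


class TestScaleUV:
    def test_simple_column(self):
        out = scale_uv(pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 9.0]}))
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_names_trait(self):
        with pytest.raises(ValueError, match="awn_length"):
            scale_uv(pd.DataFrame({"awn_length": [2.0, 2.0, 2.0]}))

    def test_random_table_unit_moments(self, rng):
        data = pd.DataFrame(rng.normal(5, 3, size=(40, 6)),
                            columns=[f"t{i}" for i in range(6)])
        out = scale_uv(data)
        assert np.abs(out.mean()).max() < 1e-12
        assert np.abs(out.std(ddof=1) - 1).max() < 1e-12

    def test_missing_cells_stay_missing(self):
        data = pd.DataFrame({"x": [1.0, np.nan, 3.0, 4.0]})
        out = scale_uv(data)
        assert out["x"].isna().tolist() == [False, True, False, False]


class TestBpcaImpute:
    def test_complete_matrix_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        out = bpca_impute(X, n_components=2, n_steps=20)
        assert np.array_equal(out.to_numpy(), X.to_numpy())

    def test_rank1_heldout_reconstruction(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=8)
        X = np.outer(u, v)
        mask = rng.random(X.shape) < 0.10
        # keep at least one observed cell per row/column
        mask[0, :] = False
        mask[:, 0] = False
        Xm = X.copy()
        Xm[mask] = np.nan
        out = bpca_impute(Xm, n_components=1, n_steps=100)
        assert np.abs(out[mask] - X[mask]).max() < 1e-3

    def test_observed_cells_never_altered(self, rng):
        X = rng.normal(size=(40, 6))
        Xm = X.copy()
        miss = rng.random(X.shape) < 0.2
        Xm[miss] = np.nan
        out = bpca_impute(Xm, n_components=3, n_steps=30)
        assert np.array_equal(out[~miss], X[~miss])

    def test_em_loglik_nondecreasing(self, rng):
        X = rng.normal(size=(60, 8)) @ rng.normal(size=(8, 8))
        Xm = X.copy()
        Xm[rng.random(X.shape) < 0.15] = np.nan
        result = bpca_impute(Xm, n_components=3, n_steps=100, full_output=True)
        diffs = np.diff(result.loglik_trace)
        assert (diffs >= -1e-6 * np.abs(result.loglik_trace[:-1])).all()

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="n_components"):
            bpca_impute(X, n_components=4)

    def test_all_missing_column_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        X[:, 2] = np.nan
        with pytest.raises(ValueError, match="all-missing"):
            bpca_impute(X, n_components=2)


class TestPCA:
    def test_perfectly_correlated_pc1_100(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"a": x, "b": 3 * x})
        result = pca(scale_uv(data))
        assert result.contributions[0] == pytest.approx(100.0, abs=1e-9)

    def test_known_eigenvalues(self, rng):
        # columns with variances 4, 2, 1 and zero correlation by construction
        n = 2000
        base = rng.standard_normal((n, 3))
        base -= base.mean(axis=0)
        # orthogonalize exactly, then scale to target variances
        qmat, _ = np.linalg.qr(base)
        data = qmat * np.sqrt(n - 1) * np.array([2.0, np.sqrt(2.0), 1.0])
        result = pca(pd.DataFrame(data, columns=list("abc")))
        assert result.contributions == pytest.approx(
            [100 * 4 / 7, 100 * 2 / 7, 100 * 1 / 7], abs=1e-6
        )

    def test_full_rank_reconstruction(self, rng):
        data = pd.DataFrame(rng.normal(size=(25, 6)))
        result = pca(data)
        centered = data.to_numpy() - data.to_numpy().mean(axis=0)
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        assert np.abs(recon - centered).max() < 1e-8

    def test_contributions_sum_100(self, rng):
        result = pca(pd.DataFrame(rng.normal(size=(30, 5))))
        assert result.contributions.sum() == pytest.approx(100.0, abs=1e-9)

    def test_loadings_orthonormal(self, rng):
        result = pca(pd.DataFrame(rng.normal(size=(30, 5))))
        L = result.loadings.to_numpy()
        assert np.abs(L.T @ L - np.eye(5)).max() < 1e-8

    def test_sign_convention(self, rng):
        result = pca(pd.DataFrame(rng.normal(size=(30, 4))))
        L = result.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] > 0


class TestClusterTraits:
    def test_duplicated_traits_merge_first_at_zero(self, rng):
        loadings = pd.DataFrame(
            rng.normal(size=(4, 3)), index=["t1", "t2", "t3", "t4"]
        )
        loadings.loc["t2"] = loadings.loc["t1"]
        dend = cluster_traits(loadings)
        first = dend.linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        merged = {dend.labels[int(first[0])], dend.labels[int(first[1])]}
        assert merged == {"t1", "t2"}

    def test_correlated_traits_first_merged(self, rng):
        n = 200
        base = rng.normal(size=n)
        data = pd.DataFrame(
            {
                "days_to_heading": base + rng.normal(0, 0.1, n),
                "days_to_flowering": base + rng.normal(0, 0.1, n),
                "awn_length": rng.normal(size=n),
                "plant_height": rng.normal(size=n),
            }
        )
        result = pca(scale_uv(data))
        dend = cluster_traits(result.loadings, n_components_used=3)
        first = dend.linkage[0]
        merged = {dend.labels[int(first[0])], dend.labels[int(first[1])]}
        assert merged == {"days_to_heading", "days_to_flowering"}

    def test_merge_sequence_matches_exhaustive_ward_oracle(self, rng):
        loadings = pd.DataFrame(rng.normal(size=(5, 4)),
                                index=[f"t{i}" for i in range(5)])
        dend = cluster_traits(loadings)
        oracle = hierarchy.linkage(loadings.to_numpy(), method="ward")
        assert np.allclose(dend.linkage, oracle)

    def test_ward_heights_nondecreasing(self, rng):
        loadings = pd.DataFrame(rng.normal(size=(12, 4)))
        dend = cluster_traits(loadings.set_index(loadings.index.astype(str)))
        heights = dend.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestRhat:
    def test_constant_identical_chains_exactly_one(self):
        # zero within-chain variance, equal means -> defined as exactly 1
        chains = np.full((2, 8), 3.0)
        assert rhat(chains) == 1.0

    def test_identical_stationary_chains_b_zero(self):
        # identical chains whose split halves share the same mean: B = 0 and
        # the statistic collapses to its finite-sample floor sqrt((n-1)/n)
        chains = np.tile(np.array([1.0, 2.0, 2.0, 1.0]), (2, 1))
        assert rhat(chains) == pytest.approx(np.sqrt(1.0 / 2.0), abs=1e-12)

    def test_separated_chains_large(self, rng):
        chains = np.vstack(
            [rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)]
        )
        assert rhat(chains) > 1.5

    def test_longhand_evaluation(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        # split into 4 half-chains of length 2: (1,2), (3,4), (1,2), (3,4)
        split = np.array([[1, 2], [1, 2], [3, 4], [3, 4]], dtype=float)
        n = 2
        W = split.var(axis=1, ddof=1).mean()  # = 0.5
        B = n * split.mean(axis=1).var(ddof=1)  # = 2 * var([1.5,1.5,3.5,3.5])
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(chains) == pytest.approx(expected, abs=1e-12)

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 10)))


def _simulate(spec_kwargs=None, n_per_lineage=15, seasons=("s1", "s2"),
              replicates=2, seed=0, **gen_kwargs):
    base = dict(
        beta0=50.0,
        beta1={"A": 0.0, "B": 0.0},
        beta2={s: 0.0 for s in seasons},
        beta3={},
        sigma_gamma=1.0,
        sigma_eps=1.0,
    )
    base.update(spec_kwargs or {})
    spec = GLMMSpec(**base)
    accs = {
        lin: [f"{lin}{i}" for i in range(n_per_lineage)]
        for lin in spec.lineages
    }
    design = make_design(accs, list(seasons), replicates)
    return spec, gen_phenotypes(spec, design, seed=seed, **gen_kwargs)


class TestFitGlmm:
    def test_null_effects_cis_cover_zero(self):
        _spec, table = _simulate(seed=3)
        summary = fit_glmm(table, chains=2, iterations=800, burnin=200, seed=1)
        for name in summary.table.index:
            if name.startswith(("lineage[", "season[")):
                row = summary.table.loc[name]
                assert row["q2.5"] <= 0.0 <= row["q97.5"]

    def test_retained_draws_at_paper_budget(self):
        _spec, table = _simulate(n_per_lineage=4, seed=4)
        summary = fit_glmm(table, chains=4, iterations=5000, burnin=1000, seed=2)
        assert summary.draws == 16_000
        assert summary.chains == 4

    def test_effect_recovery(self):
        _spec, table = _simulate({"beta1": {"A": 0.0, "B": 10.0}},
                                 n_per_lineage=30, seed=5)
        summary = fit_glmm(table, chains=2, iterations=1500, burnin=500, seed=3)
        row = summary.table.loc["lineage[B]"]
        assert row["q2.5"] <= 10.0 <= row["q97.5"]
        assert row["mean"] == pytest.approx(10.0, abs=1.0)

    def test_interaction_recovery(self):
        _spec, table = _simulate(
            {"beta3": {("B", "s2"): 5.0}}, n_per_lineage=40, seed=6
        )
        summary = fit_glmm(table, chains=2, iterations=1500, burnin=500, seed=4)
        row = summary.table.loc["lineage[B]:season[s2]"]
        assert row["q2.5"] <= 5.0 <= row["q97.5"]

    def test_variance_components_recovered(self):
        _spec, table = _simulate(
            {"sigma_gamma": 3.0, "sigma_eps": 1.0}, n_per_lineage=60,
            replicates=3, seed=7,
        )
        summary = fit_glmm(table, chains=2, iterations=1500, burnin=500, seed=5)
        assert summary.table.loc["sigma_gamma", "mean"] == pytest.approx(3.0, rel=0.2)
        assert summary.table.loc["sigma_eps", "mean"] == pytest.approx(1.0, rel=0.1)

    def test_requires_two_lineages_and_seasons(self):
        table = pd.DataFrame(
            {
                "accession": ["a", "b"],
                "lineage": ["A", "A"],
                "season": ["s1", "s2"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="2 lineages"):
            fit_glmm(table)

    def test_nonconverged_flagged_not_suppressed(self):
        _spec, table = _simulate(seed=8)
        # absurdly short chains rarely pass split-Rhat on all parameters
        summary = fit_glmm(table, chains=2, iterations=8, burnin=0, seed=6)
        assert summary.table is not None
        assert isinstance(summary.converged, bool)

    def test_bias_shrinks_with_n(self):
        biases = []
        for n in (30, 90, 270):
            errors = []
            for seed in range(3):
                _spec, table = _simulate(
                    {"beta1": {"A": 0.0, "B": 2.0}}, n_per_lineage=n // 2,
                    seed=100 + seed,
                )
                summary = fit_glmm(table, chains=2, iterations=600, burnin=200,
                                   seed=seed)
                errors.append(abs(summary.table.loc["lineage[B]", "mean"] - 2.0))
            biases.append(np.mean(errors))
        assert biases[2] < biases[0]


class TestFloweringDendrogram:
    def test_identical_accessions_first_merge_zero(self, rng):
        values = pd.DataFrame(
            rng.normal(50, 5, size=(6, 4)),
            index=[f"a{i}" for i in range(6)],
            columns=["s17", "s18", "s19", "s20"],
        )
        values.loc["a1"] = values.loc["a0"]
        dend = flowering_dendrogram(values)
        first = dend.linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-9)
        merged = {dend.labels[int(first[0])], dend.labels[int(first[1])]}
        assert merged == {"a0", "a1"}

    def test_two_groups_separated_recovered(self, rng):
        early = rng.normal(100, 1, size=(10, 4))
        late = rng.normal(110, 1, size=(10, 4))  # 5 pooled sd apart after pooling
        values = pd.DataFrame(
            np.vstack([early, late]),
            index=[f"e{i}" for i in range(10)] + [f"l{i}" for i in range(10)],
            columns=["s17", "s18", "s19", "s20"],
        )
        dend = flowering_dendrogram(values)
        cut = dend.cut(2)
        early_clusters = {cut[f"e{i}"] for i in range(10)}
        late_clusters = {cut[f"l{i}"] for i in range(10)}
        assert len(early_clusters) == 1 and len(late_clusters) == 1
        assert early_clusters != late_clusters

    def test_four_seasons_accepted(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(5, 4)),
            index=[f"a{i}" for i in range(5)],
            columns=["2016-2017", "2017-2018", "2018-2019", "2019-2020"],
        )
        dend = flowering_dendrogram(values)
        assert len(dend.labels) == 5

    def test_all_missing_accession_excluded_with_warning(self, rng):
        values = pd.DataFrame(
            rng.normal(size=(4, 3)),
            index=["a", "b", "c", "d"],
            columns=["s1", "s2", "s3"],
        )
        values.loc["c"] = np.nan
        with pytest.warns(UserWarning, match="no seasons"):
            dend = flowering_dendrogram(values)
        assert "c" not in dend.labels

    def test_newick_export_parses(self, rng):
        import dendropy

        values = pd.DataFrame(
            rng.normal(size=(5, 3)),
            index=[f"a{i}" for i in range(5)],
            columns=["s1", "s2", "s3"],
        )
        newick = flowering_dendrogram(values).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == 5
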