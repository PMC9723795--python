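"""PLS fitting, relevance weights, bipartite thresholding, CAG extraction, canopy."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from raretide.cagbin import (
    BipartiteGraph,
    build_bipartite,
    bin_pls,
    canopy_binning,
    extract_cags,
    fit_pls,
    partition_ari,
    relevance_weights,
)
from raretide.synthdata import GeneratorConfig, generate
from raretide.tables import ClrTable, clr_from_counts, clr_transform


def clr_of(df: pd.DataFrame) -> ClrTable:
    """CLR of a strictly positive abundance DataFrame (features x samples)."""
    return clr_transform(df / df.sum(axis=0))


def expected_mode_clr(ds):
    return clr_of(ds.otu_expected), clr_of(ds.gene_expected)


class TestFitPls:
    def test_zero_components_rejected(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        with pytest.raises(ValueError):
            fit_pls(oc, gc, n_components=0)

    def test_too_many_components_rejected(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        with pytest.raises(ValueError):
            fit_pls(oc, gc, n_components=45)

    def test_scores_mutually_orthogonal(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        model = fit_pls(oc, gc, n_components=5)
        gram = model.x_scores.T.to_numpy() @ model.x_scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_rank_one_response_loads_on_driving_otu(self):
        # Y depends on a single X column: that OTU must dominate the weights,
        # matching the brute-force covariance-maximization solution.
        rng = np.random.default_rng(0)
        n = 30
        x = rng.normal(size=(6, n))
        x_clr = x - x.mean(axis=0)
        y = np.outer(np.ones(4), x_clr[2]) * rng.normal(1, 0.1, size=(4, 1))
        y_clr = y - y.mean(axis=0)
        oc = ClrTable(pd.DataFrame(x_clr, index=[f"o{i}" for i in range(6)],
                                   columns=[f"s{j}" for j in range(n)]))
        gc = ClrTable(pd.DataFrame(y_clr, index=[f"g{i}" for i in range(4)],
                                   columns=[f"s{j}" for j in range(n)]))
        model = fit_pls(oc, gc, n_components=1)
        w = model.x_weights["comp1"].abs()
        assert w.idxmax() == "o2"
        # brute force: the standardized column with max |cov| to each Y column
        Xs = (x_clr - x_clr.mean(axis=1, keepdims=True)).T
        Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=1)
        Ys = y_clr.T - y_clr.T.mean(axis=0)
        cov = np.abs(Xs.T @ Ys).sum(axis=1)
        assert np.argmax(cov) == 2

    def test_fit_improves_with_components(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        Y = gc.values.T.to_numpy()
        Y = (Y - Y.mean(axis=0)) / np.where(Y.std(axis=0, ddof=1) == 0, 1, Y.std(axis=0, ddof=1))

        def resid_norm(k):
            m = fit_pls(oc, gc, n_components=k)
            T = m.x_scores.to_numpy()
            C = m.y_loadings.to_numpy()
            return np.linalg.norm(Y - T @ C.T)

        assert resid_norm(6) <= resid_norm(1) + 1e-9

    def test_matches_sklearn_score_subspace(self, small_dataset):
        from sklearn.cross_decomposition import PLSRegression

        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        model = fit_pls(oc, gc, n_components=3)
        sk = PLSRegression(n_components=3, scale=True).fit(
            oc.values.T.to_numpy(), gc.values.T.to_numpy()
        )
        q1, _ = np.linalg.qr(model.x_scores.to_numpy())
        q2, _ = np.linalg.qr(sk.x_scores_)
        canonical = np.linalg.svd(q1.T @ q2, compute_uv=False)
        np.testing.assert_allclose(canonical, 1.0, atol=1e-6)

    def test_keep_x_sparsity_respected(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        model = fit_pls(oc, gc, n_components=2, keep_x=[3, 3])
        for kept, col in zip(model.kept_x, model.x_weights.columns):
            assert len(kept) <= 3
            nonzero = (model.x_weights[col] != 0).sum()
            assert nonzero <= 3

    def test_rank_deficient_returns_fewer_components(self):
        # rank-1 X: only one informative component exists; asking for 2 warns
        rng = np.random.default_rng(1)
        latent = rng.normal(size=6)
        loads = rng.normal(size=4)
        x = np.outer(loads, latent)
        x = x - x.mean(axis=0)
        oc = ClrTable(pd.DataFrame(x, index=[f"o{i}" for i in range(4)],
                                   columns=[f"s{j}" for j in range(6)]))
        with pytest.warns(RuntimeWarning):
            model = fit_pls(oc, oc, n_components=2)
        assert model.n_components == 1


class TestRelevanceWeights:
    def test_gene_identical_to_otu_weight_near_one(self, recovery_config):
        ds = generate(GeneratorConfig(noise_sd=0.0, seed=3, **recovery_config))
        oc, gc = expected_mode_clr(ds)
        model = fit_pls(oc, gc, n_components=7)
        w = relevance_weights(model, oc, gc)
        for gene, cag in ds.truth_gene_to_cag.items():
            assert w.loc[ds.truth_cag_anchor[cag], gene] > 0.99

    def test_sign_flip_invariance(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        model = fit_pls(oc, gc, n_components=2)
        w1 = relevance_weights(model, oc, gc)
        model.x_scores.iloc[:, 0] *= -1  # joint sign flip of one component
        w2 = relevance_weights(model, oc, gc)
        np.testing.assert_allclose(w1.to_numpy(), w2.to_numpy(), atol=1e-12)

    def test_zero_variance_gene_gets_zero_weight(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        model = fit_pls(oc, gc, n_components=2)
        # two genes constant over time (CLR +1/-1): zero variance -> weight 0
        flat = ClrTable(pd.DataFrame(
            [[1.0] * len(gc.sample_ids), [-1.0] * len(gc.sample_ids)],
            index=["g_flat_hi", "g_flat_lo"], columns=gc.sample_ids,
        ))
        w = relevance_weights(model, oc, flat)
        assert np.abs(w.to_numpy()).max() == 0

    def test_weights_clipped(self, small_dataset):
        oc = clr_from_counts(small_dataset.otu_table)
        gc = clr_from_counts(small_dataset.gene_table)
        model = fit_pls(oc, gc, n_components=4)
        w = relevance_weights(model, oc, gc).to_numpy()
        assert w.min() >= -1 and w.max() <= 1


class TestBuildBipartite:
    def test_all_below_threshold_empty(self):
        w = pd.DataFrame(0.5, index=["o1"], columns=["g1", "g2"])
        g = build_bipartite(w, threshold=0.8)
        assert g.edges == [] and g.otu_nodes == [] and g.gene_nodes == []

    def test_single_edge(self):
        w = pd.DataFrame([[0.9, 0.1]], index=["o1"], columns=["g1", "g2"])
        g = build_bipartite(w, threshold=0.8)
        assert g.edges == [("o1", "g1", 0.9)]
        assert g.otu_nodes == ["o1"] and g.gene_nodes == ["g1"]

    def test_matches_brute_force_thresholding(self):
        rng = np.random.default_rng(4)
        w = pd.DataFrame(
            rng.uniform(-1, 1, size=(6, 10)),
            index=[f"o{i}" for i in range(6)],
            columns=[f"g{j}" for j in range(10)],
        )
        g = build_bipartite(w, threshold=0.4)
        want = {
            (w.index[i], w.columns[j])
            for i in range(6)
            for j in range(10)
            if w.iloc[i, j] >= 0.4
        }
        assert {(o, ge) for o, ge, _ in g.edges} == want

    def test_signed_mode_drops_negative(self):
        w = pd.DataFrame([[-0.95]], index=["o1"], columns=["g1"])
        assert build_bipartite(w, threshold=0.8, mode="signed").edges == []
        assert len(build_bipartite(w, threshold=0.8, mode="abs").edges) == 1

    def test_nonfinite_rejected(self):
        w = pd.DataFrame([[np.nan]], index=["o"], columns=["g"])
        with pytest.raises(ValueError):
            build_bipartite(w)


class TestExtractCags:
    def test_star_graph_single_cag(self):
        g = BipartiteGraph(
            otu_nodes=["o1"],
            gene_nodes=[f"g{i}" for i in range(5)],
            edges=[("o1", f"g{i}", 0.9) for i in range(5)],
        )
        cags = extract_cags(g)
        assert len(cags) == 1
        assert cags[0].member_genes == {f"g{i}" for i in range(5)}
        assert cags[0].anchor_otu == "o1"

    def test_unique_mode_max_weight_wins(self):
        g = BipartiteGraph(
            otu_nodes=["o1", "o2"],
            gene_nodes=["g1"],
            edges=[("o1", "g1", 0.85), ("o2", "g1", 0.95)],
        )
        cags = extract_cags(g, assignment="unique")
        assert len(cags) == 1 and cags[0].anchor_otu == "o2"

    def test_multi_mode_allows_sharing(self):
        g = BipartiteGraph(
            otu_nodes=["o1", "o2"],
            gene_nodes=["g1"],
            edges=[("o1", "g1", 0.85), ("o2", "g1", 0.95)],
        )
        cags = extract_cags(g, assignment="multi")
        assert len(cags) == 2
        assert all(c.member_genes == {"g1"} for c in cags)

    def test_tie_broken_lexicographically(self):
        g = BipartiteGraph(
            otu_nodes=["oB", "oA"],
            gene_nodes=["g1"],
            edges=[("oB", "g1", 0.9), ("oA", "g1", 0.9)],
        )
        cags = extract_cags(g, assignment="unique")
        assert cags[0].anchor_otu == "oA"


class TestRecovery:
    def test_noise_free_expected_mode_ari_one_across_thresholds(self, recovery_config):
        ds = generate(GeneratorConfig(noise_sd=0.0, seed=5, **recovery_config))
        oc, gc = expected_mode_clr(ds)
        for thr in (0.05, 0.5, 0.9, 0.99):
            cags, _, _ = bin_pls(oc, gc, n_components=7, threshold=thr)
            assert partition_ari(ds.truth_gene_to_cag, cags) == 1.0

    def test_noisy_recovery(self, recovery_config):
        ds = generate(GeneratorConfig(noise_sd=0.2, seed=6, **recovery_config))
        from raretide.tables import clr_from_counts

        cags, _, _ = bin_pls(
            clr_from_counts(ds.otu_table),
            clr_from_counts(ds.gene_table),
            n_components=7,
            threshold=0.8,
        )
        assert partition_ari(ds.truth_gene_to_cag, cags) >= 0.90

    def test_ari_degrades_monotonically_with_noise(self, recovery_config):
        from raretide.tables import clr_from_counts

        aris = []
        for noise in (0.0, 0.4, 1.5):
            ds = generate(GeneratorConfig(noise_sd=noise, seed=7, **recovery_config))
            cags, _, _ = bin_pls(
                clr_from_counts(ds.otu_table),
                clr_from_counts(ds.gene_table),
                n_components=7,
                threshold=0.8,
            )
            aris.append(partition_ari(ds.truth_gene_to_cag, cags))
        assert aris[0] + 1e-9 >= aris[1] >= aris[2] - 0.05

    def test_members_meet_threshold_to_anchor(self, recovery_config):
        ds = generate(GeneratorConfig(noise_sd=0.2, seed=8, **recovery_config))
        from raretide.tables import clr_from_counts

        oc = clr_from_counts(ds.otu_table)
        gc = clr_from_counts(ds.gene_table)
        cags, model, _ = bin_pls(oc, gc, n_components=7, threshold=0.8)
        w = relevance_weights(model, oc, gc)
        for cag in cags:
            for gene in cag.member_genes:
                assert w.loc[cag.anchor_otu, gene] >= 0.8


class TestCanopy:
    def test_duplicated_profile_groups(self):
        base = np.array([10, 40, 5, 25, 60, 15])
        arr = np.vstack([base, base * 2, base * 3, base[::-1], base[::-1] * 2])
        table = make_table(arr)
        cags = canopy_binning(table)
        assert len(cags) == 2
        partition = sorted(tuple(sorted(c.member_genes)) for c in cags)
        assert partition == [("f0", "f1", "f2"), ("f3", "f4")]

    def test_orthogonal_profiles_singletons(self):
        arr = np.eye(4, dtype=int) * 100 + 1
        cags = canopy_binning(make_table(arr))
        assert len(cags) == 4
        assert all(len(c.member_genes) == 1 for c in cags)

    def test_noise_free_matches_pls_and_truth(self, recovery_config):
        ds = generate(GeneratorConfig(noise_sd=0.0, seed=9, **recovery_config))
        oc, gc = expected_mode_clr(ds)
        pls_cags, _, _ = bin_pls(oc, gc, n_components=7, threshold=0.8)
        canopy_cags = canopy_binning(ds.gene_table)
        assert partition_ari(ds.truth_gene_to_cag, canopy_cags) == 1.0
        assert partition_ari(ds.truth_gene_to_cag, pls_cags) == 1.0

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            canopy_binning(make_table([[1, 2], [3, 4]]))
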