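import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from rootatlas import annotate as ann
from rootatlas.containers import ExpressionMatrix
from rootatlas.synthetic import AtlasConfig, generate_atlas


def _expr(values, gene_prefix="g", cell_prefix="c"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        pd.Index([f"{gene_prefix}{i}" for i in range(values.shape[0])]),
        pd.Index([f"{cell_prefix}{j}" for j in range(values.shape[1])]),
    )


class TestMarkerSet:
    def test_duplicate_marker_rejected(self):
        with pytest.raises(ValueError, match="assigned to both"):
            ann.MarkerSet({"a": ["g1"], "b": ["g1"]})

    def test_restrict_reports_missing(self):
        ms = ann.MarkerSet({"a": ["g0", "gX"], "b": ["g1"]})
        sub = ms.restrict_to(["g0", "g1"])
        assert sub.markers == {"a": ["g0"], "b": ["g1"]}
        assert sub.missing == ["gX"]


class TestEmbedPca:
    def test_rank_identity(self, rng):
        # rank-2 input: components beyond 2 carry ~0 variance
        u = rng.standard_normal((30, 2))
        v = rng.standard_normal((2, 100))
        expr = _expr(u @ v)
        scores = ann.embed_pca(expr, n_components=5)
        var = scores.var(axis=0)
        assert var[2:].max() < 1e-20 * var[0]

    def test_projection_variance_bound(self, rng):
        X = rng.standard_normal((40, 60))
        expr = _expr(X)
        scores = ann.embed_pca(expr, n_components=10)
        assert scores.var(axis=0, ddof=1).sum() <= X.T.var(axis=0, ddof=1).sum() + 1e-9

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((40, 60))
        s1 = ann.embed_pca(_expr(X), n_components=5)
        s2 = ann.embed_pca(_expr(X), n_components=5)
        np.testing.assert_allclose(s1, s2)

    def test_too_few_cells_errors(self, rng):
        expr = _expr(rng.standard_normal((30, 10)))
        with pytest.raises(ValueError, match="fewer cells"):
            ann.embed_pca(expr, n_components=20)

    def test_types_separate_in_pca(self, small_config, small_atlas):
        from rootatlas.preprocess import normalize

        cm, truth = small_atlas
        expr = normalize(cm)
        scores = ann.embed_pca(expr, n_components=10)
        tt = truth.cells["true_type"].to_numpy()
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(tt)
        assert silhouette_score(scores, tt) > silhouette_score(scores, shuffled)


class TestClusterCells:
    def test_two_blobs_recovered(self, rng):
        a = rng.standard_normal((60, 3))
        b = rng.standard_normal((60, 3)) + 12.0
        emb = np.vstack([a, b])
        ca = ann.cluster_cells(emb, resolution=0.1, k=10, seed=0)
        memb = ca.membership.to_numpy()
        assert ca.n_clusters == 2
        # each blob is one pure cluster (ARI = 1)
        assert len(set(memb[:60])) == 1 and len(set(memb[60:])) == 1
        assert memb[0] != memb[60]

    def test_resolution_monotonicity(self, rng):
        emb = rng.standard_normal((300, 5))
        graph = ann.build_snn_graph(emb, k=10)
        n_prev = 0
        for res in [0.2, 1.0, 5.0, 20.0]:
            ca = ann.cluster_cells(emb, res, k=10, seed=0, graph=graph)
            assert ca.n_clusters >= n_prev
            n_prev = ca.n_clusters

    def test_colocated_duplicate_same_cluster(self, rng):
        emb = rng.standard_normal((80, 3))
        emb[1] = emb[0]  # exact duplicate
        ca = ann.cluster_cells(emb, resolution=0.5, k=10, seed=0)
        assert ca.membership.iloc[0] == ca.membership.iloc[1]

    def test_k_too_large_errors(self, rng):
        emb = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="k="):
            ann.cluster_cells(emb, 1.0, k=10)

    def test_seeded_determinism(self, rng):
        emb = rng.standard_normal((200, 4))
        a = ann.cluster_cells(emb, 2.0, k=10, seed=3)
        b = ann.cluster_cells(emb, 2.0, k=10, seed=3)
        pd.testing.assert_series_equal(a.membership, b.membership)


class TestScoreClusters:
    def _setup(self):
        # 3 clusters x 6 genes; cluster 0 expresses type-A markers only
        values = np.array(
            [
                [5.0, 5.0, 0.0, 0.0, 0.0, 0.0],  # gA1
                [4.0, 4.0, 0.0, 0.0, 0.0, 0.0],  # gA2
                [0.0, 0.0, 5.0, 5.0, 0.0, 0.0],  # gB1
                [0.0, 0.0, 4.0, 4.0, 0.0, 0.0],  # gB2
                [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # flat
                [0.0, 0.0, 0.0, 0.0, 3.0, 3.0],  # other
            ]
        )
        expr = _expr(values)
        clusters = ann.ClusterAssignment(
            "low", pd.Series([0, 0, 1, 1, 2, 2], index=expr.cell_ids)
        )
        markers = ann.MarkerSet({"A": ["g0", "g1"], "B": ["g2", "g3"]})
        return expr, clusters, markers

    def test_exclusive_markers_label(self):
        expr, clusters, markers = self._setup()
        scores = ann.score_clusters_by_markers(expr, clusters, markers)
        assert scores.labels[0] == "A"
        assert scores.labels[1] == "B"
        assert scores.labels[2] == ann.UNANNOTATED

    def test_flat_expression_all_unannotated(self):
        values = np.ones((4, 6))
        expr = _expr(values)
        clusters = ann.ClusterAssignment(
            "low", pd.Series([0, 0, 1, 1, 2, 2], index=expr.cell_ids)
        )
        markers = ann.MarkerSet({"A": ["g0"], "B": ["g1"]})
        scores = ann.score_clusters_by_markers(expr, clusters, markers, z_min=0.5)
        assert all(v == ann.UNANNOTATED for v in scores.labels.values())

    def test_z_rows_sum_to_zero(self):
        expr, clusters, markers = self._setup()
        scores = ann.score_clusters_by_markers(expr, clusters, markers)
        sums = scores.gene_z.sum(axis=1).to_numpy()
        assert np.all(np.abs(sums) < 1e-9)

    def test_empty_markers_error(self):
        expr, clusters, _ = self._setup()
        with pytest.raises(ValueError, match="marker"):
            ann.score_clusters_by_markers(expr, clusters, ann.MarkerSet({}))

    def test_cluster_label_accuracy_on_atlas(self, annotated_default):
        res = annotated_default["result"]
        tt = annotated_default["truth_types"]
        for clusters, labels in [
            (res.clusters_high, res.labels_high),
        ]:
            memb = clusters.membership
            correct = 0
            for c in range(clusters.n_clusters):
                cells = memb.index[memb == c]
                majority = tt.loc[cells].mode().iloc[0]
                if labels.loc[cells].iloc[0] == majority:
                    correct += 1
            assert correct / clusters.n_clusters >= 0.95


class TestConsensus:
    def test_agreement_rule(self):
        low = pd.Series(["A", "A", "B"], index=["c0", "c1", "c2"])
        high = pd.Series(["A", "B", "B"], index=["c0", "c1", "c2"])
        cons = ann.consensus_annotation(low, high)
        assert list(cons.table["type"]) == ["A", ann.UNANNOTATED, "B"]

    def test_identical_maps_all_confident(self):
        low = pd.Series(["A", "B"], index=["c0", "c1"])
        cons = ann.consensus_annotation(low, low.copy())
        assert (cons.table["source"] == "consensus").all()

    def test_cell_set_mismatch_errors(self):
        low = pd.Series(["A"], index=["c0"])
        high = pd.Series(["A"], index=["cX"])
        with pytest.raises(ValueError, match="different cell sets"):
            ann.consensus_annotation(low, high)

    def test_consensus_beats_single_resolutions(self, annotated_default):
        res = annotated_default["result"]
        tt = annotated_default["truth_types"]
        cons = res.consensus.table["type"]
        mask = cons != ann.UNANNOTATED
        cons_acc = (cons[mask] == tt[mask]).mean()
        for single in [res.labels_low, res.labels_high]:
            m = single != ann.UNANNOTATED
            assert cons_acc >= (single[m] == tt[m]).mean() - 1e-12


class TestReferenceProfiles:
    def test_single_cell_profile_equals_cell(self):
        values = np.array([[1.0, 5.0], [2.0, 6.0]])
        expr = _expr(values)
        cons = ann.consensus_annotation(
            pd.Series(["A", "B"], index=expr.cell_ids),
            pd.Series(["A", "B"], index=expr.cell_ids),
        )
        prof = ann.build_reference_profiles(expr, cons)
        np.testing.assert_allclose(prof.profiles["A"], values[:, 0])
        np.testing.assert_allclose(prof.profiles["B"], values[:, 1])

    def test_permutation_invariance(self, rng):
        values = rng.standard_normal((10, 20))
        expr = _expr(values)
        types = pd.Series(["A"] * 10 + ["B"] * 10, index=expr.cell_ids)
        cons = ann.consensus_annotation(types, types.copy())
        p1 = ann.build_reference_profiles(expr, cons)
        perm = rng.permutation(20)
        expr2 = ExpressionMatrix(values[:, perm], expr.gene_ids, expr.cell_ids[perm])
        cons2 = ann.consensus_annotation(types.iloc[perm], types.iloc[perm])
        p2 = ann.build_reference_profiles(expr2, cons2)
        pd.testing.assert_frame_equal(p1.profiles, p2.profiles)

    def test_no_consensus_cells_errors(self):
        expr = _expr(np.ones((3, 2)))
        una = pd.Series([ann.UNANNOTATED] * 2, index=expr.cell_ids)
        cons = ann.consensus_annotation(una, una.copy())
        with pytest.raises(ValueError, match="no consensus"):
            ann.build_reference_profiles(expr, cons)


class TestCorrelationAnnotate:
    def test_identical_cell_gets_r_one(self, rng):
        prof_vals = rng.standard_normal((20, 2))
        profiles = ann.ReferenceProfiles(
            pd.DataFrame(prof_vals, columns=["A", "B"],
                         index=[f"g{i}" for i in range(20)])
        )
        values = np.column_stack([prof_vals[:, 0], prof_vals[:, 1]])
        expr = _expr(values)
        out = ann.correlation_annotate(expr, profiles)
        assert list(out.table["type"]) == ["A", "B"]
        np.testing.assert_allclose(out.table["r"], [1.0, 1.0], atol=1e-12)

    def test_tie_flagged_lexicographic(self):
        g = [f"g{i}" for i in range(4)]
        prof = pd.DataFrame(
            {"B": [1.0, 2.0, 3.0, 4.0], "A": [1.0, 2.0, 3.0, 4.0]}, index=g
        )[["A", "B"]]
        profiles = ann.ReferenceProfiles(prof)
        expr = _expr(np.array([[1.0], [2.0], [3.0], [4.0]]))
        out = ann.correlation_annotate(expr, profiles)
        assert out.table["type"].iloc[0] == "A"
        assert bool(out.table["tie"].iloc[0])

    def test_constant_cell_unannotated(self, rng):
        prof = pd.DataFrame(
            rng.standard_normal((5, 2)), columns=["A", "B"],
            index=[f"g{i}" for i in range(5)],
        )
        profiles = ann.ReferenceProfiles(prof)
        expr = _expr(np.ones((5, 1)))
        out = ann.correlation_annotate(expr, profiles)
        assert out.table["type"].iloc[0] == ann.UNANNOTATED

    def test_unannotated_reduced_to_constant_cells(self, annotated_default):
        table = annotated_default["result"].labels.table
        expr = annotated_default["expr"]
        n_constant = int((expr.values.std(axis=0) == 0).sum())
        assert (table["type"] == ann.UNANNOTATED).sum() == n_constant


class TestStageAnnotate:
    def test_exact_profile_match(self, rng):
        prof = pd.DataFrame(
            rng.standard_normal((10, 3)),
            columns=["meristem", "elongation", "maturation"],
            index=[f"g{i}" for i in range(10)],
        )
        expr = _expr(prof["meristem"].to_numpy()[:, None])
        out = ann.stage_annotate(expr, prof)
        assert out["stage"].iloc[0] == "meristem"

    def test_identical_zone_profiles_tie(self, rng):
        col = rng.standard_normal(10)
        prof = pd.DataFrame(
            {"z1": col, "z2": col}, index=[f"g{i}" for i in range(10)]
        )
        expr = _expr(rng.standard_normal((10, 3)))
        out = ann.stage_annotate(expr, prof)
        assert out["tie"].all()


class TestSampleSimilarity:
    def test_duplicated_sample_perfect_corr(self, small_atlas):
        cm, _ = small_atlas
        sim = ann.sample_similarity(cm)
        assert np.allclose(np.diag(sim), 1.0)
        np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T, atol=1e-12)

    def test_single_sample_errors(self, small_atlas):
        cm, _ = small_atlas
        cm2 = cm.subset_cells(
            (cm.cell_meta["sample"] == cm.cell_meta["sample"].iloc[0]).to_numpy()
        )
        with pytest.raises(ValueError, match="2 samples"):
            ann.sample_similarity(cm2)

    def test_same_condition_more_similar(self):
        # needs planted condition effects, otherwise conditions are exchangeable
        cfg = AtlasConfig(
            n_genes=400, n_cells=2000, conditions=("gel", "soil"), seed=5,
        ).with_planted_degs(
            ("gel", "soil"),
            {"cortex": 30, "exodermis": 30, "stele": 30}, log2fc=3.0,
        )
        cm, _ = generate_atlas(cfg)
        sim = ann.sample_similarity(cm)
        cond = {s: s.split("_")[0] for s in sim.index}
        same, cross = [], []
        for i, si in enumerate(sim.index):
            for j, sj in enumerate(sim.index):
                if j <= i:
                    continue
                (same if cond[si] == cond[sj] else cross).append(sim.iloc[i, j])
        assert np.mean(same) > np.mean(cross)
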