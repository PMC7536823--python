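"""Centroid projection: feature selection, similarity consensus, assignment."""

import numpy as np
import pandas as pd
import pytest

import regulonatlas as ra
from regulonatlas.harmonise import ReferenceVocabulary, mapped_cells
from regulonatlas.io_formats import UNASSIGNED, ValidationError


def _expr(values, genes=None, cells=None, normalised=False):
    values = np.asarray(values, dtype=float)
    genes = genes or ["g%02d" % i for i in range(values.shape[0])]
    cells = cells or ["c%02d" % i for i in range(values.shape[1])]
    return ra.ExpressionMatrix(values, genes, cells, normalised=normalised)


class TestSelectProjectionFeatures:
    def test_planted_dropout_outlier_ranks_first(self):
        """A gene dropping out far more than its mean predicts must be the
        top feature in an otherwise trend-following matrix."""
        rng = np.random.default_rng(0)
        n_cells = 200
        rows, names = [], []
        # trend-followers: dropout decays smoothly with mean
        for i, mean in enumerate(np.geomspace(0.2, 20, 30)):
            x = rng.poisson(mean, size=n_cells).astype(float)
            rows.append(x)
            names.append("trend%02d" % i)
        # outlier: high mean but zero in most cells
        outlier = np.zeros(n_cells)
        outlier[:20] = 60.0
        rows.append(outlier)
        names.append("outlier")
        expr = _expr(np.array(rows), genes=names)
        feats = ra.select_projection_features(expr, n_features=5)
        assert feats[0] == "outlier"

    def test_zero_dropout_gene_ranks_below_high_dropout_peer(self):
        rng = np.random.default_rng(1)
        always = np.full(100, 5.0)               # 0% dropout
        half = np.where(rng.random(100) < 0.5, 10.0, 0.0)  # ~50% dropout, same mean
        filler = rng.poisson(2.0, size=(20, 100)).astype(float)
        expr = _expr(np.vstack([always, half, filler]),
                     genes=["always", "half"] + ["f%02d" % i for i in range(20)])
        feats = ra.select_projection_features(expr, n_features=expr.n_genes)
        assert feats.index("half") < feats.index("always")

    def test_n_features_total_returns_all_nonzero_genes(self, tiny_expr):
        feats = ra.select_projection_features(tiny_expr, n_features=tiny_expr.n_genes)
        expected = {g for g, row in zip(tiny_expr.gene_ids, tiny_expr.values) if row.sum() > 0}
        assert set(feats) == expected

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            ra.select_projection_features(
                _expr(np.zeros((4, 5)) + np.eye(4, 5) * 0)  # all-zero
            )


class TestComputeCentroids:
    def test_single_cell_type_centroid_is_that_cell(self):
        expr = _expr([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]], cells=["a", "b"])
        labels = pd.Series({"a": "T1", "b": "T2"})
        cent = ra.compute_centroids(expr, labels, expr.gene_ids)
        assert np.array_equal(cent["T1"].to_numpy(), [1.0, 2.0, 3.0])

    def test_median_of_odd_group(self):
        expr = _expr([[1.0, 3.0, 5.0]], genes=["g"], cells=["a", "b", "c"])
        labels = pd.Series({"a": "T", "b": "T", "c": "T"})
        cent = ra.compute_centroids(expr, labels, ["g"])
        assert cent.loc["g", "T"] == 3.0

    def test_invariant_to_cell_order(self, tiny_expr):
        labels = pd.Series(
            ["T%d" % (i % 3) for i in range(tiny_expr.n_cells)], index=tiny_expr.cell_ids
        )
        cent1 = ra.compute_centroids(tiny_expr, labels, tiny_expr.gene_ids[:5])
        perm = list(reversed(tiny_expr.cell_ids))
        shuffled = tiny_expr.subset_cells(perm)
        cent2 = ra.compute_centroids(shuffled, labels.loc[perm], tiny_expr.gene_ids[:5])
        pd.testing.assert_frame_equal(cent1, cent2)

    def test_unknown_feature_rejected(self, tiny_expr):
        labels = pd.Series("T", index=tiny_expr.cell_ids)
        with pytest.raises(ValueError, match="unknown"):
            ra.compute_centroids(tiny_expr, labels, ["nope"])


class TestProjectCells:
    def test_cell_identical_to_centroid_assigned_with_similarity_one(self):
        cent = pd.DataFrame(
            {"T1": [5.0, 1.0, 0.0, 2.0], "T2": [0.0, 4.0, 3.0, 1.0]},
            index=["g0", "g1", "g2", "g3"],
        )
        expr = _expr(cent["T1"].to_numpy()[:, None], genes=list(cent.index), cells=["c"])
        res = ra.project_cells(expr, cent, threshold=0.7)
        row = res.loc["c"]
        assert row["assigned_type"] == "T1"
        for m in ("cosine", "pearson", "spearman"):
            assert row["%s_similarity" % m] == pytest.approx(1.0)

    def test_all_similarities_below_threshold_unassigned(self):
        cent = pd.DataFrame({"T1": [1.0, 0.0, 0.0], "T2": [0.0, 1.0, 0.0]},
                            index=["g0", "g1", "g2"])
        expr = _expr(np.array([[0.2], [0.19], [5.0]]), genes=list(cent.index), cells=["c"])
        res = ra.project_cells(expr, cent, threshold=0.99)
        assert res.loc["c", "assigned_type"] == UNASSIGNED

    def test_two_of_three_measures_suffice(self):
        """Cosine and Spearman agreeing on one type beats a lone Pearson
        vote for another, provided the agreeing similarity clears the
        threshold — the worked consensus example."""
        res = pd.DataFrame  # placeholder to keep names local
        # construct via the consensus logic directly: cosine->T1, pearson->T2,
        # spearman->T1 with sims 0.9/0.8/0.75 using crafted vectors is
        # brittle; instead check the rule through a centroid layout where
        # ranks and raw values disagree.
        cent = pd.DataFrame(
            {"T1": [10.0, 4.0, 3.0, 2.0, 1.0], "T2": [2.0, 3.0, 4.0, 10.0, 1.0]},
            index=["g%d" % i for i in range(5)],
        )
        cell = np.array([9.0, 5.0, 3.0, 2.5, 1.0])
        expr = _expr(cell[:, None], genes=list(cent.index), cells=["c"])
        out = ra.project_cells(expr, cent, threshold=0.7)
        row = out.loc["c"]
        votes = [row["%s_type" % m] for m in ("cosine", "pearson", "spearman")]
        assert votes.count("T1") >= 2
        assert row["assigned_type"] == "T1"

    def test_cosine_invariant_to_cell_scaling(self):
        cent = pd.DataFrame({"T1": [1.0, 2.0, 3.0], "T2": [3.0, 2.0, 1.0]},
                            index=["g0", "g1", "g2"])
        base = np.array([1.0, 2.1, 2.9])
        e1 = _expr(base[:, None], genes=list(cent.index), cells=["c"])
        e2 = _expr((10 * base)[:, None], genes=list(cent.index), cells=["c"])
        r1 = ra.project_cells(e1, cent, 0.7)
        r2 = ra.project_cells(e2, cent, 0.7)
        assert r1.loc["c", "cosine_similarity"] == pytest.approx(
            r2.loc["c", "cosine_similarity"]
        )

    def test_spearman_invariant_to_monotone_transform(self):
        cent = pd.DataFrame({"T1": [1.0, 2.0, 3.0, 4.0], "T2": [4.0, 3.0, 2.0, 1.0]},
                            index=["g%d" % i for i in range(4)])
        base = np.array([1.0, 3.0, 4.0, 9.0])
        e1 = _expr(base[:, None], genes=list(cent.index), cells=["c"])
        e2 = _expr(np.exp(base)[:, None], genes=list(cent.index), cells=["c"])
        r1 = ra.project_cells(e1, cent, 0.7)
        r2 = ra.project_cells(e2, cent, 0.7)
        assert r1.loc["c", "spearman_similarity"] == pytest.approx(
            r2.loc["c", "spearman_similarity"]
        )

    def test_constant_cell_makes_pearson_and_spearman_abstain(self):
        cent = pd.DataFrame({"T1": [1.0, 2.0, 3.0], "T2": [3.0, 2.0, 1.0]},
                            index=["g0", "g1", "g2"])
        expr = _expr(np.full((3, 1), 2.0), genes=list(cent.index), cells=["c"])
        res = ra.project_cells(expr, cent, 0.7)
        assert np.isnan(res.loc["c", "pearson_similarity"])
        assert np.isnan(res.loc["c", "spearman_similarity"])
        assert res.loc["c", "assigned_type"] == UNASSIGNED  # one vote is not enough


class TestIntegratedAnnotation:
    def _setup(self, assigned):
        vocab = ReferenceVocabulary(["T1", "T2"], {"T1": "G1", "T2": "G2"})
        table = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(assigned))],
                "atlas": "A",
                "tissue": "t",
                "author_label": "L",
                "reference_type": UNASSIGNED,
                "cell_group": UNASSIGNED,
                "cycle_phase": "",
            }
        )
        proj = pd.DataFrame({"assigned_type": assigned},
                            index=[f"c{i}" for i in range(len(assigned))])
        return proj, vocab, ra.CellAnnotation(table)

    def test_all_assigned_keeps_every_cell(self):
        proj, vocab, base = self._setup(["T1"] * 6)
        ann, _ = ra.build_integrated_annotation(proj, vocab, base)
        assert len(mapped_cells(ann)) == 6

    def test_unassigned_cells_excluded_downstream(self):
        proj, vocab, base = self._setup(["T1"] * 9 + [UNASSIGNED])
        ann, contingency = ra.build_integrated_annotation(proj, vocab, base)
        assert len(mapped_cells(ann)) == 9
        assert ann.table["cell_group"].tolist().count("G1") == 9
        assert contingency.loc["L", "T1"] == 9

    def test_synthetic_low_noise_harmonisation_recovers_planted_types(self, small_truth):
        """Coarse-labelled noiseless atlas maps back onto planted types."""
        ref_profile = ra.AtlasProfile("ref", 20000.0, -30.0, 5.0, "reference", 600)
        coarse_profile = ra.AtlasProfile("co", 20000.0, -30.0, 5.0, "coarse", 600)
        ref_expr, ref_ann = ra.generate_atlas(small_truth, ref_profile, seed=2)
        co_expr, co_ann = ra.generate_atlas(small_truth, coarse_profile, seed=3)
        feats_r = ra.select_projection_features(ref_expr, 150)
        feats_c = ra.select_projection_features(co_expr, 150)
        feats = sorted(set(feats_r) & set(feats_c))
        from regulonatlas.preprocess import normalise

        ref_n, co_n = normalise(ref_expr), normalise(co_expr)
        labels = ref_ann.lookup("author_label").loc[ref_n.cell_ids]
        cent = ra.compute_centroids(ref_n, labels, feats)
        proj = ra.project_cells(co_n, cent, threshold=0.7)
        truth_types = co_ann.lookup("reference_type")
        acc = ra.harmonisation_accuracy(proj["assigned_type"], truth_types)
        assert acc >= 0.95


def test_vocabulary_requires_total_group_map():
    with pytest.raises(ValidationError):
        ReferenceVocabulary(["T1", "T2"], {"T1": "G1"})
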