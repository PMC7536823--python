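"""Normalisation, pseudobulk dialect, feature filter, cycle phases."""

import numpy as np
import pandas as pd
import pytest

import regulonatlas as ra
from regulonatlas.io_formats import ValidationError
from regulonatlas.preprocess import cycle_phase


def _expr(values, genes=None, cells=None, normalised=False):
    values = np.asarray(values, dtype=float)
    genes = genes or ["g%02d" % i for i in range(values.shape[0])]
    cells = cells or ["c%02d" % i for i in range(values.shape[1])]
    return ra.ExpressionMatrix(values, genes, cells, normalised=normalised)


def _annotation(cells, atlas="A", tissue="t", label="L"):
    n = len(cells)
    if isinstance(label, str):
        label = [label] * n
    return ra.CellAnnotation(pd.DataFrame({
        "cell_id": cells, "atlas": atlas, "tissue": tissue, "author_label": label,
        "reference_type": label, "cell_group": "G1x", "cycle_phase": "",
    }))


class TestNormalise:
    def test_proportional_cells_become_identical(self):
        expr = _expr([[2.0, 6.0], [4.0, 12.0]])
        out = ra.normalise(expr)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_hand_scaling_example(self):
        # libraries 2 and 4; median library 3; both cells scale to [3, 0]
        expr = _expr([[2.0, 4.0], [0.0, 0.0]])
        out = ra.normalise(expr)
        np.testing.assert_allclose(out.values[0], np.log1p(3.0))
        np.testing.assert_allclose(out.values[1], 0.0)

    def test_zero_library_cell_dropped_with_warning(self):
        expr = _expr([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero library"):
            out = ra.normalise(expr)
        assert out.n_cells == 1


class TestRegressAndScale:
    def _covs(self, cells, lib, mito=None):
        return pd.DataFrame(
            {"library_size": lib, "mito_fraction": mito if mito is not None else 0.0},
            index=cells,
        )

    def test_gene_linear_in_library_size_becomes_zero(self):
        lib = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        expr = _expr((2.0 + 3.0 * lib)[None, :], genes=["g"], normalised=True)
        out = ra.regress_and_scale(expr, self._covs(expr.cell_ids, lib))
        np.testing.assert_allclose(out.values[0], 0.0, atol=1e-10)

    def test_output_genes_centred_and_unit_variance(self, tiny_expr):
        rng = np.random.default_rng(2)
        covs = self._covs(tiny_expr.cell_ids, rng.random(tiny_expr.n_cells),
                          rng.random(tiny_expr.n_cells))
        out = ra.regress_and_scale(tiny_expr, covs)
        nondegenerate = out.values.std(axis=1) > 0
        assert nondegenerate.any()
        np.testing.assert_allclose(out.values[nondegenerate].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values[nondegenerate].std(axis=1), 1.0, atol=1e-10)

    def test_gene_orthogonal_to_covariates_equals_plain_zscore(self):
        rng = np.random.default_rng(3)
        n = 400
        lib = rng.normal(size=n)
        y = rng.normal(size=n)
        y = y - np.polyval(np.polyfit(lib, y, 1), lib)  # orthogonalise vs lib
        y = y - y.mean() + 5.0
        y = y - y.min() + 0.1  # keep non-negative for the container
        expr = _expr(y[None, :], genes=["g"], normalised=True)
        out = ra.regress_and_scale(expr, self._covs(expr.cell_ids, lib))
        z = (y - y.mean()) / y.std()
        np.testing.assert_allclose(out.values[0], z, atol=1e-8)

    def test_constant_covariates_degrade_to_centring(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _expr(y[None, :], genes=["g"], normalised=True)
        out = ra.regress_and_scale(expr, self._covs(expr.cell_ids, 1.0))
        z = (y - y.mean()) / y.std()
        np.testing.assert_allclose(out.values[0], z, atol=1e-10)


class TestSelectExpressedFeatures:
    def test_inclusive_ten_percent_boundary(self):
        values = np.zeros((2, 100))
        values[0, :10] = 1.0  # exactly 10% -> kept
        values[1, :9] = 1.0   # 9% -> dropped
        expr = _expr(values, genes=["at_boundary", "below"])
        assert ra.select_expressed_features(expr, 0.10) == ["at_boundary"]

    def test_fraction_one_requires_everywhere_nonzero(self):
        values = np.ones((2, 10))
        values[1, 3] = 0.0
        expr = _expr(values, genes=["full", "gap"])
        assert ra.select_expressed_features(expr, 1.0) == ["full"]


class TestMakePseudobulk:
    def test_identical_members_give_that_vector(self):
        cell_vec = np.array([1.0, 0.0, 3.5])
        values = np.tile(cell_vec[:, None], (1, 50))
        cells = ["c%02d" % i for i in range(50)]
        expr = _expr(values, cells=cells)
        pb = ra.make_pseudobulk(expr, _annotation(cells), cells_per_sample=50, seed=0)
        assert pb.values.shape[1] == 1
        np.testing.assert_allclose(pb.values[:, 0], cell_vec)

    def test_nonzero_mean_dialect(self):
        # gene values [2, 0, 4] across a 3-cell sample average to 3.0
        cells = ["a", "b", "c"]
        expr = _expr(np.array([[2.0, 0.0, 4.0]]), genes=["g"], cells=cells)
        pb = ra.make_pseudobulk(expr, _annotation(cells), cells_per_sample=3, seed=0)
        assert pb.values[0, 0] == pytest.approx(3.0)

    def test_all_zero_gene_yields_zero_not_missing(self):
        cells = ["a", "b", "c"]
        expr = _expr(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]]), cells=cells)
        pb = ra.make_pseudobulk(expr, _annotation(cells), cells_per_sample=3, seed=0)
        assert pb.values[0, 0] == 0.0

    def test_small_stratum_dropped(self):
        cells = ["c%02d" % i for i in range(49)]
        expr = _expr(np.ones((3, 49)), cells=cells)
        with pytest.raises(ValidationError, match="no stratum"):
            ra.make_pseudobulk(expr, _annotation(cells), cells_per_sample=50, seed=0)

    def test_disjoint_samples_and_floor_count(self):
        cells = ["c%03d" % i for i in range(130)]
        expr = _expr(np.ones((2, 130)), cells=cells)
        pb = ra.make_pseudobulk(expr, _annotation(cells), cells_per_sample=50, seed=1)
        assert len(pb.sample_ids) == 2  # floor(130/50)
        members = [set(m.split(";")) for m in pb.sample_meta["member_cells"]]
        assert not (members[0] & members[1])
        assert all(len(m) == 50 for m in members)

    def test_invariant_to_cell_order_given_seed(self):
        rng = np.random.default_rng(4)
        cells = ["c%03d" % i for i in range(60)]
        values = rng.poisson(2.0, size=(5, 60)).astype(float)
        expr = _expr(values, cells=cells)
        ann = _annotation(cells)
        pb1 = ra.make_pseudobulk(expr, ann, 20, seed=9)
        perm = list(reversed(cells))
        pb2 = ra.make_pseudobulk(expr.subset_cells(perm), ann, 20, seed=9)
        np.testing.assert_allclose(pb1.values, pb2.values)
        assert pb1.sample_meta["member_cells"].tolist() == pb2.sample_meta["member_cells"].tolist()

    def test_plain_mean_conserves_stratum_mean_library(self):
        rng = np.random.default_rng(5)
        cells = ["c%03d" % i for i in range(40)]
        values = rng.poisson(3.0, size=(6, 40)).astype(float)
        expr = _expr(values, cells=cells)
        pb = ra.make_pseudobulk(expr, _annotation(cells), 40, seed=0, nonzero_mean=False)
        mean_library = values.sum(axis=0).mean()
        assert pb.values[:, 0].sum() == pytest.approx(mean_library)

    def test_pseudobulk_reduces_noise(self, small_atlas):
        expr, ann = small_atlas
        normed = ra.normalise(expr)
        pb = ra.make_pseudobulk(normed, ann.subset(normed.cell_ids), 20, seed=0)
        # compare per-gene variance within one author label
        label = pb.sample_meta["author_label"].mode().iloc[0]
        cols = pb.sample_meta["author_label"] == label
        var_pb = pb.values[:, cols.to_numpy()].var(axis=1).mean()
        sc_cells = ann.table.loc[ann.table["author_label"] == label, "cell_id"]
        idx = [normed.cell_ids.index(c) for c in sc_cells if c in set(normed.cell_ids)]
        var_sc = normed.values[:, idx].var(axis=1).mean()
        assert var_pb <= var_sc


class TestCycleScoring:
    @pytest.mark.parametrize(
        "s,g2m,expected",
        [(0.8, 0.2, "S"), (0.3, 0.3, "G1"), (0.6, 0.9, "G2M"), (0.5, 0.5, "G1")],
    )
    def test_phase_decision_rule(self, s, g2m, expected):
        assert cycle_phase(s, g2m) == expected

    def test_marker_driven_cell_gets_its_phase(self):
        rng = np.random.default_rng(6)
        n_genes, n_cells = 60, 8
        values = rng.poisson(2.0, size=(n_genes, n_cells)).astype(float)
        genes = ["g%02d" % i for i in range(n_genes)]
        s_set, g2m_set = set(genes[:5]), set(genes[5:10])
        values[:5, 0] += 10.0   # cell 0: strong S markers
        values[5:10, 1] += 10.0  # cell 1: strong G2M markers
        expr = _expr(values, genes=genes)
        scores = ra.score_cell_cycle(expr, s_set, g2m_set, seed=0)
        assert scores.loc[0, "phase"] == "S"
        assert scores.loc[1, "phase"] == "G2M"

    def test_flat_cell_is_g1(self):
        values = np.full((30, 3), 2.0)
        expr = _expr(values)
        scores = ra.score_cell_cycle(
            expr, set(expr.gene_ids[:4]), set(expr.gene_ids[4:8]), seed=0
        )
        assert (scores["phase"] == "G1").all()

    def test_empty_intersection_rejected(self, tiny_expr):
        with pytest.raises(ValidationError, match="intersection"):
            ra.score_cell_cycle(tiny_expr, {"nope"}, set(tiny_expr.gene_ids[:3]), seed=0)

    def test_deterministic_given_seed(self, tiny_expr):
        s, g = set(tiny_expr.gene_ids[:4]), set(tiny_expr.gene_ids[4:8])
        a = ra.score_cell_cycle(tiny_expr, s, g, seed=3)
        b = ra.score_cell_cycle(tiny_expr, s, g, seed=3)
        pd.testing.assert_frame_equal(a, b)
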