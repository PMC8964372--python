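"""Min-Max scaling, multi-index layout and image rendering."""

import numpy as np
import pytest

from survimage.annotation_io import GeneGroupAssignment
from survimage.cohort_data import ExpressionMatrix
from survimage.image_builder import (
    GeneImageLayout,
    MinMaxScaler,
    apply_minmax,
    build_layout,
    fit_minmax,
    render_image,
    render_images,
)


def _matrix(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return ExpressionMatrix(rows, genes, [f"s{j}" for j in range(rows.shape[1])])


class TestMinMax:
    def test_fit_direct_min_max(self):
        s = fit_minmax(_matrix([[2, 4, 6]]))
        assert s.x_min[0] == 2 and s.x_max[0] == 6

    def test_constant_and_single_sample(self):
        s = fit_minmax(_matrix([[5, 5], [3, 3]]))
        np.testing.assert_array_equal(s.x_min, s.x_max)
        s1 = fit_minmax(_matrix([[7.0]]))
        assert s1.x_min[0] == s1.x_max[0] == 7.0

    def test_linear_map_endpoints_and_midpoint(self):
        m = _matrix([[2, 4, 6]])
        scaled = apply_minmax(fit_minmax(m), m)
        np.testing.assert_allclose(scaled[0], [0, 0.5, 1])

    def test_out_of_range_clipped(self):
        s = fit_minmax(_matrix([[2, 6]]))
        new = _matrix([[8, 0]])
        scaled = apply_minmax(s, new)
        np.testing.assert_allclose(scaled[0], [1, 0])

    def test_zero_range_maps_to_zero(self):
        m = _matrix([[5, 5]])
        np.testing.assert_array_equal(apply_minmax(fit_minmax(m), m), [[0, 0]])

    def test_unknown_gene_rejected(self):
        s = fit_minmax(_matrix([[1, 2]], ["g0"]))
        with pytest.raises(KeyError):
            apply_minmax(s, _matrix([[1, 2]], ["other"]))


def _assignment(mapping, order):
    return GeneGroupAssignment(order, mapping)


class TestBuildLayout:
    def test_group_then_descending_mean(self):
        a = _assignment({"a": "G1", "b": "G1", "c": "G2"}, ["G1", "G2"])
        scaler = fit_minmax(_matrix(np.zeros((3, 2)), ["a", "b", "c"]))
        layout = build_layout(a, {"a": 1.0, "b": 3.0, "c": 2.0}, scaler)
        assert layout.ordered_genes == ["b", "a", "c"]
        assert layout.group_boundaries == [("G1", 0, 2), ("G2", 2, 3)]

    @pytest.mark.parametrize("k, side", [(5, 3), (1000, 32), (4, 2), (1, 1)])
    def test_grid_side_is_ceil_sqrt(self, k, side):
        genes = [f"g{i:04d}" for i in range(k)]
        a = _assignment({g: "G" for g in genes}, ["G"])
        scaler = fit_minmax(_matrix(np.zeros((k, 2)), genes))
        layout = build_layout(a, {g: 0.0 for g in genes}, scaler)
        assert layout.side == side

    def test_missing_mean_rejected(self):
        a = _assignment({"a": "G"}, ["G"])
        scaler = fit_minmax(_matrix(np.zeros((1, 2)), ["a"]))
        with pytest.raises(ValueError, match="mean"):
            build_layout(a, {}, scaler)

    def test_order_invariant_to_input_gene_order(self, rng):
        genes = [f"g{i}" for i in range(9)]
        means = {g: float(rng.random()) for g in genes}
        vals = rng.random((9, 4))
        order1 = list(genes)
        perm = list(rng.permutation(9))
        a1 = _assignment({g: "G" for g in order1}, ["G"])
        a2 = _assignment({genes[i]: "G" for i in perm}, ["G"])
        s1 = fit_minmax(_matrix(vals, genes))
        s2 = fit_minmax(_matrix(vals[perm], [genes[i] for i in perm]))
        l1 = build_layout(a1, means, s1)
        l2 = build_layout(a2, means, s2)
        assert l1.ordered_genes == l2.ordered_genes

    def test_json_round_trip(self, tmp_path):
        a = _assignment({"a": "G1", "b": "G1", "c": "G2"}, ["G1", "G2"])
        scaler = fit_minmax(_matrix(np.arange(6).reshape(3, 2), ["a", "b", "c"]))
        layout = build_layout(a, {"a": 1.0, "b": 3.0, "c": 2.0}, scaler)
        layout.to_json(tmp_path / "layout.json")
        again = GeneImageLayout.from_json(tmp_path / "layout.json")
        assert again.ordered_genes == layout.ordered_genes
        assert again.side == layout.side
        np.testing.assert_array_equal(again.scaler.x_min, layout.scaler.x_min)


class TestRenderImage:
    def _layout(self, k, values):
        genes = [f"g{i}" for i in range(k)]
        a = _assignment({g: "G" for g in genes}, ["G"])
        m = _matrix(values, genes)
        scaler = fit_minmax(m)
        # means chosen so the sorted order is g0, g1, ... (descending means)
        means = {g: float(k - i) for i, g in enumerate(genes)}
        return build_layout(a, means, scaler), m

    def test_row_major_fill(self):
        # every gene spans [0, 1] (samples s1, s2), so s0's scaled values
        # are exactly 1, .5, .25, 0 for genes g0..g3
        vals = np.array([[1, 0, 1], [0.5, 0, 1], [0.25, 0, 1], [0, 0, 1]])
        layout, m = self._layout(4, vals)
        img = render_image(layout, m.sample_vector("s0"), "s0")
        np.testing.assert_allclose(img.pixels, [[1, 0.5], [0.25, 0]])

    def test_pad_cells_are_zero(self):
        vals = np.ones((3, 2)) * np.array([1, 2])
        layout, m = self._layout(3, vals)
        img = render_image(layout, m.sample_vector("s0"), "s0")
        assert img.pixels[1, 1] == 0.0

    def test_all_zero_vector_gives_zero_image(self):
        vals = np.vstack([np.array([0.0, 1.0])] * 4)
        layout, m = self._layout(4, vals)
        img = render_image(layout, m.sample_vector("s0"))
        np.testing.assert_array_equal(img.pixels, np.zeros((2, 2)))

    def test_missing_gene_value_rejected(self):
        layout, m = self._layout(4, np.random.default_rng(0).random((4, 3)))
        with pytest.raises(KeyError):
            render_image(layout, {"g0": 0.1}, "s")

    def test_batch_matches_single_sample_rendering(self, rng):
        vals = rng.random((7, 5))
        layout, m = self._layout(7, vals)
        batch = render_images(layout, m)
        for j, sid in enumerate(m.sample_ids):
            single = render_image(layout, m.sample_vector(sid), sid)
            np.testing.assert_allclose(batch[j], single.pixels, atol=1e-12)


class TestImageInvariants:
    def test_pixel_multiset_bijection_and_sample_independence(self, small_cohort, small_annotation, rng):
        """Non-pad pixels equal the scaled gene values; rendering is per-sample."""
        from survimage.annotation_io import (
            assign_groups_from_hierarchy,
            assign_groups_from_pathways,
        )

        cohort, _ = small_cohort
        assets = small_annotation.assets()
        ids = cohort.labeled_sample_ids[:20]
        m = cohort.expression.subset_samples(ids)
        genes = m.gene_ids[:30]
        msub = m.subset_genes(genes)
        scaler = fit_minmax(msub)
        means = dict(zip(genes, msub.values.mean(axis=1)))
        scaled = apply_minmax(scaler, msub)
        for assign in (
            assign_groups_from_hierarchy(assets.hierarchy, assets.annotation_to_gene, genes),
            assign_groups_from_pathways(assets.pathways, genes),
        ):
            layout = build_layout(assign, means, scaler)
            imgs = render_images(layout, msub)
            for j in range(len(ids)):
                flat = np.sort(imgs[j].ravel())[-len(genes):]
                np.testing.assert_allclose(
                    np.sort(scaled[:, j]), flat, atol=1e-12
                )
            # independence: rendering a single sample matches the batch bit for bit
            solo = render_image(layout, msub.sample_vector(ids[3]), ids[3])
            np.testing.assert_array_equal(solo.pixels, imgs[3])
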