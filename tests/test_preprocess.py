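"""Patch extraction, normalization, HVG union, batch correction."""

import numpy as np
import pytest

from histex import (
    DataError,
    ExpressionMatrix,
    SlideImage,
    SpotGrid,
    batch_correct,
    drop_empty_spots,
    extract_patches,
    normalize_expression,
    select_hvg_union,
)


def grid_image(side=64, seed=0):
    rng = np.random.default_rng(seed)
    return SlideImage(pixels=rng.integers(0, 256, (side, side, 3), dtype=np.uint8))


def spots_at(coords, in_tissue=None):
    coords = np.asarray(coords, dtype=float)
    return SpotGrid(spot_ids=[f"s{i}" for i in range(len(coords))],
                    pixel_xy=coords,
                    in_tissue=None if in_tissue is None
                    else np.asarray(in_tissue, dtype=bool))


def norm_matrix(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        spot_ids=[f"s{i}" for i in range(values.shape[0])],
        gene_ids=gene_ids or [f"g{j}" for j in range(values.shape[1])],
        layer="normalized",
    )


class TestExtractPatches:
    def test_center_spot_full_size_patch_is_whole_image(self):
        img = grid_image(side=224)
        ps = extract_patches(img, spots_at([(112, 112)]), patch_size=224)
        np.testing.assert_array_equal(ps.patches[0].transpose(1, 2, 0), img.pixels)

    def test_corner_spot_padded_white(self):
        img = grid_image(side=64)
        ps = extract_patches(img, spots_at([(0, 0)]), patch_size=32)
        patch = ps.patches[0].transpose(1, 2, 0)
        assert np.all(patch[:16, :16] == 255)          # top-left quadrant padded
        np.testing.assert_array_equal(patch[16:, 16:], img.pixels[:16, :16])

    def test_matches_independent_slice_oracle(self):
        # checkerboard so any offset error shows up
        side, p = 96, 24
        board = ((np.indices((side, side)).sum(axis=0) % 2) * 255).astype(np.uint8)
        img = SlideImage(pixels=np.stack([board] * 3, axis=-1))
        r, c = 40, 57
        ps = extract_patches(img, spots_at([(r, c)]), patch_size=p)
        oracle = img.pixels[r - p // 2 : r + p // 2, c - p // 2 : c + p // 2]
        np.testing.assert_array_equal(ps.patches[0].transpose(1, 2, 0), oracle)

    def test_shape_and_in_tissue_filter(self):
        img = grid_image(side=64)
        spots = spots_at([(10, 10), (20, 20), (30, 30)],
                         in_tissue=[True, False, True])
        ps = extract_patches(img, spots, patch_size=16)
        assert ps.patches.shape == (2, 3, 16, 16)
        assert ps.spot_ids == ["s0", "s2"]

    def test_spot_outside_image_raises(self):
        img = grid_image(side=64)
        with pytest.raises(DataError, match="s0"):
            extract_patches(img, spots_at([(200, 200)]), patch_size=16)


class TestNormalizeExpression:
    def _counts(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            values=values, spot_ids=[f"s{i}" for i in range(values.shape[0])],
            gene_ids=[f"g{j}" for j in range(values.shape[1])], layer="counts")

    def test_hand_computed_values(self):
        out = normalize_expression(self._counts([[2, 2], [1, 3]]), target_sum=4)
        np.testing.assert_allclose(out.values[0], [np.log(3), np.log(3)])
        # row [1,3] at target 8 scales to [2,6]
        out8 = normalize_expression(self._counts([[1, 3]]), target_sum=8)
        np.testing.assert_allclose(out8.values[0], [np.log(3), np.log(7)])
        assert out.layer == "normalized"

    def test_row_total_conserved_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.poisson(4.0, size=(6, 9)).astype(float)
            counts[:, 0] += 1
            out = normalize_expression(self._counts(counts), target_sum=1e4)
            np.testing.assert_allclose(np.expm1(out.values).sum(axis=1), 1e4,
                                       rtol=1e-9)

    def test_matches_scanpy_normalization(self):
        """Independent cross-check against the community implementation."""
        sc = pytest.importorskip("scanpy")
        import anndata

        rng = np.random.default_rng(7)
        counts = rng.poisson(5.0, size=(8, 6)).astype(float) + 1
        ad = anndata.AnnData(counts.copy())
        sc.pp.normalize_total(ad, target_sum=1e4)
        sc.pp.log1p(ad)
        ours = normalize_expression(self._counts(counts), target_sum=1e4)
        np.testing.assert_allclose(ours.values, ad.X, rtol=1e-6)

    def test_zero_total_spot_raises_and_drop_empty_works(self):
        counts = self._counts([[1, 2], [0, 0]])
        with pytest.raises(DataError, match="s1"):
            normalize_expression(counts)
        kept, dropped = drop_empty_spots(counts)
        assert dropped == ["s1"]
        assert kept.spot_ids == ["s0"]


class TestSelectHvgUnion:
    def test_identical_sections_union_is_n_hvg(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 8))
        a, b = norm_matrix(vals), norm_matrix(vals.copy())
        assert len(select_hvg_union([a, b], n_hvg=3)) == 3

    def test_disjoint_top_sets_union_is_double(self):
        # section a varies only genes 0..2; section b only genes 3..5
        a_vals = np.zeros((6, 6))
        b_vals = np.zeros((6, 6))
        a_vals[:, :3] = np.random.default_rng(1).normal(size=(6, 3)) * 5
        b_vals[:, 3:] = np.random.default_rng(2).normal(size=(6, 3)) * 5
        union = select_hvg_union([norm_matrix(a_vals), norm_matrix(b_vals)],
                                 n_hvg=3)
        assert len(union) == 6

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(5)
        vals_a = rng.normal(size=(12, 6)) * rng.uniform(0.1, 3.0, size=6)
        vals_b = rng.normal(size=(12, 6)) * rng.uniform(0.1, 3.0, size=6)
        a, b = norm_matrix(vals_a), norm_matrix(vals_b)
        union = select_hvg_union([a, b], n_hvg=2)
        expected = set()
        for vals in (vals_a, vals_b):
            var = [(vals[:, j].var(), a.gene_ids[j]) for j in range(6)]
            top = sorted(var, key=lambda t: (-t[0], t[1]))[:2]
            expected.update(g for _, g in top)
        assert union == sorted(expected)

    def test_deterministic_under_column_permutation(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(10, 7)) * rng.uniform(0.5, 2.0, size=7)
        a = norm_matrix(vals)
        perm = rng.permutation(7)
        b = norm_matrix(vals[:, perm], gene_ids=[a.gene_ids[j] for j in perm])
        assert select_hvg_union([a], 3) == select_hvg_union([b], 3)

    def test_n_hvg_too_large_raises(self):
        with pytest.raises(DataError, match="n_hvg"):
            select_hvg_union([norm_matrix(np.ones((3, 2)))], n_hvg=5)


class TestBatchCorrect:
    def test_none_is_identity_with_relabel(self):
        a = norm_matrix(np.arange(6.0).reshape(3, 2))
        (out,) = batch_correct([a], method="none")
        np.testing.assert_array_equal(out.values, a.values)
        assert out.layer == "corrected"

    def test_center_scale_zero_means_per_section(self):
        rng = np.random.default_rng(3)
        sections = [norm_matrix(rng.normal(size=(8, 5)) + i * 2) for i in range(2)]
        out = batch_correct(sections, method="center_scale")
        for o in out:
            np.testing.assert_allclose(o.values.mean(axis=0), 0, atol=1e-9)
            assert np.all(np.isfinite(o.values))

    def test_center_scale_matches_hand_computation(self):
        a = norm_matrix(np.array([[1.0, 0.0, 2.0], [3.0, 0.0, 4.0]]))
        b = norm_matrix(np.array([[5.0, 1.0, 0.0], [7.0, 1.0, 2.0]]))
        out_a, out_b = batch_correct([a, b], method="center_scale")
        pooled = np.vstack([a.values, b.values])
        sd = pooled.std(axis=0)
        sd[sd == 0] = 1.0  # zero-variance genes divided by 1
        np.testing.assert_allclose(
            out_a.values, (a.values - a.values.mean(axis=0)) / sd)
        np.testing.assert_allclose(
            out_b.values, (b.values - b.values.mean(axis=0)) / sd)

    def test_external_hook_shape_validated(self):
        a = norm_matrix(np.ones((3, 2)))
        with pytest.raises(DataError, match="shape"):
            batch_correct([a], method="external_harmony",
                          harmony_hook=lambda vs: [np.ones((2, 2))])
        (out,) = batch_correct([a], method="external_harmony",
                               harmony_hook=lambda vs: [v * 2 for v in vs])
        np.testing.assert_array_equal(out.values, a.values * 2)
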