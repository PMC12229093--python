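"""Preprocessing: cropping, normalization, panel selection, augmentation, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotfusion.spatial_dataset import (
    GenePanel,
    SpotSlice,
    augment_patch,
    center_crop,
    load_slice,
    normalize_expression,
    read_slice_dir,
    select_hvg,
    select_target_genes,
    write_slice_dir,
)
from spotfusion.synthetic import SyntheticSpec, generate_slice


class TestCenterCrop:
    def test_interior_crop_is_plain_slice(self, rng):
        img = rng.integers(0, 255, (100, 100, 3), dtype=np.uint8)
        out = center_crop(img, (50, 50), 40)
        assert np.array_equal(out, img[30:70, 30:70])

    def test_full_size_centered_is_identity(self, rng):
        img = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
        assert np.array_equal(center_crop(img, (20, 20), 40), img)

    def test_border_crop_matches_pad_then_slice_oracle(self, rng):
        img = rng.integers(0, 255, (60, 60, 3), dtype=np.uint8)
        size = 40
        out = center_crop(img, (5, 5), size)
        padded = np.pad(img, ((size, size), (size, size), (0, 0)))
        oracle = padded[size + 5 - size // 2: size + 5 + size - size // 2,
                        size + 5 - size // 2: size + 5 + size - size // 2]
        assert np.array_equal(out, oracle)

    def test_center_pixel_preserved(self, rng):
        img = rng.integers(0, 255, (30, 50, 3), dtype=np.uint8)
        out = center_crop(img, (10, 20), 9)
        assert np.array_equal(out[4, 4], img[20, 10])

    def test_center_outside_image_errors(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="outside"):
            center_crop(img, (20, 5), 4)


class TestNormalize:
    def test_hand_arithmetic(self):
        counts = np.array([[1, 1, 2]])
        out = normalize_expression(counts)
        expected = np.log1p(np.array([250_000, 250_000, 500_000]))
        assert np.allclose(out[0], expected)

    def test_zero_count_maps_to_zero_and_single_gene_value(self):
        out = normalize_expression(np.array([[0, 7], [3, 0]]))
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0
        assert np.isclose(out[0, 1], np.log1p(1e6))
        assert np.isclose(out[1, 0], np.log1p(1e6))

    def test_all_zero_spot_identified_in_error(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_expression(np.array([[1, 2], [0, 0]]))

    def test_cpm_row_sums_and_rank_preserved(self, rng):
        counts = rng.integers(0, 50, (20, 30))
        counts[:, 0] += 1  # no all-zero spots
        out = normalize_expression(counts)
        assert np.allclose((np.expm1(out)).sum(axis=1), 1e6, rtol=1e-6)
        for i in range(20):
            order_c = np.argsort(counts[i], kind="stable")
            order_n = np.argsort(out[i], kind="stable")
            assert np.array_equal(order_c, order_n)


class TestPanels:
    def test_constant_gene_ranks_last(self, rng):
        x = rng.random((30, 5))
        x[:, 2] = 1.3
        names = list("abcde")
        panel = select_hvg(x, names, k=4)
        assert "c" not in panel.names and panel.size == 4

    def test_k_equals_all_genes_is_deterministic(self, rng):
        x = rng.random((10, 6))
        names = [f"g{i}" for i in range(6)]
        p1 = select_hvg(x, names, k=6)
        p2 = select_hvg(x, names, k=6)
        assert p1.names == p2.names and set(p1.names) == set(names)

    def test_planted_high_dispersion_genes_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.normal(5.0, 0.1, (200, 40)).clip(min=0)
        planted = [3, 11, 27]
        for g in planted:
            x[:, g] = rng.choice([0.2, 9.0], size=200)
        names = [f"g{i:02d}" for i in range(40)]
        panel = select_hvg(x, names, k=3)
        assert sorted(panel.names) == [names[g] for g in planted]

    def test_target_selection_matches_sort_oracle(self, rng):
        x = rng.random((25, 15))
        names = [f"g{i:02d}" for i in range(15)]
        panel = select_target_genes(x, names, k=7)
        oracle = [names[i] for i in np.argsort(-x.mean(axis=0), kind="stable")[:7]]
        assert panel.names == oracle

    def test_tie_at_boundary_keeps_lexicographically_smaller(self):
        x = np.zeros((4, 3))
        x[:, 1] = 2.0  # columns 0 and 2 tie at zero
        panel = select_target_genes(x, ["zz", "mid", "aa"], k=2)
        assert panel.names == ["mid", "aa"]

    def test_selection_permutation_invariant(self, rng):
        x = rng.random((12, 9))
        names = [f"g{i}" for i in range(9)]
        perm = rng.permutation(9)
        p1 = select_hvg(x, names, k=4)
        p2 = select_hvg(x[:, perm], [names[i] for i in perm], k=4)
        assert set(p1.names) == set(p2.names)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            select_hvg(rng.random((5, 3)), list("abc"), k=4)
        with pytest.raises(ValueError):
            select_target_genes(rng.random((5, 3)), list("abc"), k=4)


class TestAugment:
    def test_same_seed_is_identical(self, rng):
        patch = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
        a = augment_patch(patch, 123)
        b = augment_patch(patch, 123)
        assert np.array_equal(a, b)

    def test_zero_jitter_zero_flip_is_identity(self, rng):
        patch = rng.integers(0, 255, (40, 40, 3), dtype=np.uint8)
        out = augment_patch(patch, 7, scale_range=(1.0, 1.0), flip_prob=0.0,
                            brightness=0.0, contrast=0.0)
        assert np.array_equal(out, patch)

    def test_mean_shift_bounded_by_brightness(self, rng):
        # mid-range patch so clipping cannot bias the mean
        patch = np.full((40, 40, 3), 128, dtype=np.uint8)
        bound = 0.1
        for seed in range(100):
            out = augment_patch(patch, seed, scale_range=(1.0, 1.0), flip_prob=0.0,
                                brightness=bound, contrast=0.0)
            shift = abs(out.astype(float).mean() - 128.0)
            assert shift <= bound * 255.0 + 0.5  # rounding slack


class TestSliceIO:
    def test_round_trip_equals_original(self, tmp_path, small_slice):
        slc, _ = small_slice
        write_slice_dir(slc, tmp_path / "slice")
        back = read_slice_dir(tmp_path / "slice")
        assert back.slice_id == slc.slice_id
        assert np.array_equal(back.patches, slc.patches)
        assert np.array_equal(back.counts, slc.counts)
        assert back.gene_names == slc.gene_names
        assert np.allclose(back.coords, slc.coords)

    def test_load_slice_crops_at_coordinates(self, tmp_path, rng):
        from PIL import Image
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        img = rng.integers(0, 255, (200, 200, 3), dtype=np.uint8)
        Image.fromarray(img).save(tmp_path / "slide.png")
        counts = rng.integers(1, 9, (3, 4))
        mmwrite(tmp_path / "counts.mtx", csr_matrix(counts))
        (tmp_path / "genes.tsv").write_text("g1\ng2\ng3\ng4\n")
        (tmp_path / "coords.tsv").write_text("50\t60\n100\t100\n150\t40\n")
        slc = load_slice(tmp_path / "counts.mtx", tmp_path / "genes.tsv",
                         tmp_path / "coords.tsv", tmp_path / "slide.png", patch_size=40)
        assert slc.n == 3 and slc.patches.shape == (3, 40, 40, 3)
        assert np.array_equal(slc.patches[0], img[40:80, 30:70])

    def test_row_count_mismatch_names_file(self, tmp_path, rng):
        from PIL import Image
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        Image.fromarray(np.zeros((50, 50, 3), dtype=np.uint8)).save(tmp_path / "s.png")
        mmwrite(tmp_path / "counts.mtx", csr_matrix(rng.integers(1, 5, (3, 2))))
        (tmp_path / "genes.tsv").write_text("a\nb\n")
        (tmp_path / "coords.tsv").write_text("10\t10\n20\t20\n")
        with pytest.raises(ValueError, match="coords.tsv"):
            load_slice(tmp_path / "counts.mtx", tmp_path / "genes.tsv",
                       tmp_path / "coords.tsv", tmp_path / "s.png", patch_size=8)

    def test_out_of_bounds_coordinates_list_spots(self, tmp_path, rng):
        from PIL import Image
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        Image.fromarray(np.zeros((50, 50, 3), dtype=np.uint8)).save(tmp_path / "s.png")
        mmwrite(tmp_path / "counts.mtx", csr_matrix(rng.integers(1, 5, (2, 2))))
        (tmp_path / "genes.tsv").write_text("a\nb\n")
        (tmp_path / "coords.tsv").write_text("10\t10\n99\t10\n")
        with pytest.raises(ValueError, match=r"\[1\]"):
            load_slice(tmp_path / "counts.mtx", tmp_path / "genes.tsv",
                       tmp_path / "coords.tsv", tmp_path / "s.png", patch_size=8)


class TestInvariants:
    def test_spot_slice_validation(self, rng):
        with pytest.raises(ValueError, match="inconsistent"):
            SpotSlice("s", np.zeros((2, 4, 4, 3), np.uint8), np.ones((3, 2), int),
                      ["a", "b"], np.zeros((3, 2)))
        with pytest.raises(ValueError, match="unique"):
            SpotSlice("s", np.zeros((2, 4, 4, 3), np.uint8), np.ones((2, 2), int),
                      ["a", "a"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="non-negative"):
            SpotSlice("s", np.zeros((2, 4, 4, 3), np.uint8),
                      np.array([[1, -1], [0, 2]]), ["a", "b"], np.zeros((2, 2)))

    def test_gene_panel_kinds(self):
        with pytest.raises(ValueError):
            GenePanel(["a"], kind="other")
        assert GenePanel(["a", "b"], kind="hvg").size == 2

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_generated_slices_always_valid(self, seed):
        spec = SyntheticSpec(grid_shape=(2, 3), n_genes=10, latent_dim=2,
                             image_size=8, rng_seed=seed)
        slc, z = generate_slice(spec)
        slc.validate()  # raises on violation
        assert z.shape == (6, 2)
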