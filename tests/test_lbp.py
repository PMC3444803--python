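import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbptop import LabelVolume, Volume
from lbptop import lbp as L
from oracles import lbp_code_at, uniformity_oracle

P8_FULL = 255  # all-ones code for P=8


class TestPlaneCodes:
    def test_constant_volume_codes_all_ones(self):
        # ties count as >=, so a flat image produces the all-ones code
        v = Volume(np.full((10, 10, 10), 4.2))
        for plane in L.PLANES:
            codes, valid = L.lbp_codes_plane(v, L.NeighborhoodSpec(plane=plane))
            assert valid.any()
            assert np.all(codes[valid] == P8_FULL)

    def test_strict_local_maximum_codes_zero(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 10.0
        codes, valid = L.lbp_codes_plane(Volume(data), L.NeighborhoodSpec(plane="xy"))
        assert valid[4, 4, 4] and codes[4, 4, 4] == 0

    def test_square_sampling_worked_example(self):
        # center 5 with neighbors (6,4,5,7,2,5,8,1) in angular order -> 109
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 5.0
        offsets = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
        for (da, db), val in zip(offsets, [6, 4, 5, 7, 2, 5, 8, 1]):
            data[2 + da, 2 + db, 2] = val
        codes, valid = L.lbp_codes_plane(
            Volume(data), L.NeighborhoodSpec(sampling="square", plane="xy")
        )
        assert valid[2, 2, 2]
        assert codes[2, 2, 2] == 109
        assert codes[2, 2, 2] == lbp_code_at(data, (2, 2, 2), (0, 1), sampling="square")

    @pytest.mark.parametrize("plane", L.PLANES)
    @pytest.mark.parametrize("R_vox", [1.0, 2.0])
    def test_codes_match_bruteforce_oracle(self, rng, plane, R_vox):
        data = rng.standard_normal((10, 10, 10))
        codes, valid = L.lbp_codes_plane(Volume(data), L.NeighborhoodSpec(R_mm=R_vox, plane=plane))
        axes = L.PLANE_AXES[plane]
        for c in np.argwhere(valid)[:: max(1, valid.sum() // 60)]:
            assert codes[tuple(c)] == lbp_code_at(data, tuple(c), axes, R_vox=R_vox)

    def test_anisotropic_in_plane_spacing_rejected(self):
        v = Volume(np.zeros((8, 8, 8)), spacing=[1.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="isotropic"):
            L.lbp_codes_plane(v, L.NeighborhoodSpec(plane="xy"))

    def test_subvoxel_radius_rejected(self):
        v = Volume(np.zeros((8, 8, 8)), spacing=[2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="voxels"):
            L.lbp_codes_plane(v, L.NeighborhoodSpec(R_mm=1.0, plane="xy"))

    def test_radius_in_mm_divided_by_spacing(self):
        # identical texture at 1 mm/R=1 mm and 2 mm/R=2 mm must encode identically
        rng = np.random.default_rng(3)
        data = rng.standard_normal((12, 12, 12))
        c1, _ = L.lbp_codes_plane(Volume(data, [1, 1, 1]), L.NeighborhoodSpec(R_mm=1.0))
        c2, _ = L.lbp_codes_plane(Volume(data, [2, 2, 2]), L.NeighborhoodSpec(R_mm=2.0))
        np.testing.assert_array_equal(c1, c2)


class TestLbpTop:
    def test_constant_volume_all_planes_full_code(self):
        codes = L.lbp_top(Volume(np.ones((16, 16, 16))), P=8, R_mm=1.0)
        for plane in L.PLANES:
            assert np.all(codes.plane_codes(plane)[codes.valid] == P8_FULL)

    def test_variation_only_along_z_leaves_xy_constant(self, rng):
        data = np.broadcast_to(rng.standard_normal(12), (12, 12, 12)).copy()  # varies along z only
        codes = L.lbp_top(Volume(data), P=8, R_mm=1.0)
        assert np.all(codes.codes_xy[codes.valid] == P8_FULL)

    def test_joint_validity_is_conjunction_of_plane_masks(self, random_volume):
        codes = L.lbp_top(random_volume, P=8, R_mm=2.0)
        expected = np.ones(random_volume.shape, dtype=bool)
        for plane in L.PLANES:
            _, v = L.lbp_codes_plane(random_volume, L.NeighborhoodSpec(R_mm=2.0, plane=plane))
            expected &= v
        np.testing.assert_array_equal(codes.valid, expected)

    def test_anisotropic_volume_rejected_without_flag(self):
        v = Volume(np.zeros((8, 8, 8)), spacing=[1.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="anisotropic"):
            L.lbp_top(v)

    def test_shift_invariance_away_from_boundary(self, rng):
        data = rng.standard_normal((14, 14, 14))
        shifted = np.roll(data, (2, 1, 3), axis=(0, 1, 2))
        c0 = L.lbp_top(Volume(data), R_mm=1.0)
        c1 = L.lbp_top(Volume(shifted), R_mm=1.0)
        joint = c0.valid & np.roll(c0.valid, (2, 1, 3), axis=(0, 1, 2)) & c1.valid
        for plane in L.PLANES:
            rolled = np.roll(c0.plane_codes(plane), (2, 1, 3), axis=(0, 1, 2))
            np.testing.assert_array_equal(c1.plane_codes(plane)[joint], rolled[joint])


class TestMonotoneInvariance:
    def test_square_codes_exactly_invariant_under_exp(self, rng):
        data = rng.standard_normal((12, 12, 12))
        a = L.lbp_top(Volume(data), sampling="square")
        b = L.lbp_top(Volume(np.exp(data)), sampling="square")
        for plane in L.PLANES:
            np.testing.assert_array_equal(a.plane_codes(plane)[a.valid], b.plane_codes(plane)[b.valid])

    def test_circular_codes_exactly_invariant_under_integer_affine(self, rng):
        # interpolation commutes with affine intensity maps
        data = rng.integers(0, 100, size=(12, 12, 12)).astype(float)
        a = L.lbp_top(Volume(data))
        b = L.lbp_top(Volume(4.0 * data + 32.0))
        for plane in L.PLANES:
            np.testing.assert_array_equal(a.plane_codes(plane)[a.valid], b.plane_codes(plane)[b.valid])

    def test_circular_codes_nearly_invariant_under_exp(self, rng):
        # bilinear samples do not commute with nonlinear maps; flips are rare
        data = rng.standard_normal((14, 14, 14))
        a = L.lbp_top(Volume(data))
        b = L.lbp_top(Volume(np.exp(data)))
        n, flips = 0, 0
        for plane in L.PLANES:
            xa, xb = a.plane_codes(plane)[a.valid], b.plane_codes(plane)[b.valid]
            flips += np.sum(np.bitwise_count(np.bitwise_xor(xa, xb)))
            n += 8 * xa.size
        assert flips / n < 0.05


class TestUniformity:
    @pytest.mark.parametrize(
        "bits,expected",
        [("00000000", 0), ("01110000", 2), ("01010101", 8), ("11111111", 0), ("00000001", 2)],
    )
    def test_transition_counts(self, bits, expected):
        assert L.uniformity(int(bits, 2), 8) == expected

    @settings(max_examples=200, derandomize=True)
    @given(P=st.integers(4, 12), data=st.data())
    def test_matches_rotation_oracle(self, P, data):
        code = data.draw(st.integers(0, 2**P - 1))
        assert L.uniformity(code, P) == uniformity_oracle(code, P)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            L.uniformity(256, 8)


class TestUniformMap:
    @pytest.mark.parametrize("P,expected_bins", [(8, 59), (4, 15), (6, 33)])
    def test_bin_census_matches_bruteforce(self, P, expected_bins):
        umap = L.build_uniform_map(P)
        n_uniform = sum(uniformity_oracle(c, P) <= 2 for c in range(2**P))
        assert n_uniform == expected_bins - 1
        assert umap.n_bins == expected_bins == P * (P - 1) + 3
        # uniform codes get distinct ascending labels; the rest share the last bin
        uniform_codes = [c for c in range(2**P) if uniformity_oracle(c, P) <= 2]
        assert list(umap.table[uniform_codes]) == list(range(n_uniform))
        assert np.all(umap.table[[c for c in range(2**P) if c not in uniform_codes]] == expected_bins - 1)

    def test_all_zero_and_all_one_codes_not_in_catchall(self):
        umap = L.build_uniform_map(8)
        assert umap.table[0] != umap.table[255]
        assert umap.n_bins - 1 not in (umap.table[0], umap.table[255])


class TestRegionHistograms:
    def test_whole_brain_length_and_conservation(self, random_volume, whole_mask):
        codes = L.lbp_top(random_volume, P=8, R_mm=1.0)
        fv = L.region_histograms(codes, whole_mask, normalize=False)
        assert len(fv) == 177
        n_valid = codes.valid.sum()
        for plane in L.PLANES:
            block = [v for v, t in zip(fv.values, fv.index) if t[1] == plane]
            assert np.sum(block) == n_valid

    def test_multi_region_conservation_and_order(self, random_volume):
        labels = np.zeros((16, 16, 16), dtype=np.int64)
        labels[:8], labels[8:] = 3, 11
        atlas = LabelVolume(labels)
        codes = L.lbp_top(random_volume, P=8, R_mm=1.0)
        fv = L.region_histograms(codes, atlas, normalize=False)
        assert len(fv) == L.feature_dimension(2)
        assert [t[0] for t in fv.index[:177]] == [3] * 177  # regions ascending
        for lab in (3, 11):
            n_valid = ((atlas.labels == lab) & codes.valid).sum()
            for plane in L.PLANES:
                block = [v for v, t in zip(fv.values, fv.index) if t[:2] == (lab, plane)]
                assert np.sum(block) == n_valid

    def test_normalized_blocks_sum_to_one(self, random_volume, whole_mask):
        codes = L.lbp_top(random_volume, P=8, R_mm=1.0)
        fv = L.region_histograms(codes, whole_mask, normalize=True)
        for plane in L.PLANES:
            block = [v for v, t in zip(fv.values, fv.index) if t[1] == plane]
            assert abs(np.sum(block) - 1.0) < 1e-9

    def test_empty_region_gives_zero_block_not_nan(self, random_volume, caplog):
        labels = np.ones((16, 16, 16), dtype=np.int64)
        labels[0, 0, 0] = 5  # a boundary voxel: never valid
        codes = L.lbp_top(random_volume, P=8, R_mm=1.0)
        fv = L.region_histograms(codes, LabelVolume(labels), normalize=True)
        region5 = np.array([v for v, t in zip(fv.values, fv.index) if t[0] == 5])
        assert np.all(region5 == 0.0) and not np.any(np.isnan(fv.values))

    def test_constant_volume_mass_in_full_code_bin(self, whole_mask):
        codes = L.lbp_top(Volume(np.ones((16, 16, 16))), P=8, R_mm=1.0)
        umap = L.build_uniform_map(8)
        fv = L.region_histograms(codes, whole_mask, umap, normalize=False)
        full_bin = int(umap.table[255])
        for plane in L.PLANES:
            block = {t[2]: v for v, t in zip(fv.values, fv.index) if t[1] == plane}
            assert block[full_bin] == codes.valid.sum()
            assert sum(v for b, v in block.items() if b != full_bin) == 0

    def test_shape_mismatch_rejected(self, random_volume):
        codes = L.lbp_top(random_volume, P=8, R_mm=1.0)
        with pytest.raises(ValueError, match="shape"):
            L.region_histograms(codes, LabelVolume(np.ones((8, 8, 8), dtype=np.int64)))

    @pytest.mark.parametrize("n_regions,expected", [(1, 177), (116, 20532), (190, 33630)])
    def test_dimension_law(self, n_regions, expected):
        assert L.feature_dimension(n_regions, P=8) == expected


class TestExtractFeatures:
    def test_group_shapes_and_determinism(self, rng, whole_mask):
        volumes = [Volume(rng.standard_normal((16, 16, 16))) for _ in range(3)]
        volumes.append(Volume(volumes[0].data.copy()))  # duplicate subject
        groups = L.extract_features(volumes, whole_mask, radii_mm=(1.0, 2.0, 3.0))
        assert [g.matrix.shape for g in groups] == [(4, 177)] * 3
        for g in groups:
            np.testing.assert_array_equal(g.matrix[0], g.matrix[3])  # identical rows
        # permuting subjects permutes rows only
        perm_groups = L.extract_features(volumes[::-1], whole_mask, radii_mm=(1.0,))
        np.testing.assert_array_equal(perm_groups[0].matrix, groups[0].matrix[::-1])

    def test_misaligned_subject_aborts_with_id(self, rng, whole_mask):
        volumes = [Volume(rng.standard_normal((16, 16, 16))), Volume(rng.standard_normal((8, 8, 8)))]
        with pytest.raises(ValueError, match="subject 1"):
            L.extract_features(volumes, whole_mask, radii_mm=(1.0,))

    def test_extractor_transformer_contract(self, rng, whole_mask):
        volumes = [Volume(rng.standard_normal((16, 16, 16))) for _ in range(2)]
        ext = L.LBPTOPExtractor(atlas=whole_mask, radii_mm=(1.0, 2.0)).fit()
        X = ext.transform(volumes)
        assert X.shape == (2, 354)
        assert [s.stop - s.start for s in ext.group_slices_] == [177, 177]
        assert ext.whole_brain_flags_ == [True, True]


class TestSkimageCrossCheck:
    @pytest.mark.filterwarnings("ignore:Applying `local_binary_pattern`")
    def test_xy_codes_match_skimage_on_continuous_slice(self, rng):
        # independent 2D implementation; bit order differs by a fixed rotation
        skimage_feature = pytest.importorskip("skimage.feature")
        data = rng.standard_normal((14, 14, 14))
        codes, valid = L.lbp_codes_plane(Volume(data), L.NeighborhoodSpec(R_mm=1.0, plane="xy"))
        k = 6
        sk = skimage_feature.local_binary_pattern(data[:, :, k], 8, 1.0, method="default").astype(int)
        remapped = np.zeros_like(sk)
        for p in range(8):
            remapped |= ((sk >> ((p + 6) % 8)) & 1) << p
        np.testing.assert_array_equal(remapped[1:-1, 1:-1], codes[1:-1, 1:-1, k])
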