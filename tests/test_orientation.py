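import numpy as np
import pytest

import trabtex as tt
import reference as ref
from trabtex.phantoms import PhantomSpec, generate


def _code_from_offsets(nbhd, offsets):
    """Pattern code whose markers are the given integer neighbor offsets."""
    code = 0
    rounded = np.round(tt.NEIGHBOR_OFFSETS).astype(int)
    for off in offsets:
        idx = np.flatnonzero((rounded == np.asarray(off)).all(axis=1))
        assert len(idx) == 1
        code |= 1 << int(idx[0])
    return code


@pytest.fixture
def rules():
    return tt.PatternValidity()


class TestValidity:
    def test_too_few_markers_invalid(self, nbhd, rules):
        code = _code_from_offsets(nbhd, [(0, 0, 1), (0, 0, -1)])  # popcount 2
        assert not tt.is_valid_pattern(code, nbhd, rules)

    def test_too_many_markers_invalid(self, nbhd, rules):
        code = (2 ** 26 - 1) & ~1  # popcount 25
        assert not tt.is_valid_pattern(code, nbhd, rules)

    def test_compact_axial_line_valid(self, nbhd, rules):
        code = _code_from_offsets(nbhd, [(0, 0, 1), (0, 0, -1), (1, 0, 0)])
        assert tt.is_valid_pattern(code, nbhd, rules) == ref.pattern_valid(
            code, nbhd.positions
        )

    def test_centroid_rule_matches_geometric_oracle(self, rng, nbhd, rules):
        rules_no = tt.PatternValidity(centroid_rule=False)
        for code in rng.integers(1, 2 ** 26, 300):
            code = int(code)
            assert tt.is_valid_pattern(code, nbhd, rules) == ref.pattern_valid(
                code, nbhd.positions
            )
            assert tt.is_valid_pattern(code, nbhd, rules_no) == ref.pattern_valid(
                code, nbhd.positions, centroid_rule=False
            )


class TestPatternElevation:
    def test_z_aligned_line_is_90_degrees(self, nbhd, rules):
        code = _code_from_offsets(nbhd, [(0, 0, 1), (0, 0, -1), (1, 0, 1), (1, 0, -1)])
        if tt.is_valid_pattern(code, nbhd, rules):
            assert tt.pattern_elevation(code, nbhd, rules) == pytest.approx(90.0, abs=1e-9)

    def test_x_aligned_line_is_0_degrees(self, nbhd, rules):
        code = _code_from_offsets(nbhd, [(1, 0, 0), (-1, 0, 0), (1, 1, 0), (-1, 1, 0)])
        assert tt.pattern_elevation(code, nbhd, rules) == pytest.approx(0.0, abs=1e-9)

    def test_matches_covariance_eigen_oracle(self, rng, nbhd, rules):
        checked = 0
        for code in rng.integers(1, 2 ** 26, 500):
            code = int(code)
            if not tt.is_valid_pattern(code, nbhd, rules):
                continue
            try:
                got = tt.pattern_elevation(code, nbhd, rules)
            except ValueError:
                continue  # eigen tie: no unique principal axis
            assert got == pytest.approx(
                ref.pattern_elevation(code, nbhd.positions), abs=1e-9
            )
            checked += 1
        assert checked > 100

    def test_invalid_pattern_raises(self, nbhd, rules):
        with pytest.raises(ValueError):
            tt.pattern_elevation(_code_from_offsets(nbhd, [(0, 0, 1)]), nbhd, rules)


class TestElevationField:
    def test_longitudinal_rods_recover_near_90(self):
        nbhd = tt.build_neighborhood(1.5)
        spec = PhantomSpec(
            kind="rod_lattice", elevation_deg=90, element_radius_vox=1.2,
            spacing_vox=8.0, size_vox=(48, 48, 48), noise_sd=0.0, seed=2,
        )
        vol, _ = generate(spec)
        mask = tt.analysis_mask(vol, nbhd, 60.0)
        field = tt.elevation_field(vol, mask, nbhd)
        assert tt.elevation_summary(field).mean_elevation_deg == pytest.approx(90, abs=5)

    def test_transverse_rods_recover_near_0(self):
        nbhd = tt.build_neighborhood(1.5)
        spec = PhantomSpec(
            kind="rod_lattice", elevation_deg=0, element_radius_vox=1.2,
            spacing_vox=8.0, size_vox=(48, 48, 48), noise_sd=0.0, seed=2,
        )
        vol, _ = generate(spec)
        mask = tt.analysis_mask(vol, nbhd, 60.0)
        field = tt.elevation_field(vol, mask, nbhd)
        assert tt.elevation_summary(field).mean_elevation_deg == pytest.approx(0, abs=5)

    def test_constant_volume_has_no_valid_voxels(self, nbhd):
        vol = tt.GrayVolume(np.full((8, 8, 8), 80.0), 27.8)
        mask = tt.eligibility_mask(vol, nbhd, -np.inf)
        field = tt.elevation_field(vol, mask, nbhd)  # all popcount-26 codes
        assert not field.valid_mask.any()

    def test_mirror_flips_preserve_elevation(self, random_volume, nbhd, rules):
        mask = tt.analysis_mask(random_volume, nbhd, -np.inf)
        field = tt.elevation_field(random_volume, mask, nbhd, rules)
        for axis in (0, 1, 2):
            flipped = tt.GrayVolume(np.flip(random_volume.data, axis).copy(), 27.8)
            fmask = tt.analysis_mask(flipped, nbhd, -np.inf)
            ffield = tt.elevation_field(flipped, fmask, nbhd, rules)
            assert np.allclose(
                np.flip(ffield.angles, axis), field.angles, atol=1e-9, equal_nan=True
            )


class TestElevationSummary:
    def _field(self, angles):
        return tt.ElevationField(np.asarray(angles, float))

    def test_uniform_field_mean_and_zero_entropy(self):
        s = tt.elevation_summary(self._field(np.full((4, 4, 4), 45.0)))
        assert s.mean_elevation_deg == pytest.approx(45.0)
        assert s.elevation_entropy_bits == 0.0

    def test_two_value_field_one_bit(self):
        angles = np.full((4, 4, 4), 0.0)
        angles[2:] = 90.0
        s = tt.elevation_summary(self._field(angles))
        assert s.mean_elevation_deg == pytest.approx(45.0)
        assert s.elevation_entropy_bits == pytest.approx(1.0)

    def test_matches_direct_histogram_oracle(self, rng):
        angles = rng.uniform(0, 90, (6, 6, 6))
        angles[rng.uniform(size=angles.shape) < 0.3] = np.nan
        field = self._field(angles)
        s = tt.elevation_summary(field)
        valid = angles[np.isfinite(angles)]
        counts = np.bincount(np.minimum((valid // 5).astype(int), 17), minlength=18)
        p = counts[counts > 0] / counts.sum()
        assert s.mean_elevation_deg == pytest.approx(valid.mean())
        assert s.elevation_entropy_bits == pytest.approx(-(p * np.log2(p)).sum())

    def test_all_invalid_is_an_error(self):
        with pytest.raises(ValueError):
            tt.elevation_summary(self._field(np.full((3, 3, 3), np.nan)))


class TestALCM:
    def test_uniform_field_single_diagonal_cell(self):
        field = tt.ElevationField(np.full((5, 5, 5), 45.0))
        alcm = tt.compute_alcm(field)
        assert alcm.cells.sum() == pytest.approx(1.0)
        assert alcm.cells[9, 9] == pytest.approx(1.0)  # 45 deg -> bin 9

    def test_two_half_volumes_concentrate_on_two_diagonal_cells(self):
        angles = np.full((6, 6, 6), 2.0)
        angles[:, :, 3:] = 88.0
        alcm = tt.compute_alcm(tt.ElevationField(angles))
        ref_counts = ref.alcm_counts(angles, 5.0, 18)
        assert np.allclose(alcm.cells, ref_counts / ref_counts.sum(), atol=1e-12)
        diag_mass = alcm.cells[0, 0] + alcm.cells[17, 17]
        off_mass = alcm.cells[0, 17] + alcm.cells[17, 0]
        assert diag_mass > 0.8 and 0 < off_mass < 0.2
        assert np.allclose(alcm.cells, alcm.cells.T)

    @pytest.mark.parametrize("adjacency", [6, 26])
    def test_matches_pair_enumeration_oracle(self, rng, adjacency):
        angles = rng.uniform(0, 90, (6, 6, 6))
        angles[rng.uniform(size=angles.shape) < 0.4] = np.nan
        alcm = tt.compute_alcm(tt.ElevationField(angles), adjacency)
        counts = ref.alcm_counts(angles, 5.0, 18, adjacency)
        assert np.allclose(alcm.cells, counts / counts.sum(), atol=1e-12)

    def test_no_valid_pairs_is_an_error(self):
        angles = np.full((5, 5, 5), np.nan)
        angles[0, 0, 0] = 45.0  # single isolated valid voxel
        with pytest.raises(ValueError):
            tt.compute_alcm(tt.ElevationField(angles))


class TestHomogeneity:
    def test_diagonal_mass_gives_exactly_one(self):
        cells = np.zeros((18, 18))
        cells[3, 3] = 0.6
        cells[10, 10] = 0.4
        assert tt.homogeneity_of_elevation(tt.ALCMatrix(cells, 18)) == 1.0

    def test_adjacent_bin_mass_gives_half(self):
        cells = np.zeros((18, 18))
        cells[4, 5] = 1.0
        assert tt.homogeneity_of_elevation(tt.ALCMatrix(cells, 18)) == pytest.approx(0.5)

    def test_matches_double_sum_oracle_and_decreases_with_distance(self, rng):
        cells = rng.uniform(size=(18, 18))
        cells = cells / cells.sum()
        got = tt.homogeneity_of_elevation(tt.ALCMatrix(cells, 18))
        expected = sum(
            cells[i, j] / (1 + abs(i - j)) for i in range(18) for j in range(18)
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0 < got <= 1

    def test_moving_mass_off_diagonal_lowers_homogeneity(self):
        def h(d):
            cells = np.zeros((18, 18))
            cells[0, d] = 1.0
            return tt.homogeneity_of_elevation(tt.ALCMatrix(cells, 18))

        values = [h(d) for d in range(5)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestStructuralHeterogeneity:
    def test_mixed_orientations_raise_entropy(self):
        nbhd = tt.build_neighborhood(1.5)
        kwargs = dict(element_radius_vox=1.2, spacing_vox=8.0, noise_sd=0.0)
        single = tt.mixed_rod_phantom([90.0], size_vox=(48, 48, 48), seed=3, **kwargs)
        mixed = tt.mixed_rod_phantom([90.0, 0.0], size_vox=(48, 48, 48), seed=3, **kwargs)
        entropies = []
        for vol in (single, mixed):
            mask = tt.analysis_mask(vol, nbhd, 60.0)
            field = tt.elevation_field(vol, mask, nbhd)
            entropies.append(tt.elevation_summary(field).elevation_entropy_bits)
        assert entropies[0] < entropies[1]
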