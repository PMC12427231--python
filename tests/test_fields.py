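import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apa_htp.errors import ConfigurationError, DegenerateInputError, FormatError, UnsupportedVersionError
from apa_htp.fields import (
    AntennaRing,
    FieldMatrix,
    TotalField,
    assemble_field_matrix,
    dominant_component,
    lossy_medium_constants,
    read_field_container,
    superpose_field,
    synthesize_surrogate_fields,
    write_field_container,
)
from apa_htp.phantom import (
    CylinderLayer,
    PhantomConfig,
    Tissue,
    TissueTable,
    VoxelGrid,
    build_layered_cylinder_phantom,
)


def homogeneous_phantom(sigma: float, spacing=2.0, radius=30.0):
    table = TissueTable([Tissue("medium", 50.0, sigma, 1000.0, 0.5, 3000.0, 10.0)])
    cfg = PhantomConfig(
        layers=[CylinderLayer(radius, "medium")],
        height_mm=20.0,
        spacing_mm=spacing,
        table=table,
    )
    return build_layered_cylinder_phantom(cfg)


def toy_matrix(m=4, n=2, seed=0):
    rng = np.random.default_rng(seed)
    grid = VoxelGrid((m, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    values = rng.normal(size=(3 * m, n)) + 1j * rng.normal(size=(3 * m, n))
    voxel_index = np.stack([np.arange(m), np.zeros(m, int), np.zeros(m, int)], axis=1)
    return FieldMatrix(grid=grid, values=values, voxel_index=voxel_index,
                       frequency_hz=434e6, antenna_positions_mm=np.zeros((n, 3)))


class TestSurrogate:
    def test_lossless_medium_pure_spreading(self):
        """sigma = 0: |e(d2)| / |e(d1)| = d1 / d2 along the boresight ray."""
        phantom = homogeneous_phantom(sigma=0.0)
        ring = AntennaRing(n_antennas=1, radius_mm=60.0, height_mm=0.0)
        matrix = synthesize_surrogate_fields(phantom, ring, reference_tissue="medium")
        # boresight: voxels on the y=0, z=0 row (antenna at (60, 0, 0))
        centers = phantom.grid.index_centers(matrix.voxel_index)
        on_ray = (np.abs(centers[:, 1]) < 1e-9) & (np.abs(centers[:, 2]) < 1e-9)
        field = matrix.column_field(0)
        mags = np.linalg.norm(field[on_ray], axis=1)
        d = np.abs(centers[on_ray, 0] - 60.0)
        order = np.argsort(d)
        d, mags = d[order], mags[order]
        np.testing.assert_allclose(mags[1:] / mags[0], d[0] / d[1:], rtol=1e-10)

    def test_lossy_medium_matches_closed_form(self):
        """Ratio follows (d1/d2) exp(-alpha (d2-d1)) with the textbook alpha."""
        sigma, eps_r, f = 0.8, 56.9, 434e6
        phantom = homogeneous_phantom(sigma=sigma)
        # evaluate alpha independently of the package helper
        omega = 2 * np.pi * f
        eps = eps_r * 8.8541878128e-12
        # pull eps_r from the table used by the phantom
        eps = phantom.table.tissue(1).eps_r * 8.8541878128e-12
        mu0 = 4e-7 * np.pi
        lt = sigma / (omega * eps)
        alpha_ref = omega * np.sqrt(mu0 * eps / 2) * np.sqrt(np.sqrt(1 + lt**2) - 1)

        ring = AntennaRing(n_antennas=1, radius_mm=60.0)
        matrix = synthesize_surrogate_fields(phantom, ring, reference_tissue="medium")
        centers = phantom.grid.index_centers(matrix.voxel_index)
        on_ray = (np.abs(centers[:, 1]) < 1e-9) & (np.abs(centers[:, 2]) < 1e-9)
        field = matrix.column_field(0)
        mags = np.linalg.norm(field[on_ray], axis=1)
        d_m = np.abs(centers[on_ray, 0] - 60.0) * 1e-3
        order = np.argsort(d_m)
        d_m, mags = d_m[order], mags[order]
        expected = (d_m[0] / d_m[1:]) * np.exp(-alpha_ref * (d_m[1:] - d_m[0]))
        np.testing.assert_allclose(mags[1:] / mags[0], expected, rtol=1e-10)

    def test_dominant_axis_at_least_5x_transverse(self, fixture5):
        _, matrix, _ = fixture5
        for n in range(matrix.n_antennas):
            field = matrix.column_field(n)
            z = np.abs(field[:, 2])
            nonzero = z > 0
            assert np.all(z[nonzero] >= 5.0 * np.abs(field[nonzero, 0]))
            assert np.all(z[nonzero] >= 5.0 * np.abs(field[nonzero, 1]))

    def test_strict_decay_along_rays(self, fixture5):
        """|e| strictly decreases with distance along source rays (sampled)."""
        _, matrix, _ = fixture5
        centers = matrix.grid.index_centers(matrix.voxel_index)
        # antennas 0 and 4 sit on the y=0 line, so that row is a source ray
        for n in (0, 4):
            src = matrix.antenna_positions_mm[n]
            field = matrix.column_field(n)
            mags = np.linalg.norm(field, axis=1)
            # voxels on the horizontal row through the source height z
            row = (np.abs(centers[:, 1] - 0.0) < 1e-9) & (np.abs(centers[:, 2] - src[2]) < 2.6)
            if row.sum() < 3:
                continue
            d = np.linalg.norm(centers[row] - src, axis=1)
            order = np.argsort(d)
            m = mags[row][order]
            assert np.all(np.diff(m) < 0) or np.all(np.diff(m[m > 0]) < 0)

    def test_ring_inside_tissue_rejected(self):
        phantom = homogeneous_phantom(sigma=0.5)
        with pytest.raises(ConfigurationError, match="outside"):
            synthesize_surrogate_fields(phantom, AntennaRing(4, radius_mm=10.0),
                                        reference_tissue="medium")

    def test_missing_reference_tissue_rejected(self):
        phantom = homogeneous_phantom(sigma=0.5)
        with pytest.raises(ConfigurationError):
            synthesize_surrogate_fields(phantom, AntennaRing(4, radius_mm=60.0),
                                        reference_tissue="nope")

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            AntennaRing(4, radius_mm=60.0, frequency_hz=0.0)
        with pytest.raises(ValueError):
            lossy_medium_constants(50.0, 0.5, -1.0)


class TestStacking:
    def test_n1_m2_shape_and_row_order(self):
        grid = VoxelGrid((2, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        fld = np.zeros((2, 1, 1, 3), dtype=complex)
        fld[0, 0, 0] = [1, 3, 5]
        fld[1, 0, 0] = [2, 4, 6]
        mask = np.ones((2, 1, 1), dtype=bool)
        matrix = assemble_field_matrix([fld], grid, mask, 434e6)
        assert matrix.values.shape == (6, 1)
        np.testing.assert_array_equal(matrix.values[:, 0], [1, 2, 3, 4, 5, 6])

    def test_stack_unstack_round_trip(self, fixture8):
        _, matrix, _ = fixture8
        for n in (0, matrix.n_antennas - 1):
            field = matrix.column_field(n)  # unstack
            restacked = field.T.reshape(-1)
            np.testing.assert_array_equal(restacked, matrix.values[:, n])

    def test_columns_match_per_antenna_fields(self, rng):
        grid = VoxelGrid((3, 2, 2), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        mask = rng.random((3, 2, 2)) > 0.3
        mask[0, 0, 0] = True
        flds = [rng.normal(size=(3, 2, 2, 3)) + 1j * rng.normal(size=(3, 2, 2, 3))
                for _ in range(3)]
        matrix = assemble_field_matrix(flds, grid, mask, 434e6)
        m = matrix.m_voxels
        for n in range(3):
            expected = flds[n][mask]  # (M, 3)
            np.testing.assert_array_equal(matrix.values[:, n].reshape(3, m).T, expected)

    def test_row_voxel_bijection(self, fixture8):
        _, matrix, _ = fixture8
        m = matrix.m_voxels
        seen = set()
        for row in range(0, 3 * m, max(1, m // 7)):
            pair = matrix.unrow(row)
            assert matrix.row_of(*pair) == row
            seen.add(pair)
        assert len(seen) == len({matrix.unrow(r) for r in range(0, 3 * m, max(1, m // 7))})

    def test_mismatched_grid_rejected(self):
        grid = VoxelGrid((2, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        bad = np.zeros((3, 1, 1, 3), dtype=complex)
        with pytest.raises(FormatError):
            assemble_field_matrix([bad], grid, np.ones((2, 1, 1), bool), 434e6)


class TestSuperposition:
    def test_unit_excitation_reproduces_column(self, fixture8):
        _, matrix, _ = fixture8
        b = np.zeros(matrix.n_antennas, dtype=complex)
        b[2] = 1.0
        total = superpose_field(matrix, b)
        np.testing.assert_array_equal(total.values, matrix.column_field(2))

    def test_linearity(self, fixture8, rng):
        _, matrix, _ = fixture8
        b1 = rng.normal(size=matrix.n_antennas) + 1j * rng.normal(size=matrix.n_antennas)
        b2 = rng.normal(size=matrix.n_antennas) + 1j * rng.normal(size=matrix.n_antennas)
        lhs = superpose_field(matrix, b1 + b2).values
        rhs = superpose_field(matrix, b1).values + superpose_field(matrix, b2).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_two_antenna_hand_arithmetic(self):
        """4 voxels, 2 antennas, b = (1, j): per-voxel sums by hand."""
        m = toy_matrix(m=4, n=2, seed=7)
        b = np.array([1.0, 1.0j])
        total = superpose_field(m, b)
        f0, f1 = m.column_field(0), m.column_field(1)
        for v in range(4):
            for c in range(3):
                assert total.values[v, c] == f0[v, c] + 1j * f1[v, c]

    @given(scale=st.complex_numbers(max_magnitude=1e3, allow_nan=False, allow_infinity=False))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity(self, scale):
        matrix = toy_matrix(m=5, n=3, seed=3)
        b = np.array([1.0 + 0.5j, -0.25j, 2.0])
        lhs = superpose_field(matrix, scale * b).values
        rhs = scale * superpose_field(matrix, b).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_length_mismatch_rejected(self, fixture8):
        _, matrix, _ = fixture8
        with pytest.raises(ValueError):
            superpose_field(matrix, np.ones(matrix.n_antennas + 1))


class TestDominantComponent:
    def test_surrogate_is_z(self, fixture8):
        _, matrix, _ = fixture8
        assert dominant_component(matrix) == "z"

    def test_y_only(self):
        m = toy_matrix(m=3, n=1)
        m.values[:] = 0
        m.values[3:6, 0] = 1.0  # y block
        assert dominant_component(m) == "y"

    def test_tie_breaks_to_x(self):
        m = toy_matrix(m=2, n=1)
        m.values[:] = 0
        m.values[0:2, 0] = 1.0  # x block
        m.values[4:6, 0] = 1.0  # z block, equal mean magnitude
        assert dominant_component(m) == "x"

    def test_all_zero_rejected(self):
        m = toy_matrix(m=2, n=1)
        m.values[:] = 0
        with pytest.raises(DegenerateInputError):
            dominant_component(m)


class TestContainer:
    def test_round_trip_bit_identical(self, tmp_path, fixture8):
        _, matrix, _ = fixture8
        path = tmp_path / "EN.h5"
        write_field_container(matrix, path)
        loaded = read_field_container(path)
        np.testing.assert_array_equal(loaded.values, matrix.values)
        np.testing.assert_array_equal(loaded.voxel_index, matrix.voxel_index)
        assert loaded.grid == matrix.grid
        assert loaded.frequency_hz == matrix.frequency_hz
        assert loaded.r0_ohm == matrix.r0_ohm
        np.testing.assert_array_equal(loaded.antenna_positions_mm, matrix.antenna_positions_mm)

    def test_m_less_than_n_warns(self, caplog):
        grid = VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        with caplog.at_level(logging.WARNING, logger="apa_htp.fields"):
            FieldMatrix(grid=grid, values=np.ones((3, 4), complex),
                        voxel_index=np.zeros((1, 3), int),
                        frequency_hz=434e6, antenna_positions_mm=np.zeros((4, 3)))
        assert any("ill-posed" in rec.message for rec in caplog.records)

    def test_version_mismatch_rejected(self, tmp_path, fixture8):
        import h5py

        _, matrix, _ = fixture8
        path = tmp_path / "EN.h5"
        write_field_container(matrix, path)
        with h5py.File(path, "r+") as f:
            f.attrs["format_version"] = 99
        with pytest.raises(UnsupportedVersionError):
            read_field_container(path)

    def test_missing_spacing_attr_rejected(self, tmp_path, fixture8):
        import h5py

        _, matrix, _ = fixture8
        path = tmp_path / "EN.h5"
        write_field_container(matrix, path)
        with h5py.File(path, "r+") as f:
            del f.attrs["grid_spacing_mm"]
        with pytest.raises(FormatError, match="grid_spacing_mm"):
            read_field_container(path)

    def test_corrupted_shape_rejected(self, tmp_path, fixture8):
        import h5py

        _, matrix, _ = fixture8
        path = tmp_path / "EN.h5"
        write_field_container(matrix, path)
        with h5py.File(path, "r+") as f:
            del f["voxel_index"]
            f.create_dataset("voxel_index", data=np.zeros((matrix.m_voxels - 1, 3), int))
        with pytest.raises(FormatError):
            read_field_container(path)
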