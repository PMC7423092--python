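"""CCP4 map I/O, coordinate transforms and voxel selection."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edunits import UnitCell, map_statistics, read_ccp4, voxels_within_radius, write_ccp4
from edunits.ccp4 import (
    CCP4FormatError,
    OutOfExtentError,
    TruncatedMapError,
    UnsupportedModeError,
)

from conftest import make_map


def roundtrip(dmap, axis_order=(1, 2, 3)):
    buf = io.BytesIO()
    write_ccp4(dmap, buf, axis_order=axis_order)
    buf.seek(0)
    return read_ccp4(buf)


class TestUnitCell:
    def test_volume_formula_triclinic(self):
        cell = UnitCell(10, 12, 14, 80, 95, 110)
        ca, cb, cg = (np.cos(np.radians(x)) for x in (80, 95, 110))
        expected = 10 * 12 * 14 * np.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
        assert cell.volume == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("angles", [(90, 90, 90), (90, 90, 120), (80, 95, 110)])
    def test_fractionalize_orthogonalize_roundtrip(self, angles):
        cell = UnitCell(11.0, 13.0, 17.0, *angles)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-20, 20, size=(50, 3))
        back = cell.orthogonalize(cell.fractionalize(pts))
        assert np.allclose(back, pts, rtol=1e-9, atol=1e-9)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(10, 10, 10, 0, 90, 90)


class TestReadWrite:
    def test_roundtrip_identity(self):
        rng = np.random.default_rng(1)
        dmap = make_map(rng.normal(size=(6, 5, 4)).astype(np.float32),
                        symmetry_text="X,Y,Z".ljust(80))
        back = roundtrip(dmap)
        assert back.grid.dtype == np.float32
        np.testing.assert_array_equal(back.grid, dmap.grid)
        assert back.start == dmap.start
        assert back.intervals == dmap.intervals
        assert back.cell.parameters == pytest.approx(dmap.cell.parameters, rel=1e-6)
        assert back.symmetry_text.strip() == "X,Y,Z"

    @pytest.mark.parametrize("axis_order", list(itertools.permutations((1, 2, 3))))
    def test_axis_permutation_normalized_on_read(self, axis_order):
        """Any of the six storage orders recovers the canonical x/y/z grid."""
        rng = np.random.default_rng(2)
        dmap = make_map(rng.normal(size=(5, 4, 3)).astype(np.float32), start=(1, -2, 3))
        back = roundtrip(dmap, axis_order=axis_order)
        np.testing.assert_array_equal(back.grid, dmap.grid)
        assert back.start == dmap.start

    def test_permuted_file_matches_index_permutation_oracle(self):
        """The file's column-fastest layout is the transposed grid."""
        rng = np.random.default_rng(3)
        dmap = make_map(rng.normal(size=(4, 3, 2)).astype(np.float32))
        buf = io.BytesIO()
        write_ccp4(dmap, buf, axis_order=(3, 1, 2))  # cols=z, rows=x, secs=y
        raw = buf.getvalue()
        data = np.frombuffer(raw[1024:], dtype="<f4").reshape(3, 4, 2)  # (sec=y, row=x, col=z)
        oracle = np.transpose(dmap.grid, (1, 0, 2))  # y, x, z
        np.testing.assert_array_equal(data, oracle)

    def test_single_voxel_map(self):
        dmap = make_map(np.full((1, 1, 1), 7.5, dtype=np.float32))
        assert roundtrip(dmap).grid[0, 0, 0] == np.float32(7.5)

    def test_missing_magic_rejected(self):
        with pytest.raises(CCP4FormatError):
            read_ccp4(io.BytesIO(b"\0" * 2048))

    def test_unsupported_mode_rejected(self):
        dmap = make_map(np.zeros((2, 2, 2), dtype=np.float32))
        buf = io.BytesIO()
        write_ccp4(dmap, buf)
        raw = bytearray(buf.getvalue())
        raw[12:16] = (1).to_bytes(4, "little")  # mode word
        with pytest.raises(UnsupportedModeError):
            read_ccp4(io.BytesIO(bytes(raw)))

    def test_truncated_data_rejected(self):
        dmap = make_map(np.zeros((4, 4, 4), dtype=np.float32))
        buf = io.BytesIO()
        write_ccp4(dmap, buf)
        with pytest.raises(TruncatedMapError):
            read_ccp4(io.BytesIO(buf.getvalue()[:-10]))

    def test_gemmi_reads_our_files_identically(self, tmp_path):
        """Cross-check the writer against an independent CCP4 reader."""
        gemmi = pytest.importorskip("gemmi")
        rng = np.random.default_rng(4)
        dmap = make_map(rng.normal(size=(6, 5, 4)).astype(np.float32))
        path = tmp_path / "m.ccp4"
        with open(path, "wb") as fh:
            write_ccp4(dmap, fh)
        m = gemmi.read_ccp4_map(str(path))
        np.testing.assert_array_equal(np.array(m.grid, copy=False), dmap.grid)
        assert m.grid.unit_cell.a == pytest.approx(dmap.cell.a, rel=1e-6)


class TestStatistics:
    def test_constant_field(self):
        stats = map_statistics(make_map(np.ones((8, 8, 8))))
        assert stats.mean == 1.0 and stats.sigma == 0.0

    def test_single_hot_voxel(self):
        grid = np.zeros((10, 10, 10))
        grid[3, 4, 5] = 100.0
        stats = map_statistics(make_map(grid))
        assert stats.max == 100.0
        assert stats.mean == pytest.approx(0.1)

    def test_plus_minus_one(self):
        grid = np.ones((4, 4, 4))
        grid[:2] = -1.0
        stats = map_statistics(make_map(grid))
        assert stats.mean == 0.0 and stats.sigma == 1.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        dmap = make_map(rng.normal(2.0, 3.0, size=(7, 6, 5)))
        grid = dmap.grid
        stats = map_statistics(dmap)
        mean = sum(float(v) for v in grid.ravel()) / grid.size
        var = sum((float(v) - mean) ** 2 for v in grid.ravel()) / grid.size
        assert stats.mean == pytest.approx(mean, rel=1e-12)
        assert stats.sigma == pytest.approx(np.sqrt(var), rel=1e-9)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_sigma_scales_linearly(self, k):
        rng = np.random.default_rng(6)
        grid = rng.normal(size=(5, 5, 5))
        s1 = map_statistics(make_map(grid)).sigma
        s2 = map_statistics(make_map(k * grid)).sigma
        assert s2 == pytest.approx(abs(k) * s1, rel=1e-5)


class TestTransforms:
    def test_axis_aligned_arithmetic(self):
        dmap = make_map(np.zeros((10, 10, 10)))
        assert dmap.xyz_to_crs((2.5, 0.5, 9.5)) == (2, 0, 9)
        assert dmap.crs_to_xyz((2, 0, 9)) == pytest.approx([2.5, 0.5, 9.5])

    def test_inverse_pair_on_hexagonal_cell(self):
        cell = UnitCell(10, 10, 12, 90, 90, 120)
        dmap = make_map(np.zeros((8, 8, 8)), cell=cell, intervals=(8, 8, 8))
        for idx in [(0, 0, 0), (3, 5, 7), (7, 0, 4)]:
            assert dmap.xyz_to_crs(dmap.crs_to_xyz(idx)) == idx

    def test_out_of_extent_signalled_on_partial_map(self):
        dmap = make_map(np.zeros((4, 4, 4)), cell=UnitCell(10, 10, 10),
                        intervals=(10, 10, 10))
        with pytest.raises(OutOfExtentError):
            dmap.xyz_to_crs((9.5, 0.5, 0.5))

    def test_containing_voxel_matches_nearest_center_oracle(self):
        cell = UnitCell(9, 11, 13, 90, 101, 90)  # monoclinic
        dmap = make_map(np.zeros((6, 7, 8)), cell=cell, intervals=(6, 7, 8))
        rng = np.random.default_rng(7)
        indices = np.column_stack([rng.integers(0, n, 50) for n in (6, 7, 8)])
        centers = dmap.crs_to_xyz(indices)
        all_idx = np.array(list(np.ndindex(6, 7, 8)))
        all_centers = dmap.crs_to_xyz(all_idx)
        for idx, point in zip(indices, centers):
            nearest = all_idx[np.argmin(np.linalg.norm(all_centers - point, axis=1))]
            assert dmap.xyz_to_crs(point) == tuple(nearest)


class TestVoxelsWithinRadius:
    def brute_force(self, dmap, center, radius, images=1):
        """Exhaustive scan over every voxel center and its periodic images."""
        hits = {}
        full = dmap.full_coverage()
        cell_edges = np.array([dmap.cell.a, dmap.cell.b, dmap.cell.c])
        for idx in np.ndindex(*dmap.extent):
            base = dmap.crs_to_xyz(idx)
            for shift in itertools.product(range(-images, images + 1), repeat=3):
                if any(s != 0 and not f for s, f in zip(shift, full)):
                    continue
                frac_shift = dmap.cell.orthogonalize(np.asarray(shift, dtype=float))
                d = np.linalg.norm(base + frac_shift - np.asarray(center))
                if d <= radius:
                    hits[idx] = min(hits.get(idx, np.inf), d)
        return hits

    def test_tiny_radius_center_on_voxel_center(self):
        dmap = make_map(np.zeros((10, 10, 10)))
        idx, dist, partial = voxels_within_radius(dmap, dmap.crs_to_xyz((4, 4, 4)), 0.4)
        assert len(idx) == 1 and tuple(idx[0]) == (4, 4, 4) and not partial

    def test_matches_brute_force_interior(self):
        cell = UnitCell(5, 5, 5)
        dmap = make_map(np.zeros((10, 10, 10)), cell=cell, intervals=(10, 10, 10))
        idx, dist, partial = voxels_within_radius(dmap, (2.4, 2.6, 2.5), 0.84)
        got = {tuple(i) for i in idx}
        assert got == set(self.brute_force(dmap, (2.4, 2.6, 2.5), 0.84))
        assert not partial

    def test_periodic_boundary_matches_brute_force(self):
        cell = UnitCell(5, 5, 5)
        dmap = make_map(np.zeros((10, 10, 10)), cell=cell, intervals=(10, 10, 10))
        center = (0.1, 4.9, 0.0)
        idx, dist, _ = voxels_within_radius(dmap, center, 0.9)
        oracle = self.brute_force(dmap, center, 0.9)
        assert {tuple(i) for i in idx} == set(oracle)
        for i, d in zip(idx, dist):
            assert d == pytest.approx(oracle[tuple(i)], abs=1e-9)

    def test_partial_map_flags_truncation(self):
        dmap = make_map(np.zeros((4, 4, 4)), cell=UnitCell(10, 10, 10),
                        intervals=(10, 10, 10))
        _, _, partial = voxels_within_radius(dmap, (3.9, 2.0, 2.0), 1.0)
        assert partial

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        r1=st.floats(0.2, 1.2),
        r2=st.floats(0.2, 1.2),
        x=st.floats(0.0, 5.0),
        y=st.floats(0.0, 5.0),
    )
    def test_monotone_in_radius(self, r1, r2, x, y):
        dmap = make_map(np.zeros((10, 10, 10)), cell=UnitCell(5, 5, 5),
                        intervals=(10, 10, 10))
        small, large = sorted((r1, r2))
        s1, _, _ = voxels_within_radius(dmap, (x, y, 2.5), small)
        s2, _, _ = voxels_within_radius(dmap, (x, y, 2.5), large)
        assert {tuple(i) for i in s1} <= {tuple(i) for i in s2}

    def test_large_radius_warns(self):
        dmap = make_map(np.zeros((10, 10, 10)))
        with pytest.warns(UserWarning):
            voxels_within_radius(dmap, (5, 5, 5), 6.0)
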