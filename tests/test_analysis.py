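"""Density ratio chain: clouds, normalization, correction, conversion."""

import dataclasses

import numpy as np
import pytest

from edunits import (
    ConversionFactor,
    DensityCloud,
    analyze_entry,
    map_statistics,
    parse_structure,
)
from edunits.analysis import (
    NoQualifyingChainError,
    aggregate_cloud,
    atom_cloud,
    chain_deviation_fraction,
    conversion_factor,
    correct_bfactor,
    fit_bfactor_slopes,
    normalize_volume,
)
from edunits.atomtypes import ATOM_TYPES
from edunits.synthetic import FixtureSpec, make_entry, synth_density_map

from conftest import make_map


def cloud(**kw):
    base = dict(owner=("A",), level="atom", indices=np.empty((0, 3), dtype=int),
                total_density=0.0, electrons=1.0, volume=0)
    base.update(kw)
    return DensityCloud(**base)


class TestClosedFormEquations:
    """Hand-computable identities of the ratio chain."""

    def test_volume_normalization_identity_case(self):
        c = cloud(ratio=0.7, volume=25)
        assert normalize_volume(c, 25).r_norm == pytest.approx(0.7)

    def test_volume_normalization_arithmetic(self):
        c = cloud(ratio=1.0, volume=20)
        assert normalize_volume(c, 25).r_norm == pytest.approx(1.25)

    def test_volume_normalization_proportionality(self):
        r1 = normalize_volume(cloud(ratio=1.0, volume=40), 20).r_norm
        r2 = normalize_volume(cloud(ratio=1.0, volume=20), 20).r_norm
        assert r2 == pytest.approx(2 * r1)

    def test_deviation_fraction_identity_and_arithmetic(self):
        conv = ConversionFactor(1.0, 1)
        assert chain_deviation_fraction(1.0, conv) == 0.0
        assert chain_deviation_fraction(1.1, conv) == pytest.approx(0.1)

    def test_bfactor_correction_noop_at_median(self):
        conv = ConversionFactor(2.0, 1)
        c = cloud(ratio=1.0, r_norm=2.2, f=0.1)
        correct_bfactor(c, np.log(20.0), np.log(20.0), slope=0.3, conv=conv)
        assert c.f_corrected == pytest.approx(c.f)
        assert c.r_corrected == pytest.approx(c.r_norm)

    def test_bfactor_correction_arithmetic(self):
        conv = ConversionFactor(1.0, 1)
        c = cloud(f=0.0)
        correct_bfactor(c, 0.5, 0.0, slope=0.2, conv=conv)
        assert c.f_corrected == pytest.approx(0.1)
        assert c.r_corrected == pytest.approx(1.1)

    def test_ratio_fraction_roundtrip(self):
        conv = ConversionFactor(0.83, 3)
        c = cloud(f=0.21)
        correct_bfactor(c, 1.0, 0.4, slope=-0.15, conv=conv)
        assert chain_deviation_fraction(c.r_corrected, conv) == pytest.approx(
            c.f_corrected, abs=1e-12
        )

    def test_conversion_factor_median_conventions(self):
        assert conversion_factor([cloud(ratio=0.9)]).value == pytest.approx(0.9)
        chains = [cloud(ratio=r) for r in (0.8, 1.2, 1.0)]
        assert conversion_factor(chains).value == pytest.approx(1.0)
        chains = [cloud(ratio=r) for r in (0.8, 1.0, 1.2, 1.4)]
        assert conversion_factor(chains).value == pytest.approx(1.1)

    def test_no_qualifying_chain_raises(self):
        with pytest.raises(NoQualifyingChainError):
            conversion_factor([])


class TestAtomCloud:
    def gaussian_map(self, z=8, b=20.0, occ=1.0, scale=1.0):
        spec = FixtureSpec(sequences=("G",), zero_mean=False, scale=scale, seed=3)
        text = (
            "CRYST1   16.000   16.000   16.000  90.00  90.00  90.00 P 1           1\n"
            f"ATOM      1  O   GLY A   1       8.000   8.000   8.000{occ:6.2f}{b:6.2f}"
            "           O\n"
            "END\n"
        )
        model = parse_structure(text)
        dmap = synth_density_map(model, spec)
        return model, dmap, spec

    def test_isolated_gaussian_matches_brute_force_sum(self):
        model, dmap, spec = self.gaussian_map(scale=2.5)
        stats = map_statistics(dmap)
        atom = model.atoms[0]
        c = atom_cloud(dmap, stats, atom, radius=0.9, threshold_sigma=1.5)
        # oracle: exhaustive scan over the whole grid
        total = 0.0
        n_vox = 0
        thr = 1.5 * stats.sigma
        for idx in np.ndindex(*dmap.extent):
            d = np.linalg.norm(dmap.crs_to_xyz(idx) - atom.xyz)
            v = float(dmap.grid[idx])
            if d <= 0.9 and v > thr:
                total += v
                n_vox += 1
        assert c.volume == n_vox
        assert c.total_density == pytest.approx(total, rel=1e-6)
        assert c.ratio == pytest.approx(total / 8.0, rel=1e-6)

    def test_half_occupancy_doubles_ratio(self):
        model1, dmap, _ = self.gaussian_map(occ=1.0)
        stats = map_statistics(dmap)
        atom = model1.atoms[0]
        full = atom_cloud(dmap, stats, atom, 0.9)
        atom_half = dataclasses.replace(atom, occupancy=0.5)
        half = atom_cloud(dmap, stats, atom_half, 0.9)
        assert half.ratio == pytest.approx(2 * full.ratio)

    def test_zero_density_region_flagged_empty(self):
        model, dmap, _ = self.gaussian_map()
        stats = map_statistics(dmap)
        far = dataclasses.replace(model.atoms[0], xyz=np.array([2.0, 2.0, 2.0]))
        c = atom_cloud(dmap, stats, far, 0.9)
        assert c.empty and c.volume == 0


class TestAggregation:
    def grid_map(self):
        grid = np.zeros((10, 10, 10))
        grid[2, 2, 2] = 1.0
        grid[2, 2, 3] = 2.0
        grid[5, 5, 5] = 4.0
        return make_map(grid)

    def make(self, indices, electrons=8.0, owner=("A", 1, "", "X")):
        idx = np.array(indices, dtype=int).reshape(-1, 3)
        return DensityCloud(owner=owner, level="atom", indices=idx,
                            total_density=0.0, electrons=electrons, volume=len(idx))

    def test_disjoint_union_adds(self):
        dmap = self.grid_map()
        a = self.make([(2, 2, 2)])
        b = self.make([(5, 5, 5)])
        agg = aggregate_cloud([a, b], dmap, "residue", min_atoms=2)
        assert agg.total_density == pytest.approx(5.0)
        assert agg.volume == 2
        assert agg.electrons == pytest.approx(16.0)

    def test_shared_voxel_counted_once(self):
        dmap = self.grid_map()
        a = self.make([(2, 2, 2), (2, 2, 3)])
        b = self.make([(2, 2, 3), (5, 5, 5)])
        agg = aggregate_cloud([a, b], dmap, "residue", min_atoms=2)
        assert agg.volume == 3
        assert agg.total_density == pytest.approx(7.0)  # 1 + 2 + 4, shared voxel once

    def test_three_atom_residue_below_floor(self):
        dmap = self.grid_map()
        clouds = [self.make([(2, 2, 2)]) for _ in range(3)]
        assert aggregate_cloud(clouds, dmap, "residue", min_atoms=4) is None


class TestSlopeFit:
    def test_exact_line_recovered(self):
        log_b = np.linspace(2.0, 4.0, 10)
        f = 0.2 * log_b - 0.7
        slopes = fit_bfactor_slopes(f, log_b, ["C_single"] * 10, {t: 0.0 for t in ATOM_TYPES})
        assert slopes["C_single"] == pytest.approx(0.2, abs=1e-9)

    def test_two_points_fall_back_to_default(self):
        defaults = {t: -0.123 for t in ATOM_TYPES}
        slopes = fit_bfactor_slopes(
            np.array([0.1, 0.2]), np.array([2.0, 3.0]), ["S_single"] * 2, defaults
        )
        assert slopes["S_single"] == pytest.approx(-0.123)

    def test_constant_b_falls_back_to_default(self):
        defaults = {t: 0.077 for t in ATOM_TYPES}
        slopes = fit_bfactor_slopes(
            np.array([0.1, 0.2, 0.3]), np.full(3, 2.0), ["O_single"] * 3, defaults
        )
        assert slopes["O_single"] == pytest.approx(0.077)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        log_b = rng.uniform(2, 4, 100)
        f = -0.3 * log_b + 0.5 + rng.normal(0, 0.05, 100)
        slopes = fit_bfactor_slopes(f, log_b, ["N_single"] * 100, {t: 0.0 for t in ATOM_TYPES})
        x = np.column_stack([log_b, np.ones(100)])
        beta = np.linalg.solve(x.T @ x, x.T @ f)
        assert slopes["N_single"] == pytest.approx(beta[0], rel=1e-9)


class TestEntryAnalysis:
    def test_two_chain_entry_report_shape(self, default_spec, default_entry):
        model, dmap = default_entry
        res = analyze_entry(model, dmap, radii=default_spec.radii)
        assert len(res.chain_table) == 2
        ts = res.type_stats
        assert len(ts) == 13
        assert np.isfinite(ts.median_f_corrected).all()
        assert res.conversion_factor > 0

    def test_rerun_is_byte_identical(self, default_spec, default_entry, tmp_path):
        model, dmap = default_entry
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        analyze_entry(model, dmap, radii=default_spec.radii).to_json(p1)
        analyze_entry(model, dmap, radii=default_spec.radii).to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scale_invariance_of_deviation_fractions(self, default_spec, default_entry, k):
        model, dmap = default_entry
        res1 = analyze_entry(model, dmap, radii=default_spec.radii)
        scaled = dataclasses.replace(dmap, grid=dmap.grid.astype(np.float64) * k, _stats=None)
        res2 = analyze_entry(model, scaled, radii=default_spec.radii)
        a1, a2 = res1.atom_table, res2.atom_table
        assert res2.conversion_factor == pytest.approx(k * res1.conversion_factor, rel=1e-5)
        ok = (a1.flag == "ok") & (a2.flag == "ok")
        np.testing.assert_allclose(a2.f[ok], a1.f[ok], rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(a2.f_corrected[ok], a1.f_corrected[ok], rtol=1e-9, atol=1e-9)

    def test_cached_evaluator_agrees_with_direct_analysis(self, default_spec, default_entry):
        """The optimizer's fast path must reproduce the reference pipeline."""
        from edunits.radii import EntryCache

        model, dmap = default_entry
        res = analyze_entry(model, dmap, radii=default_spec.radii)
        cache = EntryCache(model, dmap)
        ev = cache.evaluate(default_spec.radii.as_vector())
        assert ev["ok"]
        assert ev["conv"] == pytest.approx(res.conversion_factor, rel=1e-9)
        table = res.atom_table
        direct = {
            (a.chain_id, a.residue_seq, a.name): fc
            for a, fc in zip(model.atoms, table.f_corrected)
        }
        for atom, fc, valid in zip(cache.atoms, ev["f_corrected"], ev["valid"]):
            if valid:
                assert fc == pytest.approx(
                    direct[(atom.chain_id, atom.residue_seq, atom.name)], rel=1e-9
                )

    def test_zero_occupancy_atoms_excluded(self, default_spec):
        spec = dataclasses.replace(default_spec, seed=5)
        model, dmap = make_entry(spec)
        model.atoms[10].occupancy = 0.0
        res = analyze_entry(model, dmap, radii=spec.radii)
        assert res.atom_table.flag.iloc[10] == "zero_occupancy"
        assert not np.isfinite(res.atom_table.f_corrected.iloc[10])
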