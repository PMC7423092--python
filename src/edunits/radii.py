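"""Per-atom-type radii, B-factor slope defaults, and radius optimization.

The optimization drives every atom type's pooled median corrected chain
deviation fraction below a tolerance (0.05 by default) by adjusting one
radius at a time: at each iteration the type with the largest absolute
median is selected, candidate radii within +/-0.3 A of the incumbent are
scanned on a 0.01 A grid, the candidate whose median is closest to zero is
adopted, and the B-factor slope tables are refit before the next iteration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .atomtypes import ATOM_TYPES
from .ccp4 import DensityMap, map_statistics, voxels_within_radius
from .config import AnalysisConfig
from .structure import StructureModel

RADIUS_BOUNDS = (0.3, 1.5)

# Literature starting radii and the radii after whole-archive optimization.
LITERATURE_RADII_VALUES = {
    "C_single": 0.77, "C_single_bb": 0.77,
    "C_double": 0.67, "C_double_bb": 0.67,
    "C_intermediate": 0.72,
    "O_single": 0.67, "O_double": 0.60, "O_double_bb": 0.60, "O_intermediate": 0.64,
    "N_single": 0.70, "N_single_bb": 0.70, "N_intermediate": 0.62,
    "S_single": 1.04,
}
OPTIMIZED_RADII_VALUES = {
    "C_single": 0.84, "C_single_bb": 0.72,
    "C_double": 0.67, "C_double_bb": 0.61,
    "C_intermediate": 0.72,
    "O_single": 0.80, "O_double": 0.71, "O_double_bb": 0.77, "O_intermediate": 0.71,
    "N_single": 0.95, "N_single_bb": 0.70, "N_intermediate": 0.77,
    "S_single": 0.75,
}


@dataclass(frozen=True)
class RadiiSet:
    """Complete per-atom-type radius set (Angstrom)."""

    values: dict[str, float]
    provenance: str = "user"

    def __post_init__(self) -> None:
        missing = set(ATOM_TYPES) - set(self.values)
        if missing:
            raise ValueError(f"radii missing for {sorted(missing)}")
        for t, r in self.values.items():
            if not (RADIUS_BOUNDS[0] < r < RADIUS_BOUNDS[1]):
                raise ValueError(f"radius {r} for {t} outside {RADIUS_BOUNDS}")

    def __getitem__(self, atom_type: str) -> float:
        return self.values[atom_type]

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[t] for t in ATOM_TYPES])

    @classmethod
    def from_vector(cls, vec: np.ndarray, provenance: str = "optimized") -> "RadiiSet":
        return cls(dict(zip(ATOM_TYPES, (float(v) for v in vec))), provenance)

    def save(self, path: str | Path) -> None:
        lines = [f"{t} = {self.values[t]:.4f}" for t in ATOM_TYPES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path, provenance: str = "user") -> "RadiiSet":
        values = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                key, val = (s.strip() for s in line.split("=", 1))
                values[key] = float(val)
        return cls(values, provenance)


@dataclass(frozen=True)
class SlopeTable:
    """Default per-type B-factor slopes for types with < 3 atoms."""

    values: dict[str, float]
    provenance: str = "user"

    def __getitem__(self, atom_type: str) -> float:
        return self.values.get(atom_type, 0.0)

    def save(self, path: str | Path) -> None:
        lines = [f"{t} = {self.values.get(t, 0.0):.6f}" for t in ATOM_TYPES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path, provenance: str = "user") -> "SlopeTable":
        values = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                key, val = (s.strip() for s in line.split("=", 1))
                values[key] = float(val)
        return cls(values, provenance)


LITERATURE_RADII = RadiiSet(LITERATURE_RADII_VALUES, "literature")
OPTIMIZED_RADII = RadiiSet(OPTIMIZED_RADII_VALUES, "optimized")

# Median per-type slopes of the chain deviation fraction against log(B),
# derived from a fixed-seed synthetic calibration sample (see docs); they
# are negative throughout because density capture falls with increasing B.
DEFAULT_SLOPE_VALUES = {
    "C_double": -0.509, "C_double_bb": -0.485,
    "C_intermediate": -0.559,
    "C_single": -0.613, "C_single_bb": -0.559,
    "N_intermediate": -0.621, "N_single": -0.634, "N_single_bb": -0.566,
    "O_double": -0.627, "O_double_bb": -0.603,
    "O_intermediate": -0.622, "O_single": -0.641,
    "S_single": -0.649,
}
DEFAULT_SLOPES = SlopeTable(DEFAULT_SLOPE_VALUES, "synthetic-calibration")


# ---------------------------------------------------------------------------
# cached evaluation


class EntryCache:
    """Pre-extracted voxel neighborhoods of one entry for fast re-evaluation.

    For every usable atom the significant voxels within the maximal radius
    are stored with their distances, so evaluating a candidate radii set
    reduces to prefix sums and a union pass per chain; results agree with
    the direct analysis path (cross-checked in the test suite).
    """

    def __init__(
        self,
        structure: StructureModel,
        dmap: DensityMap,
        config: AnalysisConfig | None = None,
        max_radius: float = RADIUS_BOUNDS[1],
    ) -> None:
        cfg = config or AnalysisConfig()
        self.config = cfg
        stats = map_statistics(dmap)
        threshold = (
            cfg.density_threshold_sigma * stats.sigma if cfg.threshold_atom_sums else -np.inf
        )
        shape = dmap.extent

        atoms = [a for a in structure.atoms if a.occupancy > 0 and a.b_factor > 0]
        dists, vox_flat, values, ptr = [], [], [], [0]
        kept_atoms = []
        for atom in atoms:
            idx, d, partial = voxels_within_radius(dmap, atom.xyz, max_radius)
            if partial:
                continue  # conservatively excluded at every candidate radius
            vals = dmap.values_at(idx)
            keep = vals > threshold
            idx, d, vals = idx[keep], d[keep], vals[keep]
            order = np.argsort(d)
            idx, d, vals = idx[order], d[order], vals[order]
            kept_atoms.append(atom)
            dists.append(d)
            vox_flat.append(np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape))
            values.append(vals.astype(np.float64))
            ptr.append(ptr[-1] + len(d))

        self.atoms = kept_atoms
        self.n = len(kept_atoms)
        self.dist = np.concatenate(dists) if dists else np.empty(0)
        self.value = np.concatenate(values) if values else np.empty(0)
        self.ptr = np.asarray(ptr)
        self.row_atom = np.repeat(np.arange(self.n), np.diff(self.ptr))
        self.type_idx = np.array([ATOM_TYPES.index(a.atom_type) for a in kept_atoms])
        self.z_eff = np.array([a.electrons * a.occupancy for a in kept_atoms])
        self.log_b = np.log([a.b_factor for a in kept_atoms])
        self.chain_ids = np.array([a.chain_id for a in kept_atoms])

        # per-chain unique-voxel tables for union sums
        flat_all = np.concatenate(vox_flat) if vox_flat else np.empty(0, dtype=int)
        self.chains = {}
        for cid in np.unique(self.chain_ids):
            sel = np.nonzero(self.chain_ids == cid)[0]
            pair_atom = np.concatenate(
                [np.full(self.ptr[i + 1] - self.ptr[i], i) for i in sel]
            ).astype(int)
            pair_rows = np.concatenate(
                [np.arange(self.ptr[i], self.ptr[i + 1]) for i in sel]
            ).astype(int)
            pair_vox = flat_all[pair_rows]
            uniq, inv = np.unique(pair_vox, return_inverse=True)
            uval = np.zeros(len(uniq))
            uval[inv] = self.value[pair_rows]
            self.chains[str(cid)] = dict(
                atom_rows=sel,
                pair_atom=pair_atom,
                pair_dist=self.dist[pair_rows],
                pair_uvox=inv,
                uval=uval,
            )

    def _counts_and_sums(self, cutoffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = self.dist <= cutoffs[self.row_atom]
        counts = np.bincount(self.row_atom, weights=mask, minlength=self.n).astype(int)
        sums = np.bincount(self.row_atom, weights=self.value * mask, minlength=self.n)
        return counts, sums

    def evaluate(
        self,
        radii_vec: np.ndarray,
        default_slopes: dict[str, float] | None = None,
        slopes: dict[str, float] | None = None,
        min_chain_atoms: int | None = None,
    ) -> dict:
        """Per-atom f_corrected (and per-entry slopes) at the given radii."""
        from .analysis import fit_bfactor_slopes

        cfg = self.config
        min_chain = cfg.chain_min_atoms if min_chain_atoms is None else min_chain_atoms
        cutoffs = radii_vec[self.type_idx]
        volumes, totals = self._counts_and_sums(cutoffs)
        valid = volumes > 0
        ratio = np.full(self.n, np.nan)
        ratio[valid] = totals[valid] / self.z_eff[valid]

        median_vt = np.full(len(ATOM_TYPES), np.nan)
        for t in range(len(ATOM_TYPES)):
            mask = (self.type_idx == t) & valid
            if mask.any():
                median_vt[t] = np.median(volumes[mask])
        r_norm = np.full(self.n, np.nan)
        r_norm[valid] = ratio[valid] * median_vt[self.type_idx[valid]] / volumes[valid]

        chain_ratios = []
        for cid, ch in self.chains.items():
            rows = ch["atom_rows"]
            members = valid[rows]
            if members.sum() < min_chain:
                continue
            include = (ch["pair_dist"] <= cutoffs[ch["pair_atom"]])
            hit = np.zeros(len(ch["uval"]), dtype=bool)
            hit[ch["pair_uvox"][include]] = True
            total = ch["uval"][hit].sum()
            electrons = self.z_eff[rows][members].sum()
            chain_ratios.append(total / electrons)
        if not chain_ratios:
            return dict(ok=False)
        conv = float(np.median(chain_ratios))

        f = (r_norm - conv) / conv
        type_names = np.array(ATOM_TYPES)[self.type_idx]
        if slopes is None:
            slopes = fit_bfactor_slopes(
                f[valid], self.log_b[valid], type_names[valid],
                default_slopes or {t: 0.0 for t in ATOM_TYPES},
            )
        slope_vec = np.array([slopes[t] for t in ATOM_TYPES])
        med_logb = np.full(len(ATOM_TYPES), np.nan)
        for t in range(len(ATOM_TYPES)):
            mask = (self.type_idx == t) & valid
            if mask.any():
                med_logb[t] = np.median(self.log_b[mask])
        f_corr = f + (self.log_b - med_logb[self.type_idx]) * slope_vec[self.type_idx]
        return dict(
            ok=True,
            f_corrected=f_corr,
            valid=valid,
            types=self.type_idx,
            conv=conv,
            slopes=slopes,
        )


def _pool_medians(evaluations: list[dict]) -> dict[str, float]:
    pooled: dict[str, list[np.ndarray]] = {t: [] for t in ATOM_TYPES}
    for ev in evaluations:
        if not ev["ok"]:
            continue
        for t in range(len(ATOM_TYPES)):
            mask = (ev["types"] == t) & ev["valid"] & np.isfinite(ev["f_corrected"])
            if mask.any():
                pooled[ATOM_TYPES[t]].append(ev["f_corrected"][mask])
    return {
        t: float(np.median(np.concatenate(v))) for t, v in pooled.items() if v
    }


def build_caches(
    sample: Sequence[tuple[StructureModel, DensityMap]],
    config: AnalysisConfig | None = None,
) -> list[EntryCache]:
    caches = []
    for structure, dmap in sample:
        try:
            caches.append(EntryCache(structure, dmap, config))
        except Exception:
            continue  # entry skipped; logged by callers that care
    if not caches:
        raise ValueError("every entry in the sample failed to build")
    return caches


def evaluate_radii(
    sample: Sequence[tuple[StructureModel, DensityMap]] | list[EntryCache],
    radii: RadiiSet,
    slopes: SlopeTable | None = None,
    config: AnalysisConfig | None = None,
) -> dict[str, float]:
    """Pooled per-type median f_corrected of a sample at the given radii."""
    caches = sample if sample and isinstance(sample[0], EntryCache) else build_caches(sample, config)
    vec = radii.as_vector()
    defaults = (slopes or DEFAULT_SLOPES).values
    evals = [c.evaluate(vec, default_slopes=defaults) for c in caches]
    if not any(ev["ok"] for ev in evals):
        raise ValueError("no entry produced a conversion factor")
    return _pool_medians(evals)


@dataclass
class OptimizationState:
    """Append-only record of one radius-optimization run."""

    radii: RadiiSet
    slopes: SlopeTable
    medians: dict[str, float]
    iterations: int
    converged: bool
    history: list[dict] = field(default_factory=list)

    def save_log(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "atom_type", "radius", "median_f", "worst_abs_median"])
            for row in self.history:
                writer.writerow(
                    [row["iteration"], row["atom_type"], f"{row['radius']:.4f}",
                     f"{row['median_f']:.6f}", f"{row['worst']:.6f}"]
                )


def optimize_radii(
    sample: Sequence[tuple[StructureModel, DensityMap]] | list[EntryCache],
    initial: RadiiSet,
    tolerance: float = 0.05,
    step: float = 0.01,
    span: float = 0.3,
    max_iterations: int = 100,
    slopes: SlopeTable | None = None,
    config: AnalysisConfig | None = None,
) -> OptimizationState:
    """One-type-at-a-time radius optimization (deterministic).

    Each iteration targets the type with the largest absolute pooled median
    f_corrected (ties broken by type-name order), scans candidates within
    ``span`` of the incumbent on a ``step`` grid clamped inside the physical
    bounds, adopts the candidate with |median| closest to zero, then refits
    slopes.  A type whose best candidate improves its median by less than
    1e-4 is frozen for one round to prevent cycling.
    """
    caches = sample if sample and isinstance(sample[0], EntryCache) else build_caches(sample, config)
    current = {t: float(r) for t, r in initial.values.items()}
    default_slopes = dict((slopes or DEFAULT_SLOPES).values)
    frozen: set[str] = set()
    history: list[dict] = []

    def evaluate_full(vec: np.ndarray) -> tuple[dict[str, float], list[dict]]:
        evals = [c.evaluate(vec, default_slopes=default_slopes) for c in caches]
        return _pool_medians(evals), evals

    def refit_defaults(evals: list[dict]) -> None:
        per_type: dict[str, list[float]] = {t: [] for t in ATOM_TYPES}
        for ev in evals:
            if ev["ok"]:
                for t, s in ev["slopes"].items():
                    per_type[t].append(s)
        for t, vals in per_type.items():
            if vals:
                default_slopes[t] = float(np.median(vals))

    vec = np.array([current[t] for t in ATOM_TYPES])
    medians, evals = evaluate_full(vec)
    refit_defaults(evals)
    converged = max(abs(m) for m in medians.values()) < tolerance
    iteration = 0
    while not converged and iteration < max_iterations:
        iteration += 1
        candidates_order = sorted(
            (t for t in medians if t not in frozen),
            key=lambda t: (-abs(medians[t]), t),
        )
        frozen.clear()
        if not candidates_order:
            break
        target = candidates_order[0]
        ti = ATOM_TYPES.index(target)
        r0 = current[target]
        lo = max(RADIUS_BOUNDS[0] + step, r0 - span)
        hi = min(RADIUS_BOUNDS[1] - step, r0 + span)
        grid = np.round(np.arange(lo, hi + step / 2, step), 6)
        best_r, best_med = r0, medians[target]
        # candidate scan with slopes frozen at their last-adopted values
        frozen_slopes = [ev.get("slopes") if ev["ok"] else None for ev in evals]
        for r in grid:
            trial = vec.copy()
            trial[ti] = r
            trial_evals = [
                c.evaluate(trial, slopes=s) if s is not None
                else c.evaluate(trial, default_slopes=default_slopes)
                for c, s in zip(caches, frozen_slopes)
            ]
            med = _pool_medians(trial_evals).get(target, np.inf)
            if abs(med) < abs(best_med) - 1e-12:
                best_r, best_med = float(r), med
        if abs(medians[target]) - abs(best_med) < 1e-4:
            frozen.add(target)  # no real improvement: skip this type next round
        current[target] = best_r
        vec[ti] = best_r
        medians, evals = evaluate_full(vec)
        refit_defaults(evals)
        history.append(
            dict(
                iteration=iteration,
                atom_type=target,
                radius=best_r,
                median_f=medians.get(target, np.nan),
                worst=max(abs(m) for m in medians.values()),
            )
        )
        converged = max(abs(m) for m in medians.values()) < tolerance

    return OptimizationState(
        radii=RadiiSet({t: current[t] for t in ATOM_TYPES}, "optimized"),
        slopes=SlopeTable(dict(default_slopes), "optimized"),
        medians=medians,
        iterations=iteration,
        converged=converged,
        history=history,
    )
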