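"""Electron density ratio analysis: from sigma-scaled maps to electrons.

The central quantity is the electron density ratio r_i of an atom: the sum
of significant map density within the atom's type radius divided by its
(occupancy-adjusted) electron count.  Atom ratios are aggregated into
residue and chain clouds (shared voxels counted once), the chain-median
ratio median(r_c) becomes the structure's conversion factor from arbitrary
density units to electrons, and each atom ratio is refined in three steps:

    r_norm      = r_i * median(V_t) / V_i          (voxel-count smoothing)
    f           = (r_norm - median(r_c)) / median(r_c)
    f_corrected = f + (log(b_i) - median(log b_t)) * s_t
    r_corrected = f_corrected * median(r_c) + median(r_c)

where V_t, b_t and the slope s_t are per-atom-type statistics of the same
structure and b_i is the atom's isotropic B-factor (natural logarithm).

The public surface follows the statsmodels convention: build a
:class:`DensityScaleModel` from a structure and its 2Fo-Fc map, call
``fit()`` and work with the returned :class:`DensityScaleResults`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atomtypes import ATOM_TYPES
from .ccp4 import DensityMap, MapStats, map_statistics, read_ccp4, voxels_within_radius
from .config import AnalysisConfig
from .structure import StructureModel, TypedAtom, parse_structure

class NoQualifyingChainError(ValueError):
    """No chain cloud met the atom-count floor; no conversion factor."""


class AggregationError(ValueError):
    """Attempted to aggregate clouds with mixed owners."""


@dataclass
class DensityCloud:
    """Voxels attributed to an atom, residue or chain, and its ratio chain."""

    owner: tuple
    level: str  # atom | residue | chain
    indices: np.ndarray  # (n, 3) storage voxel indices
    total_density: float
    electrons: float  # occupancy-adjusted electron count
    volume: int
    ratio: float = np.nan
    r_norm: float = np.nan
    f: float = np.nan
    f_corrected: float = np.nan
    r_corrected: float = np.nan
    partial: bool = False
    n_atoms: int = 1

    @property
    def empty(self) -> bool:
        return self.volume == 0


@dataclass
class ConversionFactor:
    """Median chain density ratio: arbitrary density units per electron."""

    value: float
    n_chains: int


def atom_cloud(
    dmap: DensityMap,
    stats: MapStats,
    atom: TypedAtom,
    radius: float,
    threshold_sigma: float | None = 1.5,
) -> DensityCloud:
    """Significant voxels within ``radius`` of the atom and its ratio r_i.

    Occupancy enters as effective electrons Z_i * occupancy, which is
    equivalent to dividing the density sum by the occupancy.
    """
    indices, _, partial = voxels_within_radius(dmap, atom.xyz, radius)
    values = dmap.values_at(indices) if len(indices) else np.empty(0)
    if threshold_sigma is not None:
        keep = values > threshold_sigma * stats.sigma
        indices, values = indices[keep], values[keep]
    total = float(values.sum(dtype=np.float64))
    electrons = atom.electrons * atom.occupancy
    cloud = DensityCloud(
        owner=(atom.chain_id, atom.residue_seq, atom.insertion_code, atom.name),
        level="atom",
        indices=indices,
        total_density=total,
        electrons=electrons,
        volume=len(indices),
        partial=partial,
    )
    if cloud.volume and electrons > 0:
        cloud.ratio = total / electrons
    return cloud


def aggregate_cloud(
    clouds: Sequence[DensityCloud],
    dmap: DensityMap,
    level: str,
    min_atoms: int,
) -> DensityCloud | None:
    """Union of atom clouds at residue or chain level.

    Voxels shared between atoms are counted once; returns ``None`` when
    fewer than ``min_atoms`` contributing atom clouds are available.
    """
    owners = {c.owner[0] if level == "chain" else c.owner[:3] for c in clouds}
    if len(owners) > 1:
        raise AggregationError(f"mixed owners in {level} aggregation: {owners}")
    members = [c for c in clouds if not c.empty and not c.partial]
    if len(members) < min_atoms:
        return None
    indices = np.unique(np.concatenate([c.indices for c in members]), axis=0)
    total = float(dmap.values_at(indices).sum(dtype=np.float64))
    electrons = float(sum(c.electrons for c in members))
    cloud = DensityCloud(
        owner=owners.pop(),
        level=level,
        indices=indices,
        total_density=total,
        electrons=electrons,
        volume=len(indices),
        n_atoms=len(members),
    )
    cloud.ratio = total / electrons
    return cloud


def normalize_volume(cloud: DensityCloud, median_volume: float) -> DensityCloud:
    """Apply the voxel-count smoothing r_norm = r_i * median(V_t) / V_i."""
    if cloud.volume > 0:
        cloud.r_norm = cloud.ratio * median_volume / cloud.volume
    return cloud


def chain_deviation_fraction(r_norm: float, conv: ConversionFactor) -> float:
    """f = (r_norm - median(r_c)) / median(r_c)."""
    if not np.isfinite(conv.value) or conv.value <= 0:
        raise NoQualifyingChainError("conversion factor undefined")
    return (r_norm - conv.value) / conv.value


def conversion_factor(chain_clouds: Sequence[DensityCloud]) -> ConversionFactor:
    """Median of qualifying chain ratios (even count: mean of middle pair)."""
    ratios = [c.ratio for c in chain_clouds if np.isfinite(c.ratio)]
    if not ratios:
        raise NoQualifyingChainError("no qualifying chain cloud")
    return ConversionFactor(value=float(np.median(ratios)), n_chains=len(ratios))


def fit_bfactor_slopes(
    f_values: np.ndarray,
    log_b: np.ndarray,
    types: Sequence[str],
    default_slopes: dict[str, float],
    min_points: int = 3,
) -> dict[str, float]:
    """Per-type OLS slope of the chain deviation fraction against log(b).

    Types with fewer than ``min_points`` atoms, or without B-factor spread,
    fall back to the supplied default slope table.
    """
    types = np.asarray(types)
    slopes: dict[str, float] = {}
    for t in ATOM_TYPES:
        mask = (types == t) & np.isfinite(f_values) & np.isfinite(log_b)
        x, y = log_b[mask], f_values[mask]
        if len(x) < min_points or np.ptp(x) < 1e-12:
            slopes[t] = float(default_slopes.get(t, 0.0))
            continue
        slopes[t] = float(np.polyfit(x, y, 1)[0])
    return slopes


def correct_bfactor(
    cloud: DensityCloud,
    log_b: float,
    median_log_b: float,
    slope: float,
    conv: ConversionFactor,
) -> DensityCloud:
    """Apply the B-factor correction (and its inverse map back to a ratio)."""
    cloud.f_corrected = cloud.f + (log_b - median_log_b) * slope
    cloud.r_corrected = cloud.f_corrected * conv.value + conv.value
    return cloud


# ---------------------------------------------------------------------------
# model / results


class DensityScaleModel:
    """Per-structure model tying a coordinate model to its 2Fo-Fc map.

    Parameters
    ----------
    structure : StructureModel
        Parsed, typed coordinate model.
    density_map : DensityMap
        The sigma-scaled 2Fo-Fc map in the same crystal frame.
    radii : dict or RadiiSet, optional
        Per-atom-type radii (Angstrom); defaults to the optimized set.
    slopes : dict, optional
        Default B-factor slopes for sparse atom types.
    config : AnalysisConfig, optional
    """

    def __init__(self, structure, density_map, radii=None, slopes=None, config=None):
        from .radii import DEFAULT_SLOPES, OPTIMIZED_RADII, RadiiSet, SlopeTable

        self.structure: StructureModel = structure
        self.density_map: DensityMap = density_map
        if radii is None:
            radii = OPTIMIZED_RADII
        self.radii = radii if isinstance(radii, RadiiSet) else RadiiSet(dict(radii), "user")
        if slopes is None:
            slopes = DEFAULT_SLOPES
        self.slopes = slopes if isinstance(slopes, SlopeTable) else SlopeTable(dict(slopes), "user")
        self.config = config or AnalysisConfig()

    @classmethod
    def from_files(cls, pdb_path, map_path, **kwargs) -> "DensityScaleModel":
        with open(pdb_path) as fh:
            structure = parse_structure(fh)
        with open(map_path, "rb") as fh:
            dmap = read_ccp4(fh)
        return cls(structure, dmap, **kwargs)

    def fit(self) -> "DensityScaleResults":
        cfg = self.config
        dmap = self.density_map
        stats = map_statistics(dmap)
        thr = cfg.density_threshold_sigma if cfg.threshold_atom_sums else None

        atoms = self.structure.atoms
        clouds: list[DensityCloud] = []
        usable = np.zeros(len(atoms), dtype=bool)
        for i, atom in enumerate(atoms):
            radius = self.radii[atom.atom_type]
            cloud = atom_cloud(dmap, stats, atom, radius, thr)
            clouds.append(cloud)
            usable[i] = (
                atom.occupancy > 0
                and atom.b_factor > 0
                and not cloud.empty
                and not cloud.partial
            )

        types = np.array([a.atom_type for a in atoms])
        volumes = np.array([c.volume for c in clouds], dtype=float)
        median_vt = {
            t: float(np.median(volumes[(types == t) & usable]))
            for t in ATOM_TYPES
            if ((types == t) & usable).any()
        }
        for i, (atom, cloud) in enumerate(zip(atoms, clouds)):
            if usable[i]:
                normalize_volume(cloud, median_vt[atom.atom_type])

        # residue and chain aggregation over usable atom clouds
        index_of = {id(a): i for i, a in enumerate(atoms)}
        residue_clouds: dict[tuple, DensityCloud] = {}
        for key, members in self.structure.residues().items():
            idx = [index_of[id(a)] for a in members]
            cs = [clouds[i] for i in idx if usable[i]]
            if not cs:
                continue
            agg = aggregate_cloud(cs, dmap, "residue", cfg.residue_min_atoms)
            if agg is not None:
                residue_clouds[key] = agg
        chain_clouds: dict[str, DensityCloud] = {}
        for chain_id, members in self.structure.chains().items():
            idx = [index_of[id(a)] for a in members]
            cs = [clouds[i] for i in idx if usable[i]]
            if not cs:
                continue
            agg = aggregate_cloud(cs, dmap, "chain", cfg.chain_min_atoms)
            if agg is not None:
                chain_clouds[chain_id] = agg

        conv = conversion_factor(list(chain_clouds.values()))

        log_b = np.array(
            [np.log(a.b_factor) if a.b_factor > 0 else np.nan for a in atoms]
        )
        f_values = np.full(len(atoms), np.nan)
        for i, cloud in enumerate(clouds):
            if usable[i] and np.isfinite(cloud.r_norm):
                cloud.f = chain_deviation_fraction(cloud.r_norm, conv)
                f_values[i] = cloud.f

        fitted_slopes = fit_bfactor_slopes(
            f_values[usable], log_b[usable], types[usable], self.slopes.values
        )
        median_log_bt = {
            t: float(np.median(log_b[(types == t) & usable]))
            for t in ATOM_TYPES
            if ((types == t) & usable).any()
        }
        for i, (atom, cloud) in enumerate(zip(atoms, clouds)):
            if usable[i] and np.isfinite(cloud.f):
                correct_bfactor(
                    cloud,
                    log_b[i],
                    median_log_bt[atom.atom_type],
                    fitted_slopes[atom.atom_type],
                    conv,
                )

        return DensityScaleResults(
            model=self,
            atom_clouds=clouds,
            usable=usable,
            residue_clouds=residue_clouds,
            chain_clouds=chain_clouds,
            conversion=conv,
            median_volumes=median_vt,
            median_log_b=median_log_bt,
            slopes=fitted_slopes,
            map_stats=stats,
        )


@dataclass
class DensityScaleResults:
    """Fit results: conversion factor, ratio chain and per-type statistics."""

    model: DensityScaleModel
    atom_clouds: list[DensityCloud]
    usable: np.ndarray
    residue_clouds: dict[tuple, DensityCloud]
    chain_clouds: dict[str, DensityCloud]
    conversion: ConversionFactor
    median_volumes: dict[str, float]
    median_log_b: dict[str, float]
    slopes: dict[str, float]
    map_stats: MapStats
    _tables: dict = field(default_factory=dict, repr=False)

    @property
    def conversion_factor(self) -> float:
        return self.conversion.value

    # -- tables ----------------------------------------------------------

    @property
    def atom_table(self) -> pd.DataFrame:
        if "atom" not in self._tables:
            rows = []
            for atom, cloud, ok in zip(
                self.model.structure.atoms, self.atom_clouds, self.usable
            ):
                flag = "ok"
                if atom.occupancy <= 0:
                    flag = "zero_occupancy"
                elif atom.b_factor <= 0:
                    flag = "nonpositive_b"
                elif cloud.empty:
                    flag = "empty"
                elif cloud.partial:
                    flag = "partial"
                rows.append(
                    dict(
                        chain=atom.chain_id,
                        residue_seq=atom.residue_seq,
                        residue=atom.residue_name,
                        atom=atom.name,
                        atom_type=atom.atom_type,
                        electrons=atom.electrons,
                        occupancy=atom.occupancy,
                        b_factor=atom.b_factor,
                        volume=cloud.volume,
                        ratio=cloud.ratio,
                        r_norm=cloud.r_norm,
                        f=cloud.f,
                        f_corrected=cloud.f_corrected,
                        r_corrected=cloud.r_corrected,
                        flag=flag if not ok else "ok",
                    )
                )
            self._tables["atom"] = pd.DataFrame(rows)
        return self._tables["atom"]

    @property
    def residue_table(self) -> pd.DataFrame:
        rows = [
            dict(
                chain=key[0], residue_seq=key[1], residue=key[3],
                n_atoms=c.n_atoms, volume=c.volume,
                total_density=c.total_density, electrons=c.electrons, ratio=c.ratio,
            )
            for key, c in self.residue_clouds.items()
        ]
        return pd.DataFrame(rows)

    @property
    def chain_table(self) -> pd.DataFrame:
        rows = [
            dict(
                chain=cid, n_atoms=c.n_atoms, volume=c.volume,
                total_density=c.total_density, electrons=c.electrons, ratio=c.ratio,
            )
            for cid, c in self.chain_clouds.items()
        ]
        return pd.DataFrame(rows)

    @property
    def type_stats(self) -> pd.DataFrame:
        at = self.atom_table
        ok = at[at.flag == "ok"]
        rows = []
        for t in ATOM_TYPES:
            sub = ok[ok.atom_type == t]
            if sub.empty:
                continue
            rows.append(
                dict(
                    atom_type=t,
                    n_atoms=len(sub),
                    median_volume=self.median_volumes.get(t, np.nan),
                    median_log_b=self.median_log_b.get(t, np.nan),
                    slope=self.slopes.get(t, np.nan),
                    median_f=float(sub.f.median()),
                    median_f_corrected=float(sub.f_corrected.median()),
                )
            )
        return pd.DataFrame(rows)

    def type_medians(self) -> dict[str, float]:
        """Per-type median corrected chain deviation fraction."""
        ts = self.type_stats
        return dict(zip(ts.atom_type, ts.median_f_corrected))

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        buf = io.StringIO()
        n_atoms = int(self.usable.sum())
        buf.write("Electron density scale analysis\n")
        buf.write("=" * 47 + "\n")
        buf.write(f"Atoms analyzed:        {n_atoms} / {len(self.atom_clouds)}\n")
        buf.write(f"Residue clouds:        {len(self.residue_clouds)}\n")
        buf.write(f"Chain clouds:          {len(self.chain_clouds)}\n")
        buf.write(
            f"Conversion factor:     {self.conversion.value:.6g} "
            f"density units / electron ({self.conversion.n_chains} chains)\n"
        )
        buf.write(f"Map sigma:             {self.map_stats.sigma:.6g}\n\n")
        buf.write(
            self.type_stats.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
            )
        )
        return buf.getvalue()

    def to_csv(self, directory: str | Path, prefix: str = "entry") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in (
            ("atoms", self.atom_table),
            ("residues", self.residue_table),
            ("chains", self.chain_table),
            ("types", self.type_stats),
        ):
            path = directory / f"{prefix}_{name}.csv"
            table.to_csv(path, index=False)
            written.append(path)
        return written

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "conversion_factor": self.conversion.value,
            "n_chains": self.conversion.n_chains,
            "map_sigma": self.map_stats.sigma,
            "type_stats": self.type_stats.to_dict(orient="records"),
            "atoms": json.loads(self.atom_table.to_json(orient="records")),
            "residues": json.loads(self.residue_table.to_json(orient="records")),
            "chains": json.loads(self.chain_table.to_json(orient="records")),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    def difference_analysis(self, fofc_map: DensityMap, n_sigma: float | None = None,
                            include_symmetry: bool = True):
        """Blob detection on the companion Fo-Fc map, in electrons."""
        from .blobs import analyze_difference_map

        cfg = self.model.config
        return analyze_difference_map(
            fofc_map,
            self.model.structure,
            self.conversion,
            n_sigma=n_sigma if n_sigma is not None else cfg.difference_threshold_sigma,
            connectivity=cfg.blob_connectivity,
            assign_cutoff=cfg.blob_assign_cutoff,
            include_symmetry=include_symmetry,
        )


def analyze_entry(
    structure: StructureModel,
    density_map: DensityMap,
    radii=None,
    slopes=None,
    config: AnalysisConfig | None = None,
) -> DensityScaleResults:
    """One-call orchestration: build the model and fit it."""
    return DensityScaleModel(structure, density_map, radii, slopes, config).fit()
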