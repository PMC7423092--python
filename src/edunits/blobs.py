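"""Difference-map discrepancies quantified as blobs of electrons.

A blob is a maximal connected set (26-neighbor connectivity by default) of
Fo-Fc voxels beyond the significance threshold, taken about zero because
deposited sigma-scaled maps are effectively zero-meaned.  Dividing a blob's
absolute density sum by the structure's conversion factor (the chain-median
density ratio from the companion 2Fo-Fc analysis) expresses the discrepancy
in electrons: positive blobs suggest unmodeled atoms, negative blobs
misplaced ones.

The module also provides the F000 estimate: the electron count of the full
unit cell divided by its volume, the constant offset omitted from
zero-meaned maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .analysis import ConversionFactor
from .ccp4 import DensityMap, MapStats, map_statistics
from .structure import AtomRecord, StructureModel, element_electrons
from .symmetry import expand_environment, operators_for_space_group


class MissingConversionError(ValueError):
    """Blob electron estimates need the 2Fo-Fc analysis to run first."""


@dataclass
class Blob:
    """One connected significant difference-density region."""

    sign: str  # "positive" | "negative"
    indices: np.ndarray
    total_density: float
    centroid: np.ndarray  # density-weighted, Cartesian Angstrom
    volume: float  # Angstrom^3
    electron_estimate: float = np.nan
    nearest_atom: str | None = None
    nearest_residue: str | None = None
    nearest_distance: float = np.nan


def significant_voxels(
    dmap: DensityMap, stats: MapStats, n_sigma: float = 3.0, sign: str = "positive"
) -> np.ndarray:
    """Boolean mask of voxels beyond ``n_sigma * sigma`` about zero."""
    if n_sigma <= 0:
        raise ValueError("n_sigma must be positive")
    if sign == "positive":
        return dmap.grid > n_sigma * stats.sigma
    if sign == "negative":
        return dmap.grid < -n_sigma * stats.sigma
    raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")


def find_blobs(
    dmap: DensityMap, mask: np.ndarray, sign: str, connectivity: int = 26
) -> list[Blob]:
    """Partition a significance mask into connected blobs.

    Blobs are sorted by decreasing absolute total density.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=int)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(mask, structure=structure)
    blobs: list[Blob] = []
    if n == 0:
        return blobs
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    boundaries = np.searchsorted(flat, np.arange(1, n + 2), side="left", sorter=order)
    all_idx = np.column_stack(np.unravel_index(order, labels.shape))
    for lab in range(1, n + 1):
        idx = all_idx[boundaries[lab - 1] : boundaries[lab]]
        values = dmap.values_at(idx)
        weights = np.abs(values)
        centers = dmap.crs_to_xyz(idx)
        centroid = (centers * weights[:, None]).sum(axis=0) / weights.sum()
        blobs.append(
            Blob(
                sign=sign,
                indices=idx,
                total_density=float(values.sum(dtype=np.float64)),
                centroid=centroid,
                volume=len(idx) * dmap.voxel_volume,
            )
        )
    blobs.sort(key=lambda b: -abs(b.total_density))
    return blobs


def blob_electrons(blob: Blob, conv: ConversionFactor) -> float:
    """Absolute electron content: |sum of blob density| / median(r_c)."""
    if conv is None or not np.isfinite(conv.value) or conv.value <= 0:
        raise MissingConversionError(
            "no valid conversion factor; run the 2Fo-Fc analysis first"
        )
    return abs(blob.total_density) / conv.value


def assign_blobs(
    blobs: list[Blob], atoms: list[AtomRecord], cutoff: float = 5.0
) -> list[Blob]:
    """Annotate each blob with its nearest model (or symmetry) atom."""
    if not atoms or not blobs:
        return blobs
    coords = np.array([a.xyz for a in atoms])
    tree = cKDTree(coords)
    centroids = np.array([b.centroid for b in blobs])
    dists, idx = tree.query(centroids, k=1)
    for blob, d, i in zip(blobs, dists, idx):
        if d <= cutoff:
            a = atoms[i]
            blob.nearest_atom = f"{a.chain_id}.{a.residue_seq}.{a.name}"
            blob.nearest_residue = f"{a.chain_id}.{a.residue_seq}.{a.residue_name}"
            blob.nearest_distance = float(d)
        else:
            blob.nearest_atom = None
            blob.nearest_residue = None
            blob.nearest_distance = float(d)
    return blobs


@dataclass
class BlobReport:
    """All significant blobs of one Fo-Fc map, annotated and in electrons."""

    blobs: list[Blob]
    n_sigma: float
    conversion: ConversionFactor

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            dict(
                blob_id=i,
                sign=b.sign,
                electrons=b.electron_estimate,
                volume=b.volume,
                centroid_x=b.centroid[0],
                centroid_y=b.centroid[1],
                centroid_z=b.centroid[2],
                nearest_residue=b.nearest_residue,
                distance=b.nearest_distance,
            )
            for i, b in enumerate(self.blobs)
        ]
        return pd.DataFrame(rows)

    def near_residue(
        self, chain_id: str, residue_seq: int, radius: float, model: StructureModel
    ) -> list[Blob]:
        """Region-of-interest query: blobs within ``radius`` of a residue."""
        coords = [
            a.xyz
            for a in model.atoms
            if a.chain_id == chain_id and a.residue_seq == residue_seq
        ]
        if not coords:
            return []
        tree = cKDTree(np.array(coords))
        return [
            b for b in self.blobs if tree.query(b.centroid, k=1)[0] <= radius
        ]


def analyze_difference_map(
    fofc_map: DensityMap,
    structure: StructureModel,
    conv: ConversionFactor,
    n_sigma: float = 3.0,
    connectivity: int = 26,
    assign_cutoff: float = 5.0,
    include_symmetry: bool = True,
) -> BlobReport:
    """Detect, quantify and assign positive and negative blobs."""
    stats = map_statistics(fofc_map)
    blobs: list[Blob] = []
    for sign in ("positive", "negative"):
        mask = significant_voxels(fofc_map, stats, n_sigma, sign)
        blobs.extend(find_blobs(fofc_map, mask, sign, connectivity))
    for blob in blobs:
        blob.electron_estimate = blob_electrons(blob, conv)
    atoms: list[AtomRecord] = list(structure.atoms)
    if include_symmetry and structure.cell is not None:
        try:
            ops = operators_for_space_group(
                symbol=structure.space_group, symmetry_text=fofc_map.symmetry_text
            )
            atoms = atoms + list(expand_environment(structure, ops, fofc_map))
        except Exception:
            pass  # fall back to model atoms only
    assign_blobs(blobs, atoms, assign_cutoff)
    blobs.sort(key=lambda b: -abs(b.total_density))
    return BlobReport(blobs=blobs, n_sigma=n_sigma, conversion=conv)


@dataclass
class F000Result:
    """Unit-cell electron count and the implied density offset."""

    electrons: float
    offset: float  # e / Angstrom^3
    n_operators: int


def f000_estimate(model: StructureModel, n_operators: int | None = None) -> F000Result:
    """Estimate F000 = total unit-cell electrons, and F000 / V in e/A^3.

    Sums occupancy-weighted electron counts over the asymmetric unit
    (hydrogen-folded counts for standard-residue atoms and waters,
    element-only for other hetero atoms) and multiplies by the space-group
    operator count.  Bulk solvent is deliberately not modelled.
    """
    if model.cell is None:
        raise ValueError("F000 estimate requires a unit cell")
    if n_operators is None:
        n_operators = len(operators_for_space_group(model.space_group))
    asu = sum(a.electrons * a.occupancy for a in model.atoms)
    asu += sum(element_electrons(a) * a.occupancy for a in model.waters)
    asu += sum(element_electrons(a) * a.occupancy for a in model.hetero)
    f000 = asu * n_operators
    return F000Result(
        electrons=float(f000),
        offset=float(f000 / model.cell.volume),
        n_operators=n_operators,
    )


def add_f000_offset(dmap: DensityMap, result: F000Result) -> DensityMap:
    """Return a copy of the map with the F000/V offset added to every voxel."""
    return replace(
        dmap,
        grid=dmap.grid + result.offset,
        _stats=None,
    )
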