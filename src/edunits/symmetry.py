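"""Crystallographic symmetry expansion of the structure model.

Density voxels near the borders of the deposited asymmetric unit can belong
to symmetry mates of the model; expanding the environment with the space
group's operators plus the 27 neighbor-cell translations makes sure every
voxel close to the map has its contributing atoms present.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .ccp4 import DensityMap
from .structure import StructureModel, TypedAtom


class UnknownSpaceGroupError(ValueError):
    """Hermann-Mauguin symbol not recognized and no header operators given."""


@dataclass(frozen=True)
class SymOp:
    """Fractional-basis symmetry operator x' = R x + t."""

    rot: tuple[tuple[float, ...], ...]
    tran: tuple[float, ...]

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot)

    @property
    def tran_array(self) -> np.ndarray:
        return np.array(self.tran)

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymOp":
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        return cls(tuple(map(tuple, rot)), tuple(tran))

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0)), (0.0, 0.0, 0.0))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.allclose(self.rot_array, np.eye(3), atol=tol)
            and np.allclose(self.tran_array, 0.0, atol=tol)
        )

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.rot_array.T + self.tran_array


def operators_for_space_group(
    symbol: str | None = None, symmetry_text: str | None = None
) -> list[SymOp]:
    """Symmetry operators from CCP4 header triplet text or an H-M symbol.

    Header records take precedence over the symbol when both are given; the
    identity operator is always included.
    """
    ops: list[SymOp] = []
    if symmetry_text and symmetry_text.strip():
        text = symmetry_text
        records = [text[i : i + 80] for i in range(0, len(text), 80)] if "\n" not in text else text.splitlines()
        for rec in records:
            rec = rec.strip().strip("\x00").strip()
            if not rec:
                continue
            ops.append(SymOp.from_gemmi(gemmi.Op(rec.lower())))
    elif symbol:
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise UnknownSpaceGroupError(f"unknown space group {symbol!r}")
        ops = [SymOp.from_gemmi(op) for op in sg.operations()]
    else:
        raise UnknownSpaceGroupError("no space-group symbol or symmetry records")
    if not any(op.is_identity() for op in ops):
        ops.insert(0, SymOp.identity())
    return ops


def operator_count(model: StructureModel) -> int:
    """Number of symmetry operators of the model's space group."""
    return len(operators_for_space_group(model.space_group))


def map_bounding_box(dmap: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian min/max corners of the stored map extent."""
    start = np.asarray(dmap.start, dtype=float)
    ext = np.asarray(dmap.extent, dtype=float)
    n = np.asarray(dmap.intervals, dtype=float)
    corners = []
    for bits in itertools.product((0.0, 1.0), repeat=3):
        frac = (start + np.asarray(bits) * ext) / n
        corners.append(dmap.cell.orthogonalize(frac))
    corners = np.array(corners)
    return corners.min(axis=0), corners.max(axis=0)


def expand_environment(
    model: StructureModel,
    ops: list[SymOp],
    dmap: DensityMap,
    buffer: float = 5.0,
    duplicate_tol: float = 1e-3,
) -> list[TypedAtom]:
    """Symmetry/translation images of model atoms near the map region.

    Applies every operator combined with the 27 neighbor-cell translations,
    keeps images within ``buffer`` Angstrom of the map's Cartesian bounding
    box, and drops images that coincide with an original atom (special
    positions).  Image atoms keep their source atom's type, electron count,
    occupancy and B-factor.
    """
    if model.cell is None:
        raise ValueError("model has no unit cell")
    if not model.atoms:
        return []
    cell = model.cell
    lo, hi = map_bounding_box(dmap)
    lo, hi = lo - buffer, hi + buffer
    coords = model.coordinates()
    frac = cell.fractionalize(coords)
    tree = cKDTree(coords)

    images: list[TypedAtom] = []
    for op in ops:
        base = op.apply(frac)
        for shift in itertools.product((-1.0, 0.0, 1.0), repeat=3):
            if op.is_identity() and shift == (0.0, 0.0, 0.0):
                continue
            cart = cell.orthogonalize(base + np.asarray(shift))
            keep = np.all((cart >= lo) & (cart <= hi), axis=1)
            if not keep.any():
                continue
            idx = np.nonzero(keep)[0]
            dists, _ = tree.query(cart[idx], k=1)
            for i, d in zip(idx, dists):
                if d <= duplicate_tol:
                    continue
                images.append(replace(model.atoms[i], xyz=cart[i].copy()))
    return images
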