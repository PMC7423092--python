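"""Crystallographic unit cell with fractional/Cartesian transforms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class UnitCell:
    """Unit cell defined by edge lengths (Angstrom) and angles (degrees).

    Provides the orthogonalization matrix (fractional -> Cartesian, PDB
    convention: a along x, b in the xy plane) and its inverse.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    _orth: np.ndarray = field(init=False, repr=False, compare=False)
    _frac: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0:
            raise ValueError("degenerate cell angles")
        v = self.a * self.b * self.c * np.sqrt(disc)
        orth = np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (self.a * self.b * sg)],
            ]
        )
        object.__setattr__(self, "_orth", orth)
        object.__setattr__(self, "_frac", np.linalg.inv(orth))

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self._orth))

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        return self._orth.copy()

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return self._frac.copy()

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> Cartesian; accepts (..., 3) arrays."""
        return np.asarray(frac, dtype=float) @ self._orth.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        """Cartesian -> fractional; accepts (..., 3) arrays."""
        return np.asarray(xyz, dtype=float) @ self._frac.T
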