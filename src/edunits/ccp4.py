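"""CCP4 electron density map reading, writing and voxel geometry.

The map is stored internally with its three array axes matching the
crystallographic x/y/z axes regardless of the axis permutation used in the
file, so downstream density code never deals with storage order.  Voxel
(i, j, k) of the array covers the grid cell starting at grid point
``start + (i, j, k)``; its *center* sits at fractional coordinate
``(start + index + 0.5) / intervals``, and distances from density voxels to
atoms are always measured from that center.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable

import numpy as np

from .cell import UnitCell

HEADER_BYTES = 1024
MAGIC_OFFSET = 208  # word 53, 0-based byte offset
MAP_MAGIC = b"MAP "


class CCP4FormatError(ValueError):
    """Stream is not a parsable CCP4 map."""


class UnsupportedModeError(CCP4FormatError):
    """Data mode other than 2 (32-bit float)."""


class TruncatedMapError(CCP4FormatError):
    """Data section shorter than the header promises."""


class OutOfExtentError(KeyError):
    """A requested voxel lies outside the stored map extent."""


@dataclass
class MapStats:
    """Whole-map statistics; sigma is the population standard deviation."""

    mean: float
    sigma: float
    min: float
    max: float


@dataclass
class DensityMap:
    """A 3D density grid in the crystallographic frame.

    grid[i, j, k] runs along crystallographic x, y, z.  ``start`` gives the
    grid index of the first stored voxel per axis and ``intervals`` the number
    of sampling intervals per full cell edge.
    """

    grid: np.ndarray
    start: tuple[int, int, int]
    intervals: tuple[int, int, int]
    cell: UnitCell
    space_group_number: int = 1
    symmetry_text: str = ""
    _stats: MapStats | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def extent(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        nx, ny, nz = self.intervals
        return self.cell.volume / (nx * ny * nz)

    def full_coverage(self) -> tuple[bool, bool, bool]:
        """Whether the stored extent spans at least one full cell per axis."""
        return tuple(e >= n for e, n in zip(self.extent, self.intervals))  # type: ignore[return-value]

    # -- coordinate transforms -------------------------------------------

    def crs_to_xyz(self, index: Iterable[int]) -> np.ndarray:
        """Cartesian coordinates of the voxel center(s) for storage indices."""
        idx = np.asarray(index, dtype=float)
        frac = (idx + np.asarray(self.start) + 0.5) / np.asarray(self.intervals, dtype=float)
        return self.cell.orthogonalize(frac)

    def xyz_to_crs(self, point: Iterable[float], wrap: bool = True) -> tuple[int, int, int]:
        """Storage index of the voxel whose cell contains ``point``.

        Wraps by whole unit-cell translations along axes with full coverage
        when ``wrap`` is true; raises :class:`OutOfExtentError` otherwise.
        """
        frac = self.cell.fractionalize(np.asarray(point, dtype=float))
        cell_idx = np.floor(frac * np.asarray(self.intervals)).astype(int)
        s = cell_idx - np.asarray(self.start)
        out = []
        for axis, (si, ext, n, full) in enumerate(
            zip(s, self.extent, self.intervals, self.full_coverage())
        ):
            if 0 <= si < ext:
                out.append(int(si))
            elif wrap and full:
                out.append(int(si % n))
            else:
                raise OutOfExtentError(f"axis {axis}: index {si} outside extent {ext}")
        return tuple(out)  # type: ignore[return-value]

    def values_at(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=int).reshape(-1, 3)
        return self.grid[idx[:, 0], idx[:, 1], idx[:, 2]]


def map_statistics(dmap: DensityMap) -> MapStats:
    """Mean, population sigma, min and max over all stored voxels."""
    g = dmap.grid
    if g.size == 0:
        raise ValueError("empty grid")
    if dmap._stats is None:
        dmap._stats = MapStats(
            mean=float(g.mean(dtype=np.float64)),
            sigma=float(g.std(dtype=np.float64)),
            min=float(g.min()),
            max=float(g.max()),
        )
    return dmap._stats


# -- binary I/O -----------------------------------------------------------


def _byte_order(header: bytes) -> str:
    stamp = header[212:216]  # word 54: machine stamp
    if stamp[:1] == b"\x11":
        return ">"
    return "<"  # 0x44 0x44 or anything else: little-endian fallback


def read_ccp4(stream: BinaryIO) -> DensityMap:
    """Read a mode-2 CCP4 map, normalizing axis order to x/y/z."""
    header = stream.read(HEADER_BYTES)
    if len(header) < HEADER_BYTES:
        raise CCP4FormatError("stream shorter than the 1024-byte CCP4 header")
    if header[MAGIC_OFFSET : MAGIC_OFFSET + 4] != MAP_MAGIC:
        raise CCP4FormatError("missing 'MAP ' magic word at header word 53")
    bo = _byte_order(header)
    ints = struct.unpack(bo + "10i", header[:40])
    nc, nr, ns, mode = ints[0], ints[1], ints[2], ints[3]
    ncstart, nrstart, nsstart = ints[4:7]
    nxyz = ints[7:10]
    cellpar = struct.unpack(bo + "6f", header[40:64])
    mapc, mapr, maps = struct.unpack(bo + "3i", header[64:76])
    ispg, nsymbt = struct.unpack(bo + "2i", header[88:96])
    if mode != 2:
        raise UnsupportedModeError(f"only mode 2 (32-bit float) is supported, got {mode}")
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise CCP4FormatError(f"invalid axis mapping {(mapc, mapr, maps)}")
    if min(nc, nr, ns) <= 0 or min(nxyz) <= 0:
        raise CCP4FormatError("non-positive grid dimensions")

    symtext = ""
    if nsymbt:
        raw = stream.read(nsymbt)
        if len(raw) < nsymbt:
            raise TruncatedMapError("symmetry text block truncated")
        symtext = raw.decode("ascii", errors="replace")

    n = nc * nr * ns
    raw = stream.read(4 * n)
    data = np.frombuffer(raw[: 4 * (len(raw) // 4)], dtype=np.dtype(bo + "f4"))
    if data.size < n:
        raise TruncatedMapError(f"expected {n} voxels, found {data.size}")
    data = data.reshape(ns, nr, nc)  # sections slowest, columns fastest

    # storage dimensions (sec, row, col) carry crystal axes (maps, mapr, mapc)
    dim_of_axis = {maps: 0, mapr: 1, mapc: 2}
    order = (dim_of_axis[1], dim_of_axis[2], dim_of_axis[3])
    grid = np.ascontiguousarray(np.transpose(data, order)).astype(np.float32)
    start_of = {mapc: ncstart, mapr: nrstart, maps: nsstart}
    start = (start_of[1], start_of[2], start_of[3])

    return DensityMap(
        grid=grid,
        start=start,
        intervals=tuple(nxyz),
        cell=UnitCell(*cellpar),
        space_group_number=ispg,
        symmetry_text=symtext,
    )


def write_ccp4(
    dmap: DensityMap, stream: BinaryIO, axis_order: tuple[int, int, int] = (1, 2, 3)
) -> None:
    """Write a mode-2 CCP4 map.

    ``axis_order`` is (mapc, mapr, maps): which crystal axis runs along
    columns, rows and sections in the file.  The default writes x fastest.
    """
    mapc, mapr, maps = axis_order
    if sorted(axis_order) != [1, 2, 3]:
        raise ValueError("axis_order must be a permutation of (1, 2, 3)")
    grid = np.asarray(dmap.grid, dtype="<f4")
    # data[s, r, c]: put crystal axis `maps` on dim 0, `mapr` on 1, `mapc` on 2
    data = np.transpose(grid, (maps - 1, mapr - 1, mapc - 1))
    ns, nr, nc = data.shape
    start = dmap.start
    stats = map_statistics(dmap)
    sym = dmap.symmetry_text.encode("ascii")
    if len(sym) % 80:
        sym += b" " * (80 - len(sym) % 80)

    header = bytearray(HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nc, nr, ns, 2,
                     start[mapc - 1], start[mapr - 1], start[maps - 1], *dmap.intervals)
    struct.pack_into("<6f", header, 40, *dmap.cell.parameters)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps)
    struct.pack_into("<3f", header, 76, stats.min, stats.max, stats.mean)
    struct.pack_into("<2i", header, 88, dmap.space_group_number, len(sym))
    header[MAGIC_OFFSET : MAGIC_OFFSET + 4] = MAP_MAGIC
    header[212:216] = b"\x44\x41\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, stats.sigma)
    struct.pack_into("<i", header, 220, 1)  # NLABL
    label = b"Written by edunits"
    header[224 : 224 + len(label)] = label

    stream.write(bytes(header))
    stream.write(sym)
    stream.write(np.ascontiguousarray(data).tobytes())


# -- voxel selection ------------------------------------------------------


def voxels_within_radius(
    dmap: DensityMap, center: Iterable[float], radius: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Voxels whose centers lie within ``radius`` Angstrom of ``center``.

    Returns ``(indices, distances, partial)``: storage indices (n, 3),
    matching center-to-point distances, and whether part of the sphere fell
    outside a not-fully-covered map axis (those voxels are skipped).
    Periodic images are included along axes that cover a full unit cell.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cell = dmap.cell
    if radius > min(cell.a, cell.b, cell.c) / 2:
        warnings.warn("radius exceeds half the shortest cell edge; wrap ambiguity")
    fc = cell.fractionalize(np.asarray(center, dtype=float))
    nvec = np.asarray(dmap.intervals, dtype=float)
    # conservative fractional half-widths from the fractionalization rows
    dfrac = radius * np.linalg.norm(cell.fractionalization_matrix, axis=1)
    lo = np.ceil((fc - dfrac) * nvec - 0.5).astype(int)
    hi = np.floor((fc + dfrac) * nvec - 0.5).astype(int)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    if any(a.size == 0 for a in axes):
        return np.empty((0, 3), dtype=int), np.empty(0), False
    ci, cj, ck = np.meshgrid(*axes, indexing="ij")
    cidx = np.column_stack([ci.ravel(), cj.ravel(), ck.ravel()])  # unwrapped cell indices
    centers = cell.orthogonalize((cidx + 0.5) / nvec)
    d = np.linalg.norm(centers - np.asarray(center, dtype=float), axis=1)
    keep = d <= radius
    cidx, d = cidx[keep], d[keep]

    s = cidx - np.asarray(dmap.start)
    partial = False
    mask = np.ones(len(s), dtype=bool)
    for axis, (ext, n, full) in enumerate(
        zip(dmap.extent, dmap.intervals, dmap.full_coverage())
    ):
        if full:
            s[:, axis] %= n
        else:
            inside = (s[:, axis] >= 0) & (s[:, axis] < ext)
            if not inside.all():
                partial = True
                mask &= inside
    s, d = s[mask], d[mask]
    if len(s):
        # wrapping can revisit a voxel: keep the closest image of each
        order = np.argsort(d, kind="stable")
        s, d = s[order], d[order]
        _, first = np.unique(s, axis=0, return_index=True)
        first.sort()
        s, d = s[first], d[first]
    return s, d, partial
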