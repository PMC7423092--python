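"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from edunits import DensityMap, FixtureSpec, UnitCell, make_entry, synth_structure


def make_map(grid, cell=None, start=(0, 0, 0), intervals=None, **kwargs) -> DensityMap:
    grid = np.asarray(grid, dtype=np.float32)
    if cell is None:
        cell = UnitCell(*(s * 1.0 for s in grid.shape), 90, 90, 90)
    if intervals is None:
        intervals = grid.shape
    return DensityMap(grid=grid, start=tuple(start), intervals=tuple(intervals),
                      cell=cell, **kwargs)


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def default_entry(default_spec):
    return make_entry(default_spec)


@pytest.fixture(scope="session")
def default_structure(default_spec):
    return synth_structure(default_spec)
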