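"""Analysis configuration with the method's default parameters."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Tunable parameters of the density analysis.

    Defaults are the method's standard values: significance at 1.5 sigma for
    model (2Fo-Fc) maps and 3 sigma for difference (Fo-Fc) maps, aggregation
    floors of 4 atoms per residue cloud and 50 per chain cloud, and the 0.05
    convergence tolerance on per-type median corrected chain deviation
    fractions.
    """

    density_threshold_sigma: float = 1.5
    difference_threshold_sigma: float = 3.0
    residue_min_atoms: int = 4
    chain_min_atoms: int = 50
    threshold_atom_sums: bool = True  # restrict Eq-1 sums to significant voxels
    symmetry_buffer: float = 5.0
    blob_connectivity: int = 26
    blob_assign_cutoff: float = 5.0
    optimization_tolerance: float = 0.05

    def save(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        cfg = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if not hasattr(cfg, key):
                raise ValueError(f"line {lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            else:
                setattr(cfg, key, float(value))
        return cfg
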