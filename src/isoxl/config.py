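"""Search/workflow configuration with the instrument-style defaults the
pipeline was designed around (Orbitrap precursor accuracy, ion-trap
fragment accuracy, tryptic digestion limits, BS3 reach)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .chem import ConfigurationError


@dataclass
class SearchConfig:
    precursor_tol_ppm: float = 3.0
    fragment_tol_da: float = 0.8
    snr_min: float = 2.0
    mass_min: float = 200.0
    mass_max: float = 5000.0
    missed_K: int = 3
    missed_R: int = 1
    max_mox: int = 2
    min_precursor_charge: int = 3
    max_fragment_charge: int = 2
    mz_min: float = 100.0
    mz_max: float = 2000.0
    pair_mass_tol_ppm: float = 5.0
    rt_tol_min: float = 0.5
    similarity_min: float = 0.6
    sas_cutoff: float = 35.0
    grid_spacing: float = 1.0
    probe_radius: float = 1.4
    fdr_target: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("precursor_tol_ppm", "fragment_tol_da", "snr_min",
                     "mass_min", "mass_max", "pair_mass_tol_ppm",
                     "rt_tol_min", "similarity_min", "sas_cutoff",
                     "grid_spacing", "probe_radius", "fdr_target"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    def as_items(self) -> list[tuple[str, object]]:
        return [(f.name, getattr(self, f.name))
                for f in dataclasses.fields(self)]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SearchConfig":
        """Flat ``key = value`` text; '#' starts a comment."""
        values: dict[str, object] = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(
                Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            caster = int if fields[key] == "int" else float
            values[key] = caster(val)
        values.update(overrides)
        return cls(**values)
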