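"""MS2 spectrum container and peak-list I/O (MGF, optional mzML).

Precursors are stored as neutral monoisotopic masses; MGF PEPMASS values
(m/z) are converted on read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .chem import InputError, mass_to_mz, mz_to_neutral_mass


@dataclass
class Spectrum:
    scan_id: str
    precursor_neutral_mass: float
    charge: int
    retention_time: float          # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise InputError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise InputError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def precursor_mz(self) -> float:
        return mass_to_mz(self.precursor_neutral_mass, self.charge)


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params["pepmass"][0]
            charge = int(params["charge"][0])
            rt_s = float(params.get("rtinseconds", 0.0))
            spectra.append(Spectrum(
                scan_id=str(params.get("title", f"scan_{len(spectra)}")),
                precursor_neutral_mass=mz_to_neutral_mass(pepmass, charge),
                charge=charge,
                retention_time=rt_s / 60.0,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
            ))
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write MGF with fixed numeric formatting (byte-stable output)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            fh.write(f"RTINSECONDS={s.retention_time * 60.0:.3f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read MS2 spectra from mzML behind the same Spectrum contract."""
    from pyteomics import mzml as _mzml

    spectra = []
    with _mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            mz0 = float(ion["selected ion m/z"])
            charge = int(ion.get("charge state", 2))
            rt = 0.0
            for sl in entry.get("scanList", {}).get("scan", []):
                if "scan start time" in sl:
                    rt = float(sl["scan start time"])
            spectra.append(Spectrum(
                scan_id=str(entry.get("id", f"scan_{len(spectra)}")),
                precursor_neutral_mass=mz_to_neutral_mass(mz0, charge),
                charge=charge,
                retention_time=rt,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
            ))
    return spectra
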