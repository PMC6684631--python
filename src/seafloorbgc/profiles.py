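"""Porewater concentration-depth profiles and their delimited-text dialect.

The on-disk format is a plain CSV with the columns

    depth_m, conc_mol_m3, porosity, temp_C, conc_sd_mol_m3

preceded by ``# key = value`` comment lines carrying the species name and
any provenance metadata. Depths are meters below seafloor, positive down,
zero at the sediment-water interface; concentrations are per volume of
porewater.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PorewaterProfile", "SPECIES"]

SPECIES = ("O2", "SO4", "DIC")

_COLUMNS = ["depth_m", "conc_mol_m3", "porosity", "temp_C", "conc_sd_mol_m3"]


@dataclass
class PorewaterProfile:
    """Depth-indexed porewater concentrations with porosity/temperature context.

    Attributes
    ----------
    species : str
        One of ``O2``, ``SO4``, ``DIC``.
    depth : ndarray
        Meters below seafloor, strictly increasing, >= 4 samples.
    conc : ndarray
        mol m^-3 of porewater, non-negative.
    porosity : ndarray
        Dimensionless, in (0, 1].
    temperature : ndarray
        deg C at each depth.
    conc_sd : ndarray
        Per-sample measurement SD, mol m^-3.
    """

    species: str
    depth: np.ndarray
    conc: np.ndarray
    porosity: np.ndarray
    temperature: np.ndarray
    conc_sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        self.depth = np.asarray(self.depth, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.porosity = np.asarray(self.porosity, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.conc_sd is None:
            self.conc_sd = np.zeros_like(self.conc)
        else:
            self.conc_sd = np.asarray(self.conc_sd, dtype=float)
        n = self.depth.size
        if n < 4:
            raise ValueError("profile needs at least 4 samples")
        for name, arr in (
            ("conc", self.conc),
            ("porosity", self.porosity),
            ("temperature", self.temperature),
            ("conc_sd", self.conc_sd),
        ):
            if arr.shape != self.depth.shape:
                raise ValueError(f"{name} shape does not match depth")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any((self.porosity <= 0) | (self.porosity > 1)):
            raise ValueError("porosity must lie in (0, 1]")
        if np.any(self.conc_sd < 0):
            raise ValueError("concentration SDs must be non-negative")

    def __len__(self) -> int:
        return self.depth.size

    def to_csv(self, path: str | Path) -> None:
        """Write the profile in the package CSV dialect."""
        path = Path(path)
        header_lines = [f"# species = {self.species}"]
        for key, value in self.metadata.items():
            header_lines.append(f"# {key} = {value}")
        frame = pd.DataFrame(
            {
                "depth_m": self.depth,
                "conc_mol_m3": self.conc,
                "porosity": self.porosity,
                "temp_C": self.temperature,
                "conc_sd_mol_m3": self.conc_sd,
            }
        )
        with path.open("w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            frame.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PorewaterProfile":
        """Read a profile written by :meth:`to_csv`."""
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"profile CSV missing columns: {missing}")
        species = meta.pop("species", None)
        if species is None:
            raise ValueError("profile CSV lacks a '# species = ...' header line")
        return cls(
            species=species,
            depth=frame["depth_m"].to_numpy(),
            conc=frame["conc_mol_m3"].to_numpy(),
            porosity=frame["porosity"].to_numpy(),
            temperature=frame["temp_C"].to_numpy(),
            conc_sd=frame["conc_sd_mol_m3"].to_numpy(),
            metadata=meta,
        )
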