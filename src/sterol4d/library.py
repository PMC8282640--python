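"""Sterol library containers and delimited-text I/O.

A library holds one row per (compound, adduct) with four-dimensional
reference values: precursor m/z, retention time (s), collision cross-section
(Å²) and a fragment spectrum.  The *standard* tier carries measured values
from authentic derivatized standards; the *extended* tier carries
machine-learning-predicted RT/CCS and rule-predicted spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import chem
from .spectra import Spectrum, read_spectra, write_spectra

__all__ = ["SterolCompound", "LibraryEntry", "SterolLibrary", "read_library", "write_library"]

STEROL_CLASSES = ("ST01", "ST02", "ST03", "ST04", "ST05")

LIBRARY_COLUMNS = [
    "name", "lm_id", "formula", "smiles", "n_oh", "class", "subclass",
    "adduct", "mz", "rt_s", "ccs_A2", "tier", "rt_source", "ccs_source",
    "spectrum_ref",
]


@dataclass(frozen=True)
class SterolCompound:
    """One sterol lipid: identity, structure and hydroxyl class."""

    name: str
    formula: str
    n_hydroxyl: int
    sterol_class: str = "ST01"
    subclass: str = ""
    lm_id: str = ""
    smiles: str = ""
    monoisotopic_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.monoisotopic_mass == 0.0 and self.formula:
            object.__setattr__(self, "monoisotopic_mass", chem.formula_mass(self.formula))
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: non-positive monoisotopic mass")
        if not 1 <= int(self.n_hydroxyl) <= 5:
            # library curation excludes sterols with no or >5 hydroxyls
            raise ValueError(
                f"{self.name}: hydroxyl count {self.n_hydroxyl} outside 1..5"
            )
        if self.sterol_class not in STEROL_CLASSES:
            raise ValueError(f"{self.name}: unknown sterol class {self.sterol_class!r}")


@dataclass(frozen=True)
class LibraryEntry:
    """One (compound, adduct) library row with 4-D reference values."""

    compound: SterolCompound
    adduct: str
    mz: float
    rt: float
    ccs: float
    spectrum: Spectrum | None = None
    tier: str = "standard"
    rt_source: str = "measured"
    ccs_source: str = "measured"
    primary: bool = True

    def __post_init__(self) -> None:
        if self.adduct not in chem.ADDUCT_SHIFTS:
            raise chem.UnknownAdductError(f"unsupported adduct {self.adduct!r}")
        if self.mz <= 0 or self.ccs <= 0:
            raise ValueError(f"{self.compound.name}: non-positive mz or ccs")
        if self.tier not in ("standard", "extended"):
            raise ValueError(f"{self.compound.name}: unknown tier {self.tier!r}")
        if self.tier == "standard" and (self.rt_source != "measured" or self.ccs_source != "measured"):
            raise ValueError(
                f"{self.compound.name}: standard-tier entries must carry measured RT and CCS"
            )

    @property
    def name(self) -> str:
        return self.compound.name

    def with_rt(self, rt: float) -> "LibraryEntry":
        return replace(self, rt=float(rt))


class SterolLibrary:
    """An ordered collection of :class:`LibraryEntry`."""

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries: list[LibraryEntry] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def tier(self) -> str:
        tiers = {e.tier for e in self.entries}
        return tiers.pop() if len(tiers) == 1 else "mixed"

    def map_rt(self, mapping) -> "SterolLibrary":
        """Apply an RT calibration mapping (callable seconds -> seconds)."""
        return SterolLibrary(e.with_rt(mapping(e.rt)) for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            c = e.compound
            rows.append({
                "name": c.name, "lm_id": c.lm_id, "formula": c.formula,
                "smiles": c.smiles, "n_oh": c.n_hydroxyl, "class": c.sterol_class,
                "subclass": c.subclass, "adduct": e.adduct,
                "mz": round(e.mz, 4), "rt_s": round(e.rt, 4), "ccs_A2": round(e.ccs, 4),
                "tier": e.tier, "rt_source": e.rt_source, "ccs_source": e.ccs_source,
                "spectrum_ref": c.name if e.spectrum is not None else "",
            })
        return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spectra: Mapping[str, Spectrum] | None = None) -> "SterolLibrary":
        missing = {"name", "formula", "n_oh", "adduct", "mz", "rt_s", "ccs_A2"} - set(df.columns)
        if missing:
            raise ValueError(f"library table missing required columns: {sorted(missing)}")

        def text(row, key, default=""):
            v = row.get(key, default)
            return default if pd.isna(v) or v == "" else str(v)

        entries = []
        for i, row in df.iterrows():
            try:
                comp = SterolCompound(
                    name=str(row["name"]), formula=str(row["formula"]),
                    n_hydroxyl=int(row["n_oh"]),
                    sterol_class=text(row, "class", "ST01"),
                    subclass=text(row, "subclass"),
                    lm_id=text(row, "lm_id"),
                    smiles=text(row, "smiles"),
                )
                ref = text(row, "spectrum_ref")
                spec = spectra.get(ref) if (spectra and ref) else None
                entries.append(LibraryEntry(
                    compound=comp, adduct=str(row["adduct"]),
                    mz=float(row["mz"]), rt=float(row["rt_s"]), ccs=float(row["ccs_A2"]),
                    spectrum=spec,
                    tier=text(row, "tier", "standard"),
                    rt_source=text(row, "rt_source", "measured"),
                    ccs_source=text(row, "ccs_source", "measured"),
                ))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"library row {i}: {exc}") from exc
        return cls(entries)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """CSV reader that accepts TSV by sniffing the header line."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_library(path: str | Path, spectra_path: str | Path | None = None) -> SterolLibrary:
    """Read a library table (CSV/TSV), joining spectra from an MSP/MGF file
    keyed by the ``spectrum_ref`` column."""
    df = _read_delimited(path)
    spectra = read_spectra(spectra_path) if spectra_path else None
    return SterolLibrary.from_frame(df, spectra)


def write_library(library: SterolLibrary, path: str | Path,
                  spectra_path: str | Path | None = None) -> None:
    library.to_frame().to_csv(path, index=False)
    if spectra_path is not None:
        spectra = {e.compound.name: e.spectrum for e in library if e.spectrum is not None}
        write_spectra(spectra, spectra_path)
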