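"""Aligned LC-IM-MS feature table: the feature-ID codec and readers.

Feature ids encode the rounded coordinate triple, e.g. ``M528T849C269`` is
the feature at m/z 528, RT 849 s, CCS 269 Å².
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .spectra import Spectrum, read_spectra

__all__ = ["Feature", "parse_feature_id", "format_feature_id", "read_features", "write_features"]

_FEATURE_ID = re.compile(r"M(\d+)T(\d+)C(\d+)$")

FEATURE_COLUMNS = ["feature_id", "mz", "rt_s", "ccs_A2"]


class FeatureIdError(ValueError):
    """Malformed feature id; carries the position where parsing failed."""

    def __init__(self, text: str, position: int):
        self.position = position
        super().__init__(f"malformed feature id {text!r} at position {position}")


def parse_feature_id(text: str) -> tuple[int, int, int]:
    """Parse ``M<mz>T<rt>C<ccs>`` into the rounded integer triple."""
    m = _FEATURE_ID.fullmatch(text or "")
    if m is None:
        raise FeatureIdError(text, _fail_position(text or ""))
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def _fail_position(text: str) -> int:
    """First index at which ``text`` stops being a prefix of M<int>T<int>C<int>."""
    i, n = 0, len(text)
    for letter in "MTC":
        if i >= n or text[i] != letter:
            return i
        i += 1
        if i >= n or not text[i].isdigit():
            return i
        while i < n and text[i].isdigit():
            i += 1
    return i  # trailing junk after a well-formed prefix


def _round_half_up(x: float) -> int:
    return int(math.floor(float(x) + 0.5))


def format_feature_id(mz: float, rt: float, ccs: float) -> str:
    """Format the rounded (half-up) coordinate triple as ``M..T..C..``."""
    return f"M{_round_half_up(mz)}T{_round_half_up(rt)}C{_round_half_up(ccs)}"


@dataclass(frozen=True)
class Feature:
    """One aligned LC-IM-MS observation."""

    feature_id: str
    mz: float
    rt: float
    ccs: float
    spectrum: Spectrum | None = None
    abundance: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_coordinates(cls, mz: float, rt: float, ccs: float, **kw) -> "Feature":
        return cls(format_feature_id(mz, rt, ccs), float(mz), float(rt), float(ccs), **kw)


def read_features(path: str | Path, spectra_path: str | Path | None = None) -> list[Feature]:
    """Read a feature table (CSV/TSV with header ``feature_id, mz, rt_s,
    ccs_A2`` plus per-sample abundance columns), joining spectra by
    feature id.  Malformed numeric cells abort with the offending line
    number."""
    from .library import _read_delimited

    df = _read_delimited(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing required columns: {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in FEATURE_COLUMNS]
    spectra = read_spectra(spectra_path) if spectra_path else {}
    feats = []
    for i, row in df.iterrows():
        try:
            mz, rt, ccs = float(row["mz"]), float(row["rt_s"]), float(row["ccs_A2"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"feature table line {i + 2}: non-numeric coordinate ({exc})") from exc
        fid = str(row["feature_id"])
        abundance = {c: float(row[c]) for c in sample_cols if pd.notna(row[c])}
        feats.append(Feature(fid, mz, rt, ccs, spectrum=spectra.get(fid), abundance=abundance))
    return feats


def write_features(features: list[Feature], path: str | Path) -> None:
    sample_cols = sorted({k for f in features for k in f.abundance})
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": round(f.mz, 4), "rt_s": f.rt, "ccs_A2": f.ccs}
        row.update({c: f.abundance.get(c) for c in sample_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=FEATURE_COLUMNS + sample_cols).to_csv(path, index=False)
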