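"""Fragment spectrum container and MSP/MGF round-trip via matchms."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["Spectrum", "read_spectra", "write_spectra"]


@dataclass(frozen=True)
class Spectrum:
    """A centroided fragment spectrum.

    Peaks are canonicalized to strictly increasing m/z (exact-duplicate m/z
    values are merged by intensity sum); intensities must be non-negative.
    ``annotations`` optionally labels each peak (e.g. ``"skeleton"`` /
    ``"derivate"`` for rule-predicted spectra).
    """

    mz: np.ndarray
    intensities: np.ndarray
    annotations: tuple[str, ...] | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        ann = self.annotations
        if ann is not None and len(ann) != len(mz):
            raise ValueError("annotations length mismatch")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if ann is not None:
            ann = tuple(ann[i] for i in order)
        # merge exact duplicates
        if len(mz) > 1 and np.any(np.diff(mz) == 0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, inten)
            if ann is not None:
                keep: dict[int, str] = {}
                for i, a in zip(inverse, ann):
                    keep.setdefault(int(i), a)
                ann = tuple(keep[i] for i in range(len(uniq)))
            mz, inten = uniq, summed
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "annotations", ann)

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def is_empty(self) -> bool:
        return len(self.mz) == 0 or float(self.intensities.max(initial=0.0)) == 0.0

    def normalized(self) -> "Spectrum":
        """Base-peak-100 normalized copy (library convention)."""
        if self.is_empty:
            return self
        scale = 100.0 / float(self.intensities.max())
        return Spectrum(self.mz, self.intensities * scale, self.annotations, dict(self.metadata))

    def peak_role(self, role: str) -> np.ndarray:
        """m/z values of peaks annotated with ``role``."""
        if self.annotations is None:
            return np.empty(0)
        mask = np.array([a == role for a in self.annotations])
        return self.mz[mask]

    @classmethod
    def from_peaks(cls, peaks: Iterable[tuple[float, float]], **kw) -> "Spectrum":
        pairs = list(peaks)
        mz = np.array([p[0] for p in pairs], dtype=float)
        inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(mz, inten, **kw)


def _to_matchms(spec: Spectrum, key: str):
    from matchms import Spectrum as MmsSpectrum

    meta = {str(k).lower(): v for k, v in spec.metadata.items()}
    meta.setdefault("compound_name", key)
    meta.setdefault("title", key)
    if spec.annotations is not None:
        meta.setdefault("peak_annotations", ";".join(spec.annotations))
    return MmsSpectrum(
        mz=np.asarray(spec.mz, dtype=float),
        intensities=np.asarray(spec.intensities, dtype=float),
        metadata=meta,
        metadata_harmonization=False,
    )


def _from_matchms(mms) -> tuple[str, Spectrum]:
    meta = dict(mms.metadata)
    key = meta.get("compound_name") or meta.get("title") or meta.get("name") or ""
    ann_raw = meta.get("peak_annotations")
    ann = tuple(ann_raw.split(";")) if ann_raw else None
    spec = Spectrum(np.asarray(mms.peaks.mz, dtype=float),
                    np.asarray(mms.peaks.intensities, dtype=float),
                    annotations=ann if ann and len(ann) == len(mms.peaks.mz) else None,
                    metadata={str(k): str(v) for k, v in meta.items()})
    return str(key), spec


def read_spectra(path: str | Path) -> dict[str, Spectrum]:
    """Read an MSP or MGF file into ``{key: Spectrum}``; keys come from the
    compound name / title field (feature ids or library names)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".msp":
        from matchms.importing import load_from_msp

        loader = load_from_msp(str(path), metadata_harmonization=False)
    elif suffix == ".mgf":
        from matchms.importing import load_from_mgf

        loader = load_from_mgf(str(path), metadata_harmonization=False)
    else:
        raise ValueError(f"unsupported spectra format {suffix!r} (use .msp or .mgf)")
    out: dict[str, Spectrum] = {}
    for mms in loader:
        if mms is None:
            continue
        key, spec = _from_matchms(mms)
        out[key] = spec
    return out


def write_spectra(spectra: Mapping[str, Spectrum], path: str | Path) -> None:
    """Write spectra to MSP or MGF (format chosen by extension)."""
    path = Path(path)
    mms_list = [_to_matchms(s, k) for k, s in spectra.items()]
    if path.exists():
        path.unlink()  # matchms appends
    if path.suffix.lower() == ".msp":
        from matchms.exporting import save_as_msp

        save_as_msp(mms_list, str(path), mode="w")
    elif path.suffix.lower() == ".mgf":
        from matchms.exporting import save_as_mgf

        save_as_mgf(mms_list, str(path))
    else:
        raise ValueError(f"unsupported spectra format {path.suffix!r}")
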