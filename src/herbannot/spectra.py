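"""Spectrum data model, MGF peak-list I/O and the tabular annotation report.

MGF is the exchange format (vendor raw / mzML conversion is out of scope).
Retention times are minutes everywhere inside the package; the MGF field
RTINSECONDS is converted at the boundary.  Polarity is inferred from the
CHARGE sign and defaults to negative, the primary acquisition mode for
saponin-rich extracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Peak",
    "Spectrum",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "write_annotation_table",
    "ANNOTATION_COLUMNS",
]


class MgfError(ValueError):
    """Malformed MGF content."""


class Peak(NamedTuple):
    mz: float
    intensity: float


def _normalize_peaks(peaks: Iterable[tuple[float, float]]) -> tuple[Peak, ...]:
    """Sort by m/z and merge coincident peaks so m/z is strictly ascending."""
    merged: dict[float, float] = {}
    for mz, inten in peaks:
        mz = float(mz)
        inten = float(inten)
        if not (np.isfinite(mz) and np.isfinite(inten)):
            raise MgfError(f"non-finite peak ({mz}, {inten})")
        if mz <= 0 or inten < 0:
            raise MgfError(f"invalid peak ({mz}, {inten})")
        merged[mz] = merged.get(mz, 0.0) + inten
    return tuple(Peak(mz, merged[mz]) for mz in sorted(merged))


@dataclass(frozen=True)
class Spectrum:
    """A product-ion spectrum: precursor, polarity, retention time and peaks."""

    spectrum_id: str
    polarity: str  # "negative" | "positive"
    precursor_mz: float
    retention_time: float  # minutes
    peaks: tuple[Peak, ...] = field(default_factory=tuple)
    ccs: float | None = None  # ion-mobility pass-through, never computed here
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity must be negative|positive, got {self.polarity!r}")
        object.__setattr__(self, "peaks", _normalize_peaks(self.peaks))

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read every BEGIN IONS/END IONS block of an MGF file.

    PEPMASS -> precursor m/z (second value, when present, -> precursor
    intensity); RTINSECONDS -> retention time in minutes; the CHARGE sign ->
    polarity (negative default when absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for i, block in enumerate(reader):
                params = block["params"]
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise MgfError(f"block {i}: missing PEPMASS")
                pepmass = params["pepmass"]
                polarity = "negative"
                charge = params.get("charge")
                if charge:
                    polarity = "negative" if int(charge[0]) < 0 else "positive"
                rt_s = float(params.get("rtinseconds", 0.0))
                spectra.append(
                    Spectrum(
                        spectrum_id=str(params.get("title", f"spectrum_{i}")),
                        polarity=polarity,
                        precursor_mz=float(pepmass[0]),
                        retention_time=rt_s / 60.0,
                        peaks=tuple(
                            zip(block["m/z array"], block["intensity array"])
                        ),
                        precursor_intensity=(
                            float(pepmass[1])
                            if len(pepmass) > 1 and pepmass[1] is not None
                            else None
                        ),
                    )
                )
    except MgfError:
        raise
    except Exception as exc:
        raise MgfError(f"cannot parse MGF {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; inverse of :func:`read_mgf` at 1e-4 m/z."""
    entries = []
    for s in spectra:
        params: dict[str, object] = {
            "title": s.spectrum_id,
            "pepmass": (
                s.precursor_mz
                if s.precursor_intensity is None
                else (s.precursor_mz, s.precursor_intensity)
            ),
            "rtinseconds": s.retention_time * 60.0,
            "charge": "1-" if s.polarity == "negative" else "1+",
        }
        if s.ccs is not None:
            params["ccs"] = s.ccs
        entries.append(
            {
                "params": params,
                "m/z array": s.mz_array,
                "intensity array": s.intensity_array,
            }
        )
    _mgf.write(entries, str(Path(path)), file_mode="w")


#: column order of the annotation report
ANNOTATION_COLUMNS = (
    "spectrum_id",
    "rt_min",
    "precursor_mz",
    "adduct",
    "formula",
    "neutral_mass",
    "compound_class",
    "subclass",
    "candidate_names",
    "confidence",
    "ppm_error",
    "matched_fragments",
)


def write_annotation_table(results, path: str | Path) -> None:
    """Write one tab-separated row per annotated spectrum (m/z at 4 dp).

    ``results`` is a sequence of ``annotate.AnnotationResult``; an empty
    sequence produces a header-only file.
    """
    rows = [r.to_row() for r in results]
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    for col in ("precursor_mz", "neutral_mass"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) or v == "" else f"{float(v):.4f}")
    df["rt_min"] = df["rt_min"].map(lambda v: "" if v == "" else f"{float(v):.2f}")
    df["ppm_error"] = df["ppm_error"].map(lambda v: "" if v == "" else f"{float(v):.2f}")
    df.to_csv(path, sep="\t", index=False)
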