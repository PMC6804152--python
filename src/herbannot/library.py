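"""Compound-library data model, CSV/JSON I/O and adduct-aware accurate-mass queries.

A library row records what the annotation rules need: the molecular formula,
the compound class (closed vocabulary), the sapogenin core for saponins, the
glycan composition as a multiset of sugar residues, and acyl substituents.
Isomers (same formula, different name) are distinct records and queries never
collapse them.  All pentoses are stored as the generic ``Pen`` residue (the
132.04 Da neutral loss cannot distinguish xylose from arabinose).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem

__all__ = [
    "COMPOUND_CLASSES",
    "SOURCE_HERBS",
    "SAPOGENIN_FORMULAS",
    "LibraryError",
    "CompoundRecord",
    "CompoundLibrary",
    "load_library",
    "save_library",
    "builtin_fixture_library",
]

COMPOUND_CLASSES = (
    "ginsenoside",
    "astragaloside",
    "phenolic_acid",
    "tanshinone",
    "flavonoid",
    "iridoid",
    "phenylpropanoid",
    "other",
)

#: the four component herbs of the formula under study
SOURCE_HERBS = ("NRR", "SMRR", "AR", "SR", "unknown")

#: sapogenin label -> neutral formula of the aglycone core
SAPOGENIN_FORMULAS = {
    "PPT": "C30H52O4",            # protopanaxatriol
    "PPD": "C30H52O3",            # protopanaxadiol
    "OA": "C30H48O3",             # oleanolic acid
    "OT": "C30H52O4",             # octillol-type (isomeric with PPT)
    "cycloastragenol": "C30H50O5",
    "soyasapogenol": "C30H50O3",  # soyasapogenol B
}

_REQUIRED_COLUMNS = ("id", "name", "formula", "compound_class")

_CSV_COLUMNS = (
    "id", "name", "formula", "compound_class", "subclass", "sapogenin",
    "source_herb", "sugar_composition", "acyl", "expected_rt",
    "reference_standard",
)


class LibraryError(ValueError):
    """Schema or content error in a compound library."""


def _parse_multiset(text: str) -> dict[str, int]:
    """Parse ``"Glc:2;Pen:1"`` into a multiset dict."""
    out: dict[str, int] = {}
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        name, _, count = token.partition(":")
        out[name.strip()] = int(count) if count else 1
    return out


def _format_multiset(ms: dict[str, int] | None) -> str:
    if not ms:
        return ""
    return ";".join(f"{k}:{v}" for k, v in sorted(ms.items()))


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry; validated on construction."""

    id: str
    name: str
    formula: str
    compound_class: str
    subclass: str = ""
    sapogenin: str = ""
    source_herb: str = "unknown"
    sugar_composition: dict[str, int] | None = None
    acyl: dict[str, int] | None = None
    expected_rt: float | None = None
    reference_standard: bool = False
    ccs: float | None = None  # pass-through only
    neutral_mass: float = field(init=False)

    def __post_init__(self) -> None:
        counts = chem.parse_formula(self.formula)  # raises on bad formula
        object.__setattr__(self, "formula", chem.format_formula(counts))
        object.__setattr__(self, "neutral_mass", chem.monoisotopic_mass(counts))
        if self.compound_class not in COMPOUND_CLASSES:
            raise LibraryError(
                f"record {self.id!r}: unknown class {self.compound_class!r}; "
                f"expected one of {COMPOUND_CLASSES}"
            )
        if self.source_herb not in SOURCE_HERBS:
            raise LibraryError(
                f"record {self.id!r}: unknown source herb {self.source_herb!r}"
            )
        if self.sapogenin and self.sapogenin not in SAPOGENIN_FORMULAS:
            raise LibraryError(
                f"record {self.id!r}: unknown sapogenin {self.sapogenin!r}"
            )
        self._check_mass_consistency()

    def _check_mass_consistency(self) -> None:
        """Sapogenin + glycosyl residues + acyls must reconcile with the formula.

        Only checked when both a sapogenin core and a sugar composition are
        given; 1e-3 Da tolerance.
        """
        if not (self.sapogenin and self.sugar_composition):
            return
        mass = chem.formula_mass(SAPOGENIN_FORMULAS[self.sapogenin])
        for sugar, n in self.sugar_composition.items():
            mass += n * chem.get_loss(sugar).mass
        for acyl_name, n in (self.acyl or {}).items():
            mass += n * chem.get_loss(acyl_name).mass
        if abs(mass - self.neutral_mass) > 1e-3:
            raise LibraryError(
                f"record {self.id!r}: sapogenin+glycan mass {mass:.4f} does not "
                f"reconcile with formula mass {self.neutral_mass:.4f}"
            )

    def to_row(self) -> dict[str, object]:
        return {
            "id": self.id,
            "name": self.name,
            "formula": self.formula,
            "compound_class": self.compound_class,
            "subclass": self.subclass,
            "sapogenin": self.sapogenin,
            "source_herb": self.source_herb,
            "sugar_composition": _format_multiset(self.sugar_composition),
            "acyl": _format_multiset(self.acyl),
            "expected_rt": "" if self.expected_rt is None else self.expected_rt,
            "reference_standard": bool(self.reference_standard),
        }


class CompoundLibrary:
    """Ordered collection of records with a sorted neutral-mass index."""

    def __init__(self, records: list[CompoundRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryError(f"duplicate record ids: {dupes}")
        self.records: list[CompoundRecord] = list(records)
        self._by_id = {r.id: r for r in self.records}
        order = np.argsort([r.neutral_mass for r in self.records], kind="stable")
        self._sorted_masses = np.array(
            [self.records[i].neutral_mass for i in order], dtype=float
        )
        self._sorted_records = [self.records[i] for i in order]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> CompoundRecord:
        return self._by_id[record_id]

    def by_name(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def query_by_neutral_mass(
        self,
        mass: float,
        tolerance_ppm: float = 10.0,
        class_filter: str | None = None,
    ) -> list[CompoundRecord]:
        """Records whose neutral mass lies within a closed ppm window of ``mass``.

        Sorted by absolute ppm error, ties broken by lexicographic id.
        """
        if tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")
        half = mass * tolerance_ppm * 1e-6
        lo = np.searchsorted(self._sorted_masses, mass - half, side="left")
        hi = np.searchsorted(self._sorted_masses, mass + half, side="right")
        hits = [
            r
            for r in self._sorted_records[lo:hi]
            if abs(chem.ppm_error(mass, r.neutral_mass)) <= tolerance_ppm
            and (class_filter is None or r.compound_class == class_filter)
        ]
        hits.sort(key=lambda r: (abs(chem.ppm_error(mass, r.neutral_mass)), r.id))
        return hits


def _record_from_row(row: dict[str, object], row_number: int) -> CompoundRecord:
    def _opt(key: str) -> str:
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return ""
        return str(v).strip()

    try:
        rt_text = _opt("expected_rt")
        ref_text = _opt("reference_standard").lower()
        sugars = _parse_multiset(_opt("sugar_composition")) or None
        acyl = _parse_multiset(_opt("acyl")) or None
        return CompoundRecord(
            id=str(row["id"]).strip(),
            name=str(row["name"]).strip(),
            formula=str(row["formula"]).strip(),
            compound_class=_opt("compound_class"),
            subclass=_opt("subclass"),
            sapogenin=_opt("sapogenin"),
            source_herb=_opt("source_herb") or "unknown",
            sugar_composition=sugars,
            acyl=acyl,
            expected_rt=float(rt_text) if rt_text else None,
            reference_standard=ref_text in ("true", "1", "yes"),
        )
    except (chem.FormulaError, LibraryError, ValueError) as exc:
        raise LibraryError(f"row {row_number}: {exc}") from exc


def load_library(path: str | Path) -> CompoundLibrary:
    """Load a compound library from CSV or JSON (by file extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise LibraryError("JSON library must be a list of records")
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise LibraryError(f"missing required columns: {missing}")
        rows = df.to_dict(orient="records")
    missing = [c for c in _REQUIRED_COLUMNS if rows and c not in rows[0]]
    if missing:
        raise LibraryError(f"missing required columns: {missing}")
    records = [_record_from_row(row, i + 1) for i, row in enumerate(rows)]
    return CompoundLibrary(records)


def save_library(library: CompoundLibrary, path: str | Path) -> None:
    """Write a library back to CSV or JSON; round-trips field-for-field."""
    path = Path(path)
    rows = [r.to_row() for r in library]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def builtin_fixture_library() -> CompoundLibrary:
    """The packaged library of compounds with published names and formulas.

    Covers every compound class (ginsenosides of PPT/PPD/OA/malonyl subtypes,
    astragalosides, a soyasaponin, salvianolic acids, tanshinones,
    isoflavones, iridoid glycosides and phenylpropanoids) from the four
    component herbs.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("herbannot.data").joinpath("fixture_library.csv")
    ) as p:
        return load_library(p)


def with_expected_rt(record: CompoundRecord, rt: float) -> CompoundRecord:
    """Copy of ``record`` with a new expected retention time (minutes)."""
    return replace(record, expected_rt=rt)
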