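"""Molecular-formula arithmetic, adducts, ppm tolerances and the neutral-loss vocabulary.

Everything downstream (library search, ladder inference, spectrum simulation)
reduces to monoisotopic mass arithmetic performed here.  Masses are
most-abundant-isotope monoisotopic masses (C = 12 exactly, H ~ 1.007825,
O ~ 15.994915); the electron mass is included in charged-species arithmetic,
so the [M-H]- delta is -1.007276 Da rather than -1.007825 Da.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

from pyteomics import mass as _pmass

__all__ = [
    "ELECTRON_MASS",
    "ATOMIC_MASSES",
    "FormulaError",
    "UnsupportedElementError",
    "AdductError",
    "AdductSpec",
    "NeutralLoss",
    "ADDUCTS",
    "NEUTRAL_LOSSES",
    "parse_formula",
    "format_formula",
    "combine_counts",
    "subtract_counts",
    "monoisotopic_mass",
    "formula_mass",
    "mz_from_adduct",
    "neutral_mass_from_mz",
    "ppm_error",
    "within_ppm",
    "adducts_for_polarity",
    "get_adduct",
    "get_loss",
    "losses_by_role",
]

ELECTRON_MASS = 0.000548579909

# Supported element set; strict Hill-notation grammar, no isotopes/charges/parens.
_SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "Cl", "Na", "P", "K")

#: element symbol -> monoisotopic mass of the most abundant isotope (Da)
ATOMIC_MASSES: dict[str, float] = {
    el: _pmass.nist_mass[el][0][0] for el in _SUPPORTED_ELEMENTS
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed molecular-formula string."""


class UnsupportedElementError(FormulaError):
    """Formula contains an element outside the supported set."""


class AdductError(KeyError):
    """Unknown adduct name."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a strict Hill-notation formula (e.g. ``"C47H80O18"``) into counts.

    Raises :class:`FormulaError` naming the offending position for malformed
    tokens and :class:`UnsupportedElementError` for unknown elements.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula string")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected token at position {pos}"
            )
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASSES:
            raise UnsupportedElementError(
                f"unsupported element {el!r} at position {pos} in {formula!r}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(
                f"zero count for element {el!r} at position {pos} in {formula!r}"
            )
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if not counts:
        raise FormulaError(f"formula {formula!r} contains no elements")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Serialize element counts in Hill order (C, H, then alphabetical).

    Formulas without carbon are written fully alphabetically, so
    ``parse -> format`` is idempotent on Hill-notation input.
    """
    counts = {el: n for el, n in counts.items() if n}
    if not counts:
        raise FormulaError("cannot format an empty composition")
    if any(n < 0 for n in counts.values()):
        raise FormulaError("negative element count")
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else []) + sorted(
            el for el in counts if el not in ("C", "H")
        )
    else:
        order = sorted(counts)
    return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order)


def combine_counts(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + n
    return out


def subtract_counts(a: dict[str, int], b: dict[str, int]) -> dict[str, int] | None:
    """``a - b`` elementwise, or None if any count would go negative."""
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) - n
        if out[el] < 0:
            return None
        if out[el] == 0:
            del out[el]
    return out or None


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a composition in Da."""
    if not counts:
        raise FormulaError("empty composition has no mass")
    try:
        return sum(ATOMIC_MASSES[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise UnsupportedElementError(f"unsupported element {exc.args[0]!r}") from exc


def formula_mass(formula: str) -> float:
    return monoisotopic_mass(parse_formula(formula))


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: m/z = (M + delta) / charge.

    ``delta`` is signed and includes the electron mass, e.g. -1.007276 Da
    for [M-H]-.
    """

    name: str
    polarity: str  # "negative" | "positive"
    delta: float
    charge: int = 1

    def mz(self, neutral_mass: float) -> float:
        return (neutral_mass + self.delta) / self.charge

    def neutral_mass(self, mz: float) -> float:
        return mz * self.charge - self.delta


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral loss (sugar residue, acyl, small molecule...)."""

    name: str
    formula: str
    mass: float
    role: str  # sugar | acyl | small | side-chain | acid-unit


def _load_adducts() -> dict[str, AdductSpec]:
    text = resources.files("herbannot.data").joinpath("adducts.json").read_text()
    registry: dict[str, AdductSpec] = {}
    for row in json.loads(text):
        delta = row["electrons"] * ELECTRON_MASS
        if row["gain"]:
            delta += formula_mass(row["gain"])
        if row["loss"]:
            delta -= formula_mass(row["loss"])
        spec = AdductSpec(row["name"], row["polarity"], delta, row["charge"])
        registry[spec.name] = spec
    return registry


def _load_losses() -> dict[str, NeutralLoss]:
    text = resources.files("herbannot.data").joinpath("losses.json").read_text()
    registry: dict[str, NeutralLoss] = {}
    for row in json.loads(text):
        if row["name"] in registry:
            raise ValueError(f"duplicate neutral-loss name {row['name']!r}")
        registry[row["name"]] = NeutralLoss(
            row["name"], row["formula"], formula_mass(row["formula"]), row["role"]
        )
    return registry


#: adduct name -> AdductSpec; exactly the negative (+HCOO, -H, +CH3COO, +Cl, +e)
#: and positive (+H, +Na, -e) single-charge adducts used for library search.
ADDUCTS: dict[str, AdductSpec] = _load_adducts()

#: loss name -> NeutralLoss (sugar residues, acyls, small molecules, acid units).
NEUTRAL_LOSSES: dict[str, NeutralLoss] = _load_losses()


def get_adduct(name: str) -> AdductSpec:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise AdductError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}") from None


def adducts_for_polarity(polarity: str) -> list[AdductSpec]:
    return [a for a in ADDUCTS.values() if a.polarity == polarity]


def get_loss(name: str) -> NeutralLoss:
    return NEUTRAL_LOSSES[name]


def losses_by_role(*roles: str) -> list[NeutralLoss]:
    return [l for l in NEUTRAL_LOSSES.values() if l.role in roles]


def mz_from_adduct(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of ``adduct`` formed from a neutral of mass ``neutral_mass`` (Da)."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    spec = get_adduct(adduct) if isinstance(adduct, str) else adduct
    return spec.mz(neutral_mass)


def neutral_mass_from_mz(mz: float, adduct: str | AdductSpec) -> float:
    """Exact inverse of :func:`mz_from_adduct`."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    spec = get_adduct(adduct) if isinstance(adduct, str) else adduct
    return spec.neutral_mass(mz)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def within_ppm(observed: float, theoretical: float, tolerance_ppm: float) -> bool:
    """Closed-interval ppm window test."""
    return abs(ppm_error(observed, theoretical)) <= tolerance_ppm


def deprotonated_mz(formula: str) -> float:
    """[M-H]- m/z for a neutral formula; the negative-mode workhorse."""
    return mz_from_adduct(formula_mass(formula), "[M-H]-")


def protonated_mz(formula: str) -> float:
    """[M+H]+ m/z for a neutral formula."""
    return mz_from_adduct(formula_mass(formula), "[M+H]+")
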