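"""Rule-based annotation of product-ion spectra from multi-herb extracts.

The characterization logic mirrors how saponin-rich tandem-MS data are read
by hand: hypothesize an adduct against the accurate-mass library, walk the
glycosidic neutral-loss ladder (successive eliminations of sugar residues),
call the sapogenin class from diagnostic aglycone ions, detect malonyl/acetyl
substitution, infer the glycan composition from the best ladder, and score
each library candidate by the fraction of its theoretical fragments observed.

Negative mode carries the saponin logic (deprotonated sapogenin ions);
positive mode covers tanshinones and flavonoids via class-specific losses
(CH3 radical, CH4, CH3OH, CO, H2O).  Diagnostic ions are matched at an
absolute +-0.02 Da tolerance, ladder fragments at ppm tolerance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import chem
from .chem import formula_mass, get_loss, mz_from_adduct, neutral_mass_from_mz, ppm_error
from .library import CompoundLibrary, CompoundRecord
from .spectra import Spectrum

__all__ = [
    "AnnotationConfig",
    "LossPath",
    "SapogeninCall",
    "GlycanInference",
    "Candidate",
    "AnnotationResult",
    "DIAGNOSTIC_IONS",
    "loss_vocabulary",
    "hypothesize_adducts",
    "find_loss_paths",
    "classify_sapogenin",
    "detect_malonyl",
    "infer_glycan_composition",
    "theoretical_fragments",
    "score_candidate",
    "annotate_spectrum",
    "summarize_classes",
]


@dataclass(frozen=True)
class AnnotationConfig:
    """Tolerances and thresholds of the annotation workflow.

    Defaults follow routine QTOF library-search practice: 10 ppm precursor
    and fragment match tolerance, a 5-count product-ion intensity floor, and
    an absolute 0.02 Da window for the 2-dp diagnostic sapogenin ions.
    """

    precursor_ppm: float = 10.0
    fragment_ppm: float = 10.0
    diagnostic_tol_da: float = 0.02
    max_chain_depth: int = 8
    min_fragment_intensity: float = 5.0
    rt_window_min: float = 0.2
    library_match_min_score: float = 0.3

    def __post_init__(self) -> None:
        for name in ("precursor_ppm", "fragment_ppm", "diagnostic_tol_da",
                     "rt_window_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnnotationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Diagnostic sapogenin ions (negative mode, deprotonated aglycone cores)
# ---------------------------------------------------------------------------

def _mh(formula: str) -> float:
    return mz_from_adduct(formula_mass(formula), "[M-H]-")


_PPT_ION = _mh("C30H52O4")        # 475.38
_PPD_ION = _mh("C30H52O3")        # 459.38
_OA_ION = _mh("C30H48O3")         # 455.35
_CYCLO_ION = _mh("C30H50O5")      # 489.36
_SOYA_ION = _mh("C30H50O3")       # 457.37
_SIDE_CHAIN = get_loss("C6H12").mass
# 3-O-GlurA oleanolic-acid saponins: decarboxylation / formic-acid-loss pair
_OA_GLURA_BASE = _OA_ION + get_loss("GlurA").mass - get_loss("H2O").mass

#: label -> (primary sapogenin ion, corroborating ions); the primary ion is
#: required for the label to fire, corroborating ions add confidence.
DIAGNOSTIC_IONS: dict[str, tuple[float, tuple[float, ...]]] = {
    "PPT": (_PPT_ION, (_PPT_ION - _SIDE_CHAIN,)),                  # 475.38 / 391.29
    "PPD": (_PPD_ION, (_PPD_ION - _SIDE_CHAIN,)),                  # 459.38 / 375.29
    "OA": (_OA_ION, ()),                                           # 455.35
    "OA_GlurA": (
        _OA_ION,
        (
            _OA_GLURA_BASE - get_loss("CO2").mass,                 # 569.38
            _OA_GLURA_BASE - get_loss("CO2").mass - get_loss("HCOOH").mass,  # 523.38
        ),
    ),
    "cycloastragenol": (_CYCLO_ION, (_mh("C26H40O2"),)),           # 489.36 / 383.30
    "soyasapogenol": (_SOYA_ION, ()),                              # 457.37
}

_SAPOGENIN_CLASS = {
    "PPT": "ginsenoside",
    "PPD": "ginsenoside",
    "OA": "ginsenoside",
    "OA_GlurA": "ginsenoside",
    "OT": "ginsenoside",
    "cycloastragenol": "astragaloside",
    "soyasapogenol": "other",
}


def loss_vocabulary(polarity: str) -> list[chem.NeutralLoss]:
    """The neutral losses searched during ladder inference for a polarity."""
    if polarity == "negative":
        names = ["Glc", "Rha", "GlurA", "Pen", "malonyl", "acetyl", "C6H12",
                 "danshensu", "caffeoyl", "feruloyl", "coumaroyl", "cinnamoyl",
                 "H2O", "CO2", "HCOOH"]
    else:
        names = ["Glc", "CH3", "CH4", "CH3OH", "CO", "H2O"]
    return [get_loss(n) for n in names]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossPath:
    """An ordered chain of neutral losses from a start node.

    ``node_mzs[i]`` is the theoretical m/z after the first ``i+1`` losses;
    ``matched_mzs[i]`` the observed peak it was matched to, with its signed
    ppm error in ``ppm_errors[i]``.
    """

    start_mz: float
    losses: tuple[str, ...]
    node_mzs: tuple[float, ...]
    matched_mzs: tuple[float, ...]
    ppm_errors: tuple[float, ...]
    truncated: bool = False

    @property
    def terminal_mz(self) -> float:
        return self.node_mzs[-1] if self.losses else self.start_mz

    def sugar_multiset(self) -> dict[str, int]:
        sugars = [n for n in self.losses if get_loss(n).role == "sugar"]
        return dict(Counter(sugars))


@dataclass(frozen=True)
class SapogeninCall:
    """Outcome of diagnostic-ion sapogenin classification."""

    label: str  # PPT | PPD | OA | OA_GlurA | cycloastragenol | soyasapogenol | none
    matched_mzs: tuple[float, ...] = ()
    intensities: tuple[float, ...] = ()
    tied_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class GlycanInference:
    sugars: dict[str, int]
    terminal_mz: float | None
    resolved: bool
    path: LossPath | None = None


@dataclass(frozen=True)
class Candidate:
    record_id: str
    name: str
    compound_class: str
    subclass: str
    adduct: str
    score: float
    ppm: float
    matched_fragments: int
    formula: str
    neutral_mass: float


@dataclass(frozen=True)
class AnnotationResult:
    spectrum_id: str
    rt_min: float
    precursor_mz: float
    polarity: str
    adduct: str
    neutral_mass: float | None
    sapogenin: SapogeninCall
    acyl_counts: dict[str, int]
    sugar_composition: dict[str, int]
    candidates: tuple[Candidate, ...]
    confidence: str  # identified_reference | library_matched | class_characterized | unknown
    compound_class: str
    subclass: str

    @property
    def top_candidate(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None

    def isomeric_top_ids(self) -> tuple[str, ...]:
        """Ids of candidates tied with the top candidate on score and |ppm|."""
        top = self.top_candidate
        if top is None:
            return ()
        return tuple(
            c.record_id
            for c in self.candidates
            if c.score == top.score and abs(c.ppm - top.ppm) < 1e-9
        )

    def to_row(self) -> dict[str, object]:
        top = self.top_candidate
        tied = [
            c.name for c in self.candidates
            if top is not None and c.score == top.score
        ]
        return {
            "spectrum_id": self.spectrum_id,
            "rt_min": self.rt_min,
            "precursor_mz": self.precursor_mz,
            "adduct": self.adduct,
            "formula": top.formula if top else "",
            "neutral_mass": self.neutral_mass if self.neutral_mass is not None else "",
            "compound_class": self.compound_class,
            "subclass": self.subclass,
            "candidate_names": "; ".join(tied),
            "confidence": self.confidence,
            "ppm_error": top.ppm if top else "",
            "matched_fragments": top.matched_fragments if top else 0,
        }


# ---------------------------------------------------------------------------
# Stage 1: adduct hypotheses
# ---------------------------------------------------------------------------

def hypothesize_adducts(
    precursor_mz: float,
    polarity: str,
    library: CompoundLibrary,
    config: AnnotationConfig | None = None,
) -> list[tuple[CompoundRecord, chem.AdductSpec, float]]:
    """All (record, adduct, ppm) pairs matching the precursor within tolerance."""
    config = config or AnnotationConfig()
    hypotheses: list[tuple[CompoundRecord, chem.AdductSpec, float]] = []
    for adduct in chem.adducts_for_polarity(polarity):
        neutral = neutral_mass_from_mz(precursor_mz, adduct)
        if neutral <= 0:
            continue
        for record in library.query_by_neutral_mass(neutral, config.precursor_ppm):
            ppm = ppm_error(precursor_mz, mz_from_adduct(record.neutral_mass, adduct))
            hypotheses.append((record, adduct, ppm))
    hypotheses.sort(key=lambda h: (abs(h[2]), h[0].id, h[1].name))
    return hypotheses


# ---------------------------------------------------------------------------
# Stage 2: neutral-loss chain search
# ---------------------------------------------------------------------------

def _match_peak(
    spectrum: Spectrum, target_mz: float, tol_da: float, min_intensity: float
):
    """Closest peak to ``target_mz`` within an absolute window, or None."""
    best = None
    best_d = tol_da
    for p in spectrum.peaks:
        if p.intensity < min_intensity:
            continue
        d = abs(p.mz - target_mz)
        if d <= best_d:
            best, best_d = p, d
    return best


def find_loss_paths(
    spectrum: Spectrum,
    start_mz: float,
    losses: Sequence[chem.NeutralLoss] | None = None,
    config: AnnotationConfig | None = None,
) -> list[LossPath]:
    """Depth-first enumeration of all maximal neutral-loss chains.

    Each step must land, within the fragment ppm tolerance, on an observed
    peak at or above the intensity floor.  Node m/z values chain
    theoretically (previous node minus loss mass), so errors do not
    accumulate from peak to peak.  Paths are returned in lexicographic order
    of their loss-name sequences; a path stopped by the depth limit is
    flagged ``truncated`` rather than raising.
    """
    config = config or AnnotationConfig()
    if losses is None:
        losses = loss_vocabulary(spectrum.polarity)
    losses = sorted(losses, key=lambda l: l.name)
    out: list[LossPath] = []

    def extend(node_mz, names, nodes, matched, ppms, depth):
        if depth >= config.max_chain_depth:
            out.append(LossPath(start_mz, names, nodes, matched, ppms, truncated=True))
            return
        extended = False
        for loss in losses:
            target = node_mz - loss.mass
            if target <= 0:
                continue
            tol_da = target * config.fragment_ppm * 1e-6
            peak = _match_peak(spectrum, target, tol_da, config.min_fragment_intensity)
            if peak is None:
                continue
            extended = True
            extend(
                target,
                names + (loss.name,),
                nodes + (target,),
                matched + (peak.mz,),
                ppms + (ppm_error(peak.mz, target),),
                depth + 1,
            )
        if not extended:
            out.append(LossPath(start_mz, names, nodes, matched, ppms))

    extend(start_mz, (), (), (), (), 0)
    out.sort(key=lambda p: p.losses)
    return out


# ---------------------------------------------------------------------------
# Stage 3: diagnostic-ion class calls
# ---------------------------------------------------------------------------

def classify_sapogenin(
    spectrum: Spectrum,
    polarity: str | None = None,
    config: AnnotationConfig | None = None,
) -> SapogeninCall:
    """Call the aglycone (sapogenin) class from diagnostic product ions.

    Diagnostic ions are matched at the absolute tolerance.  A label is
    eligible only when its primary sapogenin ion is present; among eligible
    labels the one matching more diagnostics wins, with the matched fraction
    of its diagnostic set as tie-break (so a fully matched specific label
    beats a partially matched superset label).  Remaining ties return
    ``none`` with the tied labels listed.  Positive-mode spectra return
    ``none`` by design.
    """
    config = config or AnnotationConfig()
    polarity = polarity or spectrum.polarity
    if polarity != "negative":
        return SapogeninCall("none")
    scored = []
    for label, (primary, corroborating) in DIAGNOSTIC_IONS.items():
        primary_peak = _match_peak(
            spectrum, primary, config.diagnostic_tol_da, config.min_fragment_intensity
        )
        if primary_peak is None:
            continue
        matched = [primary_peak]
        for ion in corroborating:
            peak = _match_peak(
                spectrum, ion, config.diagnostic_tol_da, config.min_fragment_intensity
            )
            if peak is not None:
                matched.append(peak)
        fraction = len(matched) / (1 + len(corroborating))
        scored.append((len(matched), fraction, label, matched))
    if not scored:
        return SapogeninCall("none")
    scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
    best = scored[0]
    ties = [s for s in scored if (s[0], s[1]) == (best[0], best[1])]
    if len(ties) > 1:
        return SapogeninCall("none", tied_labels=tuple(sorted(s[2] for s in ties)))
    return SapogeninCall(
        best[2],
        matched_mzs=tuple(p.mz for p in best[3]),
        intensities=tuple(p.intensity for p in best[3]),
    )


def detect_malonyl(
    spectrum: Spectrum,
    precursor_node_mz: float,
    config: AnnotationConfig | None = None,
) -> int:
    """Count malonyl substituents (0, 1 or 2) from CO2 / C3H2O3 neutral losses.

    Mono-malonylation shows a loss of CO2 or of the whole malonyl group from
    the deprotonated node; di-malonylation a doubled loss (which does not
    require the single-loss evidence).  Losses are matched at the absolute
    diagnostic tolerance.
    """
    config = config or AnnotationConfig()
    co2 = get_loss("CO2").mass
    mal = get_loss("malonyl").mass

    def present(delta: float) -> bool:
        return (
            _match_peak(
                spectrum,
                precursor_node_mz - delta,
                config.diagnostic_tol_da,
                config.min_fragment_intensity,
            )
            is not None
        )

    if present(2 * co2) or present(2 * mal):
        return 2
    if present(co2) or present(mal):
        return 1
    return 0


# ---------------------------------------------------------------------------
# Stage 4: glycan composition inference
# ---------------------------------------------------------------------------

def infer_glycan_composition(
    paths: Sequence[LossPath],
    sapogenin: SapogeninCall,
    config: AnnotationConfig | None = None,
) -> GlycanInference:
    """Read the sugar multiset off the ladder that reaches the sapogenin ion.

    Preference order: paths terminating at the called sapogenin diagnostic
    ion (absolute tolerance), then nearest above it, then nearest below;
    ties broken by longer path, more sugar-typed losses, then lexicographic
    loss names.  Without a sapogenin call the best path is taken but the
    terminal is flagged unresolved.
    """
    config = config or AnnotationConfig()
    paths = list(paths)
    if not paths:
        return GlycanInference({}, None, False)
    target = (
        DIAGNOSTIC_IONS[sapogenin.label][0]
        if sapogenin.label in DIAGNOSTIC_IONS
        else None
    )

    def hit_index(p: LossPath) -> int | None:
        """Index of the first node reaching the diagnostic ion, if any."""
        if target is None:
            return None
        for i, mz in enumerate(p.node_mzs):
            if abs(mz - target) <= config.diagnostic_tol_da:
                return i
        return None

    def sort_key(p: LossPath):
        n_sugars = sum(p.sugar_multiset().values())
        if target is None:
            band, dist = 2, 0.0
        elif hit_index(p) is not None:
            band, dist = 0, 0.0
        elif p.terminal_mz > target:
            band, dist = 1, p.terminal_mz - target
        else:
            band, dist = 2, target - p.terminal_mz
        return (band, dist, -len(p.losses), -n_sugars, p.losses)

    chosen = min(paths, key=sort_key)
    idx = hit_index(chosen)
    if idx is not None:
        sugars = dict(
            Counter(
                n for n in chosen.losses[: idx + 1] if get_loss(n).role == "sugar"
            )
        )
        return GlycanInference(sugars, chosen.node_mzs[idx], True, chosen)
    return GlycanInference(chosen.sugar_multiset(), chosen.terminal_mz, False, chosen)


# ---------------------------------------------------------------------------
# Stage 5: theoretical fragment sets and candidate scoring
# ---------------------------------------------------------------------------

def _sugar_sequence(sugars: dict[str, int] | None) -> list[str]:
    """Canonical elimination order: outer sugars round-robin, GlurA last.

    Non-GlurA residue types alternate, starting from the most abundant
    (lighter residue first on count ties); the core-attached glucuronic acid
    is eliminated last.
    """
    if not sugars:
        return []
    pool = {k: v for k, v in sugars.items() if k != "GlurA" and v > 0}
    order = sorted(pool, key=lambda s: (-pool[s], get_loss(s).mass, s))
    seq: list[str] = []
    remaining = dict(pool)
    while any(remaining.values()):
        for s in order:
            if remaining.get(s, 0) > 0:
                seq.append(s)
                remaining[s] -= 1
    seq.extend(["GlurA"] * sugars.get("GlurA", 0))
    return seq


def _subtractable(formula: str, *loss_names: str) -> bool:
    counts = chem.parse_formula(formula)
    for name in loss_names:
        counts = chem.subtract_counts(counts, chem.parse_formula(get_loss(name).formula))
        if counts is None:
            return False
    return counts is not None and counts.get("C", 0) >= 6


def theoretical_fragments(
    record: CompoundRecord, adduct: str | chem.AdductSpec
) -> list[tuple[float, str]]:
    """Theoretical fragment m/z values for a record under an adduct hypothesis.

    Returns ``(mz, kind)`` pairs with kind ``"ladder"`` (ppm-matched) or
    ``"diagnostic"`` (absolute-tolerance).  The set is the cumulative
    acyl+sugar neutral-loss ladder plus class-specific losses and the
    sapogenin diagnostic ions; the precursor itself is excluded.  An empty
    list means no ladder is derivable for the record.
    """
    spec = chem.get_adduct(adduct) if isinstance(adduct, str) else adduct
    mass = record.neutral_mass
    frags: list[tuple[float, str]] = []
    h2o = get_loss("H2O").mass
    co2 = get_loss("CO2").mass

    if spec.polarity == "negative":
        mh = mz_from_adduct(mass, "[M-H]-")
        if spec.name != "[M-H]-":
            # adduct stripping is the mandatory first ladder step
            frags.append((mh, "ladder"))
        node = mh
        acyl = record.acyl or {}
        n_mal = acyl.get("malonyl", 0)
        n_ace = acyl.get("acetyl", 0)
        if n_mal:
            frags += [(mh - co2, "ladder"), (mh - get_loss("malonyl").mass, "ladder")]
            if n_mal >= 2:
                frags += [
                    (mh - 2 * co2, "ladder"),
                    (mh - 2 * get_loss("malonyl").mass, "ladder"),
                ]
            node = mh - n_mal * get_loss("malonyl").mass
        for k in range(1, n_ace + 1):
            frags.append((node - k * get_loss("acetyl").mass, "ladder"))
        node -= n_ace * get_loss("acetyl").mass
        for sugar in _sugar_sequence(record.sugar_composition):
            node -= get_loss(sugar).mass
            frags.append((node, "ladder"))
        if record.sapogenin:
            label = record.sapogenin
            if label == "OA" and (record.sugar_composition or {}).get("GlurA"):
                label = "OA_GlurA"
                frags.append((_OA_GLURA_BASE, "ladder"))  # -outer sugars -H2O node
            if label == "soyasapogenol":
                frags.append((mh - h2o, "ladder"))
                pre_glura = [s for s in _sugar_sequence(record.sugar_composition)
                             if s != "GlurA"]
                if pre_glura:
                    shift = sum(get_loss(s).mass for s in pre_glura)
                    frags.append((mh - h2o - shift, "ladder"))
            primary, corroborating = DIAGNOSTIC_IONS.get(label, (None, ()))
            if primary is not None:
                frags.append((primary, "diagnostic"))
                frags += [(ion, "diagnostic") for ion in corroborating]
        elif record.compound_class == "phenolic_acid":
            dan = get_loss("danshensu")
            k = 0
            while k < 2 and _subtractable(record.formula, *["danshensu"] * (k + 1)):
                k += 1
                frags.append((mh - k * dan.mass, "ladder"))
            if k >= 1:
                rearr = mh - dan.mass - get_loss("caffeoyl").mass
                frags += [(rearr, "ladder"), (rearr - co2, "ladder")]
            else:
                frags += [(mh - h2o, "ladder"), (mh - co2, "ladder")]
        elif record.compound_class in ("iridoid", "phenylpropanoid"):
            for unit in ("feruloyl", "coumaroyl", "cinnamoyl"):
                if _subtractable(record.formula, unit):
                    u = get_loss(unit).mass
                    frags.append((mh - u, "ladder"))
                    if (record.sugar_composition or {}).get("Rha"):
                        rha = get_loss("Rha").mass
                        frags += [(mh - u - rha, "ladder"),
                                  (mh - u - rha - h2o, "ladder")]
                    break
            if (record.sugar_composition or {}).get("Glc") and _subtractable(
                record.formula, "Glc", "CH3COOH"
            ):
                frags.append(
                    (mh - get_loss("Glc").mass - get_loss("CH3COOH").mass, "ladder")
                )
            if not record.sugar_composition:
                frags += [(mh - h2o, "ladder"), (mh - co2, "ladder")]
        elif not record.sugar_composition:
            return []  # no negative-mode rule for this record
    else:  # positive mode: tanshinone / flavonoid class rules
        if record.compound_class not in ("tanshinone", "flavonoid"):
            return []
        ph = mz_from_adduct(mass, "[M+H]+")
        if record.compound_class == "tanshinone":
            frags += [
                (ph - get_loss("CH3").mass, "ladder"),
                (ph - h2o, "ladder"),
                (ph - get_loss("CO").mass, "ladder"),
                (ph - h2o - get_loss("CO").mass, "ladder"),
            ]
        else:
            node = ph
            for sugar in _sugar_sequence(record.sugar_composition):
                node -= get_loss(sugar).mass
                frags.append((node, "ladder"))
            frags += [
                (node - get_loss("CH3").mass, "ladder"),
                (node - get_loss("CH4").mass, "ladder"),
                (node - get_loss("CH3OH").mass, "ladder"),
                (node - 2 * get_loss("CO").mass, "ladder"),
                (node - formula_mass("C3H4O2"), "ladder"),
            ]

    # de-duplicate coincident ions (ladder terminals equal diagnostic ions),
    # keeping the diagnostic kind
    seen: dict[float, str] = {}
    for mz, kind in frags:
        if mz <= 0:
            continue
        key = round(mz, 5)
        if key not in seen or kind == "diagnostic":
            seen[key] = kind
    return sorted(seen.items())


def _score_matched(
    record: CompoundRecord,
    spectrum: Spectrum,
    adduct: str | chem.AdductSpec,
    config: AnnotationConfig,
) -> tuple[float, int]:
    frags = theoretical_fragments(record, adduct)
    if not frags:
        return 0.1, 0  # precursor-only floor
    matched = 0
    for mz, kind in frags:
        tol = (
            config.diagnostic_tol_da
            if kind == "diagnostic"
            else mz * config.fragment_ppm * 1e-6
        )
        if _match_peak(spectrum, mz, tol, config.min_fragment_intensity) is not None:
            matched += 1
    return matched / len(frags), matched


def score_candidate(
    record: CompoundRecord,
    spectrum: Spectrum,
    adduct: str | chem.AdductSpec,
    config: AnnotationConfig | None = None,
) -> float:
    """Fraction of the record's theoretical fragments observed in the spectrum.

    Records with no derivable ladder fall back to a 0.1 precursor-only score.
    """
    return _score_matched(record, spectrum, adduct, config or AnnotationConfig())[0]


# ---------------------------------------------------------------------------
# Stage 6: per-spectrum annotation and summaries
# ---------------------------------------------------------------------------

def _chain_start(spectrum: Spectrum, config: AnnotationConfig) -> float:
    """Ladder start node: strip an FA/acetate adduct when its loss is observed."""
    if spectrum.polarity != "negative":
        return spectrum.precursor_mz
    for strip in ("HCOOH", "CH3COOH"):
        target = spectrum.precursor_mz - get_loss(strip).mass
        tol = target * config.fragment_ppm * 1e-6
        if _match_peak(spectrum, target, tol, config.min_fragment_intensity):
            return target
    return spectrum.precursor_mz


def annotate_spectrum(
    spectrum: Spectrum,
    library: CompoundLibrary,
    config: AnnotationConfig | None = None,
) -> AnnotationResult:
    """Full per-spectrum pipeline; always returns a result.

    Confidence levels: ``identified_reference`` (top candidate is a reference
    standard whose expected retention time lies within the window and with at
    least one matched fragment) > ``library_matched`` (top score at or above
    the threshold) > ``class_characterized`` (diagnostics fired without a
    library match) > ``unknown``.
    """
    config = config or AnnotationConfig()
    hypotheses = hypothesize_adducts(
        spectrum.precursor_mz, spectrum.polarity, library, config
    )
    start = _chain_start(spectrum, config)
    paths = find_loss_paths(spectrum, start, None, config)
    sapogenin = classify_sapogenin(spectrum, spectrum.polarity, config)
    malonyl = (
        detect_malonyl(spectrum, start, config)
        if spectrum.polarity == "negative"
        else 0
    )
    glycan = infer_glycan_composition(paths, sapogenin, config)

    candidates = []
    for record, adduct, ppm in hypotheses:
        score, matched = _score_matched(record, spectrum, adduct, config)
        candidates.append(
            Candidate(
                record_id=record.id,
                name=record.name,
                compound_class=record.compound_class,
                subclass=record.subclass,
                adduct=adduct.name,
                score=score,
                ppm=ppm,
                matched_fragments=matched,
                formula=record.formula,
                neutral_mass=record.neutral_mass,
            )
        )
    candidates.sort(key=lambda c: (-c.score, abs(c.ppm), c.record_id))

    top = candidates[0] if candidates else None
    confidence = "unknown"
    if top is not None:
        record = library.get(top.record_id)
        if (
            record.reference_standard
            and record.expected_rt is not None
            and abs(spectrum.retention_time - record.expected_rt)
            <= config.rt_window_min
            and top.matched_fragments >= 1
        ):
            confidence = "identified_reference"
        elif top.score >= config.library_match_min_score:
            confidence = "library_matched"
    if confidence == "unknown" and (sapogenin.label != "none" or malonyl > 0):
        confidence = "class_characterized"

    if top is not None and confidence in ("identified_reference", "library_matched"):
        compound_class, subclass = top.compound_class, top.subclass
    elif sapogenin.label != "none":
        compound_class = _SAPOGENIN_CLASS.get(sapogenin.label, "")
        subclass = sapogenin.label
    else:
        compound_class, subclass = "", ""

    return AnnotationResult(
        spectrum_id=spectrum.spectrum_id,
        rt_min=spectrum.retention_time,
        precursor_mz=spectrum.precursor_mz,
        polarity=spectrum.polarity,
        adduct=top.adduct if top else "",
        neutral_mass=top.neutral_mass if top else None,
        sapogenin=sapogenin,
        acyl_counts={"malonyl": malonyl} if malonyl else {},
        sugar_composition=glycan.sugars,
        candidates=tuple(candidates),
        confidence=confidence,
        compound_class=compound_class,
        subclass=subclass,
    )


def summarize_classes(results: Sequence[AnnotationResult]) -> pd.DataFrame:
    """Class distribution over non-unknown annotations.

    Returns a DataFrame with ``compound_class``, ``count`` and ``percent``
    columns; percentages sum to 100 (up to rounding).
    """
    counts = Counter(
        r.compound_class
        for r in results
        if r.confidence != "unknown" and r.compound_class
    )
    if not counts:
        return pd.DataFrame(columns=["compound_class", "count", "percent"])
    total = sum(counts.values())
    rows = [
        {"compound_class": cls, "count": n, "percent": 100.0 * n / total}
        for cls, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
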