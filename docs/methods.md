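# Methods

## Scope and model

`herbannot` annotates data-dependent-acquisition (DDA) tandem-MS peak lists
from multi-herb extracts by combining three sources of evidence:

1. **Accurate-mass library search with adduct hypotheses.** Each precursor is
   inverted through every polarity-compatible adduct to a neutral-mass
   hypothesis and matched against the compound library inside a closed ±ppm
   window. Masses are most-abundant-isotope monoisotopic masses (atomic
   values taken from the NIST table shipped with pyteomics); the electron
   mass is included in charged-species arithmetic, so the [M−H]⁻ delta is
   −1.007276 Da. Only singly charged species are modelled.
2. **Glycosidic neutral-loss ladders.** Saponins and other glycosides
   fragment by successive elimination of sugar residues (Glc 162.0528, Rha
   146.0579, GlurA 176.0321, Pen 132.0423 Da; all pentoses are represented by
   the generic `Pen` because a 132 Da loss cannot distinguish xylose from
   arabinose). The chain search is an exhaustive depth-first enumeration over
   the loss vocabulary where every step must land on an observed peak; node
   m/z values chain theoretically from the start node so matching errors do
   not accumulate. When the precursor is a formate or acetate adduct, the
   loss of HCOOH/CH₃COOH to the deprotonated node is the mandatory first
   step.
3. **Diagnostic sapogenin ions and acyl losses.** Deprotonated aglycone ions
   call the class: PPT 475.3793 (corroborated by the −C₆H₁₂ side-chain ion
   391.2854), PPD 459.3844/375.2905, oleanolic acid 455.3531 (with the
   decarboxylation pair 569.3848/523.3793 diagnostic for 3-*O*-glucuronides),
   cycloastragenol 489.3585 (furan-ring rearrangement ion 383.2956),
   soyasapogenol 457.3687. Malonylation is detected from CO₂ (43.9898) or
   whole-malonyl C₃H₂O₃ (86.0004) losses off the deprotonated node, doubled
   for dimalonylation (which does not require the single-loss evidence).

Candidate scoring is the fraction of the record's theoretical fragment set
observed in the spectrum. The theoretical set is the cumulative acyl+sugar
ladder plus diagnostic ions plus class-specific losses; records with no
derivable ladder fall back to a 0.1 precursor-only score. Confidence levels:
`identified_reference` (top candidate is a reference standard, retention
time within the window, ≥1 matched fragment), `library_matched` (top score ≥
0.3), `class_characterized` (diagnostics fired without a library match),
`unknown`.

Positive mode carries no saponin logic (in-source fragmentation makes it
uninformative for saponins); tanshinones fragment by CH₃ radical, H₂O and CO
losses, isoflavones by glycosyl loss followed by CH₃/CH₄/CH₃OH/2CO/C₃H₄O₂
losses from the aglycone. The radical losses are kept in the "neutral loss"
vocabulary for uniformity.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| precursor / fragment tolerance | 10 | ppm | routine QTOF library-search tolerance |
| diagnostic-ion tolerance | 0.02 | Da | diagnostic values are conventionally quoted at 2 dp, mixing observed and theoretical values that differ by ~0.01 Da |
| min fragment intensity | 5 | counts | MS2 intensity floor of the acquisition software |
| max chain depth | 8 | losses | deepest plausible ladder (tetraglycosyl + acyls); deeper paths are flagged truncated, not dropped |
| reference RT window | 0.2 | min | typical run-to-run retention stability on a 30 min gradient |
| library-match score threshold | 0.3 | — | requires roughly a third of the theoretical ladder; qualitative criterion made explicit |

DDA defaults: MS1 0.3 s per scan over m/z 80–1500; trigger threshold 1000
counts; top-5 precursors; MS2 stops at 2000 counts TIC or 1.5 s (modelled as
`min(1.5 s, 2000/intensity)` of consumed cycle time); dynamic exclusion 6 s
(no exclusion policy is standard for this instrument class; 0 gives a
literal top-N at every scan). Injection concentration (mg/mL) and volume
(µL) enter as a multiplicative on-column load factor relative to 1 mg/mL ×
3 µL, so a 10 mg/mL × 5 µL injection loads 16.7× more material.

## Deterministic orderings and tie-breaks

All orderings are fully specified so identical inputs give identical
results: library queries sort by |ppm| then id; adduct hypotheses by (|ppm|,
record id, adduct name); loss paths lexicographically by loss-name sequence;
candidates by (score desc, |ppm| asc, id asc). Isomeric candidates tied on
score and ppm are all reported — isomerism is pervasive among ginsenosides
and collapsing to one name would be arbitrary.

Sapogenin calls rank eligible labels (primary ion present) by number of
matched diagnostics, then by the matched fraction of the label's diagnostic
set; the fraction tie-break lets a fully matched specific label (OA) beat a
partially matched superset label (OA with GlurA corroboration), and only
genuine residual ties return `none` with the tied labels listed. Glycan
inference prefers the path whose nodes reach the called sapogenin ion (the
sugar multiset is read from the prefix up to that node), then the path
terminating nearest above it, then longer paths, more sugar losses, and
lexicographic order. Degenerate inputs are defined, not exceptional: empty
spectra score 0.1, empty path sets give an unresolved empty glycan, empty
annotation lists give an empty class summary, and precision over an empty
acquisition is reported as 0 with a `precision_defined=False` flag.

The canonical sugar-elimination order used to *generate* ladders is
round-robin over residue types (most abundant first, lighter residue first
on ties) with GlurA always last, reflecting its core attachment. This
reproduces the characteristic published ladders (e.g. Glc→Pen→Glc for the
triglycosyl PPT saponin; Pen→Glc for astragalosides) without per-compound
topology data, which the library does not store.

## The simulator: what it emulates and what it does not

`simulate` stands in for the instrument so every pipeline stage is testable
at desk scale. It emulates: wide dynamic range (log-uniform abundances),
Gaussian elution (default sigma 0.05 min; no peak-shape information beyond
width is used), top-N trigger competition with threshold, dynamic exclusion
and cycle-time consumption, eluate-knockout windows (signal zeroing inside
the window — the physical valve — never intensity scaling), and injection
load scaling. Fragment intensities follow a fixed geometric profile
(precursor 100, ladder 60·0.85ᵏ, diagnostics 40) and noise peaks are uniform
below 10% of base intensity.

It does **not** emulate: isotope envelopes, multiply charged species,
in-source fragmentation, detector saturation, ion suppression,
chromatographic tailing, retention-time drift, or ion-mobility drift (CCS is
a pass-through field only). Consequently, passing recovery tests show the
annotation logic is self-consistent and the acquisition logic behaves as
specified — not that real-data recovery would reach the same rates; real
spectra add co-isolation chimeras and intensity variation that the scoring
(match-counting, intensity-free) is only partially robust to.

The knockout demonstration mirrors the published three-injection protocol:
a baseline injection (load 1×, no knockout) against a concentrated injection
(load 16.7×) with the four dominant saponin peaks' elution windows diverted
to waste. Minor components are placed below the MS1 trigger threshold at
baseline load, so the baseline acquires none of them; under the concentrated
knockout injection all are triggered and correctly annotated while the
dominant apexes are suppressed. Because knockout is time-window zeroing,
co-apex minors inside a window are sacrificed — the gain comes from minors
elsewhere in the gradient, which is exactly the exposure logic of the
physical experiment. Spectrum ids of simulated acquisitions embed the
ground-truth record id (`"<record_id>|scan<k>"`) so recovery metrics can be
computed from the annotations and mixture alone.

## Problem sizes

Default test and acceptance runs use the 40-record fixture library, mixtures
of ≤20 components, 18–30 min simulated gradients, and 500 random ≤12-peak
spectra for the chain-search/brute-force equivalence check; these sizes keep
the whole suite in the tens of seconds while exercising every rule family
(all sapogenin classes, acylated saponins, both polarities).

## Known limitations and open points

- The published single-malonyl partial loss is conventionally quoted as
  "44.01 Da", which does not match theoretical CO₂ (43.9898); the registry
  uses the theoretical CO₂ mass and treats the 2-dp quote as imprecise.
  Similarly, a handful of published observed values differ from
  formula-derived theory by 0.01–0.02 Da at 2 dp; the package always uses
  formula-derived values.
- Cryptotanshinone is stored with the formula quoted in its source
  (C₁₉H₁₂O₃) even though the compound is commonly given as C₁₉H₂₀O₃; the
  record documents the provenance rather than silently correcting it.
- The compound library stores composition (sugar multiset, acyl counts), not
  structure; linkage positions and stereochemistry are out of scope, so
  isomers are intrinsically tied and reported together.
- Scoring ignores intensities; spectral-similarity scoring against measured
  libraries is a deliberate non-goal.
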