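"""Adduct hypotheses, ladder search, diagnostic calls, scoring and annotation."""

import numpy as np
import pytest
from _oracles import brute_force_paths, path_key, random_ladder_spectrum

from herbannot import chem
from herbannot.annotate import (
    AnnotationConfig,
    AnnotationResult,
    DIAGNOSTIC_IONS,
    SapogeninCall,
    annotate_spectrum,
    classify_sapogenin,
    detect_malonyl,
    find_loss_paths,
    hypothesize_adducts,
    infer_glycan_composition,
    score_candidate,
    summarize_classes,
    theoretical_fragments,
)
from herbannot.simulate import theoretical_spectrum
from herbannot.spectra import Spectrum


def _neg(spectrum_id, precursor, peaks, rt=1.0):
    return Spectrum(spectrum_id, "negative", precursor, rt, peaks=peaks)


# the four-rung ladder of the triglycosylated PPT saponin (m/z 931.53 ->
# 769.47 -> 637.43 -> 475.38) plus the side-chain-loss corroboration ion
R1_LADDER = [
    (931.5272, 100.0),
    (769.4744, 60.0),
    (637.4321, 55.0),
    (475.3793, 50.0),
    (391.2854, 20.0),
]


class TestHypothesizeAdducts:
    def test_formate_adduct(self, lib, config):
        hyps = hypothesize_adducts(977.5327, "negative", lib, config)
        assert [(r.id, a.name) for r, a, _ in hyps] == [("noto-r1", "[M+HCOO]-")]

    def test_deprotonated(self, lib, config):
        hyps = hypothesize_adducts(931.5272, "negative", lib, config)
        assert ("noto-r1", "[M-H]-") in [(r.id, a.name) for r, a, _ in hyps]

    def test_polarity_gate(self, lib, config):
        assert hypothesize_adducts(931.5272, "positive", lib, config) == []


class TestFindLossPaths:
    def test_recovers_the_sugar_ladder(self, config):
        spec = _neg("r1", 931.5272, R1_LADDER)
        paths = find_loss_paths(spec, 931.5272, None, config)
        assert ("Glc", "Pen", "Glc") in [p.losses[:3] for p in paths if len(p.losses) >= 3]
        best = [p for p in paths if p.losses == ("Glc", "Pen", "Glc", "C6H12")]
        assert best, "full ladder including the side-chain loss"
        assert best[0].node_mzs[-2] == pytest.approx(475.3793, abs=1e-3)

    def test_no_matching_peaks_gives_empty_path(self, config):
        spec = _neg("none", 500.0, [(123.0, 10.0)])
        paths = find_loss_paths(spec, 500.0, None, config)
        assert len(paths) == 1
        assert paths[0].losses == () and paths[0].terminal_mz == 500.0

    def test_depth_limit_flags_truncation(self):
        cfg = AnnotationConfig(max_chain_depth=2)
        h2o = chem.get_loss("H2O").mass
        peaks = [(500.0 - k * h2o, 10.0) for k in range(1, 5)]
        spec = _neg("w", 500.0, peaks)
        paths = find_loss_paths(spec, 500.0, [chem.get_loss("H2O")], cfg)
        assert any(p.truncated and len(p.losses) == 2 for p in paths)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_enumeration(self, seed):
        # oracle: exhaustive enumeration of all loss sequences to depth 4
        cfg = AnnotationConfig(max_chain_depth=4)
        losses = [chem.get_loss(n) for n in ("Glc", "Rha", "Pen", "H2O", "CO2")]
        rng = np.random.default_rng(seed)
        for _ in range(50):
            spec, start = random_ladder_spectrum(rng, losses, cfg)
            got = {path_key(p) for p in find_loss_paths(spec, start, losses, cfg)}
            expect = {path_key(p) for p in brute_force_paths(spec, start, losses, cfg)}
            assert got == expect


class TestClassifySapogenin:
    @pytest.mark.parametrize(
        "peaks,label",
        [
            ([(475.379, 50.0), (391.285, 20.0)], "PPT"),
            ([(459.383, 50.0), (375.290, 20.0)], "PPD"),
            ([(455.353, 40.0), (569.385, 60.0), (523.379, 55.0)], "OA_GlurA"),
            ([(455.353, 40.0)], "OA"),
            ([(489.358, 40.0), (383.295, 10.0)], "cycloastragenol"),
            ([(457.369, 40.0)], "soyasapogenol"),
            ([(300.1, 40.0)], "none"),
        ],
    )
    def test_diagnostic_table(self, config, peaks, label):
        spec = _neg("d", 900.0, peaks)
        assert classify_sapogenin(spec, "negative", config).label == label

    def test_positive_mode_returns_none(self, config):
        spec = Spectrum("p", "positive", 295.13, 1.0, peaks=[(277.12, 10.0)])
        assert classify_sapogenin(spec, "positive", config).label == "none"

    def test_ambiguous_tie_lists_candidates(self, config):
        # both PPT and PPD primaries present, neither corroborated
        spec = _neg("t", 900.0, [(475.379, 10.0), (459.384, 10.0)])
        call = classify_sapogenin(spec, "negative", config)
        assert call.label == "none"
        assert call.tied_labels == ("PPD", "PPT")


class TestDetectMalonyl:
    MAL_MH = 1193.5961  # deprotonated malonylated tetraglucosyl PPD saponin

    def test_monomalonyl(self, config):
        spec = _neg("m", self.MAL_MH, [(1149.606, 30.0), (1107.595, 40.0)])
        assert detect_malonyl(spec, self.MAL_MH, config) == 1

    def test_no_malonyl(self, config):
        spec = _neg("m", 1107.6057, [(945.553, 30.0)])
        assert detect_malonyl(spec, 1107.6057, config) == 0

    def test_dimalonyl_needs_no_mono_evidence(self, config):
        mal2 = 2 * chem.get_loss("malonyl").mass
        spec = _neg("m", 1000.0, [(1000.0 - mal2, 30.0)])
        assert detect_malonyl(spec, 1000.0, config) == 2


class TestInferGlycan:
    def test_r1_composition(self, config):
        spec = _neg("r1", 931.5272, R1_LADDER)
        paths = find_loss_paths(spec, 931.5272, None, config)
        call = classify_sapogenin(spec, "negative", config)
        inf = infer_glycan_composition(paths, call, config)
        assert inf.sugars == {"Glc": 2, "Pen": 1}
        assert inf.resolved

    def test_empty_paths_unresolved(self, config):
        inf = infer_glycan_composition([], SapogeninCall("PPT"), config)
        assert inf.sugars == {} and not inf.resolved

    def test_sapogenin_terminated_path_beats_longer_off_node_path(self, config):
        # two ladders from one precursor: Glc -> PPT node, and a longer
        # H2O/CO2 chain ending away from any diagnostic ion
        ppt = DIAGNOSTIC_IONS["PPT"][0]
        start = ppt + chem.get_loss("Glc").mass
        h2o, co2 = chem.get_loss("H2O").mass, chem.get_loss("CO2").mass
        peaks = [
            (ppt, 50.0),
            (start - h2o, 10.0),
            (start - h2o - co2, 10.0),
            (start - h2o - co2 - h2o, 10.0),
        ]
        spec = _neg("two", start, peaks)
        paths = find_loss_paths(spec, start, None, config)
        inf = infer_glycan_composition(paths, SapogeninCall("PPT"), config)
        assert inf.path.losses == ("Glc",)
        assert inf.sugars == {"Glc": 1} and inf.resolved


class TestScoring:
    def test_noiseless_true_record_scores_one(self, lib, config):
        r1 = lib.by_name("notoginsenoside R1")
        spec = theoretical_spectrum(r1)
        assert score_candidate(r1, spec, "[M-H]-", config) == 1.0

    def test_wrong_record_scores_lower(self, lib, config):
        r1 = lib.by_name("notoginsenoside R1")
        rd = lib.by_name("ginsenoside Rd")
        spec = theoretical_spectrum(r1)
        assert score_candidate(rd, spec, "[M-H]-", config) < score_candidate(
            r1, spec, "[M-H]-", config
        )

    def test_empty_ms2_gets_precursor_floor(self, config):
        from herbannot.library import CompoundRecord

        rec = CompoundRecord("t", "bare tanshinone", "C19H18O3", "tanshinone")
        spec = _neg("e", chem.mz_from_adduct(rec.neutral_mass, "[M-H]-"), [])
        # negative-mode spectrum of a positive-mode class: no derivable ladder
        assert score_candidate(rec, spec, "[M-H]-", config) == 0.1

    def test_adding_theoretical_fragment_never_decreases_score(self, lib, config):
        r1 = lib.by_name("notoginsenoside R1")
        frags = theoretical_fragments(r1, "[M-H]-")
        rng = np.random.default_rng(3)
        # start from a partial spectrum and add matching fragments one by one
        chosen = list(rng.permutation(len(frags)))
        peaks = [(931.5272, 100.0)]
        prev = score_candidate(
            r1, _neg("p", 931.5272, peaks), "[M-H]-", config
        )
        for idx in chosen:
            peaks.append((frags[idx][0], 30.0))
            cur = score_candidate(r1, _neg("p", 931.5272, peaks), "[M-H]-", config)
            assert cur >= prev
            prev = cur
        assert prev == 1.0


class TestAnnotateSpectrum:
    def test_reference_identification(self, lib, config):
        r1 = lib.by_name("notoginsenoside R1")
        spec = theoretical_spectrum(r1, retention_time=5.74)
        res = annotate_spectrum(spec, lib, config)
        assert res.top_candidate.record_id == "noto-r1"
        assert res.confidence == "identified_reference"
        assert res.sapogenin.label == "PPT"
        assert res.sugar_composition == {"Glc": 2, "Pen": 1}

    def test_isomers_all_reported(self, lib, config):
        rec = lib.by_name("ginsenoside Re1")
        spec = theoretical_spectrum(rec)
        res = annotate_spectrum(spec, lib, config)
        assert len(res.isomeric_top_ids()) == 7
        assert "gins-re1" in res.isomeric_top_ids()

    def test_class_characterized_without_library_match(self, lib, config):
        # diagnostics fire but the precursor matches nothing in the library
        spec = _neg("orphan", 1200.777, [(455.353, 40.0), (569.385, 60.0)])
        res = annotate_spectrum(spec, lib, config)
        assert res.candidates == ()
        assert res.confidence == "class_characterized"
        assert res.compound_class == "ginsenoside"

    def test_random_noise_is_unknown(self, lib, config):
        rng = np.random.default_rng(11)
        peaks = [(float(m), 20.0) for m in rng.uniform(80, 700, size=10)]
        spec = _neg("noise", 1499.901, peaks)
        res = annotate_spectrum(spec, lib, config)
        assert res.confidence == "unknown"

    def test_determinism(self, lib, config):
        r1 = lib.by_name("notoginsenoside R1")
        spec = theoretical_spectrum(r1, noise_peaks=5, seed=9, retention_time=5.74)
        a = annotate_spectrum(spec, lib, config)
        b = annotate_spectrum(spec, lib, config)
        assert a == b
        assert isinstance(a, AnnotationResult)


class TestSummarizeClasses:
    def test_published_class_counts_give_67_percent(self, lib, config):
        counts = {
            "ginsenoside": 155, "astragaloside": 6, "phenolic_acid": 16,
            "tanshinone": 16, "flavonoid": 13, "iridoid": 6,
            "phenylpropanoid": 10, "other": 8,
        }
        results = []
        for cls, n in counts.items():
            for i in range(n):
                results.append(
                    AnnotationResult(
                        spectrum_id=f"{cls}{i}", rt_min=0.0, precursor_mz=0.0,
                        polarity="negative", adduct="", neutral_mass=None,
                        sapogenin=SapogeninCall("none"), acyl_counts={},
                        sugar_composition={}, candidates=(),
                        confidence="library_matched", compound_class=cls,
                        subclass="",
                    )
                )
        df = summarize_classes(results)
        gins = df.loc[df.compound_class == "ginsenoside", "percent"].item()
        assert round(gins) == 67
        assert gins == pytest.approx(100 * 155 / 230, abs=1e-9)
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_uniform_distribution(self):
        results = [
            AnnotationResult(
                spectrum_id=f"{cls}{i}", rt_min=0.0, precursor_mz=0.0,
                polarity="negative", adduct="", neutral_mass=None,
                sapogenin=SapogeninCall("none"), acyl_counts={},
                sugar_composition={}, candidates=(),
                confidence="library_matched", compound_class=cls, subclass="",
            )
            for cls in ("ginsenoside", "iridoid", "tanshinone", "flavonoid", "other")
            for i in range(2)
        ]
        df = summarize_classes(results)
        assert set(df["percent"]) == {20.0}

    def test_empty(self):
        assert summarize_classes([]).empty
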