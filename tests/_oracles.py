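"""Independent brute-force oracles used by the test suite.

These recompute expected results by exhaustive enumeration, sharing no code
with the package's search implementations.
"""

from __future__ import annotations

from herbannot.annotate import AnnotationConfig, LossPath
from herbannot.spectra import Spectrum


def _nearest_peak(spectrum: Spectrum, target: float, tol_da: float, min_int: float):
    best, best_d = None, tol_da
    for p in spectrum.peaks:
        if p.intensity < min_int:
            continue
        d = abs(p.mz - target)
        if d <= best_d:
            best, best_d = p, d
    return best


def _walk(spectrum, start_mz, seq, masses, config):
    """Node/matched-peak lists for a loss-name sequence, or None if unrealizable."""
    node = start_mz
    nodes, matched, ppms = [], [], []
    for name in seq:
        node = node - masses[name]
        if node <= 0:
            return None
        tol = node * config.fragment_ppm * 1e-6
        peak = _nearest_peak(spectrum, node, tol, config.min_fragment_intensity)
        if peak is None:
            return None
        nodes.append(node)
        matched.append(peak.mz)
        ppms.append(1e6 * (peak.mz - node) / node)
    return nodes, matched, ppms


def brute_force_paths(spectrum, start_mz, losses, config: AnnotationConfig):
    """All maximal loss chains by breadth-first enumeration of sequences."""
    names = sorted(l.name for l in losses)
    masses = {l.name: l.mass for l in losses}
    out = []
    frontier = [()]
    for depth in range(config.max_chain_depth + 1):
        next_frontier = []
        for seq in frontier:
            walked = _walk(spectrum, start_mz, seq, masses, config)
            if walked is None:
                continue
            if depth == config.max_chain_depth:
                out.append((seq, walked, True))
                continue
            extensions = [
                seq + (n,)
                for n in names
                if _walk(spectrum, start_mz, seq + (n,), masses, config) is not None
            ]
            if extensions:
                next_frontier.extend(extensions)
            else:
                out.append((seq, walked, False))
        frontier = next_frontier
    paths = [
        LossPath(start_mz, tuple(seq), tuple(nodes), tuple(matched), tuple(ppms), trunc)
        for seq, (nodes, matched, ppms), trunc in out
    ]
    paths.sort(key=lambda p: p.losses)
    return paths


def path_key(p: LossPath):
    """Hashable comparison key for a loss path."""
    return (
        p.losses,
        tuple(round(x, 6) for x in p.node_mzs),
        tuple(round(x, 6) for x in p.matched_mzs),
        p.truncated,
    )


def random_ladder_spectrum(rng, losses, config, max_peaks=12):
    """A random ≤``max_peaks`` spectrum with a planted loss ladder plus noise."""
    start = float(rng.uniform(600.0, 1200.0))
    masses = [l.mass for l in losses]
    n_planted = int(rng.integers(0, 5))
    node = start
    peaks = []
    for _ in range(n_planted):
        step = masses[int(rng.integers(0, len(masses)))]
        if node - step <= 80.0:
            break
        node -= step
        jitter = node * 1e-6 * rng.uniform(-0.8, 0.8) * config.fragment_ppm
        peaks.append((node + jitter, float(rng.uniform(10, 1000))))
    n_noise = int(rng.integers(0, max_peaks - len(peaks) + 1))
    for _ in range(n_noise):
        peaks.append((float(rng.uniform(80, start)), float(rng.uniform(1, 1000))))
    return (
        Spectrum("rnd", "negative", start, 1.0, peaks=tuple(peaks)),
        start,
    )
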