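"""The frozen 52-feature registry.

Every extractor output maps to exactly one registry entry; column order of
the feature table follows this list. Spellings (including the "(Fr)"/
"(wt)" method tags) are frozen so occurrence tables from different runs
are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str  # statistical | geometric | spectral | wavelet | nonlinear | multifractal
    units: str
    stage: str  # producing module


_ENTRIES = [
    # statistical
    ("M", "statistical", "ms", "timedomain"),
    ("HR", "statistical", "beats/min", "timedomain"),
    ("SDNN", "statistical", "ms", "timedomain"),
    ("CV", "statistical", "%", "timedomain"),
    ("RMSSD", "statistical", "ms", "timedomain"),
    ("NN50", "statistical", "count", "timedomain"),
    # geometric
    ("M0", "geometric", "s", "timedomain"),
    ("VR", "geometric", "s", "timedomain"),
    ("AM0", "geometric", "%", "timedomain"),
    ("SI", "geometric", "%/s^2", "timedomain"),
    ("IAB", "geometric", "%/s", "timedomain"),
    ("ARI", "geometric", "1/s^2", "timedomain"),
    ("IARP", "geometric", "%/s", "timedomain"),
    # Fourier spectral
    ("HF(Fr)", "spectral", "ms^2", "spectral"),
    ("LF(Fr)", "spectral", "ms^2", "spectral"),
    ("VLF(Fr)", "spectral", "ms^2", "spectral"),
    ("TP(Fr)", "spectral", "ms^2", "spectral"),
    ("HFn(Fr)", "spectral", "-", "spectral"),
    ("LFn(Fr)", "spectral", "-", "spectral"),
    ("VLFn(Fr)", "spectral", "-", "spectral"),
    ("LF/HF(Fr)", "spectral", "-", "spectral"),
    ("IC", "spectral", "-", "spectral"),
    ("IAS", "spectral", "-", "spectral"),
    ("HFmax(Fr)", "spectral", "ms^2/Hz", "spectral"),
    ("RF", "spectral", "Hz", "spectral"),
    # wavelet
    ("HF(wt)", "wavelet", "ms^2·s", "wavelet"),
    ("LF(wt)", "wavelet", "ms^2·s", "wavelet"),
    ("VLF(wt)", "wavelet", "ms^2·s", "wavelet"),
    ("TP(wt)", "wavelet", "ms^2·s", "wavelet"),
    ("HFn(wt)", "wavelet", "-", "wavelet"),
    ("LFn(wt)", "wavelet", "-", "wavelet"),
    ("VLFn(wt)", "wavelet", "-", "wavelet"),
    ("SDHF(wt)", "wavelet", "ms^2", "wavelet"),
    ("SDLF(wt)", "wavelet", "ms^2", "wavelet"),
    ("SDVLF(wt)", "wavelet", "ms^2", "wavelet"),
    ("LF/HF(wt)", "wavelet", "-", "wavelet"),
    ("(LF/HF)max", "wavelet", "-", "wavelet"),
    ("(LF/HF)int", "wavelet", "ratio·s", "wavelet"),
    ("Nd", "wavelet", "count", "wavelet"),
    # nonlinear
    ("H", "nonlinear", "-", "fractal"),
    # multifractal, LF then VLF scale band
    ("αminLF", "multifractal", "-", "fractal"),
    ("αmaxLF", "multifractal", "-", "fractal"),
    ("WLF", "multifractal", "-", "fractal"),
    ("H2LF", "multifractal", "-", "fractal"),
    ("H0LF", "multifractal", "-", "fractal"),
    ("W1/2LF", "multifractal", "-", "fractal"),
    ("αminVLF", "multifractal", "-", "fractal"),
    ("αmaxVLF", "multifractal", "-", "fractal"),
    ("WVLF", "multifractal", "-", "fractal"),
    ("H2VLF", "multifractal", "-", "fractal"),
    ("H0VLF", "multifractal", "-", "fractal"),
    ("W1/2VLF", "multifractal", "-", "fractal"),
]

FEATURE_REGISTRY: tuple[FeatureDescriptor, ...] = tuple(
    FeatureDescriptor(*e) for e in _ENTRIES)

FEATURE_NAMES: tuple[str, ...] = tuple(d.name for d in FEATURE_REGISTRY)

assert len(set(FEATURE_NAMES)) == len(FEATURE_NAMES) == 52


def features_by_family(family: str) -> tuple[str, ...]:
    return tuple(d.name for d in FEATURE_REGISTRY if d.family == family)
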