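"""Fourier-domain HRV features on the uniform tachogram.

Band powers over the canonical short-record bands (VLF 0.003–0.04, LF
0.04–0.15, HF 0.15–0.4 Hz; ULF is not analyzed on ~300 s records), their
normalized shares, the LF/HF sympathovagal balance, the centralization
(IC) and subcortical-activation (IAS) indices, and the HF spectral peak
(HFmax) with its frequency, conventionally read as the respiration
frequency (RF).

The PSD estimator is an averaged modified periodogram (Welch): Hann
window, 50 % overlap, per-segment linear detrend, segment length
min(record length, 150 s). Total power is defined as VLF+LF+HF so the
normalized shares sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import signal

from .series import UniformTachogram
from .synth import BANDS_HZ

SEGMENT_S = 150.0


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    psd: np.ndarray  # ms^2/Hz
    meta: dict = field(default_factory=dict)


def power_spectrum(tach: UniformTachogram, segment_s: float = SEGMENT_S,
                   overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD of the mean-removed tachogram (ms²/Hz)."""
    x = tach.values_ms
    if (x.size - 1) / tach.fs_hz < 60.0:
        raise ValueError("record shorter than 60 s; spectral analysis unreliable")
    nperseg = min(x.size, int(round(segment_s * tach.fs_hz)))
    freqs, psd = signal.welch(
        x - x.mean(), fs=tach.fs_hz, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="linear", scaling="density",
    )
    return PowerSpectrum(
        freqs_hz=freqs, psd=psd,
        meta={"estimator": "welch", "window": "hann", "nperseg": nperseg,
              "overlap": overlap, "detrend": "linear"},
    )


def band_powers(ps: PowerSpectrum) -> dict[str, float]:
    """Trapezoidal band powers (ms²) over half-open bands [low, high).

    TP = HF + LF + VLF (ULF and >0.4 Hz content excluded).
    """
    f, p = ps.freqs_hz, ps.psd
    if f[-1] < BANDS_HZ["HF"][1] - 1e-9:
        raise ValueError("spectrum does not cover the HF band up to 0.4 Hz")
    out: dict[str, float] = {}
    for band, (lo, hi) in BANDS_HZ.items():
        mask = (f >= lo) & (f < hi)
        if mask.sum() < 2:
            out[band] = 0.0
            continue
        out[band] = float(np.trapezoid(p[mask], f[mask]))
    out["TP"] = out["HF"] + out["LF"] + out["VLF"]
    return out


def spectral_indices(bp: dict[str, float], ps: PowerSpectrum) -> dict[str, float]:
    """Normalized shares, LF/HF, IC, IAS, HFmax and RF, registry-named.

    Zero denominators (TP or VLF or HF = 0) yield NaN for the affected
    ratios rather than raising.
    """
    hf, lf, vlf, tp = bp["HF"], bp["LF"], bp["VLF"], bp["TP"]
    nan = math.nan
    feats = {
        "HF(Fr)": hf, "LF(Fr)": lf, "VLF(Fr)": vlf, "TP(Fr)": tp,
        "HFn(Fr)": hf / tp if tp > 0 else nan,
        "LFn(Fr)": lf / tp if tp > 0 else nan,
        "VLFn(Fr)": vlf / tp if tp > 0 else nan,
        "LF/HF(Fr)": lf / hf if hf > 0 else nan,
        "IC": (hf + lf) / vlf if vlf > 0 else nan,
        "IAS": lf / vlf if vlf > 0 else nan,
    }
    lo, hi = BANDS_HZ["HF"]
    mask = (ps.freqs_hz >= lo) & (ps.freqs_hz < hi)
    if mask.any():
        idx = np.flatnonzero(mask)[np.argmax(ps.psd[mask])]
        feats["HFmax(Fr)"] = float(ps.psd[idx])
        feats["RF"] = float(ps.freqs_hz[idx])
    else:
        feats["HFmax(Fr)"] = nan
        feats["RF"] = nan
    return feats


def spectral_features(tach: UniformTachogram, segment_s: float = SEGMENT_S
                      ) -> dict[str, float]:
    """All 12 Fourier-domain features of a tachogram."""
    ps = power_spectrum(tach, segment_s=segment_s)
    return spectral_indices(band_powers(ps), ps)
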