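"""Continuous-wavelet band decomposition and dysfunction statistics.

A continuous wavelet transform (Coiflet-5 basis) converts the tachogram
into time-resolved VLF/LF/HF band powers, giving wavelet analogues of the
Fourier band features, the variability (SD) of each band's power over
time, and the instantaneous LF/HF ratio. Excursions of that ratio above a
decision threshold Δ (default 10) are "dysfunctions": contiguous
supra-threshold runs summarized by their count Nd, the maximal ratio
reached, and the intensity (area of the excursion above the threshold,
ratio·s).

The scale of analysis maps to frequency as a = f_c · f_s / f, with f_c the
wavelet's center frequency; each band is tiled with at least 8 voices per
octave on a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pywt
from scipy.signal import fftconvolve, hilbert

from .series import UniformTachogram
from .synth import BANDS_HZ

WAVELET = "coif5"
VOICES_PER_OCTAVE = 8
DELTA_DEFAULT = 10.0
RATIO_SMOOTH_S = 1.0
HF_FLOOR_REL = 1e-6


@dataclass
class WaveletBandSeries:
    """Instantaneous band powers on the tachogram's time grid."""

    t_s: np.ndarray
    hf_t: np.ndarray
    lf_t: np.ndarray
    vlf_t: np.ndarray
    ratio_t: np.ndarray  # LFwt/HFwt; NaN where hf_t is floored out
    fs_hz: float
    scales: dict = field(default_factory=dict)

    @property
    def dt_s(self) -> float:
        return 1.0 / self.fs_hz


@dataclass
class DysfunctionSummary:
    nd: int
    ratio_max: float  # NaN when nd == 0
    intensity: float  # ratio·s above threshold
    delta: float


def band_frequency_grid(band: str, voices: int = VOICES_PER_OCTAVE) -> np.ndarray:
    """Log-spaced frequencies tiling a band with >= ``voices`` per octave."""
    lo, hi = BANDS_HZ[band]
    n = max(int(math.ceil(voices * math.log2(hi / lo))) + 1, 4)
    return np.geomspace(lo, hi, n)


def cwt(data: np.ndarray, scales: np.ndarray, wavelet: str = WAVELET,
        precision: int = 10) -> np.ndarray:
    """Continuous wavelet transform by the integrated-wavelet algorithm.

    W(a, b) = -sqrt(a) · d/db [ (x * Ψ_a)(b) ] where Ψ_a is the integral
    of the wavelet function resampled to scale ``a``. This formulation
    accepts any wavelet with a computable ψ — including discrete
    orthogonal bases such as the Coiflets — mirroring the classic
    MATLAB-style CWT. Returns an (n_scales, n_samples) real array.
    """
    data = np.asarray(data, dtype=float)
    wav = pywt.Wavelet(wavelet) if wavelet in pywt.wavelist(kind="discrete") \
        else pywt.ContinuousWavelet(wavelet)
    int_psi, x = pywt.integrate_wavelet(wav, precision=precision)
    int_psi = np.asarray(int_psi, dtype=float)
    step = x[1] - x[0]
    span = x[-1] - x[0]
    out = np.empty((len(scales), data.size))
    for i, a in enumerate(np.asarray(scales, dtype=float)):
        j = (np.arange(a * span + 1) / (a * step)).astype(int)
        j = j[j < int_psi.size]
        kernel = int_psi[j][::-1]
        conv = fftconvolve(data, kernel, mode="full")
        coef = -np.sqrt(a) * np.diff(conv)
        d = (coef.size - data.size) // 2
        out[i] = coef[d:d + data.size]
    return out


def cwt_band_series(tach: UniformTachogram, wavelet: str = WAVELET,
                    voices: int = VOICES_PER_OCTAVE) -> WaveletBandSeries:
    """CWT band-power time series of the mean-removed tachogram.

    Per-band instantaneous power is |W(f, t)|² integrated over the band's
    frequency grid (ms² per sample tick). Cone-of-influence samples at the
    record edges are retained.
    """
    x = tach.values_ms
    if (x.size - 1) / tach.fs_hz < 60.0:
        raise ValueError("record shorter than 60 s; wavelet analysis unreliable")
    fc = pywt.central_frequency(wavelet)
    grids = {band: band_frequency_grid(band, voices) for band in BANDS_HZ}
    # Analytic-signal quadrature: with a real wavelet, |W|^2 of a tone
    # oscillates through zero at twice the tone frequency; adding the CWT
    # of the Hilbert quadrature gives an envelope-like instantaneous power.
    centered = x - x.mean()
    quadrature = np.imag(hilbert(centered))
    power = {}
    for band, freqs in grids.items():
        scales = fc * tach.fs_hz / freqs
        coef2 = 0.5 * (cwt(centered, scales, wavelet) ** 2
                       + cwt(quadrature, scales, wavelet) ** 2)
        # integrate the squared magnitude across the band's frequency grid
        power[band] = np.trapezoid(coef2, freqs, axis=0)
    hf_t, lf_t, vlf_t = power["HF"], power["LF"], power["VLF"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = lf_t / hf_t
    ratio[hf_t < HF_FLOOR_REL * max(hf_t.mean(), np.finfo(float).tiny)] = np.nan
    return WaveletBandSeries(
        t_s=tach.times_s, hf_t=hf_t, lf_t=lf_t, vlf_t=vlf_t, ratio_t=ratio,
        fs_hz=tach.fs_hz,
        scales={band: fc * tach.fs_hz / grids[band] for band in grids},
    )


def wavelet_band_features(wbs: WaveletBandSeries) -> dict[str, float]:
    """Time-integrated band powers, normalized shares, LF/HF and band SDs."""
    dt = wbs.dt_s
    hf = float(np.sum(wbs.hf_t) * dt)
    lf = float(np.sum(wbs.lf_t) * dt)
    vlf = float(np.sum(wbs.vlf_t) * dt)
    tp = hf + lf + vlf
    nan = math.nan
    return {
        "HF(wt)": hf, "LF(wt)": lf, "VLF(wt)": vlf, "TP(wt)": tp,
        "HFn(wt)": hf / tp if tp > 0 else nan,
        "LFn(wt)": lf / tp if tp > 0 else nan,
        "VLFn(wt)": vlf / tp if tp > 0 else nan,
        "LF/HF(wt)": lf / hf if hf > 0 else nan,
        "SDHF(wt)": float(np.std(wbs.hf_t)),
        "SDLF(wt)": float(np.std(wbs.lf_t)),
        "SDVLF(wt)": float(np.std(wbs.vlf_t)),
    }


def detect_dysfunctions(ratio: np.ndarray, dt_s: float,
                        delta: float = DELTA_DEFAULT,
                        intensity_mode: str = "area") -> DysfunctionSummary:
    """Run-length scan of supra-threshold excursions of a ratio series.

    A dysfunction is a maximal contiguous run of finite samples with
    ratio > delta. With ``intensity_mode="area"`` (default) the intensity
    is the rectangle-rule area above the threshold, Σ (ratio − delta)·dt
    over supra-threshold samples; ``"mean"`` reports the mean
    supra-threshold ratio value instead. NaN samples terminate runs.
    """
    if intensity_mode not in ("area", "mean"):
        raise ValueError("intensity_mode must be 'area' or 'mean'")
    ratio = np.asarray(ratio, dtype=float)
    above = np.isfinite(ratio) & (ratio > delta)
    if not above.any():
        return DysfunctionSummary(nd=0, ratio_max=math.nan, intensity=0.0,
                                  delta=delta)
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    nd = starts.size
    if intensity_mode == "area":
        intensity = float(np.sum(ratio[above] - delta) * dt_s)
    else:
        intensity = float(np.mean(ratio[above]))
    return DysfunctionSummary(nd=int(nd), ratio_max=float(np.max(ratio[above])),
                              intensity=intensity, delta=delta)


def _smooth_nan_aware(x: np.ndarray, window: int) -> np.ndarray:
    """Moving average that ignores NaNs inside the window."""
    if window <= 1:
        return x
    kernel = np.ones(window)
    finite = np.isfinite(x)
    filled = np.where(finite, x, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def dysfunction_features(wbs: WaveletBandSeries, delta: float = DELTA_DEFAULT,
                         smooth_window_s: float = RATIO_SMOOTH_S,
                         intensity_mode: str = "area") -> DysfunctionSummary:
    """Dysfunction summary of the LF/HF ratio series.

    The ratio is smoothed with a ``smooth_window_s`` moving average before
    thresholding to suppress single-sample spikes from near-zero HF power
    (0 disables smoothing).
    """
    ratio = wbs.ratio_t
    if smooth_window_s > 0:
        ratio = _smooth_nan_aware(ratio, int(round(smooth_window_s * wbs.fs_hz)))
    return detect_dysfunctions(ratio, wbs.dt_s, delta,
                               intensity_mode=intensity_mode)


def wavelet_features(tach: UniformTachogram, delta: float = DELTA_DEFAULT
                     ) -> dict[str, float]:
    """All 14 wavelet-domain features of a tachogram, registry-named."""
    wbs = cwt_band_series(tach)
    feats = wavelet_band_features(wbs)
    dys = dysfunction_features(wbs, delta=delta)
    feats["(LF/HF)max"] = dys.ratio_max if dys.nd > 0 else 0.0
    feats["(LF/HF)int"] = dys.intensity
    feats["Nd"] = float(dys.nd)
    return feats
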