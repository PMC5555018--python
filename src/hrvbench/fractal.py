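"""Nonlinear scaling features: Hurst exponent and multifractal DFA.

The Hurst exponent is estimated by the aggregated-variance method: the RMS
spread of profile increments over a time span s scales as s^H, and H is
the log-log slope (H = 0.5 uncorrelated, > 0.5 persistent, < 0.5
antipersistent).

Multifractal detrended fluctuation analysis (MFDFA) generalizes this:
segment-wise second-order polynomial detrending of the profile yields
fluctuation functions F(q, s) whose log-log slopes give the generalized
Hurst exponents H_x(q) for q in [−5, 5]; τ(q) = q·H_x(q) − 1, and the
Legendre transform α = dτ/dq, D(α) = q·α − τ gives the singularity
spectrum. Scale bands follow the LF (6–25 s) and VLF (25–300 s)
oscillation periods; the HF band is excluded (too noisy to be
informative). Spectrum scalars: H0 (height, H_x(0)), H2 (correlation
degree, H_x(2)), α_min/α_max, width W = α_max − α_min, and the half-width
W_1/2 = |H2 − H0|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import NNSeries, UniformTachogram

Q_GRID = np.arange(-5.0, 5.01, 0.5)  # 21 points, step 0.5
SCALE_BANDS_S = {"LF": (6.0, 25.0), "VLF": (25.0, 300.0)}
MIN_SEGMENTS = 4
DETREND_ORDER = 2


@dataclass
class HurstEstimate:
    hurst: float
    scales: np.ndarray
    intercept: float
    r_squared: float


@dataclass
class MultifractalSpectrum:
    q_grid: np.ndarray
    scales_s: np.ndarray
    hx_q: np.ndarray
    tau_q: np.ndarray
    alpha: np.ndarray
    d_alpha: np.ndarray
    band: str
    meta: dict = field(default_factory=dict)

    @property
    def h0(self) -> float:
        return float(self.hx_q[np.argmin(np.abs(self.q_grid))])

    @property
    def h2(self) -> float:
        return float(self.hx_q[np.argmin(np.abs(self.q_grid - 2.0))])

    @property
    def alpha_min(self) -> float:
        return float(self.alpha.min())

    @property
    def alpha_max(self) -> float:
        return float(self.alpha.max())

    @property
    def width(self) -> float:
        return self.alpha_max - self.alpha_min

    @property
    def half_width(self) -> float:
        return abs(self.h2 - self.h0)


def hurst_aggregated_variance(nn: NNSeries | np.ndarray,
                              n_scales: int = 8) -> HurstEstimate:
    """Hurst exponent from the scaling of profile-increment spread.

    The profile X is the cumulative sum of the mean-removed series; for
    each aggregation span s (log-spaced between 10 samples and n/10) the
    RMS of the increments X(t+s) − X(t) is computed, and H is the
    least-squares slope of log σ_rms vs log s.
    """
    x = nn.intervals_ms if isinstance(nn, NNSeries) else np.asarray(nn, float)
    n = x.size
    if n < 256:
        raise ValueError("Hurst estimation needs >= 256 samples")
    profile = np.cumsum(x - x.mean())
    scales = np.unique(np.geomspace(10, n // 10, n_scales).astype(int))
    if scales.size < 5:
        raise ValueError("fewer than 5 usable aggregation scales")
    sigma = np.array([np.std(profile[s:] - profile[:-s]) for s in scales])
    if np.any(sigma <= 0):
        raise ValueError("degenerate (zero-spread) increments")
    log_s, log_sigma = np.log(scales), np.log(sigma)
    slope, intercept = np.polyfit(log_s, log_sigma, 1)
    fitted = slope * log_s + intercept
    ss_res = np.sum((log_sigma - fitted) ** 2)
    ss_tot = np.sum((log_sigma - log_sigma.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HurstEstimate(hurst=float(slope), scales=scales,
                         intercept=float(intercept), r_squared=float(r2))


def _fluctuations(profile: np.ndarray, scale: int) -> np.ndarray:
    """Per-segment detrended variance, segments taken from both record ends."""
    n = profile.size
    n_seg = n // scale
    t = np.arange(scale, dtype=float)
    f2 = np.empty(2 * n_seg)
    for v in range(n_seg):
        for j, seg in enumerate((profile[v * scale:(v + 1) * scale],
                                 profile[n - (v + 1) * scale:n - v * scale])):
            coef = np.polyfit(t, seg, DETREND_ORDER)
            resid = seg - np.polyval(coef, t)
            f2[2 * v + j] = np.mean(resid ** 2)
    return f2


def mfdfa(tach: UniformTachogram | np.ndarray, band: str = "LF",
          q_grid: np.ndarray = Q_GRID, fs_hz: float | None = None,
          scale_band_s: tuple[float, float] | None = None,
          n_scales: int = 12, both_ends: bool = True) -> MultifractalSpectrum:
    """Multifractal DFA of the tachogram over one scale band.

    ``band`` selects the LF (6–25 s) or VLF (25–300 s) scale range;
    ``scale_band_s`` overrides it. The maximal scale is capped so that at
    least 4 nonoverlapping segments exist (≈75 s on a 300 s record); the
    cap is recorded in ``meta``. Segments are taken from both the start
    and the end of the record so the tail remainder is used.
    """
    if isinstance(tach, UniformTachogram):
        x, fs = tach.values_ms, tach.fs_hz
    else:
        x = np.asarray(tach, dtype=float)
        fs = fs_hz if fs_hz is not None else 1.0
    lo_s, hi_s = scale_band_s if scale_band_s is not None else SCALE_BANDS_S[band]
    n = x.size
    s_min = max(int(round(lo_s * fs)), DETREND_ORDER + 2)
    s_max = min(int(round(hi_s * fs)), n // MIN_SEGMENTS)
    capped = s_max < int(round(hi_s * fs))
    if s_max < s_min or n // s_min < 2:
        raise ValueError(f"record too short for the {band} scale band")
    scales = np.unique(np.geomspace(s_min, s_max, n_scales).astype(int))
    if scales.size < 4:
        raise ValueError("fewer than 4 usable scales in the band")

    profile = np.cumsum(x - x.mean())
    q_grid = np.asarray(q_grid, dtype=float)
    log_f = np.empty((q_grid.size, scales.size))
    tiny = np.finfo(float).tiny
    any_positive = False
    for si, s in enumerate(scales):
        f2 = _fluctuations(profile, int(s))
        if not both_ends:
            f2 = f2[::2]
        if np.any(f2 > 0):
            any_positive = True
        f2 = np.maximum(f2, tiny)
        for qi, q in enumerate(q_grid):
            if abs(q) < 1e-12:
                log_f[qi, si] = 0.5 * np.mean(np.log(f2))
            else:
                log_f[qi, si] = np.log(np.mean(f2 ** (q / 2.0))) / q
    if not any_positive:
        raise ValueError("zero-variance segments at every scale")

    log_s = np.log(scales.astype(float))
    hx = np.polyfit(log_s, log_f.T, 1)[0]
    tau = q_grid * hx - 1.0
    alpha = np.gradient(tau, q_grid)  # central differences, one-sided ends
    d_alpha = q_grid * alpha - tau
    return MultifractalSpectrum(
        q_grid=q_grid, scales_s=scales / fs, hx_q=hx, tau_q=tau,
        alpha=alpha, d_alpha=d_alpha, band=band,
        meta={"scale_cap_applied": bool(capped),
              "max_scale_s": float(scales[-1] / fs),
              "segments_from_both_ends": both_ends},
    )


def spectrum_features(ms: MultifractalSpectrum) -> dict[str, float]:
    """Band-suffixed scalar features of one multifractal spectrum."""
    b = ms.band
    return {
        f"αmin{b}": ms.alpha_min,
        f"αmax{b}": ms.alpha_max,
        f"W{b}": ms.width,
        f"H2{b}": ms.h2,
        f"H0{b}": ms.h0,
        f"W1/2{b}": ms.half_width,
    }


def fractal_features(nn: NNSeries, tach: UniformTachogram) -> dict[str, float]:
    """Hurst exponent (beat domain) plus both MFDFA band spectra (13 features)."""
    feats = {"H": hurst_aggregated_variance(nn).hurst}
    for band in ("LF", "VLF"):
        feats.update(spectrum_features(mfdfa(tach, band=band)))
    return feats
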