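"""Artifact rejection and uniform resampling of RR series.

An artifact is any R-R interval deviating from the series mean by more
than three standard deviations; mean and SD are computed once over the raw
series (single pass, not iterated after removals). The cleaned NN series
is then interpolated with a natural cubic spline onto a uniform 10 Hz grid
to form the tachogram used by the spectral, wavelet and multifractal
stages.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .series import NNSeries, RRSeries, UniformTachogram

DEFAULT_FS_HZ = 10.0


def reject_artifacts(rr: RRSeries, n_sd: float = 3.0) -> NNSeries:
    """Remove beats with |x − mean| > n_sd·SD (single-pass statistics).

    A constant series (SD = 0) keeps all beats. Beat times of the cleaned
    series are cumulative sums of the *kept* intervals: removed beats'
    durations are excised, not bridged.

    Raises
    ------
    ValueError
        If the series has fewer than 4 beats, or every beat is rejected.
    """
    x = rr.intervals_ms
    if x.size < 4:
        raise ValueError("artifact rejection needs >= 4 intervals")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        mask = np.ones(x.size, dtype=bool)
    else:
        mask = np.abs(x - mean) <= n_sd * sd
    if mask.sum() < 2:
        raise ValueError("artifact rejection removed (nearly) all beats")
    kept = x[mask]
    beat_times = np.cumsum(kept) / 1000.0
    return NNSeries(
        intervals_ms=kept,
        beat_times_s=beat_times,
        rejection_mask=mask,
        meta={
            "subject_id": rr.subject_id,
            "label": rr.label,
            "n_raw": int(x.size),
            "n_removed": int(x.size - mask.sum()),
            "rule": f"|x - mean| > {n_sd}*SD, single pass",
        },
    )


def interpolate_uniform(nn: NNSeries, fs_hz: float = DEFAULT_FS_HZ) -> UniformTachogram:
    """Natural cubic spline of NN value vs beat time on a uniform grid.

    The grid is anchored at the first beat time and never extrapolates
    beyond the last knot.
    """
    if nn.n < 4:
        raise ValueError("cubic spline interpolation needs >= 4 NN intervals")
    t = nn.beat_times_s
    spline = CubicSpline(t, nn.intervals_ms, bc_type="natural")
    n_samples = int(np.floor((t[-1] - t[0]) * fs_hz)) + 1
    grid = t[0] + np.arange(n_samples) / fs_hz
    return UniformTachogram(
        fs_hz=fs_hz, t0_s=float(t[0]), values_ms=spline(grid),
        meta=dict(nn.meta),
    )
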