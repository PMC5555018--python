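"""Time-domain HRV features: statistical moments and Baevsky geometric indices.

Statistical block: mean NN (M), heart rate, SDNN, coefficient of variation,
RMSSD and NN50. Geometric block: the NN-histogram mode (M0), mode amplitude
(AM0), variation range (VR), and the derived regulation indices SI
(Baevsky stress index), IAB, ARI and IARP.

Conventions that matter downstream:

* RMSSD divides the sum of the N−1 squared successive differences by N
  (not N−1) — kept as the source formulation of this feature bank.
* HR is reported in beats/min (60000 / M with M in ms); any strictly
  monotone rescaling of 1/M leaves classifier behaviour untouched.
* M0 and VR enter the geometric indices in seconds, which puts SI in the
  conventional Baevsky range.
"""

from __future__ import annotations

import math

import numpy as np

from .series import NNSeries

MODE_BIN_WIDTH_MS = 50.0


def statistical_features(nn: NNSeries) -> dict[str, float]:
    """M, HR, SDNN, CV, RMSSD, NN50 of the cleaned NN series."""
    x = nn.intervals_ms
    if x.size < 2:
        raise ValueError("statistical features need >= 2 NN intervals")
    m = float(x.mean())
    sdnn = float(x.std(ddof=1))
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.sum(diffs ** 2) / x.size))
    return {
        "M": m,
        "HR": 60000.0 / m,
        "SDNN": sdnn,
        "CV": 100.0 * sdnn / m,
        "RMSSD": rmssd,
        "NN50": float(np.sum(np.abs(diffs) > 50.0)),
    }


def histogram_mode(nn: NNSeries, bin_width_ms: float = MODE_BIN_WIDTH_MS
                   ) -> tuple[float, float, float]:
    """Mode (s), mode amplitude (% of beats) and variation range (s).

    Histogram bins of fixed width anchored at the series minimum; the mode
    is the center of the tallest bin (ties broken toward the lower bin).
    A constant series is degenerate (single value): the mode is the value
    itself, AM0 = 100 %, VR = 0.
    """
    x = nn.intervals_ms
    if x.size < 2:
        raise ValueError("histogram features need >= 2 NN intervals")
    lo, hi = float(x.min()), float(x.max())
    vr_s = (hi - lo) / 1000.0
    if hi == lo:
        return lo / 1000.0, 100.0, 0.0
    n_bins = int(math.ceil((hi - lo) / bin_width_ms))
    edges = lo + bin_width_ms * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    imax = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    m0_s = (edges[imax] + bin_width_ms / 2.0) / 1000.0
    am0_pct = 100.0 * counts[imax] / x.size
    return m0_s, am0_pct, vr_s


def geometric_indices(m0_s: float, am0_pct: float, vr_s: float
                      ) -> dict[str, float]:
    """Baevsky regulation indices from the histogram summary.

    SI = AM0 / (2·M0·VR), IAB = AM0/VR, ARI = 1/(M0·VR), IARP = AM0/M0.
    When VR = 0 the three VR-dividing indices are undefined and reported
    as NaN; IARP stays finite.
    """
    if m0_s <= 0:
        raise ValueError("M0 must be positive")
    if vr_s < 0:
        raise ValueError("VR must be nonnegative")
    if vr_s == 0.0:
        return {"SI": math.nan, "IAB": math.nan, "ARI": math.nan,
                "IARP": am0_pct / m0_s}
    return {
        "SI": am0_pct / (2.0 * m0_s * vr_s),
        "IAB": am0_pct / vr_s,
        "ARI": 1.0 / (m0_s * vr_s),
        "IARP": am0_pct / m0_s,
    }


def timedomain_features(nn: NNSeries) -> dict[str, float]:
    """All 13 time-domain features keyed by their registry names."""
    feats = statistical_features(nn)
    m0, am0, vr = histogram_mode(nn)
    feats.update({"M0": m0, "VR": vr, "AM0": am0})
    feats.update(geometric_indices(m0, am0, vr))
    return feats
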