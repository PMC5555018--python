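"""Core beat-series containers.

An :class:`RRSeries` holds raw beat-to-beat (R-R) intervals for one subject;
:class:`NNSeries` is the artifact-cleaned ("normal-to-normal") version, and
:class:`UniformTachogram` is the NN value resampled on a uniform time grid so
that Fourier, wavelet and detrended-fluctuation machinery can treat it as an
evenly sampled signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class RRSeries:
    """Raw beat-to-beat intervals for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    label : str
        Class label (e.g. ``"healthy"`` / ``"patient"``).
    intervals_ms : ndarray
        Ordered positive R-R durations in milliseconds.
    state : str
        Recording-state tag; ``"O"`` denotes passive orthostatic load.
    meta : dict
        Free-form provenance (generator parameters, injected-artifact
        positions, ...).
    """

    subject_id: str
    label: str
    intervals_ms: np.ndarray
    state: str = "O"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.intervals_ms.ndim != 1 or self.intervals_ms.size < 2:
            raise ValueError("intervals_ms must be a 1-d array with >= 2 beats")
        if not np.all(self.intervals_ms > 0):
            raise ValueError("all R-R intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def duration_s(self) -> float:
        return float(self.intervals_ms.sum() / 1000.0)


@dataclass
class NNSeries:
    """Artifact-cleaned intervals plus beat times of the kept beats.

    ``beat_times_s`` are cumulative sums of the *kept* intervals (removed
    beats' durations are excised, not bridged). ``rejection_mask`` has one
    flag per original beat: True = kept.
    """

    intervals_ms: np.ndarray
    beat_times_s: np.ndarray
    rejection_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rejection_mask = np.asarray(self.rejection_mask, dtype=bool)
        if self.intervals_ms.size != int(self.rejection_mask.sum()):
            raise ValueError("kept-interval count must equal number of True flags")
        if self.intervals_ms.size < 2:
            raise ValueError("NN series needs >= 2 intervals")
        if self.beat_times_s.size != self.intervals_ms.size:
            raise ValueError("beat_times_s must align with intervals_ms")

    @property
    def n(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def rejected_fraction(self) -> float:
        return float(1.0 - self.rejection_mask.mean())


@dataclass
class UniformTachogram:
    """NN value on a uniform time grid (cubic-spline interpolant).

    ``values_ms[i]`` is the interpolated R-R duration at time
    ``t0_s + i / fs_hz``.
    """

    fs_hz: float
    t0_s: float
    values_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.values_ms.ndim != 1 or self.values_ms.size < 2:
            raise ValueError("tachogram needs >= 2 samples")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values_ms.size) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return float((self.values_ms.size - 1) / self.fs_hz)


def read_rr_file(path: str | Path, subject_id: str | None = None,
                 label: str = "", state: str = "O") -> RRSeries:
    """Read a plain-text RR file: one positive interval (ms) per line.

    A single non-numeric first line is treated as a header and skipped; any
    other non-numeric or non-positive value raises with its line number.
    """
    path = Path(path)
    intervals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            try:
                value = float(text)
            except ValueError:
                if lineno == 1 and not intervals:
                    continue  # header line
                raise ValueError(
                    f"{path}: line {lineno}: not a number: {text!r}"
                ) from None
            if value <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive interval {value}")
            intervals.append(value)
    return RRSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        label=label,
        intervals_ms=np.asarray(intervals, dtype=float),
        state=state,
    )


def write_rr_file(series: RRSeries, path: str | Path) -> None:
    """Write one interval (ms) per line with stable formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for v in series.intervals_ms:
            fh.write(f"{v:.6f}\n")
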