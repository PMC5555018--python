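"""Synthetic RR-interval cohort generator.

Emulates two short-term (~300 s) recording cohorts — a "healthy" and a
"patient" group — with controlled mean heart rate, VLF/LF/HF band-power
composition, long-range (Hurst) scaling and injectable measurement
artifacts, so every downstream stage of the pipeline can be exercised
without clinical data.

Signal model: instantaneous RR(t) = mean_rr + Σ_band A_band·sin(2π f_band t
+ φ_band) + fractional-Gaussian noise with a target Hurst exponent,
evaluated at beat times (each beat advances time by the current RR). This
deliberately skips any cardiac mechanism (no integral-pulse model): the
downstream features only require band structure and scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .series import RRSeries, write_rr_file

BANDS_HZ = {"VLF": (0.003, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

_DEFAULT_MEAN_RR = {"healthy": 850.0, "patient": 700.0}
# Healthy: strong respiratory (HF) component; patient: blunted HF, raised
# VLF share and LF/HF — the band-composition contrast the analysis targets.
_DEFAULT_AMPLITUDE = {
    "healthy": {"VLF": 25.0, "LF": 30.0, "HF": 35.0},
    "patient": {"VLF": 35.0, "LF": 25.0, "HF": 12.0},
}
_DEFAULT_HURST = {"healthy": 0.7, "patient": 0.85}


class SpecValidationError(ValueError):
    """Raised when a CohortSpec field is out of range; names the field."""


@dataclass
class CohortSpec:
    """Parameters of a two-class synthetic cohort.

    Per-class fields are dicts keyed by class label. Band dicts are keyed
    by "VLF"/"LF"/"HF". All amplitudes in milliseconds.
    """

    n_per_class: dict = field(
        default_factory=lambda: {"healthy": 30, "patient": 40})
    duration_s: float = 300.0
    mean_rr_ms: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN_RR))
    amplitude_ms: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_AMPLITUDE.items()})
    band_center_hz: dict = field(
        default_factory=lambda: {"VLF": 0.01, "LF": 0.10, "HF": 0.25})
    noise_sd_ms: float = 10.0
    hurst_target: dict = field(default_factory=lambda: dict(_DEFAULT_HURST))
    artifact_fraction: float = 0.0
    artifact_scale: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        for label, count in self.n_per_class.items():
            if count < 0 or int(count) != count:
                raise SpecValidationError(f"n_per_class[{label!r}] must be a nonnegative integer")
        if self.duration_s <= 0:
            raise SpecValidationError("duration_s must be positive")
        for label, rr in self.mean_rr_ms.items():
            if rr <= 0:
                raise SpecValidationError(f"mean_rr_ms[{label!r}] must be positive")
        for label, bands in self.amplitude_ms.items():
            for band, amp in bands.items():
                if amp < 0:
                    raise SpecValidationError(f"amplitude_ms[{label!r}][{band!r}] must be nonnegative")
        for band, f in self.band_center_hz.items():
            lo, hi = BANDS_HZ[band]
            if not (lo <= f <= hi):
                raise SpecValidationError(
                    f"band_center_hz[{band!r}]={f} outside the {band} band [{lo}, {hi}] Hz")
        if self.noise_sd_ms < 0:
            raise SpecValidationError("noise_sd_ms must be nonnegative")
        for label, h in self.hurst_target.items():
            if not (0.0 < h < 1.0):
                raise SpecValidationError(f"hurst_target[{label!r}] must lie in (0, 1)")
        if not (0.0 <= self.artifact_fraction < 0.5):
            raise SpecValidationError("artifact_fraction must lie in [0, 0.5)")
        if self.artifact_fraction > 0 and self.artifact_scale <= 3:
            raise SpecValidationError("artifact_scale must exceed 3")

    @property
    def labels(self) -> list[str]:
        return list(self.n_per_class)


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies–Harte).

    Returns ``n`` samples of zero-mean, unit-variance fGn with Hurst
    exponent ``hurst``. The fGn autocovariance embeds in a nonnegative
    circulant for all H in (0, 1), so the method is exact in distribution.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst)
                   - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    # First row of the 2n-circulant embedding the Toeplitz covariance.
    row = np.concatenate([gamma, [0.0], gamma[1:][::-1]])
    eig = np.fft.fft(row).real
    eig = np.maximum(eig, 0.0)  # clip tiny negative round-off
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    sample = np.fft.fft(np.sqrt(eig / (2 * m)) * z)
    return sample.real[:n] * np.sqrt(2.0)


def generate_rr_series(spec: CohortSpec, class_label: str, seed: int,
                       subject_id: str | None = None) -> RRSeries:
    """Generate one subject's beat sequence under ``spec`` for a class.

    Beat times advance by the current RR interval; the series spans at
    least ``spec.duration_s`` (the final beat may overshoot and is kept).
    Deterministic given ``seed``.
    """
    spec.validate()
    if class_label not in spec.n_per_class:
        raise SpecValidationError(f"unknown class_label {class_label!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mean_rr = spec.mean_rr_ms[class_label]
    amps = spec.amplitude_ms[class_label]
    hurst = spec.hurst_target[class_label]
    phases = {band: rng.uniform(0, 2 * np.pi) for band in ("VLF", "LF", "HF")}

    # Upper bound on beat count: shortest plausible interval with margin.
    max_beats = int(np.ceil(spec.duration_s * 1000.0 / mean_rr * 2.0)) + 16
    noise = (fgn(max_beats, hurst, rng) * spec.noise_sd_ms
             if spec.noise_sd_ms > 0 else np.zeros(max_beats))

    intervals = np.empty(max_beats)
    t = 0.0
    i = 0
    floor_ms = max(0.1 * mean_rr, 100.0)
    while t < spec.duration_s and i < max_beats:
        rr = mean_rr + noise[i]
        for band, amp in amps.items():
            f = spec.band_center_hz[band]
            rr += amp * np.sin(2 * np.pi * f * t + phases[band])
        rr = max(rr, floor_ms)  # physiological positivity guard
        intervals[i] = rr
        t += rr / 1000.0
        i += 1
    if subject_id is None:
        subject_id = f"{class_label}_{seed}"
    return RRSeries(
        subject_id=subject_id, label=class_label,
        intervals_ms=intervals[:i].copy(),
        meta={"seed": seed, "hurst_target": hurst},
    )


def generate_cohort(spec: CohortSpec):
    """Generate the full labeled cohort.

    Returns ``(series_list, manifest)`` where manifest is a list of dicts
    with keys ``subject_id`` and ``label``. Per-subject seeds are derived
    reproducibly from ``spec.seed`` via a spawned SeedSequence.
    """
    import pandas as pd

    spec.validate()
    series: list[RRSeries] = []
    rows = []
    root = np.random.SeedSequence(spec.seed)
    children = iter(root.spawn(sum(int(n) for n in spec.n_per_class.values()) or 1))
    for label in spec.labels:
        for j in range(int(spec.n_per_class[label])):
            child = next(children)
            sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
            sid = f"{label}_{j:03d}"
            s = generate_rr_series(spec, label, sub_seed, subject_id=sid)
            if spec.artifact_fraction > 0:
                s = inject_artifacts(s, spec.artifact_fraction,
                                     spec.artifact_scale, sub_seed + 1)
            series.append(s)
            rows.append({"subject_id": sid, "label": label})
    manifest = pd.DataFrame(rows, columns=["subject_id", "label"])
    return series, manifest


def inject_artifacts(series: RRSeries, fraction: float, scale: float,
                     seed: int) -> RRSeries:
    """Replace ``floor(fraction*N)`` random beats with mean ± scale·SD outliers.

    The affected positions are recorded in ``meta['artifact_positions']`` so
    tests can check that downstream rejection recovers them. ``fraction=0``
    returns the series unchanged.
    """
    if not (0.0 <= fraction < 0.5):
        raise SpecValidationError("fraction must lie in [0, 0.5)")
    if fraction == 0.0:
        return series
    if scale <= 3:
        raise SpecValidationError("scale must exceed 3 (rejection threshold)")
    rng = np.random.default_rng(seed)
    x = series.intervals_ms.copy()
    n_art = int(np.floor(fraction * x.size))
    positions = rng.choice(x.size, size=n_art, replace=False)
    mean, sd = x.mean(), x.std(ddof=1)
    sd = max(sd, 1.0)  # SD floor so artifacts exist even on constant series
    signs = rng.choice([-1.0, 1.0], size=n_art)
    x[positions] = np.maximum(mean + signs * scale * sd, 1.0)
    meta = dict(series.meta)
    meta["artifact_positions"] = np.sort(positions)
    return RRSeries(subject_id=series.subject_id, label=series.label,
                    intervals_ms=x, state=series.state, meta=meta)


def write_cohort(series, manifest, out_dir: str | Path) -> Path:
    """Write one RR text file per subject plus a manifest CSV.

    Manifest columns: subject_id, label, file (relative path). Returns the
    manifest path. Byte-identical output for identical spec+seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    files = []
    for s in series:
        rel = f"{s.subject_id}.txt"
        write_rr_file(s, out_dir / rel)
        files.append(rel)
    manifest["file"] = files
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
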