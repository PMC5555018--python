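"""Pipeline glue: configuration, per-subject feature extraction, table I/O.

`extract_features` runs cleaning → time-domain → Fourier → wavelet →
fractal per subject and assembles the cohort feature table (one row per
subject, the 52 registry columns). `HRVFeatureExtractor` exposes the same
stage as a scikit-learn transformer so the extraction composes with
sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import fractal, spectral, timedomain, wavelet
from .preprocess import reject_artifacts, interpolate_uniform
from .registry import FEATURE_NAMES, FEATURE_REGISTRY
from .series import RRSeries, read_rr_file

logger = logging.getLogger("hrvbench")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with paper-faithful defaults."""

    fs_hz: float = 10.0
    artifact_n_sd: float = 3.0
    mode_bin_width_ms: float = 50.0
    welch_segment_s: float = 150.0
    cwt_wavelet: str = "coif5"
    cwt_voices: int = 8
    dysfunction_delta: float = 10.0
    dysfunction_smooth_s: float = 1.0
    corr_threshold: float = 0.25
    corr_method: str = "pearson"
    cv_folds: int = 5
    cv_repeats: int = 100
    scale_features: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_STAGE_NAMES = {
    stage: tuple(d.name for d in FEATURE_REGISTRY if d.stage == stage)
    for stage in ("timedomain", "spectral", "wavelet", "fractal")
}


def extract_subject_features(rr: RRSeries, config: RunConfig | None = None
                             ) -> dict[str, float]:
    """All 52 features of one subject's RR series.

    Cleaning and resampling failures abort the subject; a failure inside a
    single feature stage (e.g. degenerate scaling on a constant series)
    fills that stage's features with NaN and the row survives with flags.
    """
    config = config or RunConfig()
    nn = reject_artifacts(rr, n_sd=config.artifact_n_sd)
    tach = interpolate_uniform(nn, fs_hz=config.fs_hz)
    stages = {
        "timedomain": lambda: timedomain.timedomain_features(nn),
        "spectral": lambda: spectral.spectral_features(
            tach, segment_s=config.welch_segment_s),
        "wavelet": lambda: wavelet.wavelet_features(
            tach, delta=config.dysfunction_delta),
        "fractal": lambda: fractal.fractal_features(nn, tach),
    }
    feats: dict[str, float] = {}
    for stage, run in stages.items():
        try:
            feats.update(run())
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("subject=%s stage=%s degraded: %s",
                           rr.subject_id, stage, exc)
            feats.update({name: float("nan") for name in _STAGE_NAMES[stage]})
    logger.info("subject=%s kept=%d removed=%d",
                rr.subject_id, nn.n, nn.meta.get("n_removed", 0))
    return feats


def extract_features(series: list[RRSeries] | None = None,
                     manifest: pd.DataFrame | None = None,
                     data_dir: str | Path | None = None,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Cohort feature table: subject_id, label, then the 52 registry columns.

    Input is either an in-memory list of :class:`RRSeries` or a manifest
    DataFrame (columns subject_id, label, file) with ``data_dir``.
    Per-subject failures are collected and logged; the run continues. An
    empty result is an error.
    """
    config = config or RunConfig()
    if series is None:
        if manifest is None or data_dir is None:
            raise ValueError("provide either series or (manifest, data_dir)")
        series = [read_rr_file(Path(data_dir) / row.file,
                               subject_id=row.subject_id, label=row.label)
                  for row in manifest.itertuples()]
    rows = []
    errors: dict[str, str] = {}
    for s in series:
        try:
            feats = extract_subject_features(s, config)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            errors[s.subject_id] = str(exc)
            logger.warning("subject=%s failed: %s", s.subject_id, exc)
            continue
        row = {"subject_id": s.subject_id, "label": s.label}
        row.update({name: feats[name] for name in FEATURE_NAMES})
        rows.append(row)
    if not rows:
        raise ValueError(f"no subject produced features (errors: {errors})")
    table = pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])
    table.attrs["config_hash"] = config.config_hash
    table.attrs["errors"] = errors
    return table


class HRVFeatureExtractor(BaseEstimator, TransformerMixin):
    """scikit-learn transformer over lists of RR series.

    ``transform`` maps a list of :class:`RRSeries` to the (n_subjects, 52)
    feature matrix in registry column order; ``fit`` is stateless apart
    from recording the output feature names. Parameters mirror
    :class:`RunConfig`.
    """

    def __init__(self, fs_hz: float = 10.0, artifact_n_sd: float = 3.0,
                 welch_segment_s: float = 150.0,
                 dysfunction_delta: float = 10.0):
        self.fs_hz = fs_hz
        self.artifact_n_sd = artifact_n_sd
        self.welch_segment_s = welch_segment_s
        self.dysfunction_delta = dysfunction_delta

    def _config(self) -> RunConfig:
        return RunConfig(fs_hz=self.fs_hz, artifact_n_sd=self.artifact_n_sd,
                         welch_segment_s=self.welch_segment_s,
                         dysfunction_delta=self.dysfunction_delta)

    def fit(self, X, y=None):
        self.feature_names_out_ = list(FEATURE_NAMES)
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        config = self._config()
        rows = [
            [extract_subject_features(s, config)[name] for name in FEATURE_NAMES]
            for s in X
        ]
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing registry columns: {sorted(missing)[:5]}")
    return table
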