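import numpy as np
import pandas as pd
import pytest

import hrvbench as hb
from hrvbench.series import UniformTachogram


def single_band_spec(band: str, amplitude: float = 30.0,
                     mean_rr: float = 800.0, noise_sd: float = 0.0,
                     hurst: float = 0.5) -> hb.CohortSpec:
    """Cohort spec with energy in exactly one spectral band."""
    amps = {"VLF": 0.0, "LF": 0.0, "HF": 0.0}
    amps[band] = amplitude
    return hb.CohortSpec(
        n_per_class={"x": 1}, mean_rr_ms={"x": mean_rr},
        amplitude_ms={"x": amps}, hurst_target={"x": hurst},
        noise_sd_ms=noise_sd,
    )


def tachogram_from_values(values: np.ndarray, fs: float = 10.0) -> UniformTachogram:
    return UniformTachogram(fs_hz=fs, t0_s=0.0, values_ms=np.asarray(values, float))


@pytest.fixture(scope="session")
def healthy_series() -> hb.RRSeries:
    spec = hb.CohortSpec(n_per_class={"healthy": 1, "patient": 1})
    return hb.generate_rr_series(spec, "healthy", 42)


@pytest.fixture(scope="session")
def small_cohort_table() -> pd.DataFrame:
    """8 + 8 subject cohort feature table (session-cached; ~3 s)."""
    spec = hb.CohortSpec(n_per_class={"healthy": 8, "patient": 8}, seed=7)
    series, _ = hb.generate_cohort(spec)
    return hb.extract_features(series)


@pytest.fixture(scope="session")
def blob_table() -> pd.DataFrame:
    """Two well-separated Gaussian blobs, 30 + 40 subjects, 4 features."""
    rng = np.random.default_rng(1)
    x = np.vstack([0.25 * rng.standard_normal((30, 4)),
                   0.25 * rng.standard_normal((40, 4)) + 2.0])
    table = pd.DataFrame(x, columns=["a", "b", "c", "d"])
    table["label"] = ["healthy"] * 30 + ["patient"] * 40
    return table
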