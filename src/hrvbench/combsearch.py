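"""Correlation-filtered enumeration of n-feature combinations.

Redundant (correlated) features carry no joint information and can
mislead classifiers, so before any model is trained the feature space is
screened: only size-n subsets (n = 2…5) whose members are *pairwise*
noncorrelated — |Pearson r| below a threshold (default 0.25) — are kept.
The enumeration is incremental: a subset is only ever extended by features
compatible with every current member, so the full C(n_features, 5) space
is never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from pathlib import Path

import numpy as np
import pandas as pd

CORR_THRESHOLD = 0.25
COMBINATION_SIZES = (2, 3, 4, 5)


@dataclass(frozen=True)
class Combination:
    """An accepted feature subset with its worst pairwise correlation."""

    feature_names: tuple[str, ...]
    max_abs_corr: float

    @property
    def n(self) -> int:
        return len(self.feature_names)


def correlation_matrix(table: pd.DataFrame, method: str = "pearson"
                       ) -> pd.DataFrame:
    """Feature-by-feature correlation over subjects, pairwise-complete.

    Zero-variance (degenerate) columns get NaN correlations and are
    thereby excluded from combinations downstream.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[0] < 3:
        raise ValueError("correlation needs >= 3 subjects")
    corr = numeric.corr(method=method)  # pairwise-complete by construction
    degenerate = numeric.std(ddof=1) == 0.0
    for col in numeric.columns[degenerate]:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def count_total_combinations(n_features: int, n: int) -> int:
    """Exact binomial count C(n_features, n)."""
    if n < 0 or n > n_features:
        raise ValueError(f"cannot choose {n} from {n_features} features")
    return math.comb(n_features, n)


def enumerate_noncorrelated(corr: pd.DataFrame, n: int,
                            threshold: float = CORR_THRESHOLD
                            ) -> list[Combination]:
    """All size-n subsets whose every pair has |r| < threshold.

    Features are kept in the correlation matrix's column order and each
    accepted subset is emitted in that canonical order. Degenerate
    features (NaN correlations) never enter a subset.
    """
    if not (2 <= n <= 5):
        raise ValueError("combination size must be between 2 and 5")
    names = list(corr.columns)
    absr = np.abs(corr.to_numpy(dtype=float))
    m = len(names)
    # compat[i, j]: pair (i, j) may share a subset
    compat = (absr < threshold) & np.isfinite(absr)
    np.fill_diagonal(compat, False)

    out: list[Combination] = []

    def extend(members: list[int], allowed: np.ndarray, worst: float) -> None:
        if len(members) == n:
            out.append(Combination(tuple(names[i] for i in members), worst))
            return
        last = members[-1] if members else -1
        for j in range(last + 1, m):
            if members and not allowed[j]:
                continue
            pair_worst = worst
            if members:
                pair_worst = max(worst, float(np.max(absr[members, j])))
            extend(members + [j], allowed & compat[j] if members else compat[j],
                   pair_worst)

    extend([], np.ones(m, dtype=bool), 0.0)
    return out


def write_combinations(combos: list[Combination], path: str | Path) -> None:
    """CSV with one row per combination: n, feature names, max |r|."""
    rows = [{"n": c.n, "features": ";".join(c.feature_names),
             "max_abs_corr": c.max_abs_corr} for c in combos]
    pd.DataFrame(rows, columns=["n", "features", "max_abs_corr"]).to_csv(
        path, index=False)


def read_combinations(path: str | Path) -> list[Combination]:
    df = pd.read_csv(path)
    return [Combination(tuple(str(r.features).split(";")), float(r.max_abs_corr))
            for r in df.itertuples()]
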