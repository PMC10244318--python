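"""Contact-map quality diagnostics: lag-1 autocorrelation noise and depth sweeps.

The noise statistic is computed on the distance-normalized (observed/expected)
map: for each row of a representative region the Pearson autocorrelation at
lag 1 is taken, the per-row values are averaged, and noise is defined as
``(mean ACF - 1) * -1`` — 0 for perfectly smooth rows, 1 for independent
noise, 2 for strictly alternating rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDomainError
from .io import ContactMatrix, subsample_contacts

__all__ = ["NoiseReport", "noise_estimate", "depth_sweep"]


@dataclass
class NoiseReport:
    """Lag-1 ACF noise summary over a bin-range region."""

    region: tuple[int, int]
    row_acf: np.ndarray
    mean_acf: float
    noise: float
    n_rows_used: int


def _lag1_acf(row: np.ndarray) -> float:
    a, b = row[:-1], row[1:]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def noise_estimate(oe: ContactMatrix, region: tuple[int, int]) -> NoiseReport:
    """Noise of an O/E map over bins ``[region[0], region[1])``.

    Rows are the dense O/E vectors of the region submatrix (absent cells are
    genuine zeros). Rows with fewer than 3 entries or zero variance are
    excluded from the mean rather than contributing NaN.
    """
    lo, hi = region
    if not (0 <= lo < hi <= oe.n_bins):
        raise ValueError(f"region {region} outside [0, {oe.n_bins}]")
    sub = oe.symmetric()[lo:hi, lo:hi].toarray()
    acfs = np.array([_lag1_acf(sub[r]) for r in range(sub.shape[0])])
    usable = np.isfinite(acfs)
    if not usable.any():
        raise EmptyDomainError("no rows with computable lag-1 ACF")
    mean_acf = float(acfs[usable].mean())
    return NoiseReport(
        region=(lo, hi),
        row_acf=acfs,
        mean_acf=mean_acf,
        noise=(mean_acf - 1.0) * -1.0,
        n_rows_used=int(usable.sum()),
    )


def depth_sweep(
    m: ContactMatrix,
    depths: Sequence[int],
    seeds: Sequence[int],
    analysis: Callable[[ContactMatrix], float],
) -> pd.DataFrame:
    """Apply an analysis to subsampled maps across depths and seeds.

    Returns one row per depth with the median, mean, and spread of the
    analysis value over seeds. Depths at which the analysis fails (e.g. an
    empty map) are reported with NaN, never silently dropped.
    """
    rows = []
    for depth in depths:
        vals = []
        for seed in seeds:
            try:
                sub = subsample_contacts(m, depth, seed)
                vals.append(float(analysis(sub)))
            except Exception:
                vals.append(np.nan)
        arr = np.array(vals)
        ok = np.isfinite(arr)
        rows.append(
            {
                "depth": depth,
                "median": float(np.median(arr[ok])) if ok.any() else np.nan,
                "mean": float(arr[ok].mean()) if ok.any() else np.nan,
                "std": float(arr[ok].std()) if ok.any() else np.nan,
                "n_ok": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
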