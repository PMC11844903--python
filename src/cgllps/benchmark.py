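"""Model-vs-experiment benchmark metrics on logarithmic scales.

Saturation concentrations and viscosities span orders of magnitude, so
deviations are taken between base-10 logarithms:

    D_rel = (1/n) sum_k |log10 x_exp,k - log10 x_sim,k| / |log10 x_exp,k|
    D_rms = sqrt( (1/n) sum_k (log10 x_exp,k - log10 x_sim,k)^2 )

The relative form is undefined where x_exp = 1 (log10 x_exp = 0); those
points are rejected explicitly rather than silently skewing the average.
Experimental values measured under different conditions or in different
units are first normalised per source against a shared reference variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class BenchmarkError(ValueError):
    pass


def _as_positive_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise BenchmarkError(f"{name} must be a non-empty 1-D array")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise BenchmarkError(f"{name} must be finite and strictly positive")
    return arr


def relative_log_deviation(experimental, simulated) -> float:
    """Mean relative deviation of log10 values (dimensionless)."""
    e = _as_positive_array(experimental, "experimental")
    s = _as_positive_array(simulated, "simulated")
    if len(e) != len(s):
        raise BenchmarkError("experimental and simulated arrays differ in length")
    le, ls = np.log10(e), np.log10(s)
    if np.any(le == 0):
        raise BenchmarkError(
            "relative log deviation undefined where the experimental value is 1 "
            "(log10 = 0); rescale units or drop those points"
        )
    return float(np.mean(np.abs(le - ls) / np.abs(le)))


def rms_log_deviation(experimental, simulated) -> float:
    """Root-mean-square deviation of log10 values (decades)."""
    e = _as_positive_array(experimental, "experimental")
    s = _as_positive_array(simulated, "simulated")
    if len(e) != len(s):
        raise BenchmarkError("experimental and simulated arrays differ in length")
    return float(np.sqrt(np.mean((np.log10(e) - np.log10(s)) ** 2)))


def normalize_by_reference(
    table: pd.DataFrame,
    value_column: str,
    reference_id: str,
    id_column: str = "variant",
    source_column: str = "source",
) -> pd.DataFrame:
    """Divide each source's values by that source's reference-variant value.

    Measurements reported by different laboratories (different buffers,
    temperatures, or units) become comparable as ratios to a shared
    reference variant measured within the same source.  Every source must
    contain exactly one reference row with a positive value.
    """
    if value_column not in table or id_column not in table or source_column not in table:
        raise BenchmarkError(
            f"table needs columns {value_column!r}, {id_column!r}, {source_column!r}"
        )
    out = table.copy()
    out[value_column] = out[value_column].astype(float)
    for source, group in table.groupby(source_column):
        ref_rows = group[group[id_column] == reference_id]
        if len(ref_rows) != 1:
            raise BenchmarkError(
                f"source {source!r} has {len(ref_rows)} reference rows for "
                f"{reference_id!r}; exactly one is required"
            )
        ref = float(ref_rows[value_column].iloc[0])
        if not np.isfinite(ref) or ref <= 0:
            raise BenchmarkError(f"source {source!r}: reference value must be positive")
        out.loc[group.index, value_column] = group[value_column].astype(float) / ref
    return out


def deviation_csat(
    experimental: pd.DataFrame,
    simulated: pd.DataFrame,
    value_column: str = "csat",
    id_column: str = "variant",
) -> dict:
    """Both log-deviation metrics for saturation concentrations.

    Input frames carry one row per variant; they are aligned on
    ``id_column`` and only shared variants enter the metrics.
    """
    merged = experimental.merge(
        simulated, on=id_column, suffixes=("_exp", "_sim"), how="inner"
    )
    if merged.empty:
        raise BenchmarkError("no shared variants between experiment and simulation")
    e = merged[f"{value_column}_exp"].to_numpy()
    s = merged[f"{value_column}_sim"].to_numpy()
    return {
        "n": int(len(merged)),
        "variants": merged[id_column].tolist(),
        "relative": relative_log_deviation(e, s),
        "rms": rms_log_deviation(e, s),
    }


def deviation_viscosity(
    experimental: pd.DataFrame,
    simulated: pd.DataFrame,
    value_column: str = "viscosity",
    id_column: str = "variant",
) -> dict:
    """Both log-deviation metrics for condensate viscosities."""
    return deviation_csat(experimental, simulated, value_column, id_column)


def linear_correlation(x, y) -> dict:
    """Pearson correlation with two-sided p-value and the fitted line."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise BenchmarkError("need at least three paired points")
    res = stats.linregress(x, y)
    return {
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
    }
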