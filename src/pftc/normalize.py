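"""Consensus peak sets and the two occupancy normalizations.

The absolute normalization derives one positive factor per sample from the
constitutively bound control sites (the internal control carried in every
library): the occupancy of those sites is biologically constant, so any
systematic difference between a sample's control counts and the cross-sample
mean control profile measures that sample's IP-efficiency x depth confounder.
The relative normalization divides each site's time profile by its maximum,
which highlights the time-of-max but discards binding magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BindingMatrix, CountMatrix, NormalizationFactors

METHODS = ("control-regression", "median-ratio")


def consensus_sites(
    per_sample_sites: list[pd.DataFrame],
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Merged intervals supported by more than ``min_fraction`` of samples.

    Input intervals (columns chrom/start/end, 0-based half-open) are merged
    by single-bp overlap into union intervals; a union interval is kept iff
    intervals from strictly more than ``min_fraction`` of the samples overlap
    it. Output is sorted by (chrom, start).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_samples = len(per_sample_sites)
    pooled = []
    for k, df in enumerate(per_sample_sites):
        for _, row in df.iterrows():
            if row["end"] <= row["start"]:
                raise ValueError(
                    f"invalid interval {row['chrom']}:{row['start']}-{row['end']}"
                )
            pooled.append((row["chrom"], int(row["start"]), int(row["end"]), k))
    if not pooled:
        warnings.warn("consensus_sites: no input intervals", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "start", "end", "n_samples"])

    pooled.sort(key=lambda r: (r[0], r[1], r[2]))
    merged: list[tuple[str, int, int, set]] = []
    for chrom, start, end, k in pooled:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] | {k})
        else:
            merged.append((chrom, start, end, {k}))

    rows = [
        {"chrom": c, "start": s, "end": e, "n_samples": len(ks)}
        for c, s, e, ks in merged
        if len(ks) > min_fraction * n_samples
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_samples"])


def _zero_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y = f * x through the origin."""
    return float(x @ y) / float(x @ x)


def derive_factors(
    counts: CountMatrix | BindingMatrix,
    method: str = "control-regression",
    min_control_sites: int = 10,
    log_counts: bool = False,
) -> NormalizationFactors:
    """Per-sample normalization factors from control-site counts.

    For each sample *i*, ``control-regression`` takes the slope of the
    zero-intercept least-squares fit of the per-site cross-sample mean
    control profile against sample *i*'s control counts, so
    ``count * f_i`` sits on the common scale. ``median-ratio`` uses the
    median of per-site mean/count ratios instead. ``log_counts`` switches
    the regression variant to the geometric mean of per-site ratios
    (a log-space fit). Factors are rescaled to geometric mean 1.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if (counts.sites["role"] == "control").any():
        ctl = counts.restrict("control")
    else:
        ctl = counts  # caller passed an already-restricted control matrix
    table = ctl.counts if isinstance(ctl, CountMatrix) else ctl.values
    x = table.to_numpy(dtype=float)
    n_sites, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples to derive factors")
    if n_sites < min_control_sites:
        raise ValueError(
            f"only {n_sites} control sites; need >= {min_control_sites}"
        )
    col_zero = (x.sum(axis=0) == 0)
    if col_zero.any():
        bad = table.columns[col_zero].tolist()
        raise ValueError(f"all-zero control counts for sample(s): {bad}")

    mean_profile = x.mean(axis=1)
    factors = np.empty(n_samples)
    for i in range(n_samples):
        if method == "control-regression":
            if log_counts:
                pos = x[:, i] > 0
                factors[i] = float(
                    np.exp(np.mean(np.log(mean_profile[pos] / x[pos, i])))
                )
            else:
                factors[i] = _zero_intercept_slope(x[:, i], mean_profile)
        else:  # median-ratio
            pos = x[:, i] > 0
            factors[i] = float(np.median(mean_profile[pos] / x[pos, i]))
    if not np.all(np.isfinite(factors)) or not np.all(factors > 0):
        raise ValueError("derived non-positive or non-finite factors")
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return NormalizationFactors(
        factors=pd.Series(factors, index=table.columns, name="factor"),
        method=method + ("-log" if log_counts else ""),
        metadata={"n_control_sites": int(n_sites)},
    )


def apply_factors(
    counts: CountMatrix, factors: NormalizationFactors
) -> BindingMatrix:
    """Scale each sample column by its factor; no other transformation."""
    f = factors.reindex_like(counts)
    values = counts.counts.astype(float) * f
    return BindingMatrix(
        values=values, sites=counts.sites, manifest=counts.manifest
    )


@dataclass
class RowMaxResult:
    """Row-relative occupancy (rows x time points) plus exclusions."""

    matrix: pd.DataFrame
    excluded: list[str]


def normalize_rows_to_max(
    binding: BindingMatrix, collapse_replicates: bool = True
) -> RowMaxResult:
    """Replicate-average each site, then divide each row by its maximum.

    Every retained row has maximum exactly 1 and values in [0, 1]; ties for
    the maximum are left in place (downstream argmax resolves to the earliest
    time point). All-zero rows cannot be scaled and are excluded, reported in
    ``excluded``.
    """
    prof = binding.replicate_mean_profiles() if collapse_replicates else (
        binding.values.copy()
    )
    row_max = prof.max(axis=1)
    excluded = prof.index[row_max <= 0].tolist()
    if excluded:
        warnings.warn(
            f"normalize_rows_to_max: excluded {len(excluded)} all-zero row(s)",
            stacklevel=2,
        )
    kept = prof.loc[row_max > 0]
    return RowMaxResult(
        matrix=kept.div(row_max[row_max > 0], axis=0), excluded=excluded
    )


def normalize_series_to_max(series) -> np.ndarray:
    """Divide a numeric series by its maximum (cross-study re-scaling)."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    m = np.nanmax(arr)
    if not m > 0:
        raise ValueError(f"series maximum must be positive, got {m}")
    return arr / m
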