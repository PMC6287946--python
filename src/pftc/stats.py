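"""Temporal hypothesis tests on the normalized binding matrix.

Three families of tests:

* pairwise Welch t-tests between time points of one site, BH-adjusted over
  the 45 unordered pairs of the default 10-point design (the single-site
  "did binding change?" analysis);
* pairwise variance F-tests between time points of one site (did the
  replicate scatter change?);
* a signal-vs-control variance comparison pooling all post-stimulation
  samples, which attributes excess replicate scatter of a responsive site
  (relative to a constitutively bound control site) to biology rather than
  technique.

plus per-site / per-class time profiles and a genome-wide response table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BindingMatrix


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving (monotone in rank), output in [0, 1]. NaNs are refused
    rather than silently propagated.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value passed to bh_fdr")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test with the degenerate-variance conventions:

    zero variance in both groups -> p = 1 if the means are equal else p = 0
    (flagged by the caller as degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def variance_f_test(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float, int, int]:
    """Two-sided variance-ratio F-test: F = s2_a / s2_b, df (n_a-1, n_b-1),
    p = 2 * min(P(F <= f), P(F >= f)) capped at 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    dfa, dfb = a.size - 1, b.size - 1
    if vb == 0 or va == 0:
        raise ValueError("zero variance in variance F-test")
    f = va / vb
    p = 2.0 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0)), dfa, dfb


def _site_groups(
    binding: BindingMatrix, site_id: str
) -> list[tuple[float, np.ndarray]]:
    by_time = binding.site_values_by_time(site_id)  # raises on unknown id
    return sorted(by_time.items())


def pairwise_timepoint_tests(
    binding: BindingMatrix,
    site_id: str,
    alpha: float = 0.05,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Welch two-sided t-tests for every unordered time-point pair of a site.

    BH adjustment is applied across the pairs (the per-site family; 45 pairs
    for the default design). ``log_transform`` runs the tests on
    log2(x + 0.5), an option for the zero-inflated 0-min groups.
    """
    groups = _site_groups(binding, site_id)
    rows = []
    for (ta, va), (tb, vb) in combinations(groups, 2):
        if log_transform:
            va, vb = np.log2(va + 0.5), np.log2(vb + 0.5)
        t, p = welch_t_test(va, vb)
        rows.append(
            {
                "site_id": site_id,
                "time_a": ta,
                "time_b": tb,
                "statistic": t,
                "p_value": p,
                "degenerate": not np.isfinite(t) and p == 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out


def pairwise_variance_tests(
    binding: BindingMatrix, site_id: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided variance F-tests for every unordered time-point pair."""
    groups = _site_groups(binding, site_id)
    for t, v in groups:
        if v.size < 3:
            raise ValueError(f"need >= 3 replicates per time point (t={t})")
        if v.var(ddof=1) == 0:
            raise ValueError(f"zero replicate variance at time point {t}")
    rows = []
    for (ta, va), (tb, vb) in combinations(groups, 2):
        f, p, dfa, dfb = variance_f_test(va, vb)
        rows.append(
            {
                "site_id": site_id,
                "time_a": ta,
                "time_b": tb,
                "statistic": f,
                "df_a": dfa,
                "df_b": dfb,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out


@dataclass
class VarianceComparison:
    signal_site_id: str
    control_site_id: str
    df_signal: int
    df_control: int
    F: float
    p_value: float
    var_signal: float
    var_control: float
    cv_signal: float
    cv_control: float


def signal_vs_control_variance(
    binding: BindingMatrix,
    signal_site_id: str,
    control_site_id: str,
    min_time: float = 10.0,
) -> VarianceComparison:
    """Residual-variance F-test of a signal site against a control site.

    Pools all samples with time >= ``min_time`` (excluding the
    pre-stimulation point), subtracts each site's per-time-point means so
    that only replicate scatter remains, and compares the residual variances
    with an F-test on (N - T, N - T) degrees of freedom, N the pooled sample
    count and T the number of pooled time points. Residual coefficients of
    variation (residual SD over pooled mean) are reported alongside.
    """
    resid = {}
    var = {}
    cv = {}
    n_pooled = t_pooled = None
    for sid in (signal_site_id, control_site_id):
        groups = [
            (t, v) for t, v in _site_groups(binding, sid) if t >= min_time
        ]
        if not groups:
            raise ValueError(f"no time points at or after {min_time}")
        res = np.concatenate([v - v.mean() for _, v in groups])
        n, t = res.size, len(groups)
        if n - t < 1:
            raise ValueError("not enough residual degrees of freedom")
        n_pooled, t_pooled = n, t
        ss = float(res @ res)
        if sid == control_site_id and ss == 0:
            raise ValueError("control site has zero residual variance")
        resid[sid] = res
        var[sid] = ss / (n - t)
        grand_mean = np.concatenate([v for _, v in groups]).mean()
        cv[sid] = np.sqrt(var[sid]) / grand_mean if grand_mean > 0 else np.nan
    df = n_pooled - t_pooled
    F = var[signal_site_id] / var[control_site_id]
    p = 2.0 * min(sps.f.cdf(F, df, df), sps.f.sf(F, df, df))
    return VarianceComparison(
        signal_site_id=signal_site_id,
        control_site_id=control_site_id,
        df_signal=df,
        df_control=df,
        F=float(F),
        p_value=float(min(p, 1.0)),
        var_signal=var[signal_site_id],
        var_control=var[control_site_id],
        cv_signal=cv[signal_site_id],
        cv_control=cv[control_site_id],
    )


@dataclass
class TimeProfile:
    site_id: str
    table: pd.DataFrame  # index time_min, columns mean/sd
    time_of_max: float

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]


def profile(binding: BindingMatrix, site_id: str) -> TimeProfile:
    """Replicate mean and SD per time point; earliest time wins max ties."""
    groups = _site_groups(binding, site_id)
    table = pd.DataFrame(
        {
            "mean": [v.mean() for _, v in groups],
            "sd": [v.std(ddof=1) for _, v in groups],
        },
        index=pd.Index([t for t, _ in groups], name="time_min"),
    )
    return TimeProfile(
        site_id=site_id,
        table=table,
        time_of_max=float(table["mean"].idxmax()),  # first occurrence on ties
    )


def class_average_profile(
    binding: BindingMatrix, site_ids: list[str], label: str = "class_average"
) -> TimeProfile:
    """Mean over sites of the per-site time-point means (with across-site SD)."""
    if len(site_ids) == 0:
        raise ValueError("empty site set")
    missing = [s for s in site_ids if s not in binding.values.index]
    if missing:
        raise KeyError(f"unknown site id(s): {missing[:5]}")
    per_site = binding.replicate_mean_profiles().loc[site_ids]
    table = pd.DataFrame(
        {"mean": per_site.mean(axis=0), "sd": per_site.std(axis=0, ddof=1)}
    )
    table.index.name = "time_min"
    return TimeProfile(
        site_id=label, table=table, time_of_max=float(table["mean"].idxmax())
    )


def response_table(
    binding: BindingMatrix,
    time_a: float = 0.0,
    time_b: float = 10.0,
    alpha: float = 0.05,
    roles: tuple[str, ...] = ("signal",),
) -> pd.DataFrame:
    """Genome-wide response test: Welch ``time_a`` vs ``time_b`` per site,
    BH-adjusted across sites; plus baseline, post-activation amplitude and
    time-of-max (the inputs of the trajectory classification).

    Amplitude is mean occupancy over t >= ``time_b`` minus the ``time_a``
    mean, replicate-averaged.
    """
    sub = binding
    if roles is not None:
        keep = binding.sites.index[binding.sites["role"].isin(roles)]
        sub = BindingMatrix(
            binding.values.loc[keep], binding.sites.loc[keep], binding.manifest
        )
    cols_a = sub.manifest.index[sub.manifest["time_min"] == time_a]
    cols_b = sub.manifest.index[sub.manifest["time_min"] == time_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per compared time point")
    va = sub.values[cols_a].to_numpy()
    vb = sub.values[cols_b].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(vb, va, axis=1, equal_var=False)
    # degenerate rows (zero variance in both groups)
    degen = np.isnan(p)
    if degen.any():
        same = va.mean(axis=1) == vb.mean(axis=1)
        p = np.where(degen, np.where(same, 1.0, 0.0), p)
        t = np.where(degen, 0.0, t)
    prof = sub.replicate_mean_profiles()
    post = prof.loc[:, prof.columns >= time_b]
    out = pd.DataFrame(
        {
            "statistic": t,
            "p_value": p,
            "fdr": bh_fdr(p),
            "baseline": prof[time_a],
            "amplitude": post.mean(axis=1) - prof[time_a],
            "time_of_max": prof.idxmax(axis=1).astype(float),
        },
        index=sub.values.index,
    )
    out["significant"] = out["fdr"] < alpha
    return out
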