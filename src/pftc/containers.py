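"""In-memory containers shared by all pipeline stages.

The central objects are thin wrappers around pandas DataFrames with the
index conventions fixed once:

* site tables are indexed by ``site_id`` and carry ``chrom/start/end/role``
  (BED-style 0-based half-open coordinates, role in {"signal", "control"});
* the sample manifest is indexed by ``sample_id`` and carries
  ``time_min/replicate``;
* count and binding matrices are sites x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_ROLES = ("signal", "control")


def validate_sites(sites: pd.DataFrame) -> None:
    required = {"chrom", "start", "end", "role"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if sites.index.has_duplicates:
        dupes = sites.index[sites.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate site ids: {dupes[:5]}")
    if not (sites["end"] > sites["start"]).all():
        bad = sites.index[sites["end"] <= sites["start"]].tolist()
        raise ValueError(f"intervals with end <= start: {bad[:5]}")
    bad_roles = set(sites["role"]) - set(SITE_ROLES)
    if bad_roles:
        raise ValueError(f"unknown site roles: {sorted(bad_roles)}")


def validate_manifest(manifest: pd.DataFrame) -> None:
    required = {"time_min", "replicate"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.index.has_duplicates:
        raise ValueError("duplicate sample ids in manifest")
    pairs = manifest[["time_min", "replicate"]]
    if pairs.duplicated().any():
        raise ValueError("duplicate (time_min, replicate) pairs in manifest")
    # a full design grid: every time point must carry the same replicates
    per_time = manifest.groupby("time_min")["replicate"].apply(
        lambda r: tuple(sorted(r))
    )
    if per_time.nunique() > 1:
        raise ValueError(
            "manifest does not cover a full time x replicate grid: "
            f"{dict(per_time)}"
        )


@dataclass
class CountMatrix:
    """Raw integer read counts, sites x samples, plus site and sample metadata."""

    counts: pd.DataFrame
    sites: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        validate_sites(self.sites)
        validate_manifest(self.manifest)
        if not self.counts.index.equals(self.sites.index):
            raise ValueError("counts rows do not match site table")
        if not self.counts.columns.equals(self.manifest.index):
            raise ValueError("counts columns do not match manifest")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.manifest["time_min"].unique())

    def restrict(self, role: str) -> "CountMatrix":
        """Sub-matrix containing only sites with the given role."""
        if role not in SITE_ROLES:
            raise ValueError(f"unknown role {role!r}")
        keep = self.sites.index[self.sites["role"] == role]
        return CountMatrix(
            self.counts.loc[keep], self.sites.loc[keep], self.manifest
        )

    def samples_at(self, time_min: float) -> list[str]:
        return self.manifest.index[self.manifest["time_min"] == time_min].tolist()


@dataclass
class BindingMatrix:
    """Normalized occupancy (normalized-read-count units), sites x samples."""

    values: pd.DataFrame
    sites: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        validate_sites(self.sites)
        validate_manifest(self.manifest)
        if not self.values.index.equals(self.sites.index):
            raise ValueError("values rows do not match site table")
        if not self.values.columns.equals(self.manifest.index):
            raise ValueError("values columns do not match manifest")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative occupancy values")

    @property
    def time_points(self) -> np.ndarray:
        return np.sort(self.manifest["time_min"].unique())

    def restrict(self, role: str) -> "BindingMatrix":
        keep = self.sites.index[self.sites["role"] == role]
        return BindingMatrix(
            self.values.loc[keep], self.sites.loc[keep], self.manifest
        )

    def site_values_by_time(self, site_id: str) -> dict[float, np.ndarray]:
        """Replicate values of one site grouped by time point (time-ordered)."""
        if site_id not in self.values.index:
            raise KeyError(f"unknown site id {site_id!r}")
        row = self.values.loc[site_id]
        out: dict[float, np.ndarray] = {}
        for t in self.time_points:
            cols = self.manifest.index[self.manifest["time_min"] == t]
            out[float(t)] = row[cols].to_numpy(dtype=float)
        return out

    def replicate_mean_profiles(self) -> pd.DataFrame:
        """Sites x time-points matrix of replicate-averaged occupancy."""
        groups = self.manifest["time_min"]
        prof = self.values.T.groupby(groups).mean().T
        prof.columns = prof.columns.astype(float)
        return prof[sorted(prof.columns)]


@dataclass
class NormalizationFactors:
    """One positive scale factor per sample, geometric mean rescaled to 1."""

    factors: pd.Series
    method: str
    reference: str = "cross-sample mean control-site profile"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            raise ValueError("normalization factors must be finite and positive")

    def reindex_like(self, counts: CountMatrix) -> pd.Series:
        missing = set(counts.manifest.index) ^ set(self.factors.index)
        if missing:
            raise ValueError(
                "factor/sample mismatch; samples differing between factors and "
                f"count matrix: {sorted(missing)}"
            )
        return self.factors.reindex(counts.manifest.index)
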