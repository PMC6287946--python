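"""Named study computations reused by the analysis scripts and tests.

Each function regenerates its inputs from a seed and runs one complete
experiment of the study: the variance-attribution comparison at a strong
responder, and the two-trajectory recovery check. They exist so the
numbered analysis drivers, the test suite and the reproduction script all
execute the identical computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalize import apply_factors, derive_factors, normalize_rows_to_max
from .simulate import StudyDesign, generate_dataset
from .stats import VarianceComparison, response_table, signal_vs_control_variance
from .trajectories import cluster_embedding, embed_sites


@dataclass
class VarianceAttributionResult:
    comparison: VarianceComparison
    signal_mean: float
    control_mean: float
    n_pooled_samples: int


def variance_attribution_experiment(
    seed: int, mean_depth: float = 3.0, min_time: float = 10.0
) -> VarianceAttributionResult:
    """Residual-variance F-test of the strongest responder vs a matched control.

    Generates the default design at a depth scale putting the top responder's
    post-stimulation occupancy near 500 counts, normalizes with
    control-derived factors, picks the highest-amplitude class-A site and the
    control site with the closest post-stimulation mean, removes per-time
    means over t >= ``min_time`` and compares residual variances
    (df 45,45 for the default 9 x 6 post-stimulation grid).
    """
    ds = generate_dataset(design=StudyDesign(seed=seed, mean_depth=mean_depth))
    binding = apply_factors(ds.counts, derive_factors(ds.counts))
    resp = response_table(binding, time_b=min_time)
    top = resp["amplitude"].idxmax()
    prof = binding.replicate_mean_profiles()
    post = [c for c in prof.columns if c >= min_time]
    target = float(prof.loc[top, post].mean())
    ctl_ids = binding.sites.index[binding.sites["role"] == "control"]
    matched = (prof.loc[ctl_ids, post].mean(axis=1) - target).abs().idxmin()
    vc = signal_vs_control_variance(binding, top, matched, min_time=min_time)
    n_pooled = int(
        (binding.manifest["time_min"] >= min_time).sum()
    )
    return VarianceAttributionResult(
        comparison=vc,
        signal_mean=target,
        control_mean=float(prof.loc[matched, post].mean().mean()),
        n_pooled_samples=n_pooled,
    )


@dataclass
class TrajectoryRecoveryResult:
    agreement: float
    n_sites: int
    cluster_sizes: tuple[int, int]


def trajectory_recovery_experiment(
    seed: int, perplexity: float = 50.0
) -> TrajectoryRecoveryResult:
    """Recover the responsive vs ligand-independent split by embedding.

    Embeds row-max (shape) normalized replicate-mean profiles of the default
    fixture with t-SNE and clusters the map into two groups (k-means); the
    score is the agreement between cluster membership and the ground-truth
    responsive/non-responsive partition.
    """
    ds = generate_dataset(design=StudyDesign(seed=seed))
    binding = apply_factors(ds.counts, derive_factors(ds.counts))
    shape = normalize_rows_to_max(binding.restrict("signal")).matrix
    emb = embed_sites(shape, perplexity=perplexity, seed=seed)
    labels = cluster_embedding(emb, n_clusters=2, seed=seed)
    truth = ds.truth.site_specs.loc[shape.index, "class_label"]
    responsive = truth.isin(["A", "C"]).astype(int)
    agree = float(
        max((labels == responsive).mean(), (labels != responsive).mean())
    )
    sizes = labels.value_counts().sort_index()
    return TrajectoryRecoveryResult(
        agreement=agree,
        n_sites=int(len(labels)),
        cluster_sizes=(int(sizes.iloc[0]), int(sizes.iloc[1])),
    )
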