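"""Trajectory analysis: embedding, site classification, heatmap ordering.

The low-dimensional embedding (t-SNE) of per-site time profiles is a
visual/diagnostic device: with a dynamic-range-spanning perplexity it shows
the ligand-responsive sites and the ligand-independent sites as separate
trajectories. Because trajectory membership read off an embedding is not a
reproducible definition, class labels are assigned by an explicit
deterministic rule on (response FDR, amplitude, baseline); the embedding is
never an input to classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .containers import BindingMatrix

PERPLEXITY_SWEEP = (2, 5, 30, 50, 100, 200)


@dataclass
class Embedding:
    coords: pd.DataFrame  # index site_id, columns x/y
    perplexity: float
    seed: int
    input_description: str = "replicate-averaged time profiles"


def embed_sites(
    profiles: pd.DataFrame | BindingMatrix,
    perplexity: float = 50.0,
    seed: int = 42,
) -> Embedding:
    """2-D t-SNE embedding of per-site time profiles.

    ``profiles`` is a sites x time-points matrix (or a BindingMatrix, which
    is replicate-averaged first). Deterministic for a fixed seed.
    """
    if isinstance(profiles, BindingMatrix):
        profiles = profiles.replicate_mean_profiles()
    n = len(profiles)
    if not 1 < perplexity < n / 3:
        raise ValueError(
            f"perplexity must be in (1, n_sites/3) = (1, {n / 3:.0f}); "
            f"got {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    xy = tsne.fit_transform(profiles.to_numpy(dtype=float))
    coords = pd.DataFrame(xy, index=profiles.index, columns=["x", "y"])
    return Embedding(coords=coords, perplexity=perplexity, seed=seed)


def perplexity_sweep(
    profiles: pd.DataFrame,
    perplexities=PERPLEXITY_SWEEP,
    seed: int = 42,
) -> dict[float, Embedding]:
    """Run the embedding at each listed perplexity (stability check)."""
    return {p: embed_sites(profiles, perplexity=p, seed=seed) for p in perplexities}


def separation_score(
    embedding: Embedding, labels: pd.Series, class_a: str, class_b: str
) -> float:
    """Between-centroid distance over mean within-class coordinate spread."""
    xy = embedding.coords
    a = xy.loc[labels.index[labels == class_a]].to_numpy()
    b = xy.loc[labels.index[labels == class_b]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty class in separation_score")
    centroid_dist = float(np.linalg.norm(a.mean(0) - b.mean(0)))
    spread = float(
        np.mean(
            [
                np.linalg.norm(g - g.mean(0), axis=1).mean()
                for g in (a, b)
            ]
        )
    )
    return centroid_dist / spread


def cluster_embedding(
    embedding: Embedding, n_clusters: int = 2, seed: int = 0
) -> pd.Series:
    """k-means cluster labels on the embedding coordinates."""
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    lab = km.fit_predict(embedding.coords.to_numpy())
    return pd.Series(lab, index=embedding.coords.index, name="cluster")


def two_means_split(values: np.ndarray) -> float:
    """Exact 1-D two-cluster k-means boundary (midpoint of the two means).

    Deterministic: tries every split of the sorted values and minimizes the
    within-cluster sum of squares.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2:
        raise ValueError("need >= 2 values to split")
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    ks = np.arange(1, n)
    left = csq[:-1] - csum[:-1] ** 2 / ks
    right = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - ks)
    k = int(np.argmin(left + right)) + 1
    return float((v[:k].mean() + v[k:].mean()) / 2.0)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the operational class definition.

    ``alpha``: response-FDR cut; ``baseline_floor``: minimum 0-min occupancy
    (normalized reads) for a non-responsive site to count as constitutively
    bound; ``amplitude_split``: boundary between strong (A) and weak (C)
    responders - a number, or "2means" (exact 1-D two-means split of the
    responsive amplitudes, the default) or "quartile" (upper quartile).
    """

    alpha: float = 0.05
    baseline_floor: float = 20.0
    amplitude_split: float | str = "2means"


def classify_sites(
    response: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Assign each site to class A, B, C or unassigned.

    Rule (deterministic given thresholds): responsive sites
    (fdr < alpha and amplitude > 0) are class A if amplitude >= the amplitude
    split else class C; non-responsive sites with baseline >= the floor are
    class B (ligand-independent constitutive binding); everything else is
    unassigned. ``response`` is the table from
    :func:`pftc.stats.response_table` (site_id index; fdr, amplitude,
    baseline, time_of_max columns).
    """
    th = thresholds or ClassificationThresholds()
    out = response[["fdr", "amplitude", "baseline", "time_of_max"]].copy()
    missing = out["fdr"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} site(s) without FDR left unassigned",
            stacklevel=2,
        )
    responsive = (~missing) & (out["fdr"] < th.alpha) & (out["amplitude"] > 0)

    amps = out.loc[responsive, "amplitude"].to_numpy()
    if isinstance(th.amplitude_split, str):
        if amps.size < 2:
            split = np.inf
        elif th.amplitude_split == "2means":
            split = two_means_split(amps)
        elif th.amplitude_split == "quartile":
            split = float(np.quantile(amps, 0.75))
        else:
            raise ValueError(f"unknown amplitude split {th.amplitude_split!r}")
    else:
        split = float(th.amplitude_split)

    label = pd.Series("unassigned", index=out.index, dtype=object)
    label[responsive & (out["amplitude"] >= split)] = "A"
    label[responsive & (out["amplitude"] < split)] = "C"
    constitutive = (~responsive) & (~missing) & (out["baseline"] >= th.baseline_floor)
    label[constitutive] = "B"
    out.insert(0, "class", label)
    out.attrs["amplitude_split"] = split
    return out


@dataclass
class HeatmapView:
    """Identically ordered row-max and absolute views of the binding matrix."""

    order: list[str]
    row_max: pd.DataFrame
    absolute: pd.DataFrame
    blocks: pd.Series = field(repr=False, default=None)  # site_id -> time_of_max


def order_for_heatmap(binding: BindingMatrix) -> HeatmapView:
    """Group rows into time-of-max blocks, strongest binding first in-block.

    The same row order is applied to the row-relative (each site scaled to
    its maximum) and the absolute (control-normalized) views, so the two
    renderings of the matrix are directly comparable.
    """
    prof = binding.replicate_mean_profiles()
    keep = prof.max(axis=1) > 0
    prof = prof.loc[keep]
    time_of_max = prof.idxmax(axis=1).astype(float)  # earliest time on ties
    mean_occ = prof.mean(axis=1)
    order = (
        pd.DataFrame({"tmax": time_of_max, "mean": mean_occ})
        .sort_values(["tmax", "mean"], ascending=[True, False], kind="stable")
        .index.tolist()
    )
    ordered = prof.loc[order]
    return HeatmapView(
        order=order,
        row_max=ordered.div(ordered.max(axis=1), axis=0),
        absolute=ordered,
        blocks=time_of_max.loc[order],
    )
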