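#!/usr/bin/env python
"""Trajectory analysis: heatmaps, t-SNE sweep, A/B/C classification.

Orders the binding matrix by time-of-max to contrast the row-relative and
absolute views, embeds site profiles with a perplexity sweep, classifies
sites into ligand-responsive (A strong / C weak) and ligand-independent (B)
classes, and scores the classification against ground truth.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np

from pftc.io import read_truth, write_tsv
from pftc.plots import embedding_scatter, heatmap_pair, profile_plot
from pftc.stats import class_average_profile, response_table
from pftc.trajectories import (
    classify_sites,
    embed_sites,
    order_for_heatmap,
    perplexity_sweep,
    separation_score,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
FIG = ROOT / "figures"

spec = importlib.util.spec_from_file_location(
    "single_site", Path(__file__).parent / "03_single_site_stats.py"
)
single_site = importlib.util.module_from_spec(spec)
spec.loader.exec_module(single_site)


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    binding = single_site.load_binding()
    truth = read_truth(ROOT / "fixture" / "ground_truth.json")
    signal = binding.restrict("signal")
    resp = response_table(binding)

    view = order_for_heatmap(signal)
    heatmap_pair(view, FIG / "heatmap_rowmax_vs_absolute.png")
    block0 = view.blocks.index[view.blocks == 0.0]
    print(f"heatmap: {view.blocks.nunique()} time-of-max blocks; "
          f"{len(block0)} sites peak at 0 min (flat sites with noise-level "
          "amplitude; the block disappears in the absolute view)")

    classes = classify_sites(resp)
    write_tsv(classes, ROOT / "classification.tsv")
    truth_lab = truth.site_specs.loc[signal.values.index, "class_label"]
    expect = truth_lab.replace({"null": "unassigned"})
    acc = float((classes.loc[expect.index, "class"] == expect).mean())
    print(f"classification: {classes['class'].value_counts().to_dict()}, "
          f"amplitude split {classes.attrs['amplitude_split']:.1f} "
          f"normalized reads, accuracy vs truth {acc:.3f}")

    emb = embed_sites(signal, perplexity=50, seed=42)
    write_tsv(emb.coords.join(classes["class"]), ROOT / "embedding.tsv")
    embedding_scatter(emb, classes["class"], FIG / "tsne_classes.png")
    embedding_scatter(emb, resp["fdr"], FIG / "tsne_fdr.png", log_color=True)

    rng = np.random.default_rng(0)
    sub = []
    for cls, n in [("A", 200), ("C", 250), ("B", 150), ("null", 100)]:
        sub += list(rng.choice(truth_lab.index[truth_lab == cls], n,
                               replace=False))
    prof = signal.replicate_mean_profiles().loc[sub]
    sweep = perplexity_sweep(prof, seed=42)
    print("perplexity sweep (A-vs-B separation score, 700-site subsample):")
    for p, e in sweep.items():
        s = separation_score(e, truth_lab.loc[sub], "A", "B")
        note = "minimal structure" if p in (2, 5) else "two stable trajectories"
        print(f"  perplexity {p:>3g}: {s:5.1f}  ({note})")

    profiles = {
        f"class {lab}": class_average_profile(
            signal, classes.index[classes["class"] == lab].tolist()
        ).table
        for lab in ("A", "B", "C")
    }
    profile_plot(profiles, FIG / "class_profiles.png")
    for lab, tab in profiles.items():
        print(f"  {lab}: {tab['mean'].iloc[0]:.0f} -> "
              f"{tab['mean'].iloc[1:].mean():.0f} normalized reads")


if __name__ == "__main__":
    main()
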