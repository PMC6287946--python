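"""Shared fixtures: datasets are generated once per session and reused."""

import numpy as np
import pandas as pd
import pytest

from pftc.kinetics import assess_many
from pftc.normalize import apply_factors, derive_factors
from pftc.simulate import NoiseModel, StudyDesign, generate_dataset
from pftc.stats import response_table
from pftc.trajectories import classify_sites


@pytest.fixture(scope="session")
def default_dataset():
    """Full default design, seed 42 (the reference fixture)."""
    return generate_dataset(design=StudyDesign(seed=42))


@pytest.fixture(scope="session")
def seed1_dataset():
    return generate_dataset(design=StudyDesign(seed=1))


@pytest.fixture(scope="session")
def binding(default_dataset):
    return apply_factors(
        default_dataset.counts, derive_factors(default_dataset.counts)
    )


@pytest.fixture(scope="session")
def binding_seed1(seed1_dataset):
    return apply_factors(seed1_dataset.counts, derive_factors(seed1_dataset.counts))


@pytest.fixture(scope="session")
def response(binding):
    return response_table(binding)


@pytest.fixture(scope="session")
def classes(response):
    return classify_sites(response)


@pytest.fixture(scope="session")
def truth_labels(default_dataset):
    """Expected class calls: truth labels with null mapped to unassigned."""
    specs = default_dataset.truth.site_specs
    lab = specs.loc[specs["class_label"] != "control", "class_label"]
    return lab.replace({"null": "unassigned"})


@pytest.fixture(scope="session")
def kinetics_rates():
    """Sustained false-cyclical and cyclical detection rates (seed 42).

    500 default class-A (sustained) plus 500 full-amplitude cyclical sites
    (period 90 min), default noise, assessed per site after control
    normalization.
    """
    ds = generate_dataset(
        design=StudyDesign(
            seed=42,
            n_sites_per_class={"A": 500, "cyclical": 500},
            n_control_sites=1000,
        )
    )
    b = apply_factors(ds.counts, derive_factors(ds.counts))
    res = assess_many(b, [s for s in b.values.index if s.startswith("ER_")])
    lab = res.index.str.split("_").str[1]
    called_cyc = res["preferred_model"] == "cyclical"
    return {
        "false_cyclical": float(called_cyc[lab == "A"].mean()),
        "detection": float(called_cyc[lab == "cyclical"].mean()),
        "periods": res.loc[lab == "cyclical", "fitted_period"],
    }


@pytest.fixture(scope="session")
def null_site_pvalues():
    """0-vs-10 Welch p-values on 2000 no-dynamics, no-biological-noise sites."""
    ds = generate_dataset(
        design=StudyDesign(
            seed=7, n_sites_per_class={"null": 2000}, n_control_sites=500
        ),
        noise=NoiseModel(biological_cv=0.0),
    )
    b = apply_factors(ds.counts, derive_factors(ds.counts))
    resp = response_table(b)
    return resp["p_value"].to_numpy()


def make_binding(values: np.ndarray, time_points, n_reps) -> "object":
    """Construct a small BindingMatrix from a (sites x samples) array."""
    from pftc.containers import BindingMatrix

    rows = []
    for t in time_points:
        for r in range(1, n_reps + 1):
            rows.append((f"t{int(t):03d}_r{r}", float(t), r))
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "time_min", "replicate"]
    ).set_index("sample_id")
    n_sites = values.shape[0]
    site_ids = [f"site_{i}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_sites) * 1000,
            "end": np.arange(n_sites) * 1000 + 100,
            "role": "signal",
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    df = pd.DataFrame(values, index=sites.index, columns=manifest.index)
    return BindingMatrix(values=df, sites=sites, manifest=manifest)
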