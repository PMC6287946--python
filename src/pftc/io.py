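"""Plain-text readers and writers: BED intervals, TSV matrices, JSON truth.

All tabular outputs may carry leading ``#`` comment lines (used by the
pipeline to stamp the config hash and seed); readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BindingMatrix, CountMatrix
from .simulate import GroundTruth, SimulatedDataset


def _io_error(path: Path, exc: Exception) -> OSError:
    return OSError(f"while accessing {path}: {exc}")


def _jsonable(v):
    if isinstance(v, (np.floating, float)):
        return float(v)
    if isinstance(v, np.integer):
        return int(v)
    return v


def write_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as BED (0-based half-open; name = site_id)."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            for sid, row in sites.iterrows():
                fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{sid}\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise _io_error(path, exc)


def read_bed(path: str | Path, role: str | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "site_id"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except OSError as exc:
        raise _io_error(path, exc)
    df = df.set_index("site_id")
    if role is not None:
        df["role"] = role
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, comments: list[str] | None = None
              ) -> None:
    path = Path(path)
    try:
        with path.open("w") as fh:
            for line in comments or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t")
    except OSError as exc:  # pragma: no cover
        raise _io_error(path, exc)


def read_tsv(path: str | Path, index_col: int | str = 0) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    except OSError as exc:
        raise _io_error(path, exc)


def write_fixture(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as a plain-text fixture directory.

    Emits ``manifest.tsv``, ``signal_sites.bed``, ``control_sites.bed``,
    ``counts.tsv``, ``ground_truth.json`` and ``metadata.yaml``; the fixture
    round-trips losslessly through :func:`read_fixture`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cm = dataset.counts
    paths = {
        "manifest": directory / "manifest.tsv",
        "signal_bed": directory / "signal_sites.bed",
        "control_bed": directory / "control_sites.bed",
        "counts": directory / "counts.tsv",
        "truth": directory / "ground_truth.json",
        "metadata": directory / "metadata.yaml",
    }
    write_tsv(cm.manifest, paths["manifest"])
    write_bed(cm.sites[cm.sites["role"] == "signal"], paths["signal_bed"])
    write_bed(cm.sites[cm.sites["role"] == "control"], paths["control_bed"])
    write_tsv(cm.counts, paths["counts"])

    truth = dataset.truth
    # plain-Python dicts keep full float64 precision through json round trips
    truth_obj = {
        "site_specs": {
            str(i): {k: _jsonable(v) for k, v in row.items()}
            for i, row in truth.site_specs.iterrows()
        },
        "site_order": truth.site_specs.index.tolist(),
        "effects": {
            str(i): {k: float(v) for k, v in row.items()}
            for i, row in truth.effects.iterrows()
        },
        "sample_order": truth.effects.index.tolist(),
        "expected": {
            "columns": [float(c) for c in truth.expected.columns],
            "index": truth.expected.index.tolist(),
            "values": truth.expected.to_numpy().tolist(),
        },
    }
    try:
        paths["truth"].write_text(json.dumps(truth_obj))
        meta = {
            "seed": int(dataset.seed),
            "design": {
                "time_points_min": [float(t) for t in dataset.design.time_points_min],
                "n_replicates": int(dataset.design.n_replicates),
                "n_control_sites": int(dataset.design.n_control_sites),
                "n_sites_per_class": {
                    k: int(v) for k, v in dataset.design.n_sites_per_class.items()
                },
                "mean_depth": float(dataset.design.mean_depth),
            },
            "noise": {
                "nb_dispersion": float(dataset.noise.nb_dispersion),
                "biological_cv": float(dataset.noise.biological_cv),
                "efficiency_cv": float(dataset.noise.efficiency_cv),
                "depth_cv": float(dataset.noise.depth_cv),
            },
        }
        paths["metadata"].write_text(yaml.safe_dump(meta, sort_keys=True))
    except OSError as exc:  # pragma: no cover
        raise _io_error(directory, exc)
    return paths


def read_counts(
    counts_path: str | Path,
    manifest_path: str | Path,
    signal_bed: str | Path,
    control_bed: str | Path,
) -> CountMatrix:
    """Assemble a CountMatrix from its on-disk parts."""
    manifest = read_tsv(manifest_path)
    counts = read_tsv(counts_path)
    sites = pd.concat(
        [read_bed(signal_bed, role="signal"), read_bed(control_bed, role="control")]
    )
    counts = counts.loc[sites.index]
    counts.columns.name = manifest.index.name
    return CountMatrix(
        counts=counts.astype(np.int64), sites=sites, manifest=manifest
    )


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except OSError as exc:
        raise _io_error(path, exc)
    site_specs = pd.DataFrame.from_dict(obj["site_specs"], orient="index").loc[
        obj["site_order"]
    ]
    site_specs.index.name = "site_id"
    effects = pd.DataFrame.from_dict(obj["effects"], orient="index").loc[
        obj["sample_order"]
    ]
    effects.index.name = "sample_id"
    expected = pd.DataFrame(
        obj["expected"]["values"],
        index=pd.Index(obj["expected"]["index"], name="site_id"),
        columns=[float(c) for c in obj["expected"]["columns"]],
    )
    return GroundTruth(site_specs=site_specs, effects=effects, expected=expected)


def read_fixture(directory: str | Path) -> tuple[CountMatrix, GroundTruth, dict]:
    directory = Path(directory)
    cm = read_counts(
        directory / "counts.tsv",
        directory / "manifest.tsv",
        directory / "signal_sites.bed",
        directory / "control_sites.bed",
    )
    truth = read_truth(directory / "ground_truth.json")
    meta = yaml.safe_load((directory / "metadata.yaml").read_text())
    return cm, truth, meta


def write_binding_matrix(
    binding: BindingMatrix, path: str | Path, comments: list[str] | None = None
) -> None:
    write_tsv(binding.values, path, comments=comments)
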