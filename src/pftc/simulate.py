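"""Synthetic time-course generator.

Emulates the statistical structure of a parallel-factor ChIP-seq time course:
every library contains binding sites of a dynamic signal factor (an
estrogen-receptor-like responder) and of a constitutively bound control
factor (CTCF-like), so a per-sample immunoprecipitation-efficiency /
sequencing-depth confounder multiplies both and can be removed using the
control sites alone.

The default design is 10 time points spanning 0-90 min x 6 replicates
(60 signal-target samples). Site dynamics come in five classes:

* ``A``    - strong ligand-responsive: saturating rise after stimulation;
* ``C``    - weak ligand-responsive: same shape, smaller amplitude
             (~10 normalized reads rising to ~40);
* ``B``    - ligand-independent, constitutively bound (~35 normalized reads);
* ``null`` - weak constant background sites;
* ``cyclical`` - periodic occupancy (off by default; used to test the
             sustained-vs-cyclical model assessment).

Counts are negative-binomial around the expected occupancy
(variance = mu + dispersion * mu^2); signal sites additionally carry a
per-sample multiplicative lognormal biological factor. Setting
``nb_dispersion`` to 0 switches count noise off entirely (deterministic
rounding), which is the mode used for exact-recovery oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import BindingMatrix, CountMatrix

DEFAULT_TIME_POINTS = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)
DEFAULT_SITES_PER_CLASS = {"A": 600, "C": 1000, "B": 400, "null": 500}

CLASS_LABELS = ("A", "C", "B", "cyclical", "null")


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class DynamicsSpec:
    """Expected-occupancy dynamics of one site class.

    ``baseline`` and ``amplitude`` are in normalized-read-count units;
    ``activation_tau_min`` is the rise time constant of the saturating
    exponential; ``period_min``/``phase_min`` apply to cyclical sites only.
    """

    class_label: str
    baseline: float
    amplitude: float = 0.0
    activation_tau_min: float = 2.0
    period_min: float | None = None
    phase_min: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ConfigurationError(f"unknown class label {self.class_label!r}")
        if self.baseline < 0 or self.amplitude < 0:
            raise ConfigurationError("baseline and amplitude must be >= 0")
        if self.class_label in ("B", "null") and self.amplitude != 0:
            raise ConfigurationError(
                f"class {self.class_label} must have amplitude 0"
            )
        if self.class_label == "cyclical" and (
            self.period_min is None or self.period_min <= 0
        ):
            raise ConfigurationError("cyclical dynamics require period_min > 0")


#: Default per-class dynamics. Class B level and the class C 10->40 response
#: follow the reported normalized-read-count magnitudes; the class A rise
#: (35 -> 165) makes the 0-vs-10 min contrast overwhelmingly detectable with
#: 6 replicates while the 10..90 min plateau stays flat. tau = 2 min puts
#: occupancy at t=10 within 1% of plateau, so only 0-min contrasts respond.
DEFAULT_DYNAMICS: dict[str, DynamicsSpec] = {
    "A": DynamicsSpec("A", baseline=35.0, amplitude=130.0, activation_tau_min=2.0),
    "C": DynamicsSpec("C", baseline=10.0, amplitude=30.0, activation_tau_min=2.0),
    "B": DynamicsSpec("B", baseline=35.0),
    "null": DynamicsSpec("null", baseline=8.0),
    "cyclical": DynamicsSpec(
        "cyclical", baseline=0.0, amplitude=40.0, period_min=90.0, phase_min=22.5
    ),
}


@dataclass(frozen=True)
class StudyDesign:
    """Experimental design of the simulated time course."""

    time_points_min: tuple[float, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 6
    n_control_sites: int = 2000
    n_sites_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_CLASS)
    )
    mean_depth: float = 1.0
    control_strength_meanlog: float = math.log(500.0)
    control_strength_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points_min, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0) or tp[0] < 0:
            raise ConfigurationError(
                "time points must be non-negative and strictly increasing"
            )
        if self.n_replicates < 1 or self.n_control_sites < 1:
            raise ConfigurationError("design dimensions must be positive")
        if any(n < 0 for n in self.n_sites_per_class.values()):
            raise ConfigurationError("negative site count in class mix")
        if sum(self.n_sites_per_class.values()) < 1:
            raise ConfigurationError("no signal sites requested")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.time_points_min) * self.n_replicates


@dataclass(frozen=True)
class NoiseModel:
    """Technical and biological noise.

    ``nb_dispersion`` is the negative-binomial dispersion
    (variance = mu + dispersion * mu^2); 0 disables count noise entirely.
    ``biological_cv`` is a per-sample multiplicative lognormal coefficient of
    variation applied to signal-site occupancy only (control sites receive
    technical noise only). ``efficiency_cv`` / ``depth_cv`` set the lognormal
    spread of the per-sample IP-efficiency and sequencing-depth confounders.
    """

    nb_dispersion: float = 0.02
    biological_cv: float = 0.30
    efficiency_cv: float = 0.25
    depth_cv: float = 0.15

    def __post_init__(self) -> None:
        for name in ("nb_dispersion", "biological_cv", "efficiency_cv", "depth_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score recovery exactly.

    ``site_specs``: per-site dynamics parameters and class label;
    ``effects``: per-sample efficiency and depth factors;
    ``expected``: noiseless expected occupancy (sites x time points),
    in occupancy units, before sample effects and depth scaling.
    """

    site_specs: pd.DataFrame
    effects: pd.DataFrame
    expected: pd.DataFrame

    def confounder(self) -> pd.Series:
        """The per-sample multiplier the normalization must remove."""
        return self.effects["efficiency"] * self.effects["depth_factor"]


@dataclass
class SimulatedDataset:
    design: StudyDesign
    noise: NoiseModel
    counts: CountMatrix
    truth: GroundTruth
    seed: int


def occupancy_curve(spec: DynamicsSpec, t):
    """Expected occupancy of a site class at time ``t`` (minutes).

    Responsive classes follow a saturating exponential
    ``baseline + amplitude * (1 - exp(-t / tau))``; constant classes stay at
    baseline; cyclical sites oscillate between baseline and
    baseline + amplitude with the given period and phase.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if spec.class_label in ("A", "C"):
        occ = spec.baseline + spec.amplitude * (
            1.0 - np.exp(-t / spec.activation_tau_min)
        )
    elif spec.class_label in ("B", "null"):
        occ = spec.baseline * np.ones_like(t)
    elif spec.class_label == "cyclical":
        if spec.period_min is None or spec.period_min <= 0:
            raise ConfigurationError("cyclical spec is missing a period")
        phase = 2.0 * np.pi * (t - spec.phase_min) / spec.period_min
        occ = spec.baseline + spec.amplitude * (1.0 + np.sin(phase)) / 2.0
    else:  # pragma: no cover - guarded in DynamicsSpec
        raise ConfigurationError(f"unknown class {spec.class_label!r}")
    occ = np.maximum(occ, 0.0)
    return float(occ) if occ.ndim == 0 else occ


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size)


def sample_negative_binomial(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mu, dispersion) counts with variance mu + dispersion * mu^2.

    Drawn as a gamma-Poisson mixture. ``dispersion == 0`` is the deterministic
    mode: counts are the rounded expectations, with no sampling at all.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _synthetic_intervals(n: int, prefix: str, offset: int) -> pd.DataFrame:
    """Deterministic synthetic genomic intervals (0-based half-open)."""
    chroms = [f"chr{1 + i % 22}" for i in range(n)]
    starts = offset + 2000 * (np.arange(n) // 22)
    ids = [f"{prefix}_{i:05d}" for i in range(n)]
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + 400},
        index=pd.Index(ids, name="site_id"),
    )


def generate_dataset(
    design: StudyDesign | None = None,
    dynamics: dict[str, DynamicsSpec] | None = None,
    noise: NoiseModel | None = None,
) -> SimulatedDataset:
    """Generate a full synthetic time course with ground truth.

    Within sample *i*, the expected count of site *j* is
    ``occupancy_curve(spec_j, t_i) * efficiency_i * depth_i * mean_depth``;
    signal sites are further multiplied by a per-sample lognormal biological
    factor before negative-binomial sampling. Re-running with the same seed
    reproduces the count matrix bit-exactly.
    """
    design = design or StudyDesign()
    noise = noise or NoiseModel()
    dyn = dict(DEFAULT_DYNAMICS)
    if dynamics:
        dyn.update(dynamics)

    ss = np.random.SeedSequence(design.seed)
    rng_sites, rng_effects, rng_bio, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    tps = np.asarray(design.time_points_min, dtype=float)

    # --- manifest -----------------------------------------------------------
    rows = []
    for t in tps:
        for r in range(1, design.n_replicates + 1):
            rows.append((f"t{int(t):03d}_r{r}", float(t), r))
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "time_min", "replicate"]
    ).set_index("sample_id")

    # --- per-site specs and noiseless occupancy -----------------------------
    spec_rows = []
    for label in ("A", "C", "B", "cyclical", "null"):
        n = design.n_sites_per_class.get(label, 0)
        if label not in dyn and n > 0:
            raise ConfigurationError(f"no dynamics given for class {label!r}")
        for k in range(n):
            s = dyn[label]
            spec_rows.append(
                {
                    "site_id": f"ER_{label}_{k:05d}",
                    "class_label": label,
                    "baseline": s.baseline,
                    "amplitude": s.amplitude,
                    "activation_tau_min": s.activation_tau_min,
                    "period_min": s.period_min,
                    "phase_min": s.phase_min,
                }
            )
    signal_specs = pd.DataFrame(spec_rows).set_index("site_id")

    control_strength = rng_sites.lognormal(
        design.control_strength_meanlog,
        design.control_strength_sdlog,
        design.n_control_sites,
    )
    control_ids = [f"CTCF_{k:05d}" for k in range(design.n_control_sites)]
    control_specs = pd.DataFrame(
        {
            "class_label": "control",
            "baseline": control_strength,
            "amplitude": 0.0,
            "activation_tau_min": np.nan,
            "period_min": np.nan,
            "phase_min": np.nan,
        },
        index=pd.Index(control_ids, name="site_id"),
    )

    n_signal = len(signal_specs)
    expected_signal = np.empty((n_signal, len(tps)))
    for i, (sid, row) in enumerate(signal_specs.iterrows()):
        spec = dyn[row["class_label"]]
        expected_signal[i] = occupancy_curve(spec, tps)
    expected_control = np.repeat(
        control_strength[:, None], len(tps), axis=1
    )
    expected = pd.DataFrame(
        np.vstack([expected_signal, expected_control]),
        index=signal_specs.index.append(control_specs.index),
        columns=tps,
    )

    # --- sample effects -----------------------------------------------------
    effects = pd.DataFrame(
        {
            "efficiency": _lognormal_unit_mean(
                rng_effects, noise.efficiency_cv, len(manifest)
            ),
            "depth_factor": _lognormal_unit_mean(
                rng_effects, noise.depth_cv, len(manifest)
            ),
        },
        index=manifest.index,
    )

    # --- counts -------------------------------------------------------------
    time_idx = np.searchsorted(tps, manifest["time_min"].to_numpy())
    scale = (
        effects["efficiency"].to_numpy()
        * effects["depth_factor"].to_numpy()
        * design.mean_depth
    )
    mu = expected.to_numpy()[:, time_idx] * scale[None, :]
    bio = _lognormal_unit_mean(
        rng_bio, noise.biological_cv, (n_signal, len(manifest))
    )
    mu[:n_signal] *= bio
    counts_arr = sample_negative_binomial(rng_counts, mu, noise.nb_dispersion)
    counts = pd.DataFrame(counts_arr, index=expected.index, columns=manifest.index)

    # --- site table ---------------------------------------------------------
    signal_sites = _synthetic_intervals(n_signal, "sig", 10_000)
    signal_sites.index = signal_specs.index
    signal_sites["role"] = "signal"
    control_sites = _synthetic_intervals(design.n_control_sites, "ctl", 1_000_000)
    control_sites.index = control_specs.index
    control_sites["role"] = "control"
    sites = pd.concat([signal_sites, control_sites])

    truth = GroundTruth(
        site_specs=pd.concat([signal_specs, control_specs]),
        effects=effects,
        expected=expected,
    )
    cm = CountMatrix(counts=counts, sites=sites, manifest=manifest)
    return SimulatedDataset(
        design=design, noise=noise, counts=cm, truth=truth, seed=design.seed
    )


def expected_count_matrix(dataset: SimulatedDataset) -> BindingMatrix:
    """The exact noiseless expected counts (truth x sample effects x depth).

    This is the 'noiseless dataset' oracle: applying the normalization to it
    must recover the sample confounders exactly.
    """
    design, truth = dataset.design, dataset.truth
    tps = np.asarray(design.time_points_min, dtype=float)
    time_idx = np.searchsorted(tps, dataset.counts.manifest["time_min"].to_numpy())
    scale = truth.confounder().to_numpy() * design.mean_depth
    vals = truth.expected.to_numpy()[:, time_idx] * scale[None, :]
    values = pd.DataFrame(
        vals, index=truth.expected.index, columns=dataset.counts.manifest.index
    )
    return BindingMatrix(
        values=values,
        sites=dataset.counts.sites,
        manifest=dataset.counts.manifest,
    )


def with_noise(dataset_noise: NoiseModel, **overrides) -> NoiseModel:
    """Convenience: a copy of a noise model with fields replaced."""
    return replace(dataset_noise, **overrides)
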