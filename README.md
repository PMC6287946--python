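# pftc — parallel-factor time-course ChIP-seq analysis

Quantitative analysis of transcription-factor binding time courses measured
by ChIP-seq with an **internal control**: each library contains both the
peaks of a dynamic factor (an estrogen-receptor-like responder in MCF7-style
cells, stimulated at t = 0) and the peaks of a constitutively bound factor
(CTCF-like). Standard ChIP-seq cannot compare binding *between* samples
because immunoprecipitation efficiency and depth differ per sample; with the
control factor carried in every library, those confounders can be estimated
and removed, turning read counts into absolute binding occupancy.

The scientific question the pipeline addresses: after hormone stimulation,
is receptor binding **cyclical** (the classical ~45–90 min cycle model) or
a **sustained** step-like increase? Answering it needs per-sample
normalization (else efficiency drift masquerades as dynamics), replicate
variance decomposition (is scatter technical or biological?), and an
operational classification of binding-site trajectories.

## What is in the box

- `pftc.simulate` — a generator producing count matrices with the study's
  structure (10 time points × 6 replicates = 60 samples; site classes with
  sustained, weak, ligand-independent, null and cyclical dynamics;
  negative-binomial counts, `var = μ + φμ²`; per-sample
  efficiency × depth confounders; signal-only lognormal biological noise)
  plus the ground truth to score recovery exactly.
- `pftc.normalize` — consensus peak sets (merged intervals supported by
  more than a given fraction of samples); per-sample factors
  `f_i = Σ_j x_ij m_j / Σ_j x_ij²` (zero-intercept regression of the mean
  control profile `m` on each sample's control counts `x_i`, geometric
  mean rescaled to 1; median-of-ratios alternative); row-max and
  series-max relative normalizations.
- `pftc.stats` — pairwise Welch t-tests and variance F-tests between time
  points with Benjamini–Hochberg FDR; the signal-vs-control
  residual-variance F-test (df 45,45 for the default design) attributing
  excess replicate scatter to biology; per-site and class-average
  profiles.
- `pftc.trajectories` / `pftc.kinetics` — seeded t-SNE embedding with a
  perplexity sweep; deterministic A/B/C site classification on
  (FDR, amplitude, baseline); time-of-max heatmap ordering; nested
  sustained-vs-cyclical least-squares model comparison with an F-ratio
  test and a minimum oscillation-amplitude guard.
- `pftc.pipeline` + the `pftc` CLI — end-to-end orchestration
  (`simulate / normalize / stats / trajectories / run / validate`) with
  config-hash-stamped, bit-reproducible outputs.

The numbered scripts under `analysis/` run the whole study on synthetic
data and narrate what they find; `docs/methods.md` documents the models,
defaults and their rationale.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_single_site_stats.py
```

prints (seed 42):

```
fixture (seed 42): 4500 sites x 60 samples -> results/fixture
  per-sample confounder range: [0.521, 2.094] (what normalization must remove)
factors from 2000 control sites, range [0.460, 1.863]
  recovery of true confounders (Pearson on logs): 0.9996
  control column-mean CV: raw 0.383 -> normalized 0.0063
strongest responder: ER_A_00448 (baseline 29.1, amplitude 155.8 normalized reads)
  t-tests: 8/9 0-min contrasts significant (FDR<0.05), 0/36 others
  variance F-tests among post-stimulation pairs: 2/36 significant
  variance attribution vs CTCF_01408: F = 6.00 (df 45,45), p = 1.70e-08;
    residual CV signal 0.410 vs control 0.167 -> excess scatter is biological
genome-wide: 1612/2500 signal sites respond between 0 and 10 min (FDR < 0.05)
```

Reading it: the simulated per-sample confounders span a 4× range and the
control-regression factors recover them almost perfectly, flattening the
control column means (CV 0.38 → 0.006). At the strongest responder, only
contrasts against the pre-stimulation time point change (binding jumps
before 10 min and then stays flat — sustained, not cyclical), replicate
variance is homogeneous after stimulation, and the responder carries ~6×
the residual variance of a mean-matched control site: the extra scatter is
biological, not technical. `analysis/04_trajectories.py` then classifies
sites (accuracy vs ground truth 0.987; t-SNE class separation stable for
perplexities 30–200 and collapsing at 2 and 5) and
`analysis/05_kinetics.py` adjudicates sustained vs cyclical kinetics
(0.4% false-cyclical calls, 98% detection of full-amplitude 90-min
cycles).

Equivalent one-shot run: `pftc run --simulate --seed 42 --out results/run`,
scored against ground truth with `pftc validate --run-dir results/run`.

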