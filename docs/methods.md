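# Methods

`pftc` analyses transcription-factor binding time courses measured by
quantitative ChIP-seq with an internal control: every library contains both
the dynamic target factor's peaks (an estrogen-receptor-like responder,
"signal") and the peaks of a constitutively bound factor (CTCF-like,
"control"). Because the two factors are immunoprecipitated together, every
per-sample technical confounder — immunoprecipitation efficiency,
sequencing depth, library losses — multiplies signal and control counts
alike, and the biologically constant control peaks identify it.

## Synthetic data model

The generator produces the statistical structure the analysis assumes, at
the study's scale: 10 time points spanning 0–90 min after stimulation,
6 replicates, one library per (time, replicate) sample.

Expected occupancy of site *j* in class *k* at time *t* (all occupancies in
"normalized read count" units, i.e. counts on the common scale after
normalization):

- responsive (A strong, C weak): `b + a·(1 − exp(−t/τ))`,
- constitutive (B) and background (null): `b`,
- cyclical: `b + a·(1 + sin(2π(t − φ)/T))/2`.

The expected count of site *j* in sample *i* is
`occupancy_j(t_i) · efficiency_i · depth_i · mean_depth`, with a further
per-sample multiplicative lognormal biological factor (CV 0.30) on signal
sites only; counts are negative-binomial with variance `μ + 0.02·μ²`.
Setting the dispersion to 0 disables count sampling entirely (counts are
rounded expectations) — the deterministic mode used by exact-recovery
oracles. All randomness derives from one root seed through
`numpy.random.SeedSequence` spawning, so runs are bit-reproducible.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| time points | 0,10,…,90 min | the study design; the classical ~45-min cycle would complete twice |
| replicates | 6 | enough to characterise replicate variance |
| rise constant τ | 2 min | occupancy at t=10 is >99% of plateau, so the 0-min contrasts are the only real differences |
| class A | 35 → 165 | baseline at the reported constitutive level (~30–40 normalized reads); amplitude set so ≥99% of class-A sites clear genome-wide FDR < 0.05 at 6 replicates |
| class C | 10 → 40 | the reported weak-responder profile |
| class B | 35, flat | the reported ligand-independent level (30–40) |
| null | 8, flat | background sites below the constitutive floor |
| cyclical | 0–40, T=90, φ=22.5 | trough at t=0, peak at 45 min (the classically proposed cycle); absent from the default mix, used to test the kinetics assessor |
| class mix | A 600, C 1000, B 400, null 500; 2000 control | large enough for stable FDR behaviour, seconds-scale to simulate |
| control strengths | lognormal, median 500, sdlog 1.0 | a realistic peak-strength distribution spanning ~50–5000 counts |
| efficiency / depth CV | 0.25 / 0.15 | strong enough that unnormalized analysis visibly fails (confounders span ~4×) |
| NB dispersion | 0.02 | overdispersed counts; technical CV ≈ 15% at 500 counts |
| biological CV | 0.30 | signal-only replicate scatter, reflecting the attribution of excess responder variance to biology |

What the generator does **not** model: read-level artefacts (GC,
mappability, fragment length, duplicates), peak-calling uncertainty,
correlated site behaviour (all sites are independent given the sample
effects), or per-site amplitude heterogeneity within a class. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to real-data pathologies upstream of the
count matrix.

## Normalization

Per-sample factors come from control-site counts only. For sample *i* with
control counts `x_i` and the per-site cross-sample mean control profile
`m`, the factor is the zero-intercept least-squares slope
`f_i = Σ_j x_ij·m_j / Σ_j x_ij²`, i.e. the scale that best maps sample *i*
onto the common profile (strong sites dominate, which is desirable: their
relative counting error is smallest). Factors are rescaled to geometric
mean 1 so normalized values stay on a read-count-like scale. A
median-of-ratios estimator (`median_j m_j/x_ij`) is available and agrees
within 5% on the default data; a log-space variant (geometric mean of
ratios) sits behind a flag because it is not stated whether the original
analysis regressed raw or log counts.

Exact properties: on noiseless data the factors equal the inverse sample
confounders exactly. Rescaling one sample's raw counts by *c* divides its
factor by *c* only up to O(1/n): the rescaled column also shifts the
arithmetic-mean reference by (c−1)/n, and the geometric-mean recentring
couples the global scale to all samples. The equivariance test therefore
compares up to one global scalar at a 2% band (n = 60).

Consensus peak sets merge per-sample intervals by ≥1-bp overlap (half-open
coordinates; abutting intervals do not merge) and keep a merged interval
iff strictly more than the given fraction of samples contribute — "over
50%" is a strict inequality, so 3 of 6 samples is not enough.

The row-relative view divides each site's replicate-averaged profile by
its maximum (ties resolve to the earliest time point; all-zero rows are
excluded and reported). It is idempotent and bounded in [0,1], and is used
for the time-of-max heatmap and for re-scaling externally digitized series
(`normalize_series_to_max`).

## Temporal statistics

- Pairwise time-point comparisons: two-sided Welch t-tests (unequal
  variances; the pooled-variance flavour was not stated, and Welch is the
  safer default given mean-dependent variance), BH-adjusted within the
  45-pair per-site family. Tests run on the natural normalized scale;
  log2(x+0.5) is available for the zero-inflated 0-min groups. Degenerate
  inputs follow the conventions p = 1 (both groups constant and equal) and
  p = 0 flagged (constant but different).
- Genome-wide response: Welch 0-vs-10 per site with BH across sites — a
  deliberate simplification of a count-model differential test; with 6
  replicates on normalized counts the Welch test is well calibrated (the
  type-I property test holds it to binomial bounds around 0.05).
- Pairwise variance F-tests: `F = s²_a/s²_b`, df (5,5), two-sided
  `p = 2·min(P(F≤f), P(F≥f))`. Note a structural property of the
  multiplicative noise model: replicate variance scales with the squared
  mean, so a strong responder's 0-min variance is genuinely lower than its
  post-stimulation variance and 0-min pairs can reject; variance is
  homogeneous — and the tests assert it — among the post-stimulation time
  points.
- Variance attribution: pool all samples at t ≥ 10 min, subtract each
  site's per-time means (isolating replicate scatter from any residual
  time trend — the residualization is this package's choice), and compare
  the signal site's residual variance to a mean-matched control site's
  with df (N−T, N−T) = (45,45). Residual CVs are reported alongside since
  it is not stated whether the original comparison used raw or
  mean-scaled variances.

BH adjustment is implemented directly (step-up, cumulative minimum from
the largest rank) and property-tested against the literal definition and
against statsmodels.

## Trajectory classification

t-SNE embeds per-site replicate-averaged profiles (10 dimensions). The
embedding is seeded and deterministic, swept over perplexities
{2, 5, 30, 50, 100, 200}; class separation (centroid distance over mean
within-class spread between responsive and constitutive sites) is stable
for 30–200 and collapses at 2 and 5. Because cluster membership read off a
t-SNE map is not a reproducible definition, classes are assigned by an
explicit rule on per-site statistics, and the embedding is never an input
to classification:

- responsive (FDR < 0.05 and amplitude > 0): class **A** if amplitude ≥
  split else class **C**;
- non-responsive with baseline ≥ 20 normalized reads: class **B**;
- otherwise unassigned.

Amplitude is `mean(occupancy, t ≥ 10) − mean(occupancy, t = 0)`. The
default A/C split is an exact one-dimensional two-means partition of the
responsive amplitudes: the amplitude distribution is bimodal (weak and
strong responders) and the two-means boundary falls in the gap regardless
of the mixture proportions, whereas an upper-quartile cut assumes strong
responders are exactly a quarter of responders and misassigns the A/C
boundary otherwise. `quartile` and explicit numeric thresholds remain
config options, and the weak/strong boundary is the least-determined
threshold in the whole analysis — revisit it on real data.

Trajectory recovery (the two-major-trajectories check) clusters the t-SNE
map of **row-max-normalized** (shape) profiles into two groups: the
responsive/constitutive distinction is a statement about temporal shape,
and in absolute units a two-way partition prefers splitting off the
low-occupancy background class instead. On shape profiles the k=2 split
recovers the ground-truth responsive vs ligand-independent partition with
≥ 99% agreement.

The heatmap ordering groups sites into time-of-max blocks (within-block by
descending mean occupancy) and applies the same order to the row-relative
and absolute views; the "peaks at 0 min" block consists of flat sites
whose maximum lands on 0 by noise — their mean amplitude is far below
their replicate scatter, and the block vanishes in the absolute view.

## Kinetics assessment

Sustained model `b + a(1 − e^{−t/τ})` (3 parameters) versus cyclical model
(sustained + `A·sin(2π(t−φ)/T)`, period from the grid
{30, 45, 60, 90, 120} min; 6 parameters). Fits are deterministic
least squares: τ is profiled over a fixed grid with golden-section
refinement, the remaining parameters solved linearly for each candidate
period. The cyclical model is preferred only if the nested F-ratio for the
3 extra parameters exceeds the α = 0.05 critical value **and** the fitted
oscillation amplitude is ≥ 20% of the fitted plateau (guarding against
significant-but-negligible wiggles; both thresholds are config-exposed).
On the default noise the assessor shows ~0.4% false-cyclical calls on
sustained sites and ~98% detection of full-amplitude 90-min cycles, with
the fitted period within one grid step of 90 min. Fewer than 8 time points
is an error (the cyclical model would be under-determined).

## Pipeline

`pftc run` executes simulate (or load fixture) → normalize → stats →
trajectories; a `RunConfig` (YAML) fully determines the run, every output
table carries the config hash and root seed in a comment line, and
`run_record.yaml` embeds the resolved config — identical config and seed
reproduce every file bit-exactly. `pftc validate` scores a simulated run
against its ground truth: factor-recovery correlation (log recovered
factors vs −log true confounders), classification confusion matrix and
accuracy.

## Numerical conventions and problem sizes

Ties for any maximum resolve to the earliest time point. All intervals are
0-based half-open. Factors are finite and positive or the offending sample
is named in an error. The test suite and the reproduction script run the
full 4500-site × 60-sample design for single-pass computations and
stratified subsamples (700 sites) for the t-SNE perplexity sweep; the
kinetics operating characteristics use a dedicated 1000-site dataset.

## Known limitations

- The variance F-tests assume approximate normality within replicate
  groups; lognormal-times-NB data is right-skewed, which makes them
  slightly anti-conservative (the permutation cross-check in the tests
  quantifies the agreement).
- The genome-wide response test is a Welch test on normalized counts, not
  a negative-binomial GLM; no moderated variance shrinkage is applied.
- Classification assumes classes are tight in occupancy units; strong
  per-site strength heterogeneity within a class would require re-thinking
  the fixed baseline floor and amplitude split.
- The generator's independence assumptions understate the correlation
  structure of real cistromes.
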