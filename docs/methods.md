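# Methods

## The analysis in brief

`traitnet` implements a dimensional brain–behaviour analysis on weighted,
unthresholded connectomes of the 90 cerebral AAL regions:

1. **Functional connectomes.** ROI-averaged BOLD series (990 retained time
   points at 2 Hz) are detrended (intercept + linear trend per region),
   nuisance regressors (motion parameters, mean WM/CSF signals or their
   simulated proxies) are removed by ordinary least squares, the residuals
   are band-pass filtered to 0.01–0.1 Hz, and the zero-lagged Pearson
   correlation matrix is formed with zeros on the diagonal.
2. **Structural connectomes.** Probabilistic-tractography streamline counts
   are converted to directed connection probabilities,
   `count[i,j] / (n_i × 5000)` with `n_i` the seed region's voxel count and
   5000 samples per voxel, then symmetrized by averaging the two directions.
3. **Network metrics.** Nodal strength, characteristic path length, global
   efficiency, nodal and global clustering, and nodal local efficiency, all
   on the raw (unthresholded) weights with edge length defined as the
   reciprocal weight.
4. **Association statistics.** Metrics and behavioural measures are
   z-transformed; five confounds (age, sex, full-scale IQ, mean framewise
   displacement, brain volume) are regressed out of each metric; Spearman's
   ρ between the residuals and each behavioural measure is tested with a
   nearest-tail permutation p-value and, for nodal families, a 5%
   Benjamini–Hochberg FDR threshold.  A-priori (behaviour, region) pairs —
   by default the three theory-of-mind scores × right supramarginal gyrus,
   the AAL parcel containing the right temporoparietal junction — are
   exempted from FDR and reported with the uncorrected one-tailed p.

## Weight policies: what the unthresholded convention leaves open

Functional correlations can be negative while the distance transform `1/w`
requires non-negative weights.  `WeightPolicy` makes the resolution explicit
rather than implicit:

* `negative_mode` — `absolute` (default), `clip_to_zero`, or `keep`
  (distance-based measures then refuse to run).  The default preserves the
  reading that any non-zero weight represents adjacency.
* `degree_mode` — the `k_i` in the clustering and local-efficiency
  denominators: `binary` neighbour count (default; the convention of the
  widely used connectivity toolboxes) or the `weighted` degree (the
  definition as often printed).  Both are tested against independent
  brute-force oracles.
* `normalize_for_clustering` — whether clustering-family measures use a
  per-subject copy rescaled by the maximum off-diagonal magnitude (default
  on), making them scale-free per subject.

Local efficiency of node *i* restricts shortest paths to the subgraph
induced by *i*'s neighbours and evaluates
`E_i = ½ Σ_{j≠m∈N(i)} (w_ij w_im / d_jm(N_i))^{1/3} / (k_i(k_i−1))`.
Printed forms of this formula vary (including pairing `w_ij` with `w_jm`);
the implementation follows the standard per-neighbour-pair form, and the
brute-force neighbourhood-subgraph oracle in the test suite — not any
particular typography — is the contract.  Nodes with fewer than two
neighbours score zero, as do clustering coefficients where `k_i(k_i−1)` is
degenerate.

Characteristic path length over disconnected pairs is configurable:
`exclude` (default) averages finite pairs with a warning, `strict` raises.
Unthresholded matrices make disconnection rare, but structural matrices can
contain empty rows in principle.

## Band-pass implementation

The band (0.01–0.1 Hz) is a study constant; the filter realization is not.
On records of ~10³ samples a forward–backward IIR design (Butterworth,
available as `method="butter"`) rejects a strong 0.5 Hz component by five
orders of magnitude mid-record but leaks a few percent of its variance
through start/end transients, because the 0.01 Hz high-pass edge has an
impulse response spanning hundreds of samples.  The default is therefore an
FFT mask (`method="fft"`) that zeroes Fourier coefficients outside the band
— the ideal-filter convention of the resting-state preprocessing toolchains
this pipeline emulates — which passes a 0.05 Hz component essentially
unchanged and suppresses DC and 0.5 Hz components to numerical noise.

## Permutation inference and its calibration

The permutation p-value is `(min(#{ρ_rand < ρ_obs}, #{ρ_rand > ρ_obs}) + 1) / N`
with `N` permutations of the behaviour vector against the fixed residualized
metric (default `N = 10000`).  This "nearest-tail" construction is
deliberately reproduced as defined, and users should understand its null
behaviour: the statistic lives on `{1/N, …, ~½}` with `P(p ≤ a) ≈ 2a`, so
thresholding at 0.05 admits roughly 10% of true nulls — it is a one-sided
p-value whose side is chosen by the data.  The test suite measures exactly
this (the doubled level and the uniform-on-support distribution).  For a
directional a-priori hypothesis the same number is the ordinary one-tailed
p.  Benjamini–Hochberg correction is applied within the family of 90 nodal
p-values per (behaviour, metric) combination; exempt pairs are removed from
their family before correction.

Permutations are generated from a `SeedSequence` tree rooted at the analysis
seed, one child per (behaviour, metric, region) test in deterministic order,
so the full association table is bit-reproducible from (inputs, seed).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's own scale, so every stage is testable without acquired data:

* **ROI series.** Per subject, Gaussian noise coloured by the Cholesky
  factor of a module-structured target correlation matrix (6 modules,
  within/between levels 0.45/0.10 at baseline), plus a linear drift and
  cardiac (0.9 Hz) and respiratory (0.3 Hz) sinusoids with global phase and
  per-region loadings.  Sine/cosine proxies of the physiological components
  are exposed as nuisance regressors; drift is left to detrending.
* **Motion.** AR(1) random-walk traces (φ = 0.97) for three translations
  (mm) and three rotations (rad, scaled by the 50 mm FD sphere), with
  per-subject step scales spanning mean FD ≈ 0.05–0.5 mm.  Mean FD computed
  from these traces is the head-motion confound.
* **Streamline counts.** `Binomial(n_i × 5000, P_true[i,j])` per directed
  pair, with per-region voxel counts in [200, 1200] and a mildly asymmetric
  modular base probability matrix (row sums ≤ 1; the remainder are
  streamlines that reach no target).
* **Behaviour and confounds.** Nineteen measures on the scales of the
  instrument battery they mimic (questionnaire points, ms, s); confounds
  drawn from plausible adult-cohort ranges (age ≈ 27 ± 3 y, FSIQ ≈ 109 ± 8,
  brain volume ≈ 1.35 × 10⁶ mm³), each contributing a standardized
  coefficient of 0.10–0.15 to every measure.  Full-scale IQ doubles as a
  behavioural measure and a confound, as in the real design.

**Effect planting** manipulates topology, not metric values.  A latent
severity `u ~ N(0,1)` (truncated at ±2.5) moves both correlation levels
through `s = 2·tanh(u/2)`: within = 0.45 + 0.22 s, between = 0.10 + 0.06 s.
The map is strictly monotone (no clipping plateaus, which destroy rank
reliability in the tails), so the designated metric — by default global
efficiency of the functional connectome — is a monotone function of `u`,
and the full pipeline must recover it from simulated time series.  The
planted behaviour is `b = m̃(u) + Σ c_k z_k + σ ε` with `m̃` the true metric
standardized by its population moments; `σ` is calibrated by bisection on a
5000-draw rehearsal so the population Spearman between behaviour and the
*true* metric hits the target (±0.005, well inside the ±0.05 contract).  A
target that the irreducible confound contribution makes unreachable raises
an error; a zero target sets the signal amplitude to zero exactly.

What the generator does **not** emulate: haemodynamic convolution and
temporal autocorrelation of BOLD, spatially heterogeneous (non-modular)
connectivity, motion artefacts that corrupt the series themselves,
distance-dependent tractography biases, and item-level questionnaire
structure.  Passing tests therefore demonstrate the correctness and
calibration of the *analysis*, not the physiology of real data.

## Known quantitative behaviour

Two consequences of the design are worth stating because the test suite
measures them:

* With 990 samples band-limited to 0.01–0.1 Hz (~90 effective degrees of
  freedom), per-edge correlation noise is ≈ 0.1 SD; the rank reliability of
  estimated global efficiency across subjects is ≈ 0.98 under the default
  planting, and residualizing the metric on intercept + 5 confounds at
  n = 30 discards a further √(1 − 6/30) of the sample signal.  A planted
  true-metric Spearman of 0.5 is therefore observed at ≈ 0.44 through the
  full pipeline, and one-sided detection power at α = 0.05 sits near 0.8.
* The nearest-tail permutation p doubles the nominal level under the null
  (≈ 10% rejections at a 0.05 threshold), as described above.

## Problem sizes used by the test and acceptance harnesses

Unit tests run on reduced cohorts (12 subjects, 30 regions, 240 time
points); oracle suites use 200 random graphs with up to 20 nodes; power and
calibration checks use study-scale cohorts (30 × 90 × 990) with 200 repeats
for power, 300–1000 repeats for null calibration, and permutation counts of
500–1000 in place of the production default of 10000.  These sizes are the
package's own choice of simulation budget; all statistical conclusions they
support are stated with matching Monte-Carlo tolerances.
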