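# Methods

## Release model

Evoked EPSP amplitudes are modeled as uniform binomial quantal release:
`X = q·Binomial(n, p)` plus additive zero-mean Gaussian background noise of
SD `σ_bg`. The model assumes (i) uniform `p` and `q` across the `n` sites,
(ii) at most one quantum per site per stimulus, (iii) independent release
across sites with linear summation, and (iv) constant `n` over the
experiment. These assumptions are what make `CV = sqrt((1−p)/(n·p))`
independent of `q` and hence a presynaptic metric; Poisson or multiquantal
release models are out of scope. Where they are violated (e.g.
multivesicular release), CV analysis may still rank loci correctly but the
closed-form inversions (`p = 1/(n·CV²+1)`) no longer hold exactly.

## Reference experiment and simulator

The simulator's defaults describe a typical layer-5 pyramidal-cell paired
recording: `n = 5` release sites, `q = 0.35 mV`, baseline `p = 0.55`,
presynaptic LTD as a step to `p = 0.4` at induction, `σ_bg = 0.1 mV` fixed
across epochs, 60 baseline and 240 post-induction sweeps at a 10-s
inter-stimulus interval (a 10-min baseline and a 40-min follow-up).
Induction is an instantaneous parameter switch; no sweeps are drawn during
it. Ensembles default to 150 repetitions.

Two baseline corruptions are available:

* **Outlier** — a single sweep shifted upward by `0.1·2^j` mV (j = 0..5,
  i.e. 0.1–3.2 mV; in analytic z-score units `shift / (q·sqrt(n·p·(1−p)))`,
  0.26–8.2). The z-score deliberately excludes the background-noise term,
  which is what reproduces the reference values 4.1 and 8.2 at shifts 1.6
  and 3.2 mV. The shifted sweep defaults to the middle baseline sweep;
  ensemble-mean bias is insensitive to the placement (tested).
* **Trend** — a zero-mean arithmetic ramp of `0.6·2^j` µV per sweep
  (3.6·2^j µV/min at the 10-s ISI, so j = 4, 5 give 57.6 and 115.2 µV/min).
  Zero-mean centering means the ramp changes only the baseline variance,
  never its mean.

Both corruptions inflate the baseline CV only, raising
`1/CV²_norm = (CV_base/CV_post)²` toward the horizontal postsynaptic line
and biasing a genuinely presynaptic LTD toward a postsynaptic call.

### Randomness and pairing

All draws come from `numpy.random.default_rng`. Repetition `i` of an
ensemble is seeded by `SeedSequence([base_seed, i])`, so ensembles are
bit-reproducible across machines. In the corruption-magnitude sweeps the
per-repetition seeds are deliberately **shared across conditions** (common
random numbers): repetition `i` experiences every corruption magnitude on
the same underlying draws, so condition differences are paired comparisons.
This matters because at the two or three smallest magnitudes the corruption
moves `1/CV²_norm` by only ~10⁻⁴–10⁻³, far inside the between-ensemble
sampling noise (SEM ≈ 0.011 at 150 repetitions); with independent draws the
bias curve's small-j ordering would be dominated by noise rather than by
the corruption.

Even with pairing, two resolution limits remain and are documented rather
than hidden. First, the classification fraction has 1/150 granularity, and
at small magnitudes the expected change in the presynaptic fraction between
adjacent conditions is well below one repetition, so single repetitions can
flip against the trend (per-repetition baseline variance is a parabola in
the ramp slope whose minimum sits at a noise-determined slope of SD ≈ 3
µV/sweep, larger than the j ≤ 2 slopes). Second, a small outlier raises the
baseline mean almost as much (in CV terms) as it raises the variance, so
the expected `1/CV²_norm` is nearly flat below shifts of ~0.3 mV. The bias
direction is therefore asserted on the ensemble-mean coordinates and on the
large-magnitude fraction collapse, not on rep-for-rep fraction
monotonicity at every adjacent pair.

## Analysis choices

* Sample SDs use the `n−1` denominator.
* Background-noise correction (`σ² = σ_measured² − σ_bg²`) is available but
  **off by default**: with stable background noise it barely moves the
  normalized coordinates, and it can fail (noise-dominated epochs raise an
  error rather than returning imaginary SDs).
* The angle `φ` is computed as
  `arccos(v·d / |v||d|)` between the vector `v` from (1, 1) to the point
  and the diagonal direction `d` oriented toward the plasticity change,
  signed positive on the presynaptic side of the diagonal (below it for
  LTD, above for LTP). Group significance uses a one-sample two-tailed
  t-test of the per-experiment angles against 0, with a Wilcoxon
  signed-rank test in parallel; per-experiment angles are averaged (rather
  than taking the angle of the averaged point) so that `n` in the test is
  the number of experiments.
* Locus bands: presynaptic when `φ ≥ 0`; postsynaptic when `φ` is within
  15° of −45°; mixed otherwise, in that order. The 15° half-width is a
  package default for "on or close to the horizontal line" — no canonical
  numeric boundary exists — and is configurable (`delta_post_deg`).
* `binned_inv_cv2` computes 1/CV² over consecutive fixed-size sweep bins
  (trailing partial bin dropped, zero-CV bins reported as `inf`) to expose
  gradual trends in release statistics.

## Quality control

* **Baseline stability**: t-test of Pearson's r between amplitude and time
  over the baseline, `t = r·sqrt((N−2)/(1−r²))`; stable iff p ≥ 0.05.
  Its type-I error on stationary baselines is ≈ 5% by construction
  (verified by simulation).
* **Trend estimate**: least-squares slope in µV/min, for threshold-based
  exclusion of drifting experiments. Detrending is intentionally not
  offered — it injects model-dependent bias; exclude or truncate instead.
  No default exclusion threshold is imposed; it is a user parameter to be
  applied identically to condition and control experiments.
* **Recording stability**: input-resistance change < 30% and membrane-
  potential change < 8 mV, measured between the means of the first and
  last 10% of sweeps (the comparison window is a package choice).
* **Outlier screening**: sweeps deviating from their epoch mean by ≥ z
  threshold binomial-trial SDs are flagged, never removed; the report
  carries an advisory that removal requires independent evidence of a
  cause. Flags are invariant under constant amplitude offsets.
* **Paired-pulse ratio**: `amp2/amp1`; across sweeps the mean of per-sweep
  ratios is used (a documented choice; the ratio of means is the common
  alternative).

## Numerical and interface details

* All amplitudes are mV; trend slopes are µV/sweep internally and µV/min at
  interfaces; times are seconds; sweep indices are 0-based.
* Degenerate cases raise typed errors: `p = 0` or `p = 1` where a CV or
  z-score would be undefined, post-induction epochs with zero CV, points at
  (1, 1) for `φ`, noise-dominated corrected variances.
* Sweep CSVs are written with 6-significant-digit formatting and a fixed
  column order, so identical runs are byte-identical.

## What the simulations do and do not show

The generator reproduces the statistical structure CV analysis consumes —
binomial amplitude fluctuations, stationary Gaussian background noise, step
plasticity, and controlled corruptions. It does not emulate real-data
features such as short-term dynamics within spike bursts, slow drifts in
`q` or `n`, non-uniform release sites, amplitude-measurement error from
overlapping PSPs, or recording dropouts. Passing tests therefore validate
the analysis pipeline and its failure modes under the binomial model; they
do not certify that any particular biological dataset satisfies that model.

## Problem sizes

Default test and example runs use 150-repetition ensembles of 300-sweep
experiments (the reference design), 10⁴-sweep series for parameter-recovery
checks, and 1000 repetitions for the stability test's type-I error; the
full suite completes in a few seconds on one CPU.
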