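# cvlocus

Coefficient-of-variation (CV) analysis for localizing the expression of
long-term synaptic plasticity — presynaptic (a change in release
probability) versus postsynaptic (a change in quantal size) — together with
a Monte-Carlo simulator of plasticity experiments and reproductions of the
classic pitfalls that corrupt the method (single outlier sweeps, baseline
trends).

It is written for electrophysiologists analyzing evoked EPSP amplitude time
series from paired recordings (or careful extracellular stimulation), and
for anyone who wants to understand quantitatively why CV analysis works and
when it misleads.

## The model and the statistic

Synaptic transmission is modeled as binomial quantal release: `n`
independent release sites each release at most one vesicle per stimulus
with probability `p`, and each released quantum contributes `q` mV, so the
evoked amplitude is `X = q·Binomial(n, p)` with

```
E[X]  = μ  = n·p·q
Var[X] = σ² = n·p·(1−p)·q²        ⇒   CV = σ/μ = sqrt((1−p)/(n·p))
```

The CV is independent of `q`: synaptic noise is a purely presynaptic
signature. Plotting the normalized `1/CV²` against the normalized mean
`μ_norm` (post-induction over baseline) turns this into geometry:

* `1/CV² ∝ p` for fixed `n`, via `p = 1/(n·CV² + 1)`;
* a purely postsynaptic change (only `q`) moves the point along the
  horizontal line `y = 1`;
* a purely presynaptic change (only `p`) lands at
  `(c_pre, c_pre(1−p₀)/(1−c_pre·p₀))` with `c_pre = p/p₀`, whose chord from
  the no-change point (1, 1) has slope `1/(1−c_pre·p₀) > 1` — beyond the
  unity diagonal.

Each experiment is summarized by the signed angle `φ` between the diagonal
and the vector from (1, 1) to its point (`φ = 0` on the diagonal, `−45°` on
the horizontal line, positive on the presynaptic side), and classified as
presynaptic (`φ ≥ 0`), postsynaptic (within 15° of `−45°`), or mixed.

## Worked example

```
$ python examples/simulate_and_analyze.py
baseline mean: 0.959 mV (theory n*p*q = 5*0.55*0.35 = 0.9625 mV)
post mean:     0.749 mV (theory 0.7000 mV)
mu_norm = 0.780   (normalized strength change; < 1 means LTD)
1/CV^2_norm = 0.695   (proxy for the release-probability change)
phi = +9.2 deg   (angle from the diagonal; positive = presynaptic side)
direction = LTD, locus = presynaptic
```

One simulated experiment (60 baseline + 240 post-induction sweeps at 10-s
intervals) where the release probability dropped from 0.55 to 0.4 at
induction: the mean fell to 78% of baseline (LTD) and `1/CV²` fell with it
— the point lies below the diagonal, so the depression is called
presynaptic, which is the ground truth of the simulation.

The other examples show the pitfalls and the screening tools:

```
$ python examples/outlier_bias.py     # one bad sweep drags the call postsynaptic
$ python examples/trend_bias.py       # so does a baseline run-up
$ python examples/qc_screening.py     # Pearson-r stability test, trend estimate,
                                      # Rin/Vm criteria, advisory outlier flags
```

A thin CLI wraps the same functions:

```
cvlocus simulate --seed 1 -o exp.csv
cvlocus analyze exp.csv
cvlocus qc exp.csv
cvlocus sweep-outlier --seed 1 -o outlier_summary.csv
cvlocus sweep-trend   --seed 1 -o trend_summary.csv
```

Sweep files are plain CSV (`sweep,time_s,epoch,amplitude_mV`, optional
`rin_mohm,vm_mv` columns), so recorded experiments can be analyzed the same
way as simulated ones.

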