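"""Monte-Carlo simulation of long-term plasticity experiments.

One simulated experiment is an ordered series of evoked EPSP amplitudes
("sweeps"): a baseline epoch, an instantaneous induction switch of the
release parameters, and a post-induction epoch.  Each amplitude is drawn as
q * Binomial(n, p) plus Gaussian background noise.  Two controlled
corruptions can be injected into the baseline to study their effect on CV
analysis: a single outlier sweep shifted upward by a fixed amount, and a
zero-mean linear trend (run-up/run-down).

The reference design mirrors a typical paired-recording experiment:
60 baseline sweeps and 240 post-induction sweeps at a 10-s inter-stimulus
interval (10-min baseline, 40-min follow-up), n = 5 release sites,
q = 0.35 mV, background-noise SD 0.1 mV, and presynaptic LTD implemented as
p: 0.55 -> 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .quantal import InvalidParameterError, QuantalParams

__all__ = [
    "ExperimentDesign",
    "PlasticityScenario",
    "Perturbation",
    "SweepSeries",
    "default_ltd_scenario",
    "simulate_experiment",
    "make_ramp",
    "trend_rate",
    "run_monte_carlo",
    "derive_seed",
]

BASELINE = "baseline"
POST = "post"
INDUCTION = "induction"


class ConfigurationError(ValueError):
    """Inconsistent experiment configuration (e.g. outlier outside baseline)."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Sweep layout of a plasticity experiment.

    Defaults correspond to a 10-min baseline and a 40-min post-induction
    period at one stimulus every 10 s.
    """

    n_baseline_sweeps: int = 60
    n_post_sweeps: int = 240
    isi_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_baseline_sweeps < 1 or self.n_post_sweeps < 1:
            raise ConfigurationError("sweep counts must be >= 1")
        if self.isi_s <= 0:
            raise ConfigurationError("isi_s must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_baseline_sweeps + self.n_post_sweeps


@dataclass(frozen=True)
class PlasticityScenario:
    """Release parameters before and after induction.

    Background noise is a recording property, not a synaptic one, so it must
    be identical in both epochs.
    """

    baseline_params: QuantalParams
    post_params: QuantalParams

    def __post_init__(self) -> None:
        if self.baseline_params.sd_background != self.post_params.sd_background:
            raise ConfigurationError(
                "sd_background must be identical in baseline and post epochs"
            )


@dataclass(frozen=True)
class Perturbation:
    """Baseline corruptions: a single outlier and/or a zero-mean linear trend.

    ``outlier_shift`` (mV) is added to the sweep at baseline index
    ``outlier_sweep``; ``trend_uv_per_sweep`` is the per-sweep increment of a
    zero-mean ramp added across the baseline epoch, in microvolts per sweep.
    """

    outlier_shift: float = 0.0
    outlier_sweep: Optional[int] = None
    trend_uv_per_sweep: float = 0.0

    def __post_init__(self) -> None:
        if self.outlier_shift < 0:
            raise ConfigurationError("outlier_shift must be >= 0 mV")

    @property
    def is_null(self) -> bool:
        return (
            self.outlier_shift == 0.0
            and self.trend_uv_per_sweep == 0.0
        )


@dataclass(frozen=True)
class SweepSeries:
    """One simulated or recorded experiment: per-sweep EPSP amplitudes.

    ``epoch_labels`` mark each sweep as baseline/post (or induction for
    recorded files; induction sweeps are excluded from analysis epochs).
    Optional input-resistance and membrane-potential channels ride along for
    recording-stability QC.
    """

    amplitudes: np.ndarray
    times: np.ndarray
    epoch_labels: np.ndarray
    seed: Optional[int] = None
    rin_mohm: Optional[np.ndarray] = None
    vm_mv: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.times, dtype=float)
        lab = np.asarray(self.epoch_labels, dtype=object)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "epoch_labels", lab)
        if not (len(amp) == len(t) == len(lab)):
            raise ConfigurationError("amplitudes, times and epoch_labels must align")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ConfigurationError("times must be strictly increasing")
        for name in ("rin_mohm", "vm_mv"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                object.__setattr__(self, name, ch)
                if len(ch) != len(amp):
                    raise ConfigurationError(f"{name} channel must align with sweeps")

    def __len__(self) -> int:
        return len(self.amplitudes)

    def epoch(self, label: str) -> np.ndarray:
        """Amplitudes of the sweeps carrying the given epoch label."""
        return self.amplitudes[self.epoch_labels == label]

    def epoch_times(self, label: str) -> np.ndarray:
        return self.times[self.epoch_labels == label]

    @property
    def baseline(self) -> np.ndarray:
        return self.epoch(BASELINE)

    @property
    def post(self) -> np.ndarray:
        return self.epoch(POST)


def default_ltd_scenario(
    n_sites: int = 5,
    p_baseline: float = 0.55,
    p_post: float = 0.4,
    q_amp: float = 0.35,
    sd_background: float = 0.1,
) -> PlasticityScenario:
    """Presynaptically expressed LTD: p drops 0.55 -> 0.4, q fixed at 0.35 mV."""
    return PlasticityScenario(
        baseline_params=QuantalParams(n_sites, p_baseline, q_amp, sd_background),
        post_params=QuantalParams(n_sites, p_post, q_amp, sd_background),
    )


def make_ramp(n_sweeps: int, slope_uv_per_sweep: float) -> np.ndarray:
    """Zero-mean arithmetic ramp in mV, one offset per sweep.

    Consecutive offsets differ by ``slope_uv_per_sweep`` microvolts; the
    ramp is centered so the offsets sum to exactly zero, leaving the epoch
    mean untouched while inflating its variance.
    """
    if n_sweeps < 1:
        raise ConfigurationError("n_sweeps must be >= 1")
    slope_mv = slope_uv_per_sweep / 1000.0
    idx = np.arange(n_sweeps, dtype=float)
    return (idx - (n_sweeps - 1) / 2.0) * slope_mv


def trend_rate(slope_uv_per_sweep: float, isi_s: float) -> float:
    """Convert a per-sweep trend to a rate in microvolts per minute."""
    if isi_s <= 0:
        raise ConfigurationError("isi_s must be > 0")
    return slope_uv_per_sweep * (60.0 / isi_s)


def _draw_epoch(
    rng: np.random.Generator, n_sweeps: int, params: QuantalParams
) -> np.ndarray:
    quanta = rng.binomial(params.n_sites, params.p_release, size=n_sweeps)
    amps = params.q_amp * quanta.astype(float)
    if params.sd_background > 0:
        amps += rng.normal(0.0, params.sd_background, size=n_sweeps)
    return amps


def simulate_experiment(
    design: ExperimentDesign,
    scenario: PlasticityScenario,
    perturb: Perturbation = Perturbation(),
    seed: int = 0,
) -> SweepSeries:
    """Simulate one plasticity experiment as a sweep series.

    Each amplitude is q*Binomial(n, p_epoch) + Normal(0, sd_background);
    the baseline epoch additionally receives the zero-mean ramp and, on one
    designated sweep, the outlier shift.  Identical seeds give bit-identical
    series.

    The outlier sweep defaults to the middle baseline sweep
    (index n_baseline // 2) when a shift is requested without an index.
    """
    rng = np.random.default_rng(seed)
    nb, npost = design.n_baseline_sweeps, design.n_post_sweeps
    base = _draw_epoch(rng, nb, scenario.baseline_params)
    post = _draw_epoch(rng, npost, scenario.post_params)

    if perturb.trend_uv_per_sweep != 0.0:
        base = base + make_ramp(nb, perturb.trend_uv_per_sweep)
    if perturb.outlier_shift > 0.0:
        idx = perturb.outlier_sweep
        if idx is None:
            idx = nb // 2
        if not (0 <= idx < nb):
            raise ConfigurationError(
                f"outlier_sweep {idx} outside baseline epoch [0, {nb})"
            )
        base = base.copy()
        base[idx] += perturb.outlier_shift
    elif perturb.outlier_sweep is not None and not (
        0 <= perturb.outlier_sweep < nb
    ):
        raise ConfigurationError("outlier_sweep outside baseline epoch")

    amps = np.concatenate([base, post])
    times = np.arange(nb + npost, dtype=float) * design.isi_s
    labels = np.array([BASELINE] * nb + [POST] * npost, dtype=object)
    return SweepSeries(amplitudes=amps, times=times, epoch_labels=labels, seed=seed)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-repetition seed from a base seed and index path.

    Uses numpy's SeedSequence entropy pooling so repetitions are mutually
    well-separated yet fully reproducible across machines.
    """
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_monte_carlo(
    design: ExperimentDesign,
    scenario: PlasticityScenario,
    perturb: Perturbation = Perturbation(),
    n_reps: int = 150,
    base_seed: int = 0,
) -> List[SweepSeries]:
    """Simulate ``n_reps`` independent experiments.

    Repetition ``i`` is seeded with ``derive_seed(base_seed, i)``, so the
    ensemble is reproducible and, across perturbation conditions run with
    the same ``base_seed``, repetition ``i`` reuses the same underlying
    random draws (paired comparisons across conditions).
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    return [
        simulate_experiment(design, scenario, perturb, seed=derive_seed(base_seed, i))
        for i in range(n_reps)
    ]
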