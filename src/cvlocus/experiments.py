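"""Monte-Carlo pitfall experiments: how baseline corruptions bias CV analysis.

Two systematic sweeps over corruption magnitude, each with 150 repetitions
of the reference presynaptic-LTD experiment (p: 0.55 -> 0.4, n = 5,
q = 0.35 mV, 60 baseline / 240 post sweeps, 0.1-mV background noise):

* outlier sweep — a single baseline response shifted by 0.1 * 2^j mV for
  j = 0..5 (analytic z-scores up to 8.2);
* trend sweep — a zero-mean baseline ramp of 0.6 * 2^j microvolts per sweep
  for j = 0..5 (up to 115.2 uV/min at the 10-s inter-stimulus interval).

Both corruptions inflate only the baseline variance, so they raise
1/CV^2_norm = (CV_base/CV_post)^2 and drag a genuinely presynaptic LTD
toward the horizontal postsynaptic line — the ensemble fraction of
repetitions classified presynaptic falls as the corruption grows.

Repetition i uses the same random draws in every condition of a sweep
(paired comparison), so the bias trend across conditions is not masked by
between-condition sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .analysis import PRESYNAPTIC, CVResult, analyze_series
from .quantal import CVPoint
from .simulate import (
    ExperimentDesign,
    Perturbation,
    PlasticityScenario,
    SweepSeries,
    default_ltd_scenario,
    run_monte_carlo,
    trend_rate,
)

__all__ = [
    "SweepCondition",
    "EnsembleSummary",
    "OUTLIER_SHIFTS_MV",
    "TREND_SLOPES_UV_PER_SWEEP",
    "summarize_ensemble",
    "analyze_ensemble",
    "outlier_sweep_experiment",
    "trend_sweep_experiment",
]

J_LEVELS = range(6)
# Corruption magnitude doubles per level: 0.1*2^j mV shift, 0.6*2^j uV/sweep ramp.
OUTLIER_SHIFTS_MV = tuple(0.1 * 2**j for j in J_LEVELS)
TREND_SLOPES_UV_PER_SWEEP = tuple(0.6 * 2**j for j in J_LEVELS)


@dataclass(frozen=True)
class SweepCondition:
    """One condition of a corruption-magnitude sweep."""

    j_level: int
    perturb_kind: str  # "outlier" | "trend"
    magnitude: float  # mV shift or uV/sweep slope
    n_reps: int = 150

    def __post_init__(self) -> None:
        if not (0 <= self.j_level <= 5):
            raise ValueError("j_level must be in 0..5")
        if self.perturb_kind not in ("outlier", "trend"):
            raise ValueError("perturb_kind must be 'outlier' or 'trend'")


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-condition ensemble summary of CV-analysis outcomes."""

    mean_point: CVPoint
    sem_mu_norm: float
    sem_inv_cv2_norm: float
    fraction_presynaptic: float
    mean_phi_deg: float
    condition: Optional[SweepCondition] = None


def summarize_ensemble(
    results: Sequence[CVResult], condition: Optional[SweepCondition] = None
) -> EnsembleSummary:
    """Mean +/- SEM of the CV-plot coordinates and classification fractions."""
    if len(results) < 2:
        raise ValueError("need at least 2 results to summarize")
    mu = np.array([r.point.mu_norm for r in results])
    icv = np.array([r.point.inv_cv2_norm for r in results])
    phi = np.array([r.phi_deg for r in results])
    n = len(results)
    frac_pre = sum(r.locus == PRESYNAPTIC for r in results) / n
    return EnsembleSummary(
        mean_point=CVPoint(float(np.mean(mu)), float(np.mean(icv))),
        sem_mu_norm=float(np.std(mu, ddof=1) / np.sqrt(n)),
        sem_inv_cv2_norm=float(np.std(icv, ddof=1) / np.sqrt(n)),
        fraction_presynaptic=frac_pre,
        mean_phi_deg=float(np.mean(phi)),
        condition=condition,
    )


def analyze_ensemble(
    ensemble: Sequence[SweepSeries], delta_post_deg: float = 15.0
) -> List[CVResult]:
    """CV analysis of every repetition in an ensemble."""
    return [analyze_series(s, delta_post_deg=delta_post_deg) for s in ensemble]


def _corruption_sweep(
    kind: str,
    magnitudes: Sequence[float],
    base_seed: int,
    n_reps: int,
    design: ExperimentDesign,
    scenario: PlasticityScenario,
) -> List[EnsembleSummary]:
    summaries = []
    for j, mag in enumerate(magnitudes):
        if kind == "outlier":
            perturb = Perturbation(outlier_shift=mag)
        else:
            perturb = Perturbation(trend_uv_per_sweep=mag)
        ensemble = run_monte_carlo(
            design, scenario, perturb, n_reps=n_reps, base_seed=base_seed
        )
        results = analyze_ensemble(ensemble)
        cond = SweepCondition(j_level=j, perturb_kind=kind, magnitude=mag, n_reps=n_reps)
        summaries.append(summarize_ensemble(results, cond))
    return summaries


def outlier_sweep_experiment(
    base_seed: int = 0,
    n_reps: int = 150,
    design: Optional[ExperimentDesign] = None,
    scenario: Optional[PlasticityScenario] = None,
) -> List[EnsembleSummary]:
    """Bias of CV analysis from a single baseline outlier of growing size.

    For each j = 0..5, a shift of 0.1 * 2^j mV is added to the middle
    baseline sweep of the reference LTD experiment and the full CV analysis
    is run on ``n_reps`` repetitions.
    """
    design = design or ExperimentDesign()
    scenario = scenario or default_ltd_scenario()
    return _corruption_sweep(
        "outlier", OUTLIER_SHIFTS_MV, base_seed, n_reps, design, scenario
    )


def trend_sweep_experiment(
    base_seed: int = 0,
    n_reps: int = 150,
    design: Optional[ExperimentDesign] = None,
    scenario: Optional[PlasticityScenario] = None,
) -> List[EnsembleSummary]:
    """Bias of CV analysis from a zero-mean baseline trend of growing slope.

    For each j = 0..5, a ramp of 0.6 * 2^j microvolts per sweep (3.6 * 2^j
    uV/min at the default 10-s inter-stimulus interval) is added to the
    baseline of the reference LTD experiment.
    """
    design = design or ExperimentDesign()
    scenario = scenario or default_ltd_scenario()
    return _corruption_sweep(
        "trend", TREND_SLOPES_UV_PER_SWEEP, base_seed, n_reps, design, scenario
    )
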