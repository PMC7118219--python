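"""Recording-quality screening applied before CV analysis.

CV analysis is acutely sensitive to variance that does not come from
stochastic release: electrode drift, cell deterioration, single aberrant
sweeps.  This module implements the standard screening battery for
paired-recording plasticity experiments:

* baseline stability — a t-test of Pearson's r between amplitude and time
  over the baseline epoch;
* baseline trend estimate — least-squares slope in microvolts per minute,
  for threshold-based experiment exclusion (detrending is deliberately not
  offered: it can bias the CV depending on the detrending model);
* recording stability — input-resistance change < 30% and resting
  membrane-potential change < 8 mV over the experiment;
* outlier screening — advisory flagging of sweeps deviating from their
  epoch mean by more than a z-threshold in units of the analytic binomial
  trial SD.  Flagged sweeps are never removed automatically: an outlier
  should only be excluded given independent evidence of a cause (artifact,
  spurious spike), otherwise exclusion itself biases the analysis;
* paired-pulse ratio — second-over-first amplitude, an independent
  presynaptic corroboration when paired stimuli were delivered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .quantal import InvalidParameterError, QuantalParams
from .simulate import BASELINE, SweepSeries

__all__ = [
    "QCReport",
    "baseline_stability",
    "trend_estimate",
    "recording_stability",
    "screen_outliers",
    "paired_pulse_ratio",
    "run_qc",
    "OUTLIER_ADVISORY",
]

OUTLIER_ADVISORY = (
    "Flagged sweeps are advisory only. Remove a sweep solely given "
    "independent evidence of a cause (electrical artifact, spurious spike, "
    "stimulus failure); removal merely for being an outlier biases CV "
    "analysis."
)


@dataclass(frozen=True)
class QCReport:
    """Aggregate quality-control outcome for one experiment."""

    pearson_r: Optional[float]
    r_pvalue: Optional[float]
    baseline_stable: bool
    trend_uv_per_min: float
    rin_change_frac: Optional[float]
    vm_change_mv: Optional[float]
    recording_pass: Optional[bool]
    outlier_indices: tuple
    advisory: str
    passed: bool


def baseline_stability(series: SweepSeries, alpha: float = 0.05) -> dict:
    """Stability of the baseline epoch via a t-test of Pearson's r.

    Correlates amplitude with time over the baseline; the t statistic is
    r*sqrt((N-2)/(1-r^2)) with N-2 degrees of freedom.  The baseline is
    deemed stable when the two-tailed p-value is >= ``alpha`` (no detectable
    linear trend).  Constant amplitudes leave r undefined; the epoch is then
    reported stable with ``r_defined`` False.
    """
    amps = series.baseline
    times = series.epoch_times(BASELINE)
    if amps.size < 3:
        raise InvalidParameterError("need at least 3 baseline sweeps")
    if np.all(amps == amps[0]):
        return {"r": None, "t": None, "p": None, "stable": True, "r_defined": False}
    r, p = stats.pearsonr(times, amps)
    r = float(r)
    n = amps.size
    if abs(r) >= 1.0:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return {
        "r": r,
        "t": float(t),
        "p": float(p),
        "stable": bool(p >= alpha),
        "r_defined": True,
    }


def trend_estimate(series: SweepSeries, epoch: str = BASELINE) -> float:
    """Least-squares amplitude trend over one epoch, in microvolts per minute."""
    amps = series.epoch(epoch)
    times = series.epoch_times(epoch)
    if amps.size < 3:
        raise InvalidParameterError(f"need at least 3 sweeps in epoch {epoch!r}")
    slope_mv_per_s = stats.linregress(times, amps).slope
    return float(slope_mv_per_s) * 1000.0 * 60.0


def recording_stability(
    rin: Optional[Sequence[float]],
    vm: Optional[Sequence[float]],
    max_rin_change_frac: float = 0.30,
    max_vm_change_mv: float = 8.0,
    window_frac: float = 0.10,
) -> dict:
    """Input-resistance and membrane-potential stability over the experiment.

    Changes are measured between the means of the first and last
    ``window_frac`` of samples (at least one sample each).  The recording
    passes when the fractional Rin change is below ``max_rin_change_frac``
    and the absolute Vm change is below ``max_vm_change_mv``.  Missing
    channels yield ``pass = None`` (not evaluable).
    """

    def _edge_change(x: np.ndarray) -> tuple[float, float]:
        k = max(1, int(round(window_frac * x.size)))
        return float(np.mean(x[:k])), float(np.mean(x[-k:]))

    out: dict = {"rin_change_frac": None, "vm_change_mv": None, "pass": None}
    checks = []
    if rin is not None:
        rin = np.asarray(rin, dtype=float)
        if rin.size < 2:
            raise InvalidParameterError("need at least 2 Rin samples")
        first, last = _edge_change(rin)
        frac = abs(last - first) / abs(first)
        out["rin_change_frac"] = frac
        checks.append(frac < max_rin_change_frac)
    if vm is not None:
        vm = np.asarray(vm, dtype=float)
        if vm.size < 2:
            raise InvalidParameterError("need at least 2 Vm samples")
        first, last = _edge_change(vm)
        dv = abs(last - first)
        out["vm_change_mv"] = dv
        checks.append(dv < max_vm_change_mv)
    if checks:
        out["pass"] = all(checks)
    return out


def screen_outliers(
    series: SweepSeries,
    params: QuantalParams,
    z_threshold: float = 4.0,
) -> dict:
    """Flag sweeps deviating strongly from their epoch mean.

    Deviations are measured in units of the analytic binomial trial SD
    q*sqrt(n*p*(1-p)).  Flags are advisory: the function never removes
    sweeps, and the returned advisory text states the cause-based standard
    an exclusion must meet.
    """
    p = params.p_release
    sd = params.q_amp * math.sqrt(params.n_sites * p * (1.0 - p))
    if sd == 0.0:
        raise InvalidParameterError("binomial trial SD is zero (p = 1)")
    flagged = []
    for label in ("baseline", "post"):
        amps = series.epoch(label)
        if amps.size == 0:
            continue
        idx = np.flatnonzero(series.epoch_labels == label)
        z = np.abs(amps - np.mean(amps)) / sd
        flagged.extend(int(i) for i in idx[z >= z_threshold])
    return {
        "outlier_indices": tuple(sorted(flagged)),
        "z_threshold": z_threshold,
        "advisory": OUTLIER_ADVISORY,
    }


def paired_pulse_ratio(amp1: float, amp2: float) -> float:
    """Paired-pulse ratio, second over first amplitude.

    A changed PPR after induction corroborates a presynaptic locus.  When
    averaging over sweeps, this package takes the mean of per-sweep ratios
    (not the ratio of mean amplitudes).
    """
    if amp1 <= 0:
        raise InvalidParameterError(f"first-pulse amplitude must be > 0, got {amp1}")
    return amp2 / amp1


def run_qc(
    series: SweepSeries,
    params: QuantalParams,
    z_threshold: float = 4.0,
    alpha: float = 0.05,
) -> QCReport:
    """Run the full screening battery and aggregate into a QCReport.

    ``passed`` is the conjunction of the criteria that could be evaluated;
    outlier flags are advisory and do not enter the verdict.
    """
    stab = baseline_stability(series, alpha=alpha)
    trend = trend_estimate(series, BASELINE)
    rec = recording_stability(series.rin_mohm, series.vm_mv)
    outl = screen_outliers(series, params, z_threshold)
    verdict = stab["stable"] and (rec["pass"] is not False)
    return QCReport(
        pearson_r=stab["r"],
        r_pvalue=stab["p"],
        baseline_stable=stab["stable"],
        trend_uv_per_min=trend,
        rin_change_frac=rec["rin_change_frac"],
        vm_change_mv=rec["vm_change_mv"],
        recording_pass=rec["pass"],
        outlier_indices=outl["outlier_indices"],
        advisory=outl["advisory"],
        passed=verdict,
    )
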