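"""Coefficient-of-variation analysis of plasticity experiments.

The core statistic: per-epoch mean, SD and CV of EPSP amplitudes; the
normalized CV-plot coordinates (mu_norm, 1/CV^2_norm); the signed angle phi
of an experiment's point relative to the unity diagonal; and the resulting
locus classification (presynaptic / postsynaptic / mixed).

Geometry of the normalized plot.  The no-change point is (1, 1).  Purely
presynaptic changes move the point along a curve whose chord from (1, 1)
is steeper than the unity diagonal; purely postsynaptic changes move it
along the horizontal line y = 1.  phi measures, in degrees, how far the
vector from (1, 1) to the data point rotates away from the diagonal:
phi = 0 on the diagonal, phi = -45 deg on the horizontal line, and the sign
is chosen so the presynaptic side of the diagonal (below it for LTD, above
it for LTP) is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
from scipy import stats

from .quantal import CVPoint, InvalidParameterError
from .simulate import SweepSeries

__all__ = [
    "EpochStats",
    "CVResult",
    "epoch_stats",
    "cv_point",
    "phi_angle",
    "classify_locus",
    "analyze_series",
    "binned_inv_cv2",
    "group_phi_test",
    "LTP",
    "LTD",
    "PRESYNAPTIC",
    "POSTSYNAPTIC",
    "MIXED",
]

LTP = "LTP"
LTD = "LTD"
PRESYNAPTIC = "presynaptic"
POSTSYNAPTIC = "postsynaptic"
MIXED = "mixed"


class NoiseDominatesError(ValueError):
    """Background-noise correction left a non-positive variance."""


class InvalidEpochError(ValueError):
    """An epoch violates the preconditions of CV analysis."""


class DegenerateEpochError(ValueError):
    """An epoch has zero CV, making normalized coordinates undefined."""


@dataclass(frozen=True)
class EpochStats:
    """Mean, SD and CV of one epoch's amplitudes (mV)."""

    mean: float
    sd: float
    cv: float
    n_sweeps: int
    noise_corrected: bool = False


@dataclass(frozen=True)
class CVResult:
    """Outcome of CV analysis of one experiment."""

    point: CVPoint
    phi_deg: float
    direction: str
    locus: str


def epoch_stats(
    amplitudes: Sequence[float],
    sd_background: float = 0.0,
    correct_noise: bool = False,
) -> EpochStats:
    """Sample statistics of one epoch.

    The SD uses the n-1 denominator.  With ``correct_noise`` the background
    noise variance is subtracted: sd = sqrt(sd_measured^2 - sd_background^2);
    a non-positive corrected variance raises :class:`NoiseDominatesError`.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        raise InvalidEpochError("need at least 2 amplitudes per epoch")
    mean = float(np.mean(amps))
    if mean <= 0:
        raise InvalidEpochError(f"epoch mean must be > 0 mV, got {mean}")
    sd = float(np.std(amps, ddof=1))
    if correct_noise:
        var = sd * sd - sd_background * sd_background
        if var <= 0:
            raise NoiseDominatesError(
                "background noise variance exceeds measured variance"
            )
        sd = math.sqrt(var)
    return EpochStats(
        mean=mean, sd=sd, cv=sd / mean, n_sweeps=int(amps.size),
        noise_corrected=correct_noise,
    )


def cv_point(baseline: EpochStats, post: EpochStats) -> CVPoint:
    """Normalized CV-plot coordinates from baseline and post-induction epochs.

    mu_norm = mean_post / mean_baseline;
    1/CV^2_norm = (CV_baseline / CV_post)^2.
    """
    if baseline.cv <= 0:
        raise DegenerateEpochError("baseline CV must be > 0")
    if post.cv <= 0:
        raise DegenerateEpochError("post-induction CV is zero; point undefined")
    return CVPoint(
        mu_norm=post.mean / baseline.mean,
        inv_cv2_norm=(baseline.cv / post.cv) ** 2,
    )


def direction_of(point: CVPoint) -> str:
    """LTP if the normalized mean exceeds 1, else LTD."""
    return LTP if point.mu_norm > 1.0 else LTD


def phi_angle(point: CVPoint, direction: str) -> float:
    """Signed angle (degrees) between the diagonal and the vector (1,1)->point.

    Zero on the diagonal, -45 deg on the horizontal postsynaptic line.
    Positive on the presynaptic side of the diagonal: below it for LTD,
    above it for LTP.
    """
    vx = point.mu_norm - 1.0
    vy = point.inv_cv2_norm - 1.0
    norm = math.hypot(vx, vy)
    if norm == 0.0:
        raise InvalidParameterError("point (1, 1) has no defined angle")
    # Diagonal direction pointing the same way as the plasticity change.
    d = -1.0 if direction == LTD else 1.0
    cosang = (vx * d + vy * d) / (math.sqrt(2.0) * norm)
    cosang = min(1.0, max(-1.0, cosang))
    angle = math.degrees(math.acos(cosang))
    above = vy > vx  # above the diagonal through (1, 1)
    presyn_side = not above if direction == LTD else above
    if vy == vx:
        return 0.0
    return angle if presyn_side else -angle


def classify_locus(
    point: CVPoint, direction: str, delta_post_deg: float = 15.0
) -> str:
    """Locus call from the point's angle relative to the diagonal.

    Presynaptic when phi >= 0 (on or beyond the diagonal); postsynaptic when
    phi lies within ``delta_post_deg`` of the horizontal line's -45 deg;
    otherwise mixed.  Checks are applied in that order.
    """
    phi = phi_angle(point, direction)
    if phi >= 0.0:
        return PRESYNAPTIC
    if abs(phi - (-45.0)) <= delta_post_deg:
        return POSTSYNAPTIC
    return MIXED


def analyze_series(
    series: SweepSeries,
    sd_background: float = 0.0,
    correct_noise: bool = False,
    delta_post_deg: float = 15.0,
) -> CVResult:
    """Full CV analysis of one sweep series (baseline vs post epochs)."""
    base = epoch_stats(series.baseline, sd_background, correct_noise)
    post = epoch_stats(series.post, sd_background, correct_noise)
    point = cv_point(base, post)
    direction = direction_of(point)
    phi = phi_angle(point, direction)
    locus = classify_locus(point, direction, delta_post_deg)
    return CVResult(point=point, phi_deg=phi, direction=direction, locus=locus)


def binned_inv_cv2(series: SweepSeries, bin_sweeps: int) -> np.ndarray:
    """Time course of 1/CV^2 over consecutive bins of ``bin_sweeps`` sweeps.

    Tracks gradual trends in release statistics.  A trailing partial bin is
    dropped; a bin with zero CV yields +inf.  Induction-labeled sweeps are
    excluded.
    """
    if bin_sweeps < 2:
        raise InvalidEpochError("bin_sweeps must be >= 2")
    mask = np.isin(series.epoch_labels.astype(str), ("baseline", "post"))
    amps = series.amplitudes[mask]
    n_bins = len(amps) // bin_sweeps
    out = np.empty(n_bins, dtype=float)
    for i in range(n_bins):
        chunk = amps[i * bin_sweeps : (i + 1) * bin_sweeps]
        mean = np.mean(chunk)
        sd = np.std(chunk, ddof=1)
        out[i] = np.inf if sd == 0 else (mean / sd) ** 2
    return out


def group_phi_test(phis: Iterable[float]) -> dict:
    """Group-level significance of the angle phi across experiments.

    One-sample two-tailed t-test of the mean angle against 0 (the diagonal),
    with a Wilcoxon signed-rank test run in parallel as a non-parametric
    check.  Returns mean, SEM, t, p and the signed-rank p-value.
    """
    arr = np.asarray(list(phis), dtype=float)
    if arr.size < 2:
        raise InvalidEpochError("need at least 2 angles for a group test")
    mean = float(np.mean(arr))
    sem = float(stats.sem(arr))
    if np.allclose(arr, arr[0]) and arr[0] == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(arr, 0.0)
        t, p = float(t), float(p)
        if math.isnan(t):  # zero variance at a nonzero mean
            t = math.inf if mean > 0 else -math.inf
            p = 0.0
    if np.all(arr == 0.0):
        wilcoxon_p = 1.0
    else:
        try:
            _, wilcoxon_p = stats.wilcoxon(arr)
            wilcoxon_p = float(wilcoxon_p)
        except ValueError:
            wilcoxon_p = 1.0
    return {"mean": mean, "sem": sem, "t": t, "p": p, "wilcoxon_p": wilcoxon_p}
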