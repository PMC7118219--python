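"""Closed-form binomial quantal-release model.

Synaptic transmission is modeled as ``n`` independent release sites, each
releasing at most one transmitter quantum per stimulus with probability
``p``; a released quantum contributes a fixed postsynaptic amplitude ``q``
(in mV).  The evoked response amplitude is then a scaled binomial variate

    X = q * Binomial(n, p),

with mean mu = n*p*q and variance sigma^2 = n*p*(1-p)*q^2.  Recorded
amplitudes additionally carry background noise (membrane-potential
fluctuations, amplifier noise) modeled as additive zero-mean Gaussian noise
with standard deviation ``sd_background``.

The coefficient of variation CV = sigma/mu = sqrt((1-p)/(n*p)) is
independent of the quantal amplitude ``q``: changes in CV across a
plasticity-induction protocol therefore point to a presynaptic change in
``p``, while a pure change in ``q`` (postsynaptic) leaves the CV untouched.
This module provides the moments, the CV, its inversion to ``p``, and the
geometry of the normalized 1/CV^2-versus-mean plot used to classify the
locus of plasticity expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "QuantalParams",
    "CVPoint",
    "expected_mean",
    "expected_variance",
    "theoretical_cv",
    "theoretical_inv_cv2",
    "p_from_cv",
    "outlier_zscore",
    "presynaptic_endpoint",
    "postsynaptic_endpoint",
]


class InvalidParameterError(ValueError):
    """A model parameter violates the binomial release model's constraints."""


@dataclass(frozen=True)
class QuantalParams:
    """Binomial release model parameters.

    Parameters
    ----------
    n_sites : int
        Number of independent release sites (n >= 1).
    p_release : float
        Per-site release probability, in (0, 1].
    q_amp : float
        Quantal amplitude in mV (> 0): postsynaptic response to a single
        released vesicle.
    sd_background : float
        Standard deviation of additive background noise in mV (>= 0).
    """

    n_sites: int
    p_release: float
    q_amp: float
    sd_background: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_sites, (int,)) and self.n_sites >= 1):
            raise InvalidParameterError(
                f"n_sites must be a positive integer, got {self.n_sites!r}"
            )
        if not (0.0 < self.p_release <= 1.0):
            raise InvalidParameterError(
                f"p_release must lie in (0, 1], got {self.p_release!r}"
            )
        if not (self.q_amp > 0.0):
            raise InvalidParameterError(f"q_amp must be > 0 mV, got {self.q_amp!r}")
        if self.sd_background < 0.0:
            raise InvalidParameterError(
                f"sd_background must be >= 0 mV, got {self.sd_background!r}"
            )

    def with_(self, **changes) -> "QuantalParams":
        """Return a copy with the given fields replaced."""
        fields = dict(
            n_sites=self.n_sites,
            p_release=self.p_release,
            q_amp=self.q_amp,
            sd_background=self.sd_background,
        )
        fields.update(changes)
        return QuantalParams(**fields)


@dataclass(frozen=True)
class CVPoint:
    """One point in the normalized 1/CV^2-versus-mean plot.

    ``mu_norm`` is the post/baseline ratio of mean amplitudes (synaptic
    strength change); ``inv_cv2_norm`` is the post/baseline ratio of 1/CV^2,
    a proxy for the change in release probability.  The no-change point is
    (1, 1); LTP lies at mu_norm > 1, LTD at mu_norm < 1.
    """

    mu_norm: float
    inv_cv2_norm: float
    c_pre: Optional[float] = None
    c_post: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mu_norm", "inv_cv2_norm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")


def expected_mean(params: QuantalParams) -> float:
    """Expected response amplitude, mu = n*p*q, in mV."""
    return params.n_sites * params.p_release * params.q_amp


def expected_variance(params: QuantalParams, include_background: bool = False) -> float:
    """Response variance n*p*(1-p)*q^2 in mV^2, optionally plus sd_background^2.

    Background noise adds independently, so its variance is additive; a
    noise-corrected measured variance is recovered as
    sigma^2 = sigma_measured^2 - sigma_background^2.
    """
    p = params.p_release
    var = params.n_sites * p * (1.0 - p) * params.q_amp**2
    if include_background:
        var += params.sd_background**2
    return var


def theoretical_cv(params: QuantalParams) -> float:
    """Coefficient of variation of release, sqrt((1-p)/(n*p)).

    Independent of the quantal amplitude q — the key fact that makes CV a
    presynaptic metric.  Excludes background noise.
    """
    p = params.p_release
    return math.sqrt((1.0 - p) / (params.n_sites * p))


def theoretical_inv_cv2(params: QuantalParams, include_background: bool = False) -> float:
    """1/CV^2 of the response, optionally including the background-noise term.

    With background noise, CV^2 = (n p (1-p) q^2 + sd_bg^2) / (n p q)^2.
    """
    mu = expected_mean(params)
    var = expected_variance(params, include_background=include_background)
    if var == 0.0:
        raise InvalidParameterError("variance is zero; 1/CV^2 undefined")
    return mu**2 / var


def p_from_cv(cv: float, n_sites: int) -> float:
    """Invert the CV to the release probability, p = 1/(n*CV^2 + 1).

    Assumes the number of release sites ``n_sites`` is known and constant.
    The result always lies in (0, 1]; cv = 0 maps to deterministic release
    p = 1.
    """
    if cv < 0:
        raise InvalidParameterError(f"cv must be >= 0, got {cv!r}")
    if n_sites < 1:
        raise InvalidParameterError(f"n_sites must be >= 1, got {n_sites!r}")
    return 1.0 / (n_sites * cv * cv + 1.0)


def outlier_zscore(shift: float, params: QuantalParams) -> float:
    """Analytic z-score of a single-sweep amplitude shift.

    The shift is expressed in units of the binomial trial standard
    deviation q*sqrt(n*p*(1-p)) — the spread of a single evoked response
    under the release model, without the background-noise term.
    """
    p = params.p_release
    sd = params.q_amp * math.sqrt(params.n_sites * p * (1.0 - p))
    if sd == 0.0:
        raise InvalidParameterError(
            "binomial trial SD is zero (p = 1); z-score undefined"
        )
    return shift / sd


def presynaptic_endpoint(p0: float, c_pre: float) -> CVPoint:
    """CV-plot endpoint of a purely presynaptic change p0 -> c_pre*p0.

    With c_pre = p/p0 the normalized coordinates are
    (c_pre, c_pre*(1-p0)/(1-c_pre*p0)); the slope of the segment from the
    no-change point (1,1) to this endpoint is 1/(1-c_pre*p0) > 1, which is
    why purely presynaptic data fall beyond the unity diagonal.
    """
    if not (0.0 < p0 < 1.0):
        raise InvalidParameterError(f"p0 must lie in (0, 1), got {p0!r}")
    if c_pre <= 0.0:
        raise InvalidParameterError(f"c_pre must be > 0, got {c_pre!r}")
    p_new = c_pre * p0
    if p_new >= 1.0:
        raise InvalidParameterError(
            f"c_pre*p0 = {p_new} implies release probability >= 1"
        )
    y = c_pre * (1.0 - p0) / (1.0 - p_new)
    return CVPoint(mu_norm=c_pre, inv_cv2_norm=y, c_pre=c_pre, c_post=1.0)


def postsynaptic_endpoint(c_post: float) -> CVPoint:
    """CV-plot endpoint of a purely postsynaptic change q0 -> c_post*q0.

    The quantal amplitude cancels from the CV, so the endpoint is
    (c_post, 1): purely postsynaptic plasticity moves along the horizontal
    line y = 1.
    """
    if c_post <= 0.0:
        raise InvalidParameterError(f"c_post must be > 0, got {c_post!r}")
    return CVPoint(mu_norm=c_post, inv_cv2_norm=1.0, c_pre=1.0, c_post=c_post)
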