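"""Logistic psychometric functions for n-alternative forced-choice tasks.

The psychometric function maps stimulus magnitude ``x`` (AM depth in dB,
log percent frequency difference, log degrees of interaural phase, dB SNR,
...) to the probability of a correct response,

    p(x) = gamma + (1 - gamma - lambda) * F(x),
    F(x) = 1 / (1 + exp(-beta * (x - alpha))),

where ``gamma`` is the guess rate (fixed at the reciprocal of the number of
response alternatives in forced choice), ``lambda`` the lapse rate (lowering
the upper asymptote), ``alpha`` the midpoint and ``beta > 0`` the slope.
The same object serves three roles in the pipeline: the simulated observer,
the likelihood of the Bayesian adaptive procedure, and the target of the
post-hoc MCMC refit.

A function may be declared on a ``log`` stimulus axis, in which case
``alpha`` and ``beta`` live on log-transformed stimulus values and callers
pass raw stimuli which are log-transformed internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PsychometricFunction", "prob_correct", "threshold_at_p"]


@dataclass(frozen=True)
class PsychometricFunction:
    """Logistic psychometric function with guess and lapse asymptotes.

    Parameters
    ----------
    midpoint:
        Stimulus value at which the underlying logistic F equals 1/2,
        on the declared scale.
    slope:
        Logistic rate parameter beta (> 0), in inverse stimulus units on
        the declared scale.
    guess_rate:
        Lower asymptote, in [0, 1]; 1/m for an m-alternative forced choice.
    lapse_rate:
        Stimulus-independent error probability, in [0, 1); shrinks the
        upper asymptote to 1 - lapse_rate.
    scale:
        'linear' or 'log'.  With 'log' the midpoint/slope are defined on
        log(stimulus) and evaluation log-transforms its input.
    """

    midpoint: float
    slope: float
    guess_rate: float = 0.5
    lapse_rate: float = 0.0
    scale: str = "linear"

    def __post_init__(self) -> None:
        if not math.isfinite(self.midpoint):
            raise ValueError("midpoint must be finite")
        if not (self.slope > 0 and math.isfinite(self.slope)):
            raise ValueError("slope must be positive and finite")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ValueError("guess_rate must lie in [0, 1]")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")
        if self.guess_rate + self.lapse_rate >= 1.0:
            raise ValueError("guess_rate + lapse_rate must be < 1")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")

    # -- convenience -------------------------------------------------------

    @property
    def ceiling(self) -> float:
        return 1.0 - self.lapse_rate

    def to_linear(self) -> "PsychometricFunction":
        """Return self; log-scale functions cannot be flattened exactly."""
        if self.scale == "linear":
            return self
        return replace(self, scale="linear")

    def __call__(self, x):
        return prob_correct(self, x)


def _internal_x(pf: PsychometricFunction, x):
    """Map raw stimulus values onto the axis midpoint/slope live on."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("stimulus values must be finite")
    if pf.scale == "log":
        if np.any(x <= 0):
            raise ValueError("log-scale stimulus values must be positive")
        x = np.log(x)
    return x


def prob_correct(pf: PsychometricFunction, x):
    """Probability of a correct response at stimulus value(s) ``x``.

    Returns a float for scalar input, an ndarray otherwise.  The result is
    bounded in [guess_rate, 1 - lapse_rate] and strictly increasing in x.
    """
    scalar = np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0)
    xi = _internal_x(pf, x)
    # expit computed stably via scipy-free formulation
    z = pf.slope * (xi - pf.midpoint)
    e = np.exp(-np.abs(z))
    f = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    p = pf.guess_rate + (1.0 - pf.guess_rate - pf.lapse_rate) * f
    return float(p) if scalar else p


def threshold_at_p(pf: PsychometricFunction, p_target: float,
                   on: str = "function") -> float:
    """Stimulus value at which the function reaches a target level.

    With ``on='function'`` (default) ``p_target`` is a fraction of the
    underlying logistic F — the "1/4 point" convention, which coincides
    with ~25% correct only for a zero-guess observer.  With
    ``on='performance'`` ``p_target`` is the raw probability of a correct
    response and must lie strictly inside (guess_rate, 1 - lapse_rate).

    The fraction-1/2 point equals the midpoint exactly; the returned value
    is on the raw stimulus axis (exponentiated for log-scale functions).
    """
    if not math.isfinite(p_target):
        raise ValueError("p_target must be finite")
    if on == "performance":
        lo, hi = pf.guess_rate, 1.0 - pf.lapse_rate
        if not lo < p_target < hi:
            raise ValueError(
                f"target performance {p_target} outside the attainable "
                f"open interval ({lo}, {hi})")
        frac = (p_target - lo) / (hi - lo)
    elif on == "function":
        if not 0.0 < p_target < 1.0:
            raise ValueError(
                f"target fraction {p_target} outside the attainable open "
                f"interval (0, 1)")
        frac = p_target
    else:
        raise ValueError("on must be 'function' or 'performance'")
    xi = pf.midpoint + math.log(frac / (1.0 - frac)) / pf.slope
    return math.exp(xi) if pf.scale == "log" else xi
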