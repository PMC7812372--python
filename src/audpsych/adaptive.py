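"""Adaptive stimulus-placement procedures run against simulated observers.

Two engines:

* an updated-maximum-likelihood (UML) Bayesian procedure that keeps a
  discrete-grid posterior over (midpoint, slope, lapse) of a logistic
  psychometric function and places each trial at one of four "sweetpoints"
  — stimulus values minimising the asymptotic estimation variance of one
  parameter each — with a 2-down-1-up rule selecting among them;
* a classical transformed up-down staircase (n-down-1-up) whose 2-down-1-up
  flavour converges on the 70.7%-correct point, used for audiometry.

Both operate on a generic stimulus axis; task configuration decides whether
that axis is a physical quantity or its logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .psychometric import PsychometricFunction, prob_correct, threshold_at_p

__all__ = [
    "UMLState", "uml_init", "uml_update", "uml_next_stimulus",
    "uml_sweetpoints", "uml_posterior_mean", "uml_run",
    "sweetpoint_transition",
    "StaircaseConfig", "StaircaseTrack", "staircase_run",
]


# ---------------------------------------------------------------------------
# UML procedure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UMLState:
    """Posterior grid and book-keeping of a UML track.

    ``log_posterior`` is normalised (its exponential sums to one) over the
    cartesian grid ``grid_alpha x grid_beta x grid_lambda``.  The sweetpoint
    index selects among the four sweetpoints sorted by ascending stimulus;
    with an empty history the next stimulus is the configured start value.
    """

    grid_alpha: np.ndarray
    grid_beta: np.ndarray
    grid_lambda: np.ndarray
    log_posterior: np.ndarray
    guess_rate: float
    bounds: tuple[float, float]
    start_stimulus: float
    history: tuple[tuple[float, bool], ...] = ()
    consecutive_correct: int = 0
    current_sweetpoint_index: int = 3
    point_estimate: str = "mean"

    @property
    def n_trials(self) -> int:
        return len(self.history)


def _grid_log_prior(prior, grid: np.ndarray) -> np.ndarray:
    """Evaluate a prior (frozen scipy dist or callable density) on a grid."""
    if hasattr(prior, "logpdf"):
        lp = prior.logpdf(grid)
    elif callable(prior):
        with np.errstate(divide="ignore"):
            lp = np.log(np.asarray([prior(g) for g in grid], dtype=float))
    else:
        raise TypeError("prior must be a frozen distribution or a density")
    return np.asarray(lp, dtype=float)


def uml_init(prior_spec: dict, grids: dict, bounds: tuple[float, float],
             start_stimulus: float, guess_rate: float = 0.5,
             point_estimate: str = "mean") -> UMLState:
    """Initialise a UML track from priors discretised on a parameter grid.

    ``prior_spec`` maps 'alpha'/'beta'/'lambda' to frozen scipy
    distributions (or density callables); ``grids`` maps the same keys to
    strictly increasing 1-D arrays.  The normalised posterior equals the
    prior, and the first proposed stimulus is ``start_stimulus`` (e.g. a
    0-dB / 100% AM depth, a 10% frequency or 80% F0 difference, a 180°
    interaural phase, a 7 or 10 dB SNR, depending on the task).
    """
    ga = np.asarray(grids["alpha"], dtype=float)
    gb = np.asarray(grids["beta"], dtype=float)
    gl = np.asarray(grids["lambda"], dtype=float)
    for g, name in ((ga, "alpha"), (gb, "beta"), (gl, "lambda")):
        if g.size == 0:
            raise ValueError(f"empty {name} grid")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ValueError(f"{name} grid must be strictly increasing")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy min < max")
    if not lo <= start_stimulus <= hi:
        raise ValueError("start_stimulus outside bounds")

    lp = (_grid_log_prior(prior_spec["alpha"], ga)[:, None, None]
          + _grid_log_prior(prior_spec["beta"], gb)[None, :, None]
          + _grid_log_prior(prior_spec["lambda"], gl)[None, None, :])
    if np.all(np.isneginf(lp)):
        raise ValueError("prior has zero mass everywhere on the grid")
    lp = lp - logsumexp(lp)
    return UMLState(grid_alpha=ga, grid_beta=gb, grid_lambda=gl,
                    log_posterior=lp, guess_rate=guess_rate,
                    bounds=(float(lo), float(hi)),
                    start_stimulus=float(start_stimulus),
                    point_estimate=point_estimate)


def _grid_prob_correct(state: UMLState, stimulus: float) -> np.ndarray:
    """p(correct | theta, stimulus) over the full parameter grid."""
    a = state.grid_alpha[:, None, None]
    b = state.grid_beta[None, :, None]
    lam = state.grid_lambda[None, None, :]
    z = b * (stimulus - a)
    e = np.exp(-np.abs(z))
    f = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    return state.guess_rate + (1.0 - state.guess_rate - lam) * f


def sweetpoint_transition(index: int, consecutive_correct: int,
                          response: bool) -> tuple[int, int]:
    """2-down-1-up move on the sweetpoint index (0 = lowest stimulus).

    Two consecutive correct responses move one sweetpoint down; any
    incorrect response moves one up; the index is clamped to {0..3}.
    Returns (new_index, new_consecutive_correct).
    """
    if response:
        consecutive_correct += 1
        if consecutive_correct >= 2:
            return max(index - 1, 0), 0
        return index, consecutive_correct
    return min(index + 1, 3), 0


def uml_update(state: UMLState, stimulus: float, response: bool) -> UMLState:
    """Bayes-update the posterior with one (stimulus, response) pair.

    The new log-posterior adds the Bernoulli log-likelihood of the response
    cellwise and renormalises; the sweetpoint selection index advances by
    the 2-down-1-up rule.
    """
    if not np.isfinite(stimulus):
        raise ValueError("stimulus must be finite")
    lo, hi = state.bounds
    if not lo <= stimulus <= hi:
        raise ValueError(f"stimulus {stimulus} outside bounds {state.bounds}")
    p = _grid_prob_correct(state, float(stimulus))
    with np.errstate(divide="ignore"):
        loglik = np.log(p) if response else np.log1p(-p)
    lp = state.log_posterior + loglik
    lp = lp - logsumexp(lp)
    idx, cc = sweetpoint_transition(state.current_sweetpoint_index,
                                    state.consecutive_correct, bool(response))
    return replace(state, log_posterior=lp,
                   history=state.history + ((float(stimulus), bool(response)),),
                   consecutive_correct=cc, current_sweetpoint_index=idx)


def uml_posterior_mean(state: UMLState) -> tuple[float, float, float]:
    """Posterior means of (midpoint, slope, lapse) on the grid."""
    w = np.exp(state.log_posterior)
    a = float(np.sum(w.sum(axis=(1, 2)) * state.grid_alpha))
    b = float(np.sum(w.sum(axis=(0, 2)) * state.grid_beta))
    lam = float(np.sum(w.sum(axis=(0, 1)) * state.grid_lambda))
    return a, b, lam


def _point_estimate(state: UMLState) -> tuple[float, float, float]:
    if state.point_estimate == "mean":
        return uml_posterior_mean(state)
    if state.point_estimate == "mode":
        w = state.log_posterior
        i, j, k = np.unravel_index(int(np.argmax(w)), w.shape)
        return (float(state.grid_alpha[i]), float(state.grid_beta[j]),
                float(state.grid_lambda[k]))
    raise ValueError("point_estimate must be 'mean' or 'mode'")


def uml_sweetpoints(state: UMLState, lattice_size: int = 1001) -> np.ndarray:
    """Four stimulus values for efficient estimation, sorted ascending.

    At the current posterior point estimate (alpha, beta, lambda) each
    parameter's sweetpoint minimises the asymptotic variance proxy
    ``p(x)(1-p(x)) / (dp/dtheta)^2`` over a dense stimulus lattice spanning
    the bounds: one point for the midpoint, one on each side of the
    midpoint for the slope, and the high-performance point (in practice the
    upper bound) for the lapse rate.  All points are clipped to bounds.
    """
    a, b, lam = _point_estimate(state)
    lo, hi = state.bounds
    x = np.linspace(lo, hi, lattice_size)
    g = state.guess_rate
    z = b * (x - a)
    e = np.exp(-np.abs(z))
    f = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    p = g + (1.0 - g - lam) * f
    pq = p * (1.0 - p)
    ff = f * (1.0 - f)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_alpha = pq / ((1.0 - g - lam) * b * ff) ** 2
        v_beta = pq / ((1.0 - g - lam) * (x - a) * ff) ** 2
        v_lambda = pq / f ** 2

    def argmin_on(v: np.ndarray, mask: np.ndarray) -> float:
        vv = np.where(mask, v, np.inf)
        if not np.any(np.isfinite(vv)):
            warnings.warn("degenerate posterior: sweetpoint clipped to bounds")
            return hi if mask[-1] else lo
        return float(x[int(np.argmin(vv))])

    sp_alpha = argmin_on(v_alpha, np.ones_like(x, bool))
    below, above = x < a, x > a
    sp_beta_lo = argmin_on(v_beta, below) if below.any() else lo
    sp_beta_hi = argmin_on(v_beta, above) if above.any() else hi
    sp_lambda = argmin_on(v_lambda, np.ones_like(x, bool))
    return np.sort(np.clip([sp_beta_lo, sp_alpha, sp_beta_hi, sp_lambda],
                           lo, hi))


def uml_next_stimulus(state: UMLState) -> float:
    """Stimulus to present next: the currently selected sweetpoint.

    With an empty history the configured start stimulus is returned
    unchanged (the first trial is placed at the experimenter-defined
    starting value, e.g. the maximum AM depth).
    """
    if state.n_trials == 0:
        return state.start_stimulus
    sp = uml_sweetpoints(state)
    return float(sp[state.current_sweetpoint_index])


def uml_run(observer, state: UMLState, n_trials: int,
            rng: np.random.Generator,
            n_practice: int = 0) -> "pd.DataFrame":
    """Simulate a UML track against an observer; returns a trial log.

    ``observer`` is a PsychometricFunction (or any callable mapping a
    stimulus value to p(correct)).  The first ``n_practice`` trials are
    flagged; downstream fitting excludes them.  Columns follow the
    pipeline's trial-log layout.
    """
    import pandas as pd

    p_of = (observer if callable(observer) and
            not isinstance(observer, PsychometricFunction)
            else (lambda x: prob_correct(observer, x)))
    rows = []
    for t in range(n_trials):
        x = uml_next_stimulus(state)
        resp = bool(rng.random() < p_of(x))
        rows.append({"trial_index": t, "stimulus": x, "response": int(resp),
                     "sweetpoint_index": state.current_sweetpoint_index,
                     "is_practice": int(t < n_practice)})
        state = uml_update(state, x, resp)
    df = pd.DataFrame(rows)
    df.attrs["final_state"] = state
    return df


# ---------------------------------------------------------------------------
# Transformed up-down staircase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseConfig:
    """n-down-1-up staircase settings (dB levels; defaults for audiometry)."""

    start_level: float = 40.0
    step_initial: float = 4.0
    step_final: float = 2.0
    n_reversals_initial: int = 2
    n_reversals_measurement: int = 8
    n_down: int = 2
    min_level: float = -40.0
    max_level: float = 120.0


@dataclass
class StaircaseTrack:
    """Record of one adaptive track."""

    levels: list = field(default_factory=list)
    responses: list = field(default_factory=list)
    reversal_levels: list = field(default_factory=list)
    measurement_reversals: list = field(default_factory=list)
    threshold: float = float("nan")


def staircase_run(observer, config: StaircaseConfig,
                  rng: np.random.Generator) -> StaircaseTrack:
    """Run a transformed up-down track and estimate its threshold.

    The level drops one step after ``n_down`` consecutive correct responses
    and rises one step after any incorrect response.  The first
    ``n_reversals_initial`` reversals use the larger step (initial phase);
    the next ``n_reversals_measurement`` use the final step, and the
    threshold estimate is the mean level at those measurement-phase
    reversals.  With n_down = 2 the tracked point is the 70.7%-correct
    point of the observer's psychometric function.
    """
    if isinstance(observer, PsychometricFunction):
        if observer.slope <= 0:
            raise ValueError("observer slope must be positive")
        p_of = lambda x: prob_correct(observer, x)  # noqa: E731
    elif callable(observer):
        p_of = observer
    else:
        raise TypeError("observer must be a PsychometricFunction or callable")
    if config.step_initial <= 0 or config.step_final <= 0:
        raise ValueError("step sizes must be positive")

    track = StaircaseTrack()
    level = config.start_level
    step = config.step_initial
    n_correct = 0
    last_move = 0  # -1 down, +1 up, 0 none yet
    total_rev = config.n_reversals_initial + config.n_reversals_measurement
    while len(track.reversal_levels) < total_rev:
        resp = bool(rng.random() < p_of(level))
        track.levels.append(level)
        track.responses.append(resp)
        if resp:
            n_correct += 1
            move = -1 if n_correct >= config.n_down else 0
        else:
            move = +1
        if move != 0:
            n_correct = 0
            if last_move != 0 and move != last_move:
                track.reversal_levels.append(level)
                if len(track.reversal_levels) == config.n_reversals_initial:
                    step = config.step_final
                elif len(track.reversal_levels) > config.n_reversals_initial:
                    track.measurement_reversals.append(level)
            last_move = move
            level = float(np.clip(level + move * step,
                                  config.min_level, config.max_level))
    track.threshold = float(np.mean(track.measurement_reversals))
    return track


def updown_target(n_down: int) -> float:
    """Asymptotic probability correct tracked by an n-down-1-up rule.

    At equilibrium the chance of stepping down equals that of stepping up,
    so p^n = 1/2: p = 0.707 for 2-down-1-up, 0.5 for 1-down-1-up.
    """
    return 0.5 ** (1.0 / n_down)
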