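"""Post-hoc psychometric-function refitting by MCMC.

After an adaptive track finishes, the trial-level responses are re-fit
with a logistic psychometric function whose midpoint, slope and lapse rate
are free (guess rate fixed by the response-alternative count).  Priors are
Normal on the midpoint (on the task's linear or log stimulus axis), gamma
on the slope and on the lapse rate (the lapse prior truncated above), with
midpoint/slope prior centers taken from preliminary maximum-likelihood
fits across tracks.  Fitting the lapse rate explicitly protects the
threshold estimate from the bias that attention lapses would otherwise
introduce.

Sampling uses an adaptive random-walk Metropolis scheme on
(midpoint, log slope, log lapse); convergence is monitored with the
split-R-hat statistic and the effective sample size via arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .psychometric import PsychometricFunction, threshold_at_p

__all__ = [
    "PFPriorSpec", "PFFitSettings", "PFFit",
    "empirical_prior_centers", "fit_pf",
]


@dataclass(frozen=True)
class PFPriorSpec:
    """Priors for the free parameters of a psychometric-function fit.

    The midpoint prior is Normal(location, sd) on the declared stimulus
    axis; slope and lapse priors are gamma(shape, rate) on the positives,
    the lapse prior truncated to [0, lapse_upper) to keep short tracks
    from trading lapse against midpoint.  The guess rate is fixed and
    never sampled.
    """

    midpoint_loc: float
    midpoint_sd: float
    slope_shape: float = 2.0
    slope_rate: float = 2.0
    lapse_shape: float = 1.5
    lapse_rate_param: float = 30.0
    lapse_upper: float = 0.2
    guess_rate: float = 0.5
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.midpoint_sd <= 0:
            raise ValueError("midpoint prior sd must be positive")
        for v, name in ((self.slope_shape, "slope_shape"),
                        (self.slope_rate, "slope_rate"),
                        (self.lapse_shape, "lapse_shape"),
                        (self.lapse_rate_param, "lapse_rate_param")):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.lapse_upper < 1:
            raise ValueError("lapse_upper must lie in (0, 1)")


@dataclass(frozen=True)
class PFFitSettings:
    """MCMC settings; defaults target an ESS of ~10,000 for the midpoint."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_draws: int = 30000
    ess_floor: float = 10000.0
    rhat_max: float = 1.01
    max_retries: int = 1
    threshold_fractions: tuple[float, ...] = (0.5,)
    ci_level: float = 0.99
    seed: int = 0


@dataclass
class PFFit:
    """Posterior draws and summaries of one psychometric-function fit."""

    draws: dict                      # name -> (chains, draws) array
    rhat: dict
    ess: dict
    converged: bool
    guess_rate: float
    scale: str
    threshold_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def flat(self) -> dict:
        return {k: v.reshape(-1) for k, v in self.draws.items()}

    def median_pf(self) -> PsychometricFunction:
        f = self.flat
        return PsychometricFunction(
            midpoint=float(np.median(f["midpoint"])),
            slope=float(np.median(f["slope"])),
            guess_rate=self.guess_rate,
            lapse_rate=float(np.median(f["lapse"])),
            scale="linear")


# ---------------------------------------------------------------------------
# Preliminary maximum-likelihood fits for prior centering
# ---------------------------------------------------------------------------

def _track_arrays(track: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = track
    if "is_practice" in df.columns:
        df = df[df["is_practice"] == 0]
    x = df["stimulus"].to_numpy(dtype=float)
    r = df["response"].to_numpy(dtype=float)
    return x, r


def _nll_fixed_lapse(params, x, r, guess, lapse):
    alpha, log_beta = params
    beta = np.exp(log_beta)
    z = beta * (x - alpha)
    e = np.exp(-np.abs(z))
    f = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    p = np.clip(guess + (1.0 - guess - lapse) * f, 1e-12, 1 - 1e-12)
    return -np.sum(r * np.log(p) + (1 - r) * np.log1p(-p))


def empirical_prior_centers(tracks: Sequence[pd.DataFrame],
                            guess_rate: float = 0.5,
                            fixed_lapse: float = 0.02
                            ) -> tuple[float, float]:
    """Average per-track maximum-likelihood (midpoint, slope) estimates.

    Each track is fit by ML with the lapse fixed at a small constant for
    stability; tracks with all-correct or all-incorrect responses carry no
    information about the midpoint and are excluded with a warning.
    Returns the across-track means used to center the midpoint and slope
    priors.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to center priors")
    mids, slopes = [], []
    for i, tr in enumerate(tracks):
        x, r = _track_arrays(tr)
        if len(x) == 0 or r.min() == r.max():
            warnings.warn(f"track {i} is degenerate (uniform responses); "
                          "excluded from prior centering")
            continue
        x0 = np.array([np.median(x), 0.0])
        best = None
        for start_slope in (-1.0, 0.0, 1.0):
            res = optimize.minimize(
                _nll_fixed_lapse, np.array([x0[0], start_slope]),
                args=(x, r, guess_rate, fixed_lapse), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        mids.append(best.x[0])
        slopes.append(np.exp(best.x[1]))
    if not mids:
        raise ValueError("all tracks degenerate; cannot center priors")
    return float(np.mean(mids)), float(np.mean(slopes))


# ---------------------------------------------------------------------------
# MCMC fit
# ---------------------------------------------------------------------------

def _log_posterior(theta, x, r, prior: PFPriorSpec):
    """Unnormalised log posterior on (midpoint, log slope, log lapse).

    Prior densities are written out explicitly (up to constants) with the
    log-transform Jacobians folded in: Normal on the midpoint, gamma on
    slope and lapse, the lapse support truncated above.
    """
    alpha, log_beta, log_lapse = theta
    beta, lapse = np.exp(log_beta), np.exp(log_lapse)
    if lapse >= prior.lapse_upper or prior.guess_rate + lapse >= 1.0:
        return -np.inf
    lp = -0.5 * ((alpha - prior.midpoint_loc) / prior.midpoint_sd) ** 2
    lp += prior.slope_shape * log_beta - prior.slope_rate * beta
    lp += prior.lapse_shape * log_lapse - prior.lapse_rate_param * lapse
    if not np.isfinite(lp):
        return -np.inf
    if len(x):
        z = beta * (x - alpha)
        e = np.exp(-np.abs(z))
        f = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        p = np.clip(prior.guess_rate + (1.0 - prior.guess_rate - lapse) * f,
                    1e-12, 1 - 1e-12)
        lp += np.sum(r * np.log(p) + (1 - r) * np.log1p(-p))
    return lp


def _log_posterior_vec(theta, x, r, prior: PFPriorSpec) -> np.ndarray:
    """Vectorised log posterior over chains: theta is (C, 3)."""
    alpha, log_beta, log_lapse = theta[:, 0], theta[:, 1], theta[:, 2]
    beta, lapse = np.exp(log_beta), np.exp(log_lapse)
    lp = -0.5 * ((alpha - prior.midpoint_loc) / prior.midpoint_sd) ** 2
    lp = lp + prior.slope_shape * log_beta - prior.slope_rate * beta
    lp = lp + prior.lapse_shape * log_lapse - prior.lapse_rate_param * lapse
    if len(x):
        z = beta[:, None] * (x[None, :] - alpha[:, None])
        e = np.exp(-np.abs(z))
        f = np.where(z >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        p = np.clip(prior.guess_rate
                    + (1.0 - prior.guess_rate - lapse[:, None]) * f,
                    1e-12, 1 - 1e-12)
        lp = lp + (r[None, :] * np.log(p)
                   + (1 - r[None, :]) * np.log1p(-p)).sum(axis=1)
    bad = (lapse >= prior.lapse_upper) | (prior.guess_rate + lapse >= 1.0)
    return np.where(bad | ~np.isfinite(lp), -np.inf, lp)


def _run_chains(x, r, prior, n_chains, n_warmup, n_draws, rng):
    """Adaptive random-walk Metropolis with per-chain covariance proposals.

    All chains advance together so the per-trial likelihood is evaluated
    as one (chains x trials) array per step.
    """
    d, C = 3, n_chains
    theta = np.column_stack([
        prior.midpoint_loc + rng.normal(scale=0.1 * prior.midpoint_sd,
                                        size=C),
        np.log(prior.slope_shape / prior.slope_rate)
        + rng.normal(scale=0.1, size=C),
        np.log(min(prior.lapse_shape / prior.lapse_rate_param,
                   prior.lapse_upper / 2)) + rng.normal(scale=0.1, size=C),
    ])
    lp = _log_posterior_vec(theta, x, r, prior)
    chol = np.tile(np.diag([prior.midpoint_sd * np.sqrt(0.1),
                            np.sqrt(0.1), np.sqrt(0.1)]), (C, 1, 1))
    log_s = np.full(C, np.log(2.38 / np.sqrt(d)))
    out = np.empty((C, n_draws, d))
    hist = np.empty((n_warmup, C, d))
    for t in range(n_warmup + n_draws):
        step = np.einsum("cij,cj->ci", chol, rng.standard_normal((C, d)))
        prop = theta + np.exp(log_s)[:, None] * step
        lp_prop = _log_posterior_vec(prop, x, r, prior)
        accept = np.log(rng.random(C)) < lp_prop - lp
        theta = np.where(accept[:, None], prop, theta)
        lp = np.where(accept, lp_prop, lp)
        if t < n_warmup:
            hist[t] = theta
            # Robbins-Monro scale adaptation toward ~30% acceptance
            log_s += np.where(accept, 1.0, -0.44) * 2.0 / (t + 10)
            if t >= 200 and t % 200 == 0:
                win = hist[max(0, t - 1000):t]
                for c in range(C):
                    cov = np.cov(win[:, c, :].T) + 1e-9 * np.eye(d)
                    try:
                        chol[c] = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
        else:
            out[:, t - n_warmup] = theta
    return out


def fit_pf(trials: pd.DataFrame, priors: PFPriorSpec,
           settings: PFFitSettings = PFFitSettings()) -> PFFit:
    """Fit a logistic psychometric function to trial-level responses.

    ``trials`` is a trial log with ``stimulus`` (already on the fitting
    axis) and ``response`` columns; practice trials (is_practice == 1) are
    excluded.  Blocks of a condition should be pooled before calling.
    With no usable trials the posterior reproduces the prior.

    The fit is flagged non-converged (``converged=False``) when split
    R-hat exceeds the configured ceiling or the midpoint ESS falls below
    the floor even after the retry policy doubles the draw count;
    downstream consumers exclude flagged fits.  Threshold posteriors are
    summarised at each requested fraction of the underlying logistic
    (0.5 = midpoint; 0.25 = the quarter point).
    """
    x, r = _track_arrays(trials) if len(trials) else (np.empty(0),
                                                     np.empty(0))
    n_draws = settings.n_draws
    attempt = 0
    while True:
        rng = np.random.default_rng(settings.seed + 7919 * attempt)
        raw = _run_chains(x, r, priors, settings.n_chains,
                          settings.n_warmup, n_draws, rng)
        draws = {
            "midpoint": raw[:, :, 0],
            "slope": np.exp(raw[:, :, 1]),
            "lapse": np.exp(raw[:, :, 2]),
        }
        rhat, ess = _diagnostics(draws)
        ok = (max(rhat.values()) < settings.rhat_max
              and ess["midpoint"] >= settings.ess_floor)
        if ok or attempt >= settings.max_retries:
            break
        attempt += 1
        n_draws *= 2
    if not ok:
        warnings.warn("psychometric fit failed convergence criteria; "
                      "flagging for downstream exclusion")
    fit = PFFit(draws=draws, rhat=rhat, ess=ess, converged=bool(ok),
                guess_rate=priors.guess_rate, scale=priors.scale)
    fit.threshold_summary = _threshold_summary(fit, settings)
    return fit


def _diagnostics(draws: dict) -> tuple[dict, dict]:
    import arviz as az
    rhat, ess = {}, {}
    for k, v in draws.items():
        rhat[k] = float(az.rhat(v)) if v.shape[0] > 1 else 1.0
        ess[k] = float(az.ess(v))
    return rhat, ess


def _threshold_summary(fit: PFFit, settings: PFFitSettings) -> pd.DataFrame:
    lo_q = (1 - settings.ci_level) / 2
    rows = []
    mid = fit.flat["midpoint"]
    slope = fit.flat["slope"]
    for frac in settings.threshold_fractions:
        if frac == 0.5:
            th = mid
        else:
            th = mid + np.log(frac / (1 - frac)) / slope
        rows.append({
            "fraction": frac,
            "threshold_median": float(np.median(th)),
            "ci_lo": float(np.quantile(th, lo_q)),
            "ci_hi": float(np.quantile(th, 1 - lo_q)),
        })
    return pd.DataFrame(rows)
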