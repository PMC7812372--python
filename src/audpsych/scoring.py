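"""Derived predictor and outcome scores for the cohort analysis.

Covers lifetime-noise-exposure units and their log transform, consonance
preference from dyad pleasantness ratings, equal-temperament and
harmonic-rank stimulus arithmetic, principal components of the cognitive
test battery, the cube-root musical-experience transform and SSQ12
averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoiseExposureRecord", "tcne_units", "log_tcne",
    "consonance_preference", "et_frequency", "lowest_harmonic_rank",
    "CognitivePCs", "cognitive_pca", "music_transform", "ssq_mean",
]

# Reference exposure defining one unit of total cumulative noise exposure:
# 8 h/day, 5 days/week, 52 weeks/year for one year at 90 dBA.
_REF_HOURS_PER_YEAR = 8.0 * 5.0 * 52.0  # 2080
_REF_LEVEL_DBA = 90.0


@dataclass(frozen=True)
class NoiseExposureRecord:
    """One activity line of the structured noise-exposure interview."""

    activity: str
    level_dba: float
    hours_per_day: float
    days_per_week: float
    weeks_per_year: float
    years: float

    def __post_init__(self) -> None:
        for name in ("hours_per_day", "days_per_week", "weeks_per_year",
                     "years"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not math.isfinite(self.level_dba):
            raise ValueError("level_dba must be finite")


def tcne_units(records: Iterable[NoiseExposureRecord]) -> float:
    """Total cumulative noise exposure summed across activities.

    Each activity contributes its exposure duration relative to a working
    year (2080 h) weighted by 10^((L - 90)/10), the equal-energy trade:
    the reference activity (90 dBA, 8 h x 5 d x 52 wk x 1 y) is exactly
    one unit and +10 dBA multiplies the contribution tenfold.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one exposure record")
    total = 0.0
    for r in records:
        hours = r.hours_per_day * r.days_per_week * r.weeks_per_year * r.years
        total += (hours / _REF_HOURS_PER_YEAR) * \
            10.0 ** ((r.level_dba - _REF_LEVEL_DBA) / 10.0)
    return total


def log_tcne(units: float) -> float:
    """Base-10 log of TCNE units; a unit step is a tenfold energy change."""
    if not units > 0:
        raise ValueError("TCNE units must be positive to take the log")
    return math.log10(units)


# ---------------------------------------------------------------------------
# Consonance preference
# ---------------------------------------------------------------------------

def consonance_preference(ratings: pd.DataFrame,
                          include_practice: bool = False) -> pd.DataFrame:
    """Per-subject, per-level preference for the perfect fifth over the tritone.

    ``ratings`` needs columns subject, interval ('P5'/'TT'), dyad_level,
    root_f0, rating (in [-3, 3]); an optional is_practice column is
    excluded by default.  Each subject's ratings are z-scored across all
    of that subject's (non-practice) trials, averaged across root notes
    within interval x level, and the preference at a level is
    mean_z(P5) - mean_z(TT).  Subjects who rate every dyad identically
    have no defined preference and come back flagged with NaN.

    Returns a frame with columns subject, dyad_level, preference, defined.
    """
    df = ratings.copy()
    if "is_practice" in df.columns and not include_practice:
        df = df[df["is_practice"] == 0]
    required = {"subject", "interval", "dyad_level", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    if df["rating"].abs().max() > 3.0 + 1e-9:
        raise ValueError("ratings must lie within the [-3, 3] scale")

    out = []
    for subj, g in df.groupby("subject", sort=True):
        sd = g["rating"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            for lev in sorted(g["dyad_level"].unique()):
                out.append({"subject": subj, "dyad_level": lev,
                            "preference": np.nan, "defined": False})
            continue
        z = (g["rating"] - g["rating"].mean()) / sd
        g = g.assign(z=z)
        cell = g.groupby(["dyad_level", "interval"])["z"].mean()
        for lev in sorted(g["dyad_level"].unique()):
            try:
                pref = cell[(lev, "P5")] - cell[(lev, "TT")]
            except KeyError as err:
                raise ValueError(
                    f"subject {subj!r} lacks ratings for both intervals "
                    f"at level {lev}") from err
            out.append({"subject": subj, "dyad_level": lev,
                        "preference": float(pref), "defined": True})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Stimulus arithmetic
# ---------------------------------------------------------------------------

def et_frequency(root_hz: float, steps_of_100_cents: float) -> float:
    """Frequency a number of equal-temperament semitones above a root."""
    if not math.isfinite(root_hz) or root_hz <= 0:
        raise ValueError("root frequency must be positive and finite")
    return root_hz * 2.0 ** (steps_of_100_cents / 12.0)


def lowest_harmonic_rank(f0_hz: float, passband_low_hz: float = 1500.0,
                         minimum_rank: int | None = None) -> int:
    """Rank of the lowest harmonic of ``f0_hz`` inside a bandpass filter.

    The complex tones are bandpass filtered (1.5-2.5 kHz by default), so
    the lowest audible harmonic is ceil(edge / F0): rank 15 for a 100-Hz
    F0 at a 1.5-kHz edge, falling with rising F0 — down to rank 8 at the
    99% F0-difference cap (F0 = 199 Hz).  ``minimum_rank`` optionally
    clamps the result from below.
    """
    if f0_hz <= 0:
        raise ValueError("F0 must be positive")
    rank = math.ceil(passband_low_hz / f0_hz - 1e-12)
    if minimum_rank is not None:
        rank = max(rank, minimum_rank)
    return rank


# ---------------------------------------------------------------------------
# Cognitive PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CognitivePCs:
    """Principal components of the standardized cognitive test scores."""

    scores: np.ndarray          # subjects x components
    loadings: np.ndarray        # tests x components (unit eigenvectors)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    test_names: tuple[str, ...]


def cognitive_pca(scores: pd.DataFrame, n_retain: int = 2) -> CognitivePCs:
    """PCA of the cognitive battery on the correlation matrix.

    Each test's scores are standardized (sample mean, n-1 sd) before the
    eigendecomposition, so components are those of the correlation matrix.
    Loading vectors are oriented so their largest-magnitude element is
    positive.  All components are computed; ``scores`` holds subject
    scores on the first ``n_retain`` (the two retained as regression
    predictors by default).
    """
    X = scores.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("cognitive scores contain missing values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(scores.columns, sd) if s == 0]
        raise ValueError(f"constant cognitive test column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest-|loading| element positive in each component
    for k in range(eigvec.shape[1]):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    comp_scores = Z @ eigvec
    return CognitivePCs(
        scores=comp_scores[:, :n_retain],
        loadings=eigvec,
        eigenvalues=eigval,
        variance_fractions=eigval / eigval.sum(),
        test_names=tuple(map(str, scores.columns)),
    )


def music_transform(years) -> np.ndarray | float:
    """Cube root of years of musical practice (tames right skew)."""
    arr = np.asarray(years, dtype=float)
    if np.any(arr < 0):
        raise ValueError("years of musical practice must be non-negative")
    out = np.cbrt(arr)
    return float(out) if np.isscalar(years) else out


def ssq_mean(item_scores: Sequence[float]) -> float:
    """Mean self-reported hearing score across the 12 SSQ12 items."""
    arr = np.asarray(item_scores, dtype=float)
    if arr.size == 0 or np.isnan(arr).any():
        raise ValueError("SSQ12 items must be complete")
    return float(arr.mean())
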