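"""Synthetic study generator: cohort, ground truth, and trial-level data.

No raw cohort data accompany the study design this pipeline implements, so
every downstream module is exercised against synthetic studies whose
statistical structure matches what the analysis assumes:

* 102 participants in three balanced age bands (young 18.8-39, middle-aged
  40-59, older 60-73.6 years; 27 females / 7 males per band);
* audiometric quantities, lifetime noise exposure (log10 TCNE,
  uncorrelated with age and spanning more than three orders of magnitude),
  musical experience and two latent cognitive factors drawn from a
  Gaussian copula hitting configured pairwise correlation targets
  (e.g. age-PT2 r = 0.44, age-PTA(4-12) r = 0.84);
* four cognitive test scores built from the two latent factors with
  loadings calibrated so the correlation-matrix PCA yields ~50% / ~24%
  variance on the first two components;
* per-task thresholds (or scores) from a linear predictor with known
  coefficients, a per-subject random intercept, and Student-t residuals;
* optionally, trial-level adaptive tracks with Bernoulli responses drawn
  from each subject's generating psychometric function.

Every generated dataset is accompanied by its ground-truth sidecar so
recovery experiments can score the analysis against what generated the
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adaptive import uml_init, uml_run
from .psychometric import PsychometricFunction
from .scoring import cognitive_pca, music_transform

__all__ = [
    "SyntheticTruth", "TaskTruth", "default_truth",
    "generate_cohort", "generate_outcomes", "generate_tracks",
    "generate_dyad_ratings", "cohort_self_check", "dtt_triplet",
    "TASKS", "PREDICTOR_NAMES",
]

# ---------------------------------------------------------------------------
# Predictor correlation targets (empirically plausible pairwise values;
# the cross-audiometric entries are nuisance placeholders)
# ---------------------------------------------------------------------------

PREDICTOR_NAMES = ("age", "pt_05", "pt_2", "pta_low", "pta_high",
                   "log10_tcne", "music_y3", "cog_f1", "cog_f2")

_R_TARGET = {
    ("age", "pt_05"): 0.26, ("age", "pt_2"): 0.44,
    ("age", "pta_low"): 0.39, ("age", "pta_high"): 0.84,
    ("age", "log10_tcne"): 0.02, ("age", "music_y3"): 0.10,
    ("age", "cog_f1"): -0.06, ("age", "cog_f2"): -0.28,
    ("pt_05", "pt_2"): 0.41, ("pt_05", "pta_low"): 0.80,
    ("pt_05", "pta_high"): 0.30, ("pt_05", "log10_tcne"): -0.22,
    ("pt_05", "music_y3"): -0.01, ("pt_05", "cog_f1"): -0.13,
    ("pt_05", "cog_f2"): -0.12,
    ("pt_2", "pta_low"): 0.70, ("pt_2", "pta_high"): 0.50,
    ("pt_2", "log10_tcne"): -0.02, ("pt_2", "music_y3"): -0.03,
    ("pt_2", "cog_f1"): -0.16, ("pt_2", "cog_f2"): -0.14,
    ("pta_low", "pta_high"): 0.50, ("pta_low", "log10_tcne"): -0.14,
    ("pta_low", "music_y3"): -0.06, ("pta_low", "cog_f1"): -0.19,
    ("pta_low", "cog_f2"): -0.16,
    ("pta_high", "log10_tcne"): 0.06, ("pta_high", "music_y3"): -0.06,
    ("pta_high", "cog_f1"): -0.01, ("pta_high", "cog_f2"): -0.30,
    ("log10_tcne", "music_y3"): -0.01, ("log10_tcne", "cog_f1"): 0.05,
    ("log10_tcne", "cog_f2"): 0.07,
    ("music_y3", "cog_f1"): 0.07, ("music_y3", "cog_f2"): 0.20,
    ("cog_f1", "cog_f2"): 0.0,
}

# loadings of the four cognitive tests on the two latent factors,
# calibrated so the correlation-matrix PCA gives ~50% / ~24% variance
_COG_TESTS = ("dspan_f", "dspan_b", "rspan", "raven")
_COG_LOAD_F1 = np.array([0.62, 0.62, 0.62, 0.62])
_COG_LOAD_F2 = np.array([-0.56, -0.10, 0.56, 0.10])

_AGE_BANDS = ((18.8, 39.0), (40.0, 59.0), (60.0, 73.6))


def _target_corr_matrix() -> np.ndarray:
    k = len(PREDICTOR_NAMES)
    R = np.eye(k)
    for (a, b), r in _R_TARGET.items():
        i, j = PREDICTOR_NAMES.index(a), PREDICTOR_NAMES.index(b)
        R[i, j] = R[j, i] = r
    return R


def _nearest_pd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped projection to a positive-definite correlation."""
    val, vec = np.linalg.eigh(R)
    if val.min() > eps:
        return R
    val = np.clip(val, eps, None)
    A = vec @ np.diag(val) @ vec.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskTruth:
    """Generating model of one outcome family.

    ``conditions`` is a tuple of factor-assignment dicts; ``base`` gives
    the population mean per condition on the model axis (dB, natural-log
    units for log-scale tasks, or score units), and ``slopes`` maps a
    covariate name to per-condition slopes in model units per raw
    covariate unit.  Residuals are Student-t with ``resid_sd`` scale and
    ``resid_df`` degrees of freedom, on top of a normal per-subject
    intercept with sd ``subject_sd``.  ``observer_slope``/``observer_lapse``
    parameterise the generating psychometric function for trial-level
    simulation on the task's tracking axis.
    """

    name: str
    conditions: tuple
    base: tuple
    slopes: dict
    subject_sd: float
    resid_sd: float
    resid_df: float = 8.0
    scale: str = "linear"          # axis of `base`: raw or natural-log
    observer_slope: float = 2.0
    observer_lapse: float = 0.02


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything the generator used, kept for recovery scoring."""

    correlation_targets: dict
    tasks: dict                    # name -> TaskTruth
    seed_note: str = ""

    def to_json(self) -> str:
        payload = {
            "correlation_targets": {f"{a}|{b}": r for (a, b), r
                                    in self.correlation_targets.items()},
            "tasks": {k: asdict(v) for k, v in self.tasks.items()},
            "seed_note": self.seed_note,
        }
        return json.dumps(payload, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        corr = {tuple(k.split("|")): v
                for k, v in raw["correlation_targets"].items()}
        tasks = {}
        for name, td in raw["tasks"].items():
            td = dict(td)
            td["conditions"] = tuple(dict(c) for c in td["conditions"])
            td["base"] = tuple(td["base"])
            td["slopes"] = {k: tuple(v) for k, v in td["slopes"].items()}
            tasks[name] = TaskTruth(**td)
        return cls(correlation_targets=corr, tasks=tasks,
                   seed_note=raw.get("seed_note", ""))


def _cond(**kw) -> dict:
    return dict(kw)


def default_truth() -> SyntheticTruth:
    """Study-condition defaults for every outcome family.

    Effect sizes follow the reported posterior medians where printed —
    e.g. AM detection at 80 dB SPL sits 3.7 dB above 40 dB SPL at age 20,
    the age effect at 50 Hz grows 0.7 dB/decade faster at the high level,
    and pure-tone frequency discrimination worsens by a factor ~1.2 per
    10 dB of audiometric shift — and are otherwise small or zero.
    Slopes are per raw covariate unit (so 0.07 dB per year = 0.7 dB per
    age decade).
    """
    ln = np.log
    tasks = {}
    tasks["am"] = TaskTruth(
        name="am",
        conditions=tuple(_cond(level=lev, mod_freq=mf)
                         for lev in (40, 80) for mf in (25, 50, 100)),
        base=(-25.0, -25.0, -25.0, -21.3, -21.3, -21.3),
        slopes={
            "age": (0.05, 0.03, 0.04, 0.05, 0.10, 0.08),
            "cog_pc1": (-0.8,) * 6,
        },
        subject_sd=2.0, resid_sd=2.0, resid_df=8.0,
        scale="linear", observer_slope=0.8, observer_lapse=0.02)
    tasks["fd"] = TaskTruth(
        name="fd",
        conditions=tuple(_cond(level=lev, freq=f)
                         for lev in (40, 80) for f in (600, 2000)),
        base=(ln(0.8), ln(0.5), ln(0.7), ln(0.45)),
        slopes={
            "age": (0.002,) * 4,
            "pt_local": (ln(1.2) / 10.0,) * 4,
        },
        subject_sd=0.45, resid_sd=0.35, resid_df=8.0,
        scale="log", observer_slope=3.0, observer_lapse=0.02)
    tasks["f0d"] = TaskTruth(
        name="f0d",
        conditions=(_cond(level=40), _cond(level=80)),
        base=(ln(2.5), ln(2.0)),
        slopes={"age": (0.004, 0.006)},
        subject_sd=0.55, resid_sd=0.40, resid_df=8.0,
        scale="log", observer_slope=2.5, observer_lapse=0.02)
    tasks["ipd_mod"] = TaskTruth(
        name="ipd_mod",
        conditions=tuple(_cond(level=lev, carrier=c)
                         for lev in (40, 80) for c in (600, 2000)),
        base=(ln(20.0), ln(40.0), ln(18.0), ln(35.0)),
        slopes={
            "age": (0.0, 0.01, 0.0, 0.018),   # credible 2-kHz 80-dB effect
            "pt_local": (ln(1.3) / 10.0, ln(1.3) / 10.0, 0.0, 0.0),
        },
        subject_sd=0.5, resid_sd=0.4, resid_df=8.0,
        scale="log", observer_slope=2.5, observer_lapse=0.02)
    tasks["ipd_pt"] = TaskTruth(
        name="ipd_pt",
        conditions=(_cond(level=40), _cond(level=80)),
        base=(ln(15.0), ln(14.0)),
        slopes={"age": (0.003, 0.003)},
        subject_sd=0.5, resid_sd=0.4, resid_df=8.0,
        scale="log", observer_slope=2.5, observer_lapse=0.02)
    tasks["crm"] = TaskTruth(
        name="crm",
        conditions=tuple(_cond(level=lev, offset=off)
                         for lev in (42, 77)
                         for off in ("colocated", "offset")),
        base=(-2.0, -12.0, -2.5, -11.0),
        slopes={
            "age": (0.0,) * 4,
            "pta_low": (0.05, 0.28, 0.05, 0.17),  # SRM shrinks with PTA
            "cog_pc1": (-0.5,) * 4,
        },
        subject_sd=1.5, resid_sd=1.5, resid_df=8.0,
        scale="linear", observer_slope=0.6, observer_lapse=0.02)
    tasks["dtt"] = TaskTruth(
        name="dtt",
        conditions=(_cond(level=45), _cond(level=80)),
        base=(-8.0, -7.5),
        slopes={"age": (0.01, 0.01), "pta_low": (0.085, 0.04)},
        subject_sd=1.0, resid_sd=1.0, resid_df=8.0,
        scale="linear", observer_slope=1.0, observer_lapse=0.02)
    tasks["cons"] = TaskTruth(
        name="cons",
        conditions=tuple(_cond(dyad_level=lev, interval=iv)
                         for lev in (40, 80) for iv in ("P5", "TT")),
        base=(0.4, -0.4, 0.4, -0.4),      # preference ~0.8 at both levels
        slopes={
            "age": (-0.004, 0.004, -0.006, 0.006),  # preference falls w/ age
            "music_y3": (0.075, -0.075, 0.075, -0.075),
            "cog_pc1": (0.05, -0.05, 0.05, -0.05),
        },
        subject_sd=0.15, resid_sd=0.35, resid_df=12.0,
        scale="linear")
    tasks["ssq"] = TaskTruth(
        name="ssq",
        conditions=(_cond(),),
        base=(7.5,),
        slopes={"age": (0.0,), "pta_low": (0.0,)},
        subject_sd=0.0, resid_sd=1.0, resid_df=12.0,
        scale="linear")
    return SyntheticTruth(correlation_targets=dict(_R_TARGET), tasks=tasks)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _age_quantile(q: np.ndarray) -> np.ndarray:
    """Quantile of the equal-weight mixture of the three uniform age bands."""
    q = np.asarray(q, dtype=float)
    out = np.empty_like(q)
    for k, (lo, hi) in enumerate(_AGE_BANDS):
        sel = (q >= k / 3.0) & (q < (k + 1) / 3.0 if k < 2 else q <= 1.0)
        out[sel] = lo + (q[sel] * 3.0 - k) * (hi - lo)
    return out


def generate_cohort(n: int = 102, seed: int = 0,
                    truth: SyntheticTruth | None = None
                    ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort's predictor table from the Gaussian copula.

    Ages are mapped through a rank-based quantile transform onto the
    three-band mixture so the bands are exactly balanced (n must be
    divisible by 3); audiometric marginals are truncated normals that
    respect the selection caps (<= 20 dB HL up to 2 kHz, <= 40 dB HL at
    4 kHz); log10 TCNE is normal with sd ~1 so the cohort spans more
    than three orders of magnitude.  Sex is 27:7 female:male per band
    (scaled for other n) and carried but unused as a predictor.
    Deterministic given the seed.
    """
    if n % 3:
        raise ValueError("n must be divisible by 3 for balanced age bands")
    if truth is None:
        truth = default_truth()
    R = _nearest_pd(_target_corr_matrix())
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(len(PREDICTOR_NAMES)), R, size=n,
                                method="cholesky")
    u = stats.norm.cdf(z)
    col = {name: u[:, i] for i, name in enumerate(PREDICTOR_NAMES)}

    # rank-based age transform: exact band balance, monotone in the copula
    ranks = stats.rankdata(col["age"], method="ordinal") - 1
    age = _age_quantile((ranks + 0.5) / n)
    band = np.minimum(ranks * 3 // n, 2)

    def tnorm(u_col, mean, sd, lo, hi):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.ppf(u_col, a, b, loc=mean, scale=sd)

    pt_05 = tnorm(col["pt_05"], 5.0, 8.0, -10.0, 20.0)
    pt_2 = tnorm(col["pt_2"], 5.0, 8.0, -10.0, 20.0)
    pta_low = tnorm(col["pta_low"], 4.0, 6.0, -10.0, 20.0)
    pta_high = tnorm(col["pta_high"], 15.0, 15.0, -10.0, 70.0)
    log10_tcne = stats.norm.ppf(col["log10_tcne"], loc=0.5, scale=1.0)
    # musical practice: 40% none, else exponential years; cube root carried
    um = col["music_y3"]
    music_years = np.where(um < 0.4, 0.0,
                           stats.expon.ppf((um - 0.4) / 0.6, scale=8.0))
    f1 = z[:, PREDICTOR_NAMES.index("cog_f1")]
    f2 = z[:, PREDICTOR_NAMES.index("cog_f2")]
    resid_sd = np.sqrt(1.0 - _COG_LOAD_F1 ** 2 - _COG_LOAD_F2 ** 2)
    tests = {}
    test_scale = {"dspan_f": (10.0, 2.0), "dspan_b": (8.0, 2.0),
                  "rspan": (40.0, 10.0), "raven": (45.0, 8.0)}
    for k, tname in enumerate(_COG_TESTS):
        raw = (_COG_LOAD_F1[k] * f1 + _COG_LOAD_F2[k] * f2
               + resid_sd[k] * rng.standard_normal(n))
        m, s = test_scale[tname]
        tests[tname] = m + s * raw

    # sex: 27 females / 7 males per 34-strong band, shuffled within band
    per_band = n // 3
    n_male = max(1, round(per_band * 7 / 34))
    sex = np.empty(n, dtype=object)
    for k in range(3):
        idx = np.where(band == k)[0]
        flags = np.array(["F"] * (per_band - n_male) + ["M"] * n_male)
        rng.shuffle(flags)
        sex[idx] = flags

    df = pd.DataFrame({
        "subject": [f"S{i + 1:03d}" for i in range(n)],
        "age": age,
        "age_band": np.array(["young", "middle", "older"])[band],
        "sex": sex,
        "pt_05": pt_05, "pt_2": pt_2,
        "pta_low": pta_low, "pta_high": pta_high,
        "log10_tcne": log10_tcne,
        "tcne_units": 10.0 ** log10_tcne,
        "music_years": music_years,
        "music_y3": music_transform(music_years),
        **tests,
    })
    pcs = cognitive_pca(df[list(_COG_TESTS)])
    # orient components to a fixed loading convention: PC1 positive on
    # all tests, PC2 positive on reading span (the generic largest-loading
    # convention is sign-unstable here because the two dominant PC2
    # loadings are equal and opposite)
    s1 = np.sign(pcs.loadings[:, 0].sum()) or 1.0
    s2 = np.sign(pcs.loadings[_COG_TESTS.index("rspan"), 1]) or 1.0
    df["cog_pc1"] = s1 * pcs.scores[:, 0]
    df["cog_pc2"] = s2 * pcs.scores[:, 1]
    return df, truth


def cohort_self_check(df: pd.DataFrame) -> pd.DataFrame:
    """Achieved vs target predictor correlations (report, not a gate)."""
    proxy = {"cog_f1": "cog_pc1", "cog_f2": "cog_pc2"}
    rows = []
    for (a, b), r in _R_TARGET.items():
        ca, cb = proxy.get(a, a), proxy.get(b, b)
        rows.append({"var_a": a, "var_b": b, "target": r,
                     "achieved": float(np.corrcoef(df[ca], df[cb])[0, 1])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outcome generation (thresholds / scores, long format)
# ---------------------------------------------------------------------------

def _linear_predictor(task: TaskTruth, cohort: pd.DataFrame,
                      ci: int, cond: dict) -> np.ndarray:
    mu = np.full(len(cohort), task.base[ci], dtype=float)
    for cov, per_cond in task.slopes.items():
        if cov == "pt_local":
            key = "pt_05" if cond.get("freq", cond.get("carrier")) == 600 \
                else "pt_2"
            x = cohort[key].to_numpy(dtype=float)
        else:
            x = cohort[cov].to_numpy(dtype=float)
        mu += per_cond[ci] * (x - x.mean())
    return mu


def generate_outcomes(cohort: pd.DataFrame, truth: SyntheticTruth,
                      tasks: Sequence[str] | None = None,
                      seed: int = 0) -> dict:
    """Per-subject outcomes for each task family, long format.

    Returns a dict task name -> DataFrame with subject, the task's factor
    columns, the outcome column (raw units: log-scale tasks are
    exponentiated), a ``pt_local`` covariate column where the model uses a
    condition-dependent audiometric covariate, and the cohort predictors
    merged in.  The generating linear predictor uses mean-centered raw
    covariates, so TaskTruth slopes are directly comparable to
    unstandardized regression coefficients.
    """
    if tasks is None:
        tasks = list(truth.tasks)
    rng = np.random.default_rng(seed)
    out = {}
    for tname in tasks:
        task = truth.tasks[tname]
        rows = []
        n = len(cohort)
        u = task.subject_sd * rng.standard_normal(n)
        for ci, cond in enumerate(task.conditions):
            mu = _linear_predictor(task, cohort, ci, cond) + u
            y = mu + task.resid_sd * rng.standard_t(task.resid_df, size=n)
            block = cohort.copy()
            for k, v in cond.items():
                block[k] = v
            if "pt_local" in task.slopes:
                key = "pt_05" if cond.get("freq",
                                          cond.get("carrier")) == 600 \
                    else "pt_2"
                block["pt_local"] = cohort[key].to_numpy()
            block["outcome_model_scale"] = y
            block["outcome"] = np.exp(y) if task.scale == "log" else y
            rows.append(block)
        out[tname] = pd.concat(rows, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------

# per-task adaptive-track settings: guess rate = 1 / response alternatives,
# stimulus axis (raw or natural log of the physical quantity), start value
# and bounds on that axis
TASKS = {
    "am": {"guess": 1.0 / 3.0, "axis": "linear",
           "start": 0.0, "bounds": (-40.0, 0.0)},           # dB re 100% depth
    "fd": {"guess": 0.5, "axis": "log",
           "start": float(np.log(10.0)),
           "bounds": (float(np.log(0.01)), float(np.log(99.0)))},  # % diff
    "f0d": {"guess": 0.5, "axis": "log",
            "start": float(np.log(80.0)),
            "bounds": (float(np.log(0.01)), float(np.log(99.0)))},
    "ipd_mod": {"guess": 0.5, "axis": "log",
                "start": float(np.log(180.0)),
                "bounds": (float(np.log(0.1)), float(np.log(180.0)))},
    "ipd_pt": {"guess": 0.5, "axis": "log",
               "start": float(np.log(180.0)),
               "bounds": (float(np.log(0.1)), float(np.log(180.0)))},
    "crm": {"guess": 1.0 / 16.0, "axis": "linear",
            "start": 7.0, "bounds": (-25.0, 20.0)},          # dB SNR
    "dtt": {"guess": 1.0 / 336.0, "axis": "linear",
            "start": 10.0, "bounds": (-25.0, 20.0)},         # dB SNR
}

_DTT_DIGITS = (1, 2, 3, 4, 5, 6, 8, 9)


def dtt_triplet(rng: np.random.Generator) -> tuple[int, int, int]:
    """A digit triplet from {1..9} excluding 7, without repetition."""
    return tuple(rng.choice(_DTT_DIGITS, size=3, replace=False))


def generate_tracks(cohort: pd.DataFrame, truth: SyntheticTruth,
                    tasks: Sequence[str], seed: int = 0,
                    n_trials: int = 160, n_practice: int = 25,
                    grids: dict | None = None) -> pd.DataFrame:
    """Simulate UML adaptive tracks for each subject x condition.

    Each subject's generating psychometric function has its midpoint at
    the subject's true threshold on the task's tracking axis and the
    task's observer slope and lapse.  Responses are Bernoulli draws from
    that function at the UML-proposed stimuli; the first ``n_practice``
    trials are flagged for exclusion.  Digit-triplet trials carry the
    spoken digits (no 7, no repeats).  Returns one long trial-log table.
    """
    outcomes = generate_outcomes(cohort, truth, tasks, seed=seed)
    rng = np.random.default_rng(seed + 1)
    logs = []
    for tname in tasks:
        cfg = TASKS[tname]
        task = truth.tasks[tname]
        lo, hi = cfg["bounds"]
        table = outcomes[tname]
        factor_cols = list(task.conditions[0].keys())
        for _, row in table.iterrows():
            midpoint = row["outcome_model_scale"]
            observer = PsychometricFunction(
                midpoint=float(np.clip(midpoint, lo - 5, hi + 5)),
                slope=task.observer_slope, guess_rate=cfg["guess"],
                lapse_rate=task.observer_lapse)
            g = grids or {
                "alpha": np.linspace(lo - 5, hi + 5, 41),
                "beta": np.geomspace(task.observer_slope / 8,
                                     task.observer_slope * 8, 21),
                "lambda": np.linspace(0.0, 0.16, 5),
            }
            state = uml_init(
                prior_spec={
                    "alpha": stats.norm(0.5 * (lo + hi), 0.75 * (hi - lo)),
                    "beta": stats.gamma(2.0, scale=task.observer_slope / 2),
                    "lambda": stats.gamma(1.5, scale=1 / 30.0),
                },
                grids=g, bounds=(lo, hi), start_stimulus=cfg["start"],
                guess_rate=cfg["guess"])
            child = np.random.default_rng(rng.integers(2 ** 31))
            df = uml_run(observer, state, n_trials + n_practice, child,
                         n_practice=n_practice)
            df.attrs = {}  # drop the state object before concatenation
            df.insert(0, "subject", row["subject"])
            df.insert(1, "task", tname)
            for c in factor_cols:
                df[c] = row[c]
            if tname == "dtt":
                trips = [dtt_triplet(child) for _ in range(len(df))]
                df["digits"] = ["".join(map(str, t)) for t in trips]
            logs.append(df)
    return pd.concat(logs, ignore_index=True)


def generate_dyad_ratings(cohort: pd.DataFrame, truth: SyntheticTruth,
                          seed: int = 0, n_repeats: int = 2
                          ) -> pd.DataFrame:
    """Trial-level dyad pleasantness ratings on the -3..+3 slider.

    Ratings are generated so each subject's within-subject rating sd is
    ~1 (the interval effect plus residual noise variance sum to one), so
    the z-scored preference recovered downstream matches the generating
    preference (base[P5] - base[TT] per level) up to sampling noise.
    Root F0s run D3 (146.83 Hz) to A3 in 100-cent steps.
    """
    task = truth.tasks["cons"]
    rng = np.random.default_rng(seed)
    roots = [146.83 * 2.0 ** (s / 12.0) for s in range(8)]
    # back out half-effects per (level, interval) and a noise sd giving
    # unit total variance
    eff = {}
    for ci, cond in enumerate(task.conditions):
        eff[(cond["dyad_level"], cond["interval"])] = task.base[ci]
    mean_effect_var = np.var(list(eff.values()))
    noise_sd = np.sqrt(max(1.0 - mean_effect_var, 0.05))
    rows = []
    for _, subj in cohort.iterrows():
        for ci, cond in enumerate(task.conditions):
            mu_ij = float(_linear_predictor(task, cohort, ci, cond)[
                cohort.index[cohort["subject"] == subj["subject"]][0]])
            for root in roots:
                for _ in range(n_repeats):
                    r = mu_ij + noise_sd * rng.standard_normal()
                    rows.append({
                        "subject": subj["subject"],
                        "interval": cond["interval"],
                        "dyad_level": cond["dyad_level"],
                        "root_f0": root,
                        "rating": float(np.clip(np.round(r, 1), -3, 3)),
                        "is_practice": 0,
                    })
    return pd.DataFrame(rows)
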