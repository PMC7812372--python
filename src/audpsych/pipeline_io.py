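"""Configuration, file plumbing, model registry and the end-to-end runner.

All artifacts are delimited text (CSV with header) with JSON sidecars; a
run is reproducible from its config and seed alone.  The module also owns
the registry translating each of the nine outcome families into its
regression specification (which covariates, condition factors,
interactions and prior classes enter the model).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pf_fit, regression, synthetic_cohort
from .regression import RegressionSpec

__all__ = ["RunConfig", "run_pipeline", "model_spec", "condition_factor",
           "MODEL_FAMILIES", "read_cohort", "fit_tracks", "cli"]

log = logging.getLogger("audpsych")

_COMMON = ("age", "log10_tcne", "cog_pc1", "cog_pc2", "music_y3")


def model_spec(task: str) -> RegressionSpec:
    """Regression specification for one outcome family.

    Each family regresses its outcome on age, an audiometric covariate
    (task-specific: PT2, PT0.5, a condition-dependent one, or a pure-tone
    average), log10 TCNE, the two cognitive components and the cube-root
    musical experience, plus condition factors and the factor-by-
    {age, audiometric, noise-exposure} interactions; the speech-in-
    competition and dyad-rating families add factor-by-cognitive/musical
    interactions for the masker-offset and interval factors respectively.
    """
    def inter(factors, covs):
        return tuple((c, f) for f in factors for c in covs)

    if task == "am":
        cont = ("age", "pt_2") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", continuous=cont,
            factors=("level", "mod_freq"),
            interactions=inter(("level", "mod_freq"),
                               ("age", "pt_2", "log10_tcne")))
    if task == "fd":
        cont = ("age", "pt_local") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", transform="log", continuous=cont,
            factors=("level", "freq"),
            interactions=inter(("level", "freq"),
                               ("age", "pt_local", "log10_tcne")))
    if task == "f0d":
        cont = ("age", "pt_2") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", transform="log", continuous=cont,
            factors=("level",),
            interactions=inter(("level",), ("age", "pt_2", "log10_tcne")))
    if task == "ipd_mod":
        cont = ("age", "pt_local") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", transform="log", continuous=cont,
            factors=("level", "carrier"),
            interactions=inter(("level", "carrier"),
                               ("age", "pt_local", "log10_tcne")))
    if task == "ipd_pt":
        cont = ("age", "pt_05") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", transform="log", continuous=cont,
            factors=("level",),
            interactions=inter(("level",), ("age", "pt_05", "log10_tcne")))
    if task == "crm":
        cont = ("age", "pta_low") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", continuous=cont,
            factors=("level", "offset"),
            interactions=inter(("level", "offset"),
                               ("age", "pta_low", "log10_tcne"))
            + inter(("offset",), ("cog_pc1", "cog_pc2", "music_y3")))
    if task == "dtt":
        cont = ("age", "pta_low") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", continuous=cont,
            factors=("level",),
            interactions=inter(("level",), ("age", "pta_low", "log10_tcne")))
    if task == "cons":
        cont = ("age", "pta_low") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", continuous=cont,
            factors=("dyad_level", "interval"),
            interactions=inter(("dyad_level", "interval"),
                               ("age", "pta_low", "log10_tcne"))
            + inter(("interval",), ("cog_pc1", "cog_pc2", "music_y3")))
    if task == "ssq":
        cont = ("age", "pta_low", "pta_high") + _COMMON[1:]
        return RegressionSpec(
            outcome="outcome", continuous=cont, factors=(),
            interactions=(), random_intercept=False)
    raise ValueError(f"unknown model family {task!r}")


MODEL_FAMILIES = ("am", "fd", "f0d", "ipd_mod", "ipd_pt", "crm", "dtt",
                  "cons", "ssq")


def condition_factor(task: str) -> str | None:
    """The stimulus-level factor used for high-vs-low contrasts."""
    return {"cons": "dyad_level", "ssq": None}.get(task, "level")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    n_subjects: int = 102
    model_tasks: tuple = ("am",)
    track_tasks: tuple = ()
    track_subjects: int = 4
    track_trials: int = 160
    n_chains: int = 4
    n_warmup: int = 500
    n_draws: int = 2500
    ess_floor: float = 10000.0
    rhat_max: float = 1.01
    pf_n_draws: int = 8000
    pf_ess_floor: float = 2000.0
    outdir: str = "runs/run0"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("model_tasks", "track_tasks"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_tasks"] = list(self.model_tasks)
        d["track_tasks"] = list(self.track_tasks)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_REQUIRED_COHORT_COLS = ("subject", "age", "pt_05", "pt_2", "pta_low",
                         "pta_high", "log10_tcne", "music_y3",
                         "cog_pc1", "cog_pc2")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the columns every model may need."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COHORT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    return df


def fit_tracks(logs: pd.DataFrame, n_draws: int = 8000,
               ess_floor: float = 2000.0, seed: int = 0) -> pd.DataFrame:
    """Refit every subject x task track in a trial-log table.

    Uses each task's registered guess rate, stimulus axis and bounds for
    the priors; returns the thresholds table consumed by the regression
    stage (one row per track with a 99% interval and diagnostics).
    """
    rows = []
    for (subj, tname), g in logs.groupby(["subject", "task"]):
        cfg = synthetic_cohort.TASKS[tname]
        lo, hi = cfg["bounds"]
        priors = pf_fit.PFPriorSpec(
            midpoint_loc=0.5 * (lo + hi), midpoint_sd=0.75 * (hi - lo),
            guess_rate=cfg["guess"], scale=cfg["axis"])
        fit = pf_fit.fit_pf(
            g, priors, pf_fit.PFFitSettings(
                n_draws=n_draws, ess_floor=ess_floor, seed=seed))
        row = fit.threshold_summary.iloc[0]
        rows.append({
            "subject": subj, "task": tname,
            "threshold_median": row["threshold_median"],
            "ci99_lo": row["ci_lo"], "ci99_hi": row["ci_hi"],
            "rhat_max": max(fit.rhat.values()),
            "ess_min": min(fit.ess.values()),
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end runner
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Generate -> (track -> fit PFs) -> score -> regress -> summarise.

    Writes every stage's artifact under ``config.outdir`` and returns the
    manifest (also written as manifest.json).  Failures in a stage leave
    the manifest recording the stages that completed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}

    def record(stage: str, paths: list[Path], **extra):
        manifest["stages"][stage] = {"status": "ok", **extra}
        for p in paths:
            manifest["files"][p.name] = _sha256(p)
        log.info("stage %s complete", stage)

    try:
        # -- generate ------------------------------------------------------
        cohort, truth = synthetic_cohort.generate_cohort(
            n=config.n_subjects, seed=config.seed)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        truth_path = out / "truth.json"
        truth_path.write_text(truth.to_json())
        check = synthetic_cohort.cohort_self_check(cohort)
        check_path = out / "cohort_self_check.csv"
        check.to_csv(check_path, index=False)
        record("generate", [cohort_path, truth_path, check_path],
               seed=config.seed, n=config.n_subjects)

        # -- outcomes ------------------------------------------------------
        outcomes = synthetic_cohort.generate_outcomes(
            cohort, truth, tasks=list(config.model_tasks),
            seed=config.seed + 1)
        paths = []
        for tname, table in outcomes.items():
            p = out / f"outcomes_{tname}.csv"
            table.to_csv(p, index=False)
            paths.append(p)
        record("outcomes", paths, seed=config.seed + 1)

        # -- trial-level tracks and PF refits (optional) -------------------
        if config.track_tasks:
            sub = cohort.head(config.track_subjects)
            logs = synthetic_cohort.generate_tracks(
                sub, truth, list(config.track_tasks),
                seed=config.seed + 2, n_trials=config.track_trials)
            log_path = out / "trial_logs.csv"
            logs.to_csv(log_path, index=False)
            thresholds = fit_tracks(logs, n_draws=config.pf_n_draws,
                                    ess_floor=config.pf_ess_floor,
                                    seed=config.seed + 3)
            th_path = out / "pf_thresholds.csv"
            thresholds.to_csv(th_path, index=False)
            record("tracks", [log_path, th_path], seed=config.seed + 2)

        # -- regression ----------------------------------------------------
        settings = regression.FitSettings(
            n_chains=config.n_chains, n_warmup=config.n_warmup,
            n_draws=config.n_draws, ess_floor=config.ess_floor,
            rhat_max=config.rhat_max, seed=config.seed + 4)
        paths = []
        for tname in config.model_tasks:
            spec = model_spec(tname)
            fit = regression.fit_model(spec, outcomes[tname],
                                       settings=settings)
            ci = regression.summarize_ci(fit)
            p1 = out / f"model_{tname}_ci.csv"
            ci.to_csv(p1, index=False)
            paths.append(p1)
            summary = {
                "task": tname, "converged": fit.converged,
                "rhat": fit.rhat, "ess": fit.ess,
                "sigma_median": float(np.median(fit.sigma)),
                "nu_median": float(np.median(fit.nu)),
            }
            p2 = out / f"model_{tname}_summary.json"
            p2.write_text(json.dumps(summary, indent=2))
            paths.append(p2)
            fac = condition_factor(tname)
            if fac is not None:
                con = regression.covariate_slopes_by_factor(
                    fit, "age", fac, per=10.0)
                p3 = out / f"contrasts_{tname}_age.csv"
                con.to_csv(p3, index=False)
                paths.append(p3)
        record("regress", paths, seed=config.seed + 4)
    except Exception as err:  # manifest keeps the partial state
        manifest["stages"]["error"] = {"status": "failed", "detail": str(err)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Command-line interface (thin wrappers over the library)
# ---------------------------------------------------------------------------

import click  # noqa: E402


@click.group()
def cli():
    """Synthetic auditory-aging study pipeline."""
    logging.basicConfig(level=logging.INFO, format="%(message)s")


@cli.command()
@click.option("--seed", default=0, type=int)
@click.option("--n", "n_subjects", default=102, type=int)
@click.option("--out", "outdir", default="runs/cohort", type=str)
def generate(seed, n_subjects, outdir):
    """Generate a cohort CSV with its truth sidecar and self-check."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = synthetic_cohort.generate_cohort(n_subjects, seed)
    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "truth.json").write_text(truth.to_json())
    synthetic_cohort.cohort_self_check(cohort).to_csv(
        out / "cohort_self_check.csv", index=False)
    click.echo(f"wrote cohort of {n_subjects} to {out}")


@cli.command()
@click.option("--config", "config_path", required=True, type=str)
def run(config_path):
    """Run the full pipeline from a YAML/JSON config."""
    manifest = run_pipeline(RunConfig.from_file(config_path))
    click.echo(json.dumps({k: v for k, v in manifest["stages"].items()},
                          indent=2))


@cli.command()
@click.option("--cohort", "cohort_path", required=True, type=str)
@click.option("--truth", "truth_path", required=True, type=str)
@click.option("--task", "tasks", multiple=True, required=True, type=str)
@click.option("--subjects", default=4, type=int)
@click.option("--trials", default=160, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--out", "out_path", default="trial_logs.csv", type=str)
def track(cohort_path, truth_path, tasks, subjects, trials, seed, out_path):
    """Simulate adaptive tracks for the first N cohort subjects."""
    cohort = read_cohort(cohort_path)
    truth = synthetic_cohort.SyntheticTruth.from_json(
        Path(truth_path).read_text())
    logs = synthetic_cohort.generate_tracks(
        cohort.head(subjects), truth, list(tasks),
        seed=seed, n_trials=trials)
    logs.to_csv(out_path, index=False)
    click.echo(f"wrote {len(logs)} trials to {out_path}")


@cli.command()
@click.option("--logs", "log_path", required=True, type=str)
@click.option("--draws", default=8000, type=int)
@click.option("--ess-floor", default=2000.0, type=float)
@click.option("--seed", default=0, type=int)
@click.option("--out", "out_path", default="pf_thresholds.csv", type=str)
def fitpf(log_path, draws, ess_floor, seed, out_path):
    """Refit psychometric functions to a trial-log CSV."""
    logs = pd.read_csv(log_path)
    thresholds = fit_tracks(logs, n_draws=draws, ess_floor=ess_floor,
                            seed=seed)
    thresholds.to_csv(out_path, index=False)
    bad = int((~thresholds["converged"]).sum())
    click.echo(f"fitted {len(thresholds)} tracks "
               f"({bad} unconverged) -> {out_path}")


@cli.command()
@click.option("--ratings", "ratings_path", required=True, type=str)
@click.option("--out", "out_path", default="cons_preference.csv", type=str)
def score(ratings_path, out_path):
    """Compute consonance-preference scores from dyad ratings."""
    from . import scoring
    ratings = pd.read_csv(ratings_path)
    pref = scoring.consonance_preference(ratings)
    pref.to_csv(out_path, index=False)
    click.echo(f"wrote {len(pref)} preference rows to {out_path}")


@cli.command()
@click.option("--task", required=True,
              type=click.Choice(list(MODEL_FAMILIES)))
@click.option("--data", "data_path", required=True, type=str)
@click.option("--chains", default=4, type=int)
@click.option("--warmup", default=1000, type=int)
@click.option("--draws", default=25000, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--out", "out_path", default=None, type=str)
def regress(task, data_path, chains, warmup, draws, seed, out_path):
    """Fit the robust mixed model for one outcome family."""
    table = pd.read_csv(data_path)
    settings = regression.FitSettings(
        n_chains=chains, n_warmup=warmup, n_draws=draws, seed=seed)
    fit = regression.fit_model(model_spec(task), table, settings=settings)
    ci = regression.summarize_ci(fit)
    out_path = out_path or f"model_{task}_ci.csv"
    ci.to_csv(out_path, index=False)
    click.echo(ci.to_string(index=False))
    click.echo(f"converged={fit.converged} -> {out_path}")


@cli.command()
@click.option("--task", required=True,
              type=click.Choice(list(MODEL_FAMILIES)))
@click.option("--data", "data_path", required=True, type=str)
@click.option("--covariate", default="age", type=str)
@click.option("--per", default=10.0, type=float)
@click.option("--chains", default=4, type=int)
@click.option("--warmup", default=1000, type=int)
@click.option("--draws", default=25000, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--out", "out_path", default=None, type=str)
def contrasts(task, data_path, covariate, per, chains, warmup, draws, seed,
              out_path):
    """Per-condition covariate slopes and their pairwise differences."""
    fac = condition_factor(task)
    if fac is None:
        raise click.UsageError(f"family {task!r} has no condition factor")
    table = pd.read_csv(data_path)
    settings = regression.FitSettings(
        n_chains=chains, n_warmup=warmup, n_draws=draws, seed=seed)
    fit = regression.fit_model(model_spec(task), table, settings=settings)
    con = regression.covariate_slopes_by_factor(fit, covariate, fac, per=per)
    out_path = out_path or f"contrasts_{task}_{covariate}.csv"
    con.to_csv(out_path, index=False)
    click.echo(con.to_string(index=False))
    click.echo(f"-> {out_path}")


@cli.command()
@click.option("--outdir", required=True, type=str)
def report(outdir):
    """Print the manifest of a completed run."""
    click.echo((Path(outdir) / "manifest.json").read_text())
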