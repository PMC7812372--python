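"""Tests for the synthetic cohort / outcome / track generators."""

import numpy as np
import pandas as pd
import pytest

from audpsych import (
    SyntheticTruth, default_truth, generate_cohort, generate_outcomes,
    generate_tracks, generate_dyad_ratings, cohort_self_check, dtt_triplet,
    TASKS,
)
from audpsych.synthetic_cohort import PREDICTOR_NAMES, _R_TARGET


# ---------------------------------------------------------------------------
# Cohort structure
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort102():
    return generate_cohort(n=102, seed=11)


def test_determinism(small_cohort):
    df1, _ = small_cohort
    df2, _ = generate_cohort(n=12, seed=99)
    pd.testing.assert_frame_equal(df1, df2)
    df3, _ = generate_cohort(n=12, seed=100)
    assert not df1["age"].equals(df3["age"])


def test_age_bands_balanced_and_within_range(cohort102):
    df, _ = cohort102
    counts = df["age_band"].value_counts()
    assert counts["young"] == counts["middle"] == counts["older"] == 34
    young = df[df["age_band"] == "young"]["age"]
    older = df[df["age_band"] == "older"]["age"]
    assert young.between(18.8, 39.0).all()
    assert df[df["age_band"] == "middle"]["age"].between(40.0, 59.0).all()
    assert older.between(60.0, 73.6).all()
    with pytest.raises(ValueError):
        generate_cohort(n=100, seed=0)  # not divisible by 3


def test_sex_ratio_per_band(cohort102):
    df, _ = cohort102
    for band in ("young", "middle", "older"):
        sub = df[df["age_band"] == band]
        assert (sub["sex"] == "F").sum() == 27
        assert (sub["sex"] == "M").sum() == 7


def test_audiometric_selection_caps(cohort102):
    df, _ = cohort102
    # <= 20 dB HL up to 2 kHz, <= 40 dB HL allowed at the high average
    for col in ("pt_05", "pt_2", "pta_low"):
        assert df[col].max() <= 20.0 + 1e-9
        assert df[col].min() >= -10.0 - 1e-9
    assert df["pta_high"].max() <= 70.0 + 1e-9


def test_tcne_spans_three_orders_of_magnitude(cohort102):
    df, _ = cohort102
    assert df["log10_tcne"].max() - df["log10_tcne"].min() > 3.0
    np.testing.assert_allclose(df["tcne_units"], 10.0 ** df["log10_tcne"],
                               rtol=1e-12)


def test_music_transform_column_consistent(cohort102):
    df, _ = cohort102
    np.testing.assert_allclose(df["music_y3"],
                               np.cbrt(df["music_years"]), atol=1e-12)
    assert (df["music_years"] == 0).mean() == pytest.approx(0.4, abs=0.15)


def test_cognitive_pcs_are_orthogonal_scores(cohort102):
    df, _ = cohort102
    r = np.corrcoef(df["cog_pc1"], df["cog_pc2"])[0, 1]
    assert abs(r) < 1e-8


def test_copula_hits_correlation_targets_at_scale():
    """At n=3000 the achieved predictor correlations approach the targets
    (cognitive factors excluded: PC scores attenuate the latent values)."""
    df, _ = generate_cohort(n=3000, seed=5)
    check = cohort_self_check(df)
    direct = check[~check["var_a"].str.startswith("cog") &
                   ~check["var_b"].str.startswith("cog")]
    err = (direct["achieved"] - direct["target"]).abs()
    assert err.max() < 0.08
    # headline values individually
    by_pair = {(r.var_a, r.var_b): r.achieved
               for r in check.itertuples()}
    assert by_pair[("age", "pt_2")] == pytest.approx(0.44, abs=0.06)
    assert by_pair[("age", "pta_high")] == pytest.approx(0.84, abs=0.06)
    assert abs(by_pair[("age", "log10_tcne")]) < 0.08
    # the cognitive-factor correlations keep their sign even if attenuated
    assert by_pair[("age", "cog_f2")] < -0.1


def test_cognitive_pca_variance_fractions():
    from audpsych import cognitive_pca
    df, _ = generate_cohort(n=3000, seed=5)
    pcs = cognitive_pca(df[["dspan_f", "dspan_b", "rspan", "raven"]])
    assert pcs.variance_fractions[0] == pytest.approx(0.502, abs=0.05)
    assert pcs.variance_fractions[1] == pytest.approx(0.242, abs=0.05)


def test_self_check_covers_every_target(cohort102):
    df, _ = cohort102
    check = cohort_self_check(df)
    assert len(check) == len(_R_TARGET)
    assert set(check.columns) == {"var_a", "var_b", "target", "achieved"}


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------

def test_truth_json_round_trip():
    truth = default_truth()
    back = SyntheticTruth.from_json(truth.to_json())
    assert set(back.tasks) == set(truth.tasks)
    for name in truth.tasks:
        a, b = truth.tasks[name], back.tasks[name]
        assert a.conditions == b.conditions
        np.testing.assert_allclose(a.base, b.base, atol=1e-12)
        assert set(a.slopes) == set(b.slopes)
        for k in a.slopes:
            np.testing.assert_allclose(a.slopes[k], b.slopes[k], atol=1e-12)
        assert (a.subject_sd, a.resid_sd, a.scale) == \
            (b.subject_sd, b.resid_sd, b.scale)
    assert back.correlation_targets[("age", "pt_2")] == 0.44


def test_default_truth_covers_nine_families():
    truth = default_truth()
    assert set(truth.tasks) == {"am", "fd", "f0d", "ipd_mod", "ipd_pt",
                                "crm", "dtt", "cons", "ssq"}
    for t in truth.tasks.values():
        assert len(t.base) == len(t.conditions)
        for slopes in t.slopes.values():
            assert len(slopes) == len(t.conditions)


# ---------------------------------------------------------------------------
# Outcome generation
# ---------------------------------------------------------------------------

def test_outcomes_layout_and_determinism(cohort102):
    df, truth = cohort102
    out1 = generate_outcomes(df, truth, tasks=["am", "fd"], seed=3)
    out2 = generate_outcomes(df, truth, tasks=["am", "fd"], seed=3)
    assert set(out1) == {"am", "fd"}
    pd.testing.assert_frame_equal(out1["am"], out2["am"])
    am = out1["am"]
    assert len(am) == 102 * 6
    assert set(am["level"]) == {40, 80}
    assert set(am["mod_freq"]) == {25, 50, 100}
    # linear-scale task: outcome equals the model-scale value
    np.testing.assert_allclose(am["outcome"], am["outcome_model_scale"],
                               atol=1e-12)


def test_log_scale_outcomes_exponentiated(cohort102):
    df, truth = cohort102
    fd = generate_outcomes(df, truth, tasks=["fd"], seed=3)["fd"]
    np.testing.assert_allclose(fd["outcome"],
                               np.exp(fd["outcome_model_scale"]), rtol=1e-12)
    assert (fd["outcome"] > 0).all()


def test_pt_local_switches_with_condition(cohort102):
    df, truth = cohort102
    fd = generate_outcomes(df, truth, tasks=["fd"], seed=3)["fd"]
    low = fd[fd["freq"] == 600]
    high = fd[fd["freq"] == 2000]
    np.testing.assert_allclose(low["pt_local"], low["pt_05"], atol=1e-12)
    np.testing.assert_allclose(high["pt_local"], high["pt_2"], atol=1e-12)


def test_generating_slopes_recovered_by_ols(cohort102):
    """Regressing the model-scale outcome per condition on the centred
    covariates recovers the generating slopes (the whole point of the
    sidecar)."""
    df, truth = cohort102
    am = generate_outcomes(df, truth, tasks=["am"], seed=21)["am"]
    task = truth.tasks["am"]
    for ci, cond in enumerate(task.conditions):
        sub = am[(am["level"] == cond["level"]) &
                 (am["mod_freq"] == cond["mod_freq"])]
        X = np.column_stack([
            np.ones(len(sub)),
            sub["age"] - sub["age"].mean(),
            sub["cog_pc1"] - sub["cog_pc1"].mean(),
        ])
        b = np.linalg.lstsq(X, sub["outcome_model_scale"], rcond=None)[0]
        # noise sd ~2.8 over 102 subjects -> se(age slope) ~ 0.02
        assert b[1] == pytest.approx(task.slopes["age"][ci], abs=0.07)
        assert b[2] == pytest.approx(task.slopes["cog_pc1"][ci], abs=1.0)


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------

def test_dtt_triplet_no_seven_no_repeats(rng):
    for _ in range(200):
        t = dtt_triplet(rng)
        assert len(t) == 3 and len(set(t)) == 3
        assert 7 not in t
        assert all(1 <= d <= 9 for d in t)


def test_task_registry_covers_trackable_tasks():
    assert set(TASKS) == {"am", "fd", "f0d", "ipd_mod", "ipd_pt",
                          "crm", "dtt"}
    for cfg in TASKS.values():
        lo, hi = cfg["bounds"]
        assert lo < hi
        assert lo <= cfg["start"] <= hi
        assert 0 < cfg["guess"] < 1
        assert cfg["axis"] in ("linear", "log")


def test_generate_tracks_layout(small_cohort):
    df, truth = small_cohort
    logs = generate_tracks(df.head(2), truth, ["am"], seed=1,
                           n_trials=40, n_practice=5)
    assert len(logs) == 2 * 6 * 45  # subjects x am conditions x trials
    assert set(logs["subject"]) == set(df.head(2)["subject"])
    assert (logs.groupby(["subject", "level", "mod_freq"])["is_practice"]
            .sum() == 5).all()
    lo, hi = TASKS["am"]["bounds"]
    assert logs["stimulus"].between(lo, hi).all()
    assert logs["response"].isin([0, 1]).all()


def test_generate_tracks_dtt_digits(small_cohort):
    df, truth = small_cohort
    logs = generate_tracks(df.head(1), truth, ["dtt"], seed=1,
                           n_trials=10, n_practice=0)
    assert "digits" in logs.columns
    for s in logs["digits"]:
        assert len(s) == 3 and "7" not in s and len(set(s)) == 3


def test_tracks_follow_the_subjects_threshold(small_cohort):
    """Late-track stimuli concentrate near each subject's true threshold."""
    df, truth = small_cohort
    logs = generate_tracks(df.head(3), truth, ["am"], seed=2,
                           n_trials=120, n_practice=20)
    out = generate_outcomes(df.head(3), truth, ["am"], seed=2)["am"]
    merged = logs.merge(
        out[["subject", "level", "mod_freq", "outcome_model_scale"]],
        on=["subject", "level", "mod_freq"])
    late = merged[merged["trial_index"] >= 100]
    err = (late.groupby(["subject", "level", "mod_freq"])
           .apply(lambda g: g["stimulus"].median()
                  - g["outcome_model_scale"].iloc[0],
                  include_groups=False))
    assert err.abs().median() < 5.0


# ---------------------------------------------------------------------------
# Dyad ratings
# ---------------------------------------------------------------------------

def test_dyad_ratings_layout(small_cohort):
    df, truth = small_cohort
    ratings = generate_dyad_ratings(df, truth, seed=4, n_repeats=2)
    # subjects x 4 (level x interval) x 8 roots x 2 repeats
    assert len(ratings) == len(df) * 4 * 8 * 2
    assert ratings["rating"].between(-3, 3).all()
    assert set(ratings["interval"]) == {"P5", "TT"}
    roots = sorted(ratings["root_f0"].unique())
    assert len(roots) == 8
    assert roots[0] == pytest.approx(146.83, abs=0.01)
    assert roots[-1] == pytest.approx(146.83 * 2 ** (7 / 12), abs=0.01)


def test_dyad_ratings_recover_generating_preference(small_cohort):
    from audpsych import consonance_preference
    df, truth = small_cohort
    ratings = generate_dyad_ratings(df, truth, seed=4, n_repeats=4)
    pref = consonance_preference(ratings)
    # generating preference is 0.8 at both levels before z attenuation
    assert pref["defined"].all()
    assert pref["preference"].mean() == pytest.approx(0.8, abs=0.3)
    assert (pref["preference"] > 0).mean() > 0.9
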