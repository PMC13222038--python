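"""Inference-stage tests: chance t tests, dummy-coding re-basing, cluster
bootstrap behaviour, and the two-part zero-inflated beta likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import statsmodels.api as sm

from contiguity import (
    ConvergenceError,
    FactorSpec,
    ModelSpec,
    RunConfig,
    SeparationError,
    SimulationConfig,
    adjust_ones,
    fit_recall_model,
    fit_score_model,
    fit_zib,
    make_zib_data,
    one_sample_t,
    recode_reference,
    run_full_analysis,
    simulate_cohort,
)
from contiguity.io import item_outcomes


GROUP = FactorSpec("group", ("NC", "TBI"), "NC")


# ---------------------------------------------------------------------------
# one-sample t
# ---------------------------------------------------------------------------

class TestOneSampleT:
    def test_symmetric_sample_t_zero(self):
        res = one_sample_t([0.4, 0.5, 0.6])
        assert res.t == pytest.approx(0.0)
        assert res.df == 2

    def test_closed_form(self):
        res = one_sample_t([0.6, 0.7, 0.8])
        assert res.t == pytest.approx(0.2 / (0.1 / math.sqrt(3)))
        assert res.df == 2

    def test_matches_textbook_formula_on_random_input(self, rng):
        x = rng.normal(0.55, 0.1, size=40)
        res = one_sample_t(x)
        t = (x.mean() - 0.5) / (x.std(ddof=1) / math.sqrt(40))
        assert res.t == pytest.approx(t, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.7])
        with pytest.raises(ValueError):
            one_sample_t([0.7, 0.7, 0.7])


# ---------------------------------------------------------------------------
# spec plumbing / recode_reference
# ---------------------------------------------------------------------------

def _score_data(n_per_group=40, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, shift in (("NC", 0.0), ("TBI", delta)):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            re_p = rng.normal(0, 0.03)  # participant random effect
            for tp in ("No Delay", "Long Delay"):
                rows.append(
                    {
                        "participant_id": pid,
                        "group": g,
                        "timepoint": tp,
                        "score": 0.8
                        + shift
                        + (-0.05 if tp == "Long Delay" else 0.0)
                        + re_p
                        + rng.normal(0, 0.08),
                        "percent_recall": rng.uniform(0.3, 0.9),
                    }
                )
    return pd.DataFrame(rows)


TP = FactorSpec("timepoint", ("No Delay", "Long Delay"), "No Delay")


class TestRecodeReference:
    def test_unknown_factor_or_level(self):
        spec = ModelSpec("score", (GROUP, TP))
        with pytest.raises(KeyError):
            recode_reference(spec, "task", "narrative")
        with pytest.raises(ValueError):
            recode_reference(spec, "group", "HC")

    def test_identity_recode(self):
        spec = ModelSpec("score", (GROUP, TP))
        assert recode_reference(spec, "group", "NC") is spec

    def test_loglik_and_fitted_invariant(self):
        data = _score_data(delta=-0.06, seed=3)
        spec = ModelSpec("score", (GROUP, TP))
        fit_a = fit_score_model(data, spec, bootstrap=0)
        fit_b = fit_score_model(
            data, recode_reference(spec, "group", "TBI"), bootstrap=0
        )
        assert fit_a.llf == pytest.approx(fit_b.llf, rel=1e-8)

    def test_simple_effect_algebra_two_level_factor(self):
        # new reference simple effect = old simple effect + old interaction
        data = _score_data(delta=-0.06, seed=4)
        spec = ModelSpec("score", (GROUP, TP))
        base = fit_score_model(data, spec, bootstrap=0)
        flipped = fit_score_model(
            data, recode_reference(spec, "group", "TBI"), bootstrap=0
        )
        old_tp = base.coef("timepoint[T.Long Delay]")["estimate"]
        old_int = base.coef("group[T.TBI]:timepoint[T.Long Delay]")["estimate"]
        new_tp = flipped.coef("timepoint[T.Long Delay]")["estimate"]
        assert new_tp == pytest.approx(old_tp + old_int, rel=1e-8)


# ---------------------------------------------------------------------------
# recall-accuracy logistic model
# ---------------------------------------------------------------------------

def _item_data(n_per_group=120, logit_diff=0.0, seed=0, p_base=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    for g, d in (("NC", 0.0), ("TBI", logit_diff)):
        p = expit(logit(p_base) + d)
        for i in range(n_per_group):
            pid = f"{g}{i}"
            for tp in ("No Delay", "Long Delay"):
                for item in range(12):
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": g,
                            "timepoint": tp,
                            "recalled": int(rng.random() < p),
                        }
                    )
    return pd.DataFrame(rows)


class TestRecallModel:
    def test_null_group_effect_covered_by_ci(self):
        data = _item_data(seed=11)
        fit = fit_recall_model(
            data, ModelSpec("recalled", (GROUP, TP)), bootstrap=120, seed=1
        )
        row = fit.coef("group[T.TBI]")
        assert row["ci_lo"] <= 0 <= row["ci_hi"]

    def test_recovers_generating_logit_difference(self):
        cfg = SimulationConfig(n_per_group=200, include_wordlist=False, seed=8)
        # group logit gap at the No Delay reference: logit(.51) - logit(.65)
        expected = logit(0.51) - logit(0.65)
        ds = simulate_cohort(cfg)
        items = item_outcomes(ds.recalls, ds.manifest)
        fit = fit_recall_model(
            items,
            ModelSpec(
                "recalled",
                (GROUP, FactorSpec("timepoint", SimulationConfig().narrative_timepoints, "No Delay")),
            ),
            bootstrap=0,
        )
        est = fit.coef("group[T.TBI]")["estimate"]
        assert est == pytest.approx(expected, abs=0.15)

    def test_constant_outcome_is_separation_error(self):
        data = _item_data(seed=2)
        data["recalled"] = 1
        with pytest.raises(SeparationError):
            fit_recall_model(data, ModelSpec("recalled", (GROUP, TP)), bootstrap=0)

    def test_nonbinary_outcome_rejected(self):
        data = _item_data(seed=2)
        data.loc[0, "recalled"] = 2
        with pytest.raises(ValueError, match="binary"):
            fit_recall_model(data, ModelSpec("recalled", (GROUP, TP)), bootstrap=0)

    def test_missing_factor_level_named(self):
        data = _item_data(seed=2)
        data = data[data["group"] == "NC"]
        with pytest.raises(ValueError, match="TBI"):
            fit_recall_model(data, ModelSpec("recalled", (GROUP, TP)), bootstrap=0)


# ---------------------------------------------------------------------------
# score model
# ---------------------------------------------------------------------------

class TestScoreModel:
    def test_group_gap_detected(self):
        data = _score_data(n_per_group=200, delta=-0.06, seed=9)
        fit = fit_score_model(
            data, ModelSpec("score", (GROUP, TP)), bootstrap=150, seed=2
        )
        row = fit.coef("group[T.TBI]")
        assert row["estimate"] < 0
        assert row["ci_hi"] < 0

    def test_null_coverage_over_cohorts(self):
        hits = 0
        for seed in range(100):
            data = _score_data(n_per_group=15, delta=0.0, seed=1000 + seed)
            fit = fit_score_model(
                data, ModelSpec("score", (GROUP, TP)), bootstrap=99, seed=seed
            )
            row = fit.coef("group[T.TBI]")
            hits += row["ci_lo"] <= 0 <= row["ci_hi"]
        assert hits >= 90

    def test_centering_invariance_of_slopes(self):
        data = _score_data(n_per_group=60, delta=-0.05, seed=5)
        spec = ModelSpec("score", (GROUP, TP))
        fit_a = fit_score_model(data, spec, percent_recall=True, bootstrap=0)
        shifted = data.assign(percent_recall=data["percent_recall"] + 0.37)
        fit_b = fit_score_model(shifted, spec, percent_recall=True, bootstrap=0)
        pd.testing.assert_frame_equal(
            fit_a.coefficients, fit_b.coefficients, rtol=1e-10, atol=1e-12
        )

    def test_undefined_scores_dropped(self):
        data = _score_data(seed=6)
        data.loc[data.index[:5], "score"] = np.nan
        fit = fit_score_model(data, ModelSpec("score", (GROUP, TP)), bootstrap=0)
        assert fit.n_obs == len(data) - 5

    def test_rank_deficient_design_names_aliased_terms(self):
        data = _score_data(seed=7)
        data["dup"] = 1.0  # perfectly collinear with the intercept
        spec = ModelSpec("score", (GROUP,), covariates=("dup",))
        with pytest.raises(ValueError, match="aliased"):
            fit_score_model(data, spec, bootstrap=0)


# ---------------------------------------------------------------------------
# zero-inflated beta regression
# ---------------------------------------------------------------------------

def _zib_sim(n=5000, seed=0, b_zero=(-1.0, 0.8), b_beta=(0.5, -0.6, 0.9), phi=20.0):
    """Simulate from the two-part model itself.

    zero part: logit P(y=0) = b0 + b1*abs_lag_c
    beta part: logit mu = c0 + c1*abs_lag_c + c2*direction
    """
    rng = np.random.default_rng(seed)
    abs_lag = rng.integers(1, 6, size=n)
    direction = rng.choice([-0.5, 0.5], size=n)
    alc = abs_lag - 3.0
    pz = expit(b_zero[0] + b_zero[1] * alc)
    mu = expit(b_beta[0] + b_beta[1] * alc + b_beta[2] * direction)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    y[rng.random(n) < pz] = 0.0
    return pd.DataFrame(
        {"crp": y, "abs_lag_c": alc, "direction": direction}
    )


class TestZIB:
    def test_intercept_only_saturated_solution(self):
        df = pd.DataFrame({"crp": [0.0, 0.0, 0.5, 0.5] * 30})
        fit = fit_zib(df, ModelSpec("crp"))
        pi_hat = expit(fit.coef("Intercept", part="zero")["estimate"])
        mu_hat = expit(fit.coef("Intercept", part="beta")["estimate"])
        assert pi_hat == pytest.approx(0.5, abs=1e-6)
        assert mu_hat == pytest.approx(0.5, abs=1e-6)

    def test_parameter_recovery(self):
        df = _zib_sim(n=5000, seed=42)
        spec = ModelSpec("crp", numeric=("abs_lag_c", "direction"))
        # generating model has no abs_lag x direction interaction; fit the
        # full-factorial spec and expect ~0 there
        fit = fit_zib(df, spec)
        assert fit.coef("Intercept", "zero")["estimate"] == pytest.approx(-1.0, abs=0.1)
        assert fit.coef("abs_lag_c", "zero")["estimate"] == pytest.approx(0.8, abs=0.1)
        assert fit.coef("Intercept", "beta")["estimate"] == pytest.approx(0.5, abs=0.1)
        assert fit.coef("abs_lag_c", "beta")["estimate"] == pytest.approx(-0.6, abs=0.1)
        assert fit.coef("direction", "beta")["estimate"] == pytest.approx(0.9, abs=0.1)
        assert fit.meta["phi"] == pytest.approx(20.0, rel=0.15)

    def test_exact_ones_rejected_before_fitting(self):
        df = pd.DataFrame({"crp": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match=r"\.999"):
            fit_zib(df, ModelSpec("crp"))

    def test_adjust_ones(self):
        y = adjust_ones([0.0, 1.0, 0.25])
        assert list(y) == [0.0, 0.999, 0.25]

    def test_make_zib_data_drops_impossible_cells(self):
        crp = pd.DataFrame(
            {
                "lag": [1, 2, -1],
                "occurred": [1, 0, 0],
                "possible": [1, 2, 0],
                "crp": [1.0, 0.0, np.nan],
            }
        )
        out = make_zib_data(crp)
        assert len(out) == 2
        assert out["crp"].tolist() == [0.999, 0.0]

    def test_matches_statsmodels_two_part_oracle(self):
        # independent route: statsmodels Logit for the zero part and
        # BetaModel for the positives must agree with the joint ML fit
        from statsmodels.othermod.betareg import BetaModel

        df = _zib_sim(n=2000, seed=7)
        spec = ModelSpec("crp", numeric=("abs_lag_c", "direction"))
        fit = fit_zib(df, spec)

        X = pd.DataFrame(
            {
                "const": 1.0,
                "abs_lag_c": df["abs_lag_c"],
                "direction": df["direction"],
                "abs_lag_c:direction": df["abs_lag_c"] * df["direction"],
            }
        )
        z = (df["crp"] == 0).astype(float)
        logit_res = sm.Logit(z, X).fit(disp=0)
        pos = df["crp"] > 0
        beta_res = BetaModel(df.loc[pos, "crp"], X[pos]).fit(disp=0)

        zero_terms = ["Intercept", "abs_lag_c", "direction", "abs_lag_c:direction"]
        for ours, theirs in zip(zero_terms, logit_res.params):
            assert fit.coef(ours, "zero")["estimate"] == pytest.approx(
                theirs, abs=1e-5
            )
        for ours, theirs in zip(zero_terms, beta_res.params[:-1]):
            assert fit.coef(ours, "beta")["estimate"] == pytest.approx(
                theirs, abs=1e-4
            )
        sm_lphi = float(np.asarray(beta_res.params)[-1])  # precision on log scale
        assert fit.meta["phi"] == pytest.approx(math.exp(sm_lphi), rel=0.01)

    def test_log_link_supported(self):
        df = _zib_sim(n=1500, seed=13)
        spec = ModelSpec("crp", numeric=("abs_lag_c",))
        fit = fit_zib(df, spec, link="log")
        assert fit.converged
        assert fit.meta["link"] == "log"


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_bundle():
    ds = simulate_cohort(SimulationConfig(n_per_group=12, seed=77))
    return run_full_analysis(ds, RunConfig(bootstrap_B=0, seed=77))


class TestRunFullAnalysis:

    def test_known_effect_signs_reproduced(self):
        ds = simulate_cohort(SimulationConfig(n_per_group=60, seed=31))
        bundle = run_full_analysis(ds, RunConfig(bootstrap_B=0, seed=31))
        models = bundle["models"]
        assert models["recall_narrative"].coef("group[T.TBI]")["estimate"] < 0
        assert models["score_narrative"].coef("group[T.TBI]")["estimate"] < 0
        assert models["score_narrative"].coef("timepoint[T.Long Delay]")["estimate"] < 0
        assert models["score_wordlist"].coef("timepoint[T.Trial 1]")["estimate"] < 0
        zib = models["zib_narrative"]
        assert zib.coef("abs_lag", "zero")["estimate"] > 0
        assert zib.coef("direction", "zero")["estimate"] < 0

    def test_chance_tests_present_per_group_and_timepoint(self, small_bundle):
        chance = small_bundle["fits"].query("model == 'chance_t'")
        narrative = chance[chance["task"] == "narrative"]
        assert set(narrative.loc[narrative["part"] == "group", "term"]) == {"NC", "TBI"}
        assert len(narrative[narrative["part"] == "timepoint"]) == 3

    def test_missing_group_is_named(self):
        ds = simulate_cohort(SimulationConfig(n_per_group=4, seed=1))
        recalls = ds.recalls[ds.recalls["group"] != "TBI"]
        with pytest.raises(ValueError, match="TBI"):
            run_full_analysis((recalls, ds.manifest), RunConfig(bootstrap_B=0))

    def test_rerun_same_seed_identical_tables(self):
        ds = simulate_cohort(SimulationConfig(n_per_group=8, seed=5))
        cfg = RunConfig(bootstrap_B=25, seed=5)
        a = run_full_analysis(ds, cfg)
        b = run_full_analysis(ds, cfg)
        pd.testing.assert_frame_equal(a["fits"], b["fits"])
        pd.testing.assert_frame_equal(a["scores"], b["scores"])
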