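import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from netecol.fitness import FitnessSurface, TieFitnessModel
from netecol.outcomes import (
    OutcomeModel,
    build_outcome_table,
    fit_outcome_model,
    marginal_effect_curve,
)
from netecol.panel import Panel, WaveNetwork


def _surface_for(panel, wave, rng):
    """Arbitrary distinct-fitness surface over all ordered dyads."""
    n = panel.n
    rows = []
    p = rng.permutation(n * (n - 1)) / (n * (n - 1) - 1)
    k = 0
    for ego in panel.roster:
        for alter in panel.roster:
            if ego == alter:
                continue
            rows.append((ego, alter, p[k], p[k]))
            k += 1
    return FitnessSurface(
        table=pd.DataFrame(rows, columns=["ego", "alter", "p", "f"]),
        n=n, wave_label=wave,
    )


@pytest.fixture
def four_wave_panel():
    """Four students, four waves; dyad a->b reported at T1 and T2 only;
    student d drops out after T2."""
    roster = list("abcd")
    attributes = pd.DataFrame(
        {"sex": [0, 1, 0, 1], "ethnicity_majority": 1, "ses_high": 0},
        index=roster,
    )
    participation = pd.DataFrame(
        {"T1": True, "T2": True, "T3": [True, True, True, False],
         "T4": [True, True, True, False]},
        index=roster,
    )
    waves = [
        WaveNetwork("T1", {("a", "b"): (1, 3), ("c", "d"): (0, 1)}),
        WaveNetwork("T2", {("a", "b"): (0, 2), ("d", "a"): (0, 1)}),
        WaveNetwork("T3", {("b", "a"): (0, 1)}),
        WaveNetwork("T4", {}),
    ]
    return Panel("p4", roster, attributes, waves, participation)


def test_hand_traced_records(four_wave_panel):
    rng = np.random.default_rng(0)
    surfaces = {w: _surface_for(four_wave_panel, w, rng) for w in ("T1", "T2", "T3")}
    table = build_outcome_table(four_wave_panel, surfaces)

    rec = table[(table.wave == "T1") & (table.ego == "a") & (table.alter == "b")].iloc[0]
    assert rec.is_reported == 1
    assert rec.survival == 1  # reported again at T2
    assert rec.longevity == 1  # T2 only among future waves
    assert rec.times_past == 0
    assert rec.is_best_friend == 1 and rec.meet_freq == 3

    rec2 = table[(table.wave == "T2") & (table.ego == "a") & (table.alter == "b")].iloc[0]
    assert rec2.times_past == 1
    assert rec2.survival == 0 and rec2.longevity == 0

    # never-reported dyad that forms next wave
    form = table[(table.wave == "T2") & (table.ego == "b") & (table.alter == "a")].iloc[0]
    assert form.is_reported == 0 and form.will_form == 1

    # ego d absent at T3: no T2 records for ego d
    assert table[(table.wave == "T2") & (table.ego == "d")].empty
    # but d's records exist at T1 (participated at T1 and T2)
    assert not table[(table.wave == "T1") & (table.ego == "d")].empty


def test_will_form_and_survival_are_mutually_exclusive(four_wave_panel):
    rng = np.random.default_rng(1)
    surfaces = {w: _surface_for(four_wave_panel, w, rng) for w in ("T1", "T2", "T3")}
    table = build_outcome_table(four_wave_panel, surfaces)
    assert table.loc[table.is_reported == 1, "will_form"].isna().all()
    assert table.loc[table.is_reported == 0, "survival"].isna().all()
    assert table.loc[table.is_reported == 0, "longevity"].isna().all()


def test_longevity_equals_future_survival_chain(small_cohort):
    """Longevity at t recounts the dyad's reported appearances at t+1..T."""
    panel, _, _ = small_cohort
    rng = np.random.default_rng(2)
    labels = panel.wave_labels
    surfaces = {w: _surface_for(panel, w, rng) for w in labels[:-1]}
    table = build_outcome_table(panel, surfaces)
    reported = table[table.is_reported == 1]
    sample = reported.sample(200, random_state=0) if len(reported) > 200 else reported
    for _, rec in sample.iterrows():
        t = labels.index(rec.wave)
        future = sum(
            (rec.ego, rec.alter) in panel.wave(w).edge_set()
            for w in labels[t + 1:]
        )
        assert rec.longevity == future


def test_fitness_driven_formation_recovers_positive_sign(small_cohort):
    """On a synthetic cohort (where tie probabilities are generated by the
    fitted logit family) the will-form model shows a positive, significant
    fitness coefficient."""
    panel, _, _ = small_cohort
    surfaces = {
        w: TieFitnessModel.from_panel(panel, w).fit().fitness()
        for w in panel.wave_labels[:-1]
    }
    table = build_outcome_table(panel, surfaces)
    res = fit_outcome_model(table, "will_form")
    assert res.fitness_coef > 0
    assert res.fitness_coef / res.bse["f"] > 2


def test_singleton_clusters_match_heteroskedastic_robust_ses(four_wave_panel):
    """With each dyad appearing exactly once, clustered sandwich errors
    equal HC0 heteroskedasticity-robust errors."""
    rng = np.random.default_rng(3)
    surfaces = {w: _surface_for(four_wave_panel, w, rng) for w in ("T1", "T2", "T3")}
    table = build_outcome_table(four_wave_panel, surfaces)
    table = table.drop_duplicates(subset="dyad", keep="first").copy()
    model = OutcomeModel(table, "is_reported")
    clustered = model.fit(use_correction=False)
    hc0 = model.fit(cov_type="HC0")
    assert np.allclose(clustered.bse, hc0.bse, rtol=1e-8)


def test_glm_coefficients_match_independent_newton_solve(small_cohort):
    """Logit coefficients agree with a direct optimizer on the same
    likelihood (independent of the IRLS path)."""
    panel, _, _ = small_cohort
    rng = np.random.default_rng(4)
    surfaces = {w: _surface_for(panel, w, rng) for w in panel.wave_labels[:-1]}
    table = build_outcome_table(panel, surfaces).sample(400, random_state=1)
    model = OutcomeModel(table, "is_reported")
    res = model.fit()
    X = model.X.to_numpy(dtype=float)
    y = model.y.to_numpy(dtype=float)

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    opt = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                   options={"maxiter": 5000, "gtol": 1e-10})
    assert np.allclose(res.params.to_numpy(), opt.x, atol=1e-4)


def test_marginal_effect_closed_form_plug_in():
    """Logit formation-scale coefficients: beta_f = 10.372, alpha = -11.387
    give p = logistic(-1.015) at f = 1 with all other terms zero."""
    table = pd.DataFrame({
        "setting": "s", "wave": "T1",
        "ego": "a", "alter": "b",
        "dyad": [f"d{i}" for i in range(40)],
        "f": np.linspace(0, 1, 40),
        "is_reported": [0, 1] * 20,
        "will_form": np.nan, "survival": np.nan, "longevity": np.nan,
        "times_past": 0.0, "is_best_friend": 0.0, "meet_freq": 1,
    })
    res = fit_outcome_model(table, "is_reported")
    res.sm_results.params[:] = 0.0
    res.sm_results.params["const"] = -11.387
    res.sm_results.params["f"] = 10.372
    curve = marginal_effect_curve(res, grid=np.array([0.0, 1.0]))
    assert curve.predicted.iloc[1] == pytest.approx(expit(-1.015), abs=1e-9)
    assert curve.predicted.iloc[0] == pytest.approx(expit(-11.387), abs=1e-9)


def test_marginal_effect_monotonicity_and_flat_curve(small_cohort):
    panel, _, _ = small_cohort
    surfaces = {
        w: TieFitnessModel.from_panel(panel, w).fit().fitness()
        for w in panel.wave_labels[:-1]
    }
    table = build_outcome_table(panel, surfaces)
    res = fit_outcome_model(table, "is_reported")
    curve = res.marginal_effect_curve()
    assert res.fitness_coef > 0
    assert (np.diff(curve.predicted) > 0).all()  # strictly increasing
    res.sm_results.params["f"] = 0.0
    flat = res.marginal_effect_curve()
    assert flat.predicted.nunique() == 1


def test_unknown_or_degenerate_outcomes_raise(four_wave_panel):
    rng = np.random.default_rng(5)
    surfaces = {w: _surface_for(four_wave_panel, w, rng) for w in ("T1", "T2", "T3")}
    table = build_outcome_table(four_wave_panel, surfaces)
    with pytest.raises(ValueError, match="unknown outcome"):
        fit_outcome_model(table, "popularity")
    table["survival"] = np.where(table.is_reported == 1, 1.0, np.nan)
    with pytest.raises(ValueError, match="degenerate"):
        fit_outcome_model(table, "survival")


def test_missing_surface_raises(four_wave_panel):
    rng = np.random.default_rng(6)
    surfaces = {w: _surface_for(four_wave_panel, w, rng) for w in ("T1",)}
    with pytest.raises(ValueError, match="missing fitness surfaces"):
        build_outcome_table(four_wave_panel, surfaces)
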