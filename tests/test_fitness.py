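import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from netecol.design import COVARIATES, DyadDesign
from netecol.fitness import (
    SeparationError,
    TieFitnessModel,
    calibrate_threshold,
    fit,
    percentile_rank,
    retrieval_curve,
)


def _design_from_arrays(X: np.ndarray, y: np.ndarray) -> DyadDesign:
    """Wrap raw arrays as a standardized design (covariates taken as-is)."""
    n_dyads = len(y)
    table = pd.DataFrame(X, columns=list(COVARIATES))
    table["x1_raw"] = table["x1"]
    table["x2_raw"] = table["x2"]
    table["y"] = y
    table["ego"] = [f"e{i}" for i in range(n_dyads)]
    table["alter"] = [f"a{i}" for i in range(n_dyads)]
    return DyadDesign(table=table, n=n_dyads, wave_label="T1")


def test_intercept_only_limit_recovers_logit_of_density():
    rng = np.random.default_rng(0)
    d = 0.2
    y = (rng.random(4000) < d).astype(float)
    design = _design_from_arrays(np.zeros((4000, 6)), y)
    res = fit(design)
    assert res.constant == pytest.approx(logit(y.mean()), abs=1e-6)
    assert res.beta_R.abs().max() < 1e-8


def test_loglik_matches_independent_optimizer_on_tiny_design():
    """The GLM solution matches a direct Nelder-Mead solve of the same
    likelihood on a 4-node-scale design."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 6))
    eta = 0.5 * X[:, 0] - 0.8 * X[:, 3]
    y = (rng.random(30) < expit(eta)).astype(float)
    design = _design_from_arrays(X, y)
    res = fit(design)

    Xc = np.column_stack([np.ones(len(y)), X])

    def nll(b):
        p = expit(Xc @ b)
        return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

    opt = minimize(nll, np.zeros(7), method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
    assert res.llf == pytest.approx(-opt.fun, abs=1e-5)


def test_predict_closed_form_single_dyad():
    """All covariates zero with a typical empirical constant: p is the
    plain logistic of the constant."""
    res = fit(_design_from_arrays(
        np.zeros((400, 6)),
        (np.random.default_rng(2).random(400) < 0.3).astype(float),
    ))
    res.params[:] = 0.0
    res.params["const"] = -7.234
    design = _design_from_arrays(np.zeros((3, 6)), np.array([0.0, 1.0, 0.0]))
    p = res.predict(design)
    assert p == pytest.approx(1.0 / (1.0 + np.exp(7.234)))


def test_predict_agrees_with_elementwise_formula(small_fit):
    panel, res, surface = small_fit
    design = res.model.design
    X = design.matrix()
    eta = res.constant + X @ res.params[list(COVARIATES)].to_numpy()
    assert np.allclose(res.predict(design), expit(eta), atol=1e-12)


def test_errors_on_degenerate_outcomes():
    with pytest.raises(ValueError, match="all outcomes are 0"):
        TieFitnessModel(_design_from_arrays(np.zeros((10, 6)), np.zeros(10)))
    with pytest.raises(ValueError, match="all outcomes are 1"):
        TieFitnessModel(_design_from_arrays(np.zeros((10, 6)), np.ones(10)))


def test_perfect_separation_names_covariate():
    X = np.zeros((40, 6))
    X[:, 5] = np.repeat([0.0, 1.0], 20)
    y = X[:, 5].copy()
    with pytest.raises(SeparationError, match="x3"):
        fit(_design_from_arrays(X, y))


def test_random_effects_fit_keeps_effects_centered(small_cohort):
    panel, _, _ = small_cohort
    res = TieFitnessModel.from_panel(panel, "T2", random_effects=True).fit()
    assert abs(res.sender_effects.mean()) < 1e-8
    assert abs(res.receiver_effects.mean()) < 1e-8
    assert np.isfinite(res.params).all()


# ---------------------------------------------------------------------------
# percentile ranks
# ---------------------------------------------------------------------------

def test_percentile_rank_examples():
    assert np.allclose(percentile_rank([0.1, 0.2, 0.3]), [0.0, 0.5, 1.0])
    assert np.allclose(percentile_rank([0.1, 0.1, 0.3]), [0.25, 0.25, 1.0])


def test_percentile_rank_all_ties_warns_and_returns_half(caplog):
    with caplog.at_level("WARNING"):
        f = percentile_rank([0.2, 0.2, 0.2])
    assert np.allclose(f, 0.5)
    assert "identical" in caplog.text


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.001, 0.999), min_size=2, max_size=40, unique=True))
def test_percentile_rank_properties(p):
    p = np.asarray(p)
    f = percentile_rank(p)
    assert f.min() == 0.0 and f.max() == 1.0
    assert np.array_equal(np.argsort(p), np.argsort(f))
    # invariant to strictly monotone transforms of p
    assert np.allclose(f, percentile_rank(np.log(p / (1 - p))))
    # uniform on {0, 1/(N-1), ..., 1} absent ties: exact mean 0.5
    assert f.mean() == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# retrieval and threshold calibration
# ---------------------------------------------------------------------------

def test_retrieval_curve_direct_counts(small_fit):
    panel, res, surface = small_fit
    reported = panel.wave("T2").edge_set()
    curve = retrieval_curve(surface, reported)
    assert curve(0.0) == 1.0
    vals = surface.reported_fitness(reported)
    for x in (0.3, 0.7, 0.95):
        assert curve(x) == pytest.approx((vals >= x).mean())
    grid = np.linspace(0, 1, 50)
    out = curve(grid)
    assert (np.diff(out) <= 0).all()


def test_retrieval_curve_stepwise_example(small_fit):
    panel, res, surface = small_fit
    sub = surface.table.iloc[:2].copy()
    sub_surface = type(surface)(table=surface.table, n=surface.n)
    reported = {(sub.iloc[0].ego, sub.iloc[0].alter),
                (sub.iloc[1].ego, sub.iloc[1].alter)}
    f = surface.reported_fitness(reported)
    curve = retrieval_curve(surface, reported)
    mid = (f.min() + f.max()) / 2
    assert curve(mid) == pytest.approx(0.5)


def test_calibrate_threshold_exhaustive_scan_example():
    vals = np.arange(0.50, 0.951, 0.05)  # 10 ties: 0.50, 0.55, ..., 0.95
    calib = calibrate_threshold([vals], retrieval_target=0.9)
    assert calib.threshold == pytest.approx(0.55)
    assert calib.achieved_retrieval == pytest.approx(0.9)


def test_calibrate_threshold_full_retrieval_returns_min():
    vals = np.array([0.3, 0.8, 0.6])
    calib = calibrate_threshold([vals], retrieval_target=1.0)
    assert calib.threshold == pytest.approx(0.3)
    assert calib.achieved_retrieval == 1.0


def test_calibrate_threshold_input_validation():
    with pytest.raises(ValueError, match="retrieval_target"):
        calibrate_threshold([np.array([0.5])], retrieval_target=1.5)
    with pytest.raises(ValueError, match="no reported ties"):
        calibrate_threshold([np.array([])])


def test_calibration_guarantee_on_random_instances():
    """achieved - target lies in [0, 1/n_reported) for distinct fitness."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n_nets = rng.integers(1, 6)
        arrays = [rng.random(rng.integers(5, 80)) for _ in range(n_nets)]
        target = rng.uniform(0.05, 0.99)
        calib = calibrate_threshold(arrays, target)
        slack = calib.achieved_retrieval - target
        assert 0.0 <= slack < 1.0 / calib.n_reported
        assert calib.per_network_retrieval[0] <= calib.achieved_retrieval \
            <= calib.per_network_retrieval[1] + 1e-12
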