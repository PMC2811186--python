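"""Least-squares fitters, AICc competition and the bootstrap."""

import math

import numpy as np
import pytest

from ecothresh import (
    ModelFit,
    ResponseCurve,
    aicc,
    bootstrap_fit,
    fit_model,
    make_model,
    select_model,
)
from ecothresh.fitting import FitOptions
from ecothresh.forms import PARAM_COUNT


def _noise_free(model, P):
    return ResponseCurve(np.asarray(P, dtype=float), model.evaluate(np.asarray(P, dtype=float)))


# ---------------------------------------------------------------- AICc
def test_aicc_closed_form():
    expected = 15 * math.log(1 / 15) + 6 + 24 / 11
    assert aicc(1.0, 15, 3) == pytest.approx(expected, rel=1e-12)


def test_aicc_prefers_fewer_parameters_at_equal_rss():
    assert aicc(0.5, 15, 3) < aicc(0.5, 15, 5)


def test_aicc_approaches_aic_for_large_n():
    k, rss = 4, 2.0
    n = 10**6
    aic = n * math.log(rss / n) + 2 * k
    assert aicc(rss, n, k) - aic == pytest.approx(0.0, abs=1e-3)


def test_aicc_domain_errors():
    with pytest.raises(ValueError, match="n="):
        aicc(1.0, 5, 4)
    with pytest.raises(ValueError, match="positive"):
        aicc(0.0, 15, 3)


# ---------------------------------------------------------------- fitters
def test_piecewise_noise_free_recovery(fishing_pressures, shannon_fishing_model):
    fit = fit_model(_noise_free(shannon_fishing_model, fishing_pressures), "piecewise")
    p, truth = fit.model.params, shannon_fishing_model.params
    assert fit.converged
    for name in ("Pt", "b1", "m1", "m2"):
        assert getattr(p, name) == pytest.approx(getattr(truth, name), abs=1e-6)
    assert fit.rss < 1e-12
    assert not fit.diagnostics["degenerate_breakpoint"]


def test_piecewise_on_linear_data_flags_degenerate_breakpoint(fishing_pressures):
    lin = make_model("linear", 1.48, -2.95)
    fit = fit_model(_noise_free(lin, fishing_pressures), "piecewise")
    p = fit.model.params
    assert p.m1 == pytest.approx(p.m2, abs=1e-5)
    assert fit.diagnostics["degenerate_breakpoint"]


def test_sigmoid_noise_free_recovers_reported_inflection(resilience_habitat_model):
    P = np.linspace(0.0, 1.0, 14)
    fit = fit_model(_noise_free(resilience_habitat_model, P), "sigmoidal")
    assert fit.converged
    assert fit.model.threshold() == pytest.approx(0.41, abs=5e-3)


def test_negexp_noise_free_recovery(fishing_pressures, sablefish_fishing_model):
    fit = fit_model(_noise_free(sablefish_fishing_model, fishing_pressures), "negexp")
    p, truth = fit.model.params, sablefish_fishing_model.params
    for name in ("a0", "a1", "a2"):
        assert getattr(p, name) == pytest.approx(getattr(truth, name), abs=1e-5)


def test_fit_model_needs_enough_observations():
    c = ResponseCurve(np.linspace(0, 1, 5), np.zeros(5))
    with pytest.raises(ValueError, match="k\\+2"):
        fit_model(c, "piecewise")


def test_breakpoint_fitter_matches_exhaustive_grid(rng_instances=20):
    """The profiled breakpoint fit must match a dense exhaustive
    conditional-least-squares grid search (the brute-force oracle)."""
    rng = np.random.default_rng(7)
    for _ in range(rng_instances):
        n = int(rng.integers(10, 18))
        P = np.sort(rng.random(n))
        truth = make_model(
            "piecewise",
            float(rng.uniform(0.25, 0.75)),
            float(rng.normal(1.0, 0.5)),
            float(rng.normal(-5.0, 1.0)),
            float(rng.normal(-1.0, 0.5)),
        )
        y = truth.evaluate(P) + rng.normal(0, 0.05, n)
        fit = fit_model(ResponseCurve(P, y), "piecewise")
        u = np.unique(P)
        g = 32001
        grid = np.linspace(u[1], u[-2], g)
        F = np.stack(
            [
                np.ones((g, n)),
                np.minimum(P[None, :], grid[:, None]),
                np.clip(P[None, :] - grid[:, None], 0.0, None),
            ],
            axis=-1,
        )
        A = np.einsum("gni,gnj->gij", F, F)
        b = np.einsum("gni,n->gi", F, y)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        resid = y[None, :] - np.einsum("gni,gi->gn", F, beta)
        best = float(np.min(np.einsum("gn,gn->g", resid, resid)))
        assert abs(best - fit.rss) < 1e-6


# ---------------------------------------------------------------- selection
def _fake_fit(form, rss, n=15):
    k = PARAM_COUNT[form]
    return ModelFit(None, rss, n, k, n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1), True)


def test_select_model_majority_and_exclusions():
    good = {"linear": _fake_fit("linear", 2.0), "piecewise": _fake_fit("piecewise", 0.5)}
    flipped = {"linear": _fake_fit("linear", 0.5), "piecewise": _fake_fit("piecewise", 2.0)}
    failed = {
        "linear": ModelFit(None, math.inf, 15, 3, math.inf, False),
        "piecewise": ModelFit(None, math.inf, 15, 5, math.inf, False),
    }
    sel = select_model([good, good, flipped, failed])
    assert sel.winner == "piecewise"
    assert sel.tally == {"piecewise": 2, "linear": 1}
    assert sel.excluded == [3]
    assert sel.n_datasets == 3
    assert sel.tally_string() == "Piecewise (2/3)"


def test_select_model_tie_breaks_by_parameter_count_then_form_order():
    # identical AICc: fewest parameters wins (linear k=3 beats negexp k=4)
    a = _fake_fit("linear", 1.0)
    b = _fake_fit("negexp", 1.0)
    b.aicc = a.aicc
    sel = select_model([{"linear": a, "negexp": b}])
    assert sel.winner == "linear"
    assert sel.tie_breaks == 1


# ---------------------------------------------------------------- bootstrap
def test_bootstrap_noiseless_data_gives_degenerate_intervals(
    fishing_pressures, shannon_fishing_model
):
    curve = _noise_free(shannon_fishing_model, fishing_pressures)
    boot = bootstrap_fit(curve, "piecewise", reps=200, seed=0)
    lo, hi = boot.ci95["Pt"]
    assert hi - lo < 0.02  # limited only by the profile grid resolution
    assert np.median(boot.param_draws["Pt"]) == pytest.approx(0.33, abs=0.01)
    assert boot.significant["m1"]


def test_bootstrap_flags_insignificant_slope(fishing_pressures):
    rng = np.random.default_rng(5)
    flat = ResponseCurve(fishing_pressures, rng.normal(0.0, 0.3, fishing_pressures.size))
    boot = bootstrap_fit(flat, "linear", reps=300, seed=2)
    lo, hi = boot.ci95["m0"]
    assert lo <= 0.0 <= hi
    assert not boot.significant["m0"]


def test_bootstrap_reproducible_and_methods_differ(fishing_pressures, shannon_fishing_model):
    rng = np.random.default_rng(1)
    y = shannon_fishing_model.evaluate(fishing_pressures) + rng.normal(0, 0.05, 15)
    curve = ResponseCurve(fishing_pressures, y)
    b1 = bootstrap_fit(curve, "piecewise", reps=150, seed=42)
    b2 = bootstrap_fit(curve, "piecewise", reps=150, seed=42)
    np.testing.assert_array_equal(b1.param_draws["Pt"], b2.param_draws["Pt"])
    b3 = bootstrap_fit(curve, "piecewise", reps=150, seed=43)
    assert not np.array_equal(b1.param_draws["Pt"], b3.param_draws["Pt"])
    br = bootstrap_fit(curve, "piecewise", reps=150, seed=42, method="residual")
    assert np.median(br.param_draws["Pt"]) == pytest.approx(0.33, abs=0.05)


def test_bootstrap_requires_enough_reps(fishing_pressures, shannon_fishing_model):
    curve = _noise_free(shannon_fishing_model, fishing_pressures)
    with pytest.raises(ValueError, match="100"):
        bootstrap_fit(curve, "piecewise", reps=50)
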