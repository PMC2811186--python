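"""Response-form evaluation, derivatives and threshold definitions."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecothresh import ResponseModel, make_model
from ecothresh.forms import AmbiguousDerivative, FormParamsMismatch, PiecewiseParams

finite = st.floats(-10, 10, allow_nan=False)


@pytest.mark.parametrize(
    "form,params,P,expected,tol",
    [
        # broken-stick: intercept at zero, kink value by direct arithmetic
        ("piecewise", (0.33, 1.37, -5.58, -1.22), 0.0, 1.37, 1e-12),
        ("piecewise", (0.33, 1.37, -5.58, -1.22), 0.33, 1.37 - 5.58 * 0.33, 1e-12),
        # published sablefish decay curve, value near its reported 0.155 t/km2
        ("negexp", (-0.03, 0.52, -3.15), 0.33, 0.155, 2e-3),
        # sigmoid at zero pressure approaches c0
        ("sigmoidal", (1.34, 0.007, 0.004, 13.39), 0.0, 1.3347, 1e-4),
        ("linear", (1.48, -2.95), 0.5, 1.48 - 2.95 * 0.5, 1e-12),
        ("parabolic", (1.0, -2.0, 3.0), 0.5, 1.0 - 1.0 + 0.75, 1e-12),
    ],
)
def test_evaluate_known_values(form, params, P, expected, tol):
    assert make_model(form, *params).evaluate(P) == pytest.approx(expected, abs=tol)


def test_evaluate_is_vectorized():
    m = make_model("linear", 1.0, -2.0)
    np.testing.assert_allclose(m.evaluate([0.0, 0.5, 1.0]), [1.0, 0.0, -1.0])


@pytest.mark.parametrize(
    "form,params",
    [
        ("linear", (1.48, -2.95)),
        ("piecewise", (0.4, 1.2, -4.0, -0.5)),
        ("sigmoidal", (1.34, 0.007, 0.004, 13.39)),
        ("negexp", (-0.03, 0.52, -3.15)),
        ("parabolic", (1.0, -2.0, 3.0)),
    ],
)
def test_first_derivative_matches_finite_differences(form, params):
    m = make_model(form, *params)
    h = 1e-6
    for P in (0.05, 0.2, 0.61, 0.9):
        numeric = (m.evaluate(P + h) - m.evaluate(P - h)) / (2 * h)
        assert m.first_derivative(P) == pytest.approx(numeric, rel=1e-5, abs=1e-7)


def test_piecewise_slopes_and_breakpoint_ambiguity():
    m = make_model("piecewise", 0.33, 1.37, -5.58, -1.22)
    assert m.first_derivative(0.1) == -5.58
    assert m.first_derivative(0.5) == -1.22
    with pytest.raises(AmbiguousDerivative, match="breakpoint"):
        m.first_derivative(0.33)
    assert m.first_derivative(0.33, side="left") == -5.58
    assert m.first_derivative(0.33, side="right") == -1.22


def test_sigmoid_derivative_at_inflection_closed_form(resilience_habitat_model):
    m = resilience_habitat_model
    p = m.params
    expected = -(p.c0 - p.c1) * p.c3 / 4.0
    assert m.first_derivative(m.threshold()) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "c2,c3,expected",
    [(0.004, 13.39, 0.41), (0.081, 7.80, 0.32)],
)
def test_sigmoid_inflection_reproduces_reported_thresholds(c2, c3, expected):
    """ln(1/c2)/c3 on the two habitat-pressure sigmoid fits lands on the
    reported thresholds to two decimals — validates the adopted form."""
    m = make_model("sigmoidal", 1.5, 0.1, c2, c3)
    assert round(m.threshold(), 2) == expected


def test_forms_without_objective_threshold_return_none():
    assert make_model("linear", 1.0, -1.0).threshold() is None
    assert make_model("negexp", 0.0, 1.0, -2.0).threshold() is None
    assert make_model("parabolic", 1.0, -1.0, 1.0).threshold() is None


def test_sigmoid_requires_positive_shape_coefficients():
    with pytest.raises(ValueError, match="c2 > 0"):
        make_model("sigmoidal", 1.0, 0.0, -0.1, 5.0)
    with pytest.raises(ValueError, match="c2 > 0"):
        make_model("sigmoidal", 1.0, 0.0, 0.5, 0.0)


def test_form_params_mismatch_raises():
    with pytest.raises(FormParamsMismatch):
        ResponseModel(form="linear", params=PiecewiseParams(0.3, 1.0, -2.0, -1.0))
    with pytest.raises(FormParamsMismatch):
        make_model("spline", 1.0)


@given(Pt=st.floats(0.05, 0.95), b1=finite, m1=finite, m2=finite)
def test_piecewise_continuous_at_breakpoint(Pt, b1, m1, m2):
    m = make_model("piecewise", Pt, b1, m1, m2)
    eps = 1e-9
    left = m.evaluate(Pt - eps)
    right = m.evaluate(Pt + eps)
    assert abs(left - right) < 1e-6 * (1 + abs(left))
    # exactly at Pt the right-segment value applies and both agree
    assert m.evaluate(Pt) == pytest.approx(b1 + m1 * Pt, abs=1e-12)


@given(
    c0=st.floats(0.5, 3.0),
    c1=st.floats(-0.5, 0.4),
    c2=st.floats(0.001, 0.5),
    c3=st.floats(2.0, 30.0),
)
def test_sigmoid_second_derivative_changes_sign_at_inflection(c0, c1, c2, c3):
    m = make_model("sigmoidal", c0, c1, c2, c3)
    x0 = m.threshold()
    grid = np.linspace(x0 - 0.5, x0 + 0.5, 501)
    d2 = np.asarray(m.second_derivative(grid))
    signs = np.sign(d2[np.abs(grid - x0) > 1e-3])
    # concave-down before, concave-up after (c0 > c1 here)
    before = np.sign(d2[grid < x0 - 1e-3])
    after = np.sign(d2[grid > x0 + 1e-3])
    assert np.all(before == before[0])
    assert np.all(after == after[0])
    assert before[0] == -after[0]
    assert abs(m.second_derivative(x0)) < 1e-6 * max(1.0, np.max(np.abs(d2)))


@given(Pt=st.floats(0.1, 0.9), b1=finite, m1=finite, m2=finite)
def test_piecewise_monotone_on_each_segment(Pt, b1, m1, m2):
    m = make_model("piecewise", Pt, b1, m1, m2)
    left = np.linspace(0, Pt - 1e-6, 50)
    right = np.linspace(Pt + 1e-6, 1, 50)
    for seg, slope in ((left, m1), (right, m2)):
        d = np.diff(m.evaluate(seg))
        if slope > 0:
            assert np.all(d >= -1e-12)
        elif slope < 0:
            assert np.all(d <= 1e-12)


def test_json_round_trip():
    models = [
        make_model("piecewise", 0.33, 1.37, -5.58, -1.22),
        make_model("sigmoidal", 1.34, 0.007, 0.004, 13.39),
        make_model("linear", 1.48, -2.95),
    ]
    for m in models:
        blob = json.dumps(m.to_dict())
        back = ResponseModel.from_dict(json.loads(blob))
        assert back == m
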