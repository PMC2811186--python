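"""Synthetic food-web simulator and parametric curve generator."""

import copy

import numpy as np
import pytest

from ecothresh import generate_parametric, make_model, resilience_index
from ecothresh.attributes import compute_attributes
from ecothresh.synthetic import (
    GradientDesign,
    default_foodweb,
    simulate_gradient,
)

ATTRS = ("resilience", "npp_over_biomass", "shannon", "mean_trophic_level")


# ------------------------------------------------------------ parametric
def test_generate_parametric_zero_noise_is_exact(fishing_pressures, shannon_fishing_model):
    (c,) = generate_parametric(shannon_fishing_model, fishing_pressures, 0.0, seed=0)
    np.testing.assert_array_equal(c.values, shannon_fishing_model.evaluate(fishing_pressures))


def test_generate_parametric_seeding(fishing_pressures, shannon_fishing_model):
    a = generate_parametric(shannon_fishing_model, fishing_pressures, 0.05, 3, seed=1)
    b = generate_parametric(shannon_fishing_model, fishing_pressures, 0.05, 3, seed=1)
    c = generate_parametric(shannon_fishing_model, fishing_pressures, 0.05, 3, seed=2)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.values, y.values)
    assert not np.array_equal(a[0].values, c[0].values)
    # replicates within one call differ
    assert not np.array_equal(a[0].values, a[1].values)


def test_generate_parametric_rejects_negative_noise(fishing_pressures, shannon_fishing_model):
    with pytest.raises(ValueError):
        generate_parametric(shannon_fishing_model, fishing_pressures, -0.1)


# ------------------------------------------------------------ food web
def test_default_web_has_positive_stable_baseline(default_spec):
    default_spec.validate()  # raises on failure


def test_design_validation():
    with pytest.raises(ValueError, match="sorted"):
        GradientDesign("fishing", (1.0, 0.5))
    with pytest.raises(ValueError, match="pressure_type"):
        GradientDesign("pollution")


def test_no_pressure_change_gives_identical_snapshots_and_zero_resilience(default_spec):
    res = simulate_gradient(default_spec, GradientDesign("fishing", (1.0, 1.0, 1.0)))
    b0 = res.snapshots[0].biomass
    for snap in res.snapshots[1:]:
        for g, v in snap.biomass.items():
            assert v == pytest.approx(b0[g], rel=1e-6)
        assert resilience_index(res.baseline, snap) == pytest.approx(0.0, abs=1e-4)


def test_fishing_gradient_attributes_decline_monotonically(default_spec, fishing_gradient):
    """The shipped web reproduces the qualitative case-study behaviour:
    all four attributes decline as fishing pressure rises."""
    res = fishing_gradient
    assert all(res.equilibrated)
    attrs = [compute_attributes(res.reference, s, default_spec.groups) for s in res.snapshots]
    for name in ATTRS:
        vals = np.array([getattr(a, name) for a in attrs])
        assert np.all(np.diff(vals) <= 1e-9), f"{name} not non-increasing"
    # yields rise with fishing and the indicator declines
    landings = np.array([getattr(a, "total_landings") for a in attrs])
    assert np.all(np.diff(landings) >= -1e-9)
    sable = np.array([s.biomass["sablefish"] for s in res.snapshots])
    assert np.all(np.diff(sable) <= 1e-9)


def test_equilibrium_consistency_without_pressure(default_spec, fishing_gradient):
    """Starting at the balanced baseline and integrating with baseline
    forcing, total biomass drifts by far less than 1%: the balance routine
    really produced an equilibrium (simulator sanity)."""
    base = fishing_gradient.baseline.biomass
    target = default_spec.initial_biomass
    total0 = sum(target.values())
    total1 = sum(base.values())
    assert abs(total1 - total0) / total0 < 0.01


def test_mediation_amplifies_prey_decline_under_habitat_loss(default_spec):
    nomed = copy.deepcopy(default_spec)
    nomed.mediation = {}
    design = GradientDesign("habitat", (0.0, 1.0))
    with_med = simulate_gradient(default_spec, design)
    without = simulate_gradient(nomed, design)

    def decline(res, group):
        return res.snapshots[0].biomass[group] / res.snapshots[1].biomass[group]

    # strongly mediated juveniles crash much harder when mediation is on
    assert decline(with_med, "juvenile_fish") < decline(without, "juvenile_fish")
    assert decline(with_med, "benthic_inverts") < decline(without, "benthic_inverts")


def test_habitat_pressure_axis_is_inverted(default_spec):
    res = simulate_gradient(default_spec, GradientDesign("habitat", (0.0, 0.5, 1.0, 1.3)))
    P = res.pressures()
    assert P[0] == 1.0 and P[-1] == 0.0  # zero production = maximal pressure
    # reference state is the least-stressed (highest production) end
    assert res.reference is res.snapshots[-1]


def test_parameter_views_and_perturbation_plumbing(default_spec):
    params = default_spec.parameters()
    assert "benthic_inverts.m" in params and "detritus_export" in params
    spec2 = default_spec.with_parameters({"benthic_inverts.m": params["benthic_inverts.m"] * 1.1})
    assert spec2.consumers["benthic_inverts"].m == pytest.approx(
        default_spec.consumers["benthic_inverts"].m * 1.1
    )
    # original untouched
    assert default_spec.parameters() == params
    with pytest.raises(KeyError):
        default_spec.with_parameters({"nope.m": 1.0})


def test_biomass_table_export(default_spec, fishing_gradient):
    df = fishing_gradient.to_biomass_table()
    assert set(df.columns) == {"pressure_level", "replicate", "group", "biomass", "landings"}
    assert df["pressure_level"].nunique() == 15
    assert (df["biomass"] >= 0).all()
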