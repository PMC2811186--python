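"""Ecosystem attribute calculators and scaling conventions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecothresh import (
    BiomassSnapshot,
    FunctionalGroup,
    mean_trophic_level,
    npp_biomass_ratio,
    rescale_pressure,
    resilience_index,
    shannon_diversity,
    standardize_attributes,
    standardize_series,
    yield_metrics,
)

GROUPS = {
    "a": FunctionalGroup("a", 2.0, price_per_tonne=10.0, fished=True),
    "b": FunctionalGroup("b", 4.0, price_per_tonne=5.0, fished=True),
    "det": FunctionalGroup("det", 1.0, is_detritus=True),
}


def snap(biomass, npp=0.0, landings=None):
    return BiomassSnapshot(biomass=biomass, npp=npp, landings=landings or {})


# ---------------------------------------------------------------- resilience
def test_resilience_zero_under_proportional_change():
    before = snap({"a": 1.0, "b": 3.0, "det": 2.0})
    after = snap({"a": 2.5, "b": 7.5, "det": 5.0})
    assert resilience_index(before, after) == pytest.approx(0.0, abs=1e-12)


def test_resilience_identical_snapshots_is_zero():
    s = snap({"a": 1.0, "b": 2.0})
    assert resilience_index(s, s) == 0.0


def test_resilience_two_group_reorganization():
    # (1,1) -> (2,0.5): aggregate ratio 1.25
    before = snap({"a": 1.0, "b": 1.0})
    after = snap({"a": 2.0, "b": 0.5})
    agg = math.log(1.25)
    expected = -(abs(math.log(2) - agg) + abs(math.log(0.5) - agg))
    r = resilience_index(before, after)
    assert r == pytest.approx(expected, rel=1e-12)
    assert r < 0


def test_resilience_requires_positive_before_biomass():
    with pytest.raises(ValueError, match="'b'"):
        resilience_index(snap({"a": 1.0, "b": 0.0}), snap({"a": 1.0, "b": 1.0}))


def test_resilience_requires_matching_groups():
    with pytest.raises(ValueError, match="group set"):
        resilience_index(snap({"a": 1.0}), snap({"a": 1.0, "b": 1.0}))


@given(
    b1=st.lists(st.floats(0.1, 50.0), min_size=2, max_size=8),
    factors=st.lists(st.floats(0.2, 5.0), min_size=2, max_size=8),
    k=st.floats(0.2, 5.0),
)
def test_resilience_permutation_invariant_and_proportional_zero(b1, factors, k):
    n = min(len(b1), len(factors))
    names = [f"g{i}" for i in range(n)]
    before = snap(dict(zip(names, b1[:n])))
    after = snap({nm: b * f for nm, b, f in zip(names, b1[:n], factors[:n])})
    r = resilience_index(before, after)
    # permutation of the group labels leaves R unchanged
    perm = names[::-1]
    before_p = snap({nm: before.biomass[nm] for nm in perm})
    after_p = snap({nm: after.biomass[nm] for nm in perm})
    assert resilience_index(before_p, after_p) == pytest.approx(r, rel=1e-12, abs=1e-12)
    # scaling every group by k is a proportional response
    prop = snap({nm: v * k for nm, v in before.biomass.items()})
    assert resilience_index(before, prop) == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------- diversity
def test_shannon_equal_biomass_is_log_richness():
    s = snap({"a": 2.0, "b": 2.0})
    assert shannon_diversity(s, GROUPS) == pytest.approx(math.log(2), rel=1e-12)


def test_shannon_known_values_and_detritus_exclusion():
    s = snap({"a": 1.0, "b": 1.0, "det": 100.0})
    assert shannon_diversity(s, GROUPS) == pytest.approx(0.6931, abs=1e-4)
    only = snap({"a": 3.0, "det": 50.0})
    assert shannon_diversity(only, GROUPS) == 0.0


@given(b=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=6), k=st.floats(0.1, 10.0))
def test_shannon_invariant_to_biomass_rescaling(b, k):
    names = [f"g{i}" for i in range(len(b))]
    groups = {n: FunctionalGroup(n, 2.0) for n in names}
    h1 = shannon_diversity(snap(dict(zip(names, b))), groups)
    h2 = shannon_diversity(snap({n: v * k for n, v in zip(names, b)}), groups)
    assert h2 == pytest.approx(h1, rel=1e-9)
    assert 0.0 <= h1 <= math.log(len(b)) + 1e-9


# ---------------------------------------------------------------- trophic level
@pytest.mark.parametrize(
    "biomass,expected",
    [({"a": 1.0}, 2.0), ({"a": 1.0, "b": 1.0}, 3.0), ({"a": 3.0, "b": 1.0}, 2.5)],
)
def test_mean_trophic_level_known_values(biomass, expected):
    assert mean_trophic_level(snap(biomass), GROUPS) == pytest.approx(expected)


@given(b=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6))
def test_mean_trophic_level_within_bounds(b):
    names = [f"g{i}" for i in range(len(b))]
    tls = np.linspace(1.0, 4.5, len(b))
    groups = {n: FunctionalGroup(n, tl) for n, tl in zip(names, tls)}
    mtl = mean_trophic_level(snap(dict(zip(names, b))), groups)
    assert tls.min() - 1e-9 <= mtl <= tls.max() + 1e-9


# ---------------------------------------------------------------- npp / yields
def test_npp_biomass_ratio_excludes_detritus_and_scales():
    s = snap({"a": 2.0, "b": 3.0, "det": 95.0}, npp=10.0)
    assert npp_biomass_ratio(s, GROUPS) == pytest.approx(2.0)
    doubled = snap({"a": 4.0, "b": 6.0, "det": 95.0}, npp=10.0)
    assert npp_biomass_ratio(doubled, GROUPS) == pytest.approx(1.0)


def test_yield_metrics():
    assert yield_metrics(snap({"a": 1.0}), GROUPS) == (0.0, 0.0)
    s = snap({"a": 1.0, "b": 1.0}, landings={"a": 1.0, "b": 2.0})
    assert yield_metrics(s, GROUPS) == (3.0, 20.0)


# ---------------------------------------------------------------- scaling
def test_standardize_series_moments_and_round_trip():
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    z, t = standardize_series(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-10)
    assert z.std() == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(t.invert(z), x, rtol=1e-12)
    zf, tf = standardize_series(x, unstressed_is_high=False)
    np.testing.assert_allclose(zf, -z, rtol=1e-12)
    np.testing.assert_allclose(tf.invert(zf), x, rtol=1e-12)


def test_standardize_rejects_constant_series():
    with pytest.raises(ValueError, match="distinct"):
        standardize_series([2.0, 2.0, 2.0])


def test_standardize_attributes_table():
    df = pd.DataFrame(
        {
            "pressure": [0.0, 0.5, 1.0] * 2,
            "replicate": 0,
            "attribute": ["shannon"] * 3 + ["resilience"] * 3,
            "value_raw": [1.7, 1.5, 1.2, 0.0, -1.0, -3.0],
        }
    )
    out, transforms = standardize_attributes(df)
    for attr, sub in out.groupby("attribute"):
        assert sub["value_standardized"].mean() == pytest.approx(0.0, abs=1e-10)
        assert sub["value_standardized"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
    assert set(transforms) == {"shannon", "resilience"}
    with pytest.raises(ValueError, match="attribute"):
        standardize_attributes(pd.DataFrame({"x": [1]}))


def test_rescale_pressure_fishing_and_inverted_habitat():
    fishing = rescale_pressure(np.array([0, 0.2, 0.4, 0.6, 0.8, 1, 2, 4, 6, 8, 10]))
    assert fishing[0] == 0.0 and fishing[-1] == 1.0
    assert fishing[5] == pytest.approx(0.1)  # baseline 1x maps to 0.1
    habitat = rescale_pressure(np.arange(0.0, 1.31, 0.1), invert=True)
    assert habitat[0] == 1.0 and habitat[-1] == pytest.approx(0.0)
    assert np.all(np.diff(habitat) < 0)
    with pytest.raises(ValueError, match="constant"):
        rescale_pressure([2.0, 2.0])
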