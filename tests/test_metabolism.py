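"""Respiration, diapause duration, capability and their inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calanus_diapause.biometry import SYNTHETIC_ALLOMETRY
from calanus_diapause.metabolism import (
    ModelParams,
    assess_individual,
    diapause_duration,
    is_overwinter_capable,
    max_diapause_duration,
    required_reserve,
    respiration_rate,
)

PARAMS = ModelParams()


def test_respiration_at_reference_temperature():
    """At T = T0 (0 degC) the Arrhenius factor is unity: r = b m^(3/4) 86400."""
    r = respiration_rate(100.0, 0.0, PARAMS)
    assert r == pytest.approx(2.5e-7 * 100.0**0.75 * 86_400.0, rel=1e-12)
    assert r == pytest.approx(0.6831, abs=2e-4)


def test_respiration_below_reference():
    # 0.6831 * exp(-0.1015) by independent scalar evaluation
    r = respiration_rate(100.0, -1.0, PARAMS)
    assert r == pytest.approx(0.617, abs=1e-3)


def test_respiration_temperature_independent_when_E_zero(rng):
    p = PARAMS.with_overrides(activation_energy_eV=0.0)
    temps = rng.uniform(-2.0, 15.0, size=50)
    r = respiration_rate(np.full(50, 80.0), temps, p)
    assert np.ptp(r) == 0.0


def test_respiration_preconditions():
    with pytest.raises(ValueError):
        respiration_rate(0.0, 0.0, PARAMS)
    with pytest.raises(ValueError):
        respiration_rate(100.0, -300.0, PARAMS)


def test_respiration_warns_outside_sanity_window():
    with pytest.warns(UserWarning):
        respiration_rate(100.0, 40.0, PARAMS)


@pytest.mark.parametrize(
    "w, r, expected",
    [(150.0, 0.6831, 120.0 / 0.6831), (0.0, 0.5, 0.0)],
)
def test_diapause_duration_examples(w, r, expected):
    assert diapause_duration(w, r, PARAMS) == pytest.approx(expected, rel=1e-9)


def test_diapause_duration_linear_in_reserve():
    d1 = diapause_duration(80.0, 0.5, PARAMS)
    assert diapause_duration(160.0, 0.5, PARAMS) == pytest.approx(2 * d1, rel=1e-12)


@pytest.mark.parametrize(
    "d, expected",
    [(150.0, True), (149.999, False), (212.0, True), (0.0, False)],
)
def test_capability_boundary_is_closed(d, expected):
    assert is_overwinter_capable(d, PARAMS) is expected


def test_required_reserve_example():
    # 150 d * r(100 ug C, 0 degC) / 0.8 = 128.07 ug C
    r = respiration_rate(100.0, 0.0, PARAMS)
    assert required_reserve(r, PARAMS) == pytest.approx(128.07, abs=0.01)
    p0 = PARAMS.with_overrides(retained_fraction=0.0)
    assert required_reserve(0.5, p0) == pytest.approx(150.0 * 0.5, rel=1e-12)


def test_required_reserve_round_trip(rng):
    """duration(required_reserve(r), r) == threshold for 1000 random rates."""
    r = rng.uniform(1e-3, 5.0, size=1000)
    w_req = required_reserve(r, PARAMS)
    np.testing.assert_allclose(
        diapause_duration(w_req, r, PARAMS), PARAMS.duration_threshold_days, rtol=1e-12
    )


def test_required_reserve_matches_bisection(rng):
    from scipy.optimize import brentq

    for _ in range(50):
        m = rng.uniform(20.0, 300.0)
        t = rng.uniform(-2.0, 10.0)
        rf = rng.uniform(0.0, 0.5)
        p = PARAMS.with_overrides(retained_fraction=rf)
        r = respiration_rate(m, t, p)
        w_root = brentq(
            lambda w: diapause_duration(w, r, p) - p.duration_threshold_days,
            1e-9, 1e6, xtol=1e-12, rtol=1e-15,
        )
        assert required_reserve(r, p) == pytest.approx(w_root, rel=1e-9)


def test_post_diapause_reserve_is_retained_fraction(rng):
    """w - r*D leaves exactly 20% of the pre-diapause lipid mass."""
    w = rng.uniform(1.0, 300.0, size=200)
    r = rng.uniform(0.05, 2.0, size=200)
    d = diapause_duration(w, r, PARAMS)
    np.testing.assert_allclose(w - r * d, PARAMS.retained_fraction * w, rtol=1e-12)


def test_max_diapause_duration_saturation_and_linearity():
    # synthetic allometry: c=20, e=3, L=2 -> w_max=160; D_max = 0.8*160/0.6831
    d_max = max_diapause_duration(2.0, 100.0, 0.0, SYNTHETIC_ALLOMETRY, PARAMS)
    assert d_max == pytest.approx(187.4, abs=0.1)
    r = respiration_rate(100.0, 0.0, PARAMS)
    assert diapause_duration(160.0, r, PARAMS) == pytest.approx(d_max, rel=1e-12)
    assert diapause_duration(80.0, r, PARAMS) == pytest.approx(0.5 * d_max, rel=1e-12)


def test_max_duration_bounds_any_feasible_reserve(rng):
    L, m, t = 2.2, 120.0, -0.5
    d_max = max_diapause_duration(L, m, t, SYNTHETIC_ALLOMETRY, PARAMS)
    w_max = SYNTHETIC_ALLOMETRY.coefficient * L**SYNTHETIC_ALLOMETRY.exponent
    r = respiration_rate(m, t, PARAMS)
    for w in rng.uniform(0.0, w_max, size=100):
        assert diapause_duration(w, r, PARAMS) <= d_max + 1e-12


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    w=st.floats(1.0, 300.0),
    m=st.floats(10.0, 400.0),
    t=st.floats(-2.5, 12.0),
    dw=st.floats(0.1, 50.0),
    dm=st.floats(0.1, 50.0),
    dt=st.floats(0.1, 5.0),
)
def test_duration_monotonicity(w, m, t, dw, dm, dt):
    """D increases in w and decreases in m and (E > 0) in T."""
    base = diapause_duration(w, respiration_rate(m, t, PARAMS), PARAMS)
    assert diapause_duration(w + dw, respiration_rate(m, t, PARAMS), PARAMS) > base
    assert diapause_duration(w, respiration_rate(m + dm, t, PARAMS), PARAMS) < base
    assert diapause_duration(w, respiration_rate(m, t + dt, PARAMS), PARAMS) < base


def test_assess_individual_chained_example():
    record = {
        "individual_id": "x1",
        "station": "S1",
        "stage": "CV",
        "stratum_upper_m": 250.0,
        "stratum_lower_m": 375.0,
        "prosome_length_mm": 2.0,
        "lipid_area_mm2": 2.0,
        "total_carbon_ug": 200.0,
    }
    prof = assess_individual(record, 0.0, SYNTHETIC_ALLOMETRY, PARAMS)
    assert prof.lipid_carbon_ug == pytest.approx(0.3531, abs=1e-4)
    assert prof.structural_carbon_ug == pytest.approx(199.65, abs=1e-2)
    assert prof.capable is False  # tiny reserve cannot fuel 150 days
    # determinism: identical record gives an identical profile
    assert assess_individual(record, 0.0, SYNTHETIC_ALLOMETRY, PARAMS) == prof


def test_assess_individual_empty_sac():
    record = {
        "individual_id": "x2",
        "station": "S1",
        "stage": "CV",
        "stratum_upper_m": 0.0,
        "stratum_lower_m": 125.0,
        "prosome_length_mm": 2.0,
        "lipid_area_mm2": 0.0,
        "total_carbon_ug": 150.0,
    }
    prof = assess_individual(record, 0.0, SYNTHETIC_ALLOMETRY, PARAMS)
    assert prof.diapause_days == 0.0
    assert prof.capable is False


def test_assess_individual_attaches_id_on_failure():
    record = {
        "individual_id": "bad-1",
        "station": "S1",
        "stage": "CV",
        "stratum_upper_m": 0.0,
        "stratum_lower_m": 125.0,
        "prosome_length_mm": 2.0,
        "lipid_area_mm2": 20.0,  # implies lipid carbon far above total carbon
        "total_carbon_ug": 5.0,
    }
    with pytest.raises(ValueError, match="bad-1"):
        assess_individual(record, 0.0, SYNTHETIC_ALLOMETRY, PARAMS)


def test_params_file_round_trip():
    p = ModelParams(activation_energy_eV=0.6, duration_threshold_days=120.0)
    assert ModelParams.from_mapping(p.to_mapping()) == p


def test_params_invariants_enforced():
    with pytest.raises(ValueError):
        ModelParams(retained_fraction=1.0)
    with pytest.raises(ValueError):
        ModelParams(b=0.0)
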