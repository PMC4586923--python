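"""Analytic DIC curves: closed forms, partition identity, superposition."""

import numpy as np
import pytest

from neurodic import dic_at, dic_curves, make_stg, make_toy
from neurodic.dic import CalciumProfile, default_grid, static_iv_slope
from neurodic.timescales import TimescaleTriplet, reference_timescales


def const(x):
    return lambda v: np.full_like(np.asarray(v, dtype=float), x)


def test_all_zero_conductances_give_zero_curves(stg):
    zeroed = stg.with_gbar(**{c.name: 0.0 for c in stg.currents})
    trip = reference_timescales(stg)  # designation from the reference model
    ds = dic_curves(zeroed, triplet=trip, frozen_calcium=CalciumProfile(stg))
    for curve in (ds.g_f, ds.g_s, ds.g_u, ds.g_total):
        np.testing.assert_allclose(curve, 0.0, atol=0.0)


def test_single_fast_current_lands_entirely_in_g_f():
    """One depolarizing current with tau below tau_f everywhere: its whole
    pathway term -gbar p m^(p-1) (V - Vrev) dm/dV is fast."""
    toy = make_toy("single_gate", gbar=2.0, reversal=60.0, vhalf=-40.0, k=6.0,
                   tau=0.05, exponent=2)
    trip = TimescaleTriplet(const(0.1), const(5.0), const(100.0), {})
    v = np.linspace(-70.0, 0.0, 71)
    ds = dic_curves(toy, v, triplet=trip)
    s = toy.current_by_name("X").activation.steady_state
    expected = -2.0 * 2 * s(v) ** 1 * (v - 60.0) * s.deriv(v)
    np.testing.assert_allclose(ds.g_f, expected, rtol=1e-12)
    np.testing.assert_allclose(ds.g_s, 0.0, atol=0.0)
    np.testing.assert_allclose(ds.g_u, 0.0, atol=0.0)


def test_partition_identity_on_fixtures(stg, hh):
    for model in (stg, hh):
        ds = dic_curves(model)
        err = np.abs(ds.g_f + ds.g_s + ds.g_u - ds.g_total)
        assert np.max(err) <= 1e-10


def test_leak_does_not_enter_the_dics(stg):
    from dataclasses import replace

    ds_a = dic_curves(stg)
    ds_b = dic_curves(replace(stg, leak_g=stg.leak_g * 50.0))
    np.testing.assert_allclose(ds_a.g_total, ds_b.g_total, rtol=0, atol=0)


def test_per_channel_contributions_sum_to_aggregates(stg):
    ds = dic_curves(stg)
    total = np.sum([arr for arr in ds.per_channel.values()], axis=0)
    np.testing.assert_allclose(total[0], ds.g_f, atol=1e-12)
    np.testing.assert_allclose(total[1], ds.g_s, atol=1e-12)
    np.testing.assert_allclose(total[2], ds.g_u, atol=1e-12)


def test_superposition_of_single_channel_submodels(stg, rng):
    """DICs of a random-conductance model equal the sum of single-channel
    submodels evaluated with the full model's timescales and frozen calcium."""
    names = [c.name for c in stg.currents]
    gbars = {nm: float(g) for nm, g in zip(
        names, rng.uniform(0.2, 2.0, len(names)) * [c.gbar for c in stg.currents])}
    model = stg.with_gbar(**gbars)
    trip = reference_timescales(stg)
    frozen = CalciumProfile(stg)
    v = np.linspace(-75.0, 30.0, 106)
    full = dic_curves(model, v, triplet=trip, frozen_calcium=frozen)
    acc = np.zeros((3, v.size))
    for nm in names:
        solo = model.with_gbar(**{k: (gbars[k] if k == nm else 0.0) for k in names})
        ds = dic_curves(solo, v, triplet=trip, frozen_calcium=frozen)
        acc += np.array([ds.g_f, ds.g_s, ds.g_u])
    np.testing.assert_allclose(acc[0], full.g_f, atol=1e-9)
    np.testing.assert_allclose(acc[1], full.g_s, atol=1e-9)
    np.testing.assert_allclose(acc[2], full.g_u, atol=1e-9)


def test_dic_at_matches_grid_evaluation(stg):
    ds = dic_curves(stg)
    v = float(ds.v_grid[137])
    assert dic_at(stg, v) == pytest.approx(ds.at(v), rel=1e-12)


def test_partition_identity_at_arbitrary_point(stg):
    g_f, g_s, g_u, g = dic_at(stg, -47.3)
    assert g_f + g_s + g_u - g == pytest.approx(0.0, abs=1e-12)


def test_hh_ultraslow_curve_vanishes(hh):
    ds = dic_curves(hh)
    np.testing.assert_allclose(ds.g_u, 0.0, atol=0.0)
    # sodium activation is wholly fast
    na = ds.per_channel["Na"]
    # fast row contains the m-pathway; check the m pathway is absent from u
    assert np.max(np.abs(na[2])) == 0.0


def test_stg_curve_shapes_match_burster_phenotype(stg):
    """Fast DIC mostly positive, slow DIC negative at depolarized potentials
    with a small positive area near threshold, ultraslow negative
    subthreshold."""
    ds = dic_curves(stg)
    v = ds.v_grid
    sub = (v > -60) & (v < -20)
    assert np.mean(ds.g_f[sub] >= -1e-9) > 0.95
    dep = v > -20
    assert np.min(ds.g_s[dep]) < -20.0  # strong repolarizing peak
    th_band = (v > -55) & (v < -45)
    assert np.max(ds.g_s[th_band]) > 0.0  # slow positive-feedback area
    assert np.all(ds.g_u[(v > -45) & (v < -25)] < 0.0)


def test_static_iv_slope_matches_finite_difference(stg):
    v = np.linspace(-70, 30, 41)
    from neurodic import static_iv

    fd = (static_iv(stg, v + 1e-4) - static_iv(stg, v - 1e-4)) / 2e-4
    np.testing.assert_allclose(static_iv_slope(stg, v), fd, rtol=1e-6, atol=1e-8)


def test_default_grid_covers_working_range(stg):
    g = default_grid(stg)
    assert g[0] == stg.v_range[0] and g[-1] == pytest.approx(stg.v_range[1])
    assert np.allclose(np.diff(g), 0.1)
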