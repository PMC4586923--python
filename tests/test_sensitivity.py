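"""Sensitivity curves: finite-difference oracle, sum rules, localization."""

import numpy as np
import pytest

from neurodic import (
    dic_curves,
    make_stg,
    sensitivity_at_markers,
    sensitivity_curves,
    shift_activation,
)
from neurodic.dic import CalciumProfile
from neurodic.sensitivity import colocalization_score, static_iv_sensitivity
from neurodic.timescales import reference_timescales

V = np.linspace(-75.0, 35.0, 111)


@pytest.fixture(scope="module")
def frozen(request):
    return CalciumProfile(make_stg())


def fd_oracle(stg, name, v, frozen, rel=1e-3):
    """Central finite difference of dic_curves w.r.t. one gbar, frozen calcium."""
    trip = reference_timescales(stg)
    g0 = stg.current_by_name(name).gbar
    h = rel * max(g0, 1.0)
    up = dic_curves(stg.with_gbar(**{name: g0 + h}), v, trip, frozen)
    dn = dic_curves(stg.with_gbar(**{name: g0 - h}), v, trip, frozen)
    return np.array(
        [
            (up.g_f - dn.g_f) / (2 * h),
            (up.g_s - dn.g_s) / (2 * h),
            (up.g_u - dn.g_u) / (2 * h),
        ]
    )


@pytest.mark.parametrize("name", ["Na", "CaT", "CaS", "A", "Kd", "KCa"])
def test_analytic_curves_match_finite_difference_oracle(stg, frozen, name):
    analytic = sensitivity_curves(stg, name, V, frozen_calcium=frozen)
    fd = fd_oracle(stg, name, V, frozen)
    scale = max(np.max(np.abs(analytic)), 1e-9)
    assert np.max(np.abs(analytic - fd)) <= 1e-6 * scale


def test_curves_do_not_depend_on_the_channel_density(stg, frozen):
    a = sensitivity_curves(stg, "CaS", V, frozen_calcium=frozen)
    b = sensitivity_curves(stg.with_gbar(CaS=8.0), "CaS", V, frozen_calcium=frozen)
    np.testing.assert_allclose(a, b, atol=0.0)


def test_timescale_sum_rule(stg, frozen):
    """Fast + slow + ultraslow sensitivities telescope to the static one."""
    for name in ("Na", "Kd", "KCa"):
        s = sensitivity_curves(stg, name, V, frozen_calcium=frozen)
        trip = reference_timescales(stg)
        from neurodic.dic import channel_pathways

        total = channel_pathways(stg, name, V, trip, frozen).sum(axis=0)
        np.testing.assert_allclose(s.sum(axis=0), total, atol=1e-12)


def test_linearity_reconstructs_the_dics(stg, frozen):
    """sum_i gbar_i * dg_j/dgbar_i == g_j pointwise under frozen calcium."""
    ds = dic_curves(stg, V, frozen_calcium=frozen)
    acc = np.zeros((3, V.size))
    for c in stg.currents:
        acc += c.gbar * sensitivity_curves(stg, c.name, V, frozen_calcium=frozen)
    np.testing.assert_allclose(acc[0], ds.g_f, atol=1e-10)
    np.testing.assert_allclose(acc[1], ds.g_s, atol=1e-10)
    np.testing.assert_allclose(acc[2], ds.g_u, atol=1e-10)


def test_slow_calcium_channel_has_no_fast_pathway(stg, frozen):
    """At its reference density the slow calcium channel contributes next to
    nothing to the fast input conductance (its kinetics sit well above tau_f),
    unlike sodium whose fast pathway dominates."""
    s_cas = stg.current_by_name("CaS").gbar * sensitivity_curves(
        stg, "CaS", V, frozen_calcium=frozen
    )
    g_f = dic_curves(stg, V, frozen_calcium=frozen).g_f
    assert np.max(np.abs(s_cas[0])) < 0.01 * np.max(np.abs(g_f))


def test_static_iv_sensitivity_is_the_open_fraction_times_drive(stg):
    v = np.array([-50.0])
    c = stg.current_by_name("Kd")
    m = c.activation.x_inf(v)
    expected = m**4 * (v + 80.0)
    assert static_iv_sensitivity(stg, "Kd", v) == pytest.approx(expected)


@pytest.fixture(scope="module")
def table():
    return sensitivity_at_markers(make_stg())


class TestMarkersTable:
    def test_normalized_curves_peak_at_unity(self, table):
        for nm, arr in table.normalized.items():
            for j in range(3):
                peak = np.max(np.abs(arr[j]))
                assert peak == pytest.approx(1.0) or peak == 0.0

    def test_calcium_channels_dominate_slow_feedback_at_threshold(self, table):
        at = table.at_markers
        ca = max(at.loc["CaT", "dgs_at_vth"], at.loc["CaS", "dgs_at_vth"])
        assert ca > 0.0
        assert ca > abs(at.loc["Kd", "dgs_at_vth"])
        assert ca > abs(at.loc["KCa", "dgs_at_vth"])

    def test_delayed_rectifier_dominates_slow_feedback_at_upstate(self, table):
        at = table.at_markers
        kd = abs(at.loc["Kd", "dgs_at_vosc"])
        others = [abs(at.loc[nm, "dgs_at_vosc"]) for nm in at.index if nm != "Kd"]
        assert kd > max(others)
        assert at.loc["Kd", "dgs_at_vosc"] < 0.0  # restorative


class TestActivationShift:
    def test_zero_shift_changes_nothing(self, stg):
        shifted = shift_activation(stg, "A", "activation", 0.0)
        a = dic_curves(stg, V)
        b = dic_curves(shifted, V)
        np.testing.assert_allclose(a.g_s, b.g_s, atol=0.0)

    def test_half_activation_moves_by_exactly_delta(self, stg):
        shifted = shift_activation(stg, "A", "activation", 4.5)
        gate = shifted.current_by_name("A").activation
        base = stg.current_by_name("A").activation
        assert gate.x_inf(-27.2 + 4.5) == pytest.approx(base.x_inf(-27.2)) == pytest.approx(0.5)
        assert gate.tau(-30.0 + 4.5) == pytest.approx(base.tau(-30.0))

    def test_original_model_is_untouched(self, stg):
        before = stg.current_by_name("A").activation.x_inf(-27.2)
        shift_activation(stg, "A", "activation", 4.5)
        assert stg.current_by_name("A").activation.x_inf(-27.2) == before

    def test_unknown_gate_is_a_name_error(self, stg):
        with pytest.raises(KeyError):
            shift_activation(stg, "Kd", "inactivation", 1.0)


def test_colocalization_swaps_after_a_type_shift(stg):
    """Slow-timescale overlap orders (A,CaS) > (A,CaT) for the reference model
    and the order reverses after a +4.5 mV shift of A-type activation."""
    ref_s = colocalization_score(stg, "A", "CaS")
    ref_t = colocalization_score(stg, "A", "CaT")
    assert ref_s > ref_t
    shifted = shift_activation(stg, "A", "activation", 4.5)
    sh_s = colocalization_score(shifted, "A", "CaS")
    sh_t = colocalization_score(shifted, "A", "CaT")
    assert sh_t > sh_s
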