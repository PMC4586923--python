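"""Model construction, steady states, static I/V, simulation, spike stats."""

import numpy as np
import pytest

from neurodic import (
    IonicCurrent,
    NeuronModel,
    Trace,
    make_hh,
    make_stg,
    make_toy,
    simulate,
    static_iv,
    steady_state,
    trace_statistics,
)
from neurodic.errors import RangeError


# --------------------------------------------------------------- steady state


def test_leak_only_model_has_empty_gating_state():
    m = NeuronModel(currents=(), leak_g=0.1, leak_e=-55.0, name="leak")
    assert steady_state(m, -40.0) == {}


def test_sigmoid_activation_is_half_open_at_vhalf():
    toy = make_toy("single_gate", vhalf=-40.0, k=5.0)
    assert steady_state(toy, -40.0)["X.m"] == pytest.approx(0.5)


def test_stg_sodium_nearly_closed_at_hyperpolarized_rest(stg):
    ss = steady_state(stg, -80.0)
    assert ss["Na.m"] < 0.05
    assert 0.0 <= min(v for k, v in ss.items() if k != "Ca")
    assert max(v for k, v in ss.items() if k != "Ca") <= 1.0


def test_steady_state_is_idempotent(stg):
    v = -52.0
    y = stg.state_vector(v)
    dy = stg.state_derivative(v, y)
    assert np.max(np.abs(dy)) < 1e-12


def test_out_of_range_potential_rejected(stg):
    with pytest.raises(RangeError):
        steady_state(stg, 200.0)


# ------------------------------------------------------------------ static IV


def test_leak_only_iv_is_linear_with_zero_at_reversal():
    m = NeuronModel(currents=(), leak_g=0.2, leak_e=-55.0, name="leak")
    v = np.linspace(-80, 0, 81)
    np.testing.assert_allclose(static_iv(m, v), 0.2 * (v + 55.0), atol=1e-14)


def test_static_iv_superposition_in_maximal_conductances(stg, rng):
    """I_static is linear in every gbar (leak split off; calcium coupling
    linearized by evaluating against the reference calcium profile)."""
    from neurodic.dic import CalciumProfile

    frozen = CalciumProfile(stg)
    v = np.linspace(-75, 40, 40)
    names = [c.name for c in stg.currents]
    for _ in range(3):
        ga = dict(zip(names, rng.uniform(0, 2, len(names)) * [c.gbar for c in stg.currents]))
        gb = dict(zip(names, rng.uniform(0, 2, len(names)) * [c.gbar for c in stg.currents]))
        gsum = {k: ga[k] + gb[k] for k in ga}
        lhs = static_iv(stg.with_gbar(**gsum), v, frozen_calcium=frozen)
        leak = stg.leak_current(v)
        rhs = (
            static_iv(stg.with_gbar(**ga), v, frozen_calcium=frozen)
            + static_iv(stg.with_gbar(**gb), v, frozen_calcium=frozen)
            - leak
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_doubling_one_gbar_doubles_its_contribution(stg):
    v = np.linspace(-70, 30, 21)
    base = static_iv(stg.with_gbar(Kd=0.0), v)
    one = static_iv(stg, v) - base
    two = static_iv(stg.with_gbar(Kd=140.0), v) - base
    np.testing.assert_allclose(two, 2.0 * one, rtol=1e-12)


def test_empty_grid_is_an_error(stg):
    with pytest.raises(ValueError):
        static_iv(stg, np.array([]))


# ----------------------------------------------------------------- simulation


def test_passive_relaxation_to_leak_reversal():
    m = NeuronModel(currents=(), leak_g=0.1, leak_e=-55.0, name="leak")
    tr = simulate(m, 500.0, v0=-40.0, dt_out=1.0)
    assert tr.voltage[-1] == pytest.approx(-55.0, abs=1e-4)


def test_hh_suprathreshold_step_spikes_like_reference_implementation(hh):
    """Cross-check against an independent fixed-step RK4 integration of the
    same equations written out longhand."""
    i_app = 10.0
    tr = simulate(hh, 200.0, i_app=i_app, dt_out=0.1)
    st = trace_statistics(tr)
    assert st.n_spikes >= 8  # repetitive firing

    # independent reference: hand-written HH right-hand side, RK4, dt=0.01
    def a_m(v):
        return 0.1 * (v + 40.0) / (1.0 - np.exp(-(v + 40.0) / 10.0))

    def b_m(v):
        return 4.0 * np.exp(-(v + 65.0) / 18.0)

    def a_h(v):
        return 0.07 * np.exp(-(v + 65.0) / 20.0)

    def b_h(v):
        return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))

    def a_n(v):
        return 0.01 * (v + 55.0) / (1.0 - np.exp(-(v + 55.0) / 10.0))

    def b_n(v):
        return 0.125 * np.exp(-(v + 65.0) / 80.0)

    def rhs(y):
        v, m, h, n = y
        dv = (
            i_app
            - 120.0 * m**3 * h * (v - 50.0)
            - 36.0 * n**4 * (v + 77.0)
            - 0.3 * (v + 54.4)
        )
        return np.array(
            [
                dv,
                a_m(v) * (1 - m) - b_m(v) * m,
                a_h(v) * (1 - h) - b_h(v) * h,
                a_n(v) * (1 - n) - b_n(v) * n,
            ]
        )

    v0 = -65.0
    y = np.array(
        [
            v0,
            a_m(v0) / (a_m(v0) + b_m(v0)),
            a_h(v0) / (a_h(v0) + b_h(v0)),
            a_n(v0) / (a_n(v0) + b_n(v0)),
        ]
    )
    dt = 0.01
    times, volts = [], []
    for k in range(int(200.0 / dt)):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        times.append((k + 1) * dt)
        volts.append(y[0])
    ref = trace_statistics(Trace(time=np.array(times), voltage=np.array(volts)))
    assert ref.n_spikes == st.n_spikes
    # spike times line up within a fraction of an interspike interval
    n = min(ref.n_spikes, st.n_spikes)
    assert np.max(np.abs(ref.spike_times[:n] - st.spike_times[:n])) < 2.0


def test_clamped_gating_relaxes_monotonically_toward_steady_state(stg):
    """With V fixed, each gate moves monotonically to X_inf(V) from any side."""
    v = -40.0
    y_eq = stg.state_vector(v)
    y = stg.state_vector(-70.0)  # off-equilibrium start
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, yy: stg.state_derivative(v, yy),
        (0, 2000.0),
        y,
        t_eval=np.linspace(0, 2000.0, 400),
        rtol=1e-9,
        atol=1e-12,
        method="LSODA",
    )
    # calcium couples to the gates, so check the purely V-driven gates
    for k, name in enumerate(stg.state_names):
        if name in ("Ca", "KCa.m"):
            continue
        x = sol.y[k]
        d = np.diff(x)
        assert np.all(d >= -1e-9) or np.all(d <= 1e-9), name
        assert x[-1] == pytest.approx(y_eq[k], abs=1e-6), name


# ----------------------------------------------------------------- statistics


def test_constant_trace_has_no_spikes():
    tr = Trace(time=np.arange(0.0, 100.0, 1.0), voltage=np.full(100, -50.0))
    st = trace_statistics(tr)
    assert st.n_spikes == 0 and st.bursts == []


def test_synthetic_spike_train_splits_into_two_bursts():
    t = np.arange(0.0, 700.0, 0.5)
    v = np.full_like(t, -60.0)
    for ts in (100.0, 110.0, 120.0, 500.0, 510.0):
        v[(t >= ts) & (t < ts + 1.5)] = 20.0
    st = trace_statistics(Trace(time=t, voltage=v), burst_gap=100.0)
    assert [len(b) for b in st.bursts] == [3, 2]
    np.testing.assert_allclose(st.burst_isis[0], [10.0, 10.0], atol=0.6)
    np.testing.assert_allclose(st.burst_isis[1], [10.0], atol=0.6)
    assert st.burst_period == pytest.approx(400.0, abs=1.0)


def test_refractory_suppresses_double_counting():
    t = np.arange(0.0, 50.0, 0.1)
    v = np.where((t > 10) & (t < 11), 20.0, -60.0)
    v[(t > 11.5) & (t < 12)] = 20.0  # re-crossing within 2 ms refractory
    st = trace_statistics(Trace(time=t, voltage=v))
    assert st.n_spikes == 1


# -------------------------------------------------------------------- editing


def test_unknown_gbar_name_raises(stg):
    with pytest.raises(KeyError, match="unknown current"):
        stg.with_gbar(Nax=1.0)


def test_duplicate_current_names_rejected():
    c = IonicCurrent(name="X", gbar=1.0, reversal=0.0)
    with pytest.raises(ValueError, match="unique"):
        NeuronModel(currents=(c, c), leak_g=0.0, leak_e=-60.0)


def test_negative_gbar_needs_explicit_flag():
    with pytest.raises(ValueError):
        IonicCurrent(name="X", gbar=-1.0, reversal=0.0)
    c = IonicCurrent(name="X", gbar=-1.0, reversal=0.0, nonphysiological=True)
    assert c.gbar == -1.0
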