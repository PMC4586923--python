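"""Linear compensation: closure, affinity, the negative-conductance finding."""

import numpy as np
import pytest

from neurodic import (
    compensate,
    compensation_path,
    dic_at,
    make_stg,
    make_targets,
    static_iv,
)
from neurodic.dic import CalciumProfile
from neurodic.markers import voltage_markers
from neurodic.timescales import reference_timescales


@pytest.fixture(scope="module")
def ref():
    return make_stg()


@pytest.fixture(scope="module")
def targets(ref):
    return make_targets(ref)


def test_targets_are_deterministic(ref, targets):
    again = make_targets(ref)
    for attr in ("gs_th", "gs_osc", "gu_th", "istatic_th", "v_th", "v_osc"):
        assert getattr(again, attr) == pytest.approx(getattr(targets, attr), rel=1e-9)


def test_reference_slow_conductance_at_threshold_is_regenerative(targets):
    assert targets.gs_th > 0.0


def test_targets_scale_with_joint_conductance_scaling():
    """With the calcium-coupled channel silenced, scaling every conductance
    and the applied current jointly scales all four targets and leaves the
    marker potentials untouched (homogeneity, checked by recomputation)."""
    from dataclasses import replace

    lam = 1.7
    base = make_stg(KCa=0.0)
    scaled = replace(
        base.with_gbar(**{c.name: lam * c.gbar for c in base.currents}),
        leak_g=lam * base.leak_g,
        i_app=lam * base.i_app,
    )
    t0 = make_targets(base)
    t1 = make_targets(scaled)
    assert t1.v_th == pytest.approx(t0.v_th, abs=1e-3)
    assert t1.v_osc == pytest.approx(t0.v_osc, abs=1e-3)
    assert t1.gs_th == pytest.approx(lam * t0.gs_th, rel=1e-5)
    assert t1.gs_osc == pytest.approx(lam * t0.gs_osc, rel=1e-5)
    assert t1.gu_th == pytest.approx(lam * t0.gu_th, rel=1e-5)
    assert t1.istatic_th == pytest.approx(lam * t0.istatic_th, rel=1e-5)


def test_unperturbed_solve_returns_the_reference(ref, targets):
    res = compensate(ref, "CaS", 4.0, targets)
    assert res.i_app == pytest.approx(ref.i_app, abs=1e-9)
    assert res.gbars["Kd"] == pytest.approx(70.0, rel=1e-9)
    assert res.gbars["A"] == pytest.approx(50.0, rel=1e-9)
    assert res.gbars["KCa"] == pytest.approx(40.0, rel=1e-9)
    assert res.physiological
    for r in res.residuals.values():
        assert abs(r) < 1e-10


@pytest.mark.parametrize("factor", [0.5, 2.0, 5.0])
def test_closed_loop_reproduces_targets_frozen_calcium(ref, targets, factor):
    """Rebuild the compensated model and re-evaluate the four maintained
    quantities through the DIC/static-IV machinery (frozen reference
    calcium): they close to linear-algebra precision."""
    res = compensate(ref, "CaS", factor * 4.0, targets)
    frozen = CalciumProfile(ref)
    trip = reference_timescales(ref)
    new = res.apply(ref)
    _, gs_th, gu_th, _ = dic_at(new, targets.v_th, trip, frozen)
    _, gs_osc, _, _ = dic_at(new, targets.v_osc, trip, frozen)
    istatic = float(static_iv(new, targets.v_th, frozen_calcium=frozen)) - new.i_app
    assert gs_th == pytest.approx(targets.gs_th, abs=1e-8)
    assert gs_osc == pytest.approx(targets.gs_osc, abs=1e-8)
    assert gu_th == pytest.approx(targets.gu_th, abs=1e-8)
    assert istatic == pytest.approx(targets.istatic_th, abs=1e-8)


def test_fourfold_decrease_drives_a_type_negative(ref, targets):
    res = compensate(ref, "CaS", 1.0, targets)
    assert res.gbars["A"] < 0.0
    assert not res.physiological
    assert any("A" in f for f in res.flags)


def test_solution_components_are_affine_in_the_perturbation(ref, targets):
    """Three collinear perturbed values give collinear solutions."""
    gvals = [2.0, 6.0, 10.0]
    path = compensation_path(ref, "CaS", gvals, targets)
    for key in ("Kd", "A", "KCa"):
        y = np.array([r.gbars[key] for r in path])
        interp = y[0] + (y[2] - y[0]) * (gvals[1] - gvals[0]) / (gvals[2] - gvals[0])
        assert y[1] == pytest.approx(interp, rel=1e-9, abs=1e-12)
    y = np.array([r.i_app for r in path])
    interp = y[0] + (y[2] - y[0]) * 0.5
    assert y[1] == pytest.approx(interp, rel=1e-9, abs=1e-12)


def test_path_through_reference_passes_through_reference_solution(ref, targets):
    path = compensation_path(ref, "CaS", [3.0, 4.0, 5.0], targets)
    mid = path[1]
    assert mid.gbars["Kd"] == pytest.approx(70.0, rel=1e-9)
    assert mid.gbars["A"] == pytest.approx(50.0, rel=1e-9)
    assert mid.gbars["KCa"] == pytest.approx(40.0, rel=1e-9)


def test_a_type_conductance_rises_with_slow_calcium(ref, targets):
    """More slow-calcium positive feedback at threshold needs more A-type
    negative feedback in the slow timescale: gbar_A grows along the path."""
    lo, hi = compensation_path(ref, "CaS", [4.0, 8.0], targets)
    assert hi.gbars["A"] > lo.gbars["A"]


def test_three_unknown_variant_drops_the_static_row(ref):
    res = compensate(ref, "CaS", 8.0, include_static_row=False)
    assert res.i_app == ref.i_app
    assert set(res.gbars) == {"Kd", "A", "KCa"}
    assert all(abs(r) < 1e-8 for r in res.residuals.values())


def test_unknown_perturbed_current_raises(ref):
    with pytest.raises(KeyError):
        compensate(ref, "CaX", 1.0)
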