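"""Voltage markers: spike threshold V_th and up-state V_osc.

V_th is located as a codimension-one degenerate equilibrium of the static I/V
relation: scale one calcium maximal conductance by a factor alpha and solve
jointly for (V, alpha) such that the net steady-state current and its voltage
derivative both vanish.  At that point the resting equilibrium sits exactly at
the excitability threshold, the potential of maximal sensitivity.

V_osc is the most depolarized zero of the quasi-static I/V curve, the unstable
equilibrium around which intra-burst spiking oscillates.  Because the
oscillation is a fast-slow phenomenon, the curve is evaluated with the
ultraslow variables (calcium-channel inactivations, calcium-gated potassium
activation, the calcium pool itself in the STG model) frozen at their values
at the resting equilibrium; ``subsystem="static"`` gives the literal
full-steady-state curve instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, root

from .dic import static_iv_slope
from .errors import DesignationError, MarkerError
from .model_core import NeuronModel, static_iv
from .timescales import TimescaleTriplet, reference_timescales

__all__ = [
    "VoltageMarkers",
    "find_upstate",
    "find_threshold",
    "voltage_markers",
    "ultraslow_variables",
    "resting_potential",
    "quasi_static_iv",
]

_GRID_STEP = 0.1  # mV


@dataclass(frozen=True)
class VoltageMarkers:
    v_th: float
    v_osc: float
    metadata: dict = field(default_factory=dict)


def _net_current(model: NeuronModel, v):
    """I_static(V) - I_app: zeros are equilibria of the membrane equation."""
    return static_iv(model, v) - model.i_app


def _grid(model: NeuronModel, step=_GRID_STEP):
    lo, hi = model.v_range
    return np.arange(lo, hi + 0.5 * step, step)


def _refined_roots(fun, v_grid, xtol) -> list[float]:
    f = fun(v_grid)
    roots = []
    sign_change = np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)
    for j in sign_change:
        roots.append(brentq(lambda x: float(fun(np.array([x]))[0]),
                            v_grid[j], v_grid[j + 1], xtol=xtol))
    # exact zeros on grid points
    for j in np.flatnonzero(f == 0.0):
        roots.append(float(v_grid[j]))
    return sorted(roots)


def resting_potential(model: NeuronModel, xtol: float = 1e-6) -> float:
    """Most hyperpolarized zero of the full static I/V curve (minus I_app)."""
    roots = _refined_roots(lambda v: _net_current(model, v), _grid(model), xtol)
    if not roots:
        raise MarkerError(
            f"{model.name!r}: the net static current has no zero in {model.v_range}"
        )
    return roots[0]


def ultraslow_variables(
    model: NeuronModel, triplet: Optional[TimescaleTriplet] = None
) -> list[str]:
    """State variables at least as slow as the ultraslow reference somewhere.

    Returns state names (e.g. ``"CaS.h"``, ``"Ca"``).  Empty when the model has
    no ultraslow timescale.
    """
    if not any(c.gated for c in model.currents):
        return []
    if triplet is None:
        try:
            triplet = reference_timescales(model)
        except DesignationError:
            # no resolvable timescale structure (analytic toys): nothing to freeze
            return []
    if triplet.tau_u is None:
        return []
    v = _grid(model, 0.5)
    tu = np.asarray(triplet.tau_u(v), dtype=float)
    out = []
    for _, c, label, gate in model.gating_entries():
        if np.any(np.asarray(gate.tau(v), dtype=float) >= tu * (1 - 1e-9)):
            out.append(f"{c.name}.{label}")
    if model.calcium is not None and np.any(model.calcium.tau >= tu * (1 - 1e-9)):
        out.append("Ca")
    return out


def quasi_static_iv(
    model: NeuronModel,
    v_grid,
    frozen: dict[str, float],
) -> np.ndarray:
    """Steady-state I/V with the named state variables held at fixed values."""
    v = np.atleast_1d(np.asarray(v_grid, dtype=float))
    ca_frozen = frozen.get("Ca")
    if model.calcium is not None:
        ca = ca_frozen if ca_frozen is not None else model.ca_steady(v)
    else:
        ca = None
    i = model.leak_current(v)
    for c in model.currents:
        if not c.gated:
            i = i + c.steady_current(v, ca)
            continue
        m = h = 1.0
        for label, gate in c.gates():
            key = f"{c.name}.{label}"
            val = frozen[key] if key in frozen else gate.x_inf(v, ca)
            if label == "m":
                m = val
            else:
                h = val
        i = i + c.current(v, m, h)
    return i


def find_upstate(
    model: NeuronModel,
    subsystem: str = "slow",
    triplet: Optional[TimescaleTriplet] = None,
    xtol: float = 1e-4,
) -> float:
    """Up-state potential: most depolarized zero of the I/V curve minus I_app.

    ``subsystem="slow"`` (default) freezes the ultraslow variables at the
    resting equilibrium before looking for the zero; ``"static"`` uses the full
    steady-state curve.
    """
    if subsystem not in ("slow", "static"):
        raise ValueError("subsystem must be 'slow' or 'static'")
    frozen: dict[str, float] = {}
    if subsystem == "slow":
        names = ultraslow_variables(model, triplet)
        if names:
            v_rest = resting_potential(model)
            ca_rest = model.ca_steady(v_rest) if model.calcium is not None else None
            for nm in names:
                if nm == "Ca":
                    frozen["Ca"] = float(ca_rest)
                else:
                    cur_name, label = nm.rsplit(".", 1)
                    c = model.current_by_name(cur_name)
                    gate = c.activation if label == "m" else c.inactivation
                    frozen[nm] = float(gate.x_inf(v_rest, ca_rest))

    def fun(v):
        return quasi_static_iv(model, v, frozen) - model.i_app

    roots = _refined_roots(fun, _grid(model), xtol)
    if not roots:
        raise MarkerError(f"{model.name!r}: no zero of the I/V curve in {model.v_range}")
    return roots[-1]


def _scaled(model: NeuronModel, vary: str, alpha: float) -> NeuronModel:
    g0 = model.current_by_name(vary).gbar
    return model.with_gbar(**{vary: alpha * g0})


def _critical_points(model, v_grid, frozen_calcium=None):
    """Interior extrema of the net static current, as (V, F(V)) pairs."""
    slope = static_iv_slope(model, v_grid, frozen_calcium)
    idx = np.flatnonzero(np.sign(slope[:-1]) * np.sign(slope[1:]) < 0)
    out = []
    for j in idx:
        vc = brentq(
            lambda x: float(static_iv_slope(model, np.array([x]), frozen_calcium)[0]),
            v_grid[j],
            v_grid[j + 1],
            xtol=1e-6,
        )
        out.append((vc, float(_net_current(model, np.array([vc]))[0])))
    return out


def find_threshold(
    model: NeuronModel,
    vary: Optional[str] = None,
    alpha_range: tuple[float, float] = (0.0, 10.0),
    alpha_step: float = 0.05,
    xtol: float = 1e-3,
) -> tuple[float, dict]:
    """Spike-threshold potential via a degenerate equilibrium of the I/V curve.

    Scales the maximal conductance of the designated calcium current by alpha
    (the applied current held at its reference value) and finds (V, alpha) with
    I_static(V) - I_app = 0 and dI_static/dV = 0.  Among multiple degenerate
    points the one closest to the reference resting potential is returned.

    Returns (v_th, metadata) where metadata records the varied current, the
    critical scaling alpha and the residuals at the solution.
    """
    if vary is None:
        ca_currents = [c for c in model.currents if c.calcium_carrying]
        if not ca_currents:
            raise MarkerError(f"{model.name!r}: no calcium-carrying current to vary")
        vary = max(ca_currents, key=lambda c: c.gbar).name
    c = model.current_by_name(vary)
    if not c.calcium_carrying:
        raise MarkerError(f"{vary!r} is not calcium-carrying")
    if c.gbar <= 0:
        raise MarkerError(f"{vary!r} has zero reference conductance; cannot scale")

    v_grid = _grid(model)
    alphas = np.arange(alpha_range[0], alpha_range[1] + 0.5 * alpha_step, alpha_step)
    candidates = []  # (v, alpha) seeds where an extremum's net current crosses zero
    prev: list[tuple[float, float]] = []
    prev_alpha = None
    for a in alphas:
        pts = _critical_points(_scaled(model, vary, a), v_grid)
        if prev_alpha is not None:
            for vc, fc in pts:
                # match to the nearest extremum at the previous alpha
                near = [p for p in prev if abs(p[0] - vc) < 5.0]
                if near:
                    v0, f0 = min(near, key=lambda p: abs(p[0] - vc))
                    if f0 * fc <= 0 and (f0 != 0.0 or fc != 0.0):
                        candidates.append((0.5 * (v0 + vc), 0.5 * (prev_alpha + a)))
            # an extremum pair that vanished between alphas also marks a fold of
            # the curve family; the matched-sign-change test covers the generic
            # case, which is all the marker needs.
        prev, prev_alpha = pts, a

    if not candidates:
        raise MarkerError(
            f"{model.name!r}: no degenerate equilibrium found scaling {vary!r} over "
            f"alpha in {alpha_range}; inspect the I/V family"
        )

    def system(x):
        v, a = x
        m = _scaled(model, vary, a)
        return [
            float(_net_current(m, np.array([v]))[0]),
            float(static_iv_slope(m, np.array([v]))[0]),
        ]

    solutions = []
    for v_seed, a_seed in candidates:
        sol = root(system, x0=[v_seed, a_seed], method="hybr", tol=1e-12)
        if sol.success and alpha_range[0] - 1e-6 <= sol.x[1] <= alpha_range[1] + 1e-6:
            v_sol = float(sol.x[0])
            if model.v_range[0] <= v_sol <= model.v_range[1]:
                solutions.append((v_sol, float(sol.x[1]), float(np.max(np.abs(sol.fun)))))
    if not solutions:
        raise MarkerError(f"{model.name!r}: degenerate-equilibrium refinement failed")

    try:
        v_ref = resting_potential(model)
    except MarkerError:
        v_ref = float(np.mean(model.v_range))
    v_th, alpha_c, resid = min(solutions, key=lambda s: abs(s[0] - v_ref))
    meta = {
        "varied": vary,
        "critical_alpha": alpha_c,
        "critical_gbar": alpha_c * c.gbar,
        "residual": resid,
        "reference_rest": v_ref,
    }
    return v_th, meta


def voltage_markers(
    model: NeuronModel,
    vary: Optional[str] = None,
    upstate_subsystem: str = "slow",
) -> VoltageMarkers:
    """Both markers with method metadata."""
    v_th, meta = find_threshold(model, vary=vary)
    v_osc = find_upstate(model, subsystem=upstate_subsystem)
    meta = dict(meta)
    meta["upstate_subsystem"] = upstate_subsystem
    return VoltageMarkers(v_th=v_th, v_osc=v_osc, metadata=meta)
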