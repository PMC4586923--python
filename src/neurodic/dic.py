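"""Dynamic input conductances (DICs) computed analytically from a model.

The total transmembrane current responds to a small voltage step through the
re-equilibration of every gating variable.  Writing the membrane equation as
C dV/dt = -I_total + I_app, the contribution of variable X to the input
conductance is -(dI_total/dX)(dX_inf/dV); splitting each variable across the
fast/slow/ultraslow timescales with the log-distance weights gives

    g_f(V) = -sum_X w_fs^X   (dI/dX)(dX_inf/dV)
    g_s(V) = -sum_X (w_su^X - w_fs^X) (dI/dX)(dX_inf/dV)
    g_u(V) = -sum_X (1 - w_su^X) (dI/dX)(dX_inf/dV)

with g_f + g_s + g_u = g(V), the static (gating-mediated) input conductance.
The sign convention makes regenerative (positive-feedback) pathways positive:
sodium activation contributes positively to g_f, the delayed rectifier
negatively to g_s.  The ungated leak and the instantaneous ohmic conduction
through already-open channels are excluded: they act on the membrane's own
(quasi-instantaneous) timescale, not through gating kinetics.

Calcium-gated channels split further: their activation follows V directly on
its own time constant and indirectly through the equilibrium calcium
concentration Ca_inf(V), which relaxes on the calcium pool's (ultraslow)
timescale.  Both pathways are attributed to the gated channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import NeuronModel
from .timescales import TimescaleTriplet, reference_timescales, weights

__all__ = ["DICSet", "CalciumProfile", "calcium_profile", "dic_curves", "dic_at"]


class CalciumProfile:
    """Equilibrium calcium concentration Ca(V) with its analytic slope.

    Built from a specific model instance; freezing a reference model's profile
    and handing it to another model linearizes the calcium coupling around the
    reference (the "frozen calcium" convention of the sensitivity machinery).
    """

    def __init__(self, model: NeuronModel):
        if model.calcium is None:
            raise ValueError(f"model {model.name!r} has no calcium pool")
        self._model = model
        self._pool = model.calcium

    def __call__(self, v):
        return self._pool.ca_inf(self._model.calcium_current_steady(v))

    def deriv(self, v):
        """dCa_inf/dV from the closed-form slope of the calcium currents."""
        v = np.asarray(v, dtype=float)
        di = np.zeros_like(v)
        for c in self._model.currents:
            if not c.calcium_carrying:
                continue
            di = di + _steady_current_slope(c, v, None)
        return -self._pool.f * di


def _steady_current_slope(c, v, ca_prof=None):
    """d/dV of gbar * m_inf^p * h_inf^q * (V - rev) at gating steady state.

    For calcium-gated channels the chain through Ca(V) is included when a
    calcium profile is supplied.
    """
    from .model_core import PolynomialCurrent

    if isinstance(c, PolynomialCurrent):
        return c.gbar * np.polyval(np.polyder(np.asarray(c.coeffs, dtype=float)), v)
    ca = dca = None
    if any(g.ca_dependent for _, g in c.gates()):
        if ca_prof is None:
            raise ValueError(f"{c.name}: slope of a calcium-gated current needs a profile")
        ca, dca = ca_prof(v), ca_prof.deriv(v)
    m = c.activation.x_inf(v, ca) if c.activation is not None else 1.0
    h = c.inactivation.x_inf(v, ca) if c.inactivation is not None else 1.0
    drive = v - c.reversal
    open_f = c.open_fraction(m, h)
    out = open_f.copy() if isinstance(open_f, np.ndarray) else np.full_like(v, open_f)
    if c.activation is not None:
        p = c.activation.exponent
        q = c.inactivation.exponent if c.inactivation is not None else 0
        dm = c.activation.dxinf_dv(v, ca)
        if c.activation.ca_dependent:
            dm = dm + c.activation.dxinf_dca(v, ca) * dca
        out = out + p * m ** (p - 1) * (h ** q if q else 1.0) * drive * dm
    if c.inactivation is not None:
        q = c.inactivation.exponent
        p = c.activation.exponent if c.activation is not None else 0
        dh = c.inactivation.dxinf_dv(v, ca)
        if c.inactivation.ca_dependent:
            dh = dh + c.inactivation.dxinf_dca(v, ca) * dca
        out = out + q * h ** (q - 1) * (m ** p if p else 1.0) * drive * dh
    return c.gbar * out


def static_iv_slope(model: NeuronModel, v, frozen_calcium: Optional[CalciumProfile] = None):
    """dI_static/dV in mS/cm2, including the calcium chain of Ca-gated channels."""
    v = np.asarray(v, dtype=float)
    ca_prof = frozen_calcium
    if ca_prof is None and model.calcium is not None:
        ca_prof = CalciumProfile(model)
    out = np.full_like(v, model.leak_g)
    for c in model.currents:
        out = out + _steady_current_slope(c, v, ca_prof)
    return out


def channel_pathways(
    model: NeuronModel,
    current_name: str,
    v: np.ndarray,
    triplet: TimescaleTriplet,
    ca_prof: Optional[CalciumProfile],
):
    """Per-unit-gbar timescale split for one channel: a (3, n) array.

    Rows are the fast/slow/ultraslow contributions of all of the channel's
    gating pathways per unit maximal conductance; multiplying by gbar gives the
    channel's additive contribution to (g_f, g_s, g_u).
    """
    c = model.current_by_name(current_name)
    v = np.asarray(v, dtype=float)
    out = np.zeros((3, v.size))
    if not c.gated:
        return out
    ca = ca_prof(v) if ca_prof is not None else None
    m = c.activation.x_inf(v, ca) if c.activation is not None else 1.0
    h = c.inactivation.x_inf(v, ca) if c.inactivation is not None else 1.0
    drive = v - c.reversal
    for label, gate in c.gates():
        if label == "m":
            p = gate.exponent
            q = c.inactivation.exponent if c.inactivation is not None else 0
            dI_dx = p * m ** (p - 1) * (h ** q if q else 1.0) * drive
        else:
            q = gate.exponent
            p = c.activation.exponent if c.activation is not None else 0
            dI_dx = q * h ** (q - 1) * (m ** p if p else 1.0) * drive
        base = -dI_dx * gate.dxinf_dv(v, ca)
        w_fs, w_su = weights(gate.tau, triplet, v)
        out[0] += w_fs * base
        out[1] += (w_su - w_fs) * base
        out[2] += (1.0 - w_su) * base
        if gate.ca_dependent:
            if ca_prof is None:
                raise ValueError("calcium-gated channel needs a calcium profile")
            base_ca = -dI_dx * gate.dxinf_dca(v, ca) * ca_prof.deriv(v)
            w_fs_ca, w_su_ca = weights(model.calcium.tau, triplet, v)
            out[0] += w_fs_ca * base_ca
            out[1] += (w_su_ca - w_fs_ca) * base_ca
            out[2] += (1.0 - w_su_ca) * base_ca
    return out


@dataclass
class DICSet:
    """The four voltage-indexed conductance curves plus per-channel split."""

    v_grid: np.ndarray
    g_f: np.ndarray
    g_s: np.ndarray
    g_u: np.ndarray
    g_total: np.ndarray
    per_channel: dict[str, np.ndarray]  # name -> (3, n) additive contribution

    def at(self, v: float) -> tuple[float, float, float, float]:
        """Values at a grid point (exact) or by linear interpolation."""
        j = np.searchsorted(self.v_grid, v)
        if j < self.v_grid.size and abs(self.v_grid[j] - v) < 1e-9:
            return (
                float(self.g_f[j]),
                float(self.g_s[j]),
                float(self.g_u[j]),
                float(self.g_total[j]),
            )
        return tuple(
            float(np.interp(v, self.v_grid, c))
            for c in (self.g_f, self.g_s, self.g_u, self.g_total)
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "v_mV": self.v_grid,
            "g_f": self.g_f,
            "g_s": self.g_s,
            "g_u": self.g_u,
            "g_total": self.g_total,
        }
        for name, arr in self.per_channel.items():
            for j, ts in enumerate(("f", "s", "u")):
                cols[f"{name}_g{ts}"] = arr[j]
        return pd.DataFrame(cols)


def default_grid(model: NeuronModel, step: float = 0.1) -> np.ndarray:
    lo, hi = model.v_range
    return np.arange(lo, hi + 0.5 * step, step)


def dic_curves(
    model: NeuronModel,
    v_grid=None,
    triplet: Optional[TimescaleTriplet] = None,
    frozen_calcium: Optional[CalciumProfile] = None,
) -> DICSet:
    """Analytic fast/slow/ultraslow input conductance curves (mS/cm2).

    ``frozen_calcium`` evaluates calcium-gated channels against a fixed
    reference calcium profile instead of the model's own equilibrium calcium;
    the DICs are then exactly linear in every maximal conductance.
    """
    if v_grid is None:
        v_grid = default_grid(model)
    v = np.atleast_1d(np.asarray(v_grid, dtype=float))
    model.check_v(v)
    if triplet is None:
        triplet = reference_timescales(model)
    ca_prof = frozen_calcium
    if ca_prof is None and model.calcium is not None:
        ca_prof = calcium_profile(model)
    per_channel = {}
    for c in model.currents:
        if not c.gated:
            continue
        per_channel[c.name] = c.gbar * channel_pathways(model, c.name, v, triplet, ca_prof)
    if per_channel:
        stack = np.sum([arr for arr in per_channel.values()], axis=0)
    else:
        stack = np.zeros((3, v.size))
    g_f, g_s, g_u = stack
    g_total = stack.sum(axis=0)
    return DICSet(v, g_f, g_s, g_u, g_total, per_channel)


def calcium_profile(model: NeuronModel) -> CalciumProfile:
    """The model's own equilibrium calcium profile Ca_inf(V)."""
    return CalciumProfile(model)


def dic_at(
    model: NeuronModel,
    v: float,
    triplet: Optional[TimescaleTriplet] = None,
    frozen_calcium: Optional[CalciumProfile] = None,
) -> tuple[float, float, float, float]:
    """(g_f, g_s, g_u, g) at one potential, consistent with dic_curves."""
    ds = dic_curves(model, np.array([float(v)]), triplet, frozen_calcium)
    return (float(ds.g_f[0]), float(ds.g_s[0]), float(ds.g_u[0]), float(ds.g_total[0]))
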