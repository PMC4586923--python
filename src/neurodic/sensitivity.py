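"""Per-channel sensitivity of the dynamic input conductances.

Because each DIC is (under the frozen-calcium convention) linear in every
maximal conductance, the sensitivity of g_j to channel i is simply channel i's
timescale-split pathway term per unit gbar:

    dg_f/dgbar_i = -[ w_fs^m p m^(p-1) h^q (V - V_i) dm_inf/dV
                      + w_fs^h m^p q h^(q-1) (V - V_i) dh_inf/dV ]

and analogously for the slow (w_su - w_fs) and ultraslow (1 - w_su) shares.
The curves are independent of gbar_i itself.  For calcium-gated channels the
indirect pathway through the equilibrium calcium profile is included, with the
profile frozen at the reference model's calcium (so the linearity is exact);
the cross-dependence of that profile on the calcium-channel conductances is
deliberately excluded from the analytic curves.

Normalized "localization" curves (each divided by its maximum absolute value)
sketch where on the voltage axis each channel acts, amplitude differences
aside; colocalization of two channels' curves is what makes one channel able
to compensate for the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .dic import CalciumProfile, channel_pathways, default_grid
from .markers import VoltageMarkers, voltage_markers
from .model_core import NeuronModel
from .timescales import TimescaleTriplet, reference_timescales

__all__ = [
    "SensitivityTable",
    "sensitivity_curves",
    "static_iv_sensitivity",
    "sensitivity_at_markers",
    "shift_activation",
    "colocalization_score",
]

_TS = ("f", "s", "u")


def sensitivity_curves(
    model: NeuronModel,
    current: str,
    v_grid=None,
    triplet: Optional[TimescaleTriplet] = None,
    frozen_calcium: Optional[CalciumProfile] = None,
) -> np.ndarray:
    """(3, n) array of dg_f/dgbar, dg_s/dgbar, dg_u/dgbar for one channel."""
    if v_grid is None:
        v_grid = default_grid(model)
    v = np.atleast_1d(np.asarray(v_grid, dtype=float))
    model.check_v(v)
    if triplet is None:
        triplet = reference_timescales(model)
    ca_prof = frozen_calcium
    if ca_prof is None and model.calcium is not None:
        ca_prof = CalciumProfile(model)
    return channel_pathways(model, current, v, triplet, ca_prof)


def static_iv_sensitivity(
    model: NeuronModel,
    current: str,
    v,
    frozen_calcium: Optional[CalciumProfile] = None,
) -> np.ndarray:
    """dI_static/dgbar_i = m_inf^p h_inf^q (V - V_i), per unit conductance."""
    c = model.current_by_name(current)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    ca = None
    if any(g.ca_dependent for _, g in c.gates()):
        ca_prof = frozen_calcium or CalciumProfile(model)
        ca = ca_prof(v)
    m = c.activation.x_inf(v, ca) if c.activation is not None else 1.0
    h = c.inactivation.x_inf(v, ca) if c.inactivation is not None else 1.0
    return c.open_fraction(m, h) * (v - c.reversal)


@dataclass
class SensitivityTable:
    """All per-channel, per-timescale sensitivity curves plus marker values."""

    v_grid: np.ndarray
    curves: dict[str, np.ndarray]  # name -> (3, n)
    markers: Optional[VoltageMarkers] = None
    at_markers: Optional[pd.DataFrame] = None  # rows: channel, columns: g{f,s,u}@{th,osc}
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {"v_mV": self.v_grid}
        for name, arr in self.curves.items():
            for j, ts in enumerate(_TS):
                cols[f"dg{ts}_dgbar_{name}"] = arr[j]
        return pd.DataFrame(cols)


def sensitivity_at_markers(
    model: NeuronModel,
    markers: Optional[VoltageMarkers] = None,
    v_grid=None,
) -> SensitivityTable:
    """Sensitivity curves for every gated channel, their values at V_th and
    V_osc, and max-abs-normalized localization curves."""
    if markers is None:
        markers = voltage_markers(model)
    if v_grid is None:
        v_grid = default_grid(model)
    v = np.atleast_1d(np.asarray(v_grid, dtype=float))
    triplet = reference_timescales(model)
    ca_prof = CalciumProfile(model) if model.calcium is not None else None
    names = [c.name for c in model.currents if c.gated]
    curves = {nm: channel_pathways(model, nm, v, triplet, ca_prof) for nm in names}
    vm = np.array([markers.v_th, markers.v_osc])
    rows = {}
    for nm in names:
        at = channel_pathways(model, nm, vm, triplet, ca_prof)
        rows[nm] = {
            f"dg{ts}_at_{where}": float(at[j, k])
            for j, ts in enumerate(_TS)
            for k, where in enumerate(("vth", "vosc"))
        }
    table = SensitivityTable(
        v_grid=v,
        curves=curves,
        markers=markers,
        at_markers=pd.DataFrame(rows).T,
    )
    for nm, arr in curves.items():
        norm = np.empty_like(arr)
        for j in range(3):
            peak = np.max(np.abs(arr[j]))
            if peak == 0.0:
                table.flags.append(f"{nm}:g{_TS[j]}:all-zero, normalization skipped")
                norm[j] = arr[j]
            else:
                norm[j] = arr[j] / peak
        table.normalized[nm] = norm
    return table


def shift_activation(
    model: NeuronModel, current: str, gate: str, delta_mv: float
) -> NeuronModel:
    """A copy of the model with one gate's steady state and time constant
    translated by ``delta_mv`` along the voltage axis (positive = rightward,
    toward more depolarized potentials).  The original model is untouched."""
    c = model.current_by_name(current)
    if gate == "activation":
        if c.activation is None:
            raise KeyError(f"{current!r} has no activation gate")
        new_c = replace(c, activation=c.activation.shifted(delta_mv))
    elif gate == "inactivation":
        if c.inactivation is None:
            raise KeyError(f"{current!r} has no inactivation gate")
        new_c = replace(c, inactivation=c.inactivation.shifted(delta_mv))
    else:
        raise KeyError("gate must be 'activation' or 'inactivation'")
    currents = tuple(new_c if cc.name == current else cc for cc in model.currents)
    return replace(model, currents=currents)


def colocalization_score(
    model: NeuronModel,
    name_a: str,
    name_b: str,
    timescale: str = "s",
    v_grid=None,
) -> float:
    """Overlap of two channels' normalized sensitivity curves in one timescale.

    The inner product of the L2-normalized curves (cosine similarity), in
    magnitude: two curves localized over the same voltage range score near 1
    regardless of their signs and amplitudes -- a negative-feedback channel
    can compensate a positive-feedback one exactly where they overlap.
    """
    if v_grid is None:
        v_grid = default_grid(model)
    v = np.atleast_1d(np.asarray(v_grid, dtype=float))
    triplet = reference_timescales(model)
    ca_prof = CalciumProfile(model) if model.calcium is not None else None
    j = _TS.index(timescale)

    def curve(nm):
        arr = channel_pathways(model, nm, v, triplet, ca_prof)[j]
        norm = np.sqrt(np.trapezoid(arr * arr, v))
        if norm == 0:
            raise ValueError(f"{nm}: zero sensitivity in timescale {timescale!r}")
        return arr / norm

    na, nb = curve(name_a), curve(name_b)
    return float(abs(np.trapezoid(na * nb, v)))
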