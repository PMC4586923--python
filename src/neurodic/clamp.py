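"""Simulated voltage-clamp measurement of the dynamic input conductances.

The membrane potential is held at V*, the model is equilibrated, and a small
step of ``delta_v`` (1 mV by default) is applied while the total transmembrane
current is recorded.  Three values are read off the transient:

* I_f -- minimum of the current within 2 ms of the step onset (fast window),
* I_s -- minimum between 10 and 100 ms (slow window); if the minimum sits at
  the 10 ms boundary there is no interior minimum and the 10 ms amplitude is
  taken (flagged),
* I_u -- minimum from 1 s to the end of the stimulation (ultraslow window),

and with I_0 the first current sample after the onset (which includes the
instantaneous ohmic jump through already-open channels, so the passive
component is excluded from the dynamic currents):

    dI_f = I_f - I_0,  dI_s = I_s - I_f,  dI_u = I_u - I_s,  dI = I_u - I_0

The conductance estimates, attributed to the midpoint potential, are
g_j(V* + dV/2) = -dI_j / dV for j in {f, s, u}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dic import DICSet
from .errors import SolverError, WindowError
from .model_core import NeuronModel, Trace

__all__ = ["ClampProtocol", "ClampExtraction", "run_clamp_step", "extract", "measure_dics"]


@dataclass(frozen=True)
class ClampProtocol:
    """Step protocol and sampling for the simulated voltage clamp."""

    # default holds span rest to spike threshold; above threshold the slow
    # calcium pool has not equilibrated by the end of the ultraslow window
    # and the measured g_u is biased low (see docs/methods.md)
    v_holds: Sequence[float] = tuple(np.arange(-75.0, -47.9, 3.0))
    delta_v: float = 1.0
    hold_duration: float = 60000.0  # ms; cap for numerical equilibration
    step_duration: float = 5000.0  # ms; must cover the ultraslow window
    sample_dt: float = 0.05  # ms, dense grid before t_switch
    sample_dt_late: float = 1.0  # ms after t_switch
    t_switch: float = 10.0

    def __post_init__(self):
        if self.delta_v == 0:
            raise ValueError("delta_v must be nonzero")
        if self.step_duration <= 1000.0:
            raise ValueError("step_duration must exceed 1000 ms (ultraslow window)")

    def time_grid(self) -> np.ndarray:
        early = np.arange(0.0, self.t_switch, self.sample_dt)
        late = np.arange(self.t_switch, self.step_duration + 0.5 * self.sample_dt_late,
                         self.sample_dt_late)
        return np.concatenate([early, late])


@dataclass
class ClampExtraction:
    """Window currents and dynamic currents from one clamp step (uA/cm2)."""

    v_hold: float
    delta_v: float
    i0: float
    i_f: float
    i_s: float
    i_u: float
    di_f: float
    di_s: float
    di_u: float
    di_static: float
    flags: list[str] = field(default_factory=list)

    @property
    def conductances(self) -> tuple[float, float, float, float]:
        """(g_f, g_s, g_u, g) = -dI_j/dV at V_hold + dV/2."""
        dv = self.delta_v
        return (-self.di_f / dv, -self.di_s / dv, -self.di_u / dv, -self.di_static / dv)


def run_clamp_step(
    model: NeuronModel,
    v_hold: float,
    delta_v: Optional[float] = None,
    protocol: Optional[ClampProtocol] = None,
    rtol: float = 1e-8,
) -> Trace:
    """Clamp at v_hold (equilibrated), step to v_hold + delta_v, record current.

    The potential is algebraically clamped: only gating and calcium states
    evolve.  Equilibration at the hold potential uses the model's closed-form
    steady state, whose residual is checked against the state derivative.
    Returns a Trace whose ``current`` is the total transmembrane current and
    whose time origin is the step onset.
    """
    protocol = protocol or ClampProtocol()
    dv = protocol.delta_v if delta_v is None else delta_v
    model.check_v(v_hold)
    v_step = v_hold + dv
    model.check_v(v_step)
    y0 = model.state_vector(v_hold)
    resid = np.max(np.abs(model.state_derivative(v_hold, y0))) if y0.size else 0.0
    if resid > 1e-9:
        raise SolverError(f"hold-state residual {resid:.2e} exceeds equilibration tolerance")
    t_eval = protocol.time_grid()
    if y0.size == 0:
        # nothing evolves: current is constant after the instantaneous jump
        i_const = float(model.total_current(v_step, y0))
        current = np.full_like(t_eval, i_const)
        return Trace(time=t_eval, voltage=np.full_like(t_eval, v_step), current=current)
    sol = solve_ivp(
        lambda t, y: model.state_derivative(v_step, y),
        (0.0, protocol.step_duration),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-10,
    )
    if not sol.success:
        raise SolverError(f"clamped integration failed: {sol.message}")
    current = np.array([model.total_current(v_step, sol.y[:, j]) for j in range(sol.t.size)])
    state = {n: sol.y[k] for k, n in enumerate(model.state_names)}
    return Trace(time=sol.t, voltage=np.full_like(sol.t, v_step), state=state, current=current)


def extract(
    trace: Trace,
    protocol: Optional[ClampProtocol] = None,
    v_hold: Optional[float] = None,
) -> ClampExtraction:
    """Window currents from a clamp-step current trace (time origin = onset)."""
    protocol = protocol or ClampProtocol()
    if trace.current is None:
        raise WindowError("trace carries no current samples")
    t = trace.time - trace.time[0]
    i = np.asarray(trace.current, dtype=float)
    if t[-1] < 1000.0:
        raise WindowError(f"trace ends at {t[-1]:.1f} ms, before the 1 s ultraslow window")
    flags: list[str] = []
    i0 = float(i[0])

    fast = (t > 0) & (t <= 2.0)
    if not np.any(fast):
        raise WindowError("no samples in the (0, 2] ms fast window")
    i_f = float(np.min(i[fast]))

    slow = (t >= 10.0) & (t <= 100.0)
    if not np.any(slow):
        raise WindowError("no samples in the [10, 100] ms slow window")
    slow_idx = np.flatnonzero(slow)
    j_min = slow_idx[np.argmin(i[slow_idx])]
    if j_min == slow_idx[0]:
        # monotonically rising window: no interior minimum, take the 10 ms value
        flags.append("slow_window_no_local_min")
        i_s = float(np.interp(10.0, t, i))
    else:
        i_s = float(i[j_min])

    ultra = t >= 1000.0
    i_u = float(np.min(i[ultra]))

    di_f = i_f - i0
    di_s = i_s - i_f
    di_u = i_u - i_s
    return ClampExtraction(
        v_hold=float(v_hold) if v_hold is not None else float(trace.voltage[0]),
        delta_v=protocol.delta_v,
        i0=i0,
        i_f=i_f,
        i_s=i_s,
        i_u=i_u,
        di_f=di_f,
        di_s=di_s,
        di_u=di_u,
        di_static=i_u - i0,
        flags=flags,
    )


def measure_dics(
    model: NeuronModel,
    protocol: Optional[ClampProtocol] = None,
    return_extractions: bool = False,
):
    """Voltage-clamp estimate of the DICs at V* + dV/2 for every hold in the
    protocol.  Returns a DICSet (per-channel breakdown is not observable in a
    clamp experiment, so ``per_channel`` is empty); with
    ``return_extractions=True`` also the per-hold ClampExtraction records.
    """
    protocol = protocol or ClampProtocol()
    rows, extractions = [], []
    for v_hold in protocol.v_holds:
        tr = run_clamp_step(model, v_hold, protocol.delta_v, protocol)
        ex = extract(tr, protocol, v_hold=v_hold)
        extractions.append(ex)
        rows.append(ex.conductances)
    arr = np.asarray(rows, dtype=float)
    ds = DICSet(
        v_grid=np.asarray(protocol.v_holds, dtype=float) + 0.5 * protocol.delta_v,
        g_f=arr[:, 0],
        g_s=arr[:, 1],
        g_u=arr[:, 2],
        g_total=arr[:, 3],
        per_channel={},
    )
    return (ds, extractions) if return_extractions else ds
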