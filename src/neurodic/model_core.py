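"""Conductance-based neuron models: state, steady states, I/V curve, simulation.

A model is a collection of ionic currents of the form

    I_i = gbar_i * m_i^p * h_i^q * (V - V_i)

plus an ungated leak, an optional intracellular calcium pool, a membrane
capacitance and a constant applied current.  The membrane equation is

    C dV/dt = -(sum_i I_i + I_leak) + I_app

Units are fixed globally: mV, ms, mS/cm2, uA/cm2, uF/cm2, uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import RangeError, SolverError
from .kinetics import CalciumGatedSigmoid, KineticsFunction

__all__ = [
    "GatingVariable",
    "IonicCurrent",
    "PolynomialCurrent",
    "CalciumPool",
    "NeuronModel",
    "Trace",
    "SpikeStatistics",
    "steady_state",
    "static_iv",
    "simulate",
    "trace_statistics",
]


@dataclass(frozen=True)
class GatingVariable:
    """One first-order gating variable with voltage-dependent kinetics.

    ``steady_state`` maps V -> [0, 1] (or (V, Ca) -> [0, 1] when calcium
    dependent); ``time_constant`` maps V -> tau in ms.
    """

    name: str
    role: str  # "activation" | "inactivation"
    exponent: int
    steady_state: KineticsFunction
    time_constant: KineticsFunction

    def __post_init__(self):
        if self.role not in ("activation", "inactivation"):
            raise ValueError(f"gating role must be activation|inactivation, got {self.role!r}")
        if self.exponent < 1:
            raise ValueError("gating exponent must be a positive integer")

    @property
    def ca_dependent(self) -> bool:
        return isinstance(self.steady_state, CalciumGatedSigmoid)

    def x_inf(self, v, ca=None):
        if self.ca_dependent:
            if ca is None:
                raise ValueError(f"{self.name}: calcium-dependent gate needs a Ca value")
            return self.steady_state(v, ca)
        return self.steady_state(v)

    def dxinf_dv(self, v, ca=None):
        """Partial of the steady state w.r.t. V (at fixed Ca when Ca-dependent)."""
        if self.ca_dependent:
            return self.steady_state.deriv_v(v, ca)
        return self.steady_state.deriv(v)

    def dxinf_dca(self, v, ca):
        if not self.ca_dependent:
            return np.zeros_like(np.asarray(v, dtype=float))
        return self.steady_state.deriv_ca(v, ca)

    def tau(self, v):
        return self.time_constant(v)

    def shifted(self, delta_mv: float) -> "GatingVariable":
        return replace(
            self,
            steady_state=self.steady_state.shifted(delta_mv),
            time_constant=self.time_constant.shifted(delta_mv),
        )


@dataclass(frozen=True)
class IonicCurrent:
    """gbar * m^p * h^q * (V - reversal); h == 1 when there is no inactivation."""

    name: str
    gbar: float
    reversal: float
    activation: Optional[GatingVariable] = None
    inactivation: Optional[GatingVariable] = None
    polarity: str = "depolarizing"  # sign of the typical contribution
    calcium_carrying: bool = False
    nonphysiological: bool = False  # set when force-built with gbar < 0

    def __post_init__(self):
        if self.gbar < 0 and not self.nonphysiological:
            raise ValueError(
                f"{self.name}: negative maximal conductance requires nonphysiological=True"
            )
        if self.polarity not in ("depolarizing", "repolarizing"):
            raise ValueError("polarity must be depolarizing|repolarizing")

    @property
    def gated(self) -> bool:
        return self.activation is not None or self.inactivation is not None

    def gates(self):
        if self.activation is not None:
            yield "m", self.activation
        if self.inactivation is not None:
            yield "h", self.inactivation

    def open_fraction(self, m=1.0, h=1.0):
        f = 1.0
        if self.activation is not None:
            f = f * np.asarray(m, dtype=float) ** self.activation.exponent
        if self.inactivation is not None:
            f = f * np.asarray(h, dtype=float) ** self.inactivation.exponent
        return f

    def current(self, v, m=1.0, h=1.0):
        return self.gbar * self.open_fraction(m, h) * (np.asarray(v, dtype=float) - self.reversal)

    def steady_current(self, v, ca=None):
        m = self.activation.x_inf(v, ca) if self.activation is not None else 1.0
        h = self.inactivation.x_inf(v, ca) if self.inactivation is not None else 1.0
        return self.current(v, m, h)

    def with_gbar(self, gbar: float) -> "IonicCurrent":
        return replace(self, gbar=float(gbar), nonphysiological=gbar < 0)


@dataclass(frozen=True)
class PolynomialCurrent(IonicCurrent):
    """Instantaneous current gbar * P(V); an analytic-toy construct.

    Carries no gating, so it contributes to the static I/V curve and to the
    membrane equation but not to the dynamic input conductances.
    ``coeffs`` are numpy polyval coefficients (highest power first).
    """

    coeffs: Sequence[float] = (0.0,)

    def open_fraction(self, m=1.0, h=1.0):  # pragma: no cover - not meaningful
        return 1.0

    def current(self, v, m=1.0, h=1.0):
        return self.gbar * np.polyval(self.coeffs, np.asarray(v, dtype=float))

    def steady_current(self, v, ca=None):
        return self.current(v)


@dataclass(frozen=True)
class CalciumPool:
    """First-order intracellular calcium balance.

    tau_ca * dCa/dt = -f * sum(I_Ca) - Ca + c_rest

    ``f`` converts a calcium current density (uA/cm2) into uM; inward calcium
    current (negative) raises Ca.  ``tau`` is a model constant in ms.
    """

    tau: float = 200.0
    f: float = 9.3952
    c_rest: float = 0.05

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("calcium pool time constant must be positive")

    def ca_inf(self, i_ca):
        """Equilibrium concentration for a given total calcium current density."""
        return self.c_rest - self.f * np.asarray(i_ca, dtype=float)

    def dca_dt(self, i_ca, ca):
        return (-self.f * i_ca - ca + self.c_rest) / self.tau


@dataclass(frozen=True)
class NeuronModel:
    currents: tuple[IonicCurrent, ...]
    leak_g: float
    leak_e: float
    capacitance: float = 1.0
    calcium: Optional[CalciumPool] = None
    i_app: float = 0.0
    v_range: tuple[float, float] = (-80.0, 50.0)
    timescales: Optional[dict] = None  # {"fast": ("Na","m"), ...} designation metadata
    name: str = "model"
    info: dict = field(default_factory=dict, compare=False)  # fixture ground truth etc.

    def __post_init__(self):
        object.__setattr__(self, "currents", tuple(self.currents))
        names = [c.name for c in self.currents]
        if len(set(names)) != len(names):
            raise ValueError(f"current names must be unique, got {names}")
        for c in self.currents:
            for _, gate in c.gates():
                if gate.ca_dependent and self.calcium is None:
                    raise ValueError(
                        f"{c.name}: calcium-dependent gating requires a calcium pool"
                    )
                if gate.ca_dependent and c.calcium_carrying:
                    raise ValueError(
                        f"{c.name}: calcium-carrying current may not be calcium-gated"
                    )

    # ------------------------------------------------------------------ state

    @property
    def state_names(self) -> list[str]:
        names = [f"{c.name}.{label}" for c in self.currents for label, _ in c.gates()]
        if self.calcium is not None:
            names.append("Ca")
        return names

    def current_by_name(self, name: str) -> IonicCurrent:
        for c in self.currents:
            if c.name == name:
                return c
        raise KeyError(f"no current named {name!r}; have {[c.name for c in self.currents]}")

    def gating_entries(self):
        """Yield (state_index, current, gate_label, GatingVariable)."""
        i = 0
        for c in self.currents:
            for label, gate in c.gates():
                yield i, c, label, gate
                i += 1

    @property
    def n_states(self) -> int:
        n = sum(1 for _ in self.gating_entries())
        return n + (1 if self.calcium is not None else 0)

    def check_v(self, v):
        v = np.asarray(v, dtype=float)
        lo, hi = self.v_range
        if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
            raise RangeError(
                f"potential {v if v.ndim == 0 else [float(np.min(v)), float(np.max(v))]} mV "
                f"outside working range {self.v_range}"
            )
        return v

    # --------------------------------------------------------------- currents

    def calcium_current_steady(self, v):
        """Total calcium-carrying current with gating at steady state."""
        i_ca = np.zeros_like(np.asarray(v, dtype=float))
        for c in self.currents:
            if c.calcium_carrying:
                i_ca = i_ca + c.steady_current(v)
        return i_ca

    def ca_steady(self, v):
        """Equilibrium calcium concentration as a function of potential."""
        if self.calcium is None:
            return None
        return self.calcium.ca_inf(self.calcium_current_steady(v))

    def leak_current(self, v):
        return self.leak_g * (np.asarray(v, dtype=float) - self.leak_e)

    def total_current(self, v, y):
        """Total transmembrane current (ionic + leak) at potential v, state y."""
        y = np.asarray(y, dtype=float)
        i_tot = self.leak_current(v)
        idx = 0
        for c in self.currents:
            m = h = 1.0
            for label, _ in c.gates():
                if label == "m":
                    m = y[idx]
                else:
                    h = y[idx]
                idx += 1
            i_tot = i_tot + c.current(v, m, h)
        return i_tot

    def state_vector(self, v, ca=None) -> np.ndarray:
        """All gating at steady state for potential v; calcium at ca (or Ca_inf)."""
        if self.calcium is not None and ca is None:
            ca = self.ca_steady(v)
        y = np.empty(self.n_states)
        for i, _, _, gate in self.gating_entries():
            y[i] = gate.x_inf(v, ca)
        if self.calcium is not None:
            y[-1] = ca
        return y

    # ------------------------------------------------------------- derivative

    def state_derivative(self, v, y):
        """d/dt of gating and calcium states at (possibly clamped) potential v."""
        dy = np.empty_like(y)
        ca = y[-1] if self.calcium is not None else None
        i_ca = 0.0
        idx = 0
        for c in self.currents:
            m = h = 1.0
            for label, gate in c.gates():
                x = y[idx]
                dy[idx] = (gate.x_inf(v, ca) - x) / gate.tau(v)
                if label == "m":
                    m = x
                else:
                    h = x
                idx += 1
            if c.calcium_carrying:
                i_ca += c.current(v, m, h)
        if self.calcium is not None:
            dy[-1] = self.calcium.dca_dt(i_ca, ca)
        return dy

    def rhs(self, i_app: Callable[[float], float]):
        """Full membrane + state right-hand side; y = [V, states...]."""

        def f(t, y):
            v = y[0]
            dy = np.empty_like(y)
            dy[1:] = self.state_derivative(v, y[1:])
            i_tot = self.total_current(v, y[1:])
            dy[0] = (-(i_tot) + i_app(t)) / self.capacitance
            return dy

        return f

    # ---------------------------------------------------------------- editing

    def with_gbar(self, **gbars) -> "NeuronModel":
        """A copy with some maximal conductances replaced (name=value)."""
        known = {c.name for c in self.currents}
        unknown = set(gbars) - known
        if unknown:
            raise KeyError(f"unknown current name(s) {sorted(unknown)}; have {sorted(known)}")
        new = tuple(
            c.with_gbar(gbars[c.name]) if c.name in gbars else c for c in self.currents
        )
        return replace(self, currents=new)

    def with_i_app(self, i_app: float) -> "NeuronModel":
        return replace(self, i_app=float(i_app))


@dataclass
class Trace:
    """Simulated time series on a strictly increasing grid (ms)."""

    time: np.ndarray
    voltage: np.ndarray
    state: dict[str, np.ndarray] = field(default_factory=dict)
    current: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.size == 0:
            raise ValueError("trace may not be empty")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time grid must be strictly increasing")
        for k, v in self.state.items():
            if len(v) != len(self.time):
                raise ValueError(f"state {k!r} length differs from time grid")
        if self.current is not None and len(self.current) != len(self.time):
            raise ValueError("current length differs from time grid")


# ------------------------------------------------------------------ operations


def steady_state(model: NeuronModel, v: float) -> dict[str, float]:
    """Full state map at potential v: gating at X_inf(v), calcium at Ca_inf(v)."""
    model.check_v(v)
    y = model.state_vector(v)
    return dict(zip(model.state_names, (float(x) for x in y)))


def static_iv(
    model: NeuronModel,
    v_grid,
    include_i_app: bool = False,
    frozen_calcium: Optional[Callable] = None,
) -> np.ndarray:
    """Total steady-state membrane current I_static(V) in uA/cm2.

    ``frozen_calcium`` optionally supplies Ca(V) in place of the model's own
    equilibrium calcium (used by the compensation machinery, which linearizes
    around a fixed reference calcium profile).
    """
    v = np.atleast_1d(np.asarray(v_grid, dtype=float))
    if v.size == 0:
        raise ValueError("empty potential grid")
    model.check_v(v)
    if model.calcium is not None:
        ca = frozen_calcium(v) if frozen_calcium is not None else model.ca_steady(v)
    else:
        ca = None
    i = model.leak_current(v)
    for c in model.currents:
        i = i + c.steady_current(v, ca)
    if include_i_app:
        i = i - model.i_app
    out = np.asarray(i, dtype=float)
    return out if np.ndim(v_grid) else float(out[0])


def simulate(
    model: NeuronModel,
    duration: float,
    i_app=None,
    dt_out: float = 0.1,
    v0: float = -65.0,
    y0: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trace:
    """Integrate the full membrane equation for ``duration`` ms.

    ``i_app`` is a constant (uA/cm2) or a callable of time; default is the
    model's own applied current.  Initial state is the gating/calcium steady
    state at ``v0`` unless a full state vector ``y0`` is given.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if i_app is None:
        i_app = model.i_app
    i_fun = i_app if callable(i_app) else (lambda t, _i=float(i_app): _i)
    if y0 is None:
        y0 = np.concatenate([[v0], model.state_vector(v0)])
    t_eval = np.arange(0.0, duration + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], duration)
    sol = solve_ivp(
        model.rhs(i_fun),
        (0.0, duration),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"integration of {model.name!r} failed at t={sol.t[-1] if sol.t.size else 0:.3f} ms: "
            f"{sol.message}"
        )
    state = {n: sol.y[1 + k] for k, n in enumerate(model.state_names)}
    current = np.array(
        [model.total_current(sol.y[0, j], sol.y[1:, j]) for j in range(sol.t.size)]
    )
    return Trace(time=sol.t, voltage=sol.y[0], state=state, current=current)


@dataclass
class SpikeStatistics:
    spike_times: np.ndarray
    isis: np.ndarray
    bursts: list[np.ndarray]  # spike times per burst
    burst_isis: list[np.ndarray]  # ISIs within each burst
    burst_period: Optional[float]  # mean interval between burst onsets, ms
    duty_cycle: Optional[float]  # mean burst duration / burst period

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def spikes_per_burst(self) -> np.ndarray:
        return np.array([b.size for b in self.bursts], dtype=int)


def trace_statistics(
    trace: Trace,
    spike_threshold: float = 0.0,
    burst_gap: Optional[float] = None,
    refractory: float = 2.0,
) -> SpikeStatistics:
    """Spike and burst statistics by upward threshold crossing.

    Spikes are upward crossings of ``spike_threshold`` (linear interpolation
    within the sample step) separated by at least ``refractory`` ms.  Bursts
    are maximal spike groups separated by gaps larger than ``burst_gap``
    (default: 5x the median ISI).  A spikeless trace yields empty statistics.
    """
    t, v = trace.time, trace.voltage
    above = v >= spike_threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    for j in idx:
        frac = (spike_threshold - v[j]) / (v[j + 1] - v[j])
        tc = t[j] + frac * (t[j + 1] - t[j])
        if not times or tc - times[-1] >= refractory:
            times.append(tc)
    spike_times = np.asarray(times)
    isis = np.diff(spike_times)
    if spike_times.size < 2:
        bursts = [spike_times] if spike_times.size else []
        return SpikeStatistics(spike_times, isis, bursts, [np.array([])] * len(bursts), None, None)
    if burst_gap is None:
        burst_gap = 5.0 * float(np.median(isis))
    splits = np.flatnonzero(isis > burst_gap) + 1
    bursts = np.split(spike_times, splits)
    burst_isis = [np.diff(b) for b in bursts]
    if len(bursts) >= 2:
        onsets = np.array([b[0] for b in bursts])
        period = float(np.mean(np.diff(onsets)))
        # last burst may be truncated by the end of the trace; use full bursts
        durations = np.array([b[-1] - b[0] for b in bursts[:-1]])
        duty = float(np.mean(durations) / period) if period > 0 else None
    else:
        period = duty = None
    return SpikeStatistics(spike_times, isis, bursts, burst_isis, period, duty)
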