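"""Reference timescales and per-variable timescale weights.

Neuronal activity is decomposed into three representative timescales:

* fast      -- the activation time constant of the fastest depolarizing
               current (spike upstroke),
* slow      -- the activation time constant of the fastest repolarizing
               current (spike downstroke; upper limit of fast spiking),
* ultraslow -- the time constant of the slowest gating variable
               (adaptation, interburst dynamics).

Each state variable X with time constant tau_X(V) is then assigned a pair of
weights (w_fs, w_su) splitting its influence across the three timescales by
log-linear interpolation between the reference time constants: the fast share
is w_fs, the slow share w_su - w_fs, the ultraslow share 1 - w_su, a
nonnegative partition of unity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DesignationError
from .model_core import NeuronModel

__all__ = ["TimescaleTriplet", "WeightPair", "reference_timescales", "weights"]


@dataclass(frozen=True)
class TimescaleTriplet:
    """The three voltage-dependent reference time constants (ms).

    ``tau_u`` may be None: a two-timescale model (e.g. a pure spiker of the
    Hodgkin-Huxley type) has no ultraslow reference and every variable then
    carries w_su = 1.
    ``provenance`` records which (current, gate) supplied each reference.
    """

    tau_f: object  # callable V -> ms
    tau_s: object
    tau_u: Optional[object]
    provenance: dict

    def check_ordering(self, v_grid) -> None:
        """Fail loudly if tau_f <= tau_s <= tau_u is violated on the grid.

        Reordering would silently change the decomposition's meaning, so a
        violation is an error, not a warning.
        """
        v = np.asarray(v_grid, dtype=float)
        tf, ts = np.asarray(self.tau_f(v)), np.asarray(self.tau_s(v))
        bad = tf > ts * (1 + 1e-12)
        if self.tau_u is not None:
            tu = np.asarray(self.tau_u(v))
            bad |= ts > tu * (1 + 1e-12)
        if np.any(bad):
            vb = v[np.flatnonzero(bad)[0]]
            raise DesignationError(
                f"reference timescale ordering tau_f <= tau_s <= tau_u violated at "
                f"V = {vb:.2f} mV; supply an explicit designation"
            )


@dataclass(frozen=True)
class WeightPair:
    """Fast/slow and slow/ultraslow split weights for one variable at one V."""

    w_fs: float
    w_su: float

    def __post_init__(self):
        if not (0.0 <= self.w_fs <= self.w_su <= 1.0):
            raise ValueError(f"weights must satisfy 0 <= w_fs <= w_su <= 1, got {self}")

    @property
    def shares(self) -> tuple[float, float, float]:
        return (self.w_fs, self.w_su - self.w_fs, 1.0 - self.w_su)


def _fastest_activation(currents, kind: str, v_ref: float):
    """The gated current of given polarity with the smallest activation tau."""
    cands = [
        c for c in currents if c.polarity == kind and c.activation is not None
    ]
    if not cands:
        raise DesignationError(
            f"auto designation needs a gated {kind} current; supply an explicit map"
        )
    return min(cands, key=lambda c: float(c.activation.tau(v_ref)))


def reference_timescales(
    model: NeuronModel,
    designation: dict | str = "auto",
    v_grid=None,
) -> TimescaleTriplet:
    """Resolve (tau_f, tau_s, tau_u) for a model.

    ``designation`` is either "auto" or a map like
    ``{"fast": ("Na", "m"), "slow": ("Kd", "m"), "ultraslow": ("CaS", "h")}``
    (``"ultraslow": None`` requests the two-timescale mode).  Auto mode takes
    the fastest depolarizing activation, the fastest repolarizing activation,
    and the slowest gating variable overall (the calcium pool included); if the
    slowest variable already provides the slow reference the model degenerates
    to two timescales.  A model carrying its own designation metadata (the
    bundled fixtures do) uses it unless overridden.
    """
    if designation == "auto" and model.timescales is not None:
        designation = model.timescales
    v_lo, v_hi = model.v_range
    if v_grid is None:
        v_grid = np.arange(v_lo, v_hi + 1e-9, 0.5)
    v_mid = 0.5 * (v_lo + v_hi)

    def gate_of(ref):
        cur_name, label = ref
        c = model.current_by_name(cur_name)
        gate = c.activation if label == "m" else c.inactivation
        if gate is None:
            raise DesignationError(f"current {cur_name!r} has no gate {label!r}")
        return gate

    if designation == "auto":
        fast_c = _fastest_activation(model.currents, "depolarizing", v_mid)
        slow_c = _fastest_activation(model.currents, "repolarizing", v_mid)
        prov = {"fast": (fast_c.name, "m"), "slow": (slow_c.name, "m")}
        # slowest variable overall, by time constant averaged over the range
        slowest, slowest_tau, slowest_ref = None, -np.inf, None
        for _, c, label, gate in model.gating_entries():
            mean_tau = float(np.mean(gate.tau(v_grid)))
            if mean_tau > slowest_tau:
                slowest, slowest_tau = gate, mean_tau
                slowest_ref = (c.name, label)
        if model.calcium is not None and model.calcium.tau > slowest_tau:
            slowest_ref = ("calcium", "Ca")
            tau_u = _const(model.calcium.tau)
        elif slowest_ref is not None and slowest_ref != prov["slow"]:
            tau_u = slowest.tau
        else:
            tau_u = None
        prov["ultraslow"] = slowest_ref if tau_u is not None else None
        trip = TimescaleTriplet(fast_c.activation.tau, slow_c.activation.tau, tau_u, prov)
    else:
        if "fast" not in designation or "slow" not in designation:
            raise DesignationError("explicit designation needs 'fast' and 'slow' entries")
        tf = gate_of(designation["fast"]).tau
        ts = gate_of(designation["slow"]).tau
        u_ref = designation.get("ultraslow")
        tu = gate_of(u_ref).tau if u_ref is not None else None
        trip = TimescaleTriplet(tf, ts, tu, dict(designation))
    trip.check_ordering(v_grid)
    if model.calcium is not None and trip.tau_u is not None:
        # the calcium pool must sit wholly in the ultraslow timescale
        tu = np.asarray(trip.tau_u(v_grid))
        if np.any(model.calcium.tau < tu * (1 - 1e-9)):
            warnings.warn(
                "calcium pool time constant falls below the ultraslow reference at "
                "some potentials: intracellular calcium would leak into the slow "
                "timescale, contrary to the decomposition's assumption",
                stacklevel=2,
            )
    return trip


def _const(x: float):
    def f(v):
        return np.full_like(np.asarray(v, dtype=float), x)

    return f


def weights(tau_x, triplet: TimescaleTriplet, v) -> tuple:
    """(w_fs, w_su) for a variable with time constant tau_x at potential(s) v.

    ``tau_x`` is a scalar, an array matching v, or a callable of v.  The split
    is piecewise linear in log tau, clamped to [0, 1]:

        w_fs = (ln tau_s - ln tau_x) / (ln tau_s - ln tau_f)   on (tau_f, tau_s)
        w_su = (ln tau_u - ln tau_x) / (ln tau_u - ln tau_s)   on (tau_s, tau_u)

    with w_fs = 1 below tau_f, 0 above tau_s; w_su = 1 below tau_s, 0 above
    tau_u (and w_su = 1 identically in two-timescale mode).
    """
    v = np.asarray(v, dtype=float)
    tx = np.asarray(tau_x(v) if callable(tau_x) else tau_x, dtype=float)
    tf = np.asarray(triplet.tau_f(v), dtype=float)
    ts = np.asarray(triplet.tau_s(v), dtype=float)
    if np.any(tx <= 0) or np.any(tf <= 0) or np.any(ts <= 0):
        raise ValueError("time constants must be positive")
    w_fs = _log_interp(tx, tf, ts)
    if triplet.tau_u is None:
        w_su = np.ones_like(w_fs)
    else:
        tu = np.asarray(triplet.tau_u(v), dtype=float)
        if np.any(tu <= 0):
            raise ValueError("time constants must be positive")
        w_su = _log_interp(tx, ts, tu)
    return w_fs, w_su


def _log_interp(tx, lo, hi):
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (np.log(hi) - np.log(tx)) / (np.log(hi) - np.log(lo))
        w = np.where(np.isfinite(w), w, np.where(tx <= lo, 1.0, 0.0))
    return np.clip(w, 0.0, 1.0)


def weight_pair(tau_x: float, triplet: TimescaleTriplet, v: float) -> WeightPair:
    """Scalar convenience wrapper returning a validated WeightPair."""
    w_fs, w_su = weights(float(tau_x), triplet, float(v))
    # clamping makes w_fs <= w_su automatic except for degenerate triplets
    return WeightPair(float(min(w_fs, w_su)), float(w_su))


def weight_table(model: NeuronModel, v_grid=None, triplet: Optional[TimescaleTriplet] = None):
    """Long-format table of (v_mV, variable, w_fs, w_su) for every state
    variable, the calcium pool included; exportable as tabular text."""
    import pandas as pd

    if triplet is None:
        triplet = reference_timescales(model)
    if v_grid is None:
        lo, hi = model.v_range
        v_grid = np.arange(lo, hi + 0.05, 0.1)
    v = np.asarray(v_grid, dtype=float)
    rows = []
    for _, c, label, gate in model.gating_entries():
        w_fs, w_su = weights(gate.tau, triplet, v)
        rows.append(
            pd.DataFrame(
                {"v_mV": v, "variable": f"{c.name}.{label}", "w_fs": w_fs, "w_su": w_su}
            )
        )
    if model.calcium is not None:
        w_fs, w_su = weights(model.calcium.tau, triplet, v)
        rows.append(pd.DataFrame({"v_mV": v, "variable": "Ca", "w_fs": w_fs, "w_su": w_su}))
    return pd.concat(rows, ignore_index=True)
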