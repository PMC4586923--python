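"""Ready-made models: the STG burster, the classical squid-axon model, toys.

* ``make_stg`` -- six-current crustacean stomatogastric (STG) neuron model
  with the reference maximal conductances (Na 700, CaT 2, CaS 4, A 50, Kd 70,
  KCa 40 mS/cm2), calcium reversal +120 mV, and the timescale designation
  tau_f = tau_m(Na), tau_s = tau_m(Kd), tau_u = tau_h(CaS).
* ``make_hh`` -- the classical Hodgkin-Huxley squid-axon model (resting
  potential near -65 mV), a two-timescale validation case.
* ``make_toy`` -- analytic toys with closed-form ground truth in ``.info``.

Builders are pure: identical arguments yield identical models.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

import numpy as np
import yaml

from . import kinetics
from .io import model_from_dict
from .model_core import GatingVariable, IonicCurrent, NeuronModel, PolynomialCurrent

__all__ = ["make_stg", "make_hh", "make_toy", "FIXTURES", "get_fixture"]

_STG_GBAR_KEYS = ("Na", "CaT", "CaS", "A", "Kd", "KCa")


def _stg_config() -> dict:
    text = resources.files("neurodic.data").joinpath("stg_kinetics.yaml").read_text()
    return yaml.safe_load(text)


def make_stg(**overrides) -> NeuronModel:
    """The reference STG model; override maximal conductances by current name
    (``CaS=20``), the applied current (``i_app=...``) or the calcium reversal
    (``v_ca=...``).  Unknown keys raise KeyError.
    """
    cfg = _stg_config()
    known = set(_STG_GBAR_KEYS) | {"i_app", "v_ca"}
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(f"unknown STG override(s) {sorted(unknown)}; known: {sorted(known)}")
    for cur in cfg["currents"]:
        if cur["name"] in overrides:
            cur["gbar"] = float(overrides[cur["name"]])
        if "v_ca" in overrides and cur["name"] in ("CaT", "CaS"):
            cur["reversal"] = float(overrides["v_ca"])
    if "i_app" in overrides:
        cfg["i_app"] = float(overrides["i_app"])
    return model_from_dict(cfg)


def make_hh(i_app: float = 0.0) -> NeuronModel:
    """Classical squid-axon model (modern -65 mV resting convention).

    Rate constants in 1/ms; the model has two timescales only (fast: sodium
    activation; slow: potassium activation and sodium inactivation), so its
    ultraslow input conductance vanishes identically.
    """

    def rates(alpha, beta):
        return (
            kinetics.RateSteadyState(alpha, beta),
            kinetics.RateTimeConstant(alpha, beta),
        )

    m_inf, m_tau = rates(
        kinetics.AlphaExpLinear(0.1, -40.0, 10.0), kinetics.AlphaExp(4.0, -65.0, -18.0)
    )
    h_inf, h_tau = rates(
        kinetics.AlphaExp(0.07, -65.0, -20.0), kinetics.AlphaSigmoid(1.0, -35.0, 10.0)
    )
    n_inf, n_tau = rates(
        kinetics.AlphaExpLinear(0.01, -55.0, 10.0), kinetics.AlphaExp(0.125, -65.0, -80.0)
    )
    na = IonicCurrent(
        name="Na",
        gbar=120.0,
        reversal=50.0,
        activation=GatingVariable("Na.m", "activation", 3, m_inf, m_tau),
        inactivation=GatingVariable("Na.h", "inactivation", 1, h_inf, h_tau),
        polarity="depolarizing",
    )
    k = IonicCurrent(
        name="K",
        gbar=36.0,
        reversal=-77.0,
        activation=GatingVariable("K.m", "activation", 4, n_inf, n_tau),
        polarity="repolarizing",
    )
    return NeuronModel(
        currents=(na, k),
        leak_g=0.3,
        leak_e=-54.4,
        capacitance=1.0,
        calcium=None,
        i_app=i_app,
        v_range=(-90.0, 60.0),
        timescales={"fast": ("Na", "m"), "slow": ("K", "m"), "ultraslow": None},
        name="hh",
    )


def make_toy(kind: str, **params) -> NeuronModel:
    """Analytic toy models; closed-form ground truth lands in ``model.info``.

    kinds:
      single_gate  -- one current, sigmoid activation (vhalf, k), constant tau,
                      optional leak; DIC ground truth is closed-form.
      cubic_iv     -- instantaneous polynomial current with prescribed I/V
                      roots; exercises the up-state root selector.
      fold         -- parabolic I/V ((V-center)^2 + depth) plus a constant
                      scalable "calcium" current; the degenerate equilibrium
                      sits exactly at (center, alpha=depth).
    """
    if kind == "single_gate":
        gbar = params.pop("gbar", 1.0)
        reversal = params.pop("reversal", 0.0)
        vhalf = params.pop("vhalf", -40.0)
        k = params.pop("k", 5.0)
        tau = params.pop("tau", 50.0)
        exponent = params.pop("exponent", 1)
        leak_g = params.pop("leak_g", 0.0)
        leak_e = params.pop("leak_e", -60.0)
        polarity = params.pop("polarity", "depolarizing")
        _reject_extras(kind, params)
        ss = kinetics.Sigmoid(vhalf, k)
        gate = GatingVariable("X.m", "activation", exponent, ss, kinetics.Constant(tau))
        cur = IonicCurrent("X", gbar, reversal, activation=gate, polarity=polarity)
        model = NeuronModel(
            currents=(cur,),
            leak_g=leak_g,
            leak_e=leak_e,
            name="toy-single-gate",
        )
        info = {
            "tau": tau,
            "m_inf": ss,
            "dm_inf": ss.deriv,
            "g_pathway": lambda v, _s=ss, _g=gbar, _p=exponent, _r=reversal: (
                -_g * _p * _s(v) ** (_p - 1) * (np.asarray(v, float) - _r) * _s.deriv(v)
            ),
        }
        return replace(model, info=info)
    if kind == "cubic_iv":
        roots = tuple(params.pop("roots", (-60.0, -40.0, -15.0)))
        scale = params.pop("scale", 1e-3)
        _reject_extras(kind, params)
        coeffs = np.poly(roots) * scale
        cur = PolynomialCurrent(name="P", gbar=1.0, reversal=0.0, coeffs=tuple(coeffs))
        return NeuronModel(
            currents=(cur,),
            leak_g=0.0,
            leak_e=-60.0,
            name="toy-cubic-iv",
            info={"roots": roots},
        )
    if kind == "fold":
        center = params.pop("center", -50.0)
        depth = params.pop("depth", 2.0)
        _reject_extras(kind, params)
        parab = PolynomialCurrent(
            name="P",
            gbar=1.0,
            reversal=0.0,
            coeffs=(1.0, -2.0 * center, center**2 + depth),
        )
        ca = PolynomialCurrent(
            name="CaToy", gbar=1.0, reversal=0.0, coeffs=(-1.0,), calcium_carrying=True
        )
        return NeuronModel(
            currents=(parab, ca),
            leak_g=0.0,
            leak_e=-60.0,
            name="toy-fold",
            info={"v_th": center, "critical_alpha": depth},
        )
    raise ValueError(f"unknown toy kind {kind!r}")


def _reject_extras(kind, params):
    if params:
        raise ValueError(f"unknown parameters for toy {kind!r}: {sorted(params)}")


FIXTURES = {"stg": make_stg, "hh": make_hh}


def get_fixture(name: str, **overrides) -> NeuronModel:
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder(**overrides)
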