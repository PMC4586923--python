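"""Registry of parametric gating functions.

Every steady-state or time-constant curve used by a model is an instance of a
small set of closed forms (Boltzmann sigmoids, sigmoidal and bi-exponential
time constants, alpha/beta rate pairs).  Each form knows its own voltage
derivative where a closed form exists; otherwise a central finite difference
with a 1e-3 mV step is used.  All forms are round-trippable through a plain
``{"form": ..., params...}`` mapping, which is what the YAML model config
stores.

Units: potentials in mV, time constants in ms, calcium in uM.
"""

from __future__ import annotations

import numpy as np

_FD_STEP = 1e-3  # mV, central-difference step for forms without closed-form slope

_REGISTRY: dict[str, type] = {}


def register(name):
    def deco(cls):
        cls.form = name
        _REGISTRY[name] = cls
        return cls

    return deco


def from_dict(spec: dict) -> "KineticsFunction":
    """Build a kinetics function from its serialized form."""
    spec = dict(spec)
    try:
        form = spec.pop("form")
    except KeyError:
        raise ValueError(f"kinetics spec missing 'form': {spec!r}") from None
    try:
        cls = _REGISTRY[form]
    except KeyError:
        raise ValueError(
            f"unknown kinetics form {form!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return cls.from_params(spec)


class KineticsFunction:
    """Scalar- and array-callable function of membrane potential."""

    form: str

    def __call__(self, v):
        raise NotImplementedError

    def deriv(self, v):
        """dF/dV by central finite difference unless overridden analytically."""
        v = np.asarray(v, dtype=float)
        return (self(v + _FD_STEP) - self(v - _FD_STEP)) / (2.0 * _FD_STEP)

    def shifted(self, delta_mv: float) -> "KineticsFunction":
        """The same curve translated by ``delta_mv`` along the voltage axis."""
        if delta_mv == 0.0:
            return self
        return Shifted(self, delta_mv)

    @classmethod
    def from_params(cls, params: dict):
        try:
            return cls(**params)
        except TypeError as exc:
            raise ValueError(f"bad parameters for form {cls.form!r}: {exc}") from None

    def to_dict(self) -> dict:
        d = {"form": self.form}
        d.update(self._params())
        return d

    def _params(self) -> dict:
        raise NotImplementedError


@register("sigmoid")
class Sigmoid(KineticsFunction):
    """Boltzmann sigmoid 1 / (1 + exp(-(V - vhalf)/k)).

    k > 0 rises with depolarization (activation), k < 0 falls (inactivation).
    """

    def __init__(self, vhalf: float, k: float):
        if k == 0:
            raise ValueError("sigmoid slope k must be nonzero")
        self.vhalf = float(vhalf)
        self.k = float(k)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp(-(v - self.vhalf) / self.k))

    def deriv(self, v):
        s = self(v)
        return s * (1.0 - s) / self.k

    def _params(self):
        return {"vhalf": self.vhalf, "k": self.k}


@register("tau_sigmoid")
class TauSigmoid(KineticsFunction):
    """a + b / (1 + exp(-(V - vhalf)/k)); the workhorse time-constant form."""

    def __init__(self, a: float, b: float, vhalf: float, k: float):
        self.a, self.b, self.vhalf, self.k = map(float, (a, b, vhalf, k))

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.a + self.b / (1.0 + np.exp(-(v - self.vhalf) / self.k))

    def deriv(self, v):
        v = np.asarray(v, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(v - self.vhalf) / self.k))
        return self.b * s * (1.0 - s) / self.k

    def _params(self):
        return {"a": self.a, "b": self.b, "vhalf": self.vhalf, "k": self.k}


@register("tau_biexp")
class TauBiexp(KineticsFunction):
    """a + b / (exp((V - vh1)/k1) + exp((V - vh2)/k2)).

    Bell-shaped time constants (e.g. slow calcium channel kinetics).
    """

    def __init__(self, a, b, vh1, k1, vh2, k2):
        self.a, self.b = float(a), float(b)
        self.vh1, self.k1 = float(vh1), float(k1)
        self.vh2, self.k2 = float(vh2), float(k2)

    def _denom(self, v):
        return np.exp((v - self.vh1) / self.k1) + np.exp((v - self.vh2) / self.k2)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.a + self.b / self._denom(v)

    def deriv(self, v):
        v = np.asarray(v, dtype=float)
        d = self._denom(v)
        dd = (
            np.exp((v - self.vh1) / self.k1) / self.k1
            + np.exp((v - self.vh2) / self.k2) / self.k2
        )
        return -self.b * dd / d**2

    def _params(self):
        return {
            "a": self.a,
            "b": self.b,
            "vh1": self.vh1,
            "k1": self.k1,
            "vh2": self.vh2,
            "k2": self.k2,
        }


@register("tau_product")
class TauProduct(KineticsFunction):
    """Product of two registered forms (e.g. the sodium inactivation tau)."""

    def __init__(self, factors):
        self.factors = [
            f if isinstance(f, KineticsFunction) else from_dict(f) for f in factors
        ]
        if len(self.factors) != 2:
            raise ValueError("tau_product takes exactly two factors")

    def __call__(self, v):
        return self.factors[0](v) * self.factors[1](v)

    def deriv(self, v):
        f, g = self.factors
        return f.deriv(v) * g(v) + f(v) * g.deriv(v)

    @classmethod
    def from_params(cls, params):
        return cls(**params)

    def _params(self):
        return {"factors": [f.to_dict() for f in self.factors]}


@register("constant")
class Constant(KineticsFunction):
    def __init__(self, value: float):
        self.value = float(value)

    def __call__(self, v):
        return np.full_like(np.asarray(v, dtype=float), self.value)

    def deriv(self, v):
        return np.zeros_like(np.asarray(v, dtype=float))

    def _params(self):
        return {"value": self.value}


@register("alpha_exp_linear")
class AlphaExpLinear(KineticsFunction):
    """A (V - vhalf) / (1 - exp(-(V - vhalf)/k)), the classic rate form.

    The removable singularity at V = vhalf is filled with the limit A*k.
    """

    def __init__(self, amp: float, vhalf: float, k: float):
        self.amp, self.vhalf, self.k = float(amp), float(vhalf), float(k)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        x = (v - self.vhalf) / self.k
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.amp * (v - self.vhalf) / (1.0 - np.exp(-x))
        lim = self.amp * self.k
        return np.where(np.abs(x) < 1e-7, lim, out)

    def _params(self):
        return {"amp": self.amp, "vhalf": self.vhalf, "k": self.k}


@register("alpha_exp")
class AlphaExp(KineticsFunction):
    """A exp((V - vhalf)/k)."""

    def __init__(self, amp: float, vhalf: float, k: float):
        self.amp, self.vhalf, self.k = float(amp), float(vhalf), float(k)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.amp * np.exp((v - self.vhalf) / self.k)

    def deriv(self, v):
        return self(v) / self.k

    def _params(self):
        return {"amp": self.amp, "vhalf": self.vhalf, "k": self.k}


@register("alpha_sigmoid")
class AlphaSigmoid(KineticsFunction):
    """A / (1 + exp(-(V - vhalf)/k))."""

    def __init__(self, amp: float, vhalf: float, k: float):
        self.amp, self.vhalf, self.k = float(amp), float(vhalf), float(k)

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.amp / (1.0 + np.exp(-(v - self.vhalf) / self.k))

    def deriv(self, v):
        s = self(v) / self.amp
        return self.amp * s * (1.0 - s) / self.k

    def _params(self):
        return {"amp": self.amp, "vhalf": self.vhalf, "k": self.k}


@register("rate_steady_state")
class RateSteadyState(KineticsFunction):
    """alpha / (alpha + beta) from two rate forms (Hodgkin-Huxley style)."""

    def __init__(self, alpha, beta):
        self.alpha = alpha if isinstance(alpha, KineticsFunction) else from_dict(alpha)
        self.beta = beta if isinstance(beta, KineticsFunction) else from_dict(beta)

    def __call__(self, v):
        a, b = self.alpha(v), self.beta(v)
        return a / (a + b)

    @classmethod
    def from_params(cls, params):
        return cls(**params)

    def _params(self):
        return {"alpha": self.alpha.to_dict(), "beta": self.beta.to_dict()}


@register("rate_time_constant")
class RateTimeConstant(KineticsFunction):
    """1 / (alpha + beta) from two rate forms (ms when rates are 1/ms)."""

    def __init__(self, alpha, beta):
        self.alpha = alpha if isinstance(alpha, KineticsFunction) else from_dict(alpha)
        self.beta = beta if isinstance(beta, KineticsFunction) else from_dict(beta)

    def __call__(self, v):
        return 1.0 / (self.alpha(v) + self.beta(v))

    @classmethod
    def from_params(cls, params):
        return cls(**params)

    def _params(self):
        return {"alpha": self.alpha.to_dict(), "beta": self.beta.to_dict()}


@register("shifted")
class Shifted(KineticsFunction):
    """base evaluated at V - delta: a rightward translation by +delta mV."""

    def __init__(self, base, delta: float):
        self.base = base if isinstance(base, KineticsFunction) else from_dict(base)
        self.delta = float(delta)

    def __call__(self, v):
        return self.base(np.asarray(v, dtype=float) - self.delta)

    def deriv(self, v):
        return self.base.deriv(np.asarray(v, dtype=float) - self.delta)

    def shifted(self, delta_mv: float):
        return Shifted(self.base, self.delta + delta_mv)

    @classmethod
    def from_params(cls, params):
        return cls(**params)

    def _params(self):
        return {"base": self.base.to_dict(), "delta": self.delta}


class CalciumGatedSigmoid(KineticsFunction):
    """Calcium-dependent activation (Ca/(Ca+kd)) * sigmoid(V).

    Used by the calcium-activated potassium current: the voltage sigmoid is
    multiplied by a saturating function of intracellular calcium with
    dissociation constant ``kd`` (uM).  Calls take (V, Ca).
    """

    form = "ca_sigmoid"

    def __init__(self, vhalf: float, k: float, kd: float = 3.0):
        self.vhalf, self.k, self.kd = float(vhalf), float(k), float(kd)
        self._sig = Sigmoid(vhalf, k)

    def __call__(self, v, ca):
        ca = np.asarray(ca, dtype=float)
        return (ca / (ca + self.kd)) * self._sig(v)

    def deriv_v(self, v, ca):
        ca = np.asarray(ca, dtype=float)
        return (ca / (ca + self.kd)) * self._sig.deriv(v)

    def deriv_ca(self, v, ca):
        ca = np.asarray(ca, dtype=float)
        return (self.kd / (ca + self.kd) ** 2) * self._sig(v)

    def shifted(self, delta_mv: float):
        out = CalciumGatedSigmoid(self.vhalf + delta_mv, self.k, self.kd)
        return out

    @classmethod
    def from_params(cls, params):
        return cls(**params)

    def to_dict(self):
        return {"form": self.form, "vhalf": self.vhalf, "k": self.k, "kd": self.kd}


_REGISTRY["ca_sigmoid"] = CalciumGatedSigmoid
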