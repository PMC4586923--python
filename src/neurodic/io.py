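"""Model config (de)serialization and tabular writers.

The model description format is a small declarative YAML schema: per-current
blocks naming gating functions from the kinetics registry, plus leak, calcium
pool, capacitance, applied current and the timescale designation.  Errors name
the offending key path.  All tabular output is plain CSV with a unit-bearing
comment header so runs diff cleanly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import kinetics
from .model_core import CalciumPool, GatingVariable, IonicCurrent, NeuronModel, Trace

__all__ = [
    "model_from_dict",
    "model_to_dict",
    "load_model",
    "dump_model",
    "write_table",
    "read_trace",
    "write_trace",
]


class ConfigError(ValueError):
    pass


_MISSING = object()


def _get(d: dict, key: str, path: str, default=_MISSING):
    if key in d:
        return d[key]
    if default is not _MISSING:
        return default
    raise ConfigError(f"missing required key {path}.{key}")


def _gating_from_dict(d: dict, role: str, name: str, path: str) -> GatingVariable:
    if not isinstance(d, dict):
        raise ConfigError(f"{path} must be a mapping")
    try:
        ss = kinetics.from_dict(_get(d, "steady_state", path))
        tc = kinetics.from_dict(_get(d, "time_constant", path))
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return GatingVariable(
        name=name,
        role=role,
        exponent=int(_get(d, "exponent", path, 1)),
        steady_state=ss,
        time_constant=tc,
    )


def model_from_dict(cfg: dict) -> NeuronModel:
    if not isinstance(cfg, dict):
        raise ConfigError("model config must be a mapping")
    leak = _get(cfg, "leak", "$")
    calcium_cfg = cfg.get("calcium")
    calcium = (
        CalciumPool(
            tau=float(_get(calcium_cfg, "tau", "$.calcium")),
            f=float(_get(calcium_cfg, "f", "$.calcium")),
            c_rest=float(_get(calcium_cfg, "c_rest", "$.calcium", 0.05)),
        )
        if calcium_cfg is not None
        else None
    )
    currents = []
    for i, cur in enumerate(_get(cfg, "currents", "$")):
        path = f"$.currents[{i}]"
        name = _get(cur, "name", path)
        act = cur.get("activation")
        inact = cur.get("inactivation")
        currents.append(
            IonicCurrent(
                name=name,
                gbar=float(_get(cur, "gbar", path)),
                reversal=float(_get(cur, "reversal", path)),
                activation=_gating_from_dict(act, "activation", f"{name}.m", f"{path}.activation")
                if act is not None
                else None,
                inactivation=_gating_from_dict(
                    inact, "inactivation", f"{name}.h", f"{path}.inactivation"
                )
                if inact is not None
                else None,
                polarity=_get(cur, "polarity", path, "depolarizing"),
                calcium_carrying=bool(cur.get("calcium_carrying", False)),
            )
        )
    ts = cfg.get("timescales")
    if ts is not None:
        ts = {k: (tuple(v) if v is not None else None) for k, v in ts.items()}
    v_range = tuple(float(x) for x in _get(cfg, "v_range", "$", (-80.0, 50.0)))
    return NeuronModel(
        currents=tuple(currents),
        leak_g=float(_get(leak, "g", "$.leak")),
        leak_e=float(_get(leak, "e", "$.leak")),
        capacitance=float(_get(cfg, "capacitance", "$", 1.0)),
        calcium=calcium,
        i_app=float(_get(cfg, "i_app", "$", 0.0)),
        v_range=v_range,
        timescales=ts,
        name=str(_get(cfg, "name", "$", "model")),
    )


def _gating_to_dict(g: GatingVariable) -> dict:
    return {
        "exponent": g.exponent,
        "steady_state": g.steady_state.to_dict(),
        "time_constant": g.time_constant.to_dict(),
    }


def model_to_dict(model: NeuronModel) -> dict:
    cfg = {
        "name": model.name,
        "capacitance": model.capacitance,
        "v_range": list(model.v_range),
        "i_app": model.i_app,
        "leak": {"g": model.leak_g, "e": model.leak_e},
    }
    if model.calcium is not None:
        cfg["calcium"] = {
            "tau": model.calcium.tau,
            "f": model.calcium.f,
            "c_rest": model.calcium.c_rest,
        }
    if model.timescales is not None:
        cfg["timescales"] = {
            k: (list(v) if v is not None else None) for k, v in model.timescales.items()
        }
    cfg["currents"] = []
    for c in model.currents:
        d = {
            "name": c.name,
            "gbar": c.gbar,
            "reversal": c.reversal,
            "polarity": c.polarity,
            "calcium_carrying": c.calcium_carrying,
        }
        if c.activation is not None:
            d["activation"] = _gating_to_dict(c.activation)
        if c.inactivation is not None:
            d["inactivation"] = _gating_to_dict(c.inactivation)
        cfg["currents"].append(d)
    return cfg


def load_model(path) -> NeuronModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        return model_from_dict(cfg)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def dump_model(model: NeuronModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def write_table(df: pd.DataFrame, path, units: Optional[dict] = None, meta: Optional[dict] = None):
    """CSV with '# key: value' comment header recording units and provenance."""
    lines = []
    if units:
        lines.append("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()))
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        for ln in lines:
            fh.write(ln + "\n")
        df.to_csv(fh, index=False)


def write_trace(trace: Trace, path) -> None:
    cols = {"time_ms": trace.time, "v_mV": trace.voltage}
    if trace.current is not None:
        cols["i_total_uA_per_cm2"] = trace.current
    for k, v in trace.state.items():
        cols[k] = v
    write_table(pd.DataFrame(cols), path, units={"time": "ms", "v": "mV", "i": "uA/cm2"})


def read_trace(path) -> Trace:
    """Tabular text with at least time_ms plus v_mV and/or i_total_uA_per_cm2."""
    df = pd.read_csv(path, comment="#")
    if "time_ms" not in df.columns:
        raise ConfigError(f"{path}: trace file needs a time_ms column")
    current = df["i_total_uA_per_cm2"].to_numpy() if "i_total_uA_per_cm2" in df else None
    voltage = df["v_mV"].to_numpy() if "v_mV" in df else np.zeros(len(df))
    state = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in ("time_ms", "v_mV", "i_total_uA_per_cm2")
    }
    return Trace(time=df["time_ms"].to_numpy(), voltage=voltage, state=state, current=current)
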