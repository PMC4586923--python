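"""Linear conductance compensation preserving selected DIC values.

Given a reference model and a perturbation of one calcium maximal
conductance, find the applied current and the potassium maximal conductances
(Kd, A, KCa) that keep four quantities at their reference values:

    g_s(V_th),  g_s(V_osc),  g_u(V_th),  I_static(V_th) - I_app

The DICs are linear in the maximal conductances (frozen-calcium convention),
so the compensating set solves a 4x4 linear system A x = b: A holds the
sensitivity values of the compensating channels at the marker potentials
(plus the applied-current column), and b holds the targets minus the
contributions of the channels that are not part of the compensation (sodium
and both calcium channels, the perturbed one at its new density, plus leak in
the static row).  Sodium is excluded from the compensating set because the
calcium channels barely touch the fast timescale over their physiological
range.  Negative conductances can come out of the solve; they are reported
and flagged nonphysiological, not rejected -- the activity is determined by
the DICs regardless of how individual channels shape them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dic import CalciumProfile, dic_at
from .errors import SolverError
from .markers import VoltageMarkers, voltage_markers
from .model_core import NeuronModel, static_iv
from .sensitivity import sensitivity_curves, static_iv_sensitivity
from .timescales import reference_timescales

__all__ = [
    "CompensationTargets",
    "CompensationResult",
    "make_targets",
    "compensate",
    "compensation_path",
]

_DEFAULT_UNKNOWNS = ("Kd", "A", "KCa")
_DEFAULT_FIXED = ("Na", "CaT", "CaS")


@dataclass(frozen=True)
class CompensationTargets:
    """Reference values to be maintained, computed once on the reference model."""

    gs_th: float
    gs_osc: float
    gu_th: float
    istatic_th: float  # net current I_static(V_th) - I_app, uA/cm2
    v_th: float
    v_osc: float
    metadata: dict = field(default_factory=dict)


@dataclass
class CompensationResult:
    i_app: float
    gbars: dict[str, float]  # compensating conductances, mS/cm2
    perturbed: str
    perturbed_gbar: float
    residuals: dict[str, float]  # re-evaluated minus target, frozen-calcium path
    physiological: bool
    condition_number: float
    flags: list[str] = field(default_factory=list)

    def apply(self, model: NeuronModel) -> NeuronModel:
        """The perturbed-and-compensated model."""
        new = model.with_gbar(**{self.perturbed: self.perturbed_gbar}, **self.gbars)
        return new.with_i_app(self.i_app)


def make_targets(model: NeuronModel, markers: Optional[VoltageMarkers] = None) -> CompensationTargets:
    """The four maintained quantities of the reference model.

    Markers are located once here and reused across perturbations: the targets
    are defined before any perturbation is applied.
    """
    if markers is None:
        markers = voltage_markers(model)
    g_f, g_s, g_u, _ = dic_at(model, markers.v_th)
    _, gs_osc, _, _ = dic_at(model, markers.v_osc)
    istatic = float(static_iv(model, markers.v_th)) - model.i_app
    return CompensationTargets(
        gs_th=g_s,
        gs_osc=gs_osc,
        gu_th=g_u,
        istatic_th=istatic,
        v_th=markers.v_th,
        v_osc=markers.v_osc,
        metadata=dict(markers.metadata),
    )


def _system(
    model: NeuronModel,
    targets: CompensationTargets,
    perturbed: str,
    new_gbar: float,
    unknowns: Sequence[str],
    include_static_row: bool,
):
    """Assemble A, b on the reference model (frozen reference calcium)."""
    triplet = reference_timescales(model)
    ca_prof = CalciumProfile(model) if model.calcium is not None else None
    vth = np.array([targets.v_th])
    vosc = np.array([targets.v_osc])

    def sens(name, v):
        return sensitivity_curves(model, name, v, triplet, ca_prof)[:, 0]

    fixed = [c.name for c in model.currents if c.gated and c.name not in unknowns]
    gbar_of = {c.name: c.gbar for c in model.currents}
    gbar_of[perturbed] = float(new_gbar)

    rows = []
    rhs = []
    # row: (selector over (f,s,u), potential, target value)
    marker_rows = [(1, vth, targets.gs_th), (1, vosc, targets.gs_osc), (2, vth, targets.gu_th)]
    for j, v, tgt in marker_rows:
        row = [0.0]  # I_app does not enter the DICs
        for nm in unknowns:
            row.append(float(sens(nm, v)[j]))
        fixed_part = sum(gbar_of[nm] * float(sens(nm, v)[j]) for nm in fixed)
        rows.append(row)
        rhs.append(tgt - fixed_part)
    if include_static_row:
        row = [-1.0]  # net current I_static - I_app: dI/dI_app = -1
        for nm in unknowns:
            row.append(float(static_iv_sensitivity(model, nm, vth, ca_prof)[0]))
        fixed_part = sum(
            gbar_of[nm] * float(static_iv_sensitivity(model, nm, vth, ca_prof)[0])
            for nm in fixed
        )
        fixed_part += float(model.leak_current(vth[0]))
        # ungated currents (analytic toys) count as fixed contributions too
        for c in model.currents:
            if not c.gated and c.name not in unknowns:
                fixed_part += float(np.atleast_1d(c.steady_current(vth[0]))[0])
        rows.append(row)
        rhs.append(targets.istatic_th - fixed_part)
    return np.asarray(rows, dtype=float), np.asarray(rhs, dtype=float)


def compensate(
    model: NeuronModel,
    perturbed: str,
    new_gbar: float,
    targets: Optional[CompensationTargets] = None,
    unknowns: Sequence[str] = _DEFAULT_UNKNOWNS,
    include_static_row: bool = True,
    cond_limit: float = 1e10,
) -> CompensationResult:
    """Solve for (I_app, gbar_Kd, gbar_A, gbar_KCa) given a perturbed calcium
    conductance.  ``include_static_row=False`` drops the applied-current
    unknown and the static-current row (a 3x3 variant for probing whether
    static compensation matters).
    """
    model.current_by_name(perturbed)  # raises KeyError on unknown name
    if targets is None:
        targets = make_targets(model)
    a_mat, b = _system(model, targets, perturbed, new_gbar, unknowns, include_static_row)
    if not include_static_row:
        a_mat = a_mat[:, 1:]
    cond = float(np.linalg.cond(a_mat))
    if not np.isfinite(cond) or cond > cond_limit:
        raise SolverError(f"compensation system ill-conditioned (cond={cond:.2e})")
    x = np.linalg.solve(a_mat, b)
    if include_static_row:
        i_app, gvals = float(x[0]), x[1:]
    else:
        i_app, gvals = model.i_app, x
    gbars = dict(zip(unknowns, (float(g) for g in gvals)))
    flags = [f"gbar_{nm}<0" for nm, g in gbars.items() if g < 0]
    result = CompensationResult(
        i_app=i_app,
        gbars=gbars,
        perturbed=perturbed,
        perturbed_gbar=float(new_gbar),
        residuals={},
        physiological=not flags,
        condition_number=cond,
        flags=flags,
    )
    result.residuals = _closed_loop_residuals(model, targets, result, include_static_row)
    return result


def _closed_loop_residuals(model, targets, result, include_static_row) -> dict[str, float]:
    """Re-evaluate the four maintained quantities on the compensated model.

    Evaluation uses the reference model's frozen calcium profile -- the same
    linearization the solve used -- so a well-conditioned solve closes to
    round-off.  The residual of the exact (unfrozen) evaluation is reported
    separately by the caller if wanted.
    """
    triplet = reference_timescales(model)
    ca_prof = CalciumProfile(model) if model.calcium is not None else None
    new = result.apply(model)
    gf, gs_th, gu_th, _ = dic_at(new, targets.v_th, triplet, ca_prof)
    _, gs_osc, _, _ = dic_at(new, targets.v_osc, triplet, ca_prof)
    out = {
        "gs_th": gs_th - targets.gs_th,
        "gs_osc": gs_osc - targets.gs_osc,
        "gu_th": gu_th - targets.gu_th,
    }
    if include_static_row:
        istatic = float(static_iv(new, targets.v_th, frozen_calcium=ca_prof)) - new.i_app
        out["istatic_th"] = istatic - targets.istatic_th
    return out


def compensation_path(
    model: NeuronModel,
    perturbed: str,
    gbar_values: Sequence[float],
    targets: Optional[CompensationTargets] = None,
    **kwargs,
) -> list[CompensationResult]:
    """Compensation solutions along a sweep of the perturbed conductance.

    Each solution component is an affine function of the perturbed gbar (the
    system matrix is fixed and b is affine in it); the tests verify rather
    than assume this.
    """
    if targets is None:
        targets = make_targets(model)
    return [compensate(model, perturbed, g, targets, **kwargs) for g in gbar_values]
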