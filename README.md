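# neurodic

Dynamic input conductance analysis for conductance-based neuron models.

Neuronal firing is shaped by many ion channels whose gating kinetics span
several orders of magnitude in time.  `neurodic` condenses that complexity
into three voltage-dependent curves — the **dynamic input conductances**
g_f(V), g_s(V), g_u(V) — that aggregate every channel's contribution to the
fast (spike upstroke), slow (spike downstroke, interspike interval) and
ultraslow (adaptation, interburst) timescales of activity, with
g_f + g_s + g_u = g, the static input conductance.  On top of the
decomposition it provides per-channel sensitivity analysis and a linear
compensation solver that answers, quantitatively, how other channel densities
can co-vary to silence the effect of a perturbed channel — the kind of
degeneracy observed in real neurons of the crustacean stomatogastric ganglion
(STG) and elsewhere.

## The decomposition

For a membrane equation C dV/dt = −Σᵢ ḡᵢ mᵢ^p hᵢ^q (V−Vᵢ) − g_L(V−E_L) + I_app,
each gating variable X with kinetics τ_X(V) Ẋ = X_∞(V) − X contributes a
pathway term −(∂I/∂X)(∂X_∞/∂V) to the input conductance.  Three reference
time constants are designated — τ_f (fastest depolarizing activation), τ_s
(fastest repolarizing activation), τ_u (slowest variable) — and every
variable's pathway is split across them by weights that are piecewise linear
in log τ:

    w_fs = (ln τ_s − ln τ_X)/(ln τ_s − ln τ_f),  clamped to [0, 1]

(analogously w_su on (τ_s, τ_u)), giving

    g_f = Σ_X w_fs −(∂I/∂X)(∂X_∞/∂V),
    g_s = Σ_X (w_su − w_fs) (…),
    g_u = Σ_X (1 − w_su) (…).

Positive values are regenerative (positive feedback: sodium activation in
g_f, calcium near threshold in g_s); negative values are restorative (the
delayed rectifier in g_s).  The same curves can be *measured* by a simulated
voltage-clamp protocol (1 mV steps, current read-outs at 2 ms, 10–100 ms and
beyond 1 s), which the `clamp` module implements, so model-derived and
measurement-derived curves can be compared directly.

Because each DIC is linear in every maximal conductance, the sensitivity
curves ∂g_j/∂ḡᵢ(V) are closed-form, and holding selected DIC values fixed
under a perturbation of one conductance is a small linear solve — the
`compensation` module maintains g_s(V_th), g_s(V_osc), g_u(V_th) and the
static current at threshold by adjusting (I_app, ḡ_Kd, ḡ_A, ḡ_KCa).

Bundled fixtures: the six-current STG neuron model (I_Na, I_CaT, I_CaS,
I_A, I_Kd, I_KCa plus leak and an intracellular calcium pool; reference
densities 700, 2, 4, 50, 70, 40 mS/cm², calcium reversal +120 mV), the
classical Hodgkin–Huxley squid-axon model (a two-timescale case whose g_u
vanishes identically), and analytic toys with closed-form ground truth.

## Worked example

```python
from neurodic import (make_stg, voltage_markers, dic_at, make_targets, compensate)

model = make_stg()
vm = voltage_markers(model)          # spike threshold and up-state
g_f, g_s, g_u, g = dic_at(model, vm.v_th)
targets = make_targets(model, vm)
res = compensate(model, "CaS", 8.0, targets)   # double the slow calcium density

print(f"V_th  = {vm.v_th:.2f} mV   (critical CaS scaling {vm.metadata['critical_alpha']:.3f})")
print(f"V_osc = {vm.v_osc:.2f} mV")
print(f"DICs at threshold: g_f={g_f:.4f}  g_s={g_s:.4f}  g_u={g_u:.4f} mS/cm^2")
print(f"CaS 4->8: I_app={res.i_app:.3f}  Kd={res.gbars['Kd']:.2f}  "
      f"A={res.gbars['A']:.2f}  KCa={res.gbars['KCa']:.2f}  physiological={res.physiological}")
print("max |residual| =", max(abs(r) for r in res.residuals.values()))
```

prints, for the reference STG model:

```
V_th  = -50.31 mV   (critical CaS scaling 0.288)
V_osc = -13.99 mV
DICs at threshold: g_f=0.0181  g_s=0.0282  g_u=-0.0187 mS/cm^2
CaS 4->8: I_app=0.075  Kd=106.47  A=178.31  KCa=-18.40  physiological=False
max |residual| = 1.39e-17
```

V_th is where the resting equilibrium meets the excitability threshold
(found by scaling the slow calcium conductance to a degenerate equilibrium of
the static I/V curve); V_osc is the unstable equilibrium around which
intra-burst spikes oscillate.  The positive g_s at threshold is the slow
regenerative feedback that makes the model a burster.  Doubling the slow
calcium density can be compensated exactly (residuals at solver precision),
but only by driving the calcium-gated potassium conductance negative — the
solver reports such solutions rather than hiding them, because they flag
the physiological limits of compensation.

The same analyses are available from the shell:

```sh
neurodic markers --fixture stg
neurodic dic --fixture stg --out-dir out/
neurodic clamp --fixture stg --out-dir out/
neurodic compensate --fixture stg --perturb CaS=8 --out-dir out/
neurodic simulate --fixture stg --duration 20000 --out-dir out/
```

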