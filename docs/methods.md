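# Methods

## Model class and units

`neurodic` operates on single-compartment conductance-based models: ionic
currents I_i = ḡ_i m_i^p h_i^q (V − V_i) with first-order gating, an ungated
leak, a constant applied current, and optionally a first-order intracellular
calcium pool that gates calcium-activated channels.  Units are fixed
globally: mV, ms, mS/cm², µA/cm², µF/cm², µM.  Temperature dependence,
morphology, synapses and channel noise are out of scope.

## Timescale decomposition

Neuronal activity is treated as a succession of events in three
representative timescales.  The references are the activation time constant
of the fastest depolarizing current (τ_f), the activation time constant of
the fastest repolarizing current (τ_s, the upper limit of fast spiking), and
the time constant of the slowest variable (τ_u).  For the STG fixture these
are τ_m(Na), τ_m(Kd) and τ_h(CaS); the Hodgkin–Huxley fixture is a
two-timescale model (τ_m(Na), τ_n(K), no ultraslow).

Each variable's influence is split by log-distance weights: w_fs is 1 below
τ_f, 0 above τ_s and linear in ln τ between; w_su analogously on (τ_s, τ_u).
The shares (w_fs, w_su − w_fs, 1 − w_su) are a nonnegative partition of
unity, so g_f + g_s + g_u = g holds identically (asserted at 1e-10).
Clamping is sharp at the reference time constants, not smoothed.  If the
ordering τ_f ≤ τ_s ≤ τ_u fails anywhere in the working range the designation
is rejected loudly rather than reordered, since reordering would silently
change the decomposition's meaning.

The working range defaults to [−80, +50] mV with a 0.1 mV grid; every root
is refined by bracketing and Brent's method, so results are grid-independent
below that step.

## Sign convention

The package defines every DIC with a minus sign on the current partials,
g_j = −Σ w (∂I/∂X)(∂X_∞/∂V), so that regenerative (positive-feedback)
pathways are positive: sodium activation contributes positively to g_f, the
delayed rectifier negatively to g_s.  Capacitance is factored out (C = 1
µF/cm² in the fixtures), so all curves carry conductance units.  The ungated
leak and the instantaneous ohmic conduction through already-open channels
are excluded from the DICs: they act on the membrane's quasi-instantaneous
timescale, not through gating kinetics.  They do enter the static I/V curve.

## Calcium handling

The pool obeys τ_Ca Ċa = −f (I_CaT + I_CaS) − Ca + Ca_rest, so its
equilibrium profile is Ca_∞(V) = Ca_rest − f · I_Ca,∞(V).  The
calcium-gated potassium activation has two pathways: a direct voltage
pathway weighted at its own τ_m, and an indirect pathway through Ca_∞(V)
weighted at τ_Ca (ultraslow).  Both are attributed to the KCa channel.  A
startup check warns if τ_Ca falls below τ_u anywhere, because the
decomposition assumes intracellular calcium acts only in the ultraslow
timescale.

**Frozen-calcium convention.**  Ca_∞(V) depends on the calcium-channel
densities, which makes the DICs mildly nonlinear in ḡ_CaT/ḡ_CaS through the
KCa coupling.  All sensitivity curves, superposition statements and the
compensation solve linearize around the *reference* calcium profile
("frozen calcium"): with the profile held fixed, every DIC is exactly linear
in every ḡ.  Sensitivities therefore match finite differences of the DIC
curves (frozen calcium) to machine precision, and the compensation closes to
solver round-off along the same path.  Residuals of the exact (unfrozen)
re-evaluation are available by evaluating the rebuilt model without a frozen
profile.

## Voltage markers

*Up-state V_osc* is the most depolarized zero of the quasi-static I/V curve
minus I_app — the unstable equilibrium around which intra-burst spikes
oscillate.  Because that oscillation is a fast–slow phenomenon, the curve is
evaluated with the ultraslow variables frozen at their resting-equilibrium
values; the ultraslow set contains every state variable whose time constant
reaches τ_u somewhere in the working range (h_CaT, h_CaS, m_KCa and the
calcium pool in the STG fixture).  The full steady-state curve is available
via `subsystem="static"`; its depolarized zero (≈ −43 mV in the STG
fixture) is the resting equilibrium, not the up-state, because at full
steady state the calcium-channel inactivations and the KCa activation wipe
out the depolarized inward current.

*Spike threshold V_th* is operationalized as a codimension-one degenerate
equilibrium of the static I/V relation: scale one calcium maximal
conductance by α (the applied current held at its reference value) and solve
jointly for I = 0 and dI/dV = 0.  The α sweep covers [0, 10] in steps of
0.05 with extremum tracking, followed by a two-variable Newton polish
(residuals below 1e-6 in native units, V refined to 1e-3 mV).  Among
multiple degenerate points the one closest to the reference resting
potential is returned.  For the STG fixture, V_th ≈ −50.3 mV at α ≈ 0.29 of
the reference ḡ_CaS, and V_osc ≈ −14.0 mV.

## Simulated voltage clamp

The clamp holds V algebraically; only gating and calcium states evolve
(initialised at their closed-form steady state for the hold potential).
After a ΔV = 1 mV step, the read-outs follow fixed windows: I_0 is the first
sample after the onset (including the instantaneous ohmic jump, so the
passive component cancels from all dynamic currents), I_f the minimum
within 2 ms, I_s the minimum in [10, 100] ms (falling back, flagged, to the
10 ms amplitude when the window minimum sits on the left boundary), I_u the
minimum from 1 s to the end.  Then ΔI_f = I_f − I_0, ΔI_s = I_s − I_f,
ΔI_u = I_u − I_s telescope exactly to ΔI = I_u − I_0, and
g_j(V* + ΔV/2) = −ΔI_j/ΔV.

Default sampling is 0.05 ms before 10 ms and 1 ms after; default step
duration 5 s.  Default holds span −75 to −48 mV (rest to just below spike
threshold).  This is the protocol's validity domain in the STG fixture: at
more depolarized holds the ultraslow current change is outward, its
"minimal amplitude from 1 s" read-out sits at the 1 s boundary, and the
slow calcium pool (τ_Ca = 2 s) has not equilibrated, biasing |g_u| low by
20–30%.  Within the default holds, measured and analytic curves agree to
within 10% at the curve peaks (0.05 mS/cm² absolute near zero) for the STG
fixture.

The same agreement **cannot** be expected for the Hodgkin–Huxley fixture at
depolarized holds, and the package does not claim it: squid sodium
inactivation (τ_h ≈ 1–6 ms) sits squarely between the fast (≈ 0.2 ms) and
slow (≈ 5 ms) references, so there is no timescale-separation limit in
which the window extraction and the log-weight attribution coincide; they
differ by tens of percent above −70 mV.  The two-timescale *structure*
(g_u ≡ 0, ΔI_u ≈ 0) does hold.

## Sensitivity analysis and localization

Sensitivity curves ∂g_j/∂ḡ_i are the per-unit-conductance pathway terms
(independent of ḡ_i itself).  Values are reported at V_th and V_osc, and
normalized localization curves divide each curve by its maximum absolute
value (all-zero curves are flagged and left unnormalized).  The
colocalization score of two channels in a timescale is the magnitude of the
inner product of their L2-normalized sensitivity curves (cosine similarity):
1 means identically-shaped sensitivity ranges regardless of sign or
amplitude, which is what makes mutual compensation possible.  In the
reference STG fixture the slow-timescale score of (A, CaS) is 0.99 against
0.79 for (A, CaT); after a +4.5 mV rightward shift of the A-type activation
the ordering reverses (0.90 vs 0.95).

`shift_activation` translates a gate's steady state *and* time constant
along the voltage axis and returns a new model, leaving the original
untouched.

## Compensation

Targets (g_s(V_th), g_s(V_osc), g_u(V_th), and the net static current at
threshold) are computed once on the reference model and held fixed across
perturbations.  The unknowns are (I_app, ḡ_Kd, ḡ_A, ḡ_KCa); sodium is
excluded because the calcium channels barely touch the fast timescale over
their range of variation.  A is assembled from the analytic sensitivities at
the marker potentials, b from the targets minus the fixed channels'
(Na, CaT, perturbed CaS) contributions and leak; the solve is a direct dense
4×4 with a condition-number report (error above 1e10).  Negative
conductances are legitimate solutions, flagged `nonphysiological` — they
mark the physiological limits of the mechanism rather than solver failure.
A 3-unknown variant drops the applied-current unknown and the static row.
Because b is affine in the perturbed ḡ and A is fixed, every solution
component is exactly affine along a perturbation path (verified, not
assumed, in the tests).

## The STG fixture

Parameters live in `src/neurodic/data/stg_kinetics.yaml`, the single place
where literature-derived kinetics are recorded.  Choices the published
sources leave open, and how this package resolved them:

* **Calcium-channel activation speeds.**  The fixture assigns the fast
  bell-shaped activation time constant to the transient (CaT) channel and
  the slower sigmoidal one to the slow (CaS) channel.  This matches the
  physiology the decomposition is meant to expose — the transient calcium
  channel participates in fast excitability; the slow calcium channel
  contributes nothing to the fast timescale (its fast sensitivity is < 1% of
  the fast DIC peak) and feeds the calcium pool through its slow
  activation.
* **Calcium pool.**  f = 9.3952 µM per µA/cm² (a whole-cell conversion
  factor scaled to membrane-area units), Ca_rest = 0.05 µM, and
  τ_Ca = 2000 ms.  The pool time constant is chosen so that intracellular
  calcium is a genuinely ultraslow integrator of calcium entry — it exceeds
  τ_u everywhere — and so that the reference density set fires in bursts
  (≥ 2 spikes per burst with interburst silences, period ≈ 4 s) rather than
  in slow single-spike waves, which is what faster pool variants produce at
  these densities.  The two voltage markers are independent of τ_Ca.
* **Reference applied current** is 0; spike detection defaults: 0 mV upward
  crossing, 2 ms refractory, burst gap 5× the median ISI (reporting
  conventions only — they do not enter the method).

## Numerical choices

Time integration uses LSODA with rtol = atol = 1e-8 (1e-10 absolute for
clamped gating states); clamp traces are sampled on a piecewise grid fine
enough (0.05 ms) to resolve the 2 ms fast window.  Steady-state gating
derivatives are analytic for every registry form that has one and central
finite differences with a 1e-3 mV step otherwise (the Hodgkin–Huxley
rate-pair forms).  Linear algebra is plain dense NumPy.  Simulations in the
test suite use 20–30 s of model time with the first 6–8 s discarded as
transient; burst statistics are taken from complete interior bursts.

## Known limitations

* The decomposition and the clamp protocol agree only where gating
  timescales separate cleanly; the Hodgkin–Huxley model above −70 mV is a
  documented counterexample (see the clamp section).
* With this transcription the ultraslow sensitivity of the slow calcium
  channel at spike threshold is slightly negative (the restorative
  inactivation term outweighs the small ultraslow share of its activation).
  Two documented consequences: compensating a several-fold CaS *increase*
  drives ḡ_KCa negative rather than positive, and high-CaS bursters show
  intraburst acceleration (decreasing initial ISIs) but not the full
  parabolic (decreasing-then-increasing) ISI profile.  The corresponding
  acceptance checks are left failing rather than masked.
* Compensation maintains four point values of the curves; large
  perturbations can still reshape the curves away from those points, and
  the physiological validity of a solution is limited by the availability
  of channels with overlapping sensitivity ranges.
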