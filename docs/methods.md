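# Methods

`cuffwave` simulates the short-term central hemodynamic consequences of
inflating oscillometric cuffs above the wrists and/or ankles, in a virtual
patient with no cardiovascular regulation (no baroreflex, no cerebral
autoregulation, constant left atrial pressure).  This note documents the
model, its numerical treatment, the packaged synthetic baseline, and the
choices made where the design was genuinely open.

## Model overview

The arterial system is a rooted binary tree of 71 axisymmetric, tapered,
elastic vessel segments, from the aortic root to the terminal limb and
visceral arteries.  Blood is incompressible and Newtonian (density
1050 kg/m³, viscosity 3.5 mPa·s).  Each segment obeys the 1-D
cross-section-averaged mass and momentum equations

    ∂A/∂t + ∂(Au)/∂x = 0
    ∂u/∂t + ∂(u²/2 + P/ρ)/∂x = −k_f u/A,        k_f = 22πμ/ρ,

with luminal pressure `P = P_ext + PT(A; x)` given by an algebraic tube law
and a flat-ish velocity-profile friction coefficient (22, configurable;
Poiseuille would be 8).  At bifurcations the solver imposes continuity of
static luminal pressure and conservation of flow.  Terminal segments drain
through three-element Windkessel (R1–C–R2) elements into a constant venous
back-pressure (4 mmHg).  Inflow comes from a time-varying-elastance left
ventricle filled from a constant-pressure left atrium.

## Tube laws

**Elastic (everywhere):** `PT = β(x) (√(A/A0(x)) − 1)` with
`β = (4/3)·Eh/r0` and the stiffness-radius relation
`Eh/r0 = k1 e^{k2 r0} + k3` (k2 < 0, so k1 governs small arteries and k3
large ones).  This law linearizes at A0 to the Moens–Korteweg-type speed
`c0² = (2/3)(Eh/r0)/ρ` and reaches zero area at the finite buckling
pressure `PT = −β`.  The alternative square-root law
`PT = β(1 − √(A0/A))` was implemented first and rejected: its relative
compliance is bounded by `2/|PT|` at negative transmural pressure, which
makes a local value-and-slope match to any collapsing law unsolvable and
capped simulated cuff occlusion at ~70% flow reduction, far from the
near-total occlusion a suprasystolic cuff must produce.

**Collapsible (under cuffs):** the empirical law
`A(PT) = d·ln(a·PT + b) / (1 + e^{−c·PT})`, which spans deep collapse
(sigmoid) to logarithmic distension, with its compliance peaking within a
few mmHg of PT = 0 — the mechanism behind the oscillometric maximum.  No
published constants are packaged; instead, per segment, `b` and `d` are
calibrated so that the law matches the elastic law's area *and* relative
compliance at the segment's baseline mean transmural pressure (`c` is
raised for stiff small arteries when the default tail is too compliant).
This makes a cuff at 0 mmHg an exact no-op by construction.  The remaining
free constants are `a = 0.02/mmHg` and `c = 0.04/mmHg`, chosen once so the
occlusion structure is physiological: partial occlusion between MAP and
systolic pressure, >99% mean-flow reduction once the cuff exceeds systolic
pressure, and a plateau above.  Sharper sigmoids (c ≥ 0.05/mmHg) make the
collapse run away below systolic pressure; softer ones (c ≤ 0.03/mmHg)
leave the artery conducting at 130 mmHg.

**Under-cuff rescaling:** for a cuff at pressure `Pc`, each covered segment
keeps the elastic functional form but with new `(β′, A0′)` chosen so the
elastic law matches the collapsible law in value and slope at the expected
operating point `PT* = PT0 − Pc` (PT0 = the segment's converged baseline
mean pressure at its midpoint).  The elastic family satisfies
`A/(dA/dPT) = (β + PT)/2` identically, so the match is closed-form:

    β′ = 2A*/C* − PT*,      A0′ = A*/(1 + PT*/β′)²,

always solvable (β′ > 0).  Scales are defined at the segment midpoint and
applied multiplicatively along the taper.  Matching value plus first
derivative (not second derivative, not a least-squares window) is the
simplest local approximation around the operating point.

## Heart model

Ventricular pressure is `p_lv = E(t)(V − V0)`.  `E(t)` is a raised cosine
from Emin to Emax and back over the systolic interval `[0, tm)`, then
constant at Emin — the simplest shape honoring the four named constants
(Emin, Emax, tm, T).  The mitral and aortic paths are resistive-inertial
(`Rla, Lla`, `Rlv, Llv`); valves are pressure-gated switches, and the
aortic valve tolerates a cumulative retrograde volume `Vb` per beat before
closing (Vb = 0 recovers an ideal diode).  The end-diastolic volume `Vlv`
initializes each run; in the periodic state the filling volume is emergent.
Baseline values: T = 0.8 s, Emin = 0.08 mmHg/ml, Emax ≈ 1.95 mmHg/ml,
tm = 0.32 s, V0 = 10 ml, Vlv = 125 ml, pla = 8 mmHg, Vb = 2 ml.  Emax sits
at the low end of the normal range; together with the terminal-resistance
scale it sets how an afterload increase splits between a pressure rise and
a cardiac-output fall, and the packaged value reproduces the observed
~1:1 split (MAP up ~10%, ascending-aorta flow down ~10% under four-limb
occlusion).

## Numerics

Finite-volume two-step Lax–Wendroff (Richtmyer): half-step states at cell
interfaces, conservative update of cell averages, semi-implicit friction.
Mass is conserved to round-off by construction; the momentum equation is
integrated in velocity (Bernoulli) form so the taper enters through the
pressure flux.  Boundaries use the Riemann invariants of the tube law,
`W± = u ± 4c` along `dx/dt = u ± c`:

* junctions solve a scalar root problem in the shared luminal pressure
  (analytic-derivative Newton with a bisection safeguard); pressure
  continuity is exact by construction and the flow residual is driven to
  1e-13 relative.  The reported residual is normalized by
  `max(|Qp|, Σ|Qc|, 10⁻³·cA)` because at flow-reversal instants the
  instantaneous flow passes through zero while the round-off floor of the
  balance is `ε·cA`;
* terminals advance the Windkessel capacitor by forward Euler and solve
  the interface area against the outgoing invariant;
* the root converts the elastance model's valve flow into an interface
  flux (or a prescribed periodic inflow — used by the verification
  oracles).

The time step satisfies a global CFL condition (Courant number 0.9)
re-evaluated every step; the area floor `A ≥ 10⁻⁶·A0` bounds wave speeds in
fully collapsed states.  Convergence to the periodic steady state is a
relative L2 distance between consecutive cycles of the root pressure
waveform.  Two presets: `fine` (Δx = 2.5 mm, ε = 10⁻⁴, ≤60 cycles) and
`coarse` (Δx = 5 mm, ε = 5·10⁻⁴, ≤40 cycles).  Central metrics differ by
<0.5% between the two, so the test-suite and acceptance pipelines use
`coarse` (one steady state ≈ 3–5 s on one CPU); `fine` is the default for
standalone runs.  The hot loop is compiled with numba; results are
bit-reproducible for fixed settings.

## The packaged baseline (synthetic)

The supplementary parameter table of the original study is not packaged;
per the documented fallback, the baseline is a **synthetic** 71-segment
tree with anatomically representative topology and dimensions for a young
adult male (~175 cm): aorta (15 serial pieces), coronaries, carotids
(common/internal/external), vertebral + arm chains ending in radial,
ulnar and interosseous arteries, visceral branches, and symmetric leg
chains ending in anterior/posterior tibial and peroneal arteries.  Legs
are exactly left-right symmetric; arms share geometry but the right side
is fed through the brachiocephalic trunk.  Terminal resistances partition
cardiac output into conventional regional fractions (brain ~15%, kidneys
~15%, splanchnic ~22%, each hand ~4.5%, each foot ~5% of its leg's 12.5%);
R1 is set to the leaf's characteristic impedance (capped at 0.4·R_total)
to minimize spurious terminal reflections, and compliances give every
terminal the same RC time (0.55 s).  `scripts/build_baseline.py` scales
all terminal resistances (secant iteration) so the simulated
ascending-aorta pressure is close to 125/95/80 mmHg (achieved:
123.6/94.9/82.5 at the fine preset) and freezes the result into
`src/cuffwave/data/`.  A global stiffness scale of 0.62 on (k1, k3) sets
the aortic pulse wave speed to a young-adult value (~5 m/s).

What the synthetic baseline does and does not show: relative changes in
central pressure/flow under cuff occlusion are driven by the *fraction* of
cardiac output occluded and the heart's source impedance, both of which
are physiologic here, so the package's relative-change results are
meaningful; absolute waveform morphology (augmentation, peripheral
amplification detail) depends on the exact geometry/stiffness tables and
is not claimed to reproduce any specific subject.  Two measured
discrepancies are documented rather than tuned away: the under-cuff
area-pulsation envelope has a flat top with its argmax at a cuff pressure
of 80 mmHg (15 mmHg below central MAP; the local distal-radial mean
pressure is 92 mmHg and partial occlusion attenuates the local pulse
pressure), and the mid-cuff area still pulses at 150 mmHg because the
matched elastic law lets the section reopen transiently in systole (the
end-of-cuff section stays collapsed).

## Cuff geometry

Wrist cuffs compress the distal radial, interosseous and ulnar arteries;
ankle cuffs the distal anterior and posterior tibial arteries.  All cuffs
are 0.15 m wide and aligned so each cuff ends at the distal end of the
longest covered artery; a shorter artery is covered over
`width − (L_longest − L)` of its distal end (clipped to its length).  Each
covered artery is split into a pre-cuff segment and an under-cuff segment
(terminal and distal taper inherited); the cuff pressure acts as a uniform
external pressure on under-cuff segments only, and every other artery sees
zero external pressure.  Sweeps run 0–150 mmHg in 10 mmHg steps, each
pressure an independent steady-state experiment restarted from the same
initialization; 150 mmHg is the documented cap (results plateau well below
it and deeper collapse only stresses the area floor).

## Metrics

MAP and mean flow are period averages (trapezoid on the uniform sample
grid, period closed with the first sample); SP/DP are pressure extrema;
the area-pulsation amplitude is max − min of the cross-sectional area.
Relative changes are percentages versus the same probe's no-cuff baseline.
Standard probes sit at the midpoints of the ascending aorta, the left
common carotid (distal half) and the suprarenal abdominal aorta, plus
radial-artery probes 2 cm before the cuff, mid-cuff, and at the cuff's
distal end.

## Sensitivity analysis

Seventeen parameters are studied: the twelve heart constants, the terminal
resistance/compliance scalings SR and SC, and the stiffness constants
k1, k2, k3 — all as multiplicative factors uniform in ±10% of default.

* **Local (one-at-a-time):** one parameter varied over a multiplier grid
  with four-limb cuffs at 150 mmHg; left-CCA outputs reported as % of the
  no-cuff default baseline.
* **Global (Sobol'):** first-order indices by Saltelli sampling on a
  scrambled Sobol' sequence, estimator `S1_i = mean(f_B (f_AB_i − f_A))/V`,
  percentile-bootstrap 95% CIs over sample rows (1000 resamples).  The
  estimator is validated against analytic indices (Ishigami, additive
  linear model) and against scipy's independent implementation before use
  on the simulator.  Failed simulations are dropped and counted; the
  analysis aborts if more than 1% fail.
* **Paired cohort:** per sampled patient, a no-cuff baseline and a
  four-limb 150 mmHg run; the distribution of relative changes summarizes
  inter-patient variability.  The full-scale study size (8000 pairs) is
  far beyond a desk run; the test suite uses 12 pairs and the acceptance
  script 8 pairs at the coarse preset, which pins the cohort *mean* well
  (patient-to-patient spread of the relative changes is a few percentage
  points, so the standard error of the mean at n = 8 is ≈ 0.5 pp).

## Known limitations

* No regulation, microcirculation, venous return or cardiopulmonary loop:
  results are short-term, worst-case estimates by design.
* Static cuff mechanics only: no inflation/deflation dynamics, no wall
  viscoelasticity, circular cross-sections even when buckled.
* The under-cuff constitutive constants (a, c) are package calibrations to
  the qualitative occlusion physiology, not measurements.
* The baseline tree is synthetic; absolute flows per bed are conventional
  textbook fractions, and cardiac output (~3.6 l/min at rest) sits at the
  low end of normal as a consequence of matching the pressure targets with
  a low-normal Emax.
* At cuff pressures just above MAP the collapse is bistable in principle;
  the solver's converged branch is selected by the common quiescent
  initialization, which is also why each sweep pressure restarts fresh.
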