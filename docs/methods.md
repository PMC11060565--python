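# Methods

`pulsevol` estimates stroke volume (SV) and four cardiovascular parameters
from a single cuff-calibrated radial-artery pressure waveform by fitting a
0-1D model of the systemic circulation to the beat's Fourier signature.
This note documents the model, its numerical treatment, the synthetic data
used for testing, and the design choices that were genuinely open.

## The forward model

**1D domain.** The systemic arteries are a binary tree of tapered elastic
vessels (55 segments in the shipped production tree; a 7-segment reduced
tree for fast work).  On each vessel the cross-sectionally averaged
incompressible flow equations are solved for area `A(x,t)` and flow
`Q(x,t)`:

    dA/dt + dQ/dx = 0
    dQ/dt + d/dx(Q²/A + B) = −8πν Q/A + S_geo

assuming a parabolic velocity profile (hence the 8πν friction).  The system
is closed by the tube law

    P = P0 + f(r0) (1 − √(A0/A)),      f(r0) = (4/3)(k1 e^{k2 r0} + k3)

with vessel radii defined at the nominal distending pressure P0 = 97 mmHg
and the exponential taper `r0(x) = r_in (r_out/r_in)^{x/L}`.  `B = f√(A0A)/ρ`
is the pressure-integral flux; the geometric source `S_geo` (from df/dx and
dA0/dx) is constructed so that the rest state `A = A0(x), Q = 0` is an exact
equilibrium.  Wall constants and blood properties follow the classical
parameterization of this model family: k1 = 2·10⁷ g s⁻² cm⁻¹,
k2 = −22.53 cm⁻¹, k3 = 8.65·10⁵ g s⁻² cm⁻¹, ρ = 1.06 g/cm³,
μ = 0.049 g/(cm·s).  All internal arithmetic is CGS (1 mmHg = 1333.22
dyn/cm²); user-facing units are mmHg and ml.

**Terminals.** Every terminal vessel drains into a three-element Windkessel
(R1 in series with parallel R2‖CT referenced to PT, default 0 mmHg), with
the fixed split R1 = 0.2·RT.  The Windkessel ODE is advanced by explicit
Euler in lockstep with the 1D time step; the stability margin (dt < R2·CT,
half the formal explicit-Euler bound 2·R2·CT) is verified at setup and
violations raise a configuration error.

**Heart.** The left ventricle is a time-varying elastance
`P_lv = E_lv(t)(V_lv − V0)` with

    E_lv(t) = E_min (1 − φ(t)) + E_max φ(t)
    φ(t) = a sin(πt/t_m) − b sin(2πt/t_m)  on [0, t_m),  0 on [t_m, T)

driven by a within-beat clock that resets every period; the valve phases
(filling → isovolumic contraction → ejection → aortic closing → isovolumic
relaxation) are a separate state machine.  Filling and ejection have
resistance/inertance ODEs integrated with classical RK4; the mitral valve
closes when `V_lv` exceeds `V_max` (or, as a robustness guard against
pathological parameter combinations explored by the optimizer, if mitral
flow would reverse); the aortic valve opens when `P_lv > P_a`, starts
closing at the first retrograde flow, and shuts once the accumulated
backflow exceeds `V̄_b`.  φ is used exactly as written, without renormalizing
its peak to 1; with the default shape constants a = 0.9, b = 0.25 the peak
activation is ≈ 1.01 (reported in the calibration diagnostics as `max_phi`),
so the nominal `E_max` is effectively the peak elastance.

Fixed heart constants (not printed in the primary description of this model
family; chosen as representative of elastance-ventricle lumped models and
overridable in `HeartParams`): E_min = 0.06 mmHg/ml, P_la = 8 mmHg,
R_la = 0.01 and R_lv = 0.006 mmHg·s/ml, L_la = L_lv = 5·10⁻⁴ mmHg·s²/ml,
V̄_b = 1.5 ml.  `V_max = 120·S³` ml and `V0 = 15·S³` ml scale with the
body-size factor S.

**Personalization.** S = height/175 multiplies all lengths and radii;
terminal resistances scale by 1/S³ and compliances by S³ (a vascular bed
scales volumetrically).  The four estimated parameters are `E_max`, `t_m`,
and global multipliers `S_R`, `S_C` on all terminal resistances and
compliances.

## Numerics

* **Scheme.** Two-step (Richtmyer) Lax–Wendroff with fluxes and sources at
  half points; second order on smooth solutions (the test suite measures the
  observed order by Richardson refinement).
* **Grid.** Uniform per-segment spacing, at least 7 nodes per segment.
  Profiles: production dx ≤ 0.2 cm; `FAST` dx ≤ 1 cm and `COARSE` dx ≤ 2 cm
  for test-scale work on the reduced tree.
* **Time step.** dt = CFL·min(dx/c₀) with CFL = 0.5, evaluated at the rest
  state and rounded so an integer number of steps tiles one heart period.
  Under the tube law used here the wave speed *decreases* with distension,
  so the rest-state bound holds with a wide margin throughout the beat.
* **Boundaries.** Characteristic (ghost-point) closures using the Riemann
  invariants `W± = u ∓ 4c` of the homogeneous system: quadratic foot
  interpolation at the departure point plus the friction source integrated
  along the characteristic (omitting it biases the boundary flux and was the
  dominant per-cycle mass error).  The inlet solves `Q_imposed/A + 4c(A) = W⁻`
  for the root area; each terminal solves the outgoing characteristic
  together with the explicit-Euler Windkessel relation (characteristic
  first, then the pressure update is committed); each bifurcation solves a
  reduced 3-unknown Newton system (areas only; flows eliminated through the
  characteristics) for mass conservation and pressure continuity, scaled so
  the 10⁻¹² tolerance is expressed relative to the characteristic flow scale
  A·c, which is attainable in double precision even near zero net flow.
* **Initialization.** Uniform pressure at the subject's diastolic value:
  areas from the tube law, Q = 0, Windkessels at the same pressure, ventricle
  full (V = V_max) in filling phase.  This leaves no startup discontinuity
  (initializing at A = A0 = the 97 mmHg geometry while the Windkessels sit at
  diastolic pressure produces a startup shock that destabilizes fine grids).
* **Periodic convergence.** Cycles repeat until the radial-site waveform
  changes by less than `tol` (default 0.5 mmHg, max 15 cycles) on two
  *consecutive* cycles — valve events shift by whole time steps between early
  cycles, so the cycle-to-cycle metric decays non-monotonically and a
  single-cycle rule can stop on a lucky dip.  One further recording cycle
  produces the reported fields; its metric is the one reported.
  Inside the calibration objective the model instead runs a fixed 9 + 1
  cycles regardless of tolerance, which makes the objective a smooth,
  deterministic function of the parameters.

## The objective and the optimizer

One beat is summarized by the 13-vector `c = (a0, a1..a6, b1..b6)` of its
sine–cosine Fourier series (the constant and six harmonic pairs), computed
by direct projection sums on a uniformly sampled beat (exact for
band-limited signals; non-uniform beats are first resampled to 128 points by
monotone cubic interpolation).  The fitting error is the unweighted sum of
squared coefficient differences between the simulated and measured radial
beats; the final fit quality is also reported as MAPE at the measured sample
points.

Fourier coefficients are phase-sensitive, so both beats are foot-aligned
before projection.  The foot is located on the *6-harmonic reconstruction*
of the beat, not on the raw samples: the diastolic minimum of a raw beat is
flat, and with a few percent of measurement noise its literal argmin wanders
by tens of samples, rotating the beat's phase and corrupting the target
signature (in testing this raised the objective at the true parameters by
three orders of magnitude).  `sample_waveform` still places the raw minimum
at t = 0 for plotting and export.

**Stage 1 — particle swarm.**  15 particles, 10 iterations, global-best
update with inertia 0.7, cognitive/social weights 1.5/1.5, velocities
clamped to 20% of each bound range, reflecting box faces, seeded RNG.
Bounds: E_max ∈ [0.5, 8] mmHg/ml, t_m ∈ [0.3, 0.95 T] s, S_R ∈ [0.3, 5],
S_C ∈ [1, 30] — covering the estimated population spread with ≈3 SD margin.

**Stage 2 — gradient refinement.**  The objective is a sum of 13 squares,
so the refinement is a trust-region Gauss–Newton iteration
(`scipy.optimize.least_squares`) on the residual vector, run in normalized
box coordinates with finite-difference steps of 10⁻² of the box span.  Two
properties of the landscape drive these choices: (i) `E_max` and `S_R` trade
off along a narrow curved valley that generic quasi-Newton descent follows
poorly, while Gauss–Newton's J^T J curvature model tracks it in a few tens
of evaluations; (ii) valve events are quantized to the time step, giving the
objective a fine staircase texture that smaller difference steps would
sample instead of the underlying trend.  The iteration is restarted while it
improves, and re-launched from up to four additional particle-swarm
personal-best positions that lie in visibly different regions of the box —
but only while the incumbent fit error still corresponds to a visible
(≳ sub-mmHg) waveform discrepancy.  The best point ever evaluated is
returned, so the refined objective never exceeds the swarm's.  For generic
scalar objectives (no residual structure) `gradient_refine` falls back to
bound-constrained L-BFGS-B with central differences in the same normalized
coordinates.

Unstable or non-physical forward runs score a large fixed penalty (10⁹) and
are logged; the pipeline is bit-deterministic for a fixed seed.

## Synthetic data

No tonometry recordings are distributed; the cohort tools emulate them:

* `generate_synthetic_subject` forward-simulates the radial beat of a
  subject with known parameters, applies *multiplicative* Gaussian noise
  (applanation-tonometry noise scales with signal; default off, 2% in the
  recovery studies), re-foot-aligns, and attaches the generating truth and
  true SV.  The returned cuff pressures are the simulated beat's extremes,
  as a cuff calibration would make them.
* `generate_cohort` draws parameters from the group-level means/SDs
  estimated in hemodialysis patients (E_max 3.13 ± 1.27 mmHg/ml, t_m
  0.57 ± 0.09 s, S_R 1.66 ± 0.71, S_C 10.18 ± 4.34) or healthy controls
  (2.56 ± 1.06, 0.56 ± 0.05, 2.02 ± 0.75, 11.89 ± 4.39), truncated to the
  calibration bounds by reject-and-resample; heights from the groups'
  anthropometrics; cuff pressures and heart periods from configured
  plausible ranges.

What this does and does not establish: recovery tests on these data show
that the four parameters are *identifiable from a single beat generated by
the same model family* under realistic noise — the method's core numerical
claim.  They cannot show robustness to model misspecification (real arterial
trees are not the shipped geometry), to beat-to-beat variability, to
baseline drift (a generator flag exists but is off by default), or to device
transfer functions; conclusions about real patients require real recordings.

**Study conditions for the shipped recovery tests** (scaled down to desk
hardware): the 7-segment reduced tree with the `COARSE` grid (dx ≤ 2 cm),
fixed 10-cycle objective runs, PSO 15×10 plus the Gauss–Newton refinement.
One calibration ≈ 300–700 forward runs (≈ 1 minute); the noiseless
self-recovery returns all four parameters within ~1%, and the five-subject
2%-noise cohort keeps median per-parameter errors well inside 15%.

## Statistics

Agreement between two SV estimators uses Bland–Altman analysis on natural
logs (ratio-scale data): mean and SD of `ln(model) − ln(reference)`, limits
of agreement at mean ± 1.96 SD, all antilogged into geometric-mean ratios.
Natural logarithms are used because the reported mean difference (−0.41) and
ratio (0.66) of the hemodialysis validation study are mutually consistent
only under base e.  Pearson correlation is delegated to scipy.

## The shipped trees

The 55-segment tree geometry (lengths, proximal/distal radii at 97 mmHg,
binary connectivity from the ascending aorta to the tibial/forearm/visceral
terminals) follows the standard systemic-tree description for a 175 cm
adult.  The nominal terminal lumped parameters are constructed, not
transcribed: terminal conductances split a nominal total resistance of
0.55 mmHg·s/ml in proportion to r_out^2.7 (Murray-type scaling), and each
bed's compliance is set so that with the population-mean calibration
scalings (S_R ≈ 2, S_C ≈ 10) the bed's time constant R2·CT is ≈ 1.5 s —
i.e. the *calibrated* model, not the nominal one, lands at a physiological
systemic resistance (≈ 1.1 mmHg·s/ml) and diastolic decay.  The 7-segment
toy tree (aorta, arm with radial/ulnar terminals, trunk, visceral and leg
beds) uses hand-picked values under the same two constraints.  With the
control-mean parameters the 55-segment model shows peripheral systolic
amplification (radial SBP above aortic SBP); the toy tree, lacking the
distributed reflection sites, does not — which is why the amplification
regression test runs on the full tree.

## Known limitations

* Single ventricle, constant left-atrial pressure: no atrial kick, no
  Frank–Starling response, no venous return dynamics.
* No arteriovenous fistula segment; no coronary or pulmonary circulations.
* The characteristic boundary closures are formally first-order accurate;
  the per-cycle volume-balance defect they leave is measured in the test
  suite (< 1% of stroke volume on the production grids).
* No vessel-collapse handling: the tube law's admissible range requires
  `P − P0 < f`, and strongly hypotensive parameter combinations can leave it
  (such runs score the penalty during calibration).
* `S_C` is the most weakly identified of the four parameters (the objective
  is an order of magnitude less curved along it than along `E_max`, `t_m`,
  `S_R`), which is visible in the recovery spreads.
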