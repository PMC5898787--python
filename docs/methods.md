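# Methods

## The model

`synstress` simulates NMDA-receptor-dependent synaptic plasticity at a
glutamatergic postsynapse as a deterministic reaction-kinetics ODE system
in normalized concentration units, with time in hours. It has three
coupled layers.

### Cytosolic core: a tristable activation switch

Three species — NSF, nonactivated short-tailed AMPA subunits [R_S] and
activated subunits [R'_S] — obey

    d[NSF]/dt  = p_NSF − z_NSF [NSF] − I
    d[R_S]/dt  = p_RS  − z_RS  [R_S] − I
    d[R'_S]/dt = −z_R'S [R'_S] + I,
    I = k0([R'_S]) [R_S][NSF] − k4([R_S]) [R'_S].

The rate "constants" k0 and k4 are S-shaped functions of the species that
form the activating dimers: activated homomers R'_S R'_S promote further
activation (k0 grows with [R'_S]), nonactivated heteromers R_S R_L promote
deactivation (k4 grows with [R_S]). This double positive feedback is the
memory element. Dimerization itself is treated in quasi-steady state:
[R'_S R'_S] = (k1/k2)[R'_S]² and [R_S R_L] = (k5/k6)[R_S][R_L], with the
long-tailed pool [R_L] a constant parameter (default 1); the feedback on
activation lives entirely inside the S-curves, while the algebraic pools
feed membrane trafficking.

Because I enters all three equations with matched signs, d[NSF]−d[R_S] and
d[R_S]+d[R'_S] are linear, and every stationary state satisfies the
complementary relation p_NSF − z_NSF[NSF] = p_RS − z_RS[R_S] =
z_R'S[R'_S]. Substituting reduces the stationary problem to a scalar
equation 0 = P(x) + D(x) in x = [R'_S], with a nonnegative production
blade P = k0(x)·R_S(x)·NSF(x) and a nonpositive decay blade
D = −(z_R'S + k4)x. Intersections of the blades are the equilibria.

### S-curve calibration

The S-curves are piecewise linear by default (a low plateau, a linear
ramp, a high plateau); a logistic variant matched to the plateaus at the
ramp ends is available (`shape = smooth_sigmoid`) and preserves the whole
qualitative structure. The plateau and breakpoint values are free
parameters of the model class; the shipped defaults,

    k0: 1.3 → 2.8 over [R'_S] ∈ [0.42, 0.46]
    k4: 0.2 → 2.5 over [R_S]  ∈ [0.66, 0.74]

were calibrated once with the equilibrium module so that the all-ones
parameter set has

* exactly five stationary points, alternating stable/unstable
  (x ≈ 0.224, 0.314, 0.396, 0.427, 0.525) — the LTD, active and LTP
  states separated by the two basin boundaries;
* a tristable p_NSF window ≈ (0.83, 1.09), LTD-only below ≈ 0.80 and
  LTP-only above ≈ 1.21, so the baseline p_NSF = 1 sits inside the window
  and both the ×3 elevation and the ×0.3 / ×0.75 reductions used by the
  intervention protocols cross into the monostable regimes;
* a settled LTP/active homomer ratio (x_LTP/x_active)² ≈ 1.76, which the
  hour-5 probe reads as ≈ 2 because the readout catches the tail of the
  induction excursion.

Narrow bistable shoulders flank the tristable window (the three stable
branches are not born simultaneously); the bifurcation table folds these
shoulders into the neighboring regime label so that the regime sequence
along p_NSF is always monostable-LTD → tristable → monostable-LTP, while
the per-grid-point stationary lists retain the exact structure.

### Signaling cascade: stimulation and cortisol → production rates

The presynaptic signal s(t) drives CaMKII (b_CaMKII·s − z·CaMKII) and —
only in coincidence with postsynaptic depolarization, encoded by the gain
σ — tPA release (p_tPA·σ·s − z_tPA·tPA). Presynaptic activity releases
proBDNF (p_BDNF·s); tPA converts it to mature BDNF
(proBDNF + tPA ↔ mBDNF with rates k8, k9, the reverse rate kept as
printed). Cortisol occupies MR and GR by Michaelis–Menten saturation
([C]/([C]+M) with M_MR = 1e-4 ≪ M_GR = 5), MR drives and GR suppresses
TrkB expression (production MR·(1−GR)·p_TrkB_expr), GR drives p75 on top
of a small constitutive floor (p_p75_basal + p_p75_expr·GR). mBDNF·TrkB
and proBDNF·p75 complexes form by conservative mass action (binding
consumes ligand and receptor — the internalizing-receptor reading;
a catalytic variant is switchable), and the activated complexes move the
modulation level a:

    da/dt = b_a (actTrkB − actp75) − z_a a,

which shifts the core production rates, p_NSF_eff = max(0, p_NSF+u_NSF·a)
and p_RS_eff = max(0, p_RS+u_RS·a). The sign convention here follows the
biology (TrkB signaling raises protein production, p75 signaling lowers
it); the opposite convention is available as `a_sign_convention =
"p75_positive"` for completeness.

Fixed constants use the normalized set (unity except M_MR, M_GR, u_NSF=3,
z_tPA=0.5, z_proBDNF=0.1, z_actTrkB=z_actp75=2, p_BDNF=10, p_actTrkB=10,
p_tPA=2). Four constants the reaction scheme leaves unnamed were
calibrated once against the scenario outcomes and then frozen:

* `p_TrkB_expr = 0.35`. Under conservative binding the TrkB signal
  saturates at the receptor replenishment flux p_TrkB_expr·MR·(1−GR), so
  this constant sets the ceiling of the LTP drive; 0.35 makes the ceiling
  at low-normal cortisol just cross the upper p_NSF fold while the
  stressed ceiling stays below it.
* `p_p75_basal = 0.025`. A constitutive p75 floor is biologically standard
  and is what gives the glucocorticoid-depleted noncorrelated scenario its
  small but real depression.
* `p_actp75 = 2`. Faster p75 association shortens the proBDNF tail after
  stimulation; without it the slowly decaying drive re-captures the
  synapse into the active state before LTD can commit.
* `u_RS = 0.3`. The sensitivities are deliberately unequal (u_NSF = 3 is
  the dominant channel). A unit R_S sensitivity lets the LTD drive
  suppress [R_S], which disarms the heteromer deactivation feedback
  (k4 falls to its low plateau) exactly when the LTD state needs that
  brake to hold; with u_RS = 0.3 the brake stays armed and LTD commits.

### Membrane trafficking and transmission

Heteromers are inserted into the membrane by a CaMKII-catalyzed reaction
(k11), removed by glutamate-catalyzed decomposition (k12_removal, with
glutamate identified with s(t)) and exit spontaneously (k12_vanish); the
two removal processes share the printed symbol k12 and default to the same
value. The membrane homomer pool is algebraic, proportional to the
cytosolic quasi-steady-state pool. Transmission is
s_in = 2([R'_SR'_S_mem] + [R_SR_L_mem])·s(t); synaptic strength is probed
with a unit test pulse, so the fold change is probe-amplitude-free.
`k11 = 0.05` by default: the heteromer pathway's contribution to
transmission is kept marginal, consistent with its experimentally
demonstrated dispensability (the k11 = 0 knockout scenarios change no
outcome by more than ~6%). The decomposition products are not returned to
the cytosolic pools by default (the core equations carry no such term);
`recycle` behavior can be emulated by configuration if needed.

## Scenario conditions

The named scenarios start from a pre-equilibrated synapse (core at the
active point, cascade at its cortisol-conditioned silent steady state,
membrane pool empty; refined by 10 h of simulated silence) and read out
transmission at 0.05 h (baseline) and 5 h (outcome). Conditions are the
package's own calibrated defaults, chosen once and frozen:

* cortisol: low-normal C = 0.05 (MR ≈ 1, GR ≈ 0.01 — top of the TrkB
  bell), stress C = 5 (= M_GR, GR = 0.5), depleted C = 4e-6 (MR ≈ 0.04);
* coincidence: σ = 32 for correlated activity, σ = 0 for noncorrelated
  (no coincidence, no conversion);
* stimulation: the correlated protocol is a brief stronger boxcar
  (amplitude 0.045 on [0.1, 1.2] h), the noncorrelated protocol a
  prolonged weaker one (amplitude 0.1 on [0.1, 2.5] h), mirroring the
  high-frequency / low-frequency asymmetry of the slice experiments the
  scenarios emulate;
* interventions: p_NSF ×3 on [0, 1] h induces LTP; a subsequent reduction
  (×0.3 strong, ×0.75 small — the small value sits just below the
  mono-LTD onset, since a ×0.8 reduction lands in a bistable shoulder
  from which LTD is unreachable) is applied from t = 4 h over a scanned
  window length.

Terminal states are classified by basin membership: the core is relaxed
under baseline production rates from the end of the run and matched to
the nearest stable stationary point.

With these defaults the model reproduces the intended phenomenology:
correlated/low-cortisol ≈ 2.05× (LTP), correlated/stress 1.01×,
correlated/depleted 1.01×, noncorrelated/low 0.94×,
noncorrelated/stress 0.10× (LTD), noncorrelated/depleted 0.96×;
knockout deviations ≤ 5.6%; non-LTD window fractions 0.15 (strong
reduction) versus 0.46 (small).

## Numerics

* Integration: LSODA (stiff-capable, adaptive) at rtol 1e-8 / atol 1e-10,
  split at every waveform discontinuity so no step crosses an input jump.
  Halving the tolerances changes scenario fold changes by < 1e-6.
* Stationary points: the reduced scalar residual is bracketed on a
  uniform grid (default 4000 intervals) over the admissible interval
  [0, min(p_NSF, p_RS)/z_R'S] and refined by Brent's method to residual
  < 1e-9 and x-tolerance 1e-10.
* Stability: eigenvalues of the analytic 3×3 Jacobian; eigenvalues within
  1e-7 of the imaginary axis raise a marginal-stability error rather than
  silently classifying a fold point. The independent 1-D criterion
  (sign of the residual slope) agrees with the eigenvalue test on every
  analyzed point and is checked in the test suite.
* Piecewise-linear kinetics have kinks; the calibration keeps all
  stationary points away from them (the ramp-side one-sided derivative is
  used in the Jacobian).
* Degenerate inputs: empty admissible intervals, negative concentrations,
  misordered probes and unknown scenario names raise informative errors;
  concentrations are clipped at zero inside the right-hand side to guard
  the square-root-free mass-action terms against tiny negative solver
  excursions.
* Determinism: the model has no random numbers; a `seed` config key is
  reserved for future stochastic extensions, and rerunning any command
  from its emitted resolved configuration reproduces all outputs
  byte-for-byte.

## What the scenarios do and do not show

The scenario engine is a study of the model, not of data: stimulation
waveforms are idealized boxcars, concentrations are normalized, and the
condition constants above were chosen so the deterministic skeleton
reproduces the qualitative experimental pattern (graded LTP under
cortisol, stress-enhanced LTD, dispensable heteromer insertion,
asymmetric LTP-to-LTD conversion windows). Passing tests therefore show
that the mechanism — a tristable trafficking core steered by a
glucocorticoid-gated BDNF cascade — yields those patterns robustly at
this operating point; they do not calibrate the model to measured EPSP
magnitudes or time constants, and quantitative agreement with any
particular slice preparation is out of scope.

## Known limitations

* Dimers stand in for tetrameric receptors; spatial structure, lateral
  diffusion and slot proteins are not modeled.
* The hour-5 readout probes a decaying induction transient, so reported
  fold changes sit slightly above (LTP) or below (LTD) the settled
  attractor ratios.
* The cascade's receptor expression dynamics are first-order; receptor
  internalization and recycling are collapsed into the conservative
  binding approximation.
* GABAergic and VDCC-dependent plasticity forms, and stochastic
  (molecule-count) effects, are outside the model class.
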