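# Methods

This note documents the model equations, the numerical choices, the
default parameterization of the shipped "generic healthy male"
configuration, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure

The circulation is closed: left ventricle → aortic valve → 1D arterial
tree → regional arteriolar/capillary/venular/venous compartments → venae
cavae → right heart → pulmonary circulation → left heart. Five body
regions (head, arms, upper abdomen, lower abdomen, legs) plus the coronary
circulation partition the microvascular and venous side, so gravity can
load the different body pools separately.

### 1D arterial tree

Each artery is a straight, tapered, axisymmetric compliant tube. Mass and
momentum balance in (A, Q) variables use a momentum-correction factor
χ = 1.1 and wall friction −2(ζ+2)πνQ/A with ζ = 9, the values of a
flat-parabolic velocity profile. The tube law is

    p = p_ext + β (√A − √A0)/A0 + γ/(A0 √A) ∂A/∂t,

with β (Pa·m) derived per vessel from a prescribed reference wave speed
c0 through β = 2ρc0²√A0 (so c(A) = √(β√A/(2ρA0)) and the Riemann
invariants are u ± 4c). Gravity enters the momentum equation as
g·A·sin α·λ, where λ ∈ [−1, 1] is the signed projection of the vessel
axis on the head–feet body axis (feetward positive); supine (α = 0) the
axial gravity contribution vanishes for every vessel.

The default tree is a 21-junction *reduced* network of 13 segments in
which bilaterally symmetric vessels (carotids+vertebrals, subclavian/
brachial arms, the two legs) are merged with √2 radius scaling. It spans
the ascending aorta to the distal posterior tibial artery (z ≈ +1.35 m
below the right atrium for a tall adult male) and carries the measurement
sites used throughout: aortic arch, carotid sinus, mid-brachial
(cuff site, z ≈ +0.07 m), thoracic/abdominal aorta, iliac, distal
posterior tibial ("foot"), and the coronary main stem. All geometry,
stiffness and orientation values are plain editable YAML
(`src/orthosim/config/healthy_male_reduced.yaml`); higher-resolution trees
can be supplied as configuration without code changes. The z origin is the
right atrium, positive toward the feet.

### Lumped circulation

Compartments are 3-element RLC Windkessels (arteriolar compartments RLCR,
with the terminal characteristic impedance Z_c = ρc/A of the feeding 1D
vessel as the series element, computed from the vessel geometry at compile
time). Compartment volume is the integrated state; pressure follows from
p = (V − V_u)/C + p_ext, which makes 0D volume conservation exact. The
legs venous compartment uses the saturating law
V = V_u + (2ΔV_max/π) atan(πC0 p_tm /(2ΔV_max)) (C0 = 9 ml/mmHg,
ΔV_max = 510 ml), linear with slope C0 for negative transmural pressure.

Hydrostatic generators act on the links between compartment pressure
nodes, with magnitude ρg(z_up − z_down)sin α. Microvascular compartments
(arterioles, capillaries, venules) of one region share a single node
position — the flow-weighted z of the region's 1D terminals — so no
hydrostatic column ever appears inside the microcirculation; veins and
venae cavae carry the full regional columns (legs veins: 0.55 m to the
abdominal cava, which produces the ≈ 40 mmHg drop at 70°). The column
between a 1D terminal end and the regional micro node is applied on the
terminal coupling itself, which keeps the total gravitational work around
every regional loop exactly zero.

Venous valves (legs→abdominal cava, arms→superior cava) and the four
cardiac valves are graded non-ideal diodes: opening state ζ ∈ [0, 1] with
pressure-driven opening/closing rates, Bernoulli resistance
B = ρ/(2A_eff²), viscous resistance and inertance. Venous valves keep a
small leak area (A_min > 0); cardiac valves seal completely.

### Heart and pulmonary circulation

Chamber pressure is E(t)(V − V_u) + p_it. The ventricular normalized
elastance is a double-Hill waveform (shape constants m1 = 1.32,
m2 = 27.4, τ1 = 0.65·T_sys, τ2 = 1.09·T_sys), the atrial activation a
raised-cosine bump late in the beat (onset 0.85, duration 0.16 of RR).
The systolic duration follows T_sys = 0.35·RR^0.9 s: the systolic
*fraction* of the beat grows as heart rate rises (shorter diastole), the
mild exponent being a calibration choice that also reproduces the small
upright decrease of the beat-averaged left-ventricular pressure (the
tension–time index); a √RR rule is available per chamber via
`sys_dur_exp`. Pulmonary arteries and veins are 2-element Windkessels.
Intrathoracic pressure is −4 mmHg supine and decreases by
1.2·sin α mmHg upright, acting on all thoracic compartments; the upright
decrease is deliberately at the small end of the "few mmHg" range, the
value being calibrated jointly with the venous-tone gains against the
central-venous-pressure response.

### Coronary bed

One left-ventricular three-layer district (subepicardium/midwall/
subendocardium): per layer an arterial, intermediate and venous
compliant compartment in a resistive chain, all referenced to the
intramyocardial pressure w·p_LV with w = (1/6, 1/2, 5/6). Systolic
compression of the deep layers makes left-coronary inflow
diastole-dominant. Right-ventricular districts are not separately modeled
in the reduced network (the right coronary flow share is folded into the
single district); the bed can be disabled in configuration
(`coronary.enabled`), though all shipped results run with it enabled.

### Regulation

Afferents are exponential moving averages (τ = 2 s) of the mean
aortic-arch/carotid-sinus pressure (baroreflex) and right-atrial pressure
(cardiopulmonary reflex). Activities: n_sym = 1/(1 + (p̄/p_t)^ν) with
ν = 7 (ν = 2 for the cardiopulmonary branch), n_para = 1 − n_sym.
Effector x relaxes as τ_x ẋ = −x + x_basal + G_s(n_sym − ½) −
G_p(n_para − ½) (+ the additive cardiopulmonary term on resistance and
venous tone), clamped to bounds:

| effector | basal | G_sym | G_para | G_cp | τ (s) |
|---|---|---|---|---|---|
| heart rate (bpm) | 66 | 160 | 82 | – | 4.5 |
| ventricular E_max scale | 1 | 0.9 | – | – | 3 |
| arteriolar+capillary R scale | 1 | 2.8 | – | 1.05 | 4 |
| venous V_u scale | 1 | −0.62 | – | −0.38 | 15 |
| venous C scale | 1 | −0.18 | – | −0.12 | 15 |

The baroreflex resistance control acts on the arteriolar *and* capillary
compartments of the four peripheral regions; cerebral arterioles are
governed solely by autoregulation, and the coronary bed is uncontrolled.
Regulation set points (target pressures, CBF reference) are captured
automatically from the pre-tilt steady state as means over the last five
complete beats — the instantaneous afferent averages carry a
beat-frequency ripple that would otherwise bias the set points. Tilt-down
protocols re-use the set points captured in a supine run.

Cerebral autoregulation filters the relative CBF error
(gain 12, τ = 8 s) through an asymmetric saturating sigmoid on the
cerebral arteriolar compliance (dilation range 2.2·C_n, constriction
0.6·C_n, C_n = 0.15 ml/mmHg); arteriolar resistance follows the
Poiseuille scaling R ∝ 1/V_a² of the arteriolar volume. Intracranial
pressure is p_ic = R_csf·I_f + p_dural (offset 3.2 mmHg); upright,
p_dural = max(p_jug, 0) − ρg(z_jug − z_dural)sin α, a form that switches
continuously to the head–collapse-point column once the jugular (superior
vena cava) pressure reaches zero. p_ic loads the cerebral veins only,
which keeps their transmural pressure near zero at high tilt angles.

### Tilt protocol

α(t) holds, then ramps cosinusoidally (C¹ at both ends) over
Δα/rate seconds, then holds — so the mean ramp slope equals the nominal
tilting rate exactly (70° at 4°/s → 17.5 s). A linear ramp is available
for sensitivity checks. Rates from 1.4 to 35°/s and angles up to 90° are
supported.

## Numerics

* Space: nodal P1 discontinuous Galerkin, default element size 5 cm
  ("reduced" mode; "full" mode halves it), local Lax–Friedrichs interface
  fluxes, 2-point Gauss volume quadrature, and a rest-balanced (delta)
  form of the taper source so a pressurized vessel at its reference state
  is a discrete equilibrium. Recorded site values are element means — the
  conserved P1 quantity; the intra-element nodal sawtooth of the scheme is
  ~0.4% of the characteristic flow scale c·A.
* Time: constant global step from the CFL bound of the stiffest vessel
  (safety 0.5; ≈ 0.33 ms for the default tree), 2-step explicit
  Runge–Kutta for all 1D and 0D mass/momentum states. Stiff relaxation
  states use unconditionally stable updates once per step: exact
  exponential integration for valve opening, effectors and afferent
  averages, and a closed-form backward-Euler root for the quadratic valve
  flow equation (the Bernoulli term becomes arbitrarily stiff as a valve
  closes). Recorded flow series are boxcar-averaged over the 4 ms output
  interval to avoid aliasing of step-scale solver noise.
* Junctions: mass and total-pressure conservation with the outgoing
  characteristics of all connected vessels, Newton iteration to 1e-10
  relative tolerance; terminal and aortic-root couplings combine the
  outgoing invariant with the 0D datum (arteriolar impedance / valve
  flow). Global blood volume is conserved to ~1e-7 ml over a full
  protocol.
* Degenerate inputs: non-positive areas and non-finite states abort the
  run with a labeled error; a configured time step above the stability
  bound fails the same way rather than silently losing accuracy.

## Protocol and problem sizes

A full experiment integrates ≈ 150–250 s of model time: supine until the
beat-averaged pressure and heart rate vary < 1e-3 (relative) over 10
consecutive beats (minimum 30–40 s — the venous volume distribution
settles more slowly than the pressures), target capture, a short settle,
the ramp, and a post-tilt hold under the same steadiness criterion. All
shipped results use the reduced spatial mode; these problem sizes are the
package's default study conditions, and grid/time-step convergence checks
(element halving, dt halving) stand in for resolution-independence.

## What the defaults represent, and limits

The configuration approximates a generic healthy adult male: total blood
volume 5,700 ml distributed over the compartments by physiological
fractions, supine operating point ≈ 90/66 (MAP mmHg / HR bpm), cardiac
output ≈ 5.9 l/min, CBF ≈ 12.5 ml/s, CVP ≈ 4 mmHg. Exact per-vessel
geometry and all gains are literature-lineage defaults calibrated so the
supine state and the reported tilt responses are met simultaneously; they
ship as data, not code.

Known limitations, deliberate and inherited from the short-term scope:

* no long-term (renal/hormonal/metabolic) regulation, no respiratory
  oscillation of intrathoracic pressure, no respiratory sinus arrhythmia;
* no transcapillary filtration and no venous stress–relaxation, so very
  slow (> minutes) volume trends are not represented;
* no muscular pumping: only passive posture change is meaningful;
* jugular collapse is represented through the intracranial-pressure
  branch, not as a 1D collapsible vessel; cerebral circulation is lumped;
* with the reflex gains calibrated for the tilt response, the regulated
  supine state is only weakly damped: after large maneuvers it can ring
  at ~1/min with ±2 mmHg amplitude before settling;
* the regulation-off mode is a numerical experiment: without reflexes the
  model (like a real subject without compensation) does not sustain a
  physiological upright pressure.
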