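# Methods

`sacsim` simulates the full sensorimotor loop of reflexive saccades: a
visual world of luminous targets is imaged onto a log-polar retinotopic
grid, a rate-coded brain network selects one target by basal-ganglia
disinhibition of the deep superior colliculus, a six-channel brainstem
burst generator converts the collicular command into motoneuron firing,
a biomechanical eye rotates under that drive, and the new eye
orientation changes the retinal image — closing the loop.

## World and retinotopy

Targets are upright luminous crosses on a notional spherical screen,
placed by two Euler angles (θx about x, positive above the horizon; θy
about y, positive leftward).  The eye's rotational state (intrinsic
x→y→z Euler composition; the composition order is a convention of this
implementation and is pinned by the tests) transforms target directions
into the eye frame, where each of the 50×50 grid cells tests membership
in each active cross.  Placement is purely angular, so no screen radius
enters the computation anywhere.  Rasterization is anti-aliased with a
2×2 sub-cell sampling: without it, targets lying exactly on a grid
column produce systematically thinner activity combs than targets
between columns (a ±25% lattice artifact that propagates into
direction-dependent selection strength).

The log-polar map uses the first-order magnification model
M(ε) = M_f/(1 + ε/E2) with E2 = 2.5°, a field of view of 61° and a
50-unit field side; M_f ≈ 7.75 grid-units/° follows from requiring the
edge of view to map exactly onto the edge of the field.  The angular
coordinate is 1-based with "up" at φ=1, left at 13.5, down at 26 and
right at 38.5, and wraps modulo 50.  The foveal mask removes activity
below 1.5° eccentricity (configurable); the rendered image is blurred
with a σ = 1 grid-unit Gaussian (wrapping along φ).

## Components and network

Populations are leaky integrators stepped by forward Euler at 1 ms.
The linear family uses a_in = A(1−min(S,1)) + αR_N with a
piecewise-linear output offset by c (c < 0 gives tonic firing, c > 0 a
down-state threshold); the subthalamic population uses an exponential
transfer y = e^a − 0.9 with a reversal-modulated port; the striatal
populations scale their input by (0.2+d) (D1) and (1−d) (D2), where
d ∈ [0,1] is the dopamine level (0.7 is the healthy default).  The
update is synchronous with double buffering, so results are independent
of population ordering; every population owns a named, seeded noise
stream, making whole experiments bit-reproducible.

The network (15 populations of 2500 units) follows the architecture
described in the module docstrings: a fast/slow retinal pair forms a
phasic onset response into the superficial colliculus (express
pathway); a delayed, noisy sustained path drives FEF; FEF–thalamus and
thalamus–basal-ganglia loops perform off-centre/on-surround selection
(focused striatal inhibition of SNr against diffuse subthalamic
excitation, with GPe as gain control); SNr tonically inhibits SC_deep
and gates thalamic gain by shunting; SC_deep carries local recurrent
excitation and tecto-tectal (opposite-hemifield) inhibition and
projects through a widening Gaussian field to SC_deep2 and the output
layer SC_avg.

Most scalar weights, time constants and offsets of this circuit are not
constrained by closed-form theory; they ship as the reference
configuration in `sacsim.config`, chosen by the tuning harnesses so
that the closed loop makes single, accurate saccades with the
documented latency behaviour, and frozen.  Notable choices:

* Gaussian-kernel projections are specified by their total mass (the
  builder's peak weight is mass/kernel-sum), which keeps loop gains
  independent of kernel width; the edge-pruning threshold is 2% of the
  peak.
* The connection between FEF/thalamus and striatum decays toward the
  fovea along a logistic S-curve (midpoint r = 10, steepness 0.5/unit)
  so that foveal fixation activity cannot swamp the selection of
  peripheral targets.
* Diffuse projections deliver weight × the source *mean* (weight/N per
  edge), making the surround term independent of population size.

## Widening projection and the invariant integral

A fixed-size target images to an eccentricity-dependent blob (area
∝ M(ε)²), which breaks the assumption of size-invariant collicular
activity hills needed by an exponential motor map.  The widening
projection restores invariance: each SC_deep cell fans out to SC_deep2
with a Gaussian of width σ(r) = m_σ/M(ε(r)) − m_σ/M⁰ + σ₀ for r > r₀
(σ₀ below), clamped at σ₀ = 0.3.  With the published magnitude
m_σ = 50 and M in this implementation's grid-units/degree, σ(r) would
exceed the map size; the reference configuration therefore calibrates
m_σ = 2.0 with the invariant-integral harness
(`integral_invariance_report`), which pushes standard
eccentricity-scaled test blobs through the projection: the integrated
response varies by < 3% across r = 25–41, versus ~80% for a fixed-width
projection.  M⁰ = 12.43 and r₀ = 20 are retained as printed (the clamp
makes the r₀ junction continuous regardless of M⁰).

## Burst generator

Each of the six muscle channels has single-element LLBN, EBN, IBN, MN
populations and a pure-integrator TN; one omnipause unit is shared by
all channels.  Collicular output excites the LLBNs through weight maps
w(r,φ) = i·e^{jr}·sin₊(2π(φ−1)/50 + k), with k centring the positive
half-sine on each channel's preferred direction and the oblique maps
fixed at 1/10 of the vertical maps.  The OPN is tonically active, with
a deep bias (b = −3) so that it collapses — releasing the EBNs — only
once the summed LLBN drive is substantial; active EBNs then hold it
down (a latch), which prevents mid-saccade re-gating.  The IBNs follow
the EBNs, feed back weakly onto the LLBNs after a 8 ms transmission
delay, and drive two resets: a delayed (100 ms) shunting feedback onto
SC_deep, thalamus and FEF that extinguishes the motor command (without
it the command never stops and the eye is driven in a runaway staircase
to the edge of its range), and — in the reset variant — an inhibitory
input from each EBN to the antagonist channel's TN.  Because the
one-sided transfer of a pure integrator can only grow, the TN reset
input uses a signed transfer (clipped to [−1, 1], activation floored at
0); with the reset disabled the one-sided published form is used and
TN activity accumulates in both channels of a pair, reproducing the
no-reset behaviour.

The motoneuron output is the "bump and tonic" sum w_ebn·EBN + w_tn·TN
(with a small bias b_mn); the eye's standing angle is proportional to
the TN level, so endpoint accuracy reduces to the linearity of the
integrated burst in target eccentricity.  The weight-map exponents were
re-tuned by the endpoint harness (`tune_weight_maps` protocol: on-axis
targets, fixation offset at 0.2 s, endpoints by the 0.005-of-peak
velocity rule) to j = 0.087 (horizontal, i = 0.0016) and j = 0.095
(vertical, i = 0.0013); the published values (0.067/0.075) are the
natural starting point but compensate the particular drive dynamics of
the original implementation, not this one.

## Eye plant

A uniform sphere (7.5 g, 24 mm; inertia 2/5·m·R² = 4.32×10⁻⁷ kg m²) is
driven by six linear path actuators with head-fixed torque axes
(rectus pairs about ±x and ±y, obliques about ∓z) and restrained by a
passive orbital torque t = −K·R − C·U.  K = 10⁻³ N m/rad and
C = 5×10⁻⁵ N m s/rad give an overdamped plant with time constants of
about 11 and 39 ms and no passive overshoot; F_max = 0.1 N with a
12 mm moment arm makes full activation of one muscle correspond to
about 69°, so the working range stays well inside saturation.  The
plant advances in 25 ms steps (motoneuron input held constant over the
step) while the neural stages run at 1 ms; each plant step is
integrated by five internal classical RK4 substeps, which keeps the
fast orbital mode accurate (plain 25 ms RK4 misintegrates it) while
preserving the deterministic 25 ms input/output contract.

## Experiments, detection and study conditions

All protocols use a fixation cross of magnitude 0.2 at the null point
and targets of magnitude 0.3 (crosses of ±3° span, 2° bar) unless a
protocol varies the target luminance.  Movement onset is angular speed
above 10°/s sustained for 5 ms (latency properties are additionally
checked at a 5°/s threshold; very small 2° saccades peak below 10°/s in
this model).  Endpoints use the velocity criterion: the orientation at
the first sample after the speed peak where speed < 0.005 of peak.
Latency resolution is one plant step (25 ms).

The endpoint-accuracy experiment uses a reduced hemifield grid of 12
targets (eccentricities 6, 8.8, 11.6, 14.5°; directions 45°, 90°, 135°
from up, i.e. both obliques and the horizontal axis), three repetitions
with distinct seeds, 1.8 s trials.  With the reference configuration
the maximum per-target mean error ratio is ≈13–15% and the maximum
error-vector magnitude ≈1.5–1.7° depending on seeds; the torsional
component of the error is consistently the smallest.  These problem
sizes keep a full accuracy run under three minutes on one core; larger
grids and more repetitions sharpen the estimates but do not change the
qualitative picture.

Emergent behaviour under the same conditions: strict latency ordering
gap (+100 ms) < step < overlap (−100 ms) for dim targets; a latency
minimum at mid eccentricities with increases both near the fovea
(foveal mask starves the selection input) and far from it (smaller
retinotopic blobs); monotonic latency increase as dopamine falls from
0.7 to 0.3 (dramatic at 0.3 — selection takes >1 s); express-like short
latencies for bright (≥0.75) targets in the gap condition; two equal
opposite targets resolve to exactly one winner per trial under
tecto-tectal inhibition, and the brighter of two unequal targets
captures the first saccade; return saccades in the out-and-return
protocol overshoot the null point while the TN reset restores the
outward channel's tonic level to baseline.

## Known limitations

* The double-step critical delay is ~100–150 ms here versus ~30 ms in
  the published model: a 40 ms glimpse of the first target cannot reach
  the self-sustaining regime of the cortico-thalamic loop before the
  second target replaces it, given the 30 ms sustained-path delay and
  the loop time constants.  Short delays correctly yield single
  final-angle saccades and long delays initial-angle double responses;
  only the position of the boundary differs, and the corresponding
  acceptance check is left failing rather than re-timed.
* In the initial-angle regime the second saccade is not slower than a
  single saccade here (the published model's reset feedback made it
  pathologically slow, which that paper itself flags as a defect).
* Saccade kinematics are not calibrated to the main sequence; durations
  of oblique versus cardinal saccades differ (component stretching is
  not modelled).
* The synthetic world contains only cross/rectangle luminances with no
  photometric realism, and the model is a single left eye with no head.
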