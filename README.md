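# sacsim

A closed-loop simulator of the saccadic oculomotor system.  The package
is for computational neuroscientists who want to study saccade-target
selection and generation as *behaviour* — an eye that actually rotates
under muscle forces and thereby changes its own visual input — rather
than as isolated population activity.

The loop it closes:

```
world luminances ──(eye rotation)──► retinotopic image (50×50, log-polar)
        ▲                                     │
        │                     retina / FEF / thalamus / basal ganglia
   biomechanical eye                          │  (action selection by
  (sphere + 6 muscles)                        ▼   SNr disinhibition)
        ▲                        superior colliculus (deep layers,
        │                         widening projection → SC_avg)
   motoneurons ◄── burst generator (LLBN/EBN/IBN/TN/MN + omnipause) ◄──┘
```

## The model in brief

* **Retinotopy.** Visual direction (θx, θy) maps to collicular
  coordinates by r = M_f·E2·ln(ε/E2 + 1), φ ∝ the direction angle
  (1-based, "up" at φ = 1, left 13.5, down 26, right 38.5), with
  M(ε) = M_f/(1 + ε/E2), E2 = 2.5°, a 61° field of view and M_f fixed
  by mapping the edge of view onto the 50-unit field edge.
* **Selection.** Rate-coded leaky-integrator populations (forward
  Euler, 1 ms) implement an off-centre/on-surround basal-ganglia
  circuit: focused striatal D1 inhibition of SNr against diffuse
  subthalamic excitation, dopamine scaling striatal input by (0.2+d) /
  (1−d).  SNr dips release the deep colliculus at the winning locus.
* **Invariant hills.** A widening Gaussian projection between deep
  collicular layers (σ(r) = m_σ/M(ε(r)) − m_σ/M⁰ + σ₀, clamped at
  σ₀ = 0.3, constant inside r₀ = 20) makes the output hill's integrated
  activity independent of eccentricity (< 3% spread here).
* **Spatial–temporal transform.** Six weight maps
  w(r, φ) = i·e^{jr}·sin₊(2π(φ−1)/50 + k) convert the collicular hill
  into drives for the up/down/left/right and oblique burst channels;
  obliques are 1/10 of the vertical maps.
* **Burst generation and plant.** Each channel shapes a "bump and
  tonic" motoneuron profile (EBN burst gated by a shared omnipause
  latch; tonic neurons integrate the burst; an inhibitory feedback tap
  resets the brain after each saccade).  The eye is a 7.5 g, 24 mm
  rigid sphere with passive orbital torque −K·R − C·U, stepped at
  25 ms against the 1 ms neural clock.

## Worked example

```python
from sacsim.experiments import Simulator, run_prosaccade

sim = Simulator()                      # tuned reference configuration
df = run_prosaccade(sim, (0.0, -10.0), seeds=(1, 2, 3))
print(df[["seed", "latency", "theta_y", "error", "error_ratio",
          "peak_speed"]].round(3).to_string(index=False))
```

prints

```
 seed  latency  theta_y  error  error_ratio  peak_speed
    1      0.3  -10.742  0.742        0.074     114.925
    2      0.3  -10.695  0.695        0.070     115.049
    3      0.3  -10.704  0.704        0.070     114.806
```

Each row is one closed-loop trial of a prosaccade task: the fixation
cross (magnitude 0.2) extinguishes at 0.4 s and a target cross
(magnitude 0.3) appears 10° to the right.  The model reacts after
300 ms (`latency`), lands within ~0.7° of the target (`error`, about 7%
of the movement, `error_ratio`), and the small spread across seeds
shows the noise level of the selection circuit.  `theta_y` is the
endpoint by the velocity criterion (first sample after peak speed below
0.005 of peak); negative values are rightward.

Worlds can also be described in a JSON file (see
`examples/luminances.json`) and loaded with
`sacsim.world.load_luminances`; a `sacsim` command-line interface wraps
the experiment protocols:

```bash
sacsim prosaccade out/ --seed 1 --reps 3 --theta-y -10
sacsim gap out/ --seed 1            # gap / step / overlap latencies
sacsim surface out/ --seed 1        # hemifield endpoint-error table
```

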