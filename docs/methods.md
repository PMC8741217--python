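# Model and methods

`cxnav` is an agent-based implementation of a unified central-complex (CX)
account of insect multimodal navigation. One mechanism — *copy-and-shift* —
converts every sensory stream into the same currency: a desired-heading
activity bump in the geocentric compass frame. A ring attractor fuses
competing desired headings, and the CPU1 steering circuit converts the
fused bump minus the compass bump into a turn command. The packaged
experiments reproduce fly chemotaxis and odour-gated anemotaxis, ON/OFF
contextual switching, ant homing that fuses path integration (PI) with
nest-plume olfaction, and two displacement-recovery manoeuvres (wind
compensation and backtracking).

## Population code and copy-and-shift

All directional signals are 8-column rings with preferred directions
`phi_i = i * 45 deg` and cosine tuning `a_i = A (1 + cos(theta - phi_i)) / 2`.
Decoding is the population vector; a uniform or silent ring has magnitude 0
and no defined direction.

Copy-and-shift copies the compass bump and rolls it laterally. The 8-column
ring is band-limited-interpolated to 80 columns, rolled by
`round(shift / 4.5 deg)` columns, and downsampled back to 8, so every shift
is quantised to 4.5 deg (one interpolated column; a native column is
45 deg). Band-limited (trigonometric) interpolation is used because it
shifts a cosine bump with zero phase distortion: a one-column fine shift
decodes to exactly 4.5 deg. Piecewise-linear interpolation would bias the
decode by up to ~0.5 deg.

The shift source differs per behaviour:

* **chemotaxis** — the one-step drop in odour concentration, mapped to
  `clip(k_chemo * drop, 1, 3)` native columns in a fixed turn direction
  (default counter-clockwise); no shift while concentration is
  non-decreasing. The one-column floor makes any detectable loss command a
  45 deg cast; without it, near-tangential orbits around a gradient peak —
  where the per-step drop is second-order small — are absorbing, and
  gradient ascent stalls.
* **anemotaxis** — the egocentric upwind angle reported by the
  wedge-projection-neuron pathway (`wpn = 2 sin(theta_w - theta_h + pi)`),
  which shifts the compass bump onto the geocentric upwind direction.
* **manoeuvres** — the same upwind angle at the clutch instant (wind
  compensation) or a constant 180 deg (backtracking), stored as an
  immutable working-memory ring that later serves as the sole desired
  heading.

## Steering

CPU1 receives the desired bump rolled `offset_columns` columns
counter-clockwise (left bank) and clockwise (right bank), subtracts the
compass bump, and rectifies at zero; the turn is
`k_motor * (sum(left) - sum(right))`. With equal-amplitude bumps the turn
is proportional to `sin(|d + b|/2) - sin(|d - b|/2)` for offset `d` and
bank rotation `b`. The default is two columns (`b = 90 deg`), which makes
the command strictly monotone on `(-90, +90) deg` with zero exactly at
alignment; a one-column projection peaks at 45 deg and loses monotonicity
beyond it.

CPU1 rates carry a fixed synaptic gain of 0.42, chosen from a closed-loop
stability analysis: the raw rectified-difference slope is ~2.4 per radian
of offset, so published motor gains of 1.0–1.5 would give a discrete-time
loop gain above 2 (persistent zigzag). With the gain, tracking is
near-deadbeat at `k_motor = 1` and a damped alternation at 1.5.

## ON/OFF switching

Sensed concentration `C` and its one-step change `dC` select the active
behaviour through a truth table with thresholds `thr_o` (odour present),
`thr_on > 0` (gain) and `thr_off < 0` (loss): ON (anemotaxis) whenever
`dC >= thr_on`, or when odour is present and not being lost; OFF
(chemotaxis) when odour is present but dropping below `thr_off`; RANDOM (a
correlated random walk, default jitter 30 deg/step) when no reliable
signal exists.

## Ring-attractor fusion (ant homing)

The integration ring relaxes under

    tau dC/dt = -C + g(W_E2E C + X1 + X2 + w_I2E * mean(C)),   g(c) = max(0, rho + c)

with a cosine recurrent kernel `W_E2E[j,i] = w0 + w1 cos(phi_j - phi_i)`.
`X1` is the PI bump, whose amplitude is the remaining home-vector length
divided by the release-time length (1 at release, 0 at the nest); `X2` is
the mode-gated olfactory bump weighted by `k_o * C`. In RANDOM mode the
olfactory channel is silent and a jittered copy of the current heading
enters at a small fixed weight (`k_explore = 0.5`), so a strong home
vector dominates but a spent one lets the walk become searching. The
settled bump decodes to the amplitude-weighted circular mean of its
inputs.

Weights are not uniquely determined by the behavioural contracts; the
shipped defaults `w0 = -0.05`, `w1 = 0.15`, `w_i2e = -0.2`, `rho = 0.1`,
`tau = 1`, Euler `dt = 0.1`, `tol = 1e-5`, `max_steps = 500` were
calibrated once against two contracts: a single cue's direction is
preserved, and two-cue fusion matches the weighted-vector-mean oracle
within 5 deg over amplitude ratios 0.2–2 and separations up to 90 deg
(measured worst case 1.3 deg; stronger excitation, e.g. `w1 = 0.25` with
`rho = 0`, lets rectification harmonics alias onto the 8-column decode and
breaks the oracle bound). The exploration weight is `k_explore = 0.5`,
set by the search-coverage requirement below.

Before steering, the settled bump is re-encoded at unit amplitude
(direction preserved; skipped when the population vector is below 0.05,
i.e. no direction encoded). Cue amplitudes decide the *compromise
direction*; they should not throttle motor vigor — an ant with a
nearly-spent home vector still walks briskly.

## Odour environments

* **Gradient landscapes** (windless): `volcano`
  `C = k exp(tau (d - r/2))` inside the rim circle `d = r/2` and
  `k exp(tau (r/2 - d))` outside — maximum `k` exactly on the rim; and
  `linear`, identical outside but `max(0, k - 0.2 exp(tau (d - r/2)))`
  inside (a shallow dip, supremum approached from outside the rim).
* **Plumes** (constant wind, exactly zero wherever the angle between the
  source-to-point vector and the wind direction has non-positive cosine).
  Two spread conventions:
  `spread="downwind"` is the textbook steady-state Gaussian plume,
  `C = q / (u sigma sqrt(2 pi)) exp(-cross^2 / (2 sigma^2))` with
  `sigma = Ks * downwind`; `spread="crosswind"` evaluates both the spread
  and the exponent on the crosswind (projected) distance, which collapses
  to an odour *band* of constant width running the whole downwind
  half-plane. A guard radius (one step length) caps the `sigma -> 0`
  singularity.

The fly presets use the downwind Gaussian. The ant preset uses the
crosswind band: with the ant thresholds (`thr_o = 1.2`, `q = 20`,
`u = 10`) a downwind-widening plume exceeds threshold only in a strip
roughly 0.6 m wide and 3 m long at the nest, which neither release
corridor (offset 1.5 m) ever intersects — the maximum concentration 1.5 m
off-axis is 0.32 for *any* admissible `Ks`. The band variant makes the
nest smellable (within ~0.7 m of the plume axis) along the entire 10 m
route, which is what lets path integration hand over to olfaction for the
final approach. `Ks = 0.2` (mid-range of the admissible set
{0.5, 0.3, 0.2, 0.15, 0.1}) is the default everywhere.

Wind direction is the direction the air flows *toward*, in world frame;
in the ant arena it is `-pi/2`, blowing nest odour south over the release
zone, so upwind surging points at the nest.

## Experiment protocols (presets)

| preset | agents x steps x repeats | key bindings |
|---|---|---|
| fly_chemotaxis_{volcano,linear} | 5 x 1500 x 4 | k=10, tau=0.1, r=6, k_chemo=100, k_motor=1.0, SL=0.02, start zone ±12 |
| fly_anemotaxis | 4 x 200 x 5 | q=10, u=10, w=-pi/2, k_motor=1.5, SL=0.4, odour ON during [T/4, T/2) |
| fly_integrated | 4 x 200 x 5 | + thr_o=0.001, thr_on=0.02, thr_off=-2e-4, k_chemo=100 |
| ant_integrated | 10 x <=1200 x 2 release points | q=20, thr_o=1.2, thr_on=0.5, k_o=0.5, SL=0.05, PI = 10 m at pi/2, releases (±1.5, -10) |
| ant_wind_compensation / ant_backtracking | 20 x 100 | capture heading pi/2, SL=0.05, k_motor=1.0 |

Units: one step is the time unit; lengths are arena units — centimetres
for the fly presets, metres for the ant presets (the ant geometry — a
10 m home vector covered in ~200 steps of 0.05 — is only consistent in
metres). Turns are capped at pi/2 per step. Every agent draws its own
random stream keyed by (seed, repeat/release, agent), so runs are
bit-reproducible and shrinking the agent count yields a prefix subset.

Ant-specific protocol choices: the run caps at 1200 steps; the nest is
absorbing at 0.5 m (the model navigates to the nest *area*; locating a
centimetre-scale entrance uses local cues outside scope), so a trail ends
at first entry and its recorded length is the path to arrival. A
conspecific-nest distractor plume (same q, position (-1.0, -8.0), a free
parameter) sits near the west release corridor; disabling it shortens
mean homing paths. This with/without ordering is stochastic — it held in
3 of 4 evaluation seeds — because under parallel band plumes a same-wind
distractor mostly delays rather than misroutes.

## What the synthetic world does and does not capture

Fields are steady and analytic: no turbulence, filaments or intermittency,
no receptor adaptation or gain control, no boundaries or collisions, and
speed is constant. Odour valence equals raw concentration (no associative
memory network stands between them). Passing tests therefore demonstrate
the *circuit logic* — frame transfer, gating, optimal-style fusion,
steering — under idealised sensing, not robustness to natural plume
statistics.

## Numerical notes and degenerate inputs

Ring validation rejects non-finite or negative rates; decoding a uniform
ring reports magnitude 0 with an undefined (NaN) direction, and such rings
pass through desired-heading normalisation unchanged (hence zero turn).
The ring attractor raises on non-convergence, carrying the residual.
Plume queries at the source return the sentinel geometry (0, 0, 0).
Boundary threshold cases classify upward (`dC = thr_on` is ON,
`C = thr_o` is odour-present). The copy-and-shift quantisation rounds to
the nearest fine column except chemotaxis, whose cast floor is one native
column. Angle wrapping uses `remainder(x, 2 pi)` onto `(-pi, pi]`.

## Known limitations

* The steering asymmetry between banks is exactly antisymmetric only when
  the compass bump sits on a column; off-grid bases keep the sign but not
  the exact magnitude (8-sample aliasing).
* The distractor detour effect is weak (see above) and the
  every-agent-triggers-ON property of the integrated fly run does not hold
  under the default 30 deg random-walk jitter: pre-gate dispersal removes
  some agents from the odour wedge entirely; the guarantee is per repeat,
  not per agent.
* `k_explore`, the CPU1 gain, and the RA weights are behavioural
  calibrations, not measured quantities; alternative values satisfying the
  same contracts exist.
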