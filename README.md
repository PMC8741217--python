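# cxnav

Agent-based simulations of how the insect central complex (CX) could
coordinate multimodal navigation: odour-gradient chemotaxis, odour-gated
upwind surging (anemotaxis), ON/OFF switching between the two, ant homing
that fuses path integration with nest-plume olfaction, and the
displacement-recovery manoeuvres of desert ants (wind compensation and
backtracking). It is written for computational neuroscientists and
behavioural biologists who want a compact, fully reproducible testbed for
CX steering-circuit hypotheses.

## The model in brief

Every directional signal is an 8-column activity bump over azimuth,
`a_i = A (1 + cos(θ − φ_i)) / 2`, the heading code of the protocerebral
bridge. Three mechanisms act on these bumps:

* **Copy-and-shift** copies the compass bump and shifts it laterally to
  build a *desired heading* in the geocentric frame. The shift source is
  the behaviour: a drop in odour concentration maps to
  `clip(k_chemo·ΔC, 1, 3)` columns of 45° (chemotaxis); the
  wedge-projection-neuron signal `2 sin(θ_w − θ_h + π)` supplies the
  egocentric upwind angle (anemotaxis); manoeuvre memories use the upwind
  angle at the clutch instant or a constant 180°. Shifts are realised on
  an 80-column interpolation, so the resolution is 4.5°.
* **A ring attractor** `τ dC/dt = −C + g(W·C + X1 + X2 + w_ui·mean C)`
  fuses competing desired headings; the settled bump decodes to the
  amplitude-weighted circular mean, so cue reliability (e.g. remaining
  home-vector length, odour concentration) sets the compromise.
* **The CPU1 steering circuit** projects the desired bump into left/right
  banks (±2 columns), subtracts the compass bump, rectifies, and issues
  the turn `θ_M = k_motor (ΣL − ΣR)` — zero at alignment, monotone within
  ±90°.

An ON/OFF truth table over concentration and its temporal change gates
which behaviour drives steering. See `docs/methods.md` for assumptions,
parameter tables and limitations.

## Worked example

```python
import math
from cxnav import get_preset, run_anemotaxis_experiment
from cxnav.metrics import experiment_metrics

cfg = get_preset("fly_anemotaxis")        # plume, odour ON during steps 50-100
ts = run_anemotaxis_experiment(cfg, seed=1)
for key, val in experiment_metrics(ts).items():
    print(key, val)
```

prints (abridged):

```
mean_upwind_speed_on 0.3962596739572187
mean_upwind_speed_off 0.07058980986994522
mean_abs_angvel_on 0.03756363619180648
mean_abs_angvel_off 0.28817346667669874
```

While the odour gate is open the flies surge upwind at ~0.40 length units
per step (the step length is 0.4, so they move almost straight upwind,
turning under 0.04 rad/step); with the odour off the walk is undirected
(upwind component ~0.07) and five times as curvy. That ordering — fast,
straight, upwind motion only during odour — is the signature of
odour-gated anemotaxis.

More narrated walk-throughs live in `examples/` (one script per
capability: landscapes, the heading codec, steering, ring-attractor
fusion, the fly experiments, the ant experiments). A thin CLI wraps the
runners:

```bash
cxnav ant-homing --preset ant_integrated --seed 7 --out-dir out --plots
cxnav export-field --preset fly_anemotaxis --out-dir out
```

Each run writes `trajectories.csv` (one row per agent-step),
`metrics.json` and the resolved `config.yaml`; identical (preset, seed)
pairs are byte-identical.

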