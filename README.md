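# canmap — conjunctive space-by-movement attractor networks for cognitive mapping

`canmap` is a research implementation of a bio-inspired SLAM model built
from continuous attractor networks (CANs) of the medial entorhinal cortex
cell types: **head-direction-by-rotation cells** on a ring manifold,
**grid-by-translation cells** on a torus manifold, **local-view cells**
that calibrate both networks through pattern completion, and a
**semi-metric topological experience map** with loop-closure relaxation.
It is aimed at computational neuroscientists and robotics researchers who
want a transparent, testable Python version of the conjunctive
position-by-velocity coding scheme.

## The model

Each ring unit carries coordinates (θ, ν): θ ∈ [0, 2π) an internal head
direction, ν ∈ [−L_r, L_r] a rotation coordinate. Recurrent weights are

    J(θ,ν | θ′,ν′) = J0 + J1 · cos(θ − θ′ − ν′) · cos(λ(ν − ν′)),

so the unit most strongly driven by θ′ sits at θ′ + ν′: the asymmetry makes
the activity bump travel at a speed set by its position on the rotation
axis. A Gaussian velocity-tuned input centred at u(V) = arctan(τV) selects
that position, and the bump phase — read out as the angle of the population
Fourier sum Σ m·e^{iθ} — integrates angular velocity. The decoded rotation
phase φ maps back to angular velocity through V = tan(φ)/τ.

The torus network is the two-dimensional analogue on (θ_x, θ_y, ν_x, ν_y)
with weights J0 + J_k·cos(k‖Δθ − ν′‖)·cos(λ|Δν|), packing k = 2 bumps per
spatial axis. Its pattern is a hexagonal triad of lattice modes
(0,2), (2,−1), (−2,−1); the decoder projects the activity onto the three
grid axes (the second axis at α = arctan 2), unwraps the projection phases
over time, and converts them to metres via x = S/(2π/k)·θ̂, where S is the
grid spacing (30 m by default). Local-view cells store a scene descriptor
together with the bump phases at first sight and, on re-recognition,
inject currents that pull both networks back to the stored phases — the
loop-closure signal for the experience map, whose vertex positions are
then relaxed to minimise disagreement with the stored odometric links.

## Worked example

```python
import numpy as np
from canmap import hd
from canmap.config import RunConfig, WorldConfig
from canmap.pipeline import run_mapping, vertex_errors

cfg = RunConfig(seed=1)

# worked-example decodings: a ring state decoded at (psi, phi) = (3.25, 0.0069)
print(round(np.degrees(3.25), 2))                         # 186.21  degrees
print(round(hd.phase_to_angular_velocity(0.0069, cfg.hd), 2))  # 0.69 rad/s

# a small closed-loop mapping run: 3 noisy laps around a 40 m block
cfg.world = WorldConfig(kind="street_grid", params={
    "block": 40.0, "speed": 5.0, "omega_turn": 0.5, "n_loops": 3,
    "speed_noise_frac": 0.03, "omega_noise_sd": 0.015})
graph, log = run_mapping(cfg)
print(log.summary["n_vertices"], log.summary["n_closures"])
pre, post = vertex_errors(graph, log)
print(round(pre, 1), round(post, 1))
```

Output:

```
186.21
0.69
106 58
187.5 103.5
```

The first two lines are the printed decodings of a mid-run ring state:
the bump at phase 3.25 rad encodes a heading of 186.21° and its rotation
phase 0.0069 a counter-clockwise turn at 0.69 rad/s. The mapping run
creates 106 experience vertices and closes 58 loops over the second and
third laps; graph relaxation pulls the mean vertex error against ground
truth from 187.5 m down to 103.5 m (the map is self-consistent but
globally warped by the velocity-transfer gains noted above).

A CLI wraps the same pipeline: `canmap run config.yaml`,
`canmap simulate-world`, `canmap replay snapshots.h5`, `canmap ratemap`.

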