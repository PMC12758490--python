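# thermoflow

Joint collective-variable learning and temperature-steerable generative
modeling for molecular trajectory data.

## The problem

Molecular systems spend most of their time in a handful of metastable
states, and the interesting physics — which states exist, how populated they
are, how the balance shifts with temperature — lives in a low-dimensional
space of slow collective variables (CVs) that is expensive to sample and
awkward to model directly in full coordinates. Two tasks are usually treated
separately: *representation learning* (finding CVs and metastable states
from trajectories) and *generative modeling* (sampling the equilibrium
distribution). `thermoflow` trains them together, so the density model lives
on exactly the low-dimensional space that captures the slow dynamics.

## The model

Three jointly trained pieces:

- a **time-lagged information-bottleneck encoder/decoder**: a Gaussian
  encoder maps descriptors `X_t` to a 2-D latent mean `µ(X_t)` with a single
  learnable posterior scale `σ`, and a softmax decoder predicts the
  metastable state occupied at `t + Δt`. States are discovered
  self-consistently — starting from k-means labels, every frame is
  iteratively relabeled with its most probable decoded state, which merges
  states shorter-lived than the lag;
- a **RealNVP coupling flow** `f` with exact inverse and triangular
  Jacobian, mapping the latent space onto a prior space;
- an **exponentially tilted, temperature-steerable Gaussian prior**

  `r_T(z, τ) ∝ exp(τ‖z‖) · N(z; 0, T·I)`,

  whose probability mass peaks on the shell `‖z‖ = τT`. Both the variance
  and the peak radius grow linearly in the steerable temperature `T`, so
  trajectories recorded at different temperatures map to concentric shells
  and the model interpolates equilibrium densities at temperatures it never
  saw.

The unified loss is the lagged prediction cross-entropy plus
`β · E[log p(u|X_t) − log r_T(f(u)) − log|det J_f(u)|]` over posterior draws
`u = µ + σε`; the second term pulls the flow-transformed posterior onto the
prior and makes exact likelihoods available for every frame. Likelihoods
rank state representatives, and transition paths are interpolated in the
structured prior space (great-arc or polar-linear) and inverse-flowed back.

Everything is exercised end-to-end on two built-in Langevin simulators: a
2-D three-hole model potential (two deep basins joined by two reaction
channels, the upper one holding a shallow minimum) and the two-dimensional
Lennard-Jones 7-particle cluster, whose isomers are resolved through the
central moments of smooth per-particle coordination numbers.

## Worked example

```python
import numpy as np
from thermoflow import SimulationProtocol, simulate_langevin, ThermoFlowModel
from thermoflow.evaluation import histogram_density, symmetric_kl

proto = SimulationProtocol(n_steps=3_000_000, dt=0.001, kT=1.0, gamma=0.5,
                           stride=50, seed=7)
traj = simulate_langevin(proto)          # 60,000 frames of (x, y)

model = ThermoFlowModel(traj, lag=10, n_init_states=4, tau=2.5,
                        beta=0.003, sigma0=0.05)
result = model.fit(seed=0, stage1_cycles=5, stage1_epochs=2,
                   stage2_epochs=2, polish_epochs=15)
print(result.summary())
```

```
Joint IB + tilted-prior flow model
==============================================
frames: 60000   features: 2   lag: 10
latent dim: 2   tilt tau: 2.5   beta: 0.003
steerable temperatures: [1.0]
posterior scale sigma: 0.0909
states: 3   populations: [0.4391, 0.1374, 0.4235]
final loss: 0.2062  (cross-entropy 0.1949, regularizer 0.0114)
```

Starting from four k-means clusters, training merged the assignment into the
three physical basins: the two deep wells (populations 0.44 and 0.42) and
the shallow upper-channel state (0.14). Generation and likelihood scoring:

```python
reference = result.latent                       # encoded training frames
generated = result.generate(200_000, seed=1)    # prior -> inverse flow
kl = symmetric_kl(histogram_density(reference, reference),
                  histogram_density(generated, reference))
print(f"generation symmetric KL: {kl:.3f}")

reps = result.state_representatives()
print(np.round(traj.frames[reps], 2))
```

```
generation symmetric KL: 0.341
[[ 1.1  -0.15]
 [-0.71  1.18]
 [-1.2  -0.13]]
```

The symmetric KL divergence compares the generated latent density with the
encoded data on a 100x100 histogram (floored at 1e-5); at this small
training size it is dominated by sampling noise, and drops below 0.1 at the
reference problem sizes used in `thermoflow.protocols`. The
highest-likelihood representatives of the deep-basin states sit inside the
two wells near (±1, 0); the third state's representative lies in the
elevated upper-channel region.

A command-line interface wraps the same pipeline:

```bash
thermoflow simulate --system three_hole --steps 3000000 --stride 50 --seed 7 --out sim
thermoflow train --features sim/features.npz --tau 2.5 --states 4 --beta 0.003 --out run
thermoflow generate --checkpoint run/checkpoint.npz --n 100000 --temperature 1.5 --out gen
```

Every run writes a manifest (seed, config, file digests) so results are
reproducible from `(config, seed)`.

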