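# Methods

## Model

`thermoflow` fits a joint representation-learning + generative model to
time-ordered molecular descriptor matrices.

**Time-lagged information bottleneck.** A Gaussian encoder compresses the
descriptor row `X_t` into a `d_z = 2` latent mean `µ_θ(X_t)`; the posterior
is `N(µ_θ(X_t), σ² I)` with a single learnable, input-independent scale σ.
A softmax decoder predicts the metastable state occupied at `t + Δt`.
Because the target is the *future* state, latent coordinates are forced to
encode slow, predictive degrees of freedom; fluctuations faster than the lag
are discarded. States are not given: starting from k-means clusters, every
frame is periodically relabeled with its own most probable decoded state and
unused states are dropped, so states whose lifetime is shorter than the lag
merge into their long-lived neighbors. Relabeling iterates with training
until fewer than 0.5% of frames change on two consecutive refreshes (at most
20 refreshes).

**Coupling flow and tilted prior.** A RealNVP flow — alternating affine
coupling blocks `w_a = u_a · exp(S(u_f)) + T(u_f)` with tanh networks for S
and T, scale outputs squashed through `s_max · tanh(·/s_max)`, output layers
zero-initialized so the fresh flow is the identity — maps the latent space
to a prior space carrying the exponentially tilted Gaussian

    r_T(z, τ) ∝ exp(τ ‖z‖) · N(z; 0, T I_d),

normalized by `Z(τ√T) · (2πT)^{d/2}` where `Z(t) = E_{N(0,I)} e^{t‖w‖}` has
a closed form in Kummer's confluent hypergeometric function ₁F₁ (evaluated
via `scipy.special.hyp1f1`, with a log-scale radial quadrature fallback once
the closed form would overflow, and an independent quadrature oracle in the
tests). At τ = 0 the prior is a plain Gaussian of variance T; for τ > 0 its
mass peaks on the shell `‖z‖ = τT`. Both the shell radius and the variance
scale linearly in the steerable temperature T, which is what lets data from
different temperatures occupy concentric, partially overlapping shells.

**Unified objective.** For a batch of lagged pairs,

    L = E[ −log q(y_{t+Δt} | u) ]
      + β · E[ log N(u; µ, σ²I) − log r_T(f(u)) − log|det J_f(u)| ],

with `u = µ + σε`. The vanilla baseline (`SPIBModel`) replaces the flow
term with a VampPrior — a uniform mixture of encoder-conditioned Gaussians
at ten learnable pseudo-inputs. With an identity flow and τ = 0 the
regularizer reduces exactly to the standard-Gaussian objective (unit-tested
to 1e-6).

**Multi-temperature training.** Each trajectory carries a steerable
parameter `T_i = kT_i / min_j kT_j` (the lowest training temperature maps to
1). Only the prior term differs between temperatures; encoder, decoder and
flow are shared. Generation at an arbitrary T samples the prior at that T
and inverse-flows.

## Training schedule

Two-step training: stage 1 trains the vanilla IB with the VampPrior and
iterative relabeling until the state assignment converges; stage 2 optimizes
encoder, decoder, σ and flow jointly under the unified loss with labels
frozen, followed by one final label refresh. A third, flow-only "polish"
phase then freezes the encoder and fits the flow by maximum likelihood to
the *encoded means* with a step-decayed learning rate and Polyak averaging
of the late-stage parameters.

Two implementation choices here deserve explanation:

- **Short IB stages.** The rate term of the objective is (up to constants)
  the mutual information I(X; u), and minimizing it to convergence contracts
  the latent manifold into σ-scale blobs. A fully converged encoder makes
  the latent density so concentrated that a 100-bin histogram of the encoded
  data disagrees with an independent draw of itself (split-half symmetric KL
  above 0.3) — at that point no generative model can match the encoded
  density at histogram resolution. Stopping the IB stages shortly after
  label convergence keeps the latent a smooth image of the underlying
  landscape, which is also the regime in which likelihood ranking and path
  interpolation are physically interpretable.
- **Polish on means.** Encoding is deterministic at inference (`encode`
  returns µ), and every density evaluation — generation divergences,
  free-energy surfaces, likelihood ranking — compares against encoded means.
  The polish phase therefore fits the flow to the µ-distribution rather than
  to posterior draws; an optional sub-bin smoothing kernel
  (`polish_noise`) is available to regularize the fit.

Optimization uses Adam (lr 1e-3, batch 512) on an in-package reverse-mode
automatic-differentiation engine over numpy arrays (`thermoflow.autodiff`),
whose gradients are pinned against central finite differences in the tests.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `lag` | 10 frames | prediction horizon Δt; states living shorter than this merge. Three-hole: 10 frames = 0.5 time units. LJ7: 3 frames = 1.5 LJ time units — longer than intra-basin vibration, shorter than isomerization waiting times (lag 10 merges the three defect isomers into one state). |
| `tau` | 2.5 | tilting factor; sets the prior shell radius. 2.0 for LJ7. |
| `beta` | 0.01 (`TrainConfig`), 0.003 in the reference protocols | prediction/compression trade-off; also scales σ's equilibrium. |
| `sigma0` | 0.01 (`ThermoFlowModel`), 0.05 in the reference protocols | initial posterior scale. Large enough to keep early relabeling smooth (tiny σ makes the first refinement cycles merge states too aggressively), small enough not to blur the latent density. |
| `n_init_states` | 6 | k-means clusters for the initial labels; 4 for the three-hole runs, 10 for LJ7 (clustered in the (µ₂, µ₃) coordination-moment plane). |
| `flow_blocks`, `flow_hidden` | 8 × (32, 32) | coupling depth/width; the headline three-hole fit uses 10 × (48, 48). Narrow nets are sufficient in 2-D and fast on one core. |
| `s_max` | 3.0 | bound on each block's log-scale output; stabilizes training. |
| temperature map | `kT_i / min kT` | steerable prior parameter per trajectory. |

## Built-in simulators

Both generators use a BAOAB-splitting underdamped Langevin integrator with
unit mass and seeded, bit-reproducible noise; the production protocols
(5·10⁷ steps at dt = 0.001, stride 50 for the three-hole potential → 10⁶
frames; 10⁷ steps at dt = 0.005, stride 100 per temperature for LJ7 → 10⁵
snapshots) run in about a minute each thanks to jit compilation.

- **Three-hole potential**: two −5 wells at (±1, 0), a −3 well at (0, 5/3),
  a +3 barrier bump at (0, 1/3) and quartic confinement; kT = 1, γ = 0.5.
  Equilibrium histograms correlate with the Boltzmann weight at r > 0.95.
- **LJ7**: seven particles in 2-D with ε = σ = 1 Lennard-Jones pair
  interactions, Langevin thermostat with γ = 1 and dt = 0.005 (in LJ time
  units), plus a half-harmonic restraint (k = 5 ε/σ²) on each particle's
  distance from the cluster centroid beyond 3σ to prevent evaporation at
  the highest temperatures; the restraint ignores the small centroid
  back-force, which the thermostat absorbs. Descriptors are the sorted
  smooth coordination numbers `c_i = Σ_j (1−(r_ij/r₀)⁸)/(1−(r_ij/r₀)¹⁶)`
  with r₀ = 1.5σ; state analysis uses their second and third central
  moments (µ₂, µ₃).

What the simulators emulate — and what they do not: they produce genuine
metastable dynamics with temperature-dependent state populations, so
passing tests demonstrate CV recovery, state merging, density estimation
and temperature steering on real (if low-dimensional) Langevin data. They
do not probe high-dimensional descriptor spaces, descriptor redundancy or
noise, explicit-solvent effects, or sampling non-convergence — conclusions
about those regimes cannot be drawn from this suite.

## Desk-scale problem sizes

The reference study conditions (`thermoflow.protocols`) keep each fit at
minutes on a single core: three-hole training uses a 10⁷-step run (2·10⁵
frames) with an independent 4·10⁷-step validation run (8·10⁵ frames) as the
density reference, schedule 5×1 stage-1 epochs, 1 stage-2 epoch, 25 polish
epochs; LJ7 training uses 5·10⁶ steps per temperature (5·10⁴ snapshots
each) at kT ∈ {0.2, 0.5}. Generation divergences are measured on 8·10⁵
generated samples. The five-fold model comparison and the multi-temperature
steering check run on further-reduced slices (5·10⁴-frame folds; 5·10⁴
frames per synthetic temperature, kT ∈ {1, 3}).

## Numerical choices

- Histogram densities: 100 bins per axis spanning the reference set's
  min/max; probabilities floored at 1e-5 and renormalized; out-of-range
  points are clipped into edge bins so counts are conserved. The symmetric
  KL divergence is the full sum KL(P‖Q) + KL(Q‖P).
- MSMs: transition counts within segments at the training lag, symmetrized
  (C + Cᵀ)/2 as a detailed-balance surrogate, row-normalized;
  eigendecomposition through the similar symmetric matrix, so the spectrum
  is real. GMRQ sums the leading k eigenvalues with k defaulting to the
  model's own state count.
- Ties (likelihood ranking, nearest-neighbor backmapping) break to the
  lowest frame index.
- Metropolis sampling of the prior: vectorized random-walk chains (step
  0.5√T, 2000 burn-in steps, thinning 5, one chain per 10⁴ samples) in the
  unit-variance rescaled space; the exact radial inverse-CDF sampler serves
  as the oracle and as the default for 2-D generation.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence`, so adding a component never shifts another
  component's stream; simulations are bit-reproducible.

## Known limitations

- Generation divergence is measured against finite encoded references; at
  small reference sizes the histogram noise floor dominates (split-half KL
  of 5·10⁴ encoded frames is ≈0.3).
- The selection of the tilting factor by cross-validated generation
  divergence does not recover a "true" τ planted in synthetic data: the
  encoder may reparametrize the latent space arbitrarily (including overall
  scale), so the data-generating tilt leaves no recoverable imprint; at
  desk scale the per-τ divergence table tends to grow with τ. τ selection
  remains what it is in practice — a model-selection heuristic among
  equally admissible priors.
- Likelihood ranking inherits the encoder's Jacobian: where the encoder
  compresses basin cores, the flow density can peak at state junctions, so
  the upper-channel state's representative sits at the edge rather than the
  center of its basin (the deep-basin representatives are unaffected).
- High-temperature LJ7 generation over-weights structured (low-entropy)
  states: backmapped coordination moments track simulation within ~4% at
  the low training temperature but overshoot µ₂ by ~25–30% at the high
  one. The melting trend (µ₂ decreasing with T) is reproduced.
- Priors in latent dimension above ~8 are untested (series accuracy);
  mixtures of tilted priors are out of scope.
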