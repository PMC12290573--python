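# Methods

This package estimates effective connectivity — the directed influences
between brain regions — from multiregion BOLD fMRI time series.  A
Transformer encoder reads the observed series and emits the parameters of a
physiological dynamic causal model (P-DCM); the P-DCM generator maps those
parameters back to a BOLD series; the encoder weights are optimized until
the generated series matches the observation.  The estimator is therefore
an autoencoder whose decoder is a fixed, mechanistic forward model, and
whose latent code is scientifically interpretable: per-region neuronal
rates and the weighted edges of a hypothesis graph.

## Forward model

Each region carries six states: excitatory and inhibitory neuronal
activity (x_E, x_I), a vasoactive signal s, normalized inflow f, venous
volume v, and deoxyhemoglobin content q.  The resting state is
(0, 0, 0, 1, 1, 1) and is preserved exactly under zero input.

**Neuronal (two-state, bilinear).**

    dx_E/dt = -sigma x_E - mu x_I + (A + sum_m u_m B^m) x_E + C u_drv
    dx_I/dt = lambda (x_E - x_I)

sigma (1/s) is the excitatory self-connection (decay), lambda the rate at
which inhibition tracks excitation, and mu the inhibitory-to-excitatory
gain.  The inhibitory state is a low-passed copy of the excitatory one, so
its subtraction produces adaptation: an onset overshoot, a lower plateau,
and a negative rebound at stimulus offset.  A holds the directed
inter-regional weights (zero diagonal — self-influence lives in sigma),
B^m the modulatory gain of input channel m, C the driving weights.

**Neurovascular coupling (feedforward).**

    ds/dt = x_E - phi s
    df/dt = phi (s - (f - 1))

The vasoactive signal integrates excitatory activity with decay phi and
inflow relaxes toward 1 + s at the same rate.  No flow feedback enters the
neuronal or vasoactive equations.  Two properties motivated this form over
a pure flow integrator df/dt = s: with the two-state neuronal model the
time integral of x_E over a stimulation episode is strictly positive, so a
pure integrator would ratchet the flow upward on every block and never
return to baseline; and bounded flow excursions are required for the
balloon states to remain in their physical domain.  The chosen form keeps
the coupling strictly feedforward, returns exactly to rest, and yields the
poststimulus undershoot through the neuronal rebound.

**Balloon model with viscoelastic veins.**

    dv/dt = (f - v^(1/alpha)) / (tau_mtt + tau_visc)
    dq/dt = [ f E(f)/E0 - (v^(1/alpha) + tau_visc dv/dt) q / v ] / tau_mtt
    E(f)  = 1 - (1 - E0)^(1/f)

alpha is the Grubb flow-volume exponent, tau_mtt the mean transit time,
tau_visc the viscoelastic time constant that makes volume lag flow
(deepening the undershoot).  E(f) is the oxygen extraction fraction; it
*decreases* with inflow (E(1) = E0, E -> 0 as f -> infinity).

**BOLD observation.**

    y = V0 [ k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v) ]     (% signal change)

**S-DCM variant** (generator only): a single neuronal state
(dx/dt = -sigma x + A x + C u), classical feedback flow regulation
(ds/dt = x - kappa s - gamma (f-1), df/dt = s), and tau_visc = 0.  It
serves as the alternative data generator for robustness studies; the
decoder used in fitting is always P-DCM.

Default constants: phi = 0.6 /s, tau_mtt = 2 s, tau_visc = 4 s,
alpha = 0.32, E0 = 0.4, V0 = 4 %, k1 = 4.92, k2 = 0.57, k3 = 0.46,
kappa = 0.65 /s, gamma = 0.41 /s — standard literature values, all
configurable through `HemoParams`.  Generation defaults for the neuronal
rates are sigma = 0.5, lambda = 0.2, mu = 1.0 per region.

## Integration and gradients

The state equations are integrated with fixed-step Heun (explicit
trapezoid) on a 10 ms grid, sampled at every TR.  Heun was chosen over
plain Euler after grid-refinement checks: at 10 ms its worst-case deviation
from a 10x-refined grid is below 1e-5 of the peak response on the 3-region
benchmark, whereas Euler at the same step leaves an O(dt) error of a few
tenths of a percent.  Both Heun stages evaluate the stimulus at the left
step edge, so boxcar onsets are resolved identically on every grid.
Trajectories must keep f, v, q strictly positive and finite; violations
raise a divergence error carrying the failure time and the offending
parameters.

Gradients follow the discretize-then-differentiate principle in two
segments:

* **Decoder:** the integrator propagates forward sensitivities of the
  discrete Heun map — dY/dtheta for every output sample, exact up to
  floating point.  Unit tests pin them against central finite differences
  at relative error 1e-3 (observed agreement ~1e-8).
* **Encoder:** a small reverse-mode automatic-differentiation engine over
  numpy arrays (broadcast arithmetic, batched matmul, masked softmax,
  layer normalization, pooling) backpropagates the loss gradient from the
  decoded parameter vector into the encoder weights.

## Encoder

The T x S observation is cut into windows of length N = min(60, T) with
95% overlap (stride max(1, round(0.05 N)); only the final window is
zero-padded), stacked into a W x N x S batch, scaled per region by a
learnable diagonal embedding, and summed with sinusoidal positional
encodings.  Each of L = 2 layers applies:

1. **Across-sample attention (ASA):** scaled dot-product attention over
   the time axis (N x N, unmasked), residual + layer norm.
2. **Across-node attention (ANA):** the Q/K/V features are transposed to
   S x N and attention is computed over the region axis.  The S x S score
   matrix receives an additive mask — 0 on edges permitted by the
   hypothesis graph plus the diagonal, -infinity elsewhere — so forbidden
   entries of the attention matrix are exactly zero.  Residual + layer
   norm, then a feed-forward sublayer (width 4S) along the region axis
   with its own residual + layer norm.

At the last layer the ASA and ANA outputs are pooled (mean over windows
and time) and passed through separate single-layer summary heads: the ASA
head emits raw sigma/lambda/mu per region, the ANA head one raw value per
permitted edge.  Raw values are squashed — lo + (hi-lo) logistic(raw) for
rates, a_max tanh(raw) for edges — so every decoded parameter respects its
bounds (sigma in [0.1, 1.5], lambda in [0.05, 1.0], mu in [0.1, 2.0] 1/s,
|A| <= 1) and masked edges are identically zero.  The summary heads start
at zero, so the initial decoded parameters are the same neutral point
(midpoint rates, zero edges) for every seed; the encoder body uses a
scaled-uniform (Glorot-style) initialization under the run seed.
Modulatory (B) and driving (C) weights are estimated only when the
configuration enables them; benchmark C entries are fixed at 1 on their
permitted support.

The attention matrices are exposed diagnostically; the connectivity
estimate itself is read from the summary head, which is what feeds the
decoder.

## Fitting

Per iteration: encode the (fixed) windowed observation into theta,
integrate the P-DCM over the full run, compute the mean-squared error
against the full observation, and update the encoder weights by gradient
descent with momentum 0.8.  Three numerical safeguards make the loop
robust without altering its fixed-point structure:

* **Curvature equalization.** The loss gradient w.r.t. theta is divided by
  the damped diagonal Gauss-Newton curvature (sum of squared output
  sensitivities per parameter) before being backpropagated.  Raw
  curvatures differ by orders of magnitude between rate and edge
  parameters; without this scaling the bounded heads saturate.  The
  damping follows a Levenberg-Marquardt schedule (shrunk 1.5x on
  improvement, doubled on failure, within [1e-4, 1]).
* **Trust region.** The applied weight step is shrunk, by measurement,
  until no decoded parameter moves more than 0.12 per iteration.
* **Step rejection.** If a step drives the integrator out of its physical
  domain, the step is undone and retried at half size (up to 5 times)
  before aborting with a diagnostic.

Stopping: 100 iterations, or earlier when the absolute loss change stays
below 1e-5 on two consecutive iterations (the two-iteration requirement
guards against transient plateaus).  The best-loss iterate is returned,
with the loss trajectory, the reconstruction, and the attention maps.
Identical seeds and inputs give bit-identical results.

## Synthetic benchmarks

The generator produces the study conditions used by all tests:

* **3-region network:** driving inputs u1 -> R1 and u2 -> R2, edges
  R2 -> R3 (0.5), R1 -> R3 (0.4), R3 -> R1 (0.3); TR 1 s.
* **10-region network:** the same two driving inputs, a propagation chain
  reaching all regions, and a reciprocal R7 <-> R10 pair (weights 0.25 to
  0.5).
* **Random S-region networks:** directed edges at a requested density,
  a fraction reciprocal, weights uniform on +/-[0.1, 0.7] (magnitudes
  below 0.1 are never generated, keeping relative-error metrics defined);
  draws whose forward simulation diverges are rejected and resampled.
* **Stimuli:** two boxcar channels, 20 s ON / 40 s OFF, staggered by half
  a period, over 400 s.
* **Noise:** i.i.d. Gaussian per region with sd = sd(signal)/CNR.

These synthetic conditions exercise parameter recovery under the model's
own generative assumptions (plus S-DCM-generated data as a mismatched
generator).  They do not emulate physiological confounds of real fMRI —
drift, motion, cardiac/respiratory structure, regionally correlated noise,
or hemodynamic variability across regions — so passing recovery tests
demonstrates internal consistency and noise robustness, not field validity
on empirical data.  Face-perception hypothesis configs (m1-m4) are shipped
as parse-validated examples only; their edge lists are synthetic
reconstructions.

## Metrics

* **MAPE** (%): mean over permitted edges of |a_hat - a| / |a|, excluding
  edges with |a| < 0.1 (count reported); scale-invariant.
* **NRMSE** (%): per region, RMSE divided by the ground-truth range;
  reported per region and averaged.
* **R^2:** 1 - SS_res/SS_tot per region.
* **Log-evidence (approximation):** Gaussian log-likelihood at the
  residual-variance MLE (floored at 1e-12) minus (k/2) ln n.  This is a
  BIC-style accuracy-minus-complexity score standing in for the
  variational log-evidence of the DCM literature; its absolute values are
  not comparable to variational numbers, only differences between models
  fitted to the same data are meaningful.

## Problem sizes and reproducibility

The shipped test-suite and acceptance runs use the 3-region benchmark at
full length (400 s, TR 1 s), short 2-region instances (120 s) for gradient
and determinism checks, and the 10-region network at 200 s for forward
stability checks; these sizes keep the whole suite comfortably within a
desktop-scale run while exercising every code path.  `scripts/acceptance.py`
re-fits the noiseless 3-region benchmark from scratch over three derived
optimizer seeds and reports mean MAPE and NRMSE.  Every stochastic
component (weight initialization, noise, random networks) is driven by an
explicit integer seed, and fits are bit-reproducible given seed, config,
and input.

## Known limitations

* Effective connectivity is assumed stationary over the run; no
  time-varying coupling.
* The optimizer is a local method; with very noisy data (CNR ~ 3) or dense
  graphs, run-to-run variability across seeds grows, mirroring the general
  behavior of gradient-based DCM inversion.
* Hemodynamic constants are shared across regions and not estimated.
* The log-evidence score is an explicit approximation (see above).
* The exact constants of the published variant of the generative model are
  not public; the defaults here are standard literature values, so
  quantitative results are comparable in protocol but not digit-for-digit.
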