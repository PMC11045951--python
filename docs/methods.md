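# Methods

## Model overview

`spikepc` simulates hierarchical predictive coding with spiking neurons.
A stack of cortical areas infers the latent causes of a static image: each
area's representation units (R) generate top-down predictions of the
activity one level below, while paired positive/negative error units
(E+/E-) compute the signed mismatch between that prediction and the actual
bottom-up signal and propagate it upward.  Because spike trains cannot go
negative, the signed prediction error is carried by two complementary
populations wired with opposite excitatory/inhibitory arrangements: E+
fires when input exceeds prediction, E- when prediction exceeds input.
A separate feedforward gist (FFG) pathway — a fixed sparse random
projection from the input to a small gist population, broadcast to every
higher area — supplies a coarse stimulus prior that seeds inference instead
of a flat or random initial condition.

## Neurons

All units are adaptive exponential integrate-and-fire (AdEx) neurons:

    C_m dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_θ)/Δ_T) + I - a
    τ_a da/dt = c (V - E_L) - a

with the standard regular-spiking parameter set (C_m = 281 pF, g_L = 30 nS,
E_L = V_r = -70.6 mV, V_θ = -50.4 mV, Δ_T = 2 mV, t_ref = 2 ms, c = 4 nS,
b = 0.0805 nA, τ_a = 144 ms).  A spike is emitted on V > V_θ (strict);
V resets to V_r, a jumps by b, and the neuron holds at V_r with its input
ignored for t_ref.  The adaptation variable keeps evolving during the
refractory period — the dynamics are stated only outside it, and letting
the slow variable run is the conventional reading.  Integration is forward
Euler on a 1 ms clock; the exponential argument is clamped at +20 so a
single overshoot step cannot overflow before the reset.  Tests compare the
Euler path against an adaptive RK45 integrator with event detection:
inter-spike intervals agree within 0.5 ms at 800 pA, while absolute spike
times accumulate ~0.2 ms/spike of drift — an inherent property of the 1 ms
grid, which is why the oracle comparison is ISI-wise.

With these constants the rheobase is ≈627 pA.  Images are unit-normalised
and affinely encoded to [600, 3000] pA, so zero-intensity pixels sit just
below threshold (silent) and the brightest pixel drives ≈140 Hz.

## Synapses and the trace gain

Each neuron carries a transmitter variable Y (set to 1 on a spike — reset,
not incremented — decaying with τ_decay = 50 ms) and a trace
X (dX/dt = Y/τ_rise − X/τ_decay, τ_rise = 5 ms), one per neuron, shared by
all outgoing synapses.  The single-spike response is
X(t) = (t/τ_rise) e^(−t/τ_decay), an AMPA/NMDA-like current with peak 10/e
at 50 ms.  Postsynaptic currents are weighted sums of presynaptic traces.

Traces are O(1–10) while the rheobase is ≈627 pA, so dimensionless weights
around unity cannot drive a postsynaptic cell.  The package therefore uses
one global **trace gain** (pA per unit trace) applied to every weighted
trace sum.  Its default, 225 pA, is the least-squares value that makes
transmission through a weight-1 synapse current-preserving across the
encoding range (argmin_g Σ_I (g·X̄(I) − I)², where X̄(I) is the
steady-state window-mean trace of a neuron driven at I pA;
`calibrate_trace_gain()` recomputes it).  The current→trace curve saturates
above ~1500 pA because Y saturates at 1, so transmission is compressive at
the top of the range; the gain is a compromise that keeps mid-range
one-to-one transmission near identity.  The gain also sets the error
units' sensitivity: mismatches smaller than rheobase/gain ≈ 2.8 trace
units cannot elicit error spikes, which bounds the attainable prediction
error from below (a dead zone intrinsic to threshold neurons).

## Current assembly

Per 1 ms step, with g the trace gain and W[l] the tied matrix between
areas l and l+1 (rows: area-l+1 units, columns: area-l units):

* `I_E±^l = ±g (X_R^l − W[l]^T X_R^{l+1})` — one-to-one bottom-up input
  (weight exactly 1) minus the shared top-down prediction; antisymmetric
  by construction.
* `I_R^l = g (W[l−1](X_E+^{l−1} − X_E−^{l−1}) − X_E+^l + X_E−^l + Wg[l] X_G)`
  — bottom-up error through the tied weights, same-area error feedback
  through one-to-one links (absent at the top area, which receives no
  top-down input), and the gist term.
* `I_G = g W_IG X_R^0` — the gist population is driven by the input-unit
  traces through the sparse random projection, active as long as the
  stimulus lasts.
* Area-0 representation units receive the constant encoded input current
  only; they act as input units.

Negative assembled currents hyperpolarise (no rectification).  The per-step
order is: assemble currents from the previous step's traces → integrate
membranes → detect/reset spikes → decay Y, apply spike resets → Euler-step
X.  State is reset to rest at every stimulus onset, so presentations are
independent and bit-reproducible; ablation switches zero either the
inter-areal (PC) currents or the gist-derived currents.

## FFG weights

Input→gist entries are Gaussian with mean = SD = n_gist/n_input, masked by
independent Bernoulli(P_c = 0.05) draws; gist→R entries are dense Gaussian
with mean = SD = n_gist/n_target.  Negative draws are clipped at zero
(strictly excitatory convention).  The size-ratio orientation is genuinely
ambiguous in the source description; the package defaults to the
"gist over partner" ratio on both stages because the alternative
(n_target/n_gist ≈ 25 for gist→R) produces gist currents two orders of
magnitude above the encoding range and swamps the hierarchy.  Both printed
orientations remain selectable (`build_ffg_weights(orientation=...)`).

## Learning

After each presentation, window means of the traces over the final t_w ms
stand in for NMDA-receptor-mediated calcium signals.  For each plastic
matrix:

    ΔW+ = X̄_R^{l+1} ⊗ X̄_E+^l        ΔW− = X̄_R^{l+1} ⊗ X̄_E−^l
    W ← W + γ_w (ΔW+ − ΔW−) − α_w · 1[W > 0]

Per-sample terms are averaged over a mini-batch and applied once per batch
(a final partial batch uses its actual size).  Weights are initialised
half-normal (|N(0, 0.3)|) and clipped at zero after updates, keeping the
strictly-positive regime the L1 decay's step function implies.  Only the
inter-areal matrices learn; one-to-one and gist weights are fixed.  A
per-matrix learning-rate multiplier (`per_area_lr_scale`) replaces the
source procedure of fitting per-area rates to an exponential growth
function, which is under-specified to the point of being unreconstructible;
the default multipliers are 1.

## Protocols

Full scale (`protocols.full_scale_*`): areas 784/400/225/64 + 16 gist units
(4,307 neurons; 418,000 plastic synapses; 431,842 synapses under the
documented accounting), dt = 1 ms, T = 350 ms, t_w = 100 ms, γ_w = 1e-7,
α_w = 1e-5, batches of 32, 50 epochs on 5,120 MNIST images (512/class),
testing on 100 resampled sets of 1,280.  One source table prints
T = 350 ms while the accompanying text describes a 300–400 ms averaging
window; the package takes T = 350 with window [250, 350] and leaves T
configurable.  This run needs the MNIST IDX files and several CPU-hours;
it is supported and smoke-tested (one presentation + one update) but not
part of the routine suite.

Desk scale (`protocols.desk_*`): two areas [64, 100], 8 gist units, on
8×8 synthetic stroke images (3 classes × 8 samples), T = 550 ms,
t_w = 300 ms, γ_w = 1.5e-3, α_w = 1e-3, batches of 4, 30 epochs (~1–2 min
on one CPU).  Two calibration facts drove these choices, made once and
frozen.  First, the recurrent error loop does not settle to a fixed point:
the ~50 ms trace lag around the R↔E loop produces a sustained limit cycle
of roughly 200 ms period in which E+ and E- fire in alternation.  The
plasticity window must therefore cover at least one full cycle; windows
shorter than the cycle sample a phase and bias the LTP/LTD balance, which
caps reconstruction quality.  Second, learning rates are scale-dependent
(the Hebbian terms are products of window-mean traces whose magnitudes
depend on layer sizes and, at full scale, were themselves adjusted per
area); the desk values bring the two-area network to its error floor
within 30 epochs.  Under these conditions area-0 NRMSE falls from ~3.5 to
~0.19 and reconstruction-input correlation reaches 0.91–0.93 across seeds.

A corollary of the limit cycle: total error-unit spiking does *not* fall
below the first-50 ms rate late in a presentation (the first 50 ms are
trace ramp-up, and the converged loop keeps both error flavours active).
The error-minimisation signature used in tests is trained-vs-untrained:
training cuts total error spiking and the signed mismatch |X̄_E+ − X̄_E−|
by well over half.

## Synthetic stimuli

The generator emulates a small MNIST-like set: each class is a distinct
stroke glyph (box, bar, diagonal, cross, X, L, T, double bar; up to 8
classes) rendered at any side ≥ 6, jittered per sample by a soft sub-pixel
translation (blend of the prototype with a ±1 px zero-fill shift, weight
U(0, 0.4)), amplitude scaling U(0.8, 1.2), and clipped Gaussian pixel noise
(SD 0.06).  Calibration: within-class image correlation ≈ 0.93 vs
between-class ≈ 0.13, and every sample correlates > 0.8 with its prototype.
What it does not emulate: handwriting's topological variability, stroke
thickness variation, or class overlap — so passing desk-scale tests shows
the machinery works, not that MNIST-level accuracy figures transfer.
Perturbations act in current space after encoding (the noise model is
specified in pA): additive N(0, 300 pA) unclipped, or a square occlusion
patch set to the 600 pA floor (3×3 on 8×8 ≈ 14% of the image, comparable to
9×9 on 28×28 = 10.3%).

## Analysis

* NRMSE: RMSE normalised by the target's range — affine-invariant.
* RDMs: 1 − Spearman rank correlation between window-mean responses
  (the same statistic learning uses); constant responses are NaN-flagged,
  never silently zeroed.  Second-order RSA: Spearman correlation of the
  strict upper triangles, invariant to monotone transforms of either RDM.
* Decoding: L2-penalised multinomial logistic regression fitted once on
  training features, scored on resampled test sets; features are the
  area-1 window means (the model's designated latent representation).
* Group comparison: two-sided Mann-Whitney U (asymptotic, tie-corrected),
  with percentile-bootstrap 95% CIs of each mean.  The asymptotic p-value
  agrees with exhaustive enumeration within 0.08 for n ≤ 8 per group.

## Numerical choices and degenerate inputs

Euler at dt = 1 ms throughout (the trace peak is 1% off its closed form at
this step); exponential clamp at +20; all randomness flows through
`numpy.random.default_rng` seeds — identical seeds give bit-identical spike
rasters, weights and logs.  All-zero images are rejected by the encoder
(the unit-norm step is undefined); constant targets make NRMSE raise and
RDM entries NaN; empty stimulus sets and single-class decoding raise.
A constant (silent) reconstruction is treated as zero correlation where a
correlation must be aggregated.

## Known limitations

* The trace gain linearises one-to-one transmission only in the mid-range;
  the encode→spike→trace chain is compressive near 3,000 pA.
* The error dead zone (rheobase/gain) bounds achievable NRMSE; reported
  reconstruction correlations (~0.92 desk scale) reflect that floor plus
  the limit-cycle phase noise, not an optimisation failure.
* Deeper hierarchies lose signal upward (each spiking stage is a threshold
  nonlinearity); reconstruction from areas above 1 degrades accordingly.
* The gist pathway is fixed and non-plastic by design; FFG-only inference
  yields only a coarse, weakly correlated representation.
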