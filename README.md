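# spikepc

Hierarchical predictive coding built entirely from spiking neurons.

Perception as inference: a cortical hierarchy keeps a generative model of
its input, feeds back predictions, and feeds forward only the prediction
*errors*, which update the latent representation until the input is
explained away.  `spikepc` implements this scheme with adaptive exponential
integrate-and-fire (AdEx) neurons communicating through event-driven
spikes, for computational neuroscientists who want a biologically grounded,
fully reproducible predictive-coding simulator with its analysis battery
included.

Two features address the specific frictions of doing predictive coding
with spikes:

* **Signed errors from non-negative spike trains.** Each area carries a
  pair of error populations, E+ (input > prediction) and E−
  (prediction > input), wired with opposite excitatory/inhibitory
  arrangements, so no neuron needs a high baseline rate to encode a sign.
* **A feedforward gist pathway.** A fixed, sparse random projection maps
  the input to a small "gist" population whose activity is broadcast to
  every area as a coarse stimulus prior — inference starts from an informed
  baseline rather than zero.

## Model

Membrane dynamics (AdEx, regular-spiking constants):

    C_m dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_θ)/Δ_T) + I − a
    τ_a da/dt = c (V − E_L) − a,      spike: V > V_θ ⇒ V ← V_r, a ← a + b

Spikes drive per-neuron traces X (dX/dt = Y/τ_rise − X/τ_decay, with Y set
to 1 at each spike), an AMPA/NMDA-like postsynaptic current.  Currents are
weighted trace sums through tied inter-areal matrices W^{l,l+1}:

    I_{E±}^l = ± g ( X_R^l − (W^{l,l+1})^T X_R^{l+1} )
    I_R^l    = g ( W^{l−1,l}(X_{E+}^{l−1} − X_{E−}^{l−1}) − X_{E+}^l + X_{E−}^l
                   + W_{G,R^l} X_G )

Learning is Hebbian on window-mean traces with L1 decay:

    ΔW^{l,l+1} = γ_w ( X̄_R^{l+1} ⊗ X̄_{E+}^l − X̄_R^{l+1} ⊗ X̄_{E−}^l )
                 − α_w · 1[W > 0]

The analysis battery covers reconstruction, range-normalised RMSE (NRMSE),
representational dissimilarity matrices (1 − Spearman ρ), second-order RSA,
linear decoding, and Mann-Whitney group comparisons.  See
`docs/methods.md` for assumptions, calibration and limitations.

## Worked example

```python
import numpy as np
from spikepc import present_stimulus, reconstruct
from spikepc.protocols import desk_sim_config, train_desk_network

net, log, batch = train_desk_network(seed=7)   # 2 areas, 8x8 images, ~1 min

rows = [r for r in log if r["area"] == 0]
print(f"NRMSE epoch 0: {rows[0]['nrmse']:.3f} -> epoch 29: {rows[-1]['nrmse']:.3f}")

cors = []
for i in range(batch.n):
    buf = present_stimulus(net, batch.currents[i], desk_sim_config())
    rec = reconstruct(net, buf, from_area=1)            # top-down prediction
    cors.append(np.corrcoef(rec, buf.window_means["R0"])[0, 1])
print(f"reconstruction-input correlation: {np.mean(cors):.3f}")
```

Output:

```
NRMSE epoch 0: 3.460 -> epoch 29: 0.193
reconstruction-input correlation: 0.913
```

The falling NRMSE says the top-down prediction of the input-area activity
improves across epochs; the correlation says the trained hierarchy's
reconstruction recovers the spatial pattern of each training image from
its latent representation.  The `examples/` scripts walk through each
capability (single-neuron f-I, traces, architecture accounting, training,
noise/occlusion robustness, RSA + decoding + the gist-pathway ablation),
and a thin CLI mirrors the pipeline:

```bash
spikepc build-report                 # unit/synapse accounting (4,307 / 431,842)
spikepc train --epochs 5             # quick synthetic run into results/
spikepc ablate --ablation ffg-only   # gist pathway alone
```

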