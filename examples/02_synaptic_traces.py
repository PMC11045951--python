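"""Spike-to-current conversion through the glutamate variable and trace.

A presynaptic spike sets the transmitter variable Y to 1; Y drives the
low-pass trace X, which approximates a mixed AMPA/NMDA postsynaptic
current: X(t) = (t/5) exp(-t/50) for a single spike, peaking at 10/e
after 50 ms.
"""

import numpy as np

from spikepc import SynapticTraceState, update_glutamate, update_trace

state = SynapticTraceState.zeros(1)
xs = []
for k in range(150):
    spikes = np.array([1 if k == 0 else 0])
    update_glutamate(state, spikes, dt=1.0)
    update_trace(state, dt=1.0)
    xs.append(state.X[0])

peak, t_peak = max(xs), int(np.argmax(xs))
print(f"single-spike trace peak: {peak:.3f} at t = {t_peak} ms")
print(f"closed form 10/e = {10 * np.exp(-1):.3f} at t = 50 ms")
print(f"relative Euler error at dt = 1 ms: {abs(peak - 10 * np.exp(-1)) / (10 * np.exp(-1)):.1%}")
print("\nThe window mean of this trace over the last part of a presentation"
      "\nis the quantity that drives both the currents and the Hebbian rule.")
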