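"""Spike-to-current conversion: glutamate variable Y and synaptic trace X.

Each neuron carries one transmitter variable Y and one trace X shared by all
of its outgoing synapses.  A spike resets Y to 1 (it is *set*, not
incremented); Y then decays exponentially with ``tau_decay``.  The trace X is
a low-pass filter of Y::

    dX/dt = Y/tau_rise - X/tau_decay
    dY/dt = -Y/tau_decay,   spike => Y = 1

With tau_rise = 5 ms and tau_decay = 50 ms the single-spike response
X(t) = (t/tau_rise) exp(-t/tau_decay) approximates a mixed AMPA/NMDA
excitatory postsynaptic current: fast rise, slow decay, peak
(tau_decay/tau_rise)/e at t = tau_decay.  Postsynaptic currents are weighted
sums of presynaptic traces, I_j = sum_i W_ij X_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapticTraceState",
    "WeightMatrix",
    "update_glutamate",
    "update_trace",
    "postsynaptic_current",
]


@dataclass
class SynapticTraceState:
    """Per-neuron transmitter variable Y in [0, 1] and trace X >= 0."""

    Y: np.ndarray
    X: np.ndarray
    tau_rise: float = 5.0    #: rise time constant, ms
    tau_decay: float = 50.0  #: decay time constant, ms

    @classmethod
    def zeros(cls, n: int, tau_rise: float = 5.0, tau_decay: float = 50.0):
        return cls(Y=np.zeros(n), X=np.zeros(n), tau_rise=tau_rise,
                   tau_decay=tau_decay)

    @property
    def n(self) -> int:
        return self.Y.shape[0]


@dataclass
class WeightMatrix:
    """Connection weights; rows index postsynaptic, columns presynaptic units."""

    values: np.ndarray
    plastic: bool = False
    label: str = ""

    @property
    def shape(self):
        return self.values.shape


def update_glutamate(
    state: SynapticTraceState, spikes: np.ndarray, dt: float
) -> SynapticTraceState:
    """Euler-decay Y, then set Y = 1 for neurons that spiked this step."""
    spikes = np.asarray(spikes)
    if spikes.shape != state.Y.shape:
        raise ValueError("spike vector length does not match population")
    state.Y -= dt * state.Y / state.tau_decay
    state.Y[spikes.astype(bool)] = 1.0
    return state


def update_trace(state: SynapticTraceState, dt: float) -> SynapticTraceState:
    """One Euler step of the trace dynamics dX/dt = Y/tau_rise - X/tau_decay."""
    state.X += dt * (state.Y / state.tau_rise - state.X / state.tau_decay)
    return state


def postsynaptic_current(W: WeightMatrix, X: np.ndarray) -> np.ndarray:
    """Weighted sum of presynaptic traces, I_j = sum_i W_ij X_i.

    The weight values carry the conversion from trace units to current;
    in the network engine this is a dimensionless matrix scaled by a global
    trace gain (pA per unit trace).
    """
    X = np.asarray(X, dtype=float)
    if W.values.shape[1] != X.shape[0]:
        raise ValueError(
            f"weight matrix has {W.values.shape[1]} presynaptic columns, "
            f"trace vector has length {X.shape[0]}"
        )
    return W.values @ X
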