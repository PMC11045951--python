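"""Clocked inference loop: current assembly, stepping, and recording.

Per time step the engine (i) assembles each population's synaptic current
from the traces of the *previous* step, (ii) integrates the membranes,
(iii) detects spikes and applies resets, and (iv) updates transmitter
variables and traces with the fresh spikes.  All currents are weighted trace
sums scaled by the network's ``trace_gain`` (pA per unit trace).

Current assembly (area l, hierarchy of L+1 areas):

* error units (l < L)::

      I_E+ = g * ( X_R^l - W[l]^T X_R^{l+1} ),   I_E- = -I_E+

  The one-to-one R->E links have weight exactly 1, so the bottom-up term is
  the raw same-area representation trace; both error flavours receive the
  identical top-down prediction, with opposite signs of the two terms.
* representation units (0 < l)::

      I_R = g * ( W[l-1] X_E+^{l-1} - W[l-1] X_E-^{l-1}
                  - X_E+^l + X_E-^l + Wg[l] X_G )

  The same-area terms drop out at the top area (no top-down input there);
  the gist term is present only when the FFG pathway is enabled.
* gist units: I_G = g * W_IG X_R^0, active as long as the stimulus lasts.
* area-0 representation units receive the constant encoded input current
  only (they act as input units).

Negative assembled currents hyperpolarise; nothing is rectified.  State is
reset to rest at each stimulus onset, so presentations are independent and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import PCNetwork
from .neurons import detect_spikes_and_reset, step_membrane
from .synapses import SynapticTraceState, WeightMatrix, update_glutamate, update_trace

__all__ = [
    "SimulationConfig",
    "RecordingBuffer",
    "error_currents",
    "representation_currents",
    "gist_current",
    "present_stimulus",
]


@dataclass
class SimulationConfig:
    """Timing and ablation switches for one stimulus presentation."""

    dt: float = 1.0       #: integration step, ms
    T: float = 350.0      #: stimulus duration, ms
    t_w: float = 100.0    #: plasticity/analysis window at the end of T, ms
    record_full_traces: bool = False
    ffg_enabled: bool = True
    pc_enabled: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0 or not (0 < self.t_w <= self.T):
            raise ValueError("need dt > 0 and 0 < t_w <= T")
        if abs(self.T / self.dt - round(self.T / self.dt)) > 1e-9:
            raise ValueError("dt must divide T")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def window_steps(self) -> int:
        return int(round(self.t_w / self.dt))


@dataclass
class RecordingBuffer:
    """What a presentation leaves behind for learning and analysis."""

    window_means: dict[str, np.ndarray]        #: mean X over the final t_w
    spike_counts: dict[str, np.ndarray]        #: total spikes over T
    early_spike_counts: dict[str, np.ndarray]  #: spikes in the first 50 ms
    traces: dict[str, np.ndarray] | None = None   #: full X time series (T x n)
    spikes: dict[str, np.ndarray] | None = None   #: full rasters (T x n)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for group, data in [("window_means", self.window_means),
                                ("spike_counts", self.spike_counts)]:
                g = f.create_group(group)
                for k, v in data.items():
                    g.create_dataset(k, data=v)
            if self.traces is not None:
                g = f.create_group("traces")
                for k, v in self.traces.items():
                    g.create_dataset(k, data=v)
            if self.spikes is not None:
                g = f.create_group("spikes")
                for k, v in self.spikes.items():
                    g.create_dataset(k, data=v)

    @classmethod
    def load_hdf5(cls, path) -> "RecordingBuffer":
        import h5py

        with h5py.File(path, "r") as f:
            wm = {k: v[()] for k, v in f["window_means"].items()}
            sc = {k: v[()] for k, v in f["spike_counts"].items()}
            traces = ({k: v[()] for k, v in f["traces"].items()}
                      if "traces" in f else None)
            spikes = ({k: v[()] for k, v in f["spikes"].items()}
                      if "spikes" in f else None)
        return cls(window_means=wm, spike_counts=sc, early_spike_counts={},
                   traces=traces, spikes=spikes)


def error_currents(
    X_R_same: np.ndarray, X_R_above: np.ndarray, W: WeightMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Signed prediction-error drive (in trace units, before the gain).

    I_E+ = X_R_same - W^T X_R_above and I_E- = -I_E+: the two error flavours
    see the same bottom-up input and the same top-down prediction, wired with
    opposite excitatory/inhibitory arrangements.
    """
    X_R_same = np.asarray(X_R_same, dtype=float)
    X_R_above = np.asarray(X_R_above, dtype=float)
    if W.values.shape != (X_R_above.shape[0], X_R_same.shape[0]):
        raise ValueError(
            f"weight shape {W.values.shape} inconsistent with traces "
            f"({X_R_above.shape[0]}, {X_R_same.shape[0]})"
        )
    I_plus = X_R_same - W.values.T @ X_R_above
    return I_plus, -I_plus


def representation_currents(
    X_E_below_plus: np.ndarray,
    X_E_below_minus: np.ndarray,
    W_below: WeightMatrix,
    X_E_same_plus: np.ndarray | None = None,
    X_E_same_minus: np.ndarray | None = None,
    X_G: np.ndarray | None = None,
    W_gist: WeightMatrix | None = None,
    is_top: bool = False,
    ffg_enabled: bool = True,
) -> np.ndarray:
    """Drive to a non-input representation population (trace units).

    Bottom-up error terms propagate through the tied inter-areal matrix;
    the same-area error terms enter through one-to-one links (weight 1) and
    are absent at the top area; the gist term is added when the FFG pathway
    is enabled.
    """
    I = W_below.values @ np.asarray(X_E_below_plus, dtype=float)
    I = I - W_below.values @ np.asarray(X_E_below_minus, dtype=float)
    if not is_top:
        if X_E_same_plus is None or X_E_same_minus is None:
            raise ValueError("non-top areas need same-area error traces")
        I = I - np.asarray(X_E_same_plus) + np.asarray(X_E_same_minus)
    if ffg_enabled and W_gist is not None and X_G is not None:
        I = I + W_gist.values @ np.asarray(X_G, dtype=float)
    return I


def gist_current(X_input: np.ndarray, W_input_gist: WeightMatrix) -> np.ndarray:
    """Drive to the gist units from input-unit traces (trace units)."""
    X_input = np.asarray(X_input, dtype=float)
    if W_input_gist.values.shape[1] != X_input.shape[0]:
        raise ValueError("input trace length does not match gist projection")
    return W_input_gist.values @ X_input


def assemble_currents(
    net: PCNetwork, input_currents: np.ndarray, cfg: SimulationConfig
) -> dict[str, np.ndarray]:
    """All per-population synaptic currents (pA) from the current traces."""
    g = net.trace_gain
    L = net.top
    I: dict[str, np.ndarray] = {"R0": input_currents}
    if cfg.ffg_enabled:
        I["G"] = g * gist_current(net.R[0].trace.X, net.W_input_gist)
    else:
        I["G"] = np.zeros(net.G.state.n)
    for l in range(L):
        if cfg.pc_enabled:
            ip, im = error_currents(
                net.R[l].trace.X, net.R[l + 1].trace.X, net.W_inter[l]
            )
            I[f"E+{l}"], I[f"E-{l}"] = g * ip, g * im
        else:
            I[f"E+{l}"] = np.zeros(net.areas[l].n_units)
            I[f"E-{l}"] = np.zeros(net.areas[l].n_units)
    for l in range(1, L + 1):
        if cfg.pc_enabled:
            drive = representation_currents(
                X_E_below_plus=net.E_plus[l - 1].trace.X,
                X_E_below_minus=net.E_minus[l - 1].trace.X,
                W_below=net.W_inter[l - 1],
                X_E_same_plus=None if l == L else net.E_plus[l].trace.X,
                X_E_same_minus=None if l == L else net.E_minus[l].trace.X,
                X_G=net.G.trace.X,
                W_gist=net.W_gist_R[l - 1],
                is_top=(l == L),
                ffg_enabled=cfg.ffg_enabled,
            )
        else:
            drive = (net.W_gist_R[l - 1].values @ net.G.trace.X
                     if cfg.ffg_enabled else np.zeros(net.areas[l].n_units))
        I[f"R{l}"] = g * drive
    return I


def present_stimulus(
    net: PCNetwork, currents: np.ndarray, cfg: SimulationConfig
) -> RecordingBuffer:
    """Run one stimulus for T ms from rest and record window statistics.

    The input vector is held constant on the area-0 representation units for
    the whole presentation.  Window means of every population's trace over
    the final ``t_w`` ms are recorded, along with total spike counts and the
    counts in the first 50 ms (for inspecting error-silencing over time).
    """
    currents = np.asarray(currents, dtype=float)
    if currents.shape[0] != net.areas[0].n_units:
        raise ValueError("input length does not match area-0 size")
    if not np.isfinite(currents).all():
        raise ValueError("non-finite input currents")

    net.reset_state()
    names = net.population_names()
    n_steps, w_steps = cfg.n_steps, cfg.window_steps
    early_steps = min(n_steps, int(round(50.0 / cfg.dt)))

    window_sums = {k: np.zeros(net.population(k).state.n) for k in names}
    spike_counts = {k: np.zeros(net.population(k).state.n) for k in names}
    early_counts = {k: np.zeros(net.population(k).state.n) for k in names}
    full_traces = (
        {k: np.zeros((n_steps, net.population(k).state.n)) for k in names}
        if cfg.record_full_traces else None
    )
    full_spikes = (
        {k: np.zeros((n_steps, net.population(k).state.n), dtype=np.int8)
         for k in names}
        if cfg.record_full_traces else None
    )

    for step in range(n_steps):
        I = assemble_currents(net, currents, cfg)
        for name in names:
            pop = net.population(name)
            step_membrane(pop.state, net.params, I[name], cfg.dt)
            detect_spikes_and_reset(pop.state, net.params)
            update_glutamate(pop.trace, pop.state.spiked, cfg.dt)
            update_trace(pop.trace, cfg.dt)
            spike_counts[name] += pop.state.spiked
            if step < early_steps:
                early_counts[name] += pop.state.spiked
            if step >= n_steps - w_steps:
                window_sums[name] += pop.trace.X
            if full_traces is not None:
                full_traces[name][step] = pop.trace.X
                full_spikes[name][step] = pop.state.spiked

    window_means = {k: v / w_steps for k, v in window_sums.items()}
    return RecordingBuffer(
        window_means=window_means,
        spike_counts=spike_counts,
        early_spike_counts=early_counts,
        traces=full_traces,
        spikes=full_spikes,
    )
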