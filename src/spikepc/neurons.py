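"""Adaptive exponential integrate-and-fire (AdEx) neuron populations.

The AdEx model describes the membrane potential V (mV) of a point neuron with
a linear leak, an exponential spike-initiation term standing in for fast
sodium-channel activation, and an adaptation current a (nA)::

    C_m dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_theta)/Delta_T) + I - a
    tau_a da/dt = c (V - E_L) - a

A spike is emitted whenever V exceeds the threshold ``V_theta`` (strict
inequality); the potential is then reset to ``V_r``, the adaptation variable
is incremented by ``b``, and the neuron is held refractory at ``V_r`` for
``t_ref`` ms with its synaptic input ignored.  Adaptation keeps evolving
during the refractory period.

Unit conventions used throughout: capacitance in pF, conductances in nS,
voltages in mV, currents in pA except the adaptation variable and its
increment ``b`` which are in nA, times in ms.  With these units
pA/pF = mV/ms and nS*mV = pA, so the forward-Euler update needs a single
factor of 1000 to convert ``a`` to pA.

Integration is forward Euler on a fixed clock (default 1 ms).  The argument
of the exponential term is clamped so that a single Euler step cannot
overflow between threshold crossing and reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdExParams",
    "NeuronPopulationState",
    "step_membrane",
    "detect_spikes_and_reset",
    "f_i_curve",
]

#: Upper clamp for (V - V_theta)/Delta_T before exponentiation.  exp(20) ~ 5e8
#: is large enough that a clamped neuron crosses threshold within one step,
#: and small enough that the Euler update stays finite.
EXP_ARG_MAX = 20.0


@dataclass
class AdExParams:
    """AdEx parameters for a population (cortical regular-spiking defaults).

    Defaults follow the standard regular-spiking parameterisation of the
    model (Brette & Gerstner 2005).
    """

    C_m: float = 281.0      #: membrane capacitance, pF
    g_L: float = 30.0       #: leak conductance, nS
    E_L: float = -70.6      #: leak reversal potential, mV
    V_theta: float = -50.4  #: spike threshold, mV
    Delta_T: float = 2.0    #: slope factor of the exponential term, mV
    V_r: float = -70.6      #: post-spike reset potential, mV
    t_ref: float = 2.0      #: absolute refractory period, ms
    c: float = 4.0          #: subthreshold adaptation coupling, nS
    b: float = 0.0805       #: spike-triggered adaptation increment, nA
    tau_a: float = 144.0    #: adaptation time constant, ms

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_L <= 0 or self.tau_a <= 0 or self.Delta_T <= 0:
            raise ValueError("capacitance, conductances, slope factor and time "
                             "constants must be strictly positive")
        if self.t_ref < 0:
            raise ValueError("refractory period must be non-negative")


@dataclass
class NeuronPopulationState:
    """Mutable state of one AdEx population (vectors share one length)."""

    V: np.ndarray                     #: membrane potentials, mV
    a: np.ndarray                     #: adaptation variables, nA
    refractory_remaining: np.ndarray  #: time left in refractoriness, ms
    spiked: np.ndarray                #: 0/1 flags for the current step

    @classmethod
    def resting(cls, n: int, params: AdExParams) -> "NeuronPopulationState":
        """A population of ``n`` neurons at leak equilibrium."""
        if n <= 0:
            raise ValueError("population size must be positive")
        return cls(
            V=np.full(n, params.E_L, dtype=float),
            a=np.zeros(n, dtype=float),
            refractory_remaining=np.zeros(n, dtype=float),
            spiked=np.zeros(n, dtype=np.int8),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def validate(self, params: AdExParams | None = None) -> None:
        n = self.V.shape[0]
        if not (self.a.shape[0] == n == self.refractory_remaining.shape[0]
                == self.spiked.shape[0]):
            raise ValueError("state vectors must share one population length")
        if params is not None and (
            (self.refractory_remaining < 0).any()
            or (self.refractory_remaining > params.t_ref).any()
        ):
            raise ValueError("refractory_remaining out of [0, t_ref]")


def step_membrane(
    state: NeuronPopulationState,
    params: AdExParams,
    I: np.ndarray,
    dt: float,
) -> NeuronPopulationState:
    """One forward-Euler step of the membrane and adaptation dynamics.

    Non-refractory neurons integrate V and a; refractory neurons are clamped
    to ``V_r`` with their input ignored while the refractory timer counts
    down (adaptation still evolves).  Mutates and returns ``state``.
    """
    I = np.asarray(I, dtype=float)
    if I.shape != state.V.shape:
        raise ValueError(
            f"input current length {I.shape} does not match population {state.V.shape}"
        )
    if not np.isfinite(I).all():
        raise ValueError("non-finite input current")
    if dt <= 0:
        raise ValueError("dt must be positive")

    refractory = state.refractory_remaining > 0
    active = ~refractory

    V, a = state.V, state.a
    # Adaptation evolves everywhere; c*(V-E_L) is in pA, a in nA.
    da = dt / params.tau_a * (params.c * (V - params.E_L) * 1e-3 - a)

    exp_arg = np.minimum((V - params.V_theta) / params.Delta_T, EXP_ARG_MAX)
    # All terms in pA; a converted from nA.
    dV = dt / params.C_m * (
        -params.g_L * (V - params.E_L)
        + params.g_L * params.Delta_T * np.exp(exp_arg)
        + I
        - a * 1e3
    )

    a += da
    V[active] += dV[active]
    V[refractory] = params.V_r
    state.refractory_remaining[refractory] = np.maximum(
        state.refractory_remaining[refractory] - dt, 0.0
    )
    return state


def detect_spikes_and_reset(
    state: NeuronPopulationState, params: AdExParams
) -> NeuronPopulationState:
    """Emit spikes for neurons with V > V_theta and apply the reset rule.

    Spiking neurons get V <- V_r, a <- a + b and a fresh refractory timer;
    all others have their spike flag cleared.  Mutates and returns ``state``.
    """
    crossing = (state.V > params.V_theta) & (state.refractory_remaining <= 0)
    state.spiked[:] = 0
    state.spiked[crossing] = 1
    state.V[crossing] = params.V_r
    state.a[crossing] += params.b
    state.refractory_remaining[crossing] = params.t_ref
    return state


def f_i_curve(
    params: AdExParams,
    currents,
    duration: float = 2000.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Mean firing rate (Hz) for each constant input current (pA).

    Each current is simulated from rest in a fresh single-neuron run of
    ``duration`` ms; the rate is the total spike count divided by duration.
    """
    currents = np.asarray(currents, dtype=float)
    if not np.isfinite(currents).all():
        raise ValueError("currents must be finite")
    n_steps = int(round(duration / dt))
    rates = np.empty(currents.shape, dtype=float)
    for k, I0 in enumerate(currents.ravel()):
        state = NeuronPopulationState.resting(1, params)
        I = np.array([I0])
        count = 0
        for _ in range(n_steps):
            step_membrane(state, params, I, dt)
            detect_spikes_and_reset(state, params)
            count += int(state.spiked[0])
        rates[np.unravel_index(k, currents.shape)] = count / duration * 1e3
    return rates
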