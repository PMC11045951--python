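"""Hierarchical predictive-coding network construction and input encoding.

The network is a stack of cortical areas.  Area 0 holds input (representation)
units, one spiking neuron per pixel, plus positive and negative error
populations of the same size.  Every higher area except the top also has the
R / E+ / E- triplet; the top area has representation units only.  A small
"gist" population receives a fixed sparse random projection from the input
units and broadcasts a coarse stimulus representation to every higher
representation population as a baseline current (the feedforward gist, FFG,
pathway).

Connectivity:

* Inter-areal weights ``W[l]`` (shape: area l+1 units x area l units) are
  plastic and *tied*: transposed they carry top-down predictions to the area-l
  error units, untransposed they propagate area-l errors bottom-up to the
  area-(l+1) representation units.  Initialised half-normal (strictly
  positive).
* Intra-area links (R -> E+/E- and E+/E- -> R) are fixed one-to-one with
  weight exactly 1.
* FFG weights are fixed random Gaussians, sparsified by a Bernoulli mask for
  the input->gist stage, with negative draws clipped to zero.

Traces are dimensionless; a single ``trace_gain`` (pA per unit trace)
converts weighted trace sums into synaptic currents everywhere in the
network.  The default gain is calibrated so that transmission through a
weight-1 synapse approximates the identity on the 600-3000 pA encoding
range in the least-squares sense (see ``calibrate_trace_gain``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import AdExParams, NeuronPopulationState, f_i_curve
from .synapses import SynapticTraceState, WeightMatrix

__all__ = [
    "AreaSpec",
    "PCNetwork",
    "build_network",
    "build_ffg_weights",
    "encode_input",
    "unit_count",
    "synapse_counts",
    "calibrate_trace_gain",
    "DEFAULT_TRACE_GAIN",
]

#: pA per unit trace.  Least-squares fit of gain * meanX(I) ~= I for constant
#: drives spanning the 600-3000 pA encoding range at dt = 1 ms (the value
#: ``calibrate_trace_gain()`` reproduces).
DEFAULT_TRACE_GAIN = 225.0


@dataclass
class AreaSpec:
    """Size and role of one cortical area."""

    n_units: int
    has_errors: bool
    index: int

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("area size must be positive")


@dataclass
class _Population:
    """A spiking population with its outgoing synaptic trace state."""

    state: NeuronPopulationState
    trace: SynapticTraceState


@dataclass
class PCNetwork:
    areas: list[AreaSpec]
    params: AdExParams
    R: list[_Population]
    E_plus: list[_Population | None]
    E_minus: list[_Population | None]
    G: _Population
    W_inter: list[WeightMatrix]
    W_input_gist: WeightMatrix
    W_gist_R: list[WeightMatrix]
    P_c: float
    trace_gain: float = DEFAULT_TRACE_GAIN
    seed: int | None = None

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def top(self) -> int:
        return len(self.areas) - 1

    def reset_state(self) -> None:
        """Return every population to rest (V=E_L, a=0, Y=X=0)."""
        for pop in self.populations():
            n = pop.state.n
            pop.state.V[:] = self.params.E_L
            pop.state.a[:] = 0.0
            pop.state.refractory_remaining[:] = 0.0
            pop.state.spiked[:] = 0
            pop.trace.Y[:] = 0.0
            pop.trace.X[:] = 0.0

    def populations(self):
        for l in range(self.n_areas):
            yield self.R[l]
            if self.E_plus[l] is not None:
                yield self.E_plus[l]
                yield self.E_minus[l]
        yield self.G

    def population_names(self) -> list[str]:
        names = []
        for l in range(self.n_areas):
            names.append(f"R{l}")
            if self.E_plus[l] is not None:
                names += [f"E+{l}", f"E-{l}"]
        names.append("G")
        return names

    def population(self, name: str) -> _Population:
        if name == "G":
            return self.G
        if name.startswith("E+"):
            pop = self.E_plus[int(name[2:])]
        elif name.startswith("E-"):
            pop = self.E_minus[int(name[2:])]
        elif name.startswith("R"):
            pop = self.R[int(name[1:])]
        else:
            raise KeyError(name)
        if pop is None:
            raise KeyError(f"{name}: area has no error populations")
        return pop


def unit_count(area_sizes, n_gist: int) -> int:
    """Total neurons: R everywhere, E+/E- everywhere but the top, plus gist."""
    sizes = list(area_sizes)
    return sum(sizes) + 2 * sum(sizes[:-1]) + n_gist


def synapse_counts(area_sizes, n_gist: int, P_c: float | None = None) -> dict:
    """Closed-form synapse accounting.

    ``counted_total`` = plastic inter-areal entries + fixed one-to-one
    R->E+/E- links + dense gist->R links.  The sparse input->gist synapses
    (random, expectation n_input*n_gist*P_c) and the one-to-one E->R feedback
    links are reported separately and excluded from the counted total.
    """
    sizes = list(area_sizes)
    plastic = sum(sizes[l + 1] * sizes[l] for l in range(len(sizes) - 1))
    one_to_one_r_to_e = 2 * sum(sizes[:-1])
    gist_to_r = n_gist * sum(sizes[1:])
    counts = {
        "plastic": plastic,
        "one_to_one_r_to_e": one_to_one_r_to_e,
        "gist_to_r": gist_to_r,
        "counted_total": plastic + one_to_one_r_to_e + gist_to_r,
        "one_to_one_e_to_r_uncounted": 2 * sum(sizes[:-1]),
    }
    if P_c is not None:
        counts["input_gist_expected_uncounted"] = sizes[0] * n_gist * P_c
    return counts


def build_ffg_weights(
    n_input: int,
    n_gist: int,
    n_targets,
    P_c: float,
    seed: int,
    orientation: str = "gist_over_partner",
) -> tuple[WeightMatrix, list[WeightMatrix]]:
    """Fixed random weights of the feedforward gist pathway.

    Entries are Gaussian with mean and standard deviation both equal to a
    ratio of the connected population sizes; the input->gist matrix is
    additionally masked by independent Bernoulli(P_c) draws, and negative
    draws are clipped to zero (the network uses strictly excitatory
    synapses).

    ``orientation`` selects the size ratio:

    * ``"gist_over_partner"`` (default): n_gist/n_input for input->gist and
      n_gist/n_target for gist->R, which keeps mean weights small on both
      stages and gist-driven currents within the encoding range.
    * ``"post_over_pre"``: n_post/n_pre for each matrix.
    * ``"pre_over_post"``: n_pre/n_post for each matrix.
    """
    if not (0 < P_c <= 1):
        raise ValueError("connection probability must lie in (0, 1]")
    if n_input <= 0 or n_gist <= 0 or any(n <= 0 for n in n_targets):
        raise ValueError("population sizes must be positive")

    def ratio(n_pre: int, n_post: int, partner: int) -> float:
        if orientation == "gist_over_partner":
            return n_gist / partner
        if orientation == "post_over_pre":
            return n_post / n_pre
        if orientation == "pre_over_post":
            return n_pre / n_post
        raise ValueError(f"unknown orientation {orientation!r}")

    rng = np.random.default_rng(seed)
    r = ratio(n_input, n_gist, n_input)
    w_ig = rng.normal(r, r, size=(n_gist, n_input))
    mask = rng.random((n_gist, n_input)) < P_c
    w_ig = np.clip(w_ig, 0.0, None) * mask
    W_input_gist = WeightMatrix(w_ig, plastic=False, label="input->gist")

    W_gist_R = []
    for l, n_t in enumerate(n_targets, start=1):
        r = ratio(n_gist, n_t, n_t)
        w = np.clip(rng.normal(r, r, size=(n_t, n_gist)), 0.0, None)
        W_gist_R.append(WeightMatrix(w, plastic=False, label=f"gist->R{l}"))
    return W_input_gist, W_gist_R


def build_network(
    area_sizes,
    n_gist: int = 16,
    P_c: float = 0.05,
    seed: int = 0,
    params: AdExParams | None = None,
    init_sd: float = 0.3,
    trace_gain: float = DEFAULT_TRACE_GAIN,
    tau_rise: float = 5.0,
    tau_decay: float = 50.0,
    ffg_orientation: str = "gist_over_partner",
) -> PCNetwork:
    """Allocate all populations and weights of the hierarchy.

    Inter-areal weights are drawn |N(0, init_sd)| (half-normal, strictly
    positive); FFG weights come from :func:`build_ffg_weights`.  Fully
    reproducible given ``seed``.
    """
    sizes = list(int(s) for s in area_sizes)
    if len(sizes) < 2:
        raise ValueError("a predictive-coding hierarchy needs at least 2 areas")
    if any(s <= 0 for s in sizes) or n_gist <= 0:
        raise ValueError("population sizes must be positive")
    params = params or AdExParams()
    rng = np.random.default_rng(seed)

    areas = [
        AreaSpec(n_units=s, has_errors=(l < len(sizes) - 1), index=l)
        for l, s in enumerate(sizes)
    ]

    def pop(n: int) -> _Population:
        return _Population(
            state=NeuronPopulationState.resting(n, params),
            trace=SynapticTraceState.zeros(n, tau_rise, tau_decay),
        )

    R = [pop(s) for s in sizes]
    E_plus = [pop(s) if a.has_errors else None for s, a in zip(sizes, areas)]
    E_minus = [pop(s) if a.has_errors else None for s, a in zip(sizes, areas)]
    G = pop(n_gist)

    W_inter = [
        WeightMatrix(
            np.abs(rng.normal(0.0, init_sd, size=(sizes[l + 1], sizes[l]))),
            plastic=True,
            label=f"W{l},{l + 1}",
        )
        for l in range(len(sizes) - 1)
    ]
    ffg_seed = int(rng.integers(0, 2**31 - 1))
    W_input_gist, W_gist_R = build_ffg_weights(
        sizes[0], n_gist, sizes[1:], P_c, ffg_seed, orientation=ffg_orientation
    )
    return PCNetwork(
        areas=areas,
        params=params,
        R=R,
        E_plus=E_plus,
        E_minus=E_minus,
        G=G,
        W_inter=W_inter,
        W_input_gist=W_input_gist,
        W_gist_R=W_gist_R,
        P_c=P_c,
        trace_gain=trace_gain,
        seed=seed,
    )


def encode_input(
    image: np.ndarray, low: float = 600.0, high: float = 3000.0
) -> np.ndarray:
    """Map a non-negative pixel matrix to input currents in [low, high] pA.

    The image is flattened, normalised to a unit vector, and the attainable
    value range [0, v_max] of the normalised intensities is affinely mapped
    onto [low, high]: zero-intensity pixels receive ``low``, the brightest
    pixel receives ``high``.  Scaling an image by a positive constant leaves
    the encoding unchanged.
    """
    v = np.asarray(image, dtype=float).ravel()
    if (v < 0).any():
        raise ValueError("pixel intensities must be non-negative")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot encode an all-zero image")
    v = v / norm
    return low + (high - low) * v / v.max()


def calibrate_trace_gain(
    params: AdExParams | None = None,
    currents=(700, 800, 1000, 1400, 1800, 2200, 2600, 3000),
    duration: float = 3000.0,
    window: float = 1000.0,
    dt: float = 1.0,
    tau_rise: float = 5.0,
    tau_decay: float = 50.0,
) -> float:
    """Least-squares gain making weight-1 transmission current-preserving.

    Simulates a single neuron at each constant drive, measures the
    steady-state window-mean trace X(I), and returns
    argmin_g sum_I (g X(I) - I)^2 = sum(I X) / sum(X^2).
    """
    from .neurons import NeuronPopulationState, detect_spikes_and_reset, step_membrane
    from .synapses import update_glutamate, update_trace

    params = params or AdExParams()
    n_steps = int(round(duration / dt))
    w_steps = int(round(window / dt))
    xs = []
    for I0 in currents:
        state = NeuronPopulationState.resting(1, params)
        trace = SynapticTraceState.zeros(1, tau_rise, tau_decay)
        I = np.array([float(I0)])
        acc = 0.0
        for k in range(n_steps):
            step_membrane(state, params, I, dt)
            detect_spikes_and_reset(state, params)
            update_glutamate(trace, state.spiked, dt)
            update_trace(trace, dt)
            if k >= n_steps - w_steps:
                acc += trace.X[0]
        xs.append(acc / w_steps)
    xs = np.array(xs)
    I = np.asarray(currents, dtype=float)
    return float(I @ xs / (xs @ xs))
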