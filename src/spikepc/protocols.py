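"""Frozen experiment protocols: full-scale defaults and the desk-scale study.

``full_scale_*`` reproduce the reference configuration of the model: a
four-area hierarchy (784/400/225/64 representation units plus error pairs,
16 gist units), dt = 1 ms, 350 ms per stimulus with a 100 ms plasticity
window, mini-batches of 32 and 50 epochs on 5,120 MNIST samples.  That run
needs the MNIST IDX files and hours of CPU; it is supported, not exercised
by the test suite.

``desk_*`` define the package's desk-scale study: a two-area network on
8 x 8 synthetic stroke images, three classes, eight samples per class.
Conditions were calibrated once for this scale and then frozen:

* areas [64, 100], 8 gist units, P_c = 0.05 — a latent area somewhat larger
  than the input averages per-unit noise out of the top-down prediction;
* T = 550 ms with a 300 ms window — the recurrent error loop settles into a
  limit cycle of roughly 200 ms period (set by the 50 ms trace decay), so
  the plasticity window must cover at least one full cycle for the LTP/LTD
  balance to reflect cycle means rather than a phase;
* gamma_w = 1.5e-3, alpha_w = 1e-3, batch 4, 30 epochs — learning rates are
  scale-dependent (the Hebbian terms are products of window-mean traces,
  whose magnitudes depend on layer sizes); these values bring the two-area
  network to its prediction-error floor within 30 epochs.
"""

from __future__ import annotations

from .network import PCNetwork, build_network
from .plasticity import LearningConfig, train
from .simulation import SimulationConfig
from .stimuli import StimulusBatch, make_synthetic_digits

__all__ = [
    "full_scale_area_sizes",
    "full_scale_sim_config",
    "full_scale_learning_config",
    "desk_stimuli",
    "desk_network",
    "desk_sim_config",
    "desk_learning_config",
    "train_desk_network",
    "DESK_AREA_SIZES",
    "DESK_N_GIST",
    "DESK_OCCLUSION_PATCH",
]

#: Reference hierarchy (units per area; error pairs everywhere but the top).
FULL_SCALE_AREA_SIZES = [784, 400, 225, 64]
FULL_SCALE_N_GIST = 16

DESK_AREA_SIZES = [64, 100]
DESK_N_GIST = 8
DESK_N_CLASSES = 3
DESK_N_PER_CLASS = 8
DESK_SIDE = 8
#: 3x3 patch on an 8x8 image: 9/64 = 14% of pixels, comparable to the 9x9
#: patch on 28x28 (10.3%) used at full scale.
DESK_OCCLUSION_PATCH = 3


def full_scale_area_sizes() -> list[int]:
    return list(FULL_SCALE_AREA_SIZES)


def full_scale_sim_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**{"dt": 1.0, "T": 350.0, "t_w": 100.0, **overrides})


def full_scale_learning_config(**overrides) -> LearningConfig:
    return LearningConfig(**{
        "gamma_w": 1e-7, "alpha_w": 1e-5, "batch_size": 32, "epochs": 50,
        **overrides,
    })


def desk_stimuli(seed: int, n_per_class: int = DESK_N_PER_CLASS) -> StimulusBatch:
    """Synthetic three-class 8x8 stroke images for the desk-scale study."""
    return make_synthetic_digits(
        DESK_N_CLASSES, n_per_class, side=DESK_SIDE, seed=seed
    )


def desk_network(seed: int) -> PCNetwork:
    return build_network(DESK_AREA_SIZES, n_gist=DESK_N_GIST, P_c=0.05, seed=seed)


def desk_sim_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**{"dt": 1.0, "T": 550.0, "t_w": 300.0, **overrides})


def desk_learning_config(**overrides) -> LearningConfig:
    return LearningConfig(**{
        "gamma_w": 1.5e-3, "alpha_w": 1e-3, "batch_size": 4, "epochs": 30,
        **overrides,
    })


def train_desk_network(
    seed: int, epochs: int | None = None
) -> tuple[PCNetwork, list[dict], StimulusBatch]:
    """Build, train and return the desk-scale network with its training set.

    Seeds for data, network and shuffling are derived from ``seed`` so one
    integer reproduces the whole run.
    """
    stimuli = desk_stimuli(seed + 1)
    net = desk_network(seed)
    lr_cfg = desk_learning_config()
    if epochs is not None:
        lr_cfg.epochs = epochs
    net, log = train(net, stimuli, desk_sim_config(), lr_cfg, seed=seed + 2)
    return net, log, stimuli
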