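"""Trace-based Hebbian plasticity with L1 decay and mini-batch training.

After each stimulus presentation the window means of the error and
representation traces stand in for NMDA-receptor-mediated calcium signals.
For each plastic inter-areal matrix W (area l -> l+1) the update is a
difference of two non-negative Hebbian outer products minus an L1 decay that
acts only on positive entries::

    dW+ = mean_X_R^{l+1}  (x)  mean_X_E+^l      (LTP, excitatory error input)
    dW- = mean_X_R^{l+1}  (x)  mean_X_E-^l      (LTD, inhibitory error input)
    W  <- W + gamma_w (dW+ - dW-) - alpha_w * 1[W > 0]

Rows index the postsynaptic representation units of area l+1, columns the
presynaptic error units of area l, matching W's bottom-up orientation.
Per-sample terms are averaged over a mini-batch and applied once per batch;
weights are clipped at zero by default, keeping the strictly-positive weight
regime of the initialisation.  Only inter-areal weights learn; one-to-one
and gist-pathway weights are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import PCNetwork
from .simulation import RecordingBuffer, SimulationConfig, present_stimulus
from .synapses import WeightMatrix

__all__ = [
    "LearningConfig",
    "WeightUpdate",
    "hebbian_terms",
    "combine_and_regularize",
    "train",
    "area_nrmse",
]


@dataclass
class LearningConfig:
    """Learning-rule hyperparameters."""

    gamma_w: float = 1e-7   #: Hebbian learning rate
    alpha_w: float = 1e-5   #: L1 decay applied to positive entries
    batch_size: int = 32
    epochs: int = 50
    per_area_lr_scale: list[float] | None = None  #: multiplier per W matrix
    nonneg_weights: bool = True

    def __post_init__(self) -> None:
        if self.gamma_w < 0 or self.alpha_w < 0:
            raise ValueError("learning rate and regularizer must be >= 0")
        if self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("batch size must be positive, epochs >= 0")

    def scale(self, area: int) -> float:
        if self.per_area_lr_scale is None:
            return 1.0
        return self.per_area_lr_scale[area]


@dataclass
class WeightUpdate:
    """Raw Hebbian terms for one plastic matrix (entrywise non-negative)."""

    delta_plus: np.ndarray
    delta_minus: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.delta_plus - self.delta_minus


def hebbian_terms(
    mean_X_E_plus: np.ndarray,
    mean_X_E_minus: np.ndarray,
    mean_X_R_above: np.ndarray,
) -> WeightUpdate:
    """Outer products of window-mean traces, oriented like W^{l,l+1}."""
    ep = np.asarray(mean_X_E_plus, dtype=float)
    em = np.asarray(mean_X_E_minus, dtype=float)
    ra = np.asarray(mean_X_R_above, dtype=float)
    if (ep < 0).any() or (em < 0).any() or (ra < 0).any():
        raise ValueError("window-mean traces must be non-negative")
    if ep.shape != em.shape:
        raise ValueError("positive and negative error means differ in length")
    return WeightUpdate(
        delta_plus=np.outer(ra, ep),
        delta_minus=np.outer(ra, em),
    )


def combine_and_regularize(
    update: WeightUpdate,
    W: WeightMatrix,
    cfg: LearningConfig,
    lr_scale: float = 1.0,
) -> WeightMatrix:
    """Apply the combined Hebbian update and L1 decay to W in place.

    The decay's step function g(x) = 1 for x > 0 and 0 otherwise means
    entries already at zero do not drift negative; with ``nonneg_weights``
    any negative result is clipped back to zero.
    """
    if update.delta_plus.shape != W.values.shape:
        raise ValueError("update shape does not match weight matrix")
    g = (W.values > 0).astype(float)
    W.values += (cfg.gamma_w * lr_scale * (update.delta_plus - update.delta_minus)
                 - cfg.alpha_w * g)
    if cfg.nonneg_weights:
        np.clip(W.values, 0.0, None, out=W.values)
    return W


def area_nrmse(net: PCNetwork, buf: RecordingBuffer) -> list[float]:
    """Per-area prediction NRMSE from one presentation's window means.

    For each inter-areal pair: RMSE between the area-l representation window
    mean and its top-down prediction W^T mean_X_R^{l+1}, normalised by the
    range of the target.  NaN where the target is constant (e.g. silent).
    """
    out = []
    for l, W in enumerate(net.W_inter):
        target = buf.window_means[f"R{l}"]
        pred = W.values.T @ buf.window_means[f"R{l + 1}"]
        rng_ = target.max() - target.min()
        if rng_ == 0:
            out.append(float("nan"))
        else:
            out.append(float(np.sqrt(np.mean((target - pred) ** 2)) / rng_))
    return out


def train(
    net: PCNetwork,
    stimuli,
    sim_cfg: SimulationConfig,
    lr_cfg: LearningConfig,
    seed: int = 0,
    log_every: int = 1,
) -> tuple[PCNetwork, list[dict]]:
    """Mini-batch Hebbian training on a stimulus batch.

    Per epoch the sample order is reshuffled (seeded); per mini-batch each
    sample is presented independently, the Hebbian terms are accumulated,
    averaged over the actual batch size (the final partial batch uses its
    own size), and applied once to every plastic matrix.  Returns the
    trained network and a log of per-epoch rows
    ``{epoch, area, nrmse, mean_abs_dw}``.
    """
    if stimuli.n == 0:
        raise ValueError("empty stimulus set")
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    n = stimuli.n
    for epoch in range(lr_cfg.epochs):
        order = rng.permutation(n)
        nrmse_acc = np.zeros(len(net.W_inter))
        nrmse_cnt = np.zeros(len(net.W_inter))
        dw_acc = np.zeros(len(net.W_inter))
        n_batches = 0
        for start in range(0, n, lr_cfg.batch_size):
            idx = order[start:start + lr_cfg.batch_size]
            sums = [
                WeightUpdate(np.zeros(W.values.shape), np.zeros(W.values.shape))
                for W in net.W_inter
            ]
            for i in idx:
                buf = present_stimulus(net, stimuli.currents[i], sim_cfg)
                for l in range(len(net.W_inter)):
                    upd = hebbian_terms(
                        buf.window_means[f"E+{l}"],
                        buf.window_means[f"E-{l}"],
                        buf.window_means[f"R{l + 1}"],
                    )
                    sums[l].delta_plus += upd.delta_plus
                    sums[l].delta_minus += upd.delta_minus
                for l, v in enumerate(area_nrmse(net, buf)):
                    if np.isfinite(v):
                        nrmse_acc[l] += v
                        nrmse_cnt[l] += 1
            for l, W in enumerate(net.W_inter):
                before = W.values.copy()
                mean_upd = WeightUpdate(
                    sums[l].delta_plus / idx.size, sums[l].delta_minus / idx.size
                )
                combine_and_regularize(mean_upd, W, lr_cfg, lr_cfg.scale(l))
                dw_acc[l] += np.abs(W.values - before).mean()
            n_batches += 1
        if log_every and epoch % log_every == 0 or epoch == lr_cfg.epochs - 1:
            for l in range(len(net.W_inter)):
                log.append({
                    "epoch": epoch,
                    "area": l,
                    "nrmse": (nrmse_acc[l] / nrmse_cnt[l]
                              if nrmse_cnt[l] else float("nan")),
                    "mean_abs_dw": dw_acc[l] / max(n_batches, 1),
                })
    return net, log
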