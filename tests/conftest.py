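"""Shared fixtures: small networks and one trained desk-scale model.

The trained model is expensive (~1-2 min) and session-scoped; the learning,
robustness and ablation tests all evaluate the same trained network.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikepc import (
    PerturbationSpec,
    apply_perturbation,
    make_synthetic_digits,
    present_stimulus,
    reconstruct,
)
from spikepc.protocols import (
    DESK_OCCLUSION_PATCH,
    desk_sim_config,
    train_desk_network,
)

SEED = 7


@pytest.fixture(scope="session")
def trained_desk():
    """Desk-scale network trained to its prediction-error floor."""
    net, log, train_batch = train_desk_network(SEED)
    return net, log, train_batch


@pytest.fixture(scope="session")
def desk_eval(trained_desk):
    """Window means and reconstructions of the trained network on held-out
    clean, noisy and occluded test sets, plus an FFG-only run."""
    net, _, train_batch = trained_desk
    sim = desk_sim_config()
    sim_ffg_only = desk_sim_config(pc_enabled=False)
    test = make_synthetic_digits(3, 8, side=8, seed=SEED + 101)
    noise = apply_perturbation(test, PerturbationSpec("noise", noise_sd=300.0, seed=SEED))
    occ = apply_perturbation(
        test, PerturbationSpec("occlude", patch_size=DESK_OCCLUSION_PATCH, seed=SEED)
    )

    out = {"test": test, "noise": noise, "occ": occ, "train": train_batch}
    for key, batch, cfg in [
        ("clean", test, sim),
        ("noise", noise, sim),
        ("occ", occ, sim),
        ("ffg_only", test, sim_ffg_only),
    ]:
        inputs, latents, recons = [], [], []
        for i in range(batch.n):
            buf = present_stimulus(net, batch.currents[i], cfg)
            inputs.append(buf.window_means["R0"])
            latents.append(buf.window_means["R1"])
            recons.append(reconstruct(net, buf, from_area=1))
        out[f"{key}_inputs"] = np.array(inputs)
        out[f"{key}_latents"] = np.array(latents)
        out[f"{key}_recons"] = np.array(recons)
    train_lat, train_in, train_rec = [], [], []
    for i in range(train_batch.n):
        buf = present_stimulus(net, train_batch.currents[i], sim)
        train_lat.append(buf.window_means["R1"])
        train_in.append(buf.window_means["R0"])
        train_rec.append(reconstruct(net, buf, from_area=1))
    out["train_latents"] = np.array(train_lat)
    out["train_inputs"] = np.array(train_in)
    out["train_recons"] = np.array(train_rec)
    return out
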