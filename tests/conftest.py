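"""Shared fixtures.

Expensive end-to-end phantoms are session-scoped and reused across test
modules; everything is generated programmatically with fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

import mattmap.synthetic as syn
from mattmap.fitting import FitOptions, estimate_noise_floor, fit_map
from mattmap.isolation import isolate_vessels


@pytest.fixture(scope="session")
def small_config():
    """Small branching-tree phantom configuration for unit tests."""
    return syn.SimulationConfig(shape=(32, 32, 32), seed=5, n_trunks=2,
                                max_walkers=6)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    truth, label, control, brain = syn.make_phantom(small_config)
    return {"config": small_config, "truth": truth, "label": label,
            "control": control, "brain": brain}


def run_end_to_end(gradient: float, seed: int = 1):
    """Full cascade + fit on a 64^3 uniform-SNR phantom; returns a bundle
    with the ground truth for recovery checks."""
    cfg = syn.SimulationConfig(seed=seed, gradient=gradient, m_taper=0.0)
    truth, label, control, brain = syn.make_phantom(cfg)
    mask, series = isolate_vessels(
        label, control, brain_mask=brain, times=cfg.times,
        voxel_dims=cfg.voxel_dims, min_size=1000)
    noise_floor = estimate_noise_floor(series, mask.mask, brain_mask=brain)
    matt_map = fit_map(series, mask.mask,
                       FitOptions(variant="continuous",
                                  noise_floor=noise_floor))
    return {"config": cfg, "truth": truth, "brain": brain, "mask": mask,
            "series": series, "matt_map": matt_map}


@pytest.fixture(scope="session")
def e2e_77():
    """End-to-end run at 7.7 ms/mm path gradient, SNR 10."""
    return run_end_to_end(7.7)


@pytest.fixture(scope="session")
def e2e_66():
    """End-to-end run at 6.6 ms/mm path gradient, SNR 10."""
    return run_end_to_end(6.6)
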