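"""Shared fixtures: small synthetic cells reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mitomorph import NeuronSpec, RenderConfig, generate_neuron, render_stack


def small_spec(**overrides) -> NeuronSpec:
    """A compact arbor (order <= 3) that renders in well under a second."""
    defaults = dict(
        max_branch_order=3,
        primary_dendrite_length_um=14.0,
        mean_branch_length_um=11.0,
        branch_prob_per_order=(1.0, 0.8, 0.0),
        mito_linear_density_per_um=0.25,
    )
    defaults.update(overrides)
    return NeuronSpec(**defaults)


NOISELESS = dict(
    photon_scale=float("inf"),
    read_noise_sd=0.0,
    background_level=0.0,
    background_gradient=0.0,
)


@pytest.fixture(scope="session")
def noiseless_cell():
    """One small neuron rendered without any noise or background."""
    geom = generate_neuron(small_spec(), seed=13)
    stack, truth = render_stack(geom, RenderConfig(seed=13, **NOISELESS))
    return geom, stack, truth


@pytest.fixture(scope="session")
def noisy_cell():
    """The same neuron under the default noise model."""
    geom = generate_neuron(small_spec(), seed=13)
    stack, truth = render_stack(geom, RenderConfig(seed=13))
    return geom, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
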