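"""Shared fixtures: default config and cached synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from soclas import SessionConfig, generate_session
from soclas.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def cfg() -> SessionConfig:
    return SessionConfig()


def scaled_generator(background_factor: float = 1.0, **overrides) -> GeneratorConfig:
    """Generator config with every background component scaled by one factor.

    Used to build SNR ladders: the injected event amplitudes stay at their
    defaults while the noise floor moves.
    """
    base = GeneratorConfig()
    scale = lambda d: {k: v * background_factor for k, v in d.items()}  # noqa: E731
    params = dict(
        background_scale_uv=scale(base.background_scale_uv),
        delta_extra_uv=scale(base.delta_extra_uv),
        theta_extra_uv=scale(base.theta_extra_uv),
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="session")
def nrem_session():
    """A 15-min mixed N2/N3 session with default generator conditions."""
    gen = GeneratorConfig(duration_s=900, seed=7, stages=("N2",) * 15 + ("N3",) * 15)
    return generate_session(gen)


@pytest.fixture(scope="session")
def quiet_n3_session():
    """A low-noise 10-min all-N3 session (high-SNR events)."""
    gen = scaled_generator(
        0.15, duration_s=600, seed=11, stages=("N3",) * 20
    )
    return generate_session(gen)
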