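"""Shared synthetic fixtures.

All fixtures are generated programmatically; the shape-model parameter
sets are synthetic stand-ins constructed to have the qualitative
features of the three morphotypes (graded helicity of the effective
shape), not measured values.
"""

import numpy as np
import pytest

from chiralswim import ShapeModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def _params(A_r, p_r, omega_r, f_b=20.0, n=8, length=16.0):
    z = np.linspace(0.0, length, n)
    return ShapeModelParams(
        z=z,
        A_r=np.asarray(A_r, dtype=float),
        p_r=np.asarray(p_r, dtype=float),
        A_b=0.8 + 0.2 * np.cos(z / 7.0),
        p_b=1.5 * z / z[-1] * 2 * np.pi,
        p_o=0.3 * np.ones(n),
        omega_r=omega_r,
        f_b=f_b,
        width=np.full(n, 1.0),
    )


@pytest.fixture
def trypomastigote_like_params():
    """Strongly helical synthetic cell: large, steady phase advance of the
    rotation displacement along the whole cell."""
    z = np.linspace(0.0, 16.0, 8)
    return _params(
        A_r=np.full(8, 0.8),
        p_r=np.linspace(0.0, 3.0 * np.pi, 8),
        omega_r=2 * np.pi * 2.1,
    )


@pytest.fixture
def epimastigote_like_params():
    """Weakly chiral synthetic cell: twist confined to the anterior end."""
    z = np.linspace(0.0, 16.0, 8)
    p_r = np.concatenate([np.zeros(5), np.linspace(0.0, 0.9 * np.pi, 3)])
    A_r = np.concatenate([np.full(5, 0.3), np.full(3, 0.5)])
    return _params(A_r=A_r, p_r=p_r, omega_r=2 * np.pi * 0.5)


@pytest.fixture
def promastigote_like_params():
    """Near-axially-symmetric synthetic cell: no phase advance, tiny
    rotation amplitude, no measurable longitudinal rotation."""
    return _params(A_r=np.full(8, 0.05), p_r=np.zeros(8), omega_r=0.0)
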