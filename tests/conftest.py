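"""Shared fixtures: small analytic phantoms and a synthetic session."""

from __future__ import annotations

import numpy as np
import pytest

from presurgmap.phantom import generate_session, protocol_fixture
from presurgmap.volumes import Volume3D


def make_affine(shape, voxel_mm):
    """Axis-aligned RAS affine with the FOV centered on the world origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel_mm
    return aff


def asymmetric_blob(shape=(24, 24, 12), voxel_mm=3.0):
    """A smooth, rotationally asymmetric 3D phantom (registration target)."""
    aff = make_affine(shape, voxel_mm)
    idx = np.indices(shape).astype(float)
    c = (np.array(shape) - 1) / 2.0
    b1 = np.exp(-(((idx[0] - c[0] - 4) / 4) ** 2
                  + ((idx[1] - c[1]) / 6) ** 2
                  + ((idx[2] - c[2]) / 3) ** 2))
    b2 = 0.6 * np.exp(-(((idx[0] - c[0] + 5) / 3) ** 2
                        + ((idx[1] - c[1] - 5) / 4) ** 2
                        + ((idx[2] - c[2] + 2) / 2) ** 2))
    return Volume3D((b1 + b2) * 100.0, aff)


@pytest.fixture(scope="session")
def blob():
    return asymmetric_blob()


@pytest.fixture(scope="session")
def session_default():
    """The full-size breath-hold protocol session (32x32x16, seed 42)."""
    return generate_session(protocol_fixture("patient1_bh"))


@pytest.fixture(scope="session")
def small_session():
    """A reduced-grid session for pipeline-level tests."""
    from dataclasses import replace
    cfg = replace(protocol_fixture("patient1_rest"),
                  shape=(20, 20, 10), voxel_mm=(4.0, 4.0, 4.0), seed=7)
    return generate_session(cfg)
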