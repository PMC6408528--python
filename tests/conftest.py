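"""Shared fixtures: the heavy solver runs are session-scoped so each
simulation is executed once and inspected by several tests."""

from __future__ import annotations

import numpy as np
import pytest

import ionomark as im
from ionomark.pipeline import resonance_amplitude_sweep


@pytest.fixture(scope="session")
def beam60() -> im.BeamSpec:
    """60 MeV pencil beam, σ = 5 mm, σ_p = 100 ns (the reference setup)."""
    return im.BeamSpec()


@pytest.fixture(scope="session")
def marker22() -> im.MarkerSpec:
    """2.0 mm gold marker at 22 mm depth."""
    return im.MarkerSpec(diameter_mm=2.0, depth_mm=22.0)


@pytest.fixture(scope="session")
def ring_uniform(marker22):
    """Uniform-source ringdown of 1 MeV deposited, detector at 20.6 mm."""
    return im.ringdown(
        marker22, 1.0, 100e-9, r_detector_m=20.6e-3, duration_s=30e-6,
        record_dt_s=5e-9,
    )


@pytest.fixture(scope="session")
def beam_trace3d(beam60):
    """Coarse-grid 3-D no-marker waveform at the (20.6 mm, z=22) detector."""
    return im.beam_waveform_3d(beam60, [22.0])


@pytest.fixture(scope="session")
def detector_line_z() -> np.ndarray:
    return np.arange(10.0, 41.0, 2.0)


@pytest.fixture(scope="session")
def hybrid22(beam60, marker22, detector_line_z):
    """Hybrid with/without-marker run over the detector line."""
    return im.simulate_hybrid(beam60, marker22, detector_line_z)


@pytest.fixture(scope="session")
def amplitude_sweep(beam60):
    """Resonance amplitude vs residual range, R_res = 1..8 mm."""
    return resonance_amplitude_sweep(beam60)
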