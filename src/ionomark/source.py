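"""Thermoacoustic source construction: Grüneisen conversion and pulse shape.

Under stress and thermal confinement the deposited energy density converts
directly to an initial pressure rise ``p₀(r) = Γ(r)·E(r)`` (E as volumetric
energy density, J/m³, so p₀ is in Pa).  The beam's temporal structure is a
normalised Gaussian rate ``dG/dt`` of width σ_p; the space and time parts
of the source are separable, and the driven wave equation's right-hand side
involves ``∂²G/∂t²``.

Unit chain, tested explicitly: MeV per voxel → J/m³ (×1.602e-13 / voxel
volume) → Pa (×Γ).  All pressures stay per proton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .materials import GOLD, WATER, MaterialProperties
from .proton_dose import DoseGrid

__all__ = [
    "GaussianPulse",
    "PressureSourceField",
    "build_source",
    "pulse_derivatives",
    "MEV_TO_J",
]

MEV_TO_J = 1.602176634e-13


@dataclass(frozen=True)
class GaussianPulse:
    """Normalised Gaussian beam-pulse time profile.

    ``rate(t)`` is dG/dt, a unit-area Gaussian centred at t = 0 (the
    incident pulse peak defines the time origin); ``cumulative(t)`` is G
    itself, used for exact per-step source injection.  ``sigma_p = 0``
    degenerates to an instantaneous (initial-value) release.
    """

    sigma_p: float  # s

    def __post_init__(self) -> None:
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be non-negative")

    def rate(self, t):
        if self.sigma_p == 0:
            raise ValueError("rate undefined for an instantaneous pulse")
        s = self.sigma_p
        return np.exp(-(np.asarray(t) ** 2) / (2 * s**2)) / np.sqrt(2 * np.pi * s**2)

    def rate_derivative(self, t):
        t = np.asarray(t)
        return -t / self.sigma_p**2 * self.rate(t)

    def cumulative(self, t):
        if self.sigma_p == 0:
            return (np.asarray(t) >= 0).astype(float)
        return ndtr(np.asarray(t) / self.sigma_p)

    def spectral_envelope(self, f):
        """|FT of dG/dt| at frequency f: exp(−(2πfσ_p)²/2)."""
        return np.exp(-((2 * np.pi * np.asarray(f) * self.sigma_p) ** 2) / 2)


def pulse_derivatives(sigma_p: float, t):
    """(dG/dt, d²G/dt²) of the unit-area Gaussian pulse at times t (s)."""
    pulse = GaussianPulse(sigma_p)
    return pulse.rate(t), pulse.rate_derivative(t)


@dataclass
class PressureSourceField:
    """Separable thermoacoustic source: p₀(r) spatial map plus time pulse.

    ``p0_spatial`` is Γ(r)·E(r) in Pa per proton on the dose grid's voxels;
    ``pulse`` carries σ_p and its analytic derivatives.
    """

    p0_spatial: np.ndarray  # Pa per proton
    pulse: GaussianPulse
    spacing_mm: float
    origin_mm: tuple[float, float, float]
    medium_map: np.ndarray


def build_source(
    dose: DoseGrid,
    water: MaterialProperties = WATER,
    gold: MaterialProperties = GOLD,
    sigma_pulse_s: float = 100e-9,
    uniformise_marker_energy: bool = True,
) -> PressureSourceField:
    """Convert a dose grid into the initial-pressure source p₀ = Γ·E.

    Gold voxels use gold's Γ, water voxels water's Γ.  With
    ``uniformise_marker_energy`` (default), the energy deposited in gold is
    spread uniformly over the marker voxels before conversion — gold
    thermalises much faster than the acoustic timescale, making the marker
    a spherically symmetric source.
    """
    if dose.medium_map is None or dose.medium_map.shape != dose.energy.shape:
        raise ValueError("dose grid is missing a medium map")
    voxel_m3 = (dose.spacing_mm * 1e-3) ** 3
    energy = dose.energy.astype(float)

    gold_mask = dose.medium_map == DoseGrid.MEDIUM_GOLD
    if uniformise_marker_energy and np.any(gold_mask):
        energy = energy.copy()
        energy[gold_mask] = energy[gold_mask].sum() / gold_mask.sum()

    gamma_map = np.where(gold_mask, gold.gamma, water.gamma)
    p0 = gamma_map * energy * MEV_TO_J / voxel_m3  # Pa per proton
    return PressureSourceField(
        p0_spatial=p0,
        pulse=GaussianPulse(sigma_pulse_s),
        spacing_mm=dose.spacing_mm,
        origin_mm=dose.origin_mm,
        medium_map=dose.medium_map,
    )
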