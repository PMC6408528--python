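"""Spherically symmetric acoustic solver and closed-form marker resonance.

The gold marker behaves as a spherical acoustic resonator: the impedance
step at the gold/water interface reflects most of the internal pressure
back, and only the eigenmodes of the sphere — zero-order spherical Bessel
profiles ``sin(r')/r'`` vanishing at the surface — leak out efficiently.
The eigenfrequencies are ``f_res = n·v/φ_m`` with v the sound speed *in
gold*; for a 2.0 mm marker that is 1.62 MHz (n = 1) and 3.24 MHz (n = 2).

The solver integrates the first-order pressure / radial-velocity system on
a staggered radial grid with piecewise-constant gold-then-water profiles,
an impedance-matched outer boundary plus damping sponge, and a uniform
thermoacoustic source inside the marker.  It is fast enough to serve both
as the oracle for the 3-D solver and as the marker engine of hybrid-mode
pipeline runs.
"""

from __future__ import annotations

import numpy as np

from .materials import GOLD, WATER, MaterialProperties
from .proton_dose import MarkerSpec
from .source import MEV_TO_J, GaussianPulse
from .trace import PressureTrace

__all__ = [
    "resonance_frequency",
    "amplitude_factor",
    "radial_eigenmode",
    "ringdown",
]

_CFL = 0.3


def resonance_frequency(v_marker: float, diameter_m: float, n: int = 1) -> float:
    """Eigenfrequency f = n·v/φ_m (Hz) of the pressure-release sphere.

    ``v_marker`` is the sound speed inside the marker (m/s) and
    ``diameter_m`` the marker diameter in metres.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"mode index n must be a positive integer, got {n}")
    if v_marker <= 0 or diameter_m <= 0:
        raise ValueError("v_marker and diameter must be positive")
    return v_marker * n / diameter_m


def amplitude_factor(
    sigma_p: float, f_res: float, reference_sigma: float | None = None
):
    """Resonance-amplitude envelope exp(−(2π f σ_p)²/2) vs pulse width.

    The Gaussian pulse's Fourier magnitude at the resonance frequency; a
    longer pulse excites the MHz mode exponentially less.  With
    ``reference_sigma`` the value is normalised to that pulse width (plots
    conventionally normalise at σ_p = 100 ns).
    """
    s = np.asarray(sigma_p, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigma_p must be non-negative")
    a = np.exp(-((2 * np.pi * f_res * s) ** 2) / 2)
    if reference_sigma is not None:
        a = a / np.exp(-((2 * np.pi * f_res * reference_sigma) ** 2) / 2)
    return a if a.shape else float(a)


def radial_eigenmode(r_prime):
    """Zero-order spherical Bessel pressure profile sin(r')/r'.

    ``r' = 2πf r / v`` is the scaled radial coordinate; the profile is 1 at
    the centre and has its first zero at r' = π, which with r = φ_m/2 gives
    the fundamental f = v/φ_m.
    """
    rp = np.asarray(r_prime, dtype=float)
    if np.any(rp < 0):
        raise ValueError("r_prime must be non-negative")
    out = np.sinc(rp / np.pi)  # numpy sinc is sin(πx)/(πx)
    return out if out.shape else float(out)


def ringdown(
    marker: MarkerSpec,
    deposited_energy_mev: float,
    sigma_p_s: float,
    r_detector_m: float | np.ndarray = 20.6e-3,
    duration_s: float = 30e-6,
    dr_m: float | None = None,
    domain_m: float = 25e-3,
    water: MaterialProperties = WATER,
    gold: MaterialProperties = GOLD,
    record_dt_s: float | None = None,
    source_profile: tuple[np.ndarray, np.ndarray] | None = None,
) -> PressureTrace:
    """Marker ringdown trace(s) at one or more detector radii.

    By default the per-proton energy deposited in the marker is spread
    uniformly over the sphere, converted to an initial pressure
    ``p₀ = Γ_gold × energy density`` and injected with the Gaussian
    pulse's cumulative profile.  Passing ``source_profile`` — radial shell
    ``(edges_mm, energy_mev)`` as produced by
    :func:`ionomark.proton_dose.marker_deposition_profile` — replaces the
    uniform source with the actual spherically averaged deposition, which
    matters for amplitudes: deposition near the surface couples weakly to
    the eigenmode.  The returned trace decays by leaking energy into the
    water; its spectral peak sits at the n = 1 eigenfrequency.

    ``r_detector_m`` may be a scalar or an array of radii; detector
    positions are reported as (r, 0, 0) mm.  ``record_dt_s`` downsamples
    the recording (default: every solver step).
    """
    a = marker.radius_mm * 1e-3
    if dr_m is None:
        dr_m = marker.diameter_mm * 1e-3 / 200.0
    if dr_m > marker.diameter_mm * 1e-3 / 200.0 * (1 + 1e-9):
        raise ValueError("dr must resolve the marker: dr ≤ φ_m/200")
    r_det = np.atleast_1d(np.asarray(r_detector_m, dtype=float))
    if np.any(r_det <= 0):
        raise ValueError("detector radius must be positive")
    if np.any(r_det >= domain_m):
        raise ValueError("detector outside the solver domain")

    n = int(round(domain_m / dr_m))
    r_face = dr_m * np.arange(n + 1)
    r_cell = r_face[:-1] + dr_m / 2.0

    in_gold = r_cell < a
    rho_c = np.where(in_gold, gold.rho, water.rho)
    c_c = np.where(in_gold, gold.v, water.v)
    # Interior faces take the harmonic mean of the neighbouring densities.
    rho_f = 2.0 / (1.0 / rho_c[:-1] + 1.0 / rho_c[1:])

    dt = _CFL * dr_m / max(gold.v, water.v)
    if dt * max(gold.v, water.v) / dr_m >= 1.0:
        raise ValueError("CFL violation")

    if source_profile is None:
        # Uniform initial pressure per unit injected G.
        volume = 4.0 / 3.0 * np.pi * a**3
        p0 = np.where(
            in_gold, gold.gamma * deposited_energy_mev * MEV_TO_J / volume, 0.0
        )  # Pa per proton
    else:
        edges_mm, shell_e = source_profile
        edges = np.asarray(edges_mm, dtype=float) * 1e-3
        vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        dens = np.asarray(shell_e, dtype=float) * MEV_TO_J / vol  # J/m³
        shell_idx = np.clip(np.searchsorted(edges, r_cell, side="right") - 1,
                            0, len(dens) - 1)
        p0 = np.where(in_gold, gold.gamma * dens[shell_idx], 0.0)
    pulse = GaussianPulse(sigma_p_s)
    impulsive = sigma_p_s == 0.0

    t_start = -6.0 * sigma_p_s
    n_steps = int(np.ceil((duration_s - t_start) / dt))
    every = 1 if record_dt_s is None else max(int(round(record_dt_s / dt)), 1)

    # Damping sponge over the outer 1.5 mm, quartic grading.
    sponge_width = 1.5e-3
    sp = np.ones(n)
    m = r_cell > domain_m - sponge_width
    depth = (r_cell[m] - (domain_m - sponge_width)) / sponge_width
    sp[m] = np.exp(-3.0 * depth**4 * dt / (dr_m / water.v))
    sp_f = np.ones(n - 1)
    mf = r_face[1:-1] > domain_m - sponge_width
    depth_f = (r_face[1:-1][mf] - (domain_m - sponge_width)) / sponge_width
    sp_f[mf] = np.exp(-3.0 * depth_f**4 * dt / (dr_m / water.v))

    # Linear interpolation weights for the detector radii.
    idx = np.searchsorted(r_cell, r_det) - 1
    idx = np.clip(idx, 0, n - 2)
    frac = (r_det - r_cell[idx]) / dr_m

    p = np.zeros(n)
    u = np.zeros(n - 1)  # radial velocity at interior faces 1..n-1
    r2_f = r_face**2
    r2_c = r_cell**2
    bulk = rho_c * c_c**2

    times = []
    records = []
    if impulsive:
        p[:] = p0  # initial-value release
        g_prev = 1.0
    else:
        g_prev = pulse.cumulative(t_start)
    z_outer = water.rho * water.v

    for step in range(n_steps):
        t = t_start + step * dt
        # velocity update (u lives at t + dt/2); an initial-pressure
        # release starts with a half step to keep the staggering centred
        dt_u = dt / 2.0 if (impulsive and step == 0) else dt
        u = sp_f * (u - dt_u / rho_f * (p[1:] - p[:-1]) / dr_m)
        # outer boundary: characteristic impedance outflow
        u_outer = p[-1] / z_outer
        # pressure update
        flux = np.empty(n + 1)
        flux[0] = 0.0  # symmetry at r = 0
        flux[1:-1] = r2_f[1:-1] * u
        flux[-1] = r2_f[-1] * u_outer
        p = sp * (p - dt * bulk * (flux[1:] - flux[:-1]) / (r2_c * dr_m))
        if not impulsive:
            # source injection: exact cumulative increment of G per step
            g_next = pulse.cumulative(t + dt)
            p[in_gold] += p0[in_gold] * (g_next - g_prev)
            g_prev = g_next
        if step % every == 0:
            times.append(t + dt)
            records.append(p[idx] * (1 - frac) + p[idx + 1] * frac)

    pressure_mpa = np.asarray(records).T * 1e3  # Pa -> mPa
    positions = np.column_stack(
        [r_det * 1e3, np.zeros_like(r_det), np.zeros_like(r_det)]
    )
    return PressureTrace(np.asarray(times), pressure_mpa, positions)
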