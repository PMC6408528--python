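# Methods

This note documents the models behind `ionomark`, the defaults and why
they were chosen, the numerical machinery, and the known limits of what
the package's passing tests demonstrate.

## Physical setting

A 60 MeV proton pencil beam (lateral Gaussian σ = 5 mm at the surface,
temporal Gaussian width σ_p = 30–500 ns) enters a water phantom along +z.
A spherical gold marker of diameter φ_m = 2.0 mm sits on the beam axis at
depth Z_m. Point detectors sit on a line parallel to the axis at 20.6 mm
lateral distance. The beam pulse satisfies stress confinement
(t_s = d_c/v ≈ 3.3 µs for a 5 mm heated region) and thermal confinement,
so the deposited energy density converts directly to an initial pressure
p₀ = Γ·E. The residual range R_res = R₀ − Z_m controls how much energy the
marker receives; the amplitude of its acoustic resonance reads it back.

All lengths are handled in mm at module boundaries and SI internally;
pressures are per proton (mPa/proton in traces), deposited energies in
MeV/proton.

## Dose model (stand-in for Monte Carlo transport)

* **Stopping power**: plain Bethe formula with Z/A = 0.5551, I = 75 eV
  (water) and Z/A = 0.4011, I = 790 eV (gold, ICRU values), valid
  0.5–250 MeV. It reproduces reference water tables to 0.6 % at 10 MeV
  and 0.03 % at 100 MeV; shell/density corrections are omitted.
* **CSDA ranges**: cumulative integral of 1/S(E) from a 0.5 MeV floor on
  a 4000-node log grid, with interpolated inverse (residual energy).
  R(60 MeV, water) = 30.87 mm.
* **Range straggling**: Gaussian kernel with σ_R = 0.012·R^0.935 (R in
  cm) ≈ 0.35 mm at 60 MeV, applied as a depth convolution and as a
  quadrature over arrival energies at the marker.
* **Lateral profile**: Gaussian, σ constant with depth (σ is specified at
  the surface; growth with depth is a second-order effect at these
  depths and is not modelled).
* **Marker ray tracing**: per lateral column, water deposition up to the
  (staircase-voxelised) chord, stepped gold energy loss inside it —
  protons whose gold range is shorter than the chord stop and deposit all
  residual energy — and downstream the water depth-dose shifted by the
  chord's excess water-equivalent thickness. This produces the in-marker
  hot spot (voxel-energy ratio ≈ 9.5–11× water) and the downstream cold
  shadow.
* **Not modelled**: nuclear interactions, secondary-particle transport,
  beam energy spread. These move absolute doses at the few-percent level
  and are irrelevant to the resonance mechanism, but they do matter for
  one observable — see "amplitude-vs-depth slope" below.

## Thermoacoustic source

p₀(r) = Γ(r)·E(r), with Γ from the material table (water 0.11, gold
3.47). The temporal factor is a normalised Gaussian rate dG/dt; sources
are injected per solver step with the exact cumulative increment
ΔG = G(t+Δt) − G(t), which stays correct for any σ_p relative to the time
step and degenerates to an initial-value release at σ_p = 0.

Two marker source geometries are supported:

* **uniform** — the marker's total energy spread evenly over the sphere
  (the analytic idealisation of instant thermalisation; note that gold's
  actual thermal diffusion time over 1 mm is ~8 ms, far slower than the
  acoustic µs scale);
* **local** (pipeline default) — the spherically averaged deposition
  profile from the ray-traced chords, with the deposit of each path step
  smeared radially by the accumulated Highland multiple-Coulomb-scattering
  displacement in gold (X₀ = 3.35 mm). Only the spherical average couples
  to the radially symmetric eigenmodes, so this profile is exactly the
  source the radial solver needs.

## Wave solvers

**3-D k-space pseudospectral** (`wave3d`): first-order coupled
pressure/velocity updates; FFT gradients on half-cell staggered grids;
k-space dispersion correction κ = sinc(c_ref·k·Δt/2) with c_ref = water.
With the correction the scheme is *exact* for homogeneous media at any
stable Δt — the free-field test against the closed-form spherical-wave
solution agrees to machine precision — which is what allows a 1 mm grid
to carry the < 200 kHz beam waveform faithfully. Heterogeneous density
enters via staggered-averaged ρ in the momentum equation. Boundaries: a
10-voxel split-field PML with quartic grading (absorption verified below
−40 dB); with the PML off the domain is periodic and the discrete energy
functional is conserved to < 1 %. Initial-pressure releases start the
staggered velocity with a half step to keep the scheme time-centred.
Default CFL 0.3; an explicit Δt with CFL ≥ 1 is rejected.

**Radial solver** (`wave_radial`): first-order staggered
pressure/velocity update in spherical symmetry with 1/r² geometric flux
terms, piecewise gold/water properties (interface exactly at φ_m/2,
harmonic-mean face densities), characteristic impedance outflow plus a
1.5 mm quartic damping sponge at the outer boundary (domain 25 mm).
Default Δr = φ_m/200 (10 µm for the 2 mm marker; coarser grids are
rejected), CFL 0.3 against the gold sound speed. Halving Δr moves the
resonance estimate by 0.5 %. The simulated spectral peak sits at
1.62 MHz ± 0.2 % for the 2.0 mm marker and tracks v/φ_m within 2 % over
1–3 mm diameters; peak amplitudes across σ_p = 30–500 ns follow the
closed-form envelope exp(−(2πfσ_p)²/2) to better than 5 % wherever the
envelope is numerically resolvable.

**Hybrid mode** (`pipeline`): the observed waveform decomposes into the
beam-column wave (independent of the marker to ~2 %) and the marker wave.
The beam component is run on the coarse 3-D grid without the marker; the
marker component comes from one radial run recorded at each detector's
distance from the marker centre; the two are superposed on the radial
solver's fine time base (the beam component is spline-interpolated, safe
because it is band-limited far below the coarse Nyquist). The
with/without difference therefore equals the marker component exactly.

## Spectral conventions

Magnitude FFT after a Tukey(0.1) window with 4× zero padding; amplitudes
are |FFT|·Δt (Parseval-consistent with the windowed trace to < 1 %).
Ringdown amplitudes are extracted from the post-arrival segment
(t ≥ 12 µs at the 20.6 mm line). Calibration sweeps report amplitudes in
the mean-magnitude convention (|FFT|/N, units mPa/proton) so that C₁ is
dimensionally comparable with published mm·proton/mPa values. The
"no signal" flag requires the line to exceed 5× the median magnitude in
the 2.5–4 MHz sideband.

## Desk-scale problem sizes

The package's own reproduction runs use: 1 mm voxels on a 64×64×80 grid
(PML 10) with Δt = 200 ns for the 3-D beam stage; Δr = 10 µm, Δt ≈ 0.9 ns,
30 µs records for the radial stage; detector line z = 10–40 mm at 2 mm
pitch. The full acceptance sweep completes in about a minute on one CPU.
These sizes were chosen so that every reported quantity is grid-converged
at the percent level (verified for the resonance frequency and the
free-field oracle); the original study's 0.2 mm full-3-D configuration is
deliberately not replicated bit-for-bit — the hybrid decomposition stands
in for it.

## Design choices where the design was open

* **Case-2 boundary**: the energy model says protons stop inside the
  marker up to R_res ≈ 17 mm (a 2 mm gold chord is ≈ 19 mm of water), so
  the 9 mm case-2 edge is the *linearity* window of the amplitude curve,
  not a stopping/pass-through transition; 9 mm is kept as the
  classification default for 60 MeV.
* **Arrival-time convention**: the marker component's onset corresponds
  to the marker *surface*-to-detector distance over the water sound speed
  (19.6 mm → 13.07 µs at the co-depth detector), which the simulated
  onset reproduces within 0.3 µs; a centre-to-centre convention would
  predict 13.7 µs and does not match.
* **Noise bandwidth**: the particle-count budget defaults to
  (35/0.03)² Hz ≈ 1.36 MHz so that a 0.03 mPa/√Hz density integrates to
  35 mPa; it is an explicit parameter because the detection bandwidth is
  a transducer property.
* **Spot-position sensitivity**: defined as the worst-case relative
  change of marker-deposited energy over nominal beam placements within
  one lateral σ; for a 0.2 mm error at σ = 5 mm this gives ≈ 4 %.
* **Confinement "≪"**: operationalised as a factor-of-ten margin.

## Amplitude-vs-depth slope: a known model sensitivity

The relative slope of the resonance amplitude across case 2 depends
strongly on *where inside the sphere* the energy lands, because the
n = 1 eigenmode sin(r′)/r′ vanishes at the surface: deposition
concentrated in a near-surface cap rings the marker weakly, deposition
reaching the core rings it strongly, and the penetration depth grows
with R_res. Under the uniform source the slope equals the deposited-
energy slope, ≈ 10 %/mm; under the local-deposition source (straight
CSDA chords + Highland smear) it is ≈ 21 %/mm. Reality sits between
these: scattering, nuclear processes and beam energy spread diffuse the
deposition in ways a CSDA model cannot fully capture, and the observable
slope moves accordingly. The pipeline defaults to the local-deposition
source as the faithful counterpart of a Monte-Carlo-driven wave
simulation and reports its honest value; both source models are exposed
(`source="local" | "uniform"` in the sweep functions) so the sensitivity
can be reproduced in one line.

## Degenerate inputs and tie-breaks

Non-positive material constants, energies outside 0.5–250 MeV, markers
leaving the grid, unresolved markers (< 8 voxels/diameter, or
Δr > φ_m/200), CFL ≥ 1, detectors in the PML or outside the domain, and
non-uniform trace time axes all raise `ValueError`. Monotone traces are
flagged rather than yielding bogus bipolar metrics; spectra without a
line above the noise floor return a flagged zero amplitude. Spectral peak
location uses the maximum magnitude bin within the search band of the
zero-padded spectrum (ties resolved to the lower frequency by argmax).

## Limitations

* The dose stage is an analytic CSDA model: absolute doses carry
  few-percent errors versus Monte Carlo, and the in-marker deposition
  geometry (hence the case-2 slope, above) is its least certain output.
* Gold is treated as a fluid — no shear modes; the zero-pressure
  boundary eigenfrequency prediction is exact only for perfect
  reflection, though the simulated peak sits within 0.5 % of it.
* The propagation medium is lossless water; tissue attenuation is
  applied analytically in the range-verification budget, not inside the
  wave solvers.
* Detector modelling is a point sample at a voxel centre / interpolated
  radius; transducer impulse response and aperture are out of scope.
* Passing tests demonstrate internal consistency and agreement with the
  published desk-scale observables; they do not validate against
  experimental ionoacoustic data.
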