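# Methods

`nanoptt` simulates laser hyperthermia of nanoparticle-loaded tissue in
three stages: quasi-static nanorod optics, Monte Carlo photon transport on a
voxel grid, and an analytic solution of the perfused heat equation.  This
note records the models, the parameter choices that matter, the numerical
decisions, and the known limitations.

## Nanorod optics

A gold nanorod of diameter D and length l is treated, for its response to
light, as a prolate spheroid in the quasi-static (Rayleigh–Gans) limit.  The
depolarization factors are

    P1 = (1 - x^2)/x^2 * [ln((1+x)/(1-x))/(2x) - 1],   x = sqrt(1 - (D/l)^2),
    P2 = P3 = (1 - P1)/2,

and the per-axis polarizabilities

    alpha_i = 4 pi a b c (eps - eps_m) / (3 eps_m + 3 P_i (eps - eps_m)),

with semi-axes a = l/2, b = c = D/2, particle permittivity `eps` and host
permittivity `eps_m`.  The convention is fixed by requiring the sphere limit
(D = l, P_i = 1/3) to reproduce the Clausius–Mossotti polarizability; the
test suite verifies this reduction against an independently coded exact
n = 1 Mie term to better than 1%.  The orientation-averaged absorption cross
section is C_abs = k · Im[(alpha1+alpha2+alpha3)/3] with
k = 2 pi sqrt(eps_m)/lambda.  Absorptive hosts are rejected: the quasi-static
cross-section formula needs a transparent embedding medium.

For the volume, equivalent radius and loading arithmetic the rod is an
*s-cylinder* — a cylinder of radius b = D/2 with hemispherical end caps and
total length l — giving V = 2 pi a b² + (4/3) pi b³ (a = l/2 − b) and a
volume-equivalent radius (3V/4pi)^(1/3) ≈ 8.91 nm for the default
10 × 41 nm rod.  Mixing the spheroid (response) and s-cylinder (volume)
pictures is deliberate: the spheroid fixes the resonance, the s-cylinder
matches the rods' actual shape for mass/volume bookkeeping.

Finite-size damping: for particles smaller than the conduction-electron mean
free path (42 nm in gold) the collision rate grows from
gamma = vF/l_mfp to gamma_a = gamma + g·vF/a (g = 1, a = the s-cylinder
equivalent radius), and the particle permittivity is
eps(a) = eps_bulk(lambda) + Delta_eps, where Delta_eps is the difference of
the two Drude terms.  Defaults: plasma frequency 1.37e16 rad/s, Fermi
velocity 1.40e6 m/s.

Bulk gold dispersion ships as `data/gold_drude_synthetic.tsv`, a *synthetic*
table generated from an analytic Drude representation (eps_inf = 9.5,
ħω_p = 8.788 eV, ħγ = 0.0655 eV) of measured near-infrared gold constants;
it gives eps(808 nm) ≈ −23.2 + 1.4i, inside the spread of published
datasets, and places the longitudinal resonance of the aspect-ratio-4.1 rod
near 800 nm, consistent with the empirical resonance-vs-aspect-ratio trend.
It is valid for 600–1100 nm only — interband transitions below ~600 nm are
not modelled.  Users can substitute any (lambda, Re eps, Im eps) table.

Particle loading: mass concentration over bulk gold density (19.3 g/cm³)
gives the volume fraction (6.5e-7 for 12.5 µg/mL); dividing by the
s-cylinder volume gives the number density N ≈ 2.19e17 m⁻³; the
nano-absorption coefficient is mu_a,nano = N·C_abs ≈ 1.05 /cm (absorption
length ≈ 0.95 cm).  The packaged tumor material row also carries a lumped
absorption coefficient of 1.685 /cm; a scenario can either derive the nano
channel from the rod load (`nano_absorption: from_gnr`, the default) or
force the lumped table value (`table`).  The two differ by ~60% — one of
several mutual inconsistencies in the reference parameter set, see
"Reference parameter set" below.

## Monte Carlo photon transport

Analog transport of optical photons on the voxel grid: exponential free
paths from the local total attenuation mu_t = mu_a + mu_a,nano + mu_s, one
interaction channel drawn per collision with probability proportional to its
coefficient, Henyey–Greenstein scattering with per-material anisotropy g
(0.9 for soft tissue — a typical near-infrared value, chosen here because
the tissue data give mu_s but no phase function — and 0 for water), and
termination on absorption (the photon deposits its whole energy E0 = hc/λ in
the current voxel) or on leaving the grid (the world boundary absorbs).
Refractive-index mismatch between voxels is ignored; the scenarios are
index-matched tissue-in-tissue geometries.  A free path is re-sampled when
the photon crosses into a *different* material (valid by the memoryless
property of the exponential); same-material voxel faces never interrupt a
flight, and a single-material phantom uses a fast kernel with no face
bookkeeping at all.  The kernel is compiled with numba, runs single-threaded
and is bit-reproducible for a given (seed, n_histories).

Scored outputs are the per-voxel deposited energy (eV) and absorption count
Np.  The per-voxel statistical uncertainty estimator is 1/sqrt(Np(Np−1)).
Note its scaling: at a fixed voxel it falls like 1/Np, i.e. linearly in the
number of histories, whereas the *empirical* run-to-run error of the
deposited energy falls like 1/sqrt(n); the test suite checks both behaviours
(the empirical slope over replicate seeds is −0.5 ± 0.05).

Verification oracles: in a scattering-free absorber the deposition depth
profile recovers mu_a within 2% (and matches the truncated-exponential CDF
to Kolmogorov–Smirnov distance < 0.01 at 2e5 histories); photon number and
energy are conserved exactly; a lumped absorber and a split
(tissue + nano) absorber with the same total produce bit-identical walks.

## Laser source and flux scaling

The beam is collimated: photons start uniformly on the fiber-tip disc
(diameter d) and travel along the beam axis; no divergence is modelled.
Continuous-wave operation is a constant emission rate (default 2e6
photons/s simulated) over the irradiation time.  The *photon-flux scaling
factor* converts simulated per-voxel energies to the physical scale:

    scaling = [P / (E0[J] · pi (d/2)²)] / emission_rate,

with the tip area evaluated in **mm²** by default.  This convention is a
config switch (`area_unit: mm2|cm2|m2`) because the reference worked example
(2.1 W, 0.3 mm, 808 nm → flux ≈ 1.2e20, scaling ≈ 6e13) is only reproduced
by the mm² reading; note that multiplying deposited energy by this factor
overstates the physically emitted photon rate by the tip area in mm²
(≈ ×14 for d = 0.3 mm) — an energy-conserving alternative would divide the
physical photon rate P/E0 by the emission rate with no area factor.  The
package follows the reference convention so its temperature outputs are
comparable with the published curves; the consequences are discussed below.

## Heat conversion and bioheat diffusion

Two conversions from deposited energy to temperature are implemented:

* **Calorimetric (default, `heating: energy`)**: per-voxel
  ΔT = E[eV] · F · scaling with F = e/(m·Cp), m the voxel mass of the
  voxel's own material (F ≈ 2.77e-15 °C/eV for a 0.25 mm pancreas voxel).
* **Per-voxel nanoparticle steady state (`heating: steady`)**: for
  nanorod-loaded voxels, ΔT = N R² C_abs I / (2k) with R the voxel
  half-size and I the per-voxel irradiance
  I = E[eV]·e / (t_laser · voxel face area), flux-scaled likewise.

The per-voxel steady-state factor N R² C_abs/(2k) ≈ 1.4e-6 K·m²/W is about
10⁻³ of the calorimetric factor at the same irradiance, so a composite that
applies it only to nanorod voxels makes the loaded tumor *colder* than the
unloaded control — physically untenable.  The calorimetric route is
therefore the default for all voxels (the nano channel already concentrates
absorbed energy near the source), and the `steady` route is available for
sensitivity studies.

The perfused heat equation with constant coefficients
∂T/∂t = α∇²T + Q_b(T_b − T) + source has the Green's-function solution
"Gaussian convolution × perfusion decay": an increment field evolved for t
is convolved with the normalized Gaussian of per-axis standard deviation
sqrt(2αt) and multiplied by exp(−Q_b t).  The convolution uses a separable
truncated Gaussian filter (6σ support, zero-padded boundaries), i.e. the
far field is held at the baseline temperature (26 °C by default, the
benchmark room temperature).  A single diffusivity represents the mixture:
0.16 mm²/s for nanorod-loaded scenarios, 0.14 mm²/s for plain pancreas;
perfusion defaults to w_b = 0 (ex vivo conditions), with the blood terms
available on the material for in vivo studies.  Against an explicit
finite-difference solver the analytic evolution agrees to L∞ ≤ 2%, and the
point-impulse response matches the closed-form Gaussian to ~1e-9.

Continuous heating is superposition: each Δt slab of the per-second
deposition-rate map (default Δt = 1 s, midpoint injection) diffuses for its
remaining time.  Halving Δt moves the 2 mm probe at 30 s by < 2%; the whole
pipeline is exactly linear in beam power.

Temperatures above 100 °C are reported as-is: evaporation, coagulation and
temperature-dependent properties are not modelled, so such values are
non-physical extrapolations.  Probe series can be truncated at a reporting
threshold (155 °C in the packaged scenarios) via `apply_threshold`.

## Scenarios and geometry

* `pancreas_ptt`: a cubic 4 cm³ pancreas phantom (edge 15.87 mm, 0.25 mm
  voxels → 64³ grid, world box centered at the origin) holding a 3 cm³
  spherical tumor centered on the interstitial fiber tip at the origin.
  A 3 cm³ sphere (r = 8.95 mm) cannot fit inside a 4 cm³ cube, so the
  sphere is clipped to the world box (the clipped corners are far from the
  beam and thermally irrelevant on the 120 s horizon).  The grid covers at
  least the requested extent (voxel count = ceil(edge/pitch)).
* `pancreas_no_gnr`: matched control, homogeneous pancreas.
* `water_drop`: 0.1 mL suspension drop in a 24-well footprint (cylinder
  r = 7.75 mm → 0.53 mm depth), surface-illuminated through air for 30 s;
  the collimator diameter is not part of the reference parameter set and is
  taken as 2 mm.  The reported quantity is the surface-voxel ΔT.

Voxel convention: 0-based indices, world coordinates at voxel centers,
points map to voxels by floor((p − origin)/pitch).  The tip at the exact
grid center (0,0,0) sits on a voxel *corner* of the even-sized grid — a
consequence of the reference geometry, with consequences for peak-voxel
statistics (below).

## Reference parameter set and what passing tests show

The packaged parameter set reproduces the desk quantities exactly or nearly
so: beam energy 1.5345 eV; flux 1.21e20 and scaling 6.04e13 (mm²
convention); C_abs = 484 nm² from the pinned permittivities
(−24.718 + 3.6581i particle, 1.767 host), within 2% of the reference
476 nm²; volume fraction 6.5e-7.

The full-pipeline probe temperatures are a different matter.  The reference
set is internally inconsistent: (i) the mm² flux scaling overstates the
emitted photon rate ×14; (ii) the lumped tumor absorption (1.685 /cm), the
derived N·C_abs (1.05 /cm) and a separately quoted ~0.9 mm absorption
length disagree; (iii) heating scales with tip area as (0.3/0.6)² = 4,
while the published 40 s curves for the two diameters differ only by ~1.7;
and (iv) the per-voxel steady-state conversion is ~10³ smaller than the
calorimetric one.  No self-consistent reading reproduces all published
curves.  This package computes the default pipeline honestly (calorimetric
conversion, mm² scaling, N·C_abs absorption) and reproduces the published
*orderings* robustly — smaller tip hotter, higher power hotter,
nanorod-loaded hotter and more localized — while absolute probe
temperatures land above the published 0.3 mm values (by roughly 1.7–2.5×) and
near the published 0.6 mm value.  Tests assert the orderings strictly and
the absolute values at the stated ±30%; the absolute-value assertions for
the 0.3 mm applicator fail under the default conditions and are left
failing deliberately, as a documented property of the reference set rather
than of the implementation.

Similarly, the quoted < 0.1% peak-voxel statistical uncertainty at 2e6
histories is not met in the homogeneous pancreas phantom: with the source
on a voxel corner of the 64³ grid and an albedo of 0.9998 spreading
absorptions over ~10⁵ voxels, the peak voxel collects ~800 photons,
giving ≈ 0.13%.  (A grid with the source at a voxel center, or any of the
strongly absorbing scenarios, is comfortably below 0.1%.)

## Problem sizes

Reference runs (acceptance script) use the study's 2e6 histories
throughout.  The test suite runs the scattering-dominated homogeneous
pancreas transport at 2e6 for the precision check but scales paired
ordering comparisons down to 2e5 histories and convergence/uncertainty
sweeps to 1e4–1e6, sizes at which the checked contrasts exceed the Monte
Carlo noise by an order of magnitude.  The synthetic phantoms are
homogeneous or piecewise-homogeneous idealizations: they exercise every
code path of the pipeline but do not represent anatomical heterogeneity,
refractive interfaces, perfusion or phase change, so passing tests validate
the numerics of the stated model, not clinical accuracy.

## Known limitations

No polarization, fluorescence, Fresnel boundaries or time-resolved
transport; no particle–particle plasmonic coupling (the quasi-static single
-particle picture breaks down for clustered rods); no temperature-dependent
tissue properties, vaporization or damage integrals; a single diffusivity
per scenario; the Gans model has no retardation (rods ≪ wavelength only).
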