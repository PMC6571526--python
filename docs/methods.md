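# Methods

`pbsbeam` models a cyclotron-driven pencil-beam-scanning (PBS) proton
machine the way a Monte Carlo dose system is commissioned in practice: a
compact virtual-source description is fitted to in-air spot-size
measurements, the source energy spectrum is calibrated against depth–dose
curves in water, monitor units are converted to proton numbers through an
integral-dose calibration, and treatment plans are reduced to weighted
beamlet sources that a forward dose engine transports through voxel
phantoms.  This note records the models, their assumptions, the defaults,
and the choices made where the design was genuinely open.

## Beam geometry: two virtual sources, one simulation origin

The two scanning magnets focus the beam at different planes, so the
beamlets appear to diverge from two distinct virtual sources on the beam
axis: one for the x axis (`Z_VSADx`) and one for the y axis (`Z_VSADy`),
both upstream of the isocenter (the frame is right-handed, beam along +z,
isocenter at the origin; lengths in cm, angles in rad, energies in MeV).
Each source position is found by extrapolating the measured in-air spot
sigma linearly in z to zero.  `fit_virtual_source` pools all energies
with a shared intercept — the focal point is a property of the magnets,
not of the energy — by profiled least squares: for a trial intercept the
per-energy slopes are solved in closed form and the intercept is
optimized on the 1-D profile objective.  With a single energy this is
algebraically identical to the ordinary straight-line z-intercept.

The simulation source sits at the focal plane closest to the isocenter
(the x focus for the bundled preset).  There the beam is a *line source*:
zero sigma in x, already spread in y, with independent Gaussian
divergences per axis.  Because the sampled position and angle are
uncorrelated, such a source grows in quadrature,
`sigma(z)^2 = sigma0^2 + div^2 (z - z0)^2`, while a true point-focus beam
grows linearly.  The commissioning back-projection therefore fits
*effective* (sigma0, div) per energy by linear least squares of sigma^2
against (z - z0)^2 over the instrumented span (-20 to +20 cm around the
isocenter), which reproduces the measured spot sizes where it matters —
including the near-circular spot at the isocenter — rather than naively
propagating the focal-drift parameters.  sigma0_x is constrained to zero.
Negative fitted sigma0^2 (possible with noise) is clamped to zero with a
warning.  Polynomials of order 3 (configurable) in nominal energy
represent sigma_y(E), div_x(E), div_y(E) so no lookup tables are needed.

Beamlet direction cosines run from the origin-plane axis point to the
spot position at the isocenter ("single_origin" steering).  An optional
"two_plane" mode anchors the y deflection at the upstream y focus
instead, displacing the beamlet center in y at the origin plane; the ray
still passes through the commanded isocenter position.  Single-origin is
the default because the source initialization is stated per-origin-plane;
the difference is a sub-millimetre parallax for clinical geometries.

## Energy spectrum calibration

The source spectrum is Gaussian, parametrized by a mean kinetic energy
`E_MC` and a fractional momentum FWHM (FWHM = 2 sqrt(2 ln 2) sigma;
momentum from kinetic energy by `pc = sqrt(T^2 + 2 T m_p c^2)`,
`m_p c^2 = 938.272 MeV`).  The mean fixes the Bragg peak position; the
spread lowers the peak-to-plateau ratio.  `fit_energy_and_spread` inverts
a measured curve sequentially and exhaustively: an energy grid scan
matches the peak position (evaluated at mid-grid spread, since the peak
depth is nearly spread-independent), then a spread grid scan matches the
peak/plateau ratio at fixed energy.  Each pass ends with two successive
halvings of the grid step about the incumbent, and the two stages are run
twice: the ratio retains a weak energy dependence, and the second sweep
removes the bias it would otherwise leave in the spread.  Peak depth is
the parabolic-interpolated argmax (distal R80 is available as an optional
metric); the plateau is the mean dose over the proximal 25% of the peak
depth (configurable — "plateau" has no unique definition).  Nominal
energy to (E_MC, momentum FWHM) relations are fitted with order-3
polynomials (configurable), with monotonicity of E_MC(E_nom) verified on
a dense grid.

## Monitor-unit calibration

For each nominal energy, `k(E) = d_TPS(E) / d_MC(E)`: the planning-system
integrated dose per MU divided by the engine's integrated dose per source
proton, both in Gy cm^3 over a scoring volume that captures essentially
all deposited energy.  The integral observable makes k insensitive to how
lateral scattering redistributes dose, and k is exactly independent of
the MU of the calibration plan.  Calibration plans are single-beamlet,
one energy and one MU value per plan.  k(E) is represented by an order-2
polynomial, checked positive over the fit range.  A beamlet planned with
MU monitor units is simulated with `N_p = k(E) MU` protons, kept as a
real-valued weight; when fewer particles are sampled than planned, the
per-beamlet ratios are preserved and doses rescaled by
`total N_p / n_simulated`.

## HU-to-material conversion

The CT calibration is stoichiometric: 12 core materials (air, lung,
adipose, water, brain, muscle, liver, cartilage, trabecular and cortical
bone, plus Al and Fe), each with HU anchor, density, elemental mass
fractions and mean ionization energy, are linearly interpolated in HU
into 50 body materials and 5 Al/Fe metal mixtures.  The body set places
one material at each core HU and distributes the remaining 40 over the
nine inter-core gaps in proportion to gap width; the metal mixtures sit
at equally spaced mixing fractions including the pure endpoints.  Mass
fractions are renormalized after interpolation.  Each material owns the
HU interval bounded by the midpoints to its neighbours, which — because
density is piecewise-linear and monotone in HU — is exactly the
"closest in mass density" assignment.  The voxel's own interpolated
density (the min/max over each interval is stored) rescales the linear
stopping power.

The core fixture is implementer-supplied: tissue densities, compositions
and I-values follow the standard ICRU/ICRP compilations; the HU anchors,
in particular Al = 2700 HU and Fe = 12000 HU, are synthetic choices that
give a realistic monotone HU-density curve on an extended CT scale.

Stopping power is the Bethe formula with composition-weighted Z/A and the
material's I; shell and density-effect corrections are omitted by default
(at 10-230 MeV in tissue they are sub-percent; a simple asymptotic
density-effect term can be enabled).  Validity floor 0.5 MeV, ceiling
300 MeV.

## Forward dose engine

The engine is a desk-scale analytical/Monte-Carlo stand-in for a
general-purpose transport code: its role is to make every calibration and
verification operation exercisable end to end, not to reproduce
condensed-history physics.

*Depth dose.*  The raw curve is bin-averaged continuous-slowing-down
deposition: the residual-energy table differenced across 0.1 mm bin edges
and divided by the bin width.  (A point evaluation of the stopping power
was tried first and rejected: S(E) is near-singular at the end of range,
and sampling it produces grid-phase jitter in the peak amplitude that is
large enough to bias the spread calibration; the binned form conserves
energy exactly and is smooth in E.)  The curve is convolved with a
Gaussian whose variance combines range straggling
(`sigma = 0.012 R^0.951` cm, an empirical water fit, configurable) and
the range spread induced by the source energy spread
(`sigma_R = sigma_E / S(E)`).  Nuclear attenuation of the primary fluence
is exponential with lambda = 85 cm in water, the lost energy deposited
locally; it is off by default so that energy-conservation checks close.

*Lateral model.*  In-air transport is pure divergence drift (air treated
as vacuum).  In the phantom, multiple Coulomb scattering grows the spot
by Fermi-Eyges accumulation `sigma^2(z) = int (z-u)^2 T(u) du` of the
Highland scattering power `T = (13.6 MeV / pv)^2 / X0 (1 + 0.038
ln(l/X0))^2` with X0(water) = 36.08 cm; the logarithmic correction is
evaluated at the cumulative water-equivalent depth, floored at 1e-3 cm.
Heterogeneity enters through water-equivalent path length (cumulative
relative stopping power at a 100 MeV reference along the beamlet's
central column) for the depth coordinate and density-scaled scattering;
no beam distortion beyond WEPL scaling is modelled.

*Dose modes.*  `pencil_beam` superposes, per z-slab, the bin energy times
a separable 2-D Gaussian integrated exactly over voxel faces (difference
of normal CDFs), with sigma combining source optics drift and the MCS
growth; doses are Gy per total source proton, and absolute dose is the
grid times the plan's total N_p.  `sampled` draws particles from the
phase space; each particle carries fixed standard-normal deviates for the
optics and MCS displacements so its trajectory is continuous while the
lateral marginal at every depth matches the pencil-beam sigma, and
deposits bin energy into the voxel containing its lateral position.  Ten
batches give a per-voxel standard-error map.  The two modes agree within
statistics by construction of the marginals.

*TPS-style kernel.*  For qualitative comparison with
treatment-planning-system lateral models, `rs_style_lateral` builds the
19-Gaussian kernel (one central component, 6 on an inner ring, 12 on an
outer ring, equal component sigmas).  Ring radii 2 sigma and 4 sigma and
ring weights 30%/10% of the total are documented assumptions — the
vendor's manual is cited in the literature but its numbers are not
reproduced here.  The azimuthally averaged profile uses the exponentially
scaled Bessel form for numerical stability.  The kernel's 80-20%
penumbra is strictly wider than the single-Gaussian core at equal core
sigma, reproducing the known tendency of such halo models to spread dose
outside targets.

## Gamma analysis

`gamma_map` computes, per reference voxel above the dose threshold,
`min_e sqrt(|r_e - r_ref|^2 / dta^2 + (D_e - D_ref)^2 / (dD Dnorm)^2)`
with Dnorm the reference global maximum (global mode, the default) or the
local reference dose.  The evaluation grid is interpolated multilinearly
on an offset lattice of step dta/10 within a search radius of 3 dta (both
configurable; implementations differ here and no canonical values exist).
Offsets are visited in order of increasing distance so the search can
stop as soon as the spatial term alone exceeds the worst current minimum
— an exact, not approximate, shortcut.  The default threshold is 0 Gy on
the reference (all non-null voxels evaluated); a
20%-of-prescription threshold is the documented alternative, and raising
it typically raises passing rates because failures concentrate in the
low-dose penumbra.  The same dimension-agnostic core serves 1-D
depth–dose curves (1 mm bins) and 2-D/3-D maps.  Difference maps are
voxelwise (evaluation - reference) / prescription x 100.

## Synthetic data

The bundled `PROVISION` preset fixes the published machine constants —
virtual sources at -193.5 cm (x) and -231.5 cm (y), snout at -50 cm,
deliverable energies 98-230 MeV — while every curve is a synthetic ground
truth of realistic magnitude: div_y falls linearly from 3.6 to
2.5 mrad over the energy range, div_x = (231.5/193.5) div_y (circular
isocenter spot by construction), E_MC(E) = 3.0 + 0.98 E + 2e-5 E^2,
momentum FWHM falling from 0.91% to 0.45%, and k(E) = 1.5e8 + 5.0e5 E +
1.2e3 E^2 protons per MU.  None of these curves is read off published
figures (figure digitization is unreliable); they are flagged synthetic.

Spot generation follows the exact two-focus drift,
`sigma_a(z, E) = div_a(E) (z - z_vsad_a)`, so noise-free virtual-source
recovery is exact; Gaussian noise of configurable sigma can be added.
Depth–dose sets come from the forward engine at the preset's ground
truth.  MU records pair the engine's per-proton water integral with
k_true times that integral, so a correct pipeline recovers k_true.  The
toy verification plan delivers a prescribed dose to 1 cm^3 targets
scattered in a 12 x 12 cm^2 field in water (isocenter 15 cm deep, phantom
entry at -15 cm): per target, eight energy layers whose peaks span -1.0
to +0.7 cm about the target depth and a 7 x 7 spot grid at 5 mm spacing
are weighted by non-negative least squares to flatten the depth dose
(spread-out Bragg peak) and the lateral profile across the target face,
then scaled to the prescription at the target center.  The asymmetric
layer margins reflect the sharp distal versus shallow proximal fall-off.
Plans can be written as minimal synthetic DICOM RT Ion Plans (paired
control points per energy layer, spot maps in mm, meterset weights) for
round-trip testing of the DICOM reader.

What the generators do *not* emulate: detector response (scintillator
optics, chamber volume averaging beyond the additive noise knob), beam
delivery errors, nuclear halo build-up, patient-like heterogeneity
statistics.  Passing closure tests therefore demonstrates the internal
consistency and correctness of the fitting machinery under the stated
beam model, not agreement with any particular physical machine.

## Numerical choices and problem sizes

Water energy-range tables use 3000 nodes over 0.5-300 MeV with
trapezoidal accumulation; `csda_range` itself is adaptive quadrature.
Depth-dose convolution works on a 0.1 mm internal grid and pads by the
full kernel support before cropping.  Fermi-Eyges moments accumulate on
2000 midpoint steps.  Dose grids in the shipped workflows use 2-4 mm
voxels and phantoms of 8-16 cm aperture — sizes chosen so every pipeline
stage, including the end-to-end verification demo, runs in seconds on a
single core while keeping discretization errors well inside the stated
tolerances (energy conservation to 1%, MU closure to 0.5%).  Gamma
comparisons in the demo are evaluated on extracted 2-D planes at 5, 10
and 16 cm depth, mirroring planar-detector practice.

## Known limitations

- No secondary-particle transport, LET/RBE scoring, or detector models;
  nuclear attenuation is a single exponential with local deposition.
- The pencil-beam mode ignores beamlet tilt when accumulating WEPL
  (central-column approximation) — adequate for the <= 2 degree deflections
  of a 12 x 12 cm field, wrong for oblique incidence.
- The 30-98 MeV range-shifter regime is out of scope; the preset's energy
  floor is the cyclotron-degrader limit of 98 MeV.
- Gamma search radius (3 dta) bounds the reported gamma from above at
  3 x the spatial term; values above ~3 saturate.
- The material fixture's HU anchors are synthetic; users with a real
  scanner calibration should supply their own 12 cores.
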