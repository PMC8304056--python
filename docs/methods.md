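# Methods

This note records the models implemented in `memscatter`, their assumptions,
the defaults that matter and the design choices made where several reasonable
options existed.

## Scattering length densities and contrast

The SLD of a medium is ρ = n_fu·Σ_j b_j, with n_fu the formula-unit number
density from the mass density and molar mass, and b_j coherent scattering
lengths in fm (1 fm = 1e-5 Å).  The isotope table
(`src/memscatter/data/isotopes.json`) is frozen from Sears' 1992 compilation
plus CIAAW standard masses; `"H"` denotes ¹H (b = −3.739 fm), `"D"`/`"2H"`
deuterium (b = +6.671 fm).  The X-ray branch uses b_j = r0·Z_j with
r0 = 2.818 fm and no anomalous-dispersion energy dependence (f1 = Z, f2 = 0);
absorption (imaginary SLD) is carried by the types but defaults to zero.

Solvent mixing is linear in volume fraction, and the match-point solver is its
exact inverse; a target outside the reachable band is clipped with a warning
rather than silently extrapolated.  The critical edge is
Qc = sqrt(16π·Δρ) for positive backing−fronting contrast.  Note that the
computed heavy-water SLD at 1.1044 g/cm³ (6.36e−6 Å⁻²) differs by ~0.2% from
the conventionally quoted 6.35e−6 Å⁻²; the package always reports computed
values and does not force agreement with rounded literature numbers.

Unit conventions package-wide: lengths Å, Q Å⁻¹, SLD stored in Å⁻² and
displayed in 1e−6 Å⁻².

## Density profiles

Frames are histogrammed in z with a default bin width of 0.13 Å.  Before
binning, each frame is shifted so the centroid of its non-water atoms sits at
z = 0; without this, slow membrane drift broadens the time-averaged profile.
Coordinates are then wrapped into each frame's own box.  Slice volumes use the
instantaneous in-plane area Lx·Ly of each frame (relevant for NPT
trajectories); the grid is fixed by the first frame's Lz.  The alternative —
using the mean box area — was rejected because it breaks exact per-frame atom
count conservation, which the test suite checks to 1e-6 relative.

United-atom trajectories must declare implicit hydrogens explicitly via the
grouping configuration (per residue/atom-name pattern); the reader expands
them as extra H entries co-located with the parent heavy atom.  No hydrogen
counts are ever guessed.

Selective deuteration operates on (group, isotope) species labels of the
binned histogram, not on atom lists: the densities are untouched, only the
scattering length they are multiplied with changes.  Solvent contrast
variation re-weights the water hydrogens with b = (1−f)·b_H + f·b_D.

## Assembly of measurable systems

A simulated bilayer floats freely in water; the measured film does not.
`splice_substrate` prepends a semi-infinite fronting (Si), an oxide layer and
a water gap.  Roughness of the substrate interfaces is realized as erf-shaped
transitions evaluated on the bin grid (micro-slabs); Nevot–Croce factors are
reserved for analytic `SlabStack` models, because applying both to one
interface would double-count the damping.  Junctions are guarded: if the
profile does not begin in bulk solvent within a tolerance (default 2e-7 Å⁻²,
roughly the statistical noise of a well-averaged profile), splicing raises
instead of producing a discontinuity whose Fourier signature would contaminate
the whole curve.

Multilayers are built by tiling a unit cell that must terminate in equal half
water gaps; the merged end gap must also equal any interior gap.  Violating
this creates an alternating gap sequence, doubling the lattice constant and
adding a spurious Bragg peak at half the first-order position — a known
artefact of careless merging — so it is an error unless deliberately enabled
(`allow_asymmetry=True`, used to demonstrate the artefact).

Interlamellar disorder jitters the merged water gaps with zero-mean uniform or
normal noise (the distribution family is genuinely open; both are provided,
default uniform) over a seeded ensemble of 64 realizations.  Averaging happens
in reflectivity space — intensities, never amplitudes and never profiles —
because lamellar spacing fluctuations are uncorrelated between domains.

Solvent scaling scenarios identify solvent bins as those within 1% of the
backing SLD; `bulk_only` rescales only the trailing bulk run plus backing
(detached hydrogenated material in the reservoir), `all_solvent` every solvent
bin (isotopic contamination of the D₂O supply).

`profile_to_slabs` coarsens bins into slabs greedily while the min–max spread
of a run stays within the tolerance; tolerance 0 keeps one slab per bin.

## Reflectivity kernels

Medium wavevectors are k_j = sqrt((Q/2)² − 4π(ρ_j − ρ_fronting)), principal
complex branch (+iκ evanescent below each medium's critical edge).  The
Parratt recursion and the Abelès matrix product are implemented independently
and agree to 1e-10 relative across randomized 1–20-slab stacks, including
below Qc and with roughness; both apply the Nevot–Croce factor
exp(−2 k_j k_{j+1} σ²) per interface.  The Nevot–Croce description assumes
σ ≪ layer thickness; a warning fires when σ exceeds a third of the adjacent
slab thickness.  A σ = 3 Å erf profile binned at 0.1 Å agrees with the
analytic Nevot–Croce single interface to better than 1% up to 0.3 Å⁻¹.

The Born-limit curve sums the SLD steps at bin edges,
R = R_Fresnel·|Σ_k Δρ_k e^{iQz_k}|²/Δρ_tot², reproducing the exact Fresnel
result for a sharp interface and the exact kernels to ~5% at Q > 10·Qc for
weak contrast; below Qc it exceeds unity and the affected region is flagged in
the curve metadata.

Resolution smearing is a Gaussian in Q of width proportional to Q, with
dQ/Q interpreted as the FWHM fraction (the common reflectometry convention;
a σ-fraction mode is available).  The kernel is a 51-point normalized
quadrature over ±4σ on the linearly interpolated curve.  This convention is
this package's documented choice, not an inference about any particular
instrument's reduction software.  Bragg peaks are located on log10 R after
smearing (prominence default 0.3 decades) with parabolic sub-grid refinement;
Q grids are never auto-generated below 1e-4 Å⁻¹.

## SANS vesicle model

For spherically symmetric ρ(r), dΣ/dΩ is the squared radial Fourier
transform; for piecewise-constant shells this is the closed-form sphere-kernel
difference sum (validated against direct radial quadrature to 1e-6).
Polydispersity applies to the solvent core radius only — shell thicknesses are
held fixed — with a Schulz–Zimm distribution parameterized by (mean R0,
p = σ_R/⟨R⟩), shape z = 1/p² − 1.  The average uses Gauss–Legendre nodes over
R0 ± 5σ (truncated at R > 0) with the density folded into the weights.
Because |F(Q;R)|² oscillates in R with period π/Q, the node count is raised
deterministically from the 101-point floor to resolve those oscillations at
the largest Q requested (capped at 4001); without this the quadrature noise
roughens the chi-square landscape and least squares can stall far from the
optimum.

The absolute-intensity prefactor (vesicle number density, unit conversions,
calibration) is folded into a single fitted scale.  Fitting is weighted least
squares (Levenberg–Marquardt via lmfit) over any subset of {core radius,
polydispersity, scale, background, uniform thickness factor}; it is
deterministic from the stated start values, reports covariance-derived
uncertainties, and raises with diagnostics on non-convergence.  Instrumental
smearing of SANS curves reuses the Gaussian-in-Q kernel and is off by default.

## Synthetic fixtures

The bilayer fixture draws, per frame, head pseudo-molecules from Gaussians at
±17 Å (σ = 3 Å, equal leaflet split), tails from a Gaussian at the midplane
(σ = 6 Å) and water uniformly outside |z| = 23 Å, in a 62×62×66 Å box with
128 lipids and 3000 waters — the scale of a typical single-bilayer simulation
(≈60 Å² per lipid, ≈66 Å repeat).  Molecules are point-like (all atoms of a
molecule at one site) and frames are statistically independent: the fixture
reproduces the *density topology* of a bilayer trajectory (head maxima
flanking a tail trough, flat bulk water) and Poisson counting statistics, but
none of the physics — no intramolecular structure, no area fluctuations, no
interleaflet correlations.  Tests passing on fixtures therefore validate the
histogramming, contrast and scattering machinery, not force fields.

Noisy data curves use multiplicative Gaussian noise clipped at zero, with the
stated uncertainty set to the noise level times the noise-free model.  All
fixtures are fully determined by (spec, seed).

## Problem sizes used in the validation suite

Kernel cross-checks use 60–80 point Q grids and up to 20 slabs; lamellar
demonstrations tile 12–36 repeats of a 66 Å unit at 0.5 Å bins; disorder
ensembles use 32 realizations; parameter-recovery experiments use 90-point
SANS curves, 1% noise and 10 seeds.  These sizes were chosen so the whole
suite completes in well under a minute while keeping every statistical
assertion comfortably away from its threshold.

## Known limitations

No off-specular scattering, polarized neutrons, footprint/gravity or
multiple-scattering corrections; no inter-vesicle structure factors or
multilamellar populations; X-ray SLDs ignore anomalous dispersion; binary
trajectory formats (XTC/TRR) are a documented extension point.  The
incoherent-scattering column of the isotope table is informational only.
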