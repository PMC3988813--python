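# Methods

## Scope and model

`nanoconfine` predicts water self-diffusion under nanoconfinement from
three ingredients: (i) a characteristic confinement length δ obtained
from the effective wall potential of an atomistic solid, (ii) a
geometric scaling parameter θ = V_in/V_w, and (iii) the linear law
D(θ) = D_B[1 + (D_C/D_B − 1)θ]. Running molecular dynamics is outside
the package's scope: MD enters only as the source of trajectories the
MSD module can analyse.

Internal units are nm, kJ/mol, elementary charges, K and ps; SI
conversions happen at module boundaries. The water model defaults to
SPC/E: dipole moment 7.50×10⁻³⁰ C·m, oxygen LJ σ = 0.3166 nm,
ε = 0.6502 kJ/mol, bulk D_B = 2.60×10⁻⁹ m²/s at 300 K.

## Solvent-accessible surface

SAS areas are computed by Shrake–Rupley point sampling with a
deterministic golden-spiral point set (default 960 points per atom,
giving <1% sphere-closure error). The SAS atomic radius is σ_k/2 and
the probe radius 0.14 nm; neither is dictated by the underlying theory,
so both are configurable. With a periodic box, neighbour occlusion uses
the minimum-image convention.

The outward normal of atom *i* is the direction from the atom centre to
the centroid of its accessible points. This realizes "orthogonal to the
SAS through the atom centre" without constructing a meshed surface. A
fully exposed isolated atom has no meaningful normal (its accessible
patch is the whole sphere); such atoms are skipped by the averaging
step. Point-sampled areas are exactly translation invariant but
rotation invariant only to the angular resolution of the point set
(~0.5% at 960 points); the tests assert exactly that.

## Effective wall potential and δ

For each surface atom, U_eff is evaluated on a uniform grid
n ∈ [0.05, cutoff] nm with 2000 points along the SAS normal; the
neighbour cutoff defaults to 1.0 nm (the atom itself included). LJ
parameters are Lorentz–Berthelot-combined with the water oxygen unless
the parameter table is flagged as already water-combined (carbon
nanotube walls use pre-combined σ = 0.36 nm, ε = 0.29 kJ/mol, neutral
carbons).

The Coulomb term computes the vector-summed field of the neighbours'
partial charges with a distance-dependent relative permittivity — a
sigmoid rising from ~1 at contact to 78 in bulk (midpoint 0.4 nm,
width 0.1 nm), the standard implicit treatment of interfacial
dielectric screening; a constant-ε_r mode exists for closed-form
checks. The thermally averaged dipole energy uses the Langevin factor,
series-stabilized below x = 10⁻³.

δ_i is the distance between the zeros of U_eff + α k_B T, with
α = 0.25 (exact for planar walls, configurable for curved ones). Roots
are refined by bisection on a cubic-spline interpolant of the profile
(tolerance 10⁻⁹ nm), so halving the grid changes δ well below 0.5%.
If the profile has several sign structures, the innermost and
outermost crossings bracketing the global minimum are used — the most
conservative (largest) trapped region. Wells shallower than α k_B T
give δ_i = 0, and bulk atoms carry zero SAS weight, so the
surface-averaged δ = Σ δ_i S_loc,i / S_tot is dominated by genuine
surface atoms. The same averaging yields ε_mean, the SAS-weighted well
depth used as the adsorption energy of the supercooled-water route;
the per-structure maximum depth is also reported because the proper
choice between the two is not settled — both are exposed.

## θ and the percolation correction

V_in uses the first-order S·δ product for planes and exact shell
volumes for spheres and cylinders (inner shells capped at the pore
radius). When several influence volumes can overlap (more than one
particle, or on request) the apparent fraction is corrected as
1 − exp(−θ), the classical continuum-percolation coverage of randomly
placed overlapping volumes; the correction is strictly below the
apparent value except at 0. θ is clamped to [0, 1] at the end — the
law's domain — while the raw apparent ratio is preserved for
diagnostics. The water number density ρ_n entering V_w is an input
(with an optional relative s.d. for error propagation), not measured
from snapshots.

## Scaling law and calibration

`fit_law` performs (optionally inverse-variance weighted) least squares
of D against θ, with D_B the intercept and D_C recovered from the
slope; a negative fitted D_C is clamped to zero and the slope refitted
through the physical origin, since D_C is a diffusivity. The
density-weighted variant replaces θ by the confined number fraction
ρ_Cθ/(ρ_Cθ + ρ_B(1−θ)) and reduces to the plain law when the adsorbed
layer density equals bulk.

## Supercooled-water route to D_C

f(T) = ∫_{T0}^{T} c_p dT is integrated exactly on the piecewise-linear
interpolant of the supplied c_p table (T0 = 300 K anchor) and inverted
by bracketed root finding (10⁻⁹ K); no extrapolation beyond the table
is allowed. The well depth ε (kJ/mol, per molecule) is converted to
J/kg through the molar mass of water before entering Δh = −ε — the
dimensional bookkeeping is implicit in the original formulation and
made explicit here. Wells deeper than the table range mean the
effective temperature falls below the data: the adsorbed layer is
treated as arrested and D_C/D_B = 0 is returned with a warning. The
experimental c_p(T) and D(T)/D_B curves are *not* bundled (they are
third-party measurements); users supply two-column tables, and tests
use synthetic tables (constant c_p with an exponential diffusivity
ratio) whose composition has a closed form.

## MSD estimator

MSDs are time- and particle-averaged with the standard FFT
autocorrelation decomposition (O(N log N)); equivalence with the naive
double loop is asserted on small cases. The default fit window is
[10%, 50%] of the maximum lag, excluding the short-lag
ballistic/caging regime; D = slope/(2d). `estimate_D` reports an OLS
standard error, which understates the true uncertainty because MSD
residuals are serially correlated; `estimate_D_trajectory` fits each
particle separately and uses the particle spread, which is
statistically valid for independent particles and is what the coverage
test exercises. A block diagnostic (default 200 ps) re-estimates D on
successive lag blocks and flags runs whose last two blocks disagree by
more than 20%.

The Brownian fixture draws Gaussian steps with per-axis variance
2 D dt, optionally wrapped into a periodic box; `unwrap` accumulates
minimum-image displacements and cannot recover motion faster than half
a box per frame (documented aliasing limit).

## Relaxivity enhancement maps

The EDX chain: pixel intensities → pixel-scale SPIO density
(normalized to the total SPIO count) → Gaussian-kernel density of the
occupied pixels with bandwidth = pore diameter in pixels (the pixel
scale is instrumental; the pore scale is the physical one) → rescaled
to conserve SPIO mass → per-pore counts via the representative pore
area. The representative pore's θ̄ stacks spherical influence shells
around each SPIO (overlap-corrected), over the filled pore water
volume minus the SPIO cores. The θ map is proportional to the
pore-scale density with the constant fixed by requiring the
density-weighted mean over occupied pixels to equal θ̄; values are
clamped to [0, 1] with the clamped mass fraction logged (the averaging
constraint alone does not bound the map). The occupied-pixel threshold
(default 5% of the density maximum) is exposed because its exact
definition is an open choice.

The local SPIO volume fraction is υ = ρ_SPIO·(4/3)πr³/(h·c_fill) — the
SPIO volume under a pixel over the water column under it — and the
bulk reference υ_B spreads the same SPIOs over the whole construct, so
a uniform unconfined distribution gives En ≡ 1. Outer-sphere theory
makes r₂ ∝ υ/D, so the enhancement En = (υ/D)/(υ_B/D_B) is free of
the theory's prefactor; the absolute r₂ closed form is deliberately
not implemented (only the definitional r₂ = (1/T₂ − 1/T₀,w)/M_Fe).
Pixels with D = 0 (full confinement with D_C = 0) are excluded from
the SPIO-weighted average with a warning.

## Synthetic data

The generators are first-class code, not test helpers. The structure
builders use simple-cubic lattices (sphere, pore, slab) and the rolled
graphene construction for armchair nanotubes (C–C bond 0.142 nm);
crystallographic fidelity is not needed because the δ algorithm
consumes only positions and parameters — consequently fixture δ values
characterize the algorithm, not any specific real crystal. The
synthetic EDX scene places Gaussian-blob clusters in a raster emulating
a ~1000 nm discoidal construct with 40 nm pores, 400 nm height and
~5.1 nm SPIOs at a dense loading (~10⁶ SPIOs, local in-pore packing
~0.4). What passing tests show is that the chains are internally
consistent and recover known ground truth; they do not certify
agreement with any particular laboratory construct, whose images,
crystal structures and property tables must be supplied by the user.

## Problem sizes and determinism

Test and acceptance runs use deliberately small structures (tens to
hundreds of atoms), 10³–10⁴-frame Brownian trajectories and 128×128
rasters — sizes chosen so the full suite completes in well under a
minute of compute while keeping statistical tolerances meaningful.
Every stochastic step takes an explicit seed; identical inputs produce
bit-identical outputs throughout.
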