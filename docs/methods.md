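# Methods

## Scope and model

`beadforce` treats an elastic sensor bead as a homogeneous, isotropic,
linearly elastic solid sphere of undeformed radius r₀, shear modulus G (Pa)
and Poisson ratio ν ∈ (−1, ½). The observed surface is parametrized as a
star-convex radius function about the object center,

    r(θ, φ) = Σ_{l=0}^{lmax} Σ_{m=-l}^{l} c_{l,m} Y_{l,m}(θ, φ),

with real orthonormal spherical harmonics (∮ Y² dΩ = 1, hence
Y₀,₀ = 1/√(4π) and r₀ = c₀,₀/√(4π) by volume conservation). θ is the
colatitude in [0, π], φ the azimuth in [0, 2π); coefficients are in
micrometers. The surface displacement is assumed purely radial,
u(θ, φ) ê_r = (r − r₀) ê_r, which is the physically sensible ansatz for
chemically inert gel beads that cells cannot pull on tangentially. Under
that ansatz the deformation coefficients equal the shape coefficients for
l ≥ 1; the l = 0 component is c₀,₀ − √(4π)·r₀, which vanishes when r₀ is
inferred from the fit itself and is nonzero only when an independently
known undeformed radius is supplied (isotropic compression/swelling is
invisible to a volume-conserving radius estimate).

## The per-mode elastic solution

Mechanical equilibrium with negligible bulk forces gives the Navier–Lamé
equation (1−2ν)⁻¹ ∇(∇·u) + ∇²u = 0 with isotropic Hooke's law
T = λ tr(ε) I + 2Gε, λ = 2Gν/(1−2ν), ε = (∇u + ∇uᵀ)/2. For each degree l
the interior displacement regular at the origin is a combination of two
spheroidal solid-harmonic families,

    u₁ = ∇(r^l Y_{l,m}),
    u₂ = r² ∇(r^l Y_{l,m}) + β_l x r^l Y_{l,m},
    β_l = −(6l + 2 − ν(8l + 4)) / (l + 5 − 4ν),

where β_l is fixed by requiring u₂ to satisfy the Navier equation (direct
substitution using the homogeneity of solid harmonics). The two weights
follow from the boundary conditions at r = r₀ — radial displacement
Y_{l,m}, zero tangential displacement — a 2×2 linear solve per degree that
reduces to closed form. Degree 0 is the single hydrostatic family
u = A r ê_r with surface traction 2G(1+ν)/(1−2ν)·(u₀/r₀), and degree 1 is
passed through the same machinery (under the radial-only ansatz l = 1 is
*not* a rigid translation and carries stress; the recentring step below
makes this nearly moot in practice).

Writing the per-degree solution as u = U(ρ) Y ê_r + V(ρ) ∇ₛY with
ρ = r/r₀, the surface traction per unit (µm) coefficient amplitude is

    t_rr[l] = (G/r₀) [ λ̂ (2l/β_l + l + 3) + 2 (2l/β_l + l + 1) ],
    t_rt[l] = (G/r₀) (1 + 2/β_l),        λ̂ = λ/G,

so the radial traction map is T_rr(θ, φ) = Σ c^def_{l,m} t_rr[l] Y_{l,m}.
These dimensionless tables depend only on (l, ν); they are computed once
and cached on disk keyed by (lmax, ν), reproducing precompute-once,
evaluate-fast behavior without symbolic algebra. The default basis degree
is 15; lower-degree views are exact slices of the same tables.

Verification is dual-route: (i) a finite-difference Navier residual
(`navier_residual`, 4th-order stencils at seeded interior points,
normalized by the local Hessian magnitude with a gradient-scale floor so
linear fields remain well-posed) confirms each mode solves the bulk
equation to < 1e-5; perturbing β_l by 10% raises the residual above 1e-3,
while re-weighting the two families (which yields a different exact
solution) does not — a deliberate property of the probe. (ii) an
independent Papkovich–Neuber collocation solve of the same boundary-value
problem (tests only) reproduces the tractions to ~1e-9 relative L2, far
inside the 1% test gate.

### Forces and axes

The reported force is ∮ |T_rr| dA over the r₀-sphere by Gauss–Legendre ×
uniform-azimuth quadrature (exact for the band-limited integrand's
polynomial part; resolution ≥ 2·lmax + 2 per dimension). The integral of
the *signed* traction vector must vanish (divergence theorem on ∇·T = 0)
and is returned as a per-bead diagnostic. Because the sign convention of a
"total force" on a sensor is genuinely ambiguous, `compressive`
(∮ max(−T_rr, 0) dA) and `traction_magnitude` (∮ |T·ê_r| dA) variants are
selectable; `abs_radial` is the documented default. The compression axis
is the eigenvector of the degree-2 quadrupole tensor (the symmetric
traceless Q with n̂ᵀQn̂ equal to the degree-2 radius perturbation)
belonging to the most negative eigenvalue, sign-fixed to z ≥ 0.

## Segmentation

The operator chain is the standard Voronoi–Otsu scheme: optional white
top-hat at `background_radius`, Gaussian blur at `spot_sigma` (the expected
object scale), local maxima above the global Otsu threshold as seeds
(separable box maximum filter spanning 2·spot_sigma, then greedy
lexicographic suppression enforcing that euclidean spacing — fully
deterministic, plateau ties included), an Otsu foreground mask on an
`outline_sigma`-blurred copy, and a masked watershed on the
distance-to-seed transform (a geodesic Voronoi partition). Global Otsu is
appropriate for the small-bright-object-over-dark-background regime; voxel
anisotropy is handled by per-axis sigma scaling up to a 1.5× ratio and
rejected beyond it, since strongly anisotropic sampling biases the surface
point distribution that the SH fit relies on.

Defaults: `spot_sigma` 2 µm, `outline_sigma` 0.5 µm. The outline scale
matters: it low-passes the boundary before masking, and 1 µm of blur
already attenuates degree-2 coefficients of a 5 µm object by ~15–20%;
0.5 µm (one voxel at the reference resolution) keeps the attenuation at
the ~1% level.

Sphericity uses ψ = π¹ᐟ³(6V)²ᐟ³/A. The reported volume column is voxel
count × voxel volume, but ψ pairs the area of a marching-cubes
triangulation of the 1-voxel-smoothed binary with the volume enclosed by
that same mesh: marching cubes on a raw binary grid produces stair-step
facets that overestimate area by ~8% (ψ ≈ 0.91 for a perfect sphere),
while the smoothed, self-consistent mesh recovers ψ to better than 1% on
spheres and 1% on 2:1 spheroids. Labels under 8 voxels are flagged
unreliable rather than reported with meaningless surface statistics.

## Fitting, alignment, deformation statistics

Surface points are marching-cubes vertices of the binary label (level 0.5,
physical spacing); the initial center is the voxel centroid. The fit is
linear least squares of the point radii against the real SH design matrix
with a small Tikhonov term (1e-8 on the normal equations) for
conditioning, since marching-cubes points are angularly irregular. A
Nyquist-like guard rejects any fit with (lmax+1)² > n_points, naming the
maximum admissible degree. After the first fit, one recentring step moves
the center by the displacement encoded in the degree-1 dipole (the 3×3
dipole-to-offset map is computed once by quadrature) and refits: l = 1
power of a radius function mostly encodes center offset, and recentring
suppresses it by orders of magnitude. Default degrees: 6 for beads, 9 for
nuclei (≈ micron resolution on ~5 µm objects, 100 coefficients), both
clipped by the guard.

Alignment minimizes c₂,₀ over rotations: the degree-2 coefficients define
the quadrupole tensor Q, whose eigenvector of smallest eigenvalue (most
negative radial perturbation) is mapped to the z axis; the in-plane axis is
sign-canonicalized so the rotation is unique and alignment idempotent.
Rotated coefficients of *all* degrees are obtained by exact quadrature
projection of the rotated radius function (a Gauss–Legendre rule of
sufficient order is exact for band-limited functions, so this equals a
Wigner-D rotation to machine precision). A local post-check verifies no
nearby rotation lowers c₂,₀. Near-spherical shapes (P₂ < 1e-10 µm²) get
the identity rotation and a `degenerate_quadrupole` flag. The deformation
parameter D = |c₂,₀|/c₀,₀ is only defined on aligned expansions and the
API enforces that; D > 0.2 is the conventional strong-deformation
threshold.

## Synthetic phantoms

`fixtures.render_field` emulates fields of fluorescent blobs: star-convex
shapes with c₀,₀ = √(4π)·r₀ and random deformations confined to degrees
2–4, scaled so the maximum radial deviation is a set fraction of r₀
(default 10%, matching the small-strain regime of the elastic model; 20%
is the documented star-convexity limit of the radial parametrization).
Radii default to 4–6 µm at 0.5 µm voxels, intensities vary ±20%, placement
is rejection-sampled with a no-overlap margin, and everything derives from
a single integer seed, bit-reproducibly. Voxelization applies a one-voxel
linear partial-volume ramp at the boundary (avoiding stair-step bias in
surface extraction), and noise is applied last: Gaussian (σ relative to
peak) or Poisson (expected photon count at peak), covering both camera
regimes.

What the phantoms do *not* emulate: point-spread-function blur, spectral
crosstalk, depth-dependent attenuation, anisotropic PSFs, or non-star-convex
shapes. Passing the round-trip tests therefore demonstrates correctness of
the geometry/mechanics chain at realistic voxel sampling and noise, not
robustness to real microscope optics.

## Numerical sizes used in the tests

Test images are 64³–96³ voxels at 0.5 µm with 1–5 objects; the end-to-end
check compares pipeline forces on a 5-bead field against the forward model
applied to the ground-truth coefficients (agreement gate 10%, dominated by
voxelization error of individual coefficients). The collocation
cross-check runs 20 random coefficient sets at lmax = 6. These sizes keep
the full suite under a minute of numerics while exercising every code
path; all tolerances above are asserted in `tests/`.

## Known limitations

- Linear elasticity and small strains: tractions from deformations beyond
  ~10–20% of r₀ are extrapolations.
- The radial-displacement ansatz ignores tangential surface motion; for
  sticky interfaces the inferred tractions are a projection, not the full
  vector field.
- r₀ inference by volume conservation makes purely isotropic stress
  invisible unless an independent undeformed radius is supplied.
- Segmentation assumes bright convex-ish blobs on dark background; dense
  touching clutter is split by the seed spacing heuristic and fused pairs
  must be caught downstream (volume and doublet filters).
- Nuclei have unknown and heterogeneous mechanics: the pipeline
  deliberately refuses to compute forces for nucleus-channel runs and
  reports shape statistics only.
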