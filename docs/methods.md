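# Methods

## Nodal TPMS fields

A triply periodic minimal surface is represented by its nodal
approximation: a sum of trigonometric product terms

φ(r) = Σₖ Aₖ · fₓ(2π nₓ x / L + pₓ) · f_y(·) · f_z(·),

with each axis factor a sine, cosine or the constant 1, integer frequency
multipliers n (so periodicity is exact in floating point) and a physical
cell edge L in mm. Coordinates are always physical: the classical
substitution X = 2πx is implemented as angle = 2π·(mm / cell_size), so one
period equals one `cell_size` for *every* preset — including the
tubular-gyroid units, whose textbook forms are written in raw radians with
period 2π (use `cell_size=2π` to evaluate those forms verbatim).

Presets: P (cos X + cos Y + cos Z), D, G (gyroid), and the two bone units

- `TGab` = 20(cos x sin y + cos y sin z + cos z sin x)
  − 0.5(cos 2x cos 2y + cos 2y cos 2z + cos 2z cos 2x) − 4,
- `TGc` = 10(…) − 2(…) − 12.

The printed trailing constants are stored as constant terms of the sum and
the preset level is 0, so the surface is always {φ = 0}; `constant_part`
exposes them. (Folding them into the level instead would describe the same
surface; keeping them in the sum lets the evaluated field match the printed
expressions number-for-number.)

**Sign convention.** The solid phase is {φ ≤ level}. The nodal forms are
sign-symmetric up to translation, so the choice is a convention, not
physics; this one makes a larger level mean more material for P-like
fields, which in turn makes porosity a monotonically decreasing function of
the level — the property the calibration module relies on.

Grids are sampled at voxel centers (half-voxel inset from the domain
corner) so both domain faces are treated symmetrically; a guard
(`MAX_SAMPLE_VOXELS`, 512³) catches accidental huge allocations.

## Sigmoid blending

φ_sf = α(φ₁ − level₁) + (1−α)(φ₂ − level₂), α = 1/(1+e^(−kG)).

Subtracting the levels before mixing is deliberate: the two units may have
different iso-levels, and blending the raw values would mix incompatible
level sets. The fused field's surface is therefore always {φ_sf = 0}.

The boundary function G may be a plane, a sphere, or a general second-order
polynomial. Note the weight is a *logistic in G*, not a spatial distance
field: where |∇G| is large the transition band is geometrically thinner.
`default_steepness(cell_size) = 2π/cell_size` makes the 10–90 % band of a
unit-gradient boundary span ≈ 0.7 cell, completing the transition within
about one unit cell; k is otherwise free ("the transition gradient can be
adjusted").

n-unit scaffolds are built by an ordered cascade of binary blends; each new
unit occupies the G < 0 side of its own transition. Near triple junctions
the result depends on unit order — documented rather than symmetrized,
since the binary formula is the primitive being composed.

## Meshing

Marching cubes (scikit-image's Lewiner lookup-table implementation, which
resolves the ambiguous cube configurations) triangulates {φ = level} with
vertices linearly interpolated along grid edges. Samples within 10⁻⁶ of the
level (relative to the value range) are nudged off it: crossings that land
exactly on shared grid points otherwise pinch the mesh into degenerate
topology during vertex merging; the nudge moves affected vertices by well
under 10⁻⁴ voxel.

Closed ("capped") solids are produced by padding the volume with one
exterior layer. Where an edge voxel is solid the pad value mirrors it
through the level (2·level − v), which places the interpolated cap exactly
half a voxel out — on the physical face of the sampled box; pore edge
voxels get a value just above the level so no spurious crossings appear.
This guarantees watertightness with no surface/plane intersection code.
Box corners are chamfered at the voxel scale (the cap triangles cut the
corner cell), costing ~0.04 % of the enclosed volume at 64³ and vanishing
with refinement. Normals are oriented outward (positive enclosed volume).

STL I/O writes the standard binary layout (80-byte header, uint32 count,
50-byte facet records) or ASCII; reading validates the byte budget first
and reports the offset at which a truncated file fails. Coordinates
round-trip exactly at single precision.

## Morphometry

All metrics operate on a binary solid mask with isotropic spacing.

**TT / TS** use the Hildebrand–Rüegsegger local thickness: each phase voxel
gets the diameter of the largest sphere contained in the phase that covers
it, and TT (solid) / TS (pore) are the phase-volume-weighted means. Sphere
radii come from the Euclidean distance transform; coverage is painted in
descending radius bins of half a voxel, each bin resolved with one more
distance transform. Quantization error is bounded by the bin width; the
dominant error is the voxelization of the geometry itself (≤ 1 voxel, e.g.
a 0.2 mm slab at 64³ digitizes to 12 voxels = 0.1875 mm and TT returns
exactly that). TS uses 3-D sphere fitting — the standard 3-D
operationalization of the classical 2-D "fitting circle" description.

**Surface S** (for SAD and SMI) is the *open* marching-cubes surface of the
mask after Gaussian smoothing with σ = 1 voxel. The open surface never
closes against the domain box, so the artificial cut faces of spanning
structures are excluded by construction — equivalent to meshing the capped
solid and subtracting the cap area, but with nothing to subtract. The
smoothing removes the voxel staircase so that areas and the dilation
derivative converge to the underlying smooth geometry; it shifts interfaces
by O(σ²·curvature), negligible for features ≳ 5 voxels. One bias remains:
an open face that spans the box only extends to the outermost voxel
centers, (N−1)/N of the physical span per axis (≈ 3 % low on S at 64³,
1.6 % at 128³).

**SAD** = S/BV with BV the voxel-count solid volume (the classical BS/BV);
S per total volume is reported alongside.

**SMI** = 6·V·S′/S², with S′ the central-difference derivative of the mesh
area under a ±ε offset of every vertex along its outward normal,
ε = half a voxel. Flat plates offset to equal area (S′ = 0 → SMI 0); a
cylinder of radius R has S′ = dS/dR = 2πL (SMI 3); a sphere 8πR (SMI 4).
Measured at 128³: slab 0.000, spanning rod 2.999, interior sphere 3.995.
ε is configurable; half a voxel balances discretization noise (small ε)
against curvature nonlinearity (large ε).

## Mechanics

Gray → density is affine through two calibration points (negative
extrapolations clamp to zero); density → modulus is the piecewise power law
above, applied exactly as calibrated — its two branches disagree by ~1 % at
the 1.68 g/cm³ branch point (≈ 14 839 vs 14 647 MPa) and the branch point
itself takes the ≤ branch. Density units are g/cm³, the convention of this
calibration family. The floor rule then maps every voxel at E ≤ 5 MPa to
exactly 0.01 MPa, so pore space carries a near-air stiffness instead of
creating a singular system.

The solver meshes one trilinear hexahedral element per voxel (2×2×2 Gauss
quadrature, per-element modulus, shared Poisson ratio) and never assembles
the global matrix: the element stiffness for unit modulus is computed once
and matrix-vector products gather/scale/scatter over elements, solved with
Jacobi-preconditioned conjugate gradients (relative residual 10⁻⁸,
iteration cap 2000·∛n_voxels). Voxel hexahedra on desk-scale grids (≤ 64³)
replace unstructured tetrahedra at equal physics and a fraction of the
cost.

Boundary conditions for direction d: the min-d face is fully clamped, the
max-d face receives a uniform compressive normal displacement of
strain·span with tangential motion free (a `clamp_loaded` switch fully
clamps it instead), lateral faces are traction-free. "1 % compressive
strain" is displacement control, strain 0.01 by default. The apparent
modulus is (reaction force / apparent cross-section) / strain; mean von
Mises (from the element-centroid stress tensor) is averaged over structural
voxels (E > 0.01 MPa).

With ν = 0 these BCs reproduce the uniaxial closed forms exactly (uniform
block → E_app = E and mean von Mises = strain·E; series laminate → harmonic
mean), which is how the solver is validated; at ν > 0 the clamped face
induces genuine end effects (a uniform block reads ~3 % stiff at 16³), so
identity checks at ν = 0 are the meaningful ones.

## Calibration

Porosity and apparent modulus both respond monotonically to the level
constant (porosity exactly so, by the sign convention), so plain bisection
is used: each modulus evaluation is a full FE solve — expensive,
noise-free, but discretization-stepped, conditions where bracketing is more
robust than gradients. Defaults: porosity tolerance 0.005, modulus 2 %
relative; modulus searches run at 32³ with an optional finer verification
pass. A non-straddling bracket triggers a coarse grid scan for a sign
change (with a warning) before failing.

The alternative free parameter `amplitude_scale` multiplies only the
*oscillatory* term amplitudes: scaling the folded constant terms too would
rescale the whole field and leave the zero level set — hence the geometry —
unchanged.

## Phantoms

Binary phantoms (slab, slab array, cylinder, sphere, gyroid block) are
voxelized by center-inclusion, so the stored ground truth (porosity, TT,
TS, SAD, SMI) is exact for the analytic shape at any resolution; all
discretization error lives in the measurement, cleanly separable from the
geometry. `render_grayscale` layers imaging realism on top — two-level gray
assignment, Gaussian blur, additive Gaussian noise under an explicit seed —
emulating reconstructed micro-CT slices. It does not model beam hardening,
ring artifacts or anisotropic point-spread, and no phantom imitates real
trabecular disorder: passing tests demonstrate correctness of the metrics
and solver on known geometry, not segmentation robustness on clinical data.

`make_gradient_demo` exercises the full chain (fields → blend → mesh →
morphometry): three unit cells along x with the finer TGc unit fused into
the middle third through plane transitions (or a spherical core), yielding
a watertight graded scaffold whose slab-wise porosity profile is
non-constant and symmetric.

## Problem sizes and limitations

Default test and benchmark sizes are chosen for interactive turnaround:
morphometry at 64³–128³, homogenization at 12³–32³, meshing at 32³–64³.
Known limitations: thickness metrics require isotropic voxels; SMI needs
features of ≳ 5 voxels for the smoothing and dilation steps to sit in their
asymptotic regime; the FE solver is small-strain linear elasticity with no
damage or contact; cascade blending is order-dependent near triple
junctions; and the morphometry surface carries the (N−1)/N open-face bias
described above.
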