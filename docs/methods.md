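# Methods

This note documents the models and numerical choices behind `lapcell`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and known limitations.

## Conventions

Stacks are indexed `(x, y, z)` with 0-based voxel indices; the physical
position of a voxel is its index times the spacing (µm).  Intensities are
normalized to [0, 1] on load, and all intensity-domain parameters (σ_I, τ,
noise levels) are expressed in these normalized units.  Mesh vertices live
in physical µm coordinates.

## Segmentation

The random walker assigns each unseeded voxel the probability that a random
walk on the affinity-weighted voxel graph reaches a foreground seed first;
equivalently the probabilities are the harmonic extension of the seed
labels, obtained from the sparse SPD system L_U x_U = −Bᵀ x_M.  Affinities
are exp(−‖ΔS‖²/σ_S − ΔI²/σ_I) on the 6-connected grid (26 available).
Defaults: σ_S = 1 voxel², σ_I = 0.01 normalized units².  σ_I is the
parameter that matters: it sets the intensity contrast at which edges cut
the graph (0.01 corresponds to a ~0.1 intensity step suppressing a weight
by e⁻¹).  Spatial distances use voxel-index units by default because the
4× x/y downsampling makes the grid near-isotropic for the stack geometries
this tool targets (e.g. 0.16×0.16×0.5 µm voxels); a flag switches to
physical distances.

The system is solved by ILU-preconditioned conjugate gradients at relative
tolerance 1e−10 (direct sparse LU below 20 000 unknowns).  The tolerance is
deliberately tight: the downstream argmax is sensitive to sub-1e-8 errors
only in pathological ties, but the tight default makes the sparse solution
indistinguishable from dense linear algebra in tests.  Probabilities are
clipped to [0, 1]; the discrete maximum principle guarantees the exact
solution lies there already.

### Automatic seeding

The saliency map is the spectral residual of the downsampled stack: the
log-amplitude spectrum is smoothed with a Gaussian (σ = 2 voxels, periodic
boundary — the natural choice in the Fourier domain, and what makes the map
exactly equivariant to circular shifts), recombined with the original
phase, inverse-transformed, squared, and smoothed again.  The first
threshold level selects strongly salient voxels (mean + 2 std) as candidate
foreground and weakly salient ones (mean + std) as candidate background,
with strict inequalities, so a constant saliency map correctly produces a
no-seed error.  The second level thresholds the image intensities against
the mean of the salient-region intensities (foreground) and mean + 2 std of
the background-region intensities.  If the two second-level sets overlap,
the ambiguous voxels seed neither class.

Two refinements proved necessary for boundary accuracy on membrane-stained
cells and are part of the method:

* the foreground seed mask is eroded once (3³ structuring element) on the
  downsampled grid.  Blocks that straddle the blurred cell boundary
  otherwise become foreground seeds whose upsampled footprint anchors the
  walker outside the cell;
* the seed statistics μ_seed and τ used by the upsampling weight are
  computed by re-applying the second-level thresholds to the
  full-resolution image.  The weight compares original-resolution
  intensities with μ_seed, so estimating μ from downsample-smeared block
  values biases it towards the interior and widens τ until the weight loses
  its edge-stopping power.

An Otsu-based replacement for the first threshold level is available behind
a flag and gives similar seeds on the synthetic suite.

### Edge-preserved upsampling

The downsampled probability is cubically interpolated to the full grid and
re-weighted per class: q^c = w(I − μ^c_seed)·p^c + η with the
Tukey-biweight-style weight w(d) = (1 − (d/τ)²)² for |d| ≤ τ, else 0.
Defaults: η = 1e−3; τ_c = 2·std of the class-c seed intensities (floored at
1e−6).  The voxel label is argmax over the two class scores.  When both
weights vanish (intensity far from both seed means — typically the dim
interior of a membrane-stained cell, or the blur halo just outside), the
scores tie at η exactly; the tie falls back to the random-walker argmax,
and a residual tie at p = 0.5 is labelled background.  Labelling all
ties background instead would hollow out any cell whose interior intensity
approaches the background, which is precisely the regime this tool is for.
A variant that averages the interpolated probability over the voxel
neighbourhood is available (`neighbor_probabilities`); the default uses the
per-voxel probability.

Cleanup is a 3³ morphological close followed by retention of the largest
26-connected component.

### What segmentation accuracy means here

On the synthetic suite, the degraded condition (Gaussian noise σ = 0.1,
interior dimmed to 0.5 of the membrane intensity, 1-voxel PSF blur) yields
mean F ≈ 0.96; the ideal-imaging control (no noise, no blur) reaches
F ≈ 0.999.  With a 1-voxel blur the position of the true boundary inside
the blurred transition is ambiguous at the half-voxel level, which caps any
intensity-driven labelling around F ≈ 0.95–0.97 on these cell sizes; the
control separates algorithmic error from that irreducible ambiguity.

## Topology fixing

Spherical (genus-zero) topology is required by the spherical
parameterization.  The predicate used everywhere: exactly one 26-connected
foreground component, exactly one 6-connected background component
(border-connected, so cavities fail), and Euler–Poincaré characteristic
χ = 1 of the cubical complex (vertices − edges + faces − cells of the union
of closed unit voxel cubes, computed by OR-reductions over incident voxel
blocks).  The 26/6 pair is the standard complementary connectivity choice.

The embedding function f minimizes the Dirichlet energy ½fᵀLf on the
unit-weight 6-connected grid Laplacian subject to box constraints
v·f ≥ m, where m is the exact Euclidean distance to the set of boundary
voxels (voxels of either phase with a 6-neighbour of the opposite phase).
The margins keep the solution away from the trivial f ≡ 0.  The solver is
a damped projected Jacobi iteration f ← clamp(λ·D⁻¹Cf + (1−λ)f, l, h) with
C = D − L the adjacency part — each step moves towards the neighbour
average and projects onto the feasible box.  Iterations run only on the
narrow band m < t (default t = 3 voxels); outside the band f is frozen at
v·m.  Defaults: λ = 0.5, tolerance 1e−6 on the max per-voxel change,
max 5000 iterations.  The tolerance is tighter than the repair step needs;
it is chosen so the iterate's energy matches a reference box-constrained QP
solution to well below 1e−4 relative.

Repair proceeds in three stages.  (1) The core {f ≥ level} is marched from
level 1.5 upwards in steps of 0.5 until spherical — high level sets erode
thin protrusions first because their margins are small.  (2) The core is
dilated with a (t+1)³ box; connected components of the volume minus the
dilation are the protrusions, the remainder is the spherical body.  The
subtraction also produces small benign residues of the (even-sized,
therefore slightly asymmetric) box dilation; they are harmless false
positives that merge straight back.  (3) Protrusions are merged back in
descending size order (deterministic); each merge that preserves the
predicate is accepted.  Every remaining ill protrusion is embedded on its
own padded bounding box and expanded through decreasing level sets
(−0.1, −0.2, …) until the expansion merged into the accepted volume is
spherical — the expansion fills the tunnel a crossing pair of filopodia
encloses.  The output is always a voxel-wise superset of the input (of its
largest component when the input is disconnected), and a genus-zero input
is returned bitwise unchanged, which also makes the operation idempotent.
Inputs whose defect is a cavity rather than a handle have no spherical
level set and raise an explicit unfixable-topology error.

On the synthetic handle suite (20 cells, 1–6 handles) the repair succeeds
on all volumes and changes 0.3–1% of the voxels.

## Spherical parameterization

The voxel boundary is extracted as quads (split along a fixed diagonal for
determinism, outward orientation) with vertices at lattice corners.
Diagonal voxel contacts make the quad surface non-manifold; a pre-pass
thickens the mask by the minimal voxel set — one voxel per edge-contact
plaquette, per lone antipodal foreground pair, and per background pinch —
followed by a mesh-checked fallback that fills one voxel at any remaining
pinch vertex.  All additions are logged.  The result must be a closed
2-manifold with χ = 2.

Latitude solves the Laplace equation on the unit-weight surface graph with
θ = 0 at the north pole and π at the south pole (the stationary temperature
distribution with the poles held at fixed temperatures); by the discrete
maximum principle all other vertices lie strictly inside (0, π).  Poles are
the two extreme vertices along the principal axis of the vertex cloud.
Longitude solves the same equation with the date line — the shortest edge
path between the poles — pinned at φ = 0 and a +2π offset on every edge
that crosses the cut from the west bank, identified from the oriented
one-ring of each date-line vertex.  The bank convention is chosen so the
resulting map is orientation-preserving.  Pinning the date line
over-constrains it slightly; the subsequent optimization relaxes this.

Area relaxation minimizes Σ_faces (spherical_area/4π − surface_area/total)²
by moving each non-pole vertex towards the spherical centroids of incident
faces that map too large and away from those too small, with a global
step-halving line search that accepts a sweep only if the cost decreases
and the number of orientation-flipped spherical triangles does not
increase.  A local untangling pre-pass smooths only the vertices of flipped
triangles (smoothing everything would distort the valid majority).  On the
voxel-ball fixture the initialization is already flip-free and the
relaxation removes two thirds of the area distortion; zero flips and exact
4π total signed area are the bijectivity proxies asserted in tests.  This
local relaxation is a deliberate simplification of the full local/global
smoothing scheme of the constrained-area-distortion literature; it keeps
the accept-only-improving guarantee and is sufficient for the equiareal
quality the SPHARM stage needs.

## SPHARM representation

Real orthonormal spherical harmonics are used so that coefficients of real
coordinates stay real; the complex convention is a documented conversion
(m > 0: √2·(−1)^m Re Y_l^m; m < 0: √2·(−1)^m Im Y_l^|m|).  Coefficients
are estimated jointly for x, y, z by a QR-based least-squares solve of the
design matrix of basis values at the parameterized vertices; an
underdetermined system (< (L+1)² vertices) is an error, and a
rank-deficient design matrix (possible when the equiareal map concentrates
samples) falls back to a Tikhonov-regularized solve (λ = 1e−8) with a
warning.  Degree 42 (5547 coefficients) is the default for typical cell
shapes; reconstruction resamples the model on a level-4 subdivided
icosahedron (10·4⁴+2 = 10242 vertices) by default.  Representation error
is the RMSE over corresponding parameter pairs,
√(Σ‖M(p_i) − M̃(p_i)‖²/N); because lower-degree fits are nested
subproblems, RMSE at the fitting vertices is non-increasing in the degree.

## Shape comparison

Correspondence between time points is by equal (θ, φ); no registration is
applied (a hook accepts externally registered meshes).  The deformation map
projects the displacement between corresponding points onto the outward
normal of the earlier surface, computed analytically from the series
tangents ∂p/∂θ × ∂p/∂φ (central differences, h = 1e−5; degenerate pole
points fall back to mesh normals): positive values are protrusions,
negative retractions.  A plain Euclidean variant exists.  Coefficient time
series report per-frame Euclidean norms of the (c^x, c^y, c^z) triplet for
selected (l, m); phase detection is exposed only as the raw series plus a
largest-first-difference change-point flag.

## Synthetic-data generator

The generator emulates the degradations that make real membrane-stained
stacks hard: intensity concentrated on a 2-voxel membrane shell with the
interior dimmed towards background (`interior_dimming`, default 0.5, in
[0,1]), Gaussian PSF blur (default σ = 1 voxel), additive Gaussian noise
(default σ = 0.1 normalized units), thin straight protrusions, and
handle-forming arcs (quadratic-Bezier bridges anchored on the body, the
voxelized analogue of crossing filopodia fused at both ends).  Ground truth
is exact by construction: each protrusion/arc placement is rejection-
sampled until the Euler characteristic and both connectivities confirm the
intended genus, so a spec with n handles always yields χ = 1 − n.  Default
body radii (16, 14, 12 voxels) put cells at a scale where a handle repair
touches well under 2% of the volume, matching the thin-protrusion regime
the pipeline targets.  With blur and noise disabled the image is exactly
three-valued and Otsu's threshold recovers the mask bitwise — the clean
control used to separate algorithmic error from imaging ambiguity.

Not emulated: a realistic (anisotropic, Airy) PSF, Poisson photon
statistics, multi-cell fields of view, intensity drift over time.  Passing
the synthetic suite therefore demonstrates correctness of the machinery
under controlled degradations, not performance parity on any particular
microscope's data.

## Problem sizes

The test and acceptance runs use cells of ~58³ voxels (≈12 000 foreground
voxels, surfaces of ~4000–4500 vertices), 20-volume topology suites,
10-cell segmentation suites, and degree-42 fits on ~4000-vertex meshes —
sizes chosen so the full suite completes in about a minute on one CPU while
every stage still operates in its intended regime.

## Known limitations

* Genus-zero objects only; cavities are detected but not filled.
* Two classes (cell/background); no multi-label walker.
* The equiareal relaxation is local and accept-only; strongly elongated
  shapes retain more area distortion than a full local/global scheme would.
* Frames are processed independently; no temporal propagation.
* Very thin (1-voxel) protrusions can be lost at the 4× downsampling, the
  same regime real acquisitions struggle with.
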