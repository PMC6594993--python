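# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the package. It complements the README, which
sketches the pipeline; here the emphasis is on *why* things are the way
they are.

## Coordinate and unit conventions

SWC coordinates and radii are stored in voxel units of the associated
image. Volumes are numpy arrays indexed `[z, y, x]` (z-major, matching
TIFF page order); positions are `(x, y, z)` vectors. A node at position
p is the center of voxel `round(p)`, and voxel `v` spans `[v−0.5, v+0.5]`
per axis. Anisotropy enters in exactly one place: physical distances
multiply per-axis differences by the `voxel_aspect` triple before taking
the norm. `read_swc` defaults to the 1:1:2 x:y:z convention for stacks of
unknown voxel size (axial sampling of fluorescence stacks is typically
about half the lateral resolution); programmatic tree construction and
the simulator default to isotropic 1:1:1, which is what all synthetic
phantoms use. Inside the tracer, steps, scales and template coordinates
are in voxel units, consistent with parameters being specified in voxels;
the Hessian and the erosion/smoothing kernels divide their axial extent
by the z-aspect.

## Image formation model

The simulator deliberately omits a point-spread function: for
single-neuron stacks the voxel size normally exceeds the PSF, so
digitization (partial volume) dominates optical blur. Each parent–child
edge is rendered as a linearly tapered capsule — radius interpolated
along the edge, hemispherical caps — matching the SWC convention of
per-node radii; the solid model is a package choice since no standard
exists. Occupancy is the fraction of a `supersample`³ subgrid of each
voxel falling inside the capsule union (default supersample 2; error for
a radius-0.5 sphere is below 0.05 at supersample 4).

Noise is Poisson. SNR is defined as the mean intensity inside the neuron
above background divided by the noise standard deviation inside,
(λ_f − λ_b)/√λ_f under the Poisson model, so the foreground expectation
solving a target SNR is √λ_f = (SNR + √(SNR² + 4λ_b))/2. The background
level defaults to 10 expected photons: a nonzero background keeps this
equation well-posed and is realistic for fluorescence imaging.

Inter-voxel correlation (COR) is produced by Gaussian smoothing of the
noisy volume at scale `cor` voxels (divided by the z-aspect axially).
Smoothing attenuates iid noise by the factor f = √(∏_axes Σk²) of the
separable kernel while leaving interior means unchanged, which would
silently *raise* the measured SNR. Because the SNR statistic is invariant
under any affine intensity rescaling, no post-hoc linear rescale can undo
that; instead the foreground level is pre-compensated by solving the
photon equation for target `snr × f`. The delivered measured SNR then
matches the request exactly for cor = 0 and to within a few percent for
moderate COR on thick structures; for large COR on thin branches the
residual partial-volume variation inside the foreground biases the
measurement low (≈ 25% at COR 2 on a radius-8 cylinder). Output is
min–max scaled to 8 bits; the SNR statistic is unaffected by that choice.

## Soma model

Erosion with half-width r_s (axially divided by the z-aspect, minimum 1)
must exceed the largest branch radius and stay below the soma radius;
r_s = 0 disables detection for arbor-only data. The Kapur threshold
maximizes the sum of Shannon entropies of the two histogram partitions,
ties broken toward the lower bin. The soma radius statistic is the mean
voxel-to-centroid distance, which for an ideal ball of radius R is 3R/4.

Absence of a soma is not defined by the original procedure, so the
package decides it with three guards: (1) the blob's fitted radius must
reach r_s (a genuine soma exceeds branch scale by construction of r_s);
(2) the eroded-and-smoothed field must keep relative contrast (peak
above 1.5× its median) — erosion of an arbor-only stack leaves only a
homogeneous noise floor; (3) the blob must be bright in the *original*
image (mean ≥ median + 0.25 × (max − median)), which rejects blobs carved
out of smoothed background noise. Without guards (2)–(3), max-entropy
thresholding of a near-flat field regularly produced large spurious
"somas" on soma-less stacks, and a false root badly distorts the final
tree.

## Tubularity and seeds

Second derivatives are computed by separable Gaussian-derivative
filtering and multiplied by σ² (γ-normalization) for cross-scale
comparability. Eigenvalues are sorted by absolute value; the axial
direction is the eigenvector of the smallest-|λ| eigenvalue,
sign-normalized to non-negative z (then y, then x) since branch
directions are axial. S uses √(λ₁²+λ₂²) as specified for this filter
variant; a `use_frobenius` switch provides the classic three-eigenvalue
norm. The structureness constant is c = ½ × max S computed **globally
over the scale set**, not per scale: with a per-scale c the third
vesselness factor becomes scale-relative (υ is then invariant to
γ-normalization entirely), and on noisy thin branches the per-voxel scale
argmax flips to oversized scales whose mismatched templates subsequently
fail the correlation gate. A global c keeps the factors commensurable and
selects σ ≈ branch radius reliably.

Local maxima follow the ImageJ find-maxima semantics generalized to 3D
(26-connectivity): candidates are processed in decreasing value on the
8-bit-scaled map, and a candidate survives unless the region reachable
without descending more than τ below its value touches a higher
already-claimed maximum. Non-maximum suppression uses each candidate's
own oriented cylinder (radius 3σ, total length σ, i.e. half-length σ/2),
ties broken toward the lexicographically smallest position. Surviving
candidates are kept only if their cylindrical-template correlation
reaches c_min — the same threshold that terminates tracing.

## The particle filter

Defaults (N = 20, κ = 3, d = 3, ζ = 1, K = 20, c_min = 0.5, L = 200,
δ₉ = 4, r_g = 2, scales {2, 4, 6}, τ = 10, r_s = 6) are the method's
standard operating point; all are exposed in `PnrConfig`.

The transition prior is sampled directly — a 3D von Mises–Fisher
direction about the previous direction (closed-form inverse CDF for the
axial cosine), a Gaussian step length about d with std d/3 truncated to
(0, 2d] via inverse-CDF, and a Gaussian scale step with std ζ truncated
to |Δσ| ≤ 3ζ — so the normalization constants (η, I₀(κ)) are never
needed; the transition density used in the weight update is evaluated up
to a constant, which cancels in renormalization. The scale-truncation is
read as a bound on the *change* |σᵢ − σᵢ₋₁| ≤ 3ζ: an absolute cap of 3
voxels would contradict the multi-scale design. σ is clamped to
[0.25, max(scales) + 3ζ] to keep templates well-posed; the clamp slightly
distorts the truncated-Gaussian tails at the boundary.

The template is Gaussian across the axis, G(k, l) = e^(−(k²+l²)/2σ²),
constant along it; k, l span ⌊−3σ⌋…⌈3σ⌉ and the axial band is symmetric,
⌊−σ⌋…⌈σ⌉, so the template is centered on the node. The local frame is
u = normalize(v × ẑ) (x̂ when |v·ẑ| > 0.9), w = v × u — deterministic and
smooth except on that switch set. Image sampling is trilinear with border
replication. A constant patch returns correlation 0.

Per iteration the loop is predict → weight update
(w ∝ w_prev · p(x|x_prev) · e^{Kc}, computed in log space) → systematic
resampling when ESS = 1/Σw² < 0.8 N → posterior centroid. Correlations
travel with the particles through resampling, and the termination
statistic Σc/N is the unweighted mean over the *current* (post-resample)
set. This ordering matters: the raw proposal cloud of a κ = 3 / ζ = 1
prior contains many off-structure particles, and its mean correlation
sits below 0.5 even on noise-free cylinders; after resampling the
surviving population tracks the branch and the statistic behaves as a
branch-end detector. The direction estimate is the normalized weighted
mean of particle directions, falling back to the previous direction when
the spread is degenerate.

Each seed is traced along +v and −v. A trace that survives its first
iteration emits the seed state itself as its first node, so the two
opposite traces of one seed share a point — otherwise the first nodes of
the two half-traces sit up to 2d = 6 voxels apart and grouping at
r_g = 2 would disconnect them. With L = 0 a trace is empty. The node
density grid counts emitted nodes per voxel; the density in an in-plane
neighborhood of n voxels (n ∈ {1, 5, 9}; in-plane because stacks are
typically z-anisotropic) is checked *before* appending, and tracing stops
once it exceeds δₙ.

## Merging and tree construction

Traces are resampled to one-voxel spacing (radii and correlations
linearly interpolated) before mean-shifting. Mean-shift is synchronous
(Jacobi-style): all updates within an iteration use the previous
iteration's values; the flat kernel radius is each node's *initial*
radius and five iterations are used. Grouping is greedy in decreasing
correlation (ties toward the lower index) with the fixed radius r_g, and
produces a partition whose projected links preserve connectivity.

The BFS root is the soma when found — group nodes whose center lies
within (soma radius + node radius) of the soma center attach to it — or
otherwise the highest-correlation group. Cycle-closing edges are dropped;
unvisited components of at least `min_component` = 3 groups are emitted
as extra roots (the size cutoff is a package choice; discarding isolated
branches is presented as optional in the procedure, so pruning of
single-node terminal branches is on by default behind a flag).

## Determinism

All randomness flows from one `numpy.random.Generator` seeded by the
configuration. Candidate orderings, tie-breaks and adjacency traversals
are explicitly sorted, so two runs with the same volume, configuration
and seed produce byte-identical SWC files.

## What the synthetic data do and do not show

The generator reproduces the study conditions — SNR ∈ {1, 2, 3, 4, 5,
10, 20}, COR ∈ {0, 0.5, 1, 1.5, 2}, Poisson noise, partial-volume
rendering of SWC ground truth (`synthetic_grid()` enumerates the
10 × 7 × 5 = 350-stack design). Test phantoms are small (straight
cylinders, one bifurcation, a helix) so the full suite runs in minutes on
one CPU; the end-to-end robustness check reconstructs a bifurcating
phantom in a 64×64×16 volume, five replicates per SNR level. Passing
these tests demonstrates correct mechanics and the expected SNR response,
but not performance on real stacks: real data add uneven staining,
overlapping arbors, anisotropic PSF residues, autofluorescence and
gigavoxel volumes, none of which the phantoms contain. The metrics module
and CLI accept real TIFF/SWC pairs unchanged.

## Known limitations

- Single neuron per stack; no multi-soma segmentation.
- The soma is a single sphere; very aspherical somas are summarized
  coarsely.
- The tracer is single-branch: bifurcations are recovered through
  redundant multi-seed coverage, not through branching-aware filtering.
- SNR preservation under COR smoothing is exact only away from thin
  structures (see image formation above).
- `find_maxima_3d` floods on the 8-bit-scaled map; extremely flat
  tubularity ridges can merge into few seeds, which the density-limited
  bidirectional tracing compensates on phantoms but may under-seed very
  long, very uniform branches.
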