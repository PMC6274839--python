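# Methods

## Model and procedure

The object of analysis is the axis of a two-chain parallel coiled-coil,
treated as an inextensible elastic filament (worm-like chain). Per frame,
the axis is a polygon: weighted Cα centroids of endpoint-sharing segments
per chain, midpoints across chains as vertices, unit inter-vertex vectors
as tangents. With the default scheme the analysed span is residues
106–216, partitioned into eleven 11-residue segments (106–116, 116–126,
…, 206–216); terminal residues of each segment carry weight 0.5 so that
consecutive segments share one residue and each covers about three
helical turns. Eleven vertices give ten tangent positions.

The tangent-correlation statistic is c(s) = ⟨(t(s), ⟨t(s)⟩)⟩ with ⟨t(s)⟩
the *normalised* time-mean tangent at that position. Algebraically c(s)
equals the norm of the unnormalised mean tangent, so it is 1 for a rigid
chain and decays as exp(−s/Lp) for a Kratky–Porod chain whose body frame
is anchored at the chain start. Using the per-position mean instead of
the frame-wise first tangent is what makes the statistic valid for
intrinsically curved filaments: for a curved Kratky–Porod chain
E[t_i] = ⟨cos θ⟩^(i−1) R^(i−1) t_0 (R the deterministic per-joint
rotation), whose *norm* still decays as ⟨cos θ⟩^(i−1) — the curvature
drops out — while the straight-rod statistic picks up an extra
cos((i−1)α) factor and underestimates Lp severely (by ~3.5× at 5°/joint
over ten joints).

The arc-length coordinate of tangent *i* is the cumulative time-mean
vertex spacing from tangent 0 (s_0 = 0), giving one fixed abscissa per
ensemble. Where the origin sits is a convention; both estimators use
only differences or a free intercept, so the choice does not affect Lp.

Two estimators are exposed: ordinary least squares of ln c on s (free
intercept by default — the exponential law forces the line through the
origin, but a free intercept absorbs constant offsets from the anchoring
convention without changing the slope's meaning; a flag restores the
through-origin fit) and the secant through the first and last points.
Slopes shallower than 1e−12 /nm are reported as Lp = ∞ (rigid) rather
than a meaningless huge number. Stiffness is k = Lp·k_B·T with
k_B = 1.380649e−23 J/K; temperature is a required input of the
conversion, never inferred.

## Body frame, superposition, anchoring

The time-mean tangent is only meaningful in a body-fixed frame. The
pipeline removes rigid-body motion by least-squares superposition of the
selected Cα atoms onto an iteratively refined mean structure (two passes;
proper rotations only). A subtlety follows: superposing onto the *mean*
structure distributes orientational variance symmetrically over the span,
which flattens — and can invert — the decay of c(s). The decaying form
assumes fluctuations accumulate *along* the chain, i.e. a body frame
anchored at the start. The pipeline therefore re-anchors after
superposition: each frame's tangent set is rotated (minimal rotation) so
its first tangent coincides with the time mean of first tangents. For
generator output, whose first tangent is clamped to +z by construction,
anchoring is the identity. On clamped ground truth the
superpose-then-anchor path and the direct body-fixed path agree to within
sampling error (~1% at 500 frames in the recovery tests). Absolute c
values still depend on this convention, so cross-study comparisons should
compare slopes, not intercepts.

Uncertainty uses block averaging with 8 contiguous blocks by default
(1000 frames per block at the 8000-frame scale): snapshots saved every
10 ps are strongly autocorrelated, and a naive SEM over frames would
understate the error. Block-wise Lp estimates (profile and fit
recomputed per block) are the replicate unit for the two-tailed,
equal-variance Student's t-test used to compare conditions; the choice of
replicate unit is a design decision, since correlated time series admit
no uniquely correct one.

The local-slope (central difference of ln c) flexibility profile maps
each interior tangent position to the residue interval spanned by its
flanking segment centres; the steepest slope marks the most flexible
region, reported in "residues lo–hi" form.

## Hydrogen bonds

Only backbone amide-to-carbonyl bonds are counted: donor N to acceptor O
distance ≤ 0.35 nm and, when an amide hydrogen exists, H–N···O angle
≤ 30° — the common geometric convention in MD analysis; both cutoffs are
configurable because published counts rarely state their criterion.
Pairs closer than two residues within a chain are excluded; inter-chain
backbone bonds are included. A bond belongs to the region containing its
*donor* residue (a rule is needed for bonds straddling a boundary), and
regions may be disjoint interval unions. Donors lacking a hydrogen fall
back to the distance criterion unless `require_hydrogen` is set; note
that on an ideal helix the distance cutoff alone also admits i→i−3 and
i→i−2 pairs, so hydrogen-aware counting is strongly preferred and the
synthetic backbone places amide hydrogens for this reason.

## Synthetic generator

The generator emulates the analysed system's shape: two parallel chains,
residues 106–216, ~8000 frames, helix axes 0.49 nm from the coiled-coil
axis (inter-helix distance ~0.98 nm), ~0.1485 nm axial rise per residue,
with tunable stiffness, optional intrinsic per-joint curvature, and an
optional softened joint.

Joint angles are drawn from the exact discrete Kratky–Porod equilibrium
density p(θ) ∝ exp(−(Lp/b)(1 − cos θ)) sin θ by closed-form inverse CDF
in cos θ, written in a form stable at large stiffness; no small-angle
Gaussian approximation is made, so softened (large-angle) joints are
sampled correctly. Azimuths are uniform; frames are independent
equilibrium draws (no simulated dynamics), which makes recovery tests
sharp but means the generator does not emulate the *autocorrelation* of
real trajectories — block-averaged error bars on real data measure
something the synthetic tests cannot exercise. The default segment
length b = 1.5 nm matches the polygon spacing of the default scheme
(10 residues per vertex step × ~0.15 nm rise). The discrete chain's
effective persistence length, −b/ln⟨cos θ⟩, deviates from the nominal Lp
by under 3% at the softest setting tested (Lp = 30 nm), well inside the
10% recovery tolerance.

The pseudo-atomic builder constructs a straight ideal α-helix backbone
from standard internal coordinates (φ = −57°, ψ = −47°, ω = 180°) by
natural-extension-reference-frame placement, orients its axis by the
second-difference construction (exact for an ideal helix), places chain B
as chain A rotated 180° about the shared axis — so segment-centroid
midpoints fall *exactly* on the axis by symmetry — and bends the template
along a natural cubic spline through the worm-like-chain vertices using a
parallel-transported normal frame (grid step 0.05 nm, re-orthogonalised
at each step). Axial coordinates are mapped to arc length at b/10 per
residue, a ~4% compression of the template's natural rise that preserves
the full i→i−4 hydrogen-bond ladder (checked: 16 bonds on a 20-residue
helix, n−4 in general). The builder does not attempt real sequence, side
chains, supercoiling of the two helices about each other, or force-field
physics; it exists to give the pipeline inputs with known stiffness and
an intact hydrogen-bond ladder.

Reconstruction accuracy at the default geometry: polygon vertices land
within 0.05 nm of the sampled centerline and tangents within a few
degrees of the sampled tangents (exact for a rigid straight build).

## Numerical choices and degenerate inputs

- Coordinates are nm internally; PDB Å convert on read/write. Residue
  intervals are inclusive, author numbering.
- Rigid profiles (all c = 1) short-circuit to Lp = ∞; non-positive c
  makes the log-linear fit undefined and raises (disorder beyond the
  model) rather than silently dropping points.
- A vanishing mean tangent (|Σ t| < 1e−9·N) raises "fully disordered".
- Ties in the flexibility argmin resolve to the lowest index
  (numpy argmin); coincident polygon vertices raise.
- The comparison report asserts its own self-consistency (displayed
  ratios recomputable from the stored Lp columns) and display rounding is
  ratios to 2 decimals, percent changes to the nearest percent, Lp to one
  decimal; JSON artifacts keep full precision.
- Problem sizes in the validation suite: 8000-frame tangent ensembles for
  estimator statistics (matching the analysis scale), a few hundred
  frames for pseudo-atomic pipeline runs, which is where coordinate
  construction and hydrogen-bond counting dominate cost.

## Known limitations

- The Eq.-style correlation is computed in a chosen body frame; absolute
  c values (not slopes) depend on that convention.
- Hydrogen-bond counts depend on the geometric criterion; defaults follow
  the common convention but cannot be guaranteed to match any particular
  published counting tool.
- The generator's frames are uncorrelated in time; autocorrelation-driven
  error inflation on real trajectories is handled by block averaging but
  not emulated synthetically.
- No torsional or stretching stiffness, no anisotropic bending, no
  helical-parameter (pitch/phase) analysis, no binary trajectory formats
  in the core reader (multi-model PDB and the TSV table only).
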