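# Methods

`fibrograd` couples a forward model of ventricular electrical activation in
fibrotic tissue to an inverse procedure that estimates how much fibrosis
sits in each segment of the wall, using only two features of unipolar
surface electrograms: local activation times (LAT) and peak-to-peak
amplitudes (PtP).

## Forward model

### Tissue and fibrosis

The domain is a regular voxel grid (node position = index × `dr`,
`dr = 0.1` model space units).  Two synthetic geometries are built by
`fibrograd.geometry`: a rectangular slab whose z-min/z-max faces play the
roles of endocardium and epicardium, and a truncated half-ellipsoid
left-ventricle shell with the long axis along +Z and the base parallel to
the XY plane.  Transmural depth is computed as
`d_endo / (d_endo + d_epi)` from Euclidean distance transforms to the two
surface node sets — resolution-robust and monotone across the wall.  LV
fibers follow a linear helix-angle rule (default −60° at the endocardium
to +60° at the epicardium, rotating the local circumferential direction
toward the long axis); the midwall fiber is purely circumferential.

Fibrosis is *non-conductive node knockout*: a node with local density `D`
is removed from the conducting domain when `D` exceeds an independent
uniform(0,1) draw.  The uniform field is a pure function of (mesh, seed).
During optimization one field is drawn per run and reused for every
candidate density ("common random field"), which makes the knockout
monotone in density — raising a segment's density never un-knocks a node
— and keeps the optimizer's cost curves quasi-monotone.  Re-randomizing
per evaluation is available behind a flag for robustness studies.

### Excitation dynamics

Electrical activity follows the two-variable Aliev–Panfilov monodomain
model

    du/dt = ∇·(D∇u) − k u(u−a)(u−1) − u v
    dv/dt = −(ε + μ₁ v/(u+μ₂)) (v + k u (u−a−1))

with k = 8, a = 0.1, ε = 0.01, μ₁ = 0.2, μ₂ = 0.3 (dimensionless model
units).  Integration is explicit forward Euler with dt = 0.0015 and
dr = 0.1; the constructor enforces dt ≤ dr²/(2 tr D).  The diffusion
tensor is built per node from the fiber direction,
D = D_T I + (D_L − D_T) f fᵀ, default anisotropy D_L : D_T = 4 : 1
(configurable; the desk-scale experiments below run isotropic D = 1).

The Laplacian is a 19-point finite-difference stencil in flux form:
diagonal terms use face-averaged conductivities, cross terms average
D_ab ∂_b u between the two nodes sharing a face.  Any face whose opposite
node is non-conductive or outside the domain carries zero flux
(homogeneous Neumann); transverse derivatives fall back to one-sided
differences where a neighbour is missing, making the stencil asymmetric
near boundaries.  The stencil is verified against a symbolic-divergence
oracle on smooth fields with smoothly varying fiber tensors and converges
at second order in the interior.

The "sinus rhythm" protocol stimulates every conductive endocardial node
simultaneously at t = 0 with a current of 100 units for 0.2 time units
(the same amplitude/duration as the pacing protocol: 10 pulses, period
28.5).  Tissue activation time per node is the first upward crossing of
u ≥ 0.5.

### Electrogram synthesis and measurement conventions

A unipolar pseudo-electrogram at electrode position x sums the
transmembrane diffusion current I = ∇·(D∇u) over all conductive nodes
weighted by 1/r² (r guarded below by dr/2; the transfer constant is 1 —
all downstream comparisons are baseline-normalized, so it cancels).
Electrodes are seeded uniform samples of surface nodes, displaced two
voxel spacings outward along the local surface normal.  The standoff
matters at desk scale: at one voxel the kernel is dominated by the few
nearest nodes and the PtP inherits their individual knockout noise; two
voxels average over enough wall nodes that the per-electrode amplitude
reflects the local density rather than the particular realization.

Under simultaneous endocardial stimulation the injected current produces
a large global artifact during the stimulus window.  The package
therefore uses clinical-style pacing blanking:

- **LAT** = time of the steepest downstroke (most negative
  central-difference derivative, parabolically refined between samples,
  earliest sample on ties) *after* the stimulus window plus two sample
  intervals.  Endocardial LATs are identically 0 by convention — the
  endocardium is the stimulus and the LAT reference.
- **PtP(endo)** = max − min of the full trace: the stimulus complex *is*
  the endocardial activation complex, and its amplitude directly reflects
  the conductive node count near the electrode.
- **PtP(epi)** = max − min of the post-blank window, scoring the
  transmural activation complex rather than the remote stimulus
  artifact.  (Without the window, epicardial PtP sensitivity to the
  epicardial layer density collapses by an order of magnitude.)

An electrode whose nearest conductive node never activated is marked
blocked: LAT = +∞, PtP = 0.

Electrode scalars are spread to every surface node with radius-limited
inverse-distance weighting, w = (max(0, R−d)/(R d))², default
R = 2× the mean nearest-neighbour electrode spacing.  Nodes coincident
with an electrode take its value exactly; nodes with no finite-valued
electrode within R fall back to the nearest electrode and are flagged.

## Inverse method

For an observable X ∈ {epicardial LAT, endocardial PtP, epicardial PtP}
over N surface nodes the cost is the signed mean normalized residual

    C = (1/N) Σ (xₙ^target − xₙ^estimate) / xₙ^baseline

where the baseline comes from one zero-fibrosis run (shortest LAT,
largest PtP; endocardial LAT is excluded — it is identically zero and
carries no information).  Block sentinels collapse to ±10, large enough
that only the sign matters.  For LAT, C ≥ 0 at 0% density and turns
negative once the candidate over-slows or blocks the wave; for PtP the
signs are mirrored.

Each scalar density is searched on [0, 0.6] — above roughly 60% knockout
a 3D wave no longer propagates, so the cost at the upper end is known
only by its (assumed opposite) sign.  The search is bisection until two
evaluated points straddle the root, then Illinois-type modified false
position.  It stops when |C| < ε = 0.01 or the proposed density step
falls below D_min = 1%.  One refinement: the *returned* density is the
secant zero of the final true bracket (exactly the next false-position
iterate, returned instead of evaluated).  Shallow cost curves satisfy
|C| < ε over several percentage points of density; the secant projection
pins the estimate to the curve's actual root rather than to wherever the
last probe happened to land.

The pipeline refines in four steps, each warm-starting its first probe
from the parent estimate while keeping the full [0, 0.6] bracket:

1. one global density on the whole-epicardium LAT cost;
2. the 17 AHA segments, LAT cost restricted to each segment's epicardial
   patch (a surface node belongs to the segment of its own label);
3. the 68 sub-segments likewise (each 17-segment split 2×2 along its
   circumferential and longitudinal median planes; the apex cap into four
   circumferential quadrants, since a longitudinal cut would orphan
   children from the endocardium);
4. the three transmural layers of every 68-segment (equal-thickness
   thirds at depth 1/3 and 2/3): endocardial density fitted on
   endocardial PtP, epicardial on epicardial PtP, mid-myocardial on LAT,
   cycled endo → epi → mid until all three costs meet the tolerance at
   the end of a cycle, the densities stop moving, or a cycle cap
   (default 10) is reached.

Segments are scheduled in four fixed groups of mutually non-adjacent AHA
segments — (1,3,5,14,16), (2,4,6,13,15), (7,9,11,17), (8,10,12) — and at
the 68-level one sub-segment slot (.1 … .4) at a time.  Members of one
group are fitted *concurrently*: each proposes its candidate density,
one forward simulation evaluates them all, and each root-finder advances
on the cost from its own surface patch.  Non-adjacent segments interact
only weakly through the observables, so the result is equivalent to a
serial sweep; concurrency here is an equivalence claim about the
scheduling, not a threading mechanism.  Completed evaluations are cached
by candidate density map, so re-probing a converged configuration is
free.

## Synthetic histology-like fields

The generator emulates per-slice fibrosis density maps: each of n (default
20) slices is a 72 × 6 grid (72 circumferential × 6 transmural sectors)
drawn from a Gaussian-correlated random field (default correlation length
4 sectors, circumferentially periodic), centred at mean level 0.10 with
spread 0.08, clipped to [0, 1].  Under these defaults a focal minority of
sectors exceeds the 0.21 abnormality level.  To expand to 3D, every mesh
XY-slice is sectored 72 × 6; authored slices keep their values, in-between
sectors are filled by a natural cubic spline along z per sector (clamped
to the authored range outside it), then one arithmetic-mean pass over the
6-connected neighbourhood smooths the per-node field.

What the generator does *not* emulate: stain classification, image
registration, anisotropic scar texture, wall-motion artifacts, or any
correlation between fibrosis and wall thickness.  Passing tests therefore
demonstrate that the inverse machinery recovers knockout densities of its
own forward model — not that it quantifies histological collagen in real
tissue.

## Desk-scale experiment sizes

The package's study conditions are chosen so each experiment runs in
minutes on one CPU while keeping stochastic-realization noise below the
quantities being asserted:

- **Pattern recovery** (the four idealized patterns: transmural 25/25/25,
  sub-endocardial 35/15/2, mid-myocardial 10/35/15, sub-epicardial
  2/15/35, in percent per layer): single-segment slab 40 × 40 × 48
  (16 voxels per transmural layer), isotropic D = 1, t_end = 9, fields
  sampled every 25 steps, 72 endocardial and 81 epicardial electrodes.
  Wall depth is the critical dimension: the LAT cost amplifies an
  endocardial-layer misfit several-fold into the mid layer, and the
  knockout noise of thin layers was the dominant error source in
  under-resolved trials.
- **Conduction block**: slab 40 × 40 × 24, densities 50% and 65%, ten
  seeds each, t_end = 20.  A wave "crosses" when ≥ 75% of conductive
  far-face nodes activate; above the block threshold only minority
  percolation channels trickle through (one-third to one-half of the far
  face), and that fraction is saturated in time.
- **Mini-LV end-to-end**: shell radii (1.6, 1.6, 2.4), wall 0.7, grid
  40 × 40 × 32 (~10 000 myocardial nodes), 120/160 electrodes, t_end = 5,
  root-finder capped at 8 evaluations and 2 layer cycles.  At ~40 nodes
  per 204-segment the per-segment knockout noise is several percentage
  points, so this experiment asserts correlation between target and
  recovered densities, not per-segment accuracy.

## Numerical details and edge cases

- Explicit-stability guard at parameter construction; NaN checks abort a
  run with the divergence time.
- Activation threshold u ≥ 0.5 (upward crossing); sampled-field cadence
  sets the LAT resolution, mitigated by parabolic refinement of the
  derivative minimum.
- LAT ties resolve to the earliest sample; a trace with peak derivative
  magnitude below the noise floor (default 1e-12) returns the block
  sentinel.
- The model parameter ε = 0.01 (recovery dynamics) and the optimizer
  tolerance ε = 0.01 are distinct quantities; they live in `APParams` and
  the root-finder respectively.
- Root-finder degenerate cases: identical cost signs at every probe down
  to the minimum step return the best evaluated point flagged
  `no_root_in_interval`; an evaluation cap (default 30) returns the best
  probe flagged `max_evals`.
- Segments whose endocardial or epicardial surface patch is empty keep
  their parent density and are skipped.

## Known limitations

- The mid-myocardial density is identified only indirectly: the two PtP
  costs pin the outer layers first and the LAT residual must attribute
  whatever remains to the mid layer.  Its error is therefore the
  amplified sum of the outer-layer errors plus the LAT realization noise
  divided by a comparatively shallow slope.  At the desk-scale problem
  sizes used here this amplification sets the error floor of the
  layer-resolved experiments (the dense-outer-layer patterns and the
  mid-layer group of the mini-LV study are consistently the worst
  performers); shrinking it scales with tissue volume, not with
  algorithmic settings.

- The two-variable model's wide wavefront suppresses EGM fractionation;
  amplitudes and activation times are the only trustworthy observables.
- The sinus surrogate (simultaneous endocardial activation) ignores the
  conduction system; septal and paced-rhythm scenarios are out of scope.
- Reconstruction returns piecewise-constant per-segment densities; no
  continuous field estimation.
- Absolute diffusivities are unspecified in model units, so LATs are only
  comparable within a configuration — the baseline normalization in the
  cost is what absorbs this.
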