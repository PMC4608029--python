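# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the spirit of a software methods section: what is computed, under
which assumptions, which defaults matter, and what the synthetic tests do and
do not demonstrate about real data.

## Topological bookkeeping

A covalently closed duplex has an integer linking number `Lk`, invariant
while both strands are intact.  The relaxed reference is
`Lk₀ = round(n_bp / h)` with helical repeat `h = 10.5` bp/turn by default
(giving `Lk₀ = 32` for 336 bp and `64` for 672 bp); exact `.5` ties round
away from zero, a case never reached for these constructs.  `ΔLk = Lk − Lk₀`
and the superhelical density `σ = ΔLk/Lk₀` follow.  Twist is obtained from
conservation, `Tw = Lk − Wr`; the package never derives twist from base-pair
frames (out of scope).  Type-II topoisomerase relaxation is modelled purely
by parity: the enzyme changes `Lk` in steps of two, so even-`ΔLk` species
terminate at `ΔLk = 0` and odd ones at a `{−1, +1}` mixture.

### Writhe

`Wr` of a closed polygon is evaluated as the exact Gauss double integral:
each pair of non-adjacent segments contributes the signed solid angle of the
spherical quadrilateral spanned by the normalized endpoint-difference
directions, divided by 4π (counting ordered pairs).  The solid angle is
computed as two spherical triangles with the van Oosterom–Strackee `atan2`
formula.  An earlier arcsine-based closed form was abandoned because it has
branch failures for coplanar and (anti)parallel segment pairs — exactly the
geometry of juxtaposed minicircle strands — producing writhe errors of
order 10 for planar curves.  The `atan2` form is branch-safe; tests verify
zero writhe (< 1e-9) for planar curves of every generated class, mirror
antisymmetry, rigid-motion/scale invariance, and agreement to 1e-3 with an
independent midpoint-rule discretization of the Gauss integrand at 10×
vertex density.

Sign convention: the Gauss integral's standard orientation, under which a
right-handed crossover (the geometry of negatively supercoiled DNA) carries
node sign −1 and underwound conformations have `Wr < 0`.

### Projected crossings

Self-crossings of the polygon projected along an axis are found by exact
segment-pair intersection; the sign is `sign((t_over × t_under)·axis)`,
where the "over" strand is nearer along the axis.  Intersections landing
exactly on a vertex are kept by evaluating the parameter intervals with a
small closed-interval slack and merging duplicate records.  Near-tangential
crossings are flagged ambiguous and excluded from the signed sum.  A
Monte-Carlo test confirms the directional-average theorem: the mean signed
crossing number over uniformly random projection axes reproduces the writhe
to < 0.05.

### Cleavage-site mapping

Localizing a single-strand-breaking nuclease's cut site on a circle from
double digests: for each restriction enzyme (one known site) the two
fragment sizes place the cut at `site ± fragment` (mod circle).  The mapper
scores every integer position against all digests within a fragment-size
tolerance (default ±10 bp; tests use ±5 matching their simulated noise) and
reports the smallest circular interval covering the consistent positions,
flagging the two-candidate ambiguity of a single-enzyme digest.  Gel
migration is converted to fragment size by least-squares regression of
log₁₀(bp) on migration distance; extrapolation beyond the ladder span must
be requested explicitly.

## Synthetic phantoms

The generator emulates what a minicircle subvolume looks like after
reconstruction and low-pass filtering: a closed tube of density on a cubic
grid (default 4.52 Å/voxel).  Density at a voxel is
`exp(−d²/2r²)` of its distance `d` to the backbone curve, with tube radius
(Gaussian sigma) `r = 10 Å` — the B-form duplex radius — and exact zeros
beyond `3r`.  Contour length defaults to 336 bp × 3.4 Å/bp = 1142.4 Å
(canonical B-DNA rise); every generated curve is resampled to uniform arc
spacing and rescaled so its polygon perimeter equals the requested contour
length exactly.

One parametric form per conformational class, chosen as the minimal curve
with the class's defining features:

* **open circle** — ellipse; the `ellipticity_param` is calibrated by 1-D
  root finding so that the *measured* covariance-axis ratio `a1/a2` of the
  arc-length-uniform curve equals the parameter (the raw semi-axis ratio
  differs by a few percent at high ellipticity because arc length
  accumulates faster along the flat sides);
* **figure-8 family** — a lemniscate-like curve `(s sin t, ½ s sin 2t)`
  with the two central passages lifted out of plane by ±`crossing_offset`/2
  (25 Å for the compact figure-8, 70 Å for the open one); the chirality
  sign selects right- (negative `Wr`, default) or left-handed crossing;
* **racquet / needle** — a circular loop (loop_fraction 0.55 / 0.20 of the
  contour) plus a doubled-back handle ending in a U-turn, strands
  juxtaposed at `handle_gap = 30 Å` center-to-center;
* **handcuffs** — two terminal loops (0.30 of the contour each) joined by a
  doubled straight handle;
* **rod** — a stadium: two long juxtaposed strands closed by two apical
  U-turns of radius `handle_gap`/2.

Feasibility is enforced (loop radii above the strand gap, positive handle
lengths) with diagnostics naming the violated constraint, and every curve is
checked for self-approach below 0.9× the strand gap.  `handle_gap = 30 Å`
makes juxtaposed tubes marginally resolvable at this voxel size and tube
radius — a deliberate, realistic difficulty.

Corruption is Gaussian blur (Å) plus i.i.d. Gaussian noise expressed
relative to the on-axis peak density 1.0.  No missing-wedge anisotropy, CTF
or reconstruction artifacts are modelled; the default population noise
(`noise_sd = 0.1`, with tracer robustness demonstrated up to 0.5) is a
package choice, not an experimentally calibrated SNR.  Populations are
generated deterministically: each record's seed derives from the population
seed and record index, parameters receive a mild per-record jitter (10%
relative, clipped to feasible, class-separating ranges), and orientations
are uniformly random rotations.  The manifest allows any record to be
regenerated in isolation.

Consequently, passing tests show that the *algorithms* recover known
answers from tube-like densities with additive noise; they do not certify
performance on experimental subtomograms with anisotropic resolution,
crowding, or non-B DNA geometry.

## The tracer

The backbone is fitted as a closed polygon maximizing

```
S = w_d Σᵢ ρ(vᵢ) − w_l Σᵢ (|eᵢ| − L̄)² − w_a Σᵢ (θᵢ − θ̄)²
```

with trilinearly interpolated density ρ, target edge length
`L̄ = (expected contour length)/n`, and regular-polygon interior angle
`θ̄ = π − 2π/n`.  The expected contour length is a required input (known
construct size × 3.4 Å/bp).  Density is sampled at vertices; an
edge-midpoint sampling variant exists but is off by default.  Defaults
`w_d : w_l : w_a = 1 : 0.02 Å⁻² : 1 rad⁻²` were tuned on clean phantoms to
balance recovery RMSD against perimeter fidelity and are all exposed in
`TracerConfig`.

**Preprocessing** low-pass filters (Gaussian, 8 Å), standardizes to zero
mean/unit SD, and zeroes all above-threshold (mean + 1 SD) connected
components except the largest (26-connectivity).

**Placement.**  Each start is initialized by an elastic ring: a cyclic
chain of 100 nodes, started as a circle of radius `√(λ₁+λ₂)` (from the
thresholded density's weighted covariance) in the principal plane —
re-oriented per start by a uniformly random rotation — and updated by batch
self-organizing-map iterations against the above-threshold voxel cloud of
the largest connected component, with the ring-neighbourhood kernel width
annealed geometrically from half the ring to sub-node scale over 80 epochs.
The wide early kernel makes the basin effectively global: the ring
discovers the correct closed tour even for conformations whose backbone
doubles back on itself (rods, racquets, handcuffs), which a purely local
gradient snake started from a circle provably does not (tested; RMSD errors
of 30–120 Å).  The ring is then resampled to the initial 5-gon.

**Refinement schedule.**  Gradient ascent at 5 vertices, edge-midpoint
doubling to 10, refinement, doubling to 20, final refinement.  Each
iteration moves every vertex by `step_size` (2 Å) along its own score
gradient (density gradient by central finite differences at half-voxel
offsets; penalty gradients analytic, verified against numerical
differentiation), with backtracking halving while the score would decrease;
a stage stops when the relative improvement falls below 1e-6 or after 200
iterations, so the score is non-decreasing.  Two resolution-dependent
adaptations stabilize the coarse stages:

* the penalty weights ramp as `(n/n_final)²` — a correct compact trace
  sampled at 5 vertices necessarily has near-degenerate angles and
  chord-shortened perimeter, and full-strength restoring forces would
  unfold it (the angle-gradient's 1/sin θ factor is additionally floored at
  sin θ = 0.1);
* intermediate (subdivided, non-final) stages refine against a copy of the
  volume blurred by 0.1× the stage edge length, because freshly inserted
  midpoints can sit beyond the sharp tube's 3σ support where the density
  offers no gradient — or, under noise, a misleading one.  The final stage
  polishes against the unblurred preprocessed volume with full penalties.

Vertices pushed outside the grid are clamped to the boundary; persistent
clamping of more than half the polygon flags non-convergence.

**Multi-start verification.**  Four starts by default; the best-scoring
polygon is returned.  Agreement is the mean vertex distance between the
best start and each other start after optimal cyclic shift and optional
orientation reversal (no rigid superposition — the curves share the volume
frame), computed on a 5× resampling so sub-edge phase offsets between
otherwise identical traces do not inflate it; `converged` means agreement
< 10 Å.  Double-length (672 bp) constructs trace well with
`contour_length = 2284.8 Å` and `n_final = 40` (the 5·2ᵏ schedule extended
one doubling), recovering the perimeter within 2%.

**Known limitation — crossing chirality.**  At a 25 Å crossing separation,
4.52 Å voxels and a 10 Å tube, the two possible waist routings of a
figure-8 have identical density support and nearly identical penalties:
traces recover the backbone path to ~1 Å RMSD but may resolve the crossing
as a touch (|Wr| ≈ 0.2–0.3 instead of 0.9) and such molecules classify as
handcuffs or other.  Clean-curve classification is unaffected; on traced
data at this resolution the figure-8/handcuffs distinction should be
treated as soft.  Crossings separated by more than the contact distance
(open figure-8, 70 Å) are recovered reliably.

## Shape metrics and classification

**Radius of gyration.**  Voxels within 45 Å of the fitted path carry weight
1; beyond, the weight decays as a Gaussian whose width is set by
`w(180 Å) = 0.01`, and is zero past 180 Å (hence the generator's ≥ 180 Å
box margin, so the mask never truncates).  With density clamped at ≥ 0,
`Rg² = Σ wρ‖r − r̄‖² / Σ wρ` about the `wρ`-weighted centroid — position and
density of each voxel, no direct use of the fit vertices beyond the mask.
The raw (not normalized) volume is used.  Distances to the path come from a
Euclidean distance transform of the path rasterized onto the grid (half-a-
voxel accuracy, negligible against the 135 Å taper; an exact KD-tree mode
exists and agrees to < 1%).  Checks: a thin rasterized ring reproduces its
axis radius within 2% (the exact ring value is `√(R² + σ_eff²)`), a uniform
ball gives `a√(3/5)` within 1%, and the vectorized implementation matches a
direct-summation oracle to 1e-6.

**Axis lengths and ellipticity.**  `a1 ≥ a2 ≥ a3` are square roots of the
eigenvalues of the vertex-coordinate covariance (population
normalization — singular values of the centered coordinates / √n).
Ellipticity is `a1/a2`, i.e. the in-plane aspect ratio of the polygon; this
is an operational definition (3-D axis ratios of the final polygon, not a
2-D projection).  Descriptors are computed on a 100-point uniform
resampling of the trace to decouple them from the 20-gon discretization;
end-to-end recovery of generating ratios 1.0–2.6 is within 5% (measured
≤ 3%).

**Contact structure.**  A contour point is "in contact" when another point
at arc separation ≥ 2× the contact distance lies within the contact
distance (60 Å, i.e. strand juxtaposition at twice the duplex diameter +
margin) in space.  Maximal non-contact runs are candidate loops; runs
shorter than 0.11× the contour are discarded because hairpin U-turns
produce ~80–90 Å non-contact caps that are not loops (measured on
phantoms; a real loop run at the smallest feasible needle loop is ≥
~135 Å).  `loop_count`, the loop arc lengths, and the contact fraction of
the non-loop ("handle") arc feed the classifier.

**Classifier.**  A deterministic first-match decision list mirroring the
taxonomy's visual definitions: open circle (|Wr| < 0.35, no crossings,
contact < 0.1); open figure-8 (one crossing, strand separation > contact
distance); figure-8 (one crossing in contact, two loops ≥ 25% of contour
each); racquet (one loop ≥ 35%); needle (one smaller loop); handcuffs (two
loops, handle-arc contact fraction > 0.5); rod (no loops, contact > 0.5);
otherwise *other*.  All thresholds are package decisions shipped in
`ClassifierThresholds` — the underlying taxonomy was defined by eye, and
the subtle racquet/needle boundary is made explicit here as the 35% loop
fraction.  On clean generated populations with parameter jitter the
classifier recovers 140/140 labels; ≥ 90% is asserted in tests.

**Weighted compactness.**  Classes are weighted by increasing compaction
(open circle 1 … rod 7); the statistic is the fraction-weighted mean over
the seven named classes.  *Other* is excluded and the fractions
renormalized, since the weighting scheme enumerates only the named classes;
populations containing nothing but *other* raise an error rather than
returning a number.

## Pipeline and formats

`run_pipeline` chains generation → preprocessing/tracing → descriptors →
classification → per-group summaries (n, class counts/fractions, weighted
compactness, mean ± SD of Rg, single-record groups flagged).  Every random
stage receives a seed derived from the top-level seed via `SeedSequence`,
so a rerun reproduces all CSV outputs bit-identically; each table carries a
hash of the full configuration.  Volumes travel as mode-2 (float32) MRC
with the voxel size in the cell parameters and the volume origin in the
ORIGIN header words, axis order normalized on read; traces as CSV
(`record_id, vertex_index, x_A, y_A, z_A`) and optionally as pseudo-atom
PDB (one HETATM per vertex, CONECT closing the loop) for visualization.
Problem sizes in the shipped tests and the acceptance script — single
molecules per class for tracing, 20 molecules per class for
classification, 10 noise seeds for the robustness check — were chosen as
the smallest populations at which the statistics are stable.

## Other limitations

* No multi-molecule picking: one minicircle per subvolume is assumed.
* No atomistic modelling: twist is bookkeeping (`Lk − Wr`), never measured
  from base-pair geometry, and sequence-dependent curvature is not
  simulated.
* The 26-connectivity cleanup assumes the molecule is the largest coherent
  density; a brighter contaminant would defeat it.
* Classifier thresholds are tuned to the generator's geometry; real data
  with intermediate conformations will populate *other* more heavily.
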