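# Methods

## Problem setting

A fragmentary specimen (the *target*) is compared against one or more
more complete *reference* specimens by registering the target's surface
onto each reference and measuring per-vertex absolute distances. The mean
(MD) and standard deviation (SD) of the distance field act as a fidelity
measure between shapes: values near zero indicate near-identical surfaces.
The package covers the whole chain — mesh I/O, landmark and ICP
registration, artefact trimming and resolution matching, C2C/C2M distance
fields, and the statistical decomposition of a set of such trials.

## Registration model

**Similarity transform.** All alignment is modelled as x ↦ s·R·x + t with
s > 0 and R a proper rotation (RᵀR = I, det R = +1, both enforced to
1e-9). Reflections are excluded: mirror-image matches would be anatomical
nonsense for paired comparisons of the same element.

**Landmark (first) registration.** Given ≥3 row-paired landmark sets, the
least-squares similarity is computed in closed form from the SVD of the
cross-covariance of the centred configurations (the standard
Umeyama/Procrustes solution), with the singular-sign correction forcing
det R = +1 and the scale from the ratio of the projected covariance trace
to the source variance. `with_scale=False` returns s = 1 exactly.
Collinear configurations (second singular value < 1e-9 of the first) are
rejected as degenerate rather than silently returning an arbitrary axis.

**ICP (second) registration.** Point-to-point ICP: each iteration pairs
every source point with its nearest reference *vertex* (KD-tree;
nearest-neighbour ties resolve to the lowest index for determinism),
solves the closed-form similarity update on the correspondence set, and
composes it into the cumulative transform. Scale is re-estimated every
iteration because specimens differ in size and the workflow explicitly
re-scales during fine alignment. The recorded RMS uses the iteration's own
correspondences after its update, which makes the history mathematically
non-increasing when all correspondences are kept (each step minimises the
objective its predecessor evaluated). An optional `keep_fraction` < 1
retains only the closest pairs (outlier trimming); monotonicity is then
no longer guaranteed and it is off by default.

Defaults: 20 iterations; convergence when the RMS change per iteration is
below 1e-8 — measured relatively above 1 model unit and absolutely below
it, so that runs sitting at machine noise (RMS ~1e-14) still register as
converged. The `iteration_sweep` helper re-runs ICP at budgets 5..100 in
steps of 5 (each run independent, from the same initial transform) and
reports the first budget at which the final RMS stops changing, which on
clean pairs plateaus far below the ceiling.

## Mesh editing

**Trimming** is vertex-mask based: a face survives iff all three corners
survive; surviving coordinates are never modified, and results may be open
shells (boundary edges are expected, not an error). Sphere and half-space
selectors cover the common cases (excavation artefacts, planar fracture
cuts); boundary points count as inside the sphere.

**Decimation** is iterative edge collapse ordered by the Garland–Heckbert
quadric error metric: each vertex accumulates the squared-plane-distance
quadrics of its incident faces, each candidate edge is scored at the
position minimising the combined quadric (midpoint fallback when the 3×3
system is singular), and collapses that would flip a surviving face normal
are rejected. Ties break on the lowest vertex-index pair, making the
result deterministic. One collapse removes exactly one vertex, so the
target count is reached exactly unless valid collapses run out (logged).
Every run can report a fidelity bound — the maximum distance from any
removed vertex position to the decimated surface. `match_resolution`
decimates the higher-resolution mesh to the lower one's vertex count and
*refuses* to upsample: interpolated detail would misstate scan resolution.

## Distance fields

**C2C** is the exact Euclidean distance to the nearest reference vertex
(KD-tree accelerated, not approximate). **C2M** is the exact unsigned
distance to the nearest point on any reference triangle — face interior,
edge or vertex — computed by the barycentric region classification,
evaluated for every point against every triangle in vectorised chunks.
This brute-force-exact strategy is deliberate: at the tens-of-thousands of
vertices typical of these comparisons it runs in seconds, and it removes
any spatial-index pruning from the correctness argument. C2M ≤ C2C
pointwise by construction (triangle interiors can only be closer).

Distances are unsigned throughout; the field maximum is exposed as the
directed Hausdorff distance. Summaries use the sample SD (n−1): at the
field sizes involved the choice is numerically irrelevant, but it is fixed
and documented. Histograms use equal-width bins over [0, max] (256 by
default, rightmost bin closed). Heat maps interpolate
blue→green→yellow→red piecewise-linearly, with zero at blue and the
saturation point (field max by default) at red; the mapping is monotone,
so warmer always means farther.

`compare()` orchestrates a full trial: optional landmark initialisation,
optional ICP, distance field, and — when ICP is on — the pre-ICP summary
as well, so the effect of the fine alignment is always visible.

## Trial ANOVA

The response is the univariate mean distance of each trial; with Euclidean
distance on a single response, permutational ANOVA reduces to a
permutation test on the classical decomposition, which is what is
implemented. Type-II SS for each main effect = residual SS of the model
without that term minus residual SS of the full main-effects model (no
interactions, so type II ≡ type III); the decomposition was cross-checked
against statsmodels' `anova_lm(typ=2)` in the test suite. Inference
permutes response rows without restriction (B = 999 default, explicit
seed), recomputing every term's F against the permuted residual MS;
p = (count + 1)/(B + 1), giving a floor of 0.001 at the default B. The
effect size Z standardises the observed log F against the permuted log-F
distribution — a conventional permutation effect-size; other software may
define Z slightly differently, so only SS/MS/R²/F should be compared
across implementations at full precision. Aliased factors (no rank gained
over the other terms) raise a named error; a constant response yields all
SS = 0 and F flagged NA.

The bundled `ungual_trials.csv` records twelve comparisons of the
fragmentary theropod ungual NMV P186153 against two *Australovenator*
reference unguals, crossed over removal × method × ICP × reference, and is
the input to `scripts/acceptance.py`.

## Synthetic specimens

The generator emulates the geometry class under study, not any individual
fossil: a circular-arc axis (default 30 units long sweeping 1.6 rad) with
rings whose radius tapers as (1−u)^1.5 from a 6-unit proximal radius,
Gaussian-profile grooves on both lateral sides of the mid-section, and a
ventral bulge near the proximal end for the flexor tubercle. The shell is
closed with two pole vertices (V − E + F = 2 by construction). Degradation
removes whole vertices distal of a cut plane perpendicular to the arc axis
and inside a Euclidean ball centred on a ventral surface vertex (no
re-triangulation of cut boundaries, matching the open-shell character of
trimmed scans), then perturbs survivors along vertex normals with Gaussian
noise — along normals rather than isotropically because scanner error is
predominantly radial and this keeps the shell from self-intersecting at
small sd. Defaults (35 % distal loss, 2-unit hole, 0.05-unit noise ≈ 1 %
of the proximal diameter) represent a heavily fragmentary specimen.
All randomness flows through explicit per-operation seeds; topology is
seed-independent.

What the generator does **not** emulate: real scan texture, non-Gaussian
preparation damage, resolution anisotropy, and genuinely non-homologous
topology between specimens (all synthetic pairs share a template, which is
what makes exact landmark ground truth possible). Passing tests therefore
demonstrate the correctness of the algorithms under known geometry, not
the biological interpretation of any particular comparison.

For the replication-versus-removal experiment the reference uses a
*different* parameter set (smaller tubercle, deeper grooves, straighter
arc) so that genuine shape difference dominates the field, and the
"replicated" condition appends the target's own patch verbatim to the
reference — reproducing the mechanism by which replicated identical
surfaces pile distances at zero and make the distribution leptokurtic.

## Numerical choices and edge cases

- Coordinates are float64 end-to-end; OBJ is written at 9 significant
  digits, so OBJ round-trips are lossless at that precision. STL reads
  weld exactly coincident vertices (facet soup formats triplicate them);
  PLY round-trips 8-bit vertex colors exactly.
- Degenerate faces (repeated vertex) are dropped with a logged count,
  since fossil scans commonly contain them; out-of-range face indices are
  an error naming the offending line.
- Landmark files pair by row order; labels are documentation only.
  Coincident landmarks within 1e-8 are rejected.
- ICP with an empty source, <3 reference points, or a collapse to
  non-finite RMS raises typed errors rather than returning garbage.

## Problem sizes

The test suite and examples use claws of a few hundred to ~1,300 vertices
and clouds of up to 500 points — sizes at which every oracle comparison
(O(n²) brute force, exhaustive point-triangle minimisation, numeric
optimiser cross-checks) is itself cheap to run exactly. The algorithms
contain nothing size-specific: the same code paths handle the
tens-of-thousands-of-vertex scans of real comparisons, with C2M cost
scaling as points × triangles.

## Known limitations

- Point-to-plane ICP, deformable registration and RANSAC-style global
  initialisation are out of scope; a bad landmark initialisation can leave
  ICP in a local minimum, as in any ICP workflow.
- Surface *replication* (projecting broken-edge geometry onto the
  reference) is intentionally not implemented as an editing operation: the
  replication condition exists only inside the test suite, as appended
  identical patches, because replication demonstrably biases comparisons
  toward similarity.
- The permutation scheme shuffles rows without restriction; restricted
  (within-block) permutation is not offered.
- C2M is exact but brute-force per chunk; for meshes far beyond scan
  scale (millions of triangles) a BVH-pruned variant would be needed.
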