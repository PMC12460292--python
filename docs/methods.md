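# Methods

`disctls` estimates the volume of a tree-stem disc from a terrestrial laser
scanning (TLS) point cloud and quantifies the agreement of those estimates
with water-displacement reference measurements. This note records the
models, the parameter choices, and what the synthetic validation does and
does not demonstrate.

## Geometry pipeline

### Bottom-surface repair

A disc scanned on the ground has no returns from its bottom face. The
repair projects **every** point onto the horizontal plane through the
cloud's global minimum z and merges projection and original:

    z_min = min_i z_i,   T(p_i) = (x_i, y_i, z_min),
    P_complete = P_original ∪ P_projected.

The fill plane is horizontal at `z_min`; no ground-plane fitting is
attempted (the transform fixes z to a constant — tilted discs are the
caller's responsibility). Projecting all points, not just the rim, makes
the repaired base a dense filled plane; that is the method as stated and is
kept as the default. Under a literal set union, points already at `z_min`
would coincide with their own projections, so the default drops projected
points that coincide exactly with an original point (`dedupe_tol = 0`);
`dedupe_tol=None` keeps the literal doubling `|complete| = 2|original|`,
and positive tolerances drop near-coincident projections. Exact
deduplication preserves union semantics while avoiding coincident points
that destabilise normal estimation.

### Normal estimation and orientation

Two per-point estimators over the k-nearest-neighbour neighbourhood:

- **Quadric** (module default, k = 6): in a local PCA frame (least-variance
  axis as local z, centred on the query point) fit
  `z = ax² + by² + cxy + dx + ey + f` by least squares and take
  `N = (−2ax−cy−d, −2by−cx−e, 1)` at the origin, normalised. The local
  frame makes the height-function model valid on steep surfaces. With
  exactly 6 neighbours the 6-unknown fit interpolates — including any
  sensor noise — so larger k is advisable on real scans; rank-deficient
  designs fall back to the PCA normal and are counted.
- **PCA** (k = 8): the least-variance eigenvector of the neighbourhood
  covariance — the estimator classically paired with Poisson
  reconstruction. The pipeline's reconstruction stage uses this by default.

Sign consistency is enforced by minimum-spanning-tree propagation over the
k-NN graph (k_graph = 10) with edge weight `1 − |n_i·n_j|`; each node is
flipped to agree with its tree parent. Two refinements matter in practice:

- Neighbourhoods whose covariance is line-like (the two smaller eigenvalues
  both negligible, `(λ_max − λ_mid)/λ_max > 0.98`) have no well-defined
  normal — the bottom-fill projection compresses the entire wall onto a
  dense rim ring with exactly this pathology. Their edges are penalised so
  the MST attaches them as leaves.
- The final outward flip is resolved per *confident patch*: the graph
  restricted to edges with `|n_i·n_j| ≥ 0.85` is split into components and
  each is flipped so the majority of its normals point away from the cloud
  centroid. Sharp folds (wall-to-base, ~90°) carry no sign information
  across them, and a single global vote lets one wrongly propagated sheet
  survive; per-patch voting decides each smooth sheet independently. On a
  smooth well-sampled cloud every edge is confident and this reduces to the
  single global outward flip.

In the assembled pipeline the projected base points additionally receive
the fill plane's known outward normal (0, 0, −1) after orientation
(`anchor_base_normals=True`). With sensor noise the projected rim ring is a
zero-thickness annular lip whose one-sided orientation is genuinely
ill-posed, while the sealing plane's outward direction is fixed by
construction; anchoring it is both safe and decisive.

### Surface reconstruction

The oriented cloud is converted to an indicator-like field by solving the
Poisson equation `Δχ = ∇·V` spectrally (cosine transform, Neumann
boundaries) on a regular grid of roughly `2^depth` voxels across the
longest bounding-box side (default depth 8 ≈ 1.2 mm voxels at disc scale,
the order of the scanner's ±1 mm ranging error; a margin of 8 empty voxels
surrounds the cloud). `V` is the trilinear splat of the per-point normals
weighted by inverse local density (squared distance to the 8th neighbour,
normalised) — without this weighting the dipole moment of the splatted
sheet varies with sampling density (the repaired base is denser than the
walls) and the field acquires spurious long-range tilt. The splat is
smoothed by a 1.5-voxel Gaussian, standing in for the basis-function
smoothing of octree implementations. The isosurface at the density-weighted
mean of χ over the samples is extracted by marching cubes.

Cleanup: vertices farther from the cloud than
`max(q_{1−trim}, 4 voxels, 3 point-spacings)` are cut (Poisson inflates
unsupported bubbles; genuine surface vertices sit within about half a
sample spacing), the largest connected component is kept, faces on
non-manifold edges are cut and boundary loops are fan-triangulated around
their centroids with consistent winding, iterating up to three rounds. Rare
marching-cubes pinches are knife-edge coincidences of the level set; if
cleanup cannot resolve them the isovalue is nudged by ±0.5 % and ±1 % of
the field range and extraction retried. If no candidate is watertight the
reconstruction raises with diagnostics — a volume is never computed on an
open mesh silently. Winding is made outward by flipping all faces when the
signed volume is negative (the flip is recorded).

### Volume

For a watertight mesh with outward per-face unit normals n_i (from winding
order, never vertex normals), areas A_i and centroids p_i:

    V = (1/3) Σ_i A_i (p_i · n_i).

The per-face terms are origin-dependent; their sum is not (Σ A_i n_i = 0 on
a closed surface), and translation invariance is asserted by test rather
than assumed. The public value is the absolute value after a single global
orientation check; the raw signed value and the per-face contributions are
available for audit. Volumes convert to cm³ only at the reporting boundary
(cube of the length factor); geometry is carried in the input unit
throughout.

## Synthetic discs

The generator emulates the acquisition conditions of the validation study:
disc thickness 5 cm (sampling protocol: 5 ± 0.5 cm), areal density
1000 points/dm², three scan stations at azimuths 45°, 135°, 270° (NE, SE,
W), isotropic Gaussian sensor noise of 0.1 cm (the scanner's ±1 mm ranging
error), and ground-contact occlusion. Cross-sections are ellipses (default
circular, r = 15 cm) modulated by bark roughness: a smooth periodic
zero-mean Gaussian field over azimuth, `r(θ) = r_e(θ)(1 + g(θ))`, scaled so
the radial standard deviation equals `bark_amplitude`. The field depends on
azimuth only — bark ridges run vertically, matching longitudinal fissuring
— so the solid is a prism and its exact volume is the shoelace area of the
realized 3600-vertex profile times the height. Ground truth is always this
*realized* solid, bark included, as a water-displacement measurement would
see it.

Station visibility is azimuthal: a wall point is kept if some station lies
within 100° of its azimuth; the top face is always visible. A full
ray-casting occlusion engine is deliberately out of scope. Ground-contact
occlusion removes the bottom face and, in the same step, crops every return
at or below the ground plane (z < 0): a tripod scanner has no line of sight
below ground, and any return at ground level is removed together with the
ground during cropping. The lowest surviving points then lie on the wall
rim just above the true base, so the detected `z_min` estimates the base
from above; without this crop the literal minimum would sit ~3 noise
standard deviations *below* the base and inflate every volume by ~5 % on a
5 cm disc.

Free parameters with no reported values, chosen once on physical grounds:
bark correlation length 2° (≈1.3 cm fissure width at r = 15 cm, typical of
coarse-barked species; narrow fissures are what challenge reconstruction);
replicate reference noise 2 cm³ for the paired-table simulator; per-species
table defaults mirror the validation study's sample sizes (69/25/12/17) and
mean volumes, with a −5 cm³ TLS bias and 25 cm³ paired noise matching the
reported overall difference statistics.

## Agreement statistics

All Table-style metrics are implemented directly from their definitions,
with x = observed (reference) and y = estimated (TLS): R² = 1 − Σ(y−x)²/Σ(y−ȳ)²;
RMSE = √(Σ(y−x)²/n); RE = (1/n)Σ(x−y)/y; Bias = (1/n)Σ(y−x); rRMSE
normalises RMSE by the mean *observed* volume (this is the convention under
which the published per-species values reproduce exactly from the printed
RMSEs and species means). Bland–Altman uses the sample (n−1) SD of the
differences and limits `d̄ ± 1.96 s`; the difference direction defaults to
estimated − observed (which yields a negative mean difference under TLS
underestimation) and is configurable and echoed in every report. The CCC
uses population (n) variances by default — the convention under which the
canonical concordance estimator is defined — also configurable.

GRR is a one-factor (parts) random-effects decomposition of the replicate
reference measurements: σ²_repeatability is the within-part mean square,
σ²_parts comes from the between-part mean square via the effective
replicate count n₀ (unbalanced designs supported), negative estimates
truncate at zero, and GRR % = σ²_repeatability/σ²_total × 100. With a
single gauge and operator the measurement-system variance is the
repeatability variance; no operator factor exists in the data this models.

Kruskal–Wallis uses mid-ranks, the tie-correction divisor
`1 − Σ(t³−t)/(N³−N)` (on by default), and the χ²_{k−1} approximation; a
pooled sample with all values identical raises a degenerate-data error
which the report surfaces as "not applicable". Mann–Whitney U is computed
from rank sums (`U = n₁n₂ + n₁(n₁+1)/2 − R₁`, reporting min(U, n₁n₂−U));
the two-sided p is exact by full enumeration of the C(N, n₁) rank splits
when n₁+n₂ ≤ 12 without ties (using the symmetry of the null distribution
around n₁n₂/2), otherwise a normal approximation with tie-adjusted variance
and continuity correction. Pairwise species comparisons report raw p as
primary plus Holm-adjusted p. The species-level group variable is the raw
per-sample difference in the configured direction. α = 0.05 throughout.

The suite is organised statsmodels-style: `VolumeAgreement(data).fit()`
returns an `AgreementResults` carrying all estimates, `summary()`,
`to_dict()` (versioned JSON schema) and the Bland–Altman and scatter plots.

## What the synthetic validation shows — and does not

Passing tests show the pipeline recovers prism-like solids with vertically
ridged boundaries to well under 1 % at study densities, that the repair is
necessary (omitting it changes the error by two orders of magnitude), that
error grows with bark roughness, and that the statistics reproduce their
defining arithmetic and calibrations. They do not show field accuracy on
real bark: the generator has no beam footprint, no multi-return or
scattering physics, no registration error, no moisture or reflectance
effects, and its roughness is a smooth stationary field rather than blocky
exfoliation. Real-data error will be dominated by effects the simulator
does not model.

One behaviour deserves emphasis: with the bottom repair omitted, this
implementation *over*estimates (by ~16 % at study geometry) rather than
underestimates. The spectrally solved, unscreened indicator has no data
term pulling χ toward the outside state beneath the unsupported opening, so
the extracted surface closes toward the domain margin below the disc.
Screened octree implementations typically close such openings inward and
underestimate instead. The magnitude of the degradation (two orders beyond
the repaired pipeline's error) is robust; its sign is a property of the
reconstruction backend, not of the occlusion.

## Numerical choices and degenerate inputs

- Ties in nearest-neighbour distances are broken by point index
  (deterministic k-d tree queries); all stochastic stages are seeded and
  single-seeded per artifact, so identical configs reproduce byte-identical
  outputs.
- Normal unit length is enforced to 1e-9; the quadric's z-component of 1
  guarantees a nonzero normal.
- Zero-variance inputs to R²/CCC, all-tied rank tests, empty clouds,
  non-finite rows, and non-positive volumes all raise (or are rejected and
  counted) rather than propagating NaNs; batch runs convert per-disc
  failures into itemised exclusions and continue.
- `ReconstructionSettings.octree_depth ≥ 4` is enforced; coarser grids
  cannot resolve a disc at study densities.

## Problem sizes used in the shipped validation

Unit tests reconstruct 20k-point analytic solids at depth 7 and one
study-condition disc at depth 8; the end-to-end checks use ten seeds at
full study conditions (≈12k points per disc), the roughness sweep four
amplitudes × ten seeds, and the rank-test calibration 2000 null
replicates. These sizes make the whole suite and the acceptance script each
run in minutes on a single CPU while keeping Monte-Carlo error far below
the asserted margins.

## Known limitations

- The bottom fill assumes the disc rests flat; tilted discs need external
  levelling first.
- The reconstruction grid is uniform, so very large aspect-ratio clouds pay
  a memory cost an octree would not.
- GRR is interpretable only as repeatability here; reproducing a
  multi-operator gauge study would need data that replicate measurements
  across operators.
- The exact Mann–Whitney path enumerates C(N, n₁) splits and is only used
  for n₁+n₂ ≤ 12, matching its documented contract.
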