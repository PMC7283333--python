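# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package, module by module.

## Coordinates and units

Voxel indices are 0-based; physical coordinates are `index * voxel size` in
nanometres, with the default voxel size 107.9 nm laterally and 200 nm
axially. All geometry downstream of the image operators (contact distances,
association thresholds, hulls) is computed in nanometres because the
biological thresholds are physical while the voxel grid is anisotropic.
Contacts use a strict `< 150 nm` rule and lamina/nucleolar association a
strict `< 200 nm` rule: a pair at exactly the threshold is *not* in
contact/associated. Association distances are measured to the centers of
mask voxels.

## Image operators

**Adaptive thresholding.** Several pipelines call for a local-mean adaptive
threshold with a "sensitivity" in [0, 1]. The exact statistic is pinned for
reproducibility: the profile is the local mean over the neighbourhood
(default `2 * floor(n/16) + 1` pixels, 41 px where specified), scaled by
`1.5 - sensitivity`. Higher sensitivity marks more foreground. Where the
profile serves as a background estimate the image is divided by it, so the
scale factor largely cancels.

**Cell segmentation** (membrane stain, 2D): z-average, min-max
normalization, division by the adaptive background (sensitivity 0.1, 41 px),
clipping to the 1st/99th intensity percentiles, morphological closing (disk
radius 15 px), then watershed. Watershed markers are the connected interior
plateaus below the ridge/interior Otsu split; flooding from raw local minima
fragments cells because noise creates spurious minima. Exclusions: area
<= 2500 px or >= 20,000 px, or touching the field edge. The 15-px closing
implies segmented basins cannot be much smaller than ~2,000 px; smaller
"cells" in real data are non-cell particles, which is exactly why they are
excluded.

**Nuclear-edge mask** (per z-plane): normalize to plane maximum, divide by
adaptive background (sensitivity 0.5), clip to the 1st/3rd quartiles,
opening-by-reconstruction (disk radius 25 px), 2D gradient magnitude,
Gaussian smoothing (sigma 5 px), adaptive binarization (sensitivity 0.1)
with a floor at 10% of the gradient maximum so flat planes stay empty.
Nuclei narrower than twice the 25-px opening radius are suppressed as noise.

**Nucleolus mask**: one adaptive threshold profile is derived from the
median-filtered maximum projection normalized by its maximum; that same
normalization factor and profile binarize every median-filtered plane, with
a floor of 0.3 (relative intensity) so sparse bright blobs do not drag the
local mean down to background. Mask voxel = nucleolus-occupied.

**Spot fitting**: least-squares 3D Gaussian (amplitude, center, per-axis
widths, constant background) in an 11x11x5 window; a fit fails when the
optimizer does not converge, the window is clipped too small, or the
amplitude does not exceed twice the residual noise. Failures are per-seed.

**Drift correction**: beads are localized by the same Gaussian machinery,
matched to the reference round by nearest neighbour within 5 px after a
coarse phase-correlation alignment of z-projections, and the per-round
offset is the *median* matched displacement, robust to a minority of
mismatches. Fewer than 3 matched beads is an error. 2D mode (used for
decoding) zeroes the axial component; 3D mode serves chromatin tracing.
Correction subtracts the offset from coordinates.

**Trace linking**: within each nucleus, positions from all rounds are
partitioned by single-linkage agglomeration with a 1,500-nm cutoff (1.5x a
~1 um chromosome-territory radius), capped at two clusters (diploid
nuclei) by re-cutting at `maxclust=2` when the distance cutoff yields more.
One position per readout per trace; the brightest fit wins ties. The
clustering algorithm and cutoff are a documented choice — only "spatial
clustering" is prescribed by the underlying experimental method.

## Decoding

Per-round binarization: per plane, background = morphological opening (disk
radius 5 px), subtracted; regional maxima above the round's threshold become
ones; 3x3 dilation accounts for molecules spanning more than one pixel.
Decoding matches each pixel's 16-bit word exactly against the codebook;
optional one-bit error correction maps weight-3/5 words at Hamming distance
1 from a unique codeword (safe because the code's minimum distance is 4).
Same-gene pixels merge with 8-connectivity within a z-plane; planes decode
independently, so a molecule whose point-spread function straddles two
planes can in principle be counted twice. Error correction defaults OFF:
exact matching is the published behaviour here, correction is offered for
parity with canonical multiplexed-FISH pipelines.

**Threshold calibration.** The two published criteria — per-round signal
loads proportional to codebook-weighted reference abundances, and decoded
per-gene totals best correlated with the reference — are both invariant to
a global rescaling of all thresholds over a wide plateau, so they
under-determine the absolute detection scale. The implementation therefore
(1) constrains each round's on-pixel share to within a factor of 2 of its
predicted load, (2) maximizes the Pearson correlation of log decoded totals
with log reference abundances by deterministic coordinate descent over a
20-point logarithmic grid spanning the 50th-99.9th percentile of each
round's candidate-maxima intensities, and (3) pins the scale by raising all
thresholds jointly to the top of the correlation plateau (tolerance 0.02 on
Pearson r) — the most conservative detection consistent with the fit, which
also suppresses duplicate detections across z-planes. Correlation is
computed on `log(reference)` over positive-reference genes, making the
procedure exactly invariant to rescaled references.

**Per-cell counting**: each cell's area is eroded by a 3-px disk before
assignment (boundary molecules stay unassigned, never double-counted);
cells with area outside (2500, 20000) px or fewer than 10 molecules are
flagged and excluded from analysis views.

## Trace analytics

Mean distance matrices use pairwise deletion (only traces with both loci
present contribute to an entry) with per-pair counts recorded; entries
below `min_pairs` informative traces are missing. `min_pairs` defaults to
20 for real-scale data; tests use 2. Genomic separation between regions is
the distance between region midpoints. Power-law fits are ordinary least
squares in log-log space, excluding the diagonal and non-positive values.

Compartment scoring normalizes distances by the fitted power law, computes
Pearson correlations between row pairs of the normalized matrix — excluding
each pair's own two columns, which otherwise inject the uninformative
self-distances — and takes the first principal component of the (symmetric,
so rows-vs-columns is immaterial) correlation matrix with standard column
centring. Scores are unit-norm and oriented to correlate positively with
gene density; without gene density the orientation is flagged unset.
Compartment scoring applies to TAD-scale traces; fine-scale (kb) traces use
the same distance/contact machinery only.

## Architecture metrics

Hull-intersection volume is computed exactly by halfspace intersection of
the two hulls' facet inequalities around a Chebyshev-centre interior point
(linear programming); when the intersection is numerically degenerate the
engine falls back to a fixed-seed Monte Carlo estimate (200,000 samples in
the overlap bounding box, ~1% relative accuracy). PI is clamped to [0, 1];
groups with fewer than 4 non-coplanar points raise a degenerate-hull error
and the chromosome copy is excluded. Label-randomization controls preserve
compartment sizes per permutation; permutations leaving a degenerate group
are skipped and logged by omission. Chromosome-level lamina/nucleolar flags
use the any-B-locus rule. Surface flags are hull-vertex membership.

## Polymer simulator

**Sign convention.** The energy, read literally as
`E = sum g_AA S_i S_j + sum g_BB S_p S_q + sum g_AS (S_m - mean S_A) + sum
g_BS (mean S_B - S_n)` with an energy-*minimizing* Metropolis rule
(`accept if u < exp(E_now - E_new)`), makes same-compartment contacts and
strong-compartment surface placement *repulsive* — the opposite of the
self-association the model describes. The default `sign_mode="attractive"`
therefore minimizes the negation of that expression; only this convention
reproduces polarized compartments and the published correlation signs.
`sign_mode="as_printed"` retains the literal reading for comparison.

**Moves and contacts.** Proposals displace one uniform monomer to one of
its six axis neighbours; occupied sites and chain-bound violations abandon
the attempt without consuming the accepted-move budget or a Metropolis
draw. Contacts are strict Euclidean `< 2` lattice units (squared distance
1, 2 or 3); the adjacency bound `1 <= d <= 4` has its lower half vacuous
for distinct integer sites. Runs count 60,000 *accepted* moves; ensembles
are 100 independent runs seeded from the base seed via `SeedSequence`.

**Exact surface geometry.** The surface term needs the hull-vertex set
after every candidate move, and lattice conformations are full of exact
degeneracies (coplanar facets, points on edges). The compiled kernel builds
the hull with exact integer orientation predicates under a symbolic
perturbation along the moment curve (point `i` displaced by
`eps * (t, t^2, t^3)`, `t = i + 1`): the orientation sign is the first
non-vanishing coefficient of the eps-expansion, whose top term is a
Vandermonde determinant that never vanishes, so the incremental hull never
meets a degenerate case. Hull triangles then yield exact integer supporting
planes, and a monomer is a vertex iff the supporting planes through it span
rank 3. The same classification implemented independently on top of Qhull's
triangulation backs the full-recomputation energy oracle; the two routes
are asserted equal in tests, and kernel trajectories are asserted
bit-identical to a pure-Python reference sampler. Flat (no 3D corner)
configurations count every monomer as surface. The kernel skips hull
recomputation only when the moved monomer is not a vertex and its proposal
stays strictly inside the cached hull, which provably leaves the vertex set
unchanged.

**Initial conformations** are random walks with bond vectors drawn
uniformly from all displacements of length 1-4, retrying on collision;
the generator is a documented choice (unspecified by the procedure).

**Equilibration caveat.** Whether 60,000 accepted moves reach equilibrium
depends on the score vector. With the synthetic stand-in scores the
contact-only presets are still relaxing at 60,000 moves (mean energy keeps
falling out to ~10x longer runs, where the observed and control
polarization medians converge). The ensemble medians are therefore
sensitive to the score input; the correlation *signs* between scores and
surface ratios are robust across score vectors and are the model's
qualitative predictions.

## Synthetic data

The generators emulate: fields of view tiled with cells whose membrane
ridges, nuclear and nucleolar ellipsoids drive segmentation and masking
(Poisson shot noise over constant background); chromatin traces as 3D
fractional Brownian paths whose Hurst index equals the planted power-law
exponent of mean distance versus genomic separation, with planted
two-compartment displacement along a random axis, ~50 nm Gaussian
localization noise (the order of FISH fitting precision) and 10% uniform
locus dropout; RNA stacks with 3D Gaussian spots lit in exactly the four
barcode rounds, per-round drift applied to spots and fiducial beads alike;
and Hi-C-like counts drawn multinomially from trace contact frequencies.
They do not emulate optical aberrations, bleed-through, autofluorescence,
cell-shape irregularity, structured (non-uniform) locus dropout, or
sequence-dependent contact structure beyond the planted power law and
compartments — so passing tests demonstrate correct recovery of planted
structure, not robustness to every real-data pathology.

The bundled 50-locus compartment-score vector is a *synthetic stand-in* for
a measured score profile: two fixed low-frequency harmonics plus seeded
jitter, unit norm, chosen once to reproduce the character of measured
first-PC score profiles (smooth zero-crossing oscillation, many
weak-identity loci). Simulation medians quoted anywhere in this repository
were computed with this vector and will differ for other score inputs.

## Problem sizes

The test suite and the acceptance script run, as the package's own choice
of scale: ensembles of 100 runs x 60,000 accepted moves per preset;
segmentation on 16-cell 512x512x8 scenes; decoding on 10-gene, ~400-molecule
noiseless phantoms; distance/compartment statistics on 250-500 traces of 50
loci. Statistical checks are seeded and deterministic.
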