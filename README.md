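# nucleotrace

Analytics for multiplexed imaging of nucleome architectures: chromatin
tracing, combinatorial RNA barcode decoding, multiscale compartment and
nuclear-association statistics, and a lattice-polymer Monte Carlo model of
chromosome compartmentalization — exercised end-to-end on synthetic phantom
data with known ground truth.

## Who this is for

Labs doing sequential DNA-FISH chromatin tracing combined with multiplexed
RNA imaging (MERFISH-style) in tissue: the package covers the computational
path from raw 3D image stacks (membrane, nuclear and nucleolar stains,
per-round FISH images, fiducial beads) to per-chromosome traces, A/B
compartment scores, polarization and association statistics, per-cell
expression matrices, and a minimal polymer model that asks which
interactions suffice to explain the observed chromosome organization.

## The core quantities

**Compartment scores.** From chromatin traces, the mean spatial distance
matrix `D_ij` of the probed loci is normalized by a power-law fit
`E[D] = A * g^k` of distance versus genomic separation `g`; rows of the
normalized matrix are correlated (Pearson), and the first principal
component of the correlation matrix gives one coefficient per locus — the
compartment score `S_i`, oriented so that scores correlate positively with
gene density. Positive scores mark compartment A (active), negative
compartment B (inactive).

**Polarization index.** For one chromosome copy, build the 3D convex hulls
of the compartment-A loci and the compartment-B loci, with volumes `V_A`,
`V_B` and intersection volume `V_S`:

```
PI = sqrt((1 - V_S / V_A) * (1 - V_S / V_B))
```

PI = 1 means side-by-side (fully polarized) compartments; PI = 0 means full
overlap or one compartment wrapping the other. Observed values are compared
against controls that shuffle the A/B labels while preserving group sizes
(two-sided Wilcoxon rank-sum).

**Association and surface ratios.** A locus is lamina- (nucleolus-)
associated in a chromosome copy when it lies within 200 nm of the
nuclear-edge (nucleolus) voxel mask; it is on the chromosome surface when it
is a vertex of the convex hull of all imaged loci of that copy. Ratios are
fractions of informative copies, per locus.

**Barcode decoding.** RNA species carry 16-bit barcodes of Hamming weight 4
with pairwise distance >= 4. Each imaging round is binarized (background
opening, regional maxima above a screened threshold, 3x3 dilation), the
16-bit word at every pixel is matched against the codebook (optionally with
one-bit error correction), and adjacent same-gene pixels merge into
molecules.

**Polymer model.** A self-avoiding 50-monomer chain on a cubic lattice
(consecutive monomers 1-4 lattice units apart) with compartment-scored
interactions: same-compartment contacts closer than 2 units contribute
`g_AA * S_i * S_j` or `g_BB * S_p * S_q`, and hull-vertex (surface) monomers
contribute `g_AS * (S_m - mean S_A)` or `g_BS * (mean S_B - S_n)`.
Metropolis sampling runs for 60,000 accepted single-monomer moves; 100
independent runs form an ensemble. Presets: `bb_only` (0, 50, 0, 0),
`aa_bb` (50, 50, 0, 0), `full` (50, 50, 40, 25). See `docs/methods.md` for
the sign convention.

## Worked example

Run a small ensemble of the polymer model with intra-chromosomal A-A and
B-B attractions on the bundled synthetic compartment-score vector:

```
$ nucleotrace simulate --preset aa_bb --runs 10 --moves 20000 --seed 7 --out simdemo
{
  "preset": "aa_bb",
  "median_pi_observed": 0.5869401628493939,
  "median_pi_control": 0.24349520551062265,
  "corr_surface_score": {
    "all":  [0.16261788879601913, 0.25918118182450334],
    "A":   [-0.21096106744733795, 0.24645716280213575],
    "B":    [0.551510429218073,   0.01766259871591555]
  }
}
```

The observed median polarization index (0.59) sits well above the
label-shuffled control (0.24): intra-chromosomal self-association alone
already produces side-by-side A/B compartments. The score-versus-surface
correlations are negative for A monomers and positive for B monomers
(each pair is Pearson r with its p value) — i.e. the strongest-scored
monomers bury *inward* under contact interactions only, which is the
opposite of what is seen in imaging data and what the `full` preset (adding
surface interactions) produces. Conformations and per-run summaries land in
`simdemo/`.

The same library functions are available programmatically
(`nucleotrace.simulator.simulate_ensemble`,
`nucleotrace.tracing.compartment_scores`,
`nucleotrace.architecture.polarization_index`, ...), and
`nucleotrace phantom / decode / architecture / pipeline` expose the imaging
side of the toolkit from the shell.

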