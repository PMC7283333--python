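"""Ground-truth phantoms for every stage of the pipeline.

Each generator is a pure function of its seed and emulates one imaged
quantity: membrane/nucleus/nucleolus stacks for segmentation and masking,
chromatin traces with a planted power-law distance scaling and planted
two-compartment polarization, multiplexed RNA stacks with combinatorial
barcodes and per-round drift, and Hi-C-like contact counts sampled from
traces. The planted parameters are returned alongside the images so that
every downstream operator can be tested against known truth.

Defaults model the real study conditions: 107.9 nm pixels with a 200 nm
z-step, ~50 nm localization noise on traced loci, 10% random locus dropout,
two chromosome copies per nucleus, and diffraction-limited spots with
Poisson shot noise over a constant background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import (
    DEFAULT_VOXEL_SIZE,
    ChromatinTrace,
    Codebook,
    GenomicRegion,
    ImageStack3D,
)

__all__ = [
    "ScenePhantom",
    "gen_scene",
    "gen_traces",
    "gen_merfish_stacks",
    "gen_hic_counts",
    "gen_regions",
    "synthetic_compartment_scores",
]

#: Planted localization noise on trace positions, nm (FISH fitting precision).
TRACE_NOISE_NM = 50.0
#: Planted fraction of loci dropped from each trace.
DROPOUT_DEFAULT = 0.1
#: Mean spatial distance between genomically adjacent loci, nm.
STEP_NM_DEFAULT = 400.0
#: Centroid displacement of each compartment at full polarization, nm.
POLARIZATION_OFFSET_NM = 600.0


@dataclass
class ScenePhantom:
    """Planted truth for one synthetic field of view."""

    rng_seed: int
    voxel_size: tuple[float, float, float]
    cell_centers: np.ndarray                     # (n_cells, 2) (y, x) px
    label_map: np.ndarray                        # (ny, nx) planted cell labels
    nucleus_ellipsoids: list[dict]               # center/semiaxes in voxel units
    nucleolus_ellipsoids: list[dict]
    true_traces: list[ChromatinTrace] = field(default_factory=list)
    true_molecules: list[tuple[str, tuple[int, int, int]]] = field(default_factory=list)
    drift_truth: np.ndarray | None = None        # (n_rounds, 3) nm


def _ellipsoid_mask(shape_zyx, center_zyx, semi_zyx) -> np.ndarray:
    nz, ny, nx = shape_zyx
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = center_zyx
    az, ay, ax = semi_zyx
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def gen_scene(
    n_cells: int,
    fov_shape: tuple[int, int, int] = (512, 512, 10),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
    scores: np.ndarray | None = None,
    membrane_amp: float = 200.0,
    background: float = 20.0,
) -> tuple[ScenePhantom, dict[str, ImageStack3D]]:
    """Synthetic field of view: packed cells, nuclei, nucleoli, traces.

    ``fov_shape`` is (ny, nx, nz). Cells tile the field as a jittered grid of
    Voronoi regions whose boundaries carry the bright membrane signal; each
    cell holds one ellipsoidal nucleus with one nucleolus strictly inside it,
    and two chromosome copies traced inside the nucleus. Poisson shot noise
    is applied to every channel. Identical seeds give byte-identical stacks.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ny, nx, nz = fov_shape
    grid = int(np.ceil(np.sqrt(n_cells)))
    cell_w, cell_h = nx // grid, ny // grid
    if min(cell_w, cell_h) < 64:
        raise ValueError(
            f"field of view {ny}x{nx} too small for {n_cells} cells "
            f"(cell pitch {cell_h}x{cell_w} px < 64 px)"
        )
    rng = np.random.default_rng(seed)

    centers = []
    for i in range(n_cells):
        gy, gx = divmod(i, grid)
        cy = (gy + 0.5) * cell_h + rng.uniform(-0.08, 0.08) * cell_h
        cx = (gx + 0.5) * cell_w + rng.uniform(-0.08, 0.08) * cell_w
        centers.append((cy, cx))
    centers = np.asarray(centers)

    yy, xx = np.mgrid[:ny, :nx]
    d2 = (yy[..., None] - centers[:, 0]) ** 2 + (xx[..., None] - centers[:, 1]) ** 2
    label_map = np.argmin(d2, axis=-1).astype(np.int32) + 1

    # membrane channel: bright ridges on the Voronoi boundaries
    boundary = np.zeros((ny, nx), dtype=bool)
    boundary[:-1] |= label_map[:-1] != label_map[1:]
    boundary[:, :-1] |= label_map[:, :-1] != label_map[:, 1:]
    boundary[0] = boundary[-1] = True
    boundary[:, 0] = boundary[:, -1] = True
    mem2d = gaussian_filter(boundary.astype(float) * membrane_amp, sigma=2.0)
    membrane = np.repeat(mem2d[None], nz, axis=0) + background

    nucleus_img = np.full((nz, ny, nx), 10.0)
    fib_img = np.full((nz, ny, nx), 10.0)
    nuclei, nucleoli = [], []
    for cy, cx in centers:
        semi = (
            max(2.0, 0.35 * nz),
            0.30 * cell_h * rng.uniform(0.9, 1.1),
            0.30 * cell_w * rng.uniform(0.9, 1.1),
        )
        center = (nz / 2.0, cy, cx)
        nuclei.append({"center_zyx": center, "semi_zyx": semi})
        nucleus_img[_ellipsoid_mask((nz, ny, nx), center, semi)] += 150.0
        # nucleolus strictly inside: scaled axes, bounded offset
        nsemi = tuple(0.35 * s for s in semi)
        off = rng.uniform(-0.3, 0.3, size=3) * np.array(semi)
        ncen = tuple(np.array(center) + off * np.array([0.5, 1.0, 1.0]) * 0.5)
        nucleoli.append({"center_zyx": ncen, "semi_zyx": nsemi})
        fib_img[_ellipsoid_mask((nz, ny, nx), ncen, nsemi)] += 300.0

    nucleus_img = gaussian_filter(nucleus_img, sigma=(0.5, 2.0, 2.0))
    fib_img = gaussian_filter(fib_img, sigma=(0.5, 1.5, 1.5))

    if scores is None:
        scores = synthetic_compartment_scores()
    sx, sy, sz = voxel_size
    trace_centers = [
        (c["center_zyx"][2] * sx, c["center_zyx"][1] * sy, c["center_zyx"][0] * sz)
        for c in nuclei
    ]
    traces = gen_traces(
        n_cells,
        scores,
        polarization_strength=0.8,
        powerlaw_exponent=0.33,
        seed=int(rng.integers(2**31)),
        centers=trace_centers,
    )

    stacks = {
        "membrane": ImageStack3D(
            rng.poisson(membrane).astype(np.float64), voxel_size, "membrane"
        ),
        "nucleus": ImageStack3D(
            rng.poisson(nucleus_img).astype(np.float64), voxel_size, "nucleus"
        ),
        "fibrillarin": ImageStack3D(
            rng.poisson(fib_img).astype(np.float64), voxel_size, "fibrillarin"
        ),
    }
    phantom = ScenePhantom(
        rng_seed=seed,
        voxel_size=voxel_size,
        cell_centers=centers,
        label_map=label_map,
        nucleus_ellipsoids=nuclei,
        nucleolus_ellipsoids=nucleoli,
        true_traces=traces,
    )
    return phantom, stacks


def _fbm_cholesky(n: int, hurst: float) -> np.ndarray:
    """Cholesky factor of fractional-Brownian-motion covariance."""
    idx = np.arange(n, dtype=float)
    gij = np.abs(idx[:, None] - idx[None, :])
    cov = 0.5 * (
        idx[:, None] ** (2 * hurst)
        + idx[None, :] ** (2 * hurst)
        - gij ** (2 * hurst)
    )
    return np.linalg.cholesky(cov + 1e-9 * np.eye(n))


def gen_traces(
    n_cells: int,
    scores: np.ndarray,
    polarization_strength: float = 0.0,
    powerlaw_exponent: float = 0.33,
    seed: int = 0,
    copies_per_cell: int = 2,
    noise_nm: float = TRACE_NOISE_NM,
    dropout: float = DROPOUT_DEFAULT,
    step_nm: float = STEP_NM_DEFAULT,
    polarization_offset_nm: float = POLARIZATION_OFFSET_NM,
    centers: list[tuple[float, float, float]] | None = None,
) -> list[ChromatinTrace]:
    """Chromatin traces with planted scaling and planted polarization.

    Locus positions follow a 3D fractional Brownian path whose Hurst index
    equals ``powerlaw_exponent``, so the mean pairwise distance scales as
    genomic separation to that power. Positive- and negative-score loci are
    then displaced in opposite directions along a random axis by
    ``polarization_strength * polarization_offset_nm``, Gaussian localization
    noise is added, and a ``dropout`` fraction of loci is set missing.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0.0 <= polarization_strength <= 1.0:
        raise ValueError("polarization_strength must be in [0, 1]")
    if not 0.0 < powerlaw_exponent < 1.0:
        raise ValueError("powerlaw_exponent must be in (0, 1)")
    n_loci = scores.shape[0]
    rng = np.random.default_rng(seed)
    chol = _fbm_cholesky(n_loci, powerlaw_exponent)
    # per-coordinate sigma so that E||X_i - X_j|| = step_nm * |i-j|**H
    sigma = step_nm / (2.0 * np.sqrt(2.0 / np.pi))
    sign = np.where(scores > 0, 1.0, -1.0)

    traces = []
    for cell in range(n_cells):
        if centers is not None:
            base = np.asarray(centers[cell], dtype=float)
        else:
            base = rng.uniform(0, 50_000.0, size=3)
        for copy in range(copies_per_cell):
            offset = rng.normal(scale=1500.0, size=3) if copies_per_cell > 1 else 0.0
            path = sigma * (chol @ rng.standard_normal((n_loci, 3)))
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            disp = polarization_strength * polarization_offset_nm
            pos = (
                base
                + offset
                + path
                + sign[:, None] * disp * axis[None, :]
                + rng.normal(scale=noise_nm, size=(n_loci, 3))
            )
            if dropout > 0:
                pos[rng.uniform(size=n_loci) < dropout] = np.nan
            traces.append(ChromatinTrace(cell_id=cell, copy_id=copy, positions=pos))
    return traces


def gen_merfish_stacks(
    codebook: Codebook,
    molecules_per_gene: int,
    psf_sigma: float = 1.2,
    drift_truth: np.ndarray | None = None,
    bead_count: int = 10,
    seed: int = 0,
    fov_shape: tuple[int, int, int] = (128, 128, 6),
    amplitude: float = 500.0,
    background: float = 5.0,
    psf_sigma_z: float = 0.8,
    noise: bool = True,
    snap_z: bool = False,
) -> tuple[list[ImageStack3D], list[ImageStack3D], list[tuple[str, tuple[int, int, int]]], np.ndarray]:
    """Sixteen per-round RNA stacks plus a fiducial-bead channel per round.

    Each planted molecule renders as a 3D Gaussian spot in exactly the four
    rounds where its barcode bit is one; the per-round drift offsets (px) are
    applied to molecules and beads alike. With ``snap_z`` molecules sit at
    plane centers, so each appears in a single dominant z-plane — the regime
    the per-plane decoder assumes when counting molecules. Returns
    ``(rna_stacks, bead_stacks, molecules, drift_truth)`` where molecules are
    ``(gene_id, (x, y, z))`` true voxel positions (undrifted frame).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    n_rounds = Codebook.N_BITS
    ny, nx, nz = fov_shape
    if drift_truth is None:
        drift_truth = np.zeros((n_rounds, 3))
    drift_truth = np.asarray(drift_truth, dtype=float)
    rng = np.random.default_rng(seed)

    margin = 6 + int(np.ceil(np.abs(drift_truth).max()))
    if 2 * margin >= min(nx, ny):
        raise ValueError("field of view too small for the requested drift margin")
    molecules = []
    mol_pos, mol_word = [], []
    for gene, word in zip(codebook.genes, codebook.words):
        for _ in range(molecules_per_gene):
            x = rng.uniform(margin, nx - margin)
            y = rng.uniform(margin, ny - margin)
            z = rng.uniform(1.0, nz - 2.0)
            if snap_z:
                z = float(round(z))
            molecules.append((gene, (int(round(x)), int(round(y)), int(round(z)))))
            mol_pos.append((x, y, z))
            mol_word.append(word)
    mol_pos = np.asarray(mol_pos).reshape(-1, 3)
    mol_word = np.asarray(mol_word).reshape(-1, Codebook.N_BITS)

    bead_pos = np.column_stack(
        [
            rng.uniform(margin, nx - margin, size=bead_count),
            rng.uniform(margin, ny - margin, size=bead_count),
            rng.uniform(1.0, nz - 2.0, size=bead_count),
        ]
    )

    def render(points_xyz, amp, out):
        for x, y, z in points_xyz:
            if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
                raise ValueError(f"spot at ({x:.1f}, {y:.1f}, {z:.1f}) outside the field of view")
            x0, x1 = max(0, int(x - 5)), min(nx, int(x + 6))
            y0, y1 = max(0, int(y - 5)), min(ny, int(y + 6))
            zz, yy, xx = np.ogrid[0:nz, y0:y1, x0:x1]
            out[:, y0:y1, x0:x1] += amp * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * psf_sigma**2)
                - ((zz - z) ** 2) / (2 * psf_sigma_z**2)
            )

    rna_stacks, bead_stacks = [], []
    for r in range(n_rounds):
        img = np.full((nz, ny, nx), background, dtype=float)
        on = mol_word[:, r] == 1
        render(mol_pos[on] + drift_truth[r], amplitude, img)
        bead_img = np.full((nz, ny, nx), background, dtype=float)
        render(bead_pos + drift_truth[r], 4 * amplitude, bead_img)
        if noise:
            img = rng.poisson(img).astype(float)
            bead_img = rng.poisson(bead_img).astype(float)
        rna_stacks.append(ImageStack3D(img, channel="rna", round_index=r))
        bead_stacks.append(ImageStack3D(bead_img, channel="beads", round_index=r))
    return rna_stacks, bead_stacks, molecules, drift_truth


def gen_hic_counts(
    traces: list[ChromatinTrace],
    contact_threshold_nm: float = 150.0,
    depth: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Hi-C-like contact counts sampled from trace contact frequencies.

    Counts are multinomial over locus pairs with probabilities proportional
    to the empirical contact frequency of the traces at the threshold,
    totalling ``depth``; the matrix is symmetric with a zero diagonal.
    """
    from .tracing import contact_probability_matrix

    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    if depth <= 0:
        raise ValueError("depth must be positive")
    prob, _ = contact_probability_matrix(traces, contact_threshold_nm)
    n = prob.shape[0]
    iu = np.triu_indices(n, k=1)
    p = np.nan_to_num(prob[iu])
    if p.sum() <= 0:
        return np.zeros((n, n), dtype=int)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(depth, p / p.sum())
    counts = np.zeros((n, n), dtype=int)
    counts[iu] = draws
    counts += counts.T
    return counts


def gen_regions(
    scores: np.ndarray,
    chrom: str = "chr19",
    start_bp: int = 3_000_000,
    spacing_bp: int = 1_200_000,
    length_bp: int = 100_000,
    density_coupling: float = 20.0,
    seed: int = 0,
) -> list[GenomicRegion]:
    """Evenly spaced probed regions with gene density coupled to the scores.

    Gene density is planted to correlate positively with the compartment
    score (active compartments are gene-rich), which is what the scoring
    orientation convention relies on.
    """
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    density = 8.0 + density_coupling * scores + rng.normal(scale=0.5, size=scores.size)
    return [
        GenomicRegion(
            chrom=chrom,
            start=start_bp + i * spacing_bp,
            end=start_bp + i * spacing_bp + length_bp,
            region_id=f"TAD{i + 1}",
            gene_density=float(max(0.1, density[i])),
        )
        for i in range(scores.size)
    ]


def gen_codebook(n_genes: int, seed: int = 0) -> "Codebook":
    """Deterministic barcode codebook: 16-bit, weight-4, min pairwise HD 4.

    Words are drawn greedily from a seeded shuffle of all weight-4 words,
    keeping those at Hamming distance >= 4 from every word kept so far.
    """
    from itertools import combinations

    from .decoding import validate_codebook

    rng = np.random.default_rng(seed)
    candidates = []
    for ones in combinations(range(Codebook.N_BITS), Codebook.WEIGHT):
        w = np.zeros(Codebook.N_BITS, dtype=np.uint8)
        w[list(ones)] = 1
        candidates.append(w)
    candidates = np.array(candidates)
    rng.shuffle(candidates)
    kept: list[np.ndarray] = []
    for w in candidates:
        if all(int((w != k).sum()) >= Codebook.MIN_HD for k in kept):
            kept.append(w)
            if len(kept) == n_genes:
                break
    if len(kept) < n_genes:
        raise ValueError(f"only {len(kept)} words available at this distance")
    words = {
        f"gene{i:03d}": "".join(str(int(b)) for b in w) for i, w in enumerate(kept)
    }
    return validate_codebook(words)


def synthetic_compartment_scores(n_loci: int = 50) -> np.ndarray:
    """Synthetic stand-in for a measured 50-TAD compartment-score vector.

    This is *not* measured data: it is a deterministic synthetic vector with
    the statistical character of first-principal-component compartment
    scores along a chromosome. Measured score profiles are smooth,
    low-frequency oscillations along the genomic coordinate — compartments
    alternate in blocks of a few TADs, scores cross zero gradually, many
    TADs have weak (near-zero) compartment identity and a few have strong
    identity — and the coefficient vector has unit norm. The vector is built
    from two fixed low-frequency harmonics plus seeded jitter to reproduce
    that character. Use it wherever a realistic score input is needed and no
    measurement is available.
    """
    rng = np.random.default_rng(7)  # fixed: this vector is a named constant
    x = np.arange(n_loci) / n_loci
    profile = (
        np.sin(2 * np.pi * 2.5 * x + 0.7)
        + 0.6 * np.sin(2 * np.pi * 5.5 * x + 2.1)
        + 0.25 * rng.standard_normal(n_loci)
    )
    return profile / np.linalg.norm(profile)
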