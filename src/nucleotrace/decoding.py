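"""Pixel-based combinatorial barcode decoding of multiplexed RNA images.

Each RNA species carries a 16-bit binary barcode of constant Hamming weight
4 with pairwise Hamming distance at least 4 (an error-robust code: any
single bit flip is detectable, and correctable to a unique codeword when
error correction is enabled). The 16 imaging rounds are binarized
individually, the per-voxel bit patterns are matched against the codebook,
and adjacent same-gene pixels within a z-plane merge into single molecules.
Per-cell expression counting erodes each cell's area to avoid boundary
misassignment and applies the cell-quality exclusions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk, erosion, opening

_SQUARE3 = np.ones((3, 3), dtype=bool)

from .types import CellLabelMap, Codebook, ExpressionMatrix, ImageStack3D, Molecule

__all__ = [
    "validate_codebook",
    "binarize_round",
    "decode_pixels",
    "calibrate_thresholds",
    "count_per_cell",
]

#: Cells with fewer detected molecules than this are flagged.
MIN_MOLECULES_PER_CELL = 10

#: Cell-area QC bounds, shared with segmentation.
MIN_CELL_AREA_PX = 2500
MAX_CELL_AREA_PX = 20000


def validate_codebook(words: dict[str, str]) -> Codebook:
    """Validate gene -> 16-bit word assignments.

    Every word must have exactly 4 on-bits and every pair of words must be
    at least Hamming distance 4 apart; violations are reported with the
    offending gene names.
    """
    genes = list(words)
    mat = np.zeros((len(genes), Codebook.N_BITS), dtype=np.uint8)
    for i, g in enumerate(genes):
        w = words[g]
        if len(w) != Codebook.N_BITS or set(w) - {"0", "1"}:
            raise ValueError(f"gene {g}: word must be a 16-character bitstring")
        mat[i] = [int(ch) for ch in w]
        if mat[i].sum() != Codebook.WEIGHT:
            raise ValueError(
                f"gene {g}: word weight {int(mat[i].sum())} != {Codebook.WEIGHT}"
            )
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            hd = int((mat[i] != mat[j]).sum())
            if hd < Codebook.MIN_HD:
                raise ValueError(
                    f"genes {genes[i]} and {genes[j]}: Hamming distance {hd} < {Codebook.MIN_HD}"
                )
    return Codebook(genes=genes, words=mat)


def binarize_round(raw_stack: ImageStack3D, intensity_threshold: float) -> np.ndarray:
    """Binarize one imaging round into RNA-occupied pixels.

    Per z-plane: the background is a morphological opening with a disk of
    radius 5 px and is subtracted; regional maxima of the residual with
    intensity above the threshold become ones; the binary image is dilated
    with a 3x3 square so a molecule may occupy more than one pixel.
    """
    if intensity_threshold <= 0:
        raise ValueError("threshold must be positive")
    vox = raw_stack.voxels
    out = np.zeros(vox.shape, dtype=bool)
    selem = disk(5)
    for z in range(vox.shape[0]):
        plane = vox[z].astype(float)
        residual = plane - opening(plane, selem)
        # regional maxima: pixels equal to the local maximum of the residual
        is_max = residual == ndimage.maximum_filter(residual, size=3)
        hits = is_max & (residual > intensity_threshold)
        out[z] = dilation(hits, _SQUARE3)
    return out


def _word_lookup(codebook: Codebook, allow_one_bit_correction: bool) -> np.ndarray:
    """Map every 16-bit integer to a gene index (-1 = no match)."""
    lut = np.full(1 << Codebook.N_BITS, -1, dtype=np.int32)
    ints = codebook.word_ints()
    for gi, wi in enumerate(ints):
        lut[wi] = gi
    if allow_one_bit_correction:
        for gi, wi in enumerate(ints):
            for b in range(Codebook.N_BITS):
                neighbor = wi ^ (1 << b)
                if lut[neighbor] == -1:
                    lut[neighbor] = gi
                # MHD >= 4 guarantees each distance-1 word is near at most
                # one codeword, so collisions cannot occur
    return lut


def decode_pixels(
    bits: list[np.ndarray] | np.ndarray,
    codebook: Codebook,
    allow_one_bit_correction: bool = False,
) -> list[Molecule]:
    """Decode 16 aligned binary stacks into molecules.

    Each voxel's 16-bit pattern is matched exactly against the codebook; with
    ``allow_one_bit_correction`` patterns at Hamming distance 1 from a unique
    codeword are corrected. Adjacent same-gene pixels merge into one molecule
    within each z-plane (8-connectivity; planes are decoded independently).
    The representative voxel is the rounded component centroid and
    ``pixel_count`` records the component size.
    """
    stacks = [np.asarray(b, dtype=bool) for b in bits]
    if len(stacks) != Codebook.N_BITS:
        raise ValueError(f"expected {Codebook.N_BITS} rounds, got {len(stacks)}")
    shape = stacks[0].shape
    if any(s.shape != shape for s in stacks):
        raise ValueError("round stacks differ in shape")
    words = np.zeros(shape, dtype=np.int32)
    for r, s in enumerate(stacks):
        words |= s.astype(np.int32) << r
    lut = _word_lookup(codebook, allow_one_bit_correction)
    gene_idx = lut[words]  # (nz, ny, nx), -1 where unmatched

    molecules: list[Molecule] = []
    for z in range(shape[0]):
        plane = gene_idx[z]
        for gi in np.unique(plane):
            if gi < 0:
                continue
            comps = cc_label(plane == gi, connectivity=2)
            for prop in regionprops(comps):
                cy, cx = prop.centroid
                molecules.append(
                    Molecule(
                        gene_id=codebook.genes[gi],
                        voxel=(int(round(cx)), int(round(cy)), z),
                        pixel_count=int(prop.area),
                        z_plane=z,
                    )
                )
    return molecules


def _maxima_intensities(stack: ImageStack3D) -> np.ndarray:
    """Background-subtracted intensities of the candidate regional maxima."""
    vals = []
    selem = disk(5)
    for z in range(stack.voxels.shape[0]):
        plane = stack.voxels[z].astype(float)
        residual = plane - opening(plane, selem)
        is_max = residual == ndimage.maximum_filter(residual, size=3)
        v = residual[is_max]
        vals.append(v[v > 0])
    return np.concatenate(vals) if vals else np.zeros(0)


def calibrate_thresholds(
    raw_rounds: list[ImageStack3D],
    codebook: Codebook,
    reference_abundances: dict[str, float],
    n_grid: int = 20,
    max_sweeps: int = 2,
) -> np.ndarray:
    """Per-round binarization thresholds by adaptive screening.

    The screening targets two published criteria, with the round-loading
    criterion acting as a constraint and the correlation criterion as the
    objective: (1) the per-round on-pixel totals must stay proportional (to
    within a factor of 2) to the round loading predicted from the reference
    abundances and the codebook — each round's expected share of signal is
    the abundance-weighted sum of its bit column; (2) within that constraint,
    a deterministic coordinate-wise search maximizes the Pearson correlation
    between log decoded per-gene totals and log reference abundances. Each
    round's search grid is 20 logarithmically spaced values spanning the
    50th-99.9th percentile of its candidate regional-maxima intensities
    (the population the threshold is applied to).

    Both published criteria are invariant to a global rescaling of all
    thresholds along the correlation plateau, so the absolute scale is pinned
    by a final deterministic pass that raises each threshold to the highest
    grid value that does not degrade the correlation: the most conservative
    detection consistent with the fit, which also suppresses duplicate
    detections of one molecule in adjacent z-planes.
    """
    ref = np.array([reference_abundances.get(g, 0.0) for g in codebook.genes])
    if (ref > 0).sum() < 2:
        raise ValueError("need positive reference abundances for at least 2 genes")
    if np.allclose(ref[ref > 0], ref[ref > 0][0]) and (ref > 0).all():
        raise ValueError("degenerate reference: all abundances equal")
    n_rounds = Codebook.N_BITS
    if len(raw_rounds) != n_rounds:
        raise ValueError(f"expected {n_rounds} rounds")

    grids, cached = [], []
    for stack in raw_rounds:
        vals = _maxima_intensities(stack)
        if vals.size == 0:
            raise ValueError("a round has no candidate maxima to screen")
        lo, hi = np.percentile(vals, [50, 99.9])
        lo = max(lo, 1e-6)
        hi = max(hi, lo * 1.001)
        grid = np.geomspace(lo, hi, n_grid)
        grids.append(grid)
        cached.append([binarize_round(stack, t) for t in grid])

    npix = np.array([[b.sum() for b in row] for row in cached], dtype=float)
    loading = (ref[:, None] * codebook.words).sum(axis=0)
    share = loading / loading.sum()

    def allowed(r: int, on_counts: np.ndarray) -> np.ndarray:
        """Grid points whose share of total on-pixels is within 2x of the
        predicted round loading."""
        others = on_counts.sum() - on_counts[r]
        frac = npix[r] / np.maximum(npix[r] + others, 1.0)
        ok = (frac >= share[r] / 2.0) & (frac <= min(1.0, share[r] * 2.0))
        if not ok.any():
            ok = np.zeros_like(ok)
            ok[np.argmin(np.abs(np.log((frac + 1e-9) / share[r])))] = True
        return ok

    idx = np.zeros(n_rounds, dtype=int)  # start at the permissive end

    pos = ref > 0
    logref = np.log(ref[pos])  # log scale: invariant to rescaled references
    gi = {g: i for i, g in enumerate(codebook.genes)}

    def _score(indices: np.ndarray) -> float:
        mols = decode_pixels([cached[r][indices[r]] for r in range(n_rounds)], codebook)
        counts = np.zeros(len(codebook.genes))
        for m in mols:
            counts[gi[m.gene_id]] += 1
        logc = np.log(counts[pos] + 1.0)
        if np.std(logc) == 0:
            return -1.0
        return float(np.corrcoef(logc, logref)[0, 1])

    best_score = _score(idx)
    for _ in range(max_sweeps):
        improved = False
        for r in range(n_rounds):
            on_counts = np.array([npix[q][idx[q]] for q in range(n_rounds)])
            ok = allowed(r, on_counts)
            for ti in range(n_grid):
                if ti == idx[r] or not ok[ti]:
                    continue
                trial = idx.copy()
                trial[r] = ti
                s = _score(trial)
                if s > best_score + 1e-12:
                    best_score, idx = s, trial
                    improved = True
        if not improved:
            break

    # scale-pinning pass: raise all rounds jointly to the top of the
    # correlation plateau (tolerance 0.02 on Pearson r). The plateau runs
    # along the joint direction — raising a single round strips one bit from
    # every molecule lit in that round, while raising all rounds together
    # only drops whole (duplicate or spurious) detections.
    while idx.min() < n_grid - 1:
        trial = np.minimum(idx + 1, n_grid - 1)
        if _score(trial) < best_score - 0.02:
            break
        idx = trial
    best_score = _score(idx)
    return np.array([grids[r][idx[r]] for r in range(n_rounds)])


def count_per_cell(
    molecules: list[Molecule],
    labels: CellLabelMap,
    genes: list[str],
) -> ExpressionMatrix:
    """Per-cell molecule counts with boundary erosion and QC flags.

    Each cell's area is shrunk by erosion with a disk of radius 3 px before
    molecules are assigned, reducing misassignment between neighbouring
    cells; molecules falling outside every eroded cell stay unassigned.
    Cells are flagged when their area is outside (2500, 20000) px or they
    hold fewer than 10 molecules.
    """
    lab = labels.labels
    eroded = np.zeros_like(lab)
    selem = disk(3)
    for cell in np.unique(lab):
        if cell == 0:
            continue
        mask = erosion(lab == cell, selem)
        eroded[mask] = cell

    cell_ids = [int(c) for c in np.unique(lab) if c != 0]
    gene_index = {g: i for i, g in enumerate(genes)}
    row = {c: i for i, c in enumerate(cell_ids)}
    counts = np.zeros((len(cell_ids), len(genes)), dtype=int)
    for m in molecules:
        x, y, _ = m.voxel
        if not (0 <= y < lab.shape[0] and 0 <= x < lab.shape[1]):
            continue
        cell = int(eroded[y, x])
        if cell == 0 or m.gene_id not in gene_index:
            continue
        counts[row[cell], gene_index[m.gene_id]] += 1

    flags: dict[int, str] = {}
    for cell in cell_ids:
        reason = labels.excluded.get(cell)
        area = int((lab == cell).sum())
        if reason is not None:
            flags[cell] = reason
        elif not (MIN_CELL_AREA_PX < area < MAX_CELL_AREA_PX):
            flags[cell] = "too-small" if area <= MIN_CELL_AREA_PX else "too-large"
        elif counts[row[cell]].sum() < MIN_MOLECULES_PER_CELL:
            flags[cell] = "min-count"
    return ExpressionMatrix(counts=counts, cell_ids=cell_ids, genes=list(genes), flags=flags)
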