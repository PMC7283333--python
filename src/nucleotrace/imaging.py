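"""Image-domain operators: segmentation, landmark masks, spot fitting,
drift correction and trace linking.

Cells are segmented in 2D from the membrane (WGA) stain — tissue sections
are treated as cell monolayers — by watershed on a background-flattened,
morphologically closed image. Nuclear-edge and nucleolus voxel masks
approximate the nuclear lamina and nucleoli as landmarks for association
measurements. Diffraction-limited FISH spots are localized by least-squares
3D Gaussian fits, stage drift between sequential hybridization rounds is
estimated from fiducial beads and subtracted, and drift-corrected locus
positions are linked into per-chromosome traces by spatial clustering.

Adaptive thresholding. Several steps use a local-mean "adaptive threshold"
with a sensitivity parameter. The exact local statistic is pinned here for
reproducibility: the background/threshold profile is the local mean over the
given neighbourhood, scaled by ``1.5 - sensitivity`` (higher sensitivity
lowers the threshold and marks more foreground).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import least_squares
from skimage.filters import median as median_filter
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk, erosion, reconstruction
from skimage.segmentation import watershed

from .types import (
    CellLabelMap,
    ChromatinTrace,
    DriftTable,
    ImageStack3D,
    SpotFit,
    VoxelMask,
)

__all__ = [
    "adaptive_threshold_profile",
    "segment_cells",
    "nuclear_edge_mask",
    "nucleolus_mask",
    "fit_spots_3d",
    "detect_spots",
    "estimate_drift",
    "link_traces",
]

#: Cell-area QC bounds (pixels): cells at or below/above these are excluded.
MIN_CELL_AREA_PX = 2500
MAX_CELL_AREA_PX = 20000

#: Default cutoff (nm) for single-linkage trace clustering: 1.5x the
#: expected chromosome-territory radius (~1 um for a mid-sized chromosome).
TRACE_CLUSTER_CUTOFF_NM = 1500.0


def adaptive_threshold_profile(
    image: np.ndarray, sensitivity: float, size: int | None = None
) -> np.ndarray:
    """Local-mean threshold profile.

    The neighbourhood defaults to ``2 * floor(n / 16) + 1`` of the smaller
    image side; the local mean is scaled by ``1.5 - sensitivity``.
    """
    image = np.asarray(image, dtype=float)
    if size is None:
        size = 2 * (min(image.shape) // 16) + 1
    local_mean = ndimage.uniform_filter(image, size=size, mode="reflect")
    return local_mean * (1.5 - sensitivity)


def _minmax(image: np.ndarray) -> np.ndarray:
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def segment_cells(wga_stack: ImageStack3D) -> CellLabelMap:
    """Watershed cell segmentation from the membrane stain.

    Pipeline: average the stack along z; min-max normalize; divide out an
    adaptive background (sensitivity 0.1, 41 px neighbourhood); clip to the
    1st/99th intensity percentiles; morphological closing (disk radius 15 px)
    to connect membrane boundaries; watershed. Cells with area at or below
    2500 px, at or above 20,000 px, or touching the field edge are flagged
    excluded.
    """
    img = wga_stack.voxels.mean(axis=0)
    if img.max() == img.min():
        raise ValueError("constant membrane image: nothing to segment")
    img = _minmax(img)
    background = adaptive_threshold_profile(img, sensitivity=0.1, size=41)
    flat = img / np.maximum(background, 1e-12)
    lo, hi = np.percentile(flat, [1, 99])
    flat = np.clip((flat - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    closed = closing(flat, disk(15))
    # watershed basins of the membrane ridge image; markers are the connected
    # interior plateaus (below the ridge/interior Otsu split), which keeps
    # noise minima inside one cell from fragmenting it
    from skimage.filters import threshold_otsu

    interiors = closed < threshold_otsu(closed)
    markers = cc_label(interiors)
    labels = watershed(closed, markers=markers)

    excluded: dict[int, str] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        region = labels == lab
        area = int(region.sum())
        on_edge = (
            region[0].any() or region[-1].any() or region[:, 0].any() or region[:, -1].any()
        )
        if on_edge:
            excluded[int(lab)] = "edge"
        elif area <= MIN_CELL_AREA_PX:
            excluded[int(lab)] = "too-small"
        elif area >= MAX_CELL_AREA_PX:
            excluded[int(lab)] = "too-large"
    return CellLabelMap(labels=labels.astype(np.int32), excluded=excluded)


def nuclear_edge_mask(nucleus_stack: ImageStack3D) -> VoxelMask:
    """Voxels tracing the nuclear boundaries, plane by plane.

    Per z-plane: normalize to the plane maximum; divide out an adaptive
    background (sensitivity 0.5); clip to the 1st/3rd intensity quartiles;
    opening-by-reconstruction (disk radius 25 px) to suppress noise; 2D
    gradient magnitude; Gaussian smoothing (sigma 5 px); adaptive
    binarization (sensitivity 0.1). Empty planes give all-false planes.
    """
    stack = nucleus_stack.voxels
    out = np.zeros(stack.shape, dtype=bool)
    for z in range(stack.shape[0]):
        plane = stack[z].astype(float)
        if plane.max() <= 0:
            continue
        plane = plane / plane.max()
        background = adaptive_threshold_profile(plane, sensitivity=0.5)
        flat = plane / np.maximum(background, 1e-12)
        q1, q3 = np.percentile(flat, [25, 75])
        if q3 == q1:
            continue
        flat = np.clip((flat - q1) / (q3 - q1), 0.0, 1.0)
        seed = erosion(flat, disk(25))
        opened = reconstruction(seed, flat)
        gy, gx = np.gradient(opened)
        grad = ndimage.gaussian_filter(np.hypot(gx, gy), sigma=5)
        if grad.max() <= 0:
            continue
        thresh = adaptive_threshold_profile(grad, sensitivity=0.1)
        floor = 0.1 * grad.max()  # plateaus of zero gradient stay background
        out[z] = grad > np.maximum(thresh, floor)
    return VoxelMask(mask=out, voxel_size=nucleus_stack.voxel_size, kind="nuclear_edge")


def nucleolus_mask(fibrillarin_stack: ImageStack3D) -> VoxelMask:
    """Nucleolus-occupied voxels from the fibrillarin channel.

    An adaptive threshold profile is derived once from the median-filtered
    maximum projection (normalized by its maximum, which is stored as the
    normalization factor for the whole stack); every plane is then median
    filtered, normalized by that same factor, and binarized against the
    profile. A zero-intensity stack yields an all-false mask.
    """
    stack = fibrillarin_stack.voxels
    mip = median_filter(stack.max(axis=0).astype(float), footprint=disk(2))
    norm = mip.max()
    if norm <= 0:
        return VoxelMask(
            mask=np.zeros(stack.shape, dtype=bool),
            voxel_size=fibrillarin_stack.voxel_size,
            kind="nucleolus",
        )
    scaled = mip / norm
    profile = adaptive_threshold_profile(scaled, sensitivity=0.5)
    profile = np.maximum(profile, 0.3)  # bright-blob floor for sparse nucleoli
    out = np.zeros(stack.shape, dtype=bool)
    for z in range(stack.shape[0]):
        plane = median_filter(stack[z].astype(float), footprint=disk(2)) / norm
        out[z] = plane > profile
    return VoxelMask(mask=out, voxel_size=fibrillarin_stack.voxel_size, kind="nucleolus")


def _gaussian3d(params, zz, yy, xx):
    amp, x0, y0, z0, sx, sy, sz, bg = params
    return bg + amp * np.exp(
        -((xx - x0) ** 2) / (2 * sx**2)
        - ((yy - y0) ** 2) / (2 * sy**2)
        - ((zz - z0) ** 2) / (2 * sz**2)
    )


def fit_spots_3d(
    stack: ImageStack3D,
    candidate_seeds: np.ndarray,
    window_xy: int = 5,
    window_z: int = 2,
) -> list[SpotFit]:
    """Least-squares 3D Gaussian fits around candidate voxels.

    ``candidate_seeds`` is (n, 3) of (x, y, z) voxel indices. Each seed is
    fitted in a local window; a fit fails (``success=False``) when the
    optimizer does not converge, the fitted amplitude is not clearly above
    the residual noise, or the window is clipped below a minimum size — a
    failing seed never affects the others. Centers are reported in nm.
    """
    vox = stack.voxels.astype(float)
    nz, ny, nx = vox.shape
    sx_nm, sy_nm, sz_nm = stack.voxel_size
    results: list[SpotFit] = []
    for idx, (cx, cy, cz) in enumerate(np.asarray(candidate_seeds, dtype=int)):
        x0, x1 = max(0, cx - window_xy), min(nx, cx + window_xy + 1)
        y0, y1 = max(0, cy - window_xy), min(ny, cy + window_xy + 1)
        z0, z1 = max(0, cz - window_z), min(nz, cz + window_z + 1)
        fail = SpotFit(
            center_nm=(np.nan, np.nan, np.nan), amplitude=0.0,
            widths_nm=(np.nan, np.nan, np.nan), background=0.0,
            residual=np.inf, success=False, seed_index=idx,
        )
        if (x1 - x0) < 5 or (y1 - y0) < 5 or (z1 - z0) < 2:
            results.append(fail)
            continue
        win = vox[z0:z1, y0:y1, x0:x1]
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        bg0 = float(win.min())
        amp0 = float(win.max() - bg0)
        if amp0 <= 0:
            results.append(fail)
            continue
        p0 = [amp0, cx, cy, cz, 1.3, 1.3, 1.0, bg0]
        sol = least_squares(
            lambda p: (_gaussian3d(p, zz, yy, xx) - win).ravel(),
            p0,
            bounds=(
                [0, x0, y0, z0 - 0.5, 0.3, 0.3, 0.2, 0],
                [np.inf, x1 - 1, y1 - 1, z1 - 0.5, 10, 10, 10, np.inf],
            ),
            method="trf",
            max_nfev=200,
        )
        amp, fx, fy, fz, sx, sy, sz, bg = sol.x
        noise = float(np.std(win - _gaussian3d(sol.x, zz, yy, xx)))
        if not sol.success or amp <= 0 or amp <= 2 * noise:
            results.append(fail)
            continue
        results.append(
            SpotFit(
                center_nm=(fx * sx_nm, fy * sy_nm, fz * sz_nm),
                amplitude=float(amp),
                widths_nm=(sx * sx_nm, sy * sy_nm, sz * sz_nm),
                background=float(bg),
                residual=float(np.sqrt(np.mean(sol.fun**2))),
                success=True,
                seed_index=idx,
            )
        )
    return results


def detect_spots(stack: ImageStack3D, threshold: float, min_distance: int = 3) -> np.ndarray:
    """Candidate spot voxels: local intensity maxima above ``threshold``.

    Returns (n, 3) of (x, y, z) voxel indices, brightest first.
    """
    vox = stack.voxels
    footprint = np.ones((3, 2 * min_distance + 1, 2 * min_distance + 1))
    is_max = (vox == ndimage.maximum_filter(vox, footprint=footprint)) & (vox > threshold)
    zz, yy, xx = np.nonzero(is_max)
    order = np.argsort(vox[zz, yy, xx])[::-1]
    return np.column_stack([xx[order], yy[order], zz[order]])


def estimate_drift(
    bead_stacks: list[ImageStack3D],
    reference_round: int = 0,
    mode: str = "3d",
    match_radius_px: float = 5.0,
    detect_threshold: float | None = None,
) -> DriftTable:
    """Stage drift per imaging round from fiducial beads.

    Beads are localized by Gaussian fitting, matched to the reference round
    by nearest neighbour within ``match_radius_px`` after a coarse
    cross-correlation alignment, and the per-round offset is the median
    displacement of the matched beads (robust to individual mismatches).
    ``mode="2d"`` zeroes the axial component, as appropriate for decoding
    images registered in-plane; ``mode="3d"`` keeps it for chromatin tracing.
    Fewer than 3 matched beads in any round is an error. Offsets are in nm;
    applying the table subtracts them from coordinates.
    """
    from scipy.spatial import cKDTree
    from skimage.registration import phase_cross_correlation

    def _centers(stack: ImageStack3D) -> np.ndarray:
        thr = detect_threshold
        if thr is None:
            thr = float(stack.voxels.mean() + 5 * stack.voxels.std())
        seeds = detect_spots(stack, thr)
        fits = fit_spots_3d(stack, seeds)
        pts = np.array([f.center_nm for f in fits if f.success], dtype=float)
        return pts.reshape(-1, 3)

    ref_stack = bead_stacks[reference_round]
    ref = _centers(ref_stack)
    if ref.shape[0] < 3:
        raise ValueError("fewer than 3 beads localized in the reference round")
    sx, sy, _ = ref_stack.voxel_size
    tree = cKDTree(ref)
    offsets: dict[int, tuple[float, float, float]] = {}
    for i, stack in enumerate(bead_stacks):
        rnd = stack.round_index if stack.round_index is not None else i
        if rnd == reference_round:
            offsets[rnd] = (0.0, 0.0, 0.0)
            continue
        # coarse alignment on z-projections to survive large drifts
        shift_yx = phase_cross_correlation(
            ref_stack.voxels.max(axis=0), stack.voxels.max(axis=0), upsample_factor=1
        )[0]
        coarse = np.array([-shift_yx[1] * sx, -shift_yx[0] * sy, 0.0])
        pts = _centers(stack)
        if pts.shape[0] < 3:
            raise ValueError(f"fewer than 3 beads localized in round {rnd}")
        dist, j = tree.query(pts - coarse)
        keep = dist < match_radius_px * max(sx, sy)
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 beads matched in round {rnd}")
        med = np.median(pts[keep] - ref[j[keep]], axis=0)
        if mode == "2d":
            med[2] = 0.0
        offsets[rnd] = (float(med[0]), float(med[1]), float(med[2]))
    return DriftTable(offsets_nm=offsets, reference_round=reference_round)


def link_traces(
    positions: list[dict],
    n_loci: int,
    cluster_cutoff_nm: float = TRACE_CLUSTER_CUTOFF_NM,
    max_copies: int = 2,
) -> list[ChromatinTrace]:
    """Link drift-corrected locus positions into chromosome-copy traces.

    ``positions`` holds dicts with keys ``cell_id``, ``readout_id`` (locus
    index), ``x_nm``, ``y_nm``, ``z_nm`` and optional ``quality`` (fit
    amplitude). Within each nucleus the positions are partitioned into at
    most ``max_copies`` spatial clusters — the two chromosome copies of a
    diploid nucleus — by single-linkage agglomeration with the given
    distance cutoff; if the cutoff yields more clusters, the partition is
    re-cut at ``max_copies``. Each trace keeps at most one position per
    readout (the brightest fit wins); readouts with no assigned position
    stay missing. An empty nucleus yields no traces.
    """
    by_cell: dict[int, list[dict]] = {}
    for p in positions:
        by_cell.setdefault(int(p["cell_id"]), []).append(p)
    traces: list[ChromatinTrace] = []
    for cell_id, plist in sorted(by_cell.items()):
        xyz = np.array([[p["x_nm"], p["y_nm"], p["z_nm"]] for p in plist])
        if len(plist) == 1:
            assignments = np.array([1])
        else:
            links = linkage(xyz, method="single")
            assignments = fcluster(links, t=cluster_cutoff_nm, criterion="distance")
            if len(np.unique(assignments)) > max_copies:
                assignments = fcluster(links, t=max_copies, criterion="maxclust")
        for copy_id, cluster in enumerate(np.unique(assignments)):
            members = [p for p, a in zip(plist, assignments) if a == cluster]
            pos = np.full((n_loci, 3), np.nan)
            quality = np.full(n_loci, np.nan)
            for p in members:
                r = int(p["readout_id"])
                q = float(p.get("quality", 0.0))
                if np.isnan(quality[r]) or q > quality[r]:
                    pos[r] = (p["x_nm"], p["y_nm"], p["z_nm"])
                    quality[r] = q
            traces.append(
                ChromatinTrace(
                    cell_id=cell_id, copy_id=copy_id, positions=pos, quality=quality
                )
            )
    return traces
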