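"""Shared domain containers.

Coordinate conventions
----------------------
Voxel indices are 0-based ``(z, y, x)`` numpy order for arrays; physical
coordinates are ``(x, y, z)`` in nanometres, computed as index * voxel size.
All geometry downstream of the image operators is carried in nanometres,
because the biological thresholds of interest (150 nm contact, 200 nm
lamina/nucleolar association) are physical distances while the voxel grid is
anisotropic (107.9 nm laterally, 200 nm axially by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default lateral pixel size of the imaging system, nm.
DEFAULT_PIXEL_NM = 107.9
#: Default axial z-step, nm.
DEFAULT_ZSTEP_NM = 200.0
#: Default (x, y, z) voxel size, nm.
DEFAULT_VOXEL_SIZE = (DEFAULT_PIXEL_NM, DEFAULT_PIXEL_NM, DEFAULT_ZSTEP_NM)


@dataclass
class ImageStack3D:
    """A 3D fluorescence stack, stored ``(z, y, x)``.

    Parameters
    ----------
    voxels
        Non-negative finite intensities, shape ``(nz, ny, nx)``.
    voxel_size
        Physical voxel size ``(x, y, z)`` in nm.
    channel
        Free-form channel tag (``"membrane"``, ``"nucleus"``, ...).
    round_index
        Hybridization round for sequential imaging channels.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel: str = ""
    round_index: int | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:  # tolerate single-plane input
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.voxels < 0):
            raise ValueError("stack contains negative intensities")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class CellLabelMap:
    """2D segmentation result: positive integer labels, background 0.

    ``excluded`` maps label -> reason (``"edge"``, ``"too-small"``,
    ``"too-large"``); excluded labels stay present in ``labels`` so the caller
    can still see them, but analysis views should drop them.
    """

    labels: np.ndarray
    excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def retained_labels(self) -> np.ndarray:
        all_labels = np.unique(self.labels)
        all_labels = all_labels[all_labels > 0]
        return np.array([l for l in all_labels if l not in self.excluded], dtype=int)


@dataclass
class VoxelMask:
    """Binary 3D occupancy grid with anisotropic voxel size.

    ``kind`` distinguishes nuclear-edge shells from nucleolus bodies.
    """

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    kind: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("voxel mask must be 3D")

    def true_voxel_coords_nm(self) -> np.ndarray:
        """Physical (x, y, z) nm coordinates of the centers of true voxels."""
        zz, yy, xx = np.nonzero(self.mask)
        sx, sy, sz = self.voxel_size
        return np.column_stack([xx * sx, yy * sy, zz * sz]).astype(float)


@dataclass
class SpotFit:
    """Result of a 3D (or 2D) Gaussian fit to a diffraction-limited spot."""

    center_nm: tuple[float, float, float]
    amplitude: float
    widths_nm: tuple[float, float, float]
    background: float
    residual: float
    success: bool
    seed_index: int = -1


@dataclass
class DriftTable:
    """Per-round stage offsets relative to a reference round, nm (x, y, z)."""

    offsets_nm: dict[int, tuple[float, float, float]]
    reference_round: int

    def __post_init__(self) -> None:
        ref = self.offsets_nm.get(self.reference_round)
        if ref is None or any(abs(v) > 1e-9 for v in ref):
            raise ValueError("reference round offset must be (0, 0, 0)")

    def correct(self, positions_nm: np.ndarray, round_index: int) -> np.ndarray:
        """Subtract the round's offset from (n, 3) positions."""
        off = np.asarray(self.offsets_nm[round_index], dtype=float)
        return np.asarray(positions_nm, dtype=float) - off


@dataclass
class GenomicRegion:
    """A probed genomic segment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    region_id: str
    gene_density: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region {self.region_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ChromatinTrace:
    """Ordered 3D positions (nm) of the probed loci of one chromosome copy.

    ``positions`` has shape (n_loci, 3) with NaN rows for loci that were not
    detected in this copy. ``scale`` tags whether the trace is at the
    TAD scale or the fine (kb) scale; compartment scoring only applies to
    TAD-scale traces.
    """

    cell_id: int
    copy_id: int
    positions: np.ndarray
    scale: str = "tad"
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_loci, 3)")

    @property
    def n_loci(self) -> int:
        return self.positions.shape[0]

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of loci with a measured position."""
        return ~np.isnan(self.positions).any(axis=1)


@dataclass
class DistanceMatrix:
    """Pairwise mean spatial distances with per-pair counts.

    Entries with fewer than ``min_pairs`` informative traces are NaN.
    """

    mean_nm: np.ndarray
    counts: np.ndarray
    region_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.mean_nm = np.asarray(self.mean_nm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.mean_nm.shape != self.counts.shape:
            raise ValueError("mean and count matrices must share shape")
        n, m = self.mean_nm.shape
        if n != m:
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.mean_nm.shape[0]


@dataclass
class Codebook:
    """Combinatorial barcode codebook: gene -> 16-bit constant-weight word.

    Every word has Hamming weight 4 and the pairwise Hamming distance is at
    least 4, the error-robust code used for multiplexed RNA imaging.
    Bit order follows imaging-round order. Construct via
    :func:`nucleotrace.decoding.validate_codebook`.
    """

    genes: list[str]
    words: np.ndarray  # (n_genes, 16) uint8 of 0/1

    N_BITS = 16
    WEIGHT = 4
    MIN_HD = 4

    def word_ints(self) -> np.ndarray:
        """Words packed as integers, bit 0 = round 0."""
        weights = (1 << np.arange(self.N_BITS)).astype(np.int64)
        return (self.words.astype(np.int64) * weights).sum(axis=1)


@dataclass
class Molecule:
    """One decoded RNA molecule."""

    gene_id: str
    voxel: tuple[int, int, int]  # (x, y, z) voxel indices
    pixel_count: int
    z_plane: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")


@dataclass
class ExpressionMatrix:
    """Cells x genes integer counts with per-cell QC flags."""

    counts: np.ndarray  # (n_cells, n_genes)
    cell_ids: list[int]
    genes: list[str]
    flags: dict[int, str] = field(default_factory=dict)  # cell_id -> reason

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def analysis_view(self) -> tuple[np.ndarray, list[int]]:
        """Counts and ids restricted to cells passing QC."""
        keep = [i for i, cid in enumerate(self.cell_ids) if cid not in self.flags]
        return self.counts[keep], [self.cell_ids[i] for i in keep]
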