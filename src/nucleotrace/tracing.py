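"""Trace-level analytics: distance matrices, contacts, Hi-C comparison and
A/B compartment scoring.

Compartment scores are derived from imaged distances the same way A/B
compartments are called from Hi-C: the mean spatial distance matrix is
normalized by the expected power-law scaling of distance with genomic
separation, rows of the normalized matrix are correlated with each other,
and the first principal component of the resulting Pearson correlation
matrix gives one coefficient per region — the compartment score. The sign of
a principal component is arbitrary, so scores are oriented to correlate
positively with gene density; positive scores then mark compartment A
(active) and negative scores compartment B (inactive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ChromatinTrace, DistanceMatrix, GenomicRegion

__all__ = [
    "CompartmentResult",
    "mean_distance_matrix",
    "contact_probability",
    "contact_probability_matrix",
    "contact_probability_difference",
    "hic_contact_frequency",
    "fit_distance_powerlaw",
    "compartment_scores",
    "expression_fold_vs_score_change",
]

#: Two loci are in contact when strictly closer than this, nm.
CONTACT_THRESHOLD_NM = 150.0

#: Default minimum informative trace pairs for a distance-matrix entry.
MIN_PAIRS_DEFAULT = 20


@dataclass
class CompartmentResult:
    """Output of the compartment-scoring procedure."""

    amplitude: float
    exponent: float
    normalized: np.ndarray
    correlation: np.ndarray
    scores: np.ndarray
    oriented: bool  # True when the gene-density sign convention was applied


def _pairwise_distances(trace: ChromatinTrace) -> np.ndarray:
    p = trace.positions
    return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)


def mean_distance_matrix(
    traces: list[ChromatinTrace],
    min_pairs: int = MIN_PAIRS_DEFAULT,
    region_ids: list[str] | None = None,
) -> DistanceMatrix:
    """Mean pairwise spatial distance over traces, with pairwise deletion.

    Entry (i, j) averages the Euclidean distance between loci i and j over
    the traces in which both loci were measured; the number of such traces is
    recorded, and entries supported by fewer than ``min_pairs`` traces are
    set to NaN.
    """
    if not traces:
        raise ValueError("no traces given")
    n = traces[0].n_loci
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for t in traces:
        if t.n_loci != n:
            raise ValueError("traces have inconsistent locus counts")
        d = _pairwise_distances(t)
        ok = ~np.isnan(d)
        total[ok] += d[ok]
        counts += ok
    with np.errstate(invalid="ignore"):
        mean = np.where(counts >= max(min_pairs, 1), total / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(mean, 0.0)
    return DistanceMatrix(mean_nm=mean, counts=counts, region_ids=region_ids)


def contact_probability_matrix(
    traces: list[ChromatinTrace],
    threshold_nm: float = CONTACT_THRESHOLD_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise contact probabilities.

    A pair of loci is in contact in one trace when their spatial distance is
    strictly below ``threshold_nm`` (a pair at exactly the threshold is not
    in contact). Entry (i, j) is the fraction of traces with both loci
    measured in which the pair is in contact; pairs with no informative trace
    are NaN. Returns (probabilities, informative-counts).
    """
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    if not traces:
        raise ValueError("no traces given")
    n = traces[0].n_loci
    hits = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for t in traces:
        d = _pairwise_distances(t)
        ok = ~np.isnan(d)
        hits += ok & (d < threshold_nm)
        counts += ok
    with np.errstate(invalid="ignore"):
        prob = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return prob, counts


def contact_probability(
    traces: list[ChromatinTrace],
    threshold_nm: float = CONTACT_THRESHOLD_NM,
    anchor_region: int | None = None,
) -> np.ndarray:
    """Contact probability of every region, optionally against one anchor.

    With ``anchor_region`` given, returns the vector of probabilities that
    each region contacts the anchor (the anchor's own entry is NaN);
    otherwise returns the full pairwise matrix.
    """
    prob, _ = contact_probability_matrix(traces, threshold_nm)
    if anchor_region is None:
        return prob
    col = prob[:, anchor_region].copy()
    col[anchor_region] = np.nan
    return col


def contact_probability_difference(
    traces_a: list[ChromatinTrace],
    traces_b: list[ChromatinTrace],
    anchor_region: int,
    threshold_nm: float = CONTACT_THRESHOLD_NM,
) -> np.ndarray:
    """Per-region contact probability with an anchor, group A minus group B."""
    pa = contact_probability(traces_a, threshold_nm, anchor_region)
    pb = contact_probability(traces_b, threshold_nm, anchor_region)
    return pa - pb


def hic_contact_frequency(
    count_matrix: np.ndarray, regions: list[GenomicRegion]
) -> np.ndarray:
    """Length-normalized Hi-C contact frequency between regions.

    freq_ij = total counts between regions i and j divided by the product of
    their genomic lengths.
    """
    counts = np.asarray(count_matrix, dtype=float)
    n = len(regions)
    if counts.shape != (n, n):
        raise ValueError("count matrix must be square and match the regions")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lengths = np.array([r.length for r in regions], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("regions must have positive genomic length")
    return counts / (lengths[:, None] * lengths[None, :])


def fit_distance_powerlaw(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares power-law fit ``y = amplitude * x**exponent``.

    Performed as ordinary least squares in log-log space. Non-positive pairs
    are excluded with a warning; fewer than 3 usable pairs is an error.
    Returns (amplitude, exponent, pearson_r) where ``pearson_r`` is the
    correlation of the raw paired quantities.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    pos = ok & (x > 0) & (y > 0)
    if (ok & ~pos).any():
        warnings.warn(
            f"excluding {int((ok & ~pos).sum())} non-positive pairs from power-law fit",
            stacklevel=2,
        )
    if pos.sum() < 3:
        raise ValueError("need at least 3 positive (x, y) pairs")
    slope, intercept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
    if np.allclose(y[pos], y[pos][0]):
        slope = 0.0  # constant y: exponent exactly 0
    r = float(stats.pearsonr(x[pos], y[pos]).statistic) if not np.allclose(y[pos], y[pos][0]) else 0.0
    return float(np.exp(intercept)), float(slope), r


def _genomic_separation(regions: list[GenomicRegion]) -> np.ndarray:
    mids = np.array([r.midpoint for r in regions])
    return np.abs(mids[:, None] - mids[None, :])


def compartment_scores(
    dm: DistanceMatrix, regions: list[GenomicRegion]
) -> CompartmentResult:
    """A/B compartment scores from a mean spatial distance matrix.

    Steps: (1) fit a power law of mean distance versus genomic separation
    (region midpoints; diagonal excluded); (2) divide each entry by its
    expected distance to remove the genomic-distance trend; (3) Pearson
    correlation between all row pairs of the normalized matrix (each pair's
    own two columns excluded); (4) standard PCA of the correlation matrix
    (columns mean-centred; the matrix is symmetric so rows and columns are
    interchangeable); (5) orient the unit-norm first-PC coefficients so that
    they correlate positively with gene density.
    """
    n = dm.n
    if len(regions) != n:
        raise ValueError("regions must match the distance matrix")
    off = ~np.eye(n, dtype=bool)
    missing = np.isnan(dm.mean_nm) & off
    if missing.any():
        pairs = list(zip(*np.nonzero(missing)))[:10]
        raise ValueError(f"distance matrix has missing entries after filtering: {pairs}")

    g = _genomic_separation(regions)
    amplitude, exponent, _ = fit_distance_powerlaw(g[off], dm.mean_nm[off])
    expected = amplitude * np.where(g > 0, g, np.nan) ** exponent
    normalized = dm.mean_nm / expected
    np.fill_diagonal(normalized, 1.0)  # self-distance carries no signal

    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            xi, xj = normalized[i, keep], normalized[j, keep]
            if np.std(xi) < 1e-12 or np.std(xj) < 1e-12:
                raise ValueError(
                    "normalized rows are constant; correlations undefined "
                    "(distances follow the power law exactly)"
                )
            c = np.corrcoef(xi, xj)[0, 1]
            corr[i, j] = corr[j, i] = c

    centred = corr - corr.mean(axis=0, keepdims=True)
    # first principal component of the correlation matrix (columns as variables)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    scores = vt[0]
    scores = scores / np.linalg.norm(scores)

    density = np.array(
        [np.nan if r.gene_density is None else r.gene_density for r in regions]
    )
    oriented = False
    if np.isfinite(density).sum() >= 3:
        ok = np.isfinite(density)
        c = np.corrcoef(scores[ok], density[ok])[0, 1]
        if c < 0:
            scores = -scores
        oriented = True
    return CompartmentResult(
        amplitude=amplitude,
        exponent=exponent,
        normalized=normalized,
        correlation=corr,
        scores=scores,
        oriented=oriented,
    )


def expression_fold_vs_score_change(
    expression: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
    gene_to_region: dict[int, int],
    fold_threshold: float = 3.0,
) -> tuple[list[dict], dict[str, int]]:
    """Pair expression fold changes with compartment-score changes.

    ``expression`` maps cell type -> per-gene mean counts; ``scores`` maps
    cell type -> per-region compartment scores; ``gene_to_region`` maps gene
    index -> region index. For every ordered cell-type pair and gene, the
    fold increase of expression and the score change of the host region are
    tabulated. Genes whose fold increase strictly exceeds ``fold_threshold``
    (a fold of exactly the threshold does not count) are tallied by the sign
    of their score change. Zero-denominator folds are excluded.

    Returns (rows, tallies) with tallies keyed ``"score_up"``/``"score_down"``.
    """
    rows: list[dict] = []
    tallies = {"score_up": 0, "score_down": 0}
    types = sorted(expression)
    for a in types:
        for b in types:
            if a == b:
                continue
            for gene, region in gene_to_region.items():
                denom = expression[b][gene]
                if denom == 0:
                    continue
                fold = expression[a][gene] / denom
                dscore = scores[a][region] - scores[b][region]
                rows.append(
                    {"from": b, "to": a, "gene": gene, "fold": fold, "dscore": dscore}
                )
                if fold > fold_threshold:
                    if dscore > 0:
                        tallies["score_up"] += 1
                    elif dscore < 0:
                        tallies["score_down"] += 1
    return rows, tallies
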