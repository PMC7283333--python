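"""Metropolis Monte Carlo of a compartment-scored lattice polymer.

The chromosome is modelled as a linear, self-avoiding polymer of 50 monomers
on a cubic lattice, one monomer per probed TAD. Consecutive monomers must
stay between 1 and 4 lattice units apart. Each monomer carries the
compartment score of its TAD (positive = compartment A, otherwise B), and
the conformational energy couples the scores through two kinds of
interactions:

* contact terms: every same-compartment pair closer than 2 lattice units
  contributes ``g_AA * S_i * S_j`` (A pairs) or ``g_BB * S_p * S_q``
  (B pairs);
* surface terms: every monomer on the surface of the conformation's 3D
  convex hull — a vertex of the hull — contributes ``g_AS * (S_m -
  mean(S_A))`` if it is an A monomer or ``g_BS * (mean(S_B) - S_n)`` if it
  is a B monomer.

Sign convention. Read literally, positive ``g`` values above *penalize*
same-compartment contacts and strong-compartment surface placement under an
energy-minimizing Metropolis rule, which is the opposite of the
self-association the model is meant to express. The default
``sign_mode="attractive"`` therefore minimizes the *negation* of that
expression, which makes same-compartment contacts favourable and drives
strong-scored monomers to the territory surface; ``sign_mode="as_printed"``
keeps the literal expression for comparison.

Moves displace one uniformly chosen monomer to one of its six axis
neighbours; proposals that land on an occupied site or break the chain
bound are abandoned without touching the Metropolis budget, and 60,000
*accepted* moves constitute one run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import _mc_kernel as _k
from .architecture import (
    DegenerateHullError,
    hull_surface_flags,
    polarization_index,
    randomized_polarization,
    score_ratio_correlation,
)

__all__ = [
    "EnergyParams",
    "PRESETS",
    "MCRun",
    "SimResult",
    "init_conformation",
    "validate_conformation",
    "surface_monomer_flags",
    "energy",
    "mc_run",
    "simulate_ensemble",
]


@dataclass
class EnergyParams:
    """Dimensionless coupling strengths of the polymer energy."""

    g_aa: float = 0.0
    g_bb: float = 0.0
    g_as: float = 0.0
    g_bs: float = 0.0
    contact_radius: float = 2.0  # lattice units, strict <
    sign_mode: str = "attractive"  # or "as_printed"

    def __post_init__(self) -> None:
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be positive")
        if self.sign_mode not in ("attractive", "as_printed"):
            raise ValueError("sign_mode must be 'attractive' or 'as_printed'")

    @property
    def sign(self) -> float:
        """Multiplier mapping the printed energy onto the minimized objective."""
        return -1.0 if self.sign_mode == "attractive" else 1.0

    @property
    def surface_active(self) -> bool:
        return self.g_as != 0.0 or self.g_bs != 0.0


#: Published parameter presets for the three simulation settings.
PRESETS: dict[str, EnergyParams] = {
    "bb_only": EnergyParams(g_aa=0.0, g_bb=50.0, g_as=0.0, g_bs=0.0),
    "aa_bb": EnergyParams(g_aa=50.0, g_bb=50.0, g_as=0.0, g_bs=0.0),
    "full": EnergyParams(g_aa=50.0, g_bb=50.0, g_as=40.0, g_bs=25.0),
}

#: Accepted moves per run in the published procedure.
DEFAULT_N_ACCEPTED = 60_000
#: Independent runs per parameter set in the published procedure.
DEFAULT_N_RUNS = 100

# all displacement vectors with 1 <= |d| <= 4, used by the initializer
_INIT_STEPS = np.array(
    [
        (dx, dy, dz)
        for dx in range(-4, 5)
        for dy in range(-4, 5)
        for dz in range(-4, 5)
        if 1 <= dx * dx + dy * dy + dz * dz <= 16
    ],
    dtype=np.int64,
)


@dataclass
class MCRun:
    """One Monte Carlo trajectory."""

    positions: np.ndarray        # (n, 3) int final conformation
    energy_trace: np.ndarray     # objective after each accepted move
    n_attempts: int
    n_legal: int
    n_accepted: int
    seed: int


@dataclass
class SimResult:
    """Ensemble summary over independent runs."""

    conformations: np.ndarray          # (n_runs, n, 3)
    pi_observed: np.ndarray            # (n_runs,) NaN where hull degenerate
    pi_control: np.ndarray             # (n_runs,) label-shuffled controls
    surface_ratio: np.ndarray          # (n,) per-monomer hull-vertex frequency
    correlations: dict[str, tuple[float, float]]
    final_energies: np.ndarray
    seeds: np.ndarray
    params: EnergyParams
    energy_traces: list[np.ndarray] = field(default_factory=list)


def validate_conformation(pos: np.ndarray) -> None:
    """Assert self-avoidance and the chain adjacency bound."""
    pos = np.asarray(pos)
    if len(np.unique(pos, axis=0)) != pos.shape[0]:
        raise ValueError("conformation is not self-avoiding")
    diff = np.diff(pos, axis=0)
    dsq = (diff * diff).sum(axis=1)
    if np.any(dsq < 1) or np.any(dsq > _k.ADJ_MAX_SQ):
        raise ValueError("chain adjacency bound violated")


def init_conformation(n: int = 50, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random self-avoiding chain satisfying the adjacency bound.

    A random walk draws each bond uniformly from the displacement vectors of
    length 1..4, retrying on collisions; the whole walk restarts if a step has
    no legal continuation. Deterministic per seed.
    """
    if n < 2:
        raise ValueError("need at least 2 monomers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(100):
        pos = np.zeros((n, 3), dtype=np.int64)
        occupied = {(0, 0, 0)}
        ok = True
        for i in range(1, n):
            order = rng.permutation(len(_INIT_STEPS))
            for j in order:
                cand = pos[i - 1] + _INIT_STEPS[j]
                key = (int(cand[0]), int(cand[1]), int(cand[2]))
                if key not in occupied:
                    pos[i] = cand
                    occupied.add(key)
                    break
            else:
                ok = False
                break
        if ok:
            validate_conformation(pos)
            return pos
    raise RuntimeError("failed to build an initial self-avoiding chain")


def surface_monomer_flags(pos: np.ndarray) -> np.ndarray:
    """Which monomers are vertices (extreme points) of the conformation's
    convex hull.

    Lattice conformations are full of exact degeneracies (monomers on hull
    facets or edges without being corners), so for integer input the flags
    are computed exactly: Qhull supplies the hull triangles, each
    non-degenerate triangle yields an integer supporting plane, and a
    monomer is a vertex iff the supporting planes through it span rank 3.
    Configurations with no 3D corner at all (flat or fewer than 4 monomers)
    are all-surface by convention. Float input falls back to Qhull's own
    vertex list.
    """
    pos = np.asarray(pos)
    n = pos.shape[0]
    if not np.issubdtype(pos.dtype, np.integer):
        try:
            return hull_surface_flags(pos.astype(float))
        except (QhullError, ValueError):
            return np.ones(n, dtype=bool)
    if n < 4:
        return np.ones(n, dtype=bool)
    pos = pos.astype(np.int64)
    try:
        hull = ConvexHull(pos.astype(float))
    except QhullError:
        return np.ones(n, dtype=bool)
    simp = hull.simplices
    a = pos[simp[:, 0]]
    normals = np.cross(pos[simp[:, 1]] - a, pos[simp[:, 2]] - a)
    keep = np.any(normals != 0, axis=1)
    normals = normals[keep]
    offsets = np.einsum("ij,ij->i", normals, a[keep])
    if normals.shape[0] == 0:
        return np.ones(n, dtype=bool)
    vals = pos @ normals.T - offsets  # exact integers
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        incident = normals[vals[i] == 0]
        if incident.shape[0] < 3:
            continue
        n1 = incident[0]
        crosses = np.cross(n1, incident)
        j = np.nonzero(np.any(crosses != 0, axis=1))[0]
        if j.size == 0:
            continue
        if np.any(incident @ crosses[j[0]] != 0):
            flags[i] = True
    if not flags.any():
        return np.ones(n, dtype=bool)  # flat: everything on the surface
    return flags


def _split_scores(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    comp = np.where(scores > 0, 1, -1).astype(np.int8)
    return scores, comp


def _surface_weights(scores: np.ndarray, comp: np.ndarray, params: EnergyParams) -> np.ndarray:
    """Per-monomer printed surface-energy contribution when on the hull."""
    is_a = comp == 1
    if params.surface_active and (is_a.all() or not is_a.any()):
        raise ValueError("surface terms need at least one A and one B monomer")
    s_a_mean = scores[is_a].mean() if is_a.any() else 0.0
    s_b_mean = scores[~is_a].mean() if (~is_a).any() else 0.0
    return np.where(
        is_a,
        params.g_as * (scores - s_a_mean),
        params.g_bs * (s_b_mean - scores),
    )


def energy(pos: np.ndarray, scores: np.ndarray, params: EnergyParams) -> float:
    """Full recomputation of the conformation's energy.

    Returns the printed-expression value under ``sign_mode="as_printed"`` and
    its negation (the minimized objective) under the default
    ``sign_mode="attractive"``.
    """
    pos = np.asarray(pos, dtype=np.int64)
    scores, comp = _split_scores(scores)
    if scores.shape[0] != pos.shape[0]:
        raise ValueError("scores length must match monomer count")
    diff = pos[:, None, :] - pos[None, :, :]
    dsq = (diff * diff).sum(axis=-1).astype(float)
    contact = dsq < params.contact_radius**2
    np.fill_diagonal(contact, False)
    same_a = (comp[:, None] == 1) & (comp[None, :] == 1)
    same_b = (comp[:, None] == -1) & (comp[None, :] == -1)
    s_outer = scores[:, None] * scores[None, :]
    printed = 0.5 * (
        params.g_aa * s_outer[contact & same_a].sum()
        + params.g_bb * s_outer[contact & same_b].sum()
    )
    if params.surface_active:
        w = _surface_weights(scores, comp, params)
        printed += w[surface_monomer_flags(pos)].sum()
    return float(params.sign * printed) if params.sign_mode == "attractive" else float(printed)


def _objective(pos, scores, params) -> float:
    """Energy in the minimized-objective convention, whatever sign_mode is."""
    e = energy(pos, scores, params)
    return e if params.sign_mode == "attractive" else params.sign * e


def mc_run(
    scores: np.ndarray,
    params: EnergyParams,
    n_accepted: int = DEFAULT_N_ACCEPTED,
    seed: int = 0,
    init: np.ndarray | None = None,
    check_every: int = 1000,
) -> MCRun:
    """One Metropolis run of ``n_accepted`` accepted moves.

    Constraint-illegal proposals (occupied site, broken chain bound) are
    abandoned without a Metropolis evaluation and do not count towards the
    accepted-move budget. Deterministic per seed.
    """
    scores, comp = _split_scores(scores)
    pos = init_conformation(scores.shape[0], seed) if init is None else np.array(init, dtype=np.int64)
    validate_conformation(pos)
    if scores.shape[0] != pos.shape[0]:
        raise ValueError("scores length must match monomer count")

    sign = params.sign
    contact_sq = float(params.contact_radius**2)
    surface_active = params.surface_active
    n = len(scores)
    w = _surface_weights(scores, comp, params) if surface_active else np.zeros_like(scores)

    # kernel-maintained surface geometry; geom_state[1] = 1 asks the kernel
    # to build the initial hull and add the surface term to e_current
    vert_flags = np.zeros(n, dtype=bool)
    plane_n = np.zeros((4 * n, 3), dtype=np.int64)
    plane_d = np.zeros(4 * n, dtype=np.int64)
    geom_state = np.array([0, 1 if surface_active else 0], dtype=np.int64)
    facets_ws = np.zeros((4 * n, 3), dtype=np.int64)
    visible_ws = np.zeros(4 * n, dtype=np.bool_)
    edges_ws = np.zeros((12 * n, 2), dtype=np.int64)
    plane_n2 = np.zeros((4 * n, 3), dtype=np.int64)
    plane_d2 = np.zeros(4 * n, dtype=np.int64)
    flags2 = np.zeros(n, dtype=np.bool_)

    counters = np.zeros(3, dtype=np.int64)
    trace = np.empty(n_accepted, dtype=np.float64)
    e_current = np.array([_pair_objective(pos, scores, comp, params)])
    rng_state = _k.seed_state(seed)
    stall_attempts = 0
    next_check = 0

    while counters[_k.N_ACCEPTED] < n_accepted:
        next_check = min(n_accepted, next_check + check_every)
        before = (counters[_k.N_ATTEMPTS], counters[_k.N_ACCEPTED])
        _k.run_chunk(
            pos, scores, comp, w,
            float(params.g_aa), float(params.g_bb), contact_sq, sign,
            surface_active, vert_flags, plane_n, plane_d, geom_state,
            facets_ws, visible_ws, edges_ws, plane_n2, plane_d2, flags2,
            next_check, counters, trace, e_current, rng_state,
        )
        if counters[_k.N_ACCEPTED] == before[1]:
            stall_attempts += counters[_k.N_ATTEMPTS] - before[0]
            if stall_attempts > 20_000_000:
                raise RuntimeError("no legal move accepted after bounded attempts; frozen")
        else:
            stall_attempts = 0
        validate_conformation(pos)  # periodic self-avoidance spot check

    return MCRun(
        positions=pos,
        energy_trace=trace,
        n_attempts=int(counters[_k.N_ATTEMPTS]),
        n_legal=int(counters[_k.N_LEGAL]),
        n_accepted=int(counters[_k.N_ACCEPTED]),
        seed=seed,
    )


def _pair_objective(pos, scores, comp, params) -> float:
    """Contact-term part of the objective (no surface terms)."""
    pair_only = EnergyParams(
        g_aa=params.g_aa, g_bb=params.g_bb, g_as=0.0, g_bs=0.0,
        contact_radius=params.contact_radius, sign_mode=params.sign_mode,
    )
    e = energy(pos, scores, pair_only)
    return e if params.sign_mode == "attractive" else params.sign * e


def simulate_ensemble(
    scores: np.ndarray,
    params: EnergyParams | str,
    n_runs: int = DEFAULT_N_RUNS,
    n_accepted: int = DEFAULT_N_ACCEPTED,
    base_seed: int = 0,
    store_traces: bool = False,
) -> SimResult:
    """Independent seeded runs plus the ensemble summaries.

    Per conformation: polarization index of the A vs B monomers and one
    group-size-preserving label-shuffle control. Per monomer: the fraction of
    conformations in which it is a hull vertex (chromosome surface ratio),
    correlated against the compartment scores separately for A and B
    monomers.
    """
    if isinstance(params, str):
        params = PRESETS[params]
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    scores, comp = _split_scores(scores)
    n = scores.shape[0]
    run_seeds = np.random.SeedSequence(base_seed).generate_state(n_runs) % (2**31)

    conformations = np.zeros((n_runs, n, 3), dtype=np.int64)
    pi_obs = np.full(n_runs, np.nan)
    pi_ctrl = np.full(n_runs, np.nan)
    surface_counts = np.zeros(n)
    finals = np.zeros(n_runs)
    traces: list[np.ndarray] = []
    ctrl_rng = np.random.default_rng(np.random.SeedSequence([base_seed, 1]))

    is_a = comp == 1
    for i in range(n_runs):
        run = mc_run(scores, params, n_accepted=n_accepted, seed=int(run_seeds[i]))
        conformations[i] = run.positions
        finals[i] = run.energy_trace[-1] if n_accepted else np.nan
        if store_traces:
            traces.append(run.energy_trace)
        ptsf = run.positions.astype(float)
        try:
            pi_obs[i] = polarization_index(ptsf[is_a], ptsf[~is_a]).PI
        except DegenerateHullError:
            pass
        ctrl, _ = randomized_polarization(ptsf, is_a, n_perm=1, seed=ctrl_rng)
        if ctrl.size:
            pi_ctrl[i] = ctrl[0]
        surface_counts += surface_monomer_flags(run.positions)

    surface_ratio = surface_counts / n_runs
    correlations = score_ratio_correlation(scores, surface_ratio, split_by_sign=True)
    return SimResult(
        conformations=conformations,
        pi_observed=pi_obs,
        pi_control=pi_ctrl,
        surface_ratio=surface_ratio,
        correlations=correlations,
        final_energies=finals,
        seeds=run_seeds,
        params=params,
        energy_traces=traces,
    )
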