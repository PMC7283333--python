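"""Numba kernel for the lattice-polymer Metropolis sampler.

The whole move loop runs in compiled code: proposal draws, occupancy and
chain-adjacency checks, incremental contact-energy deltas, Metropolis
decisions, and — when the surface energy may change — an exact convex-hull
recomputation.

Convex hulls of lattice points are full of exact degeneracies (coplanar and
collinear subsets), which break naive incremental hull construction. The
kernel therefore runs the incremental algorithm on *symbolically perturbed*
points: monomer ``i`` is displaced by ``eps * (t, t^2, t^3)`` with
``t = i + 1`` (a point on the moment curve) and ``eps`` infinitesimal. Every
orientation test expands the determinant in powers of ``eps`` and returns
the sign of the first non-vanishing coefficient; the highest coefficient is
a Vandermonde determinant of distinct ``t`` values and never vanishes, so no
orientation is ever zero and the perturbed hull is always a well-formed
simplicial polytope. All coefficients are int64-exact.

Surface monomers are then classified against the *true* (unperturbed) facet
planes: each non-degenerate hull triangle (a, b, c) yields the integer plane
``n = (p_b - p_a) x (p_c - p_a)``, ``n . x = n . p_a``, which is a genuine
supporting plane of the true hull. A monomer is a hull *vertex* (extreme
point) iff the supporting planes through it span rank 3 — corners of the
hull — which reproduces Qhull's vertex set exactly while being immune to
floating-point tolerance issues.

Randomness comes from an explicit xorshift128+ state so that trajectories
are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# counters layout
N_ATTEMPTS = 0
N_LEGAL = 1
N_ACCEPTED = 2

#: chain adjacency bound: consecutive monomers no farther than 4 units.
ADJ_MAX_SQ = 16

_AXIS_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


# ---------------------------------------------------------------- RNG ----

@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31)), x


@njit(cache=True)
def _seed_pair(seed):
    s0, carry = _splitmix64(seed)
    s1, _ = _splitmix64(carry)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)
    return s0, s1


def seed_state(seed: int) -> np.ndarray:
    """Derive a non-degenerate xorshift128+ state from an integer seed."""
    state = np.empty(2, dtype=np.uint64)
    state[0], state[1] = _seed_pair(np.uint64(seed))
    return state


@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return (s0 + s1) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _uniform(state):
    return (_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ------------------------------------------------- exact hull geometry ----

@njit(cache=True, inline="always")
def _det3(a0, a1, a2, b0, b1, b2, c0, c1, c2):
    return (
        a0 * (b1 * c2 - b2 * c1)
        - a1 * (b0 * c2 - b2 * c0)
        + a2 * (b0 * c1 - b1 * c0)
    )


@njit(cache=True)
def _orient_sos(pts, a, b, c, d):
    """Sign of orient3d(a, b, c, d) under moment-curve perturbation.

    Positive means d lies above the plane through a, b, c (oriented by the
    right-hand rule); never returns 0 for distinct indices.
    """
    u10 = pts[b, 0] - pts[a, 0]; u11 = pts[b, 1] - pts[a, 1]; u12 = pts[b, 2] - pts[a, 2]
    u20 = pts[c, 0] - pts[a, 0]; u21 = pts[c, 1] - pts[a, 1]; u22 = pts[c, 2] - pts[a, 2]
    u30 = pts[d, 0] - pts[a, 0]; u31 = pts[d, 1] - pts[a, 1]; u32 = pts[d, 2] - pts[a, 2]
    c0 = _det3(u10, u11, u12, u20, u21, u22, u30, u31, u32)
    if c0 != 0:
        return 1 if c0 > 0 else -1
    ta = np.int64(a + 1); tb = np.int64(b + 1); tc = np.int64(c + 1); td = np.int64(d + 1)
    w10 = tb - ta; w11 = tb * tb - ta * ta; w12 = tb * tb * tb - ta * ta * ta
    w20 = tc - ta; w21 = tc * tc - ta * ta; w22 = tc * tc * tc - ta * ta * ta
    w30 = td - ta; w31 = td * td - ta * ta; w32 = td * td * td - ta * ta * ta
    c1 = (
        _det3(w10, w11, w12, u20, u21, u22, u30, u31, u32)
        + _det3(u10, u11, u12, w20, w21, w22, u30, u31, u32)
        + _det3(u10, u11, u12, u20, u21, u22, w30, w31, w32)
    )
    if c1 != 0:
        return 1 if c1 > 0 else -1
    c2 = (
        _det3(u10, u11, u12, w20, w21, w22, w30, w31, w32)
        + _det3(w10, w11, w12, u20, u21, u22, w30, w31, w32)
        + _det3(w10, w11, w12, w20, w21, w22, u30, u31, u32)
    )
    if c2 != 0:
        return 1 if c2 > 0 else -1
    c3 = _det3(w10, w11, w12, w20, w21, w22, w30, w31, w32)
    return 1 if c3 > 0 else -1  # Vandermonde of distinct t: never 0


@njit(cache=True)
def _build_hull(pts, facets, visible, edges):
    """Incremental 3D hull of symbolically perturbed points.

    ``facets`` (4n, 3), ``visible`` (4n,), ``edges`` (12n, 2) are caller
    workspaces. Returns the number of facets written to ``facets``; each
    facet (a, b, c) is outward-oriented: every point is on its non-positive
    side (strictly negative under perturbation). Requires n >= 4.
    """
    n = pts.shape[0]
    # initial tetrahedron from points 0..3, each face oriented away from
    # the remaining point: (1,2,3) vs 0, (0,2,3) vs 1, (0,1,3) vs 2, (0,1,2) vs 3
    nf = 0
    for f in range(4):
        if f == 0:
            a, b, c, d = 1, 2, 3, 0
        elif f == 1:
            a, b, c, d = 0, 2, 3, 1
        elif f == 2:
            a, b, c, d = 0, 1, 3, 2
        else:
            a, b, c, d = 0, 1, 2, 3
        if _orient_sos(pts, a, b, c, d) > 0:
            a, b = b, a  # flip so d is below
        facets[nf, 0] = a
        facets[nf, 1] = b
        facets[nf, 2] = c
        nf += 1
    for q in range(4, n):
        nvis = 0
        any_vis = False
        for f in range(nf):
            if _orient_sos(pts, facets[f, 0], facets[f, 1], facets[f, 2], q) > 0:
                visible[f] = True
                any_vis = True
                nvis += 1
            else:
                visible[f] = False
        if not any_vis:
            continue  # q is inside (or on the boundary of) the current hull
        # collect directed edges of visible facets
        ne = 0
        for f in range(nf):
            if visible[f]:
                for e in range(3):
                    edges[ne, 0] = facets[f, e]
                    edges[ne, 1] = facets[f, (e + 1) % 3]
                    ne += 1
        # compact away visible facets
        keep = 0
        for f in range(nf):
            if not visible[f]:
                facets[keep, 0] = facets[f, 0]
                facets[keep, 1] = facets[f, 1]
                facets[keep, 2] = facets[f, 2]
                keep += 1
        nf = keep
        # horizon edges are those whose reverse is not among visible edges
        for e in range(ne):
            x = edges[e, 0]
            y = edges[e, 1]
            is_horizon = True
            for e2 in range(ne):
                if edges[e2, 0] == y and edges[e2, 1] == x:
                    is_horizon = False
                    break
            if not is_horizon:
                continue
            # orient the new facet (x, y, q) with an interior witness: any
            # already-processed point distinct from x, y, q lies strictly
            # inside the updated hull under the symbolic perturbation
            wit = -1
            for cand in range(4):
                if cand != x and cand != y and cand != q:
                    wit = cand
                    break
            if _orient_sos(pts, x, y, q, wit) > 0:
                x, y = y, x
            facets[nf, 0] = x
            facets[nf, 1] = y
            facets[nf, 2] = q
            nf += 1
    return nf


@njit(cache=True)
def _true_planes(pts, facets, nf, plane_n, plane_d):
    """Integer supporting planes from hull triangles; drops degenerate
    (collinear in true coordinates) triangles. Returns plane count."""
    np_ = 0
    for f in range(nf):
        a = facets[f, 0]; b = facets[f, 1]; c = facets[f, 2]
        ux = pts[b, 0] - pts[a, 0]; uy = pts[b, 1] - pts[a, 1]; uz = pts[b, 2] - pts[a, 2]
        vx = pts[c, 0] - pts[a, 0]; vy = pts[c, 1] - pts[a, 1]; vz = pts[c, 2] - pts[a, 2]
        nx = uy * vz - uz * vy
        ny = uz * vx - ux * vz
        nz = ux * vy - uy * vx
        if nx == 0 and ny == 0 and nz == 0:
            continue
        plane_n[np_, 0] = nx
        plane_n[np_, 1] = ny
        plane_n[np_, 2] = nz
        plane_d[np_] = nx * pts[a, 0] + ny * pts[a, 1] + nz * pts[a, 2]
        np_ += 1
    return np_


@njit(cache=True)
def _extreme_flags(pts, plane_n, plane_d, np_, flags):
    """Exact hull-vertex flags: a point is extreme iff the supporting planes
    through it span rank 3. Falls back to all-True when the point set admits
    no 3D corner (flat or tiny configurations: everything is surface)."""
    n = pts.shape[0]
    any_extreme = False
    for i in range(n):
        flags[i] = False
        # first supporting plane through the point
        n1x = np.int64(0); n1y = np.int64(0); n1z = np.int64(0)
        have1 = False
        c12x = np.int64(0); c12y = np.int64(0); c12z = np.int64(0)
        have2 = False
        for p in range(np_):
            v = (
                plane_n[p, 0] * pts[i, 0]
                + plane_n[p, 1] * pts[i, 1]
                + plane_n[p, 2] * pts[i, 2]
                - plane_d[p]
            )
            if v != 0:
                continue
            if not have1:
                n1x = plane_n[p, 0]; n1y = plane_n[p, 1]; n1z = plane_n[p, 2]
                have1 = True
                continue
            if not have2:
                cx = n1y * plane_n[p, 2] - n1z * plane_n[p, 1]
                cy = n1z * plane_n[p, 0] - n1x * plane_n[p, 2]
                cz = n1x * plane_n[p, 1] - n1y * plane_n[p, 0]
                if cx != 0 or cy != 0 or cz != 0:
                    c12x = cx; c12y = cy; c12z = cz
                    have2 = True
                continue
            trip = c12x * plane_n[p, 0] + c12y * plane_n[p, 1] + c12z * plane_n[p, 2]
            if trip != 0:
                flags[i] = True
                any_extreme = True
                break
    if not any_extreme:
        for i in range(n):
            flags[i] = True
    return flags


@njit(cache=True)
def _rebuild_surface(pts, facets, visible, edges, plane_n, plane_d, flags):
    """Hull + planes + extreme flags in one call. Returns plane count."""
    n = pts.shape[0]
    if n < 4:
        for i in range(n):
            flags[i] = True
        return 0
    nf = _build_hull(pts, facets, visible, edges)
    np_ = _true_planes(pts, facets, nf, plane_n, plane_d)
    _extreme_flags(pts, plane_n, plane_d, np_, flags)
    return np_


@njit(cache=True, inline="always")
def _outside_planes(plane_n, plane_d, np_, x, y, z):
    """Is the integer point strictly outside any cached supporting plane?"""
    for p in range(np_):
        if plane_n[p, 0] * x + plane_n[p, 1] * y + plane_n[p, 2] * z > plane_d[p]:
            return True
    return False


# ------------------------------------------------------------ MC kernel ----

@njit(cache=True)
def pair_delta(pos, k, nx, ny, nz, scores, comp, g_aa, g_bb, sign, contact_sq):
    """Objective change of the contact terms when monomer k moves.

    ``comp`` is +1 for compartment A monomers (score > 0), -1 for B. Only
    same-compartment pairs strictly within the contact radius interact; the
    printed energy of a contact is g * S_i * S_j, and ``sign`` maps the
    printed expression onto the minimized objective.
    """
    n = pos.shape[0]
    ck = comp[k]
    g = g_aa if ck == 1 else g_bb
    if g == 0.0:
        return 0.0
    d_printed = 0.0
    for j in range(n):
        if j == k or comp[j] != ck:
            continue
        dx = pos[j, 0] - pos[k, 0]
        dy = pos[j, 1] - pos[k, 1]
        dz = pos[j, 2] - pos[k, 2]
        old_sq = dx * dx + dy * dy + dz * dz
        dx = pos[j, 0] - nx
        dy = pos[j, 1] - ny
        dz = pos[j, 2] - nz
        new_sq = dx * dx + dy * dy + dz * dz
        was = old_sq < contact_sq
        now = new_sq < contact_sq
        if was != now:
            term = g * scores[k] * scores[j]
            d_printed += term if now else -term
    return sign * d_printed


@njit(cache=True)
def run_chunk(
    pos,            # (n, 3) int64, updated in place
    scores,         # (n,) float64
    comp,           # (n,) int8: +1 = A, -1 = B
    w,              # (n,) float64 printed surface weights (zeros if inactive)
    g_aa, g_bb,     # float64 contact parameters (printed convention)
    contact_sq,     # float64 squared contact radius (strict <)
    sign,           # float64: -1 attractive (default), +1 as printed
    surface_active, # bool
    vert_flags,     # (n,) bool: current hull-vertex flags (kernel-maintained)
    plane_n,        # (4n, 3) int64 supporting-plane normals (kernel-maintained)
    plane_d,        # (4n,) int64 supporting-plane offsets
    geom_state,     # (2,) int64: [number of cached planes, needs_init]
    facets, visible, edges,               # hull workspaces
    plane_n2, plane_d2, flags2,           # proposal workspaces
    target,         # int64 total accepted moves wanted
    counters,       # (3,) int64 [attempts, legal, accepted]
    energy_trace,   # (>= target,) float64, objective after each accepted move
    e_current,      # (1,) float64 running objective
    rng_state,      # (2,) uint64
):
    n = pos.shape[0]
    if surface_active and geom_state[1] != 0:
        geom_state[0] = _rebuild_surface(pos, facets, visible, edges, plane_n, plane_d, vert_flags)
        geom_state[1] = 0
        w_sum = 0.0
        for i in range(n):
            if vert_flags[i]:
                w_sum += w[i]
        e_current[0] += sign * w_sum  # driver passes the pair part only
    while counters[N_ACCEPTED] < target:
        counters[N_ATTEMPTS] += 1
        k = int(_next_u64(rng_state) % np.uint64(n))
        d = int(_next_u64(rng_state) % np.uint64(6))
        nx = pos[k, 0] + _AXIS_STEPS[d, 0]
        ny = pos[k, 1] + _AXIS_STEPS[d, 1]
        nz = pos[k, 2] + _AXIS_STEPS[d, 2]
        # self-avoidance: give up the attempt if the site is occupied
        occupied = False
        for j in range(n):
            if pos[j, 0] == nx and pos[j, 1] == ny and pos[j, 2] == nz:
                occupied = True
                break
        if occupied:
            continue
        # chain adjacency bound for the neighbours along the polymer
        ok = True
        for nb in (k - 1, k + 1):
            if 0 <= nb < n:
                dx = pos[nb, 0] - nx
                dy = pos[nb, 1] - ny
                dz = pos[nb, 2] - nz
                dsq = dx * dx + dy * dy + dz * dz
                if dsq > ADJ_MAX_SQ or dsq < 1:
                    ok = False
                    break
        if not ok:
            continue
        counters[N_LEGAL] += 1
        d_pair = pair_delta(pos, k, nx, ny, nz, scores, comp, g_aa, g_bb, sign, contact_sq)
        u = _uniform(rng_state)
        delta = d_pair
        needs_hull = False
        if surface_active:
            # the hull (and with it the surface term) can only change if the
            # moved monomer is a hull vertex or its proposal leaves the hull
            needs_hull = vert_flags[k] or _outside_planes(
                plane_n, plane_d, geom_state[0], nx, ny, nz
            )
        if needs_hull:
            ox = pos[k, 0]; oy = pos[k, 1]; oz = pos[k, 2]
            pos[k, 0] = nx; pos[k, 1] = ny; pos[k, 2] = nz
            np2 = _rebuild_surface(pos, facets, visible, edges, plane_n2, plane_d2, flags2)
            d_surf = 0.0
            for i in range(n):
                if flags2[i] != vert_flags[i]:
                    d_surf += w[i] if flags2[i] else -w[i]
            delta = d_pair + sign * d_surf
            if u < np.exp(-delta):
                for i in range(n):
                    vert_flags[i] = flags2[i]
                for p in range(np2):
                    plane_n[p, 0] = plane_n2[p, 0]
                    plane_n[p, 1] = plane_n2[p, 1]
                    plane_n[p, 2] = plane_n2[p, 2]
                    plane_d[p] = plane_d2[p]
                geom_state[0] = np2
                e_current[0] += delta
                energy_trace[counters[N_ACCEPTED]] = e_current[0]
                counters[N_ACCEPTED] += 1
            else:
                pos[k, 0] = ox; pos[k, 1] = oy; pos[k, 2] = oz
        else:
            # Metropolis on the objective: accept iff u < exp(obj_now - obj_new)
            if u < np.exp(-delta):
                pos[k, 0] = nx; pos[k, 1] = ny; pos[k, 2] = nz
                e_current[0] += delta
                energy_trace[counters[N_ACCEPTED]] = e_current[0]
                counters[N_ACCEPTED] += 1
    return 0
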