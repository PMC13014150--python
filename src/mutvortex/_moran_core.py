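"""Compiled inner loop of the linkage-block Moran simulator.

Everything here is numba-jitted and operates on flat numpy state:

* ``loads``   (2N, C*L) float64 — per-block fitness products l_j; row
  ``2*i + h`` is haplotype h of individual i, column ``c*L + j`` is block
  j of chromosome c
* ``fitness`` (N,) float64      — product of all 2*C*L block loads

One Moran event = one uniformly chosen death + one birth from two
fitness-proportionally chosen hermaphroditic parents (sampled with
replacement from all N, selfing allowed); N events = one generation.
The compiled RNG is numba's global NumPy-legacy stream, seeded once per
run via :func:`seed_compiled_rng`.

Optional focal-block tracking (one block position shared by both modes):

* ``track_mode == 1``: genealogy of the focal block — every inheritance
  appends a parent pointer + time, giving a coalescent tree for Ne
  estimation;
* ``track_mode == 2``: a 0/1 neutral marker on the focal block, with the
  run terminating on loss or fixation (fixation-probability checks).

When Ud == Ub == 0 and the population starts clonal (all loads 1), block
loads can never change, so the event loop skips genome copying and parent
weighting entirely; only the focal-block inheritance draws are made.
This is distributionally exact for the tracked block.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EXTINCT = 1
STATUS_MARKER_LOST = 2
STATUS_MARKER_FIXED = 3


@njit(cache=True)
def seed_compiled_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _draw_boundaries(L, n_x, xb):
    """n_x distinct recombination hotspots, sorted, each in 1..L-1."""
    for i in range(n_x):
        while True:
            b = np.random.randint(1, L)
            dup = False
            for j in range(i):
                if xb[j] == b:
                    dup = True
                    break
            if not dup:
                xb[i] = b
                break
    # insertion sort (n_x is tiny)
    for i in range(1, n_x):
        key = xb[i]
        j = i - 1
        while j >= 0 and xb[j] > key:
            xb[j + 1] = xb[j]
            j -= 1
        xb[j + 1] = key


@njit(cache=True)
def _focal_source_hap(L, n_x, focal_block, xb):
    """Which parental haplotype a fresh gamete copies the focal block from."""
    h = np.random.randint(0, 2)
    _draw_boundaries(L, n_x, xb)
    flips = 0
    for k in range(n_x):
        if xb[k] <= focal_block:
            flips += 1
    if flips % 2 == 1:
        return 1 - h
    return h


@njit(cache=True, fastmath=True)
def _make_gamete(src, row0, dst, drow, C, L, n_x, xb, focal_chrom, focal_block):
    """Write a recombinant gamete of the parent whose haplotype rows are
    ``src[row0]``/``src[row0+1]`` into ``dst[drow]``; return
    (load product, focal source haplotype).

    Per chromosome: fair-coin starting haplotype, then the copy source
    switches at each of the n_x hotspot boundaries (drawn uniformly
    without replacement among the L-1 internal block boundaries).
    Chromosomes assort independently.  ``dst`` may be the population
    array itself (the caller guarantees the destination rows belong to
    neither parent) or a scratch buffer.
    """
    focal_hap = -1
    for c in range(C):
        h = np.random.randint(0, 2)
        _draw_boundaries(L, n_x, xb)
        cur = h
        pos = 0
        base = c * L
        for k in range(n_x + 1):
            end = L if k == n_x else xb[k]
            dst[drow, base + pos : base + end] = src[row0 + cur, base + pos : base + end]
            pos = end
            cur = 1 - cur
        if c == focal_chrom:
            flips = 0
            for k in range(n_x):
                if xb[k] <= focal_block:
                    flips += 1
            focal_hap = h if flips % 2 == 0 else 1 - h
    M = C * L
    a0 = 1.0
    a1 = 1.0
    a2 = 1.0
    a3 = 1.0
    j = 0
    while j + 4 <= M:
        a0 *= dst[drow, j]
        a1 *= dst[drow, j + 1]
        a2 *= dst[drow, j + 2]
        a3 *= dst[drow, j + 3]
        j += 4
    while j < M:
        a0 *= dst[drow, j]
        j += 1
    return a0 * a1 * a2 * a3, focal_hap


@njit(cache=True, fastmath=True)
def _pick_parent(fitness, tot, N):
    r = np.random.random() * tot
    acc = 0.0
    for i in range(N):
        acc += fitness[i]
        if acc >= r:
            return i
    return N - 1


@njit(cache=True, fastmath=True)
def run_generations(
    loads,
    fitness,
    n_gens,
    C,
    L,
    n_x,
    ud,
    ub,
    g_shape,
    g_scale,
    b_mean,
    track_mode,
    focal_chrom,
    focal_block,
    tracer_node,
    anc_parent,
    anc_time,
    node_offset,
    t0,
    marker,
    marker_count,
    mean_out,
    var_out,
):
    """Advance the population ``n_gens`` generations (N events each).

    Writes per-generation mean and variance of fitness into
    ``mean_out``/``var_out``.  New genealogy nodes are written into the
    chunk-local ``anc_parent``/``anc_time`` buffers and carry the global
    ids ``node_offset + k``.  Returns
    (nodes_created, marker_count, status, generations_completed).
    """
    N = fitness.shape[0]
    M = C * L
    xb = np.empty(max(n_x, 1), dtype=np.int64)
    scratch = np.empty((2, M), dtype=np.float64)
    neutral = ud == 0.0 and ub == 0.0
    k = 0

    for g in range(n_gens):
        for e in range(N):
            die = np.random.randint(0, N)
            tr1 = 0
            tr2 = 0
            if neutral:
                p1 = np.random.randint(0, N)
                p2 = np.random.randint(0, N)
                if track_mode > 0:
                    tr1 = _focal_source_hap(L, n_x, focal_block, xb)
                    tr2 = _focal_source_hap(L, n_x, focal_block, xb)
            else:
                tot = 0.0
                for i in range(N):
                    tot += fitness[i]
                if tot <= 0.0:
                    return k, marker_count, STATUS_EXTINCT, g
                p1 = _pick_parent(fitness, tot, N)
                p2 = _pick_parent(fitness, tot, N)
                direct = die != p1 and die != p2
                if direct:
                    prod1, tr1 = _make_gamete(
                        loads, 2 * p1, loads, 2 * die, C, L, n_x, xb, focal_chrom, focal_block
                    )
                    prod2, tr2 = _make_gamete(
                        loads, 2 * p2, loads, 2 * die + 1, C, L, n_x, xb, focal_chrom, focal_block
                    )
                else:
                    prod1, tr1 = _make_gamete(
                        loads, 2 * p1, scratch, 0, C, L, n_x, xb, focal_chrom, focal_block
                    )
                    prod2, tr2 = _make_gamete(
                        loads, 2 * p2, scratch, 1, C, L, n_x, xb, focal_chrom, focal_block
                    )
                w = prod1 * prod2
                nd = np.random.poisson(ud)
                nb = np.random.poisson(ub)
                for m in range(nd + nb):
                    if m < nd:
                        s = -np.random.gamma(g_shape, g_scale)
                    else:
                        s = np.random.exponential(b_mean)
                    h = np.random.randint(0, 2)
                    idx = np.random.randint(0, M)
                    fac = 1.0 + s
                    if direct:
                        old = loads[2 * die + h, idx]
                    else:
                        old = scratch[h, idx]
                    if fac <= 0.0:
                        new = 0.0
                        w = 0.0
                    else:
                        new = old * fac
                        if w > 0.0:
                            w *= fac
                    if direct:
                        loads[2 * die + h, idx] = new
                    else:
                        scratch[h, idx] = new
                if not direct:
                    loads[2 * die, :] = scratch[0]
                    loads[2 * die + 1, :] = scratch[1]
                fitness[die] = w

            if track_mode == 1:
                t = t0 + g + e / N
                par1 = tracer_node[p1, tr1]
                par2 = tracer_node[p2, tr2]
                anc_parent[k] = par1
                anc_time[k] = t
                node1 = node_offset + k
                k += 1
                anc_parent[k] = par2
                anc_time[k] = t
                node2 = node_offset + k
                k += 1
                tracer_node[die, 0] = node1
                tracer_node[die, 1] = node2
            elif track_mode == 2:
                m1 = marker[p1, tr1]
                m2 = marker[p2, tr2]
                marker_count += m1 + m2 - marker[die, 0] - marker[die, 1]
                marker[die, 0] = m1
                marker[die, 1] = m2
                if marker_count == 0:
                    return k, marker_count, STATUS_MARKER_LOST, g
                if marker_count == 2 * N:
                    return k, marker_count, STATUS_MARKER_FIXED, g

        mu = 0.0
        for i in range(N):
            mu += fitness[i]
        mu /= N
        s2 = 0.0
        for i in range(N):
            d = fitness[i] - mu
            s2 += d * d
        s2 /= N
        mean_out[g] = mu
        var_out[g] = s2

    return k, marker_count, STATUS_OK, n_gens
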