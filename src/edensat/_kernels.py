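"""Numba kernels for the incremental lattice engine.

The fast engine keeps, for every site of the L**3 cubic lattice, its occupancy
and the number of occupied face-neighbours, plus two Fenwick (binary indexed)
trees holding sampling weights: one over the empty surface sites (growth
candidates) and one over the jump-capable population N2.

Rank selection in a Fenwick tree is equivalent to indexing into the
lexicographically sorted member list, which is what lets the fast engine
reproduce the naive reference engine draw-for-draw from the same random
stream.

Sites are linearised as ``i = (x*L + y)*L + z`` so that linear order equals
lexicographic order on (x, y, z).
"""

import numba as nb
import numpy as np

__all__ = [
    "fen_update",
    "fen_select",
    "fen_total",
    "occupy",
    "vacate",
]


@nb.njit(cache=True)
def fen_update(tree, i, delta):
    """Add ``delta`` to the weight of 0-based site ``i``."""
    i += 1
    n = tree.shape[0] - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@nb.njit(cache=True)
def fen_total(tree):
    """Total weight stored in the tree."""
    n = tree.shape[0] - 1
    total = 0
    i = n
    while i > 0:
        total += tree[i]
        i -= i & (-i)
    return total


@nb.njit(cache=True)
def fen_select(tree, k):
    """Site (0-based) holding the k-th weight unit, in lexicographic order.

    ``k`` is 0-based and must satisfy 0 <= k < total weight.
    """
    n = tree.shape[0] - 1
    bit = 1
    while (bit << 1) <= n:
        bit <<= 1
    pos = 0
    rem = k
    while bit:
        npos = pos + bit
        if npos <= n and tree[npos] <= rem:
            pos = npos
            rem -= tree[npos]
        bit >>= 1
    return pos


@nb.njit(cache=True, inline="always")
def _n_inlattice_neighbors(x, y, z, L):
    n = 0
    if x > 0:
        n += 1
    if x < L - 1:
        n += 1
    if y > 0:
        n += 1
    if y < L - 1:
        n += 1
    if z > 0:
        n += 1
    if z < L - 1:
        n += 1
    return n


@nb.njit(cache=True)
def occupy(occ, adj, fen_b, fen_n2, s, L, thr, weighted):
    """Place a cell on empty site ``s`` and update all bookkeeping.

    Returns the deltas ``(d_n1, d_n2, d_boundary_weight)`` so the caller can
    maintain scalar population counters.  ``thr`` is the minimum number of
    empty face-neighbours for N2 membership (must be >= 2); ``weighted`` picks
    the adjacency-multiplicity surface variant over the deduplicated one.
    """
    sxy = L * L
    x = s // sxy
    r = s - x * sxy
    y = r // L
    z = r - y * L

    d_n1 = 0
    d_n2 = 0
    d_b = 0

    occ[s] = 1
    a = adj[s]
    if a > 0:  # s was a surface site; drop it from the growth pool
        w = a if weighted else 1
        fen_update(fen_b, s, -w)
        d_b -= w

    e_s = _n_inlattice_neighbors(x, y, z, L) - a
    if e_s >= thr:
        fen_update(fen_n2, s, 1)
        d_n2 += 1
    elif e_s >= 1:
        d_n1 += 1

    for d in range(6):
        if d == 0:
            if x == 0:
                continue
            nbx, nby, nbz = x - 1, y, z
        elif d == 1:
            if x == L - 1:
                continue
            nbx, nby, nbz = x + 1, y, z
        elif d == 2:
            if y == 0:
                continue
            nbx, nby, nbz = x, y - 1, z
        elif d == 3:
            if y == L - 1:
                continue
            nbx, nby, nbz = x, y + 1, z
        elif d == 4:
            if z == 0:
                continue
            nbx, nby, nbz = x, y, z - 1
        else:
            if z == L - 1:
                continue
            nbx, nby, nbz = x, y, z + 1
        nbi = (nbx * L + nby) * L + nbz
        old = adj[nbi]
        adj[nbi] = old + 1
        if occ[nbi]:
            # neighbour cell lost one empty face-neighbour
            e_old = _n_inlattice_neighbors(nbx, nby, nbz, L) - old
            if e_old >= thr and e_old - 1 < thr:
                fen_update(fen_n2, nbi, -1)
                d_n2 -= 1
                d_n1 += 1  # thr - 1 >= 1 empty neighbours remain
            elif e_old == 1:
                d_n1 -= 1  # became fully enclosed
        else:
            # empty neighbour gained an occupied face-neighbour
            if weighted:
                fen_update(fen_b, nbi, 1)
                d_b += 1
            elif old == 0:
                fen_update(fen_b, nbi, 1)
                d_b += 1
    return d_n1, d_n2, d_b


@nb.njit(cache=True)
def vacate(occ, adj, fen_b, fen_n2, s, L, thr, weighted):
    """Remove the cell at occupied site ``s`` (inverse of :func:`occupy`)."""
    sxy = L * L
    x = s // sxy
    r = s - x * sxy
    y = r // L
    z = r - y * L

    d_n1 = 0
    d_n2 = 0
    d_b = 0

    occ[s] = 0
    a = adj[s]
    e_s = _n_inlattice_neighbors(x, y, z, L) - a
    if e_s >= thr:
        fen_update(fen_n2, s, -1)
        d_n2 -= 1
    elif e_s >= 1:
        d_n1 -= 1
    if a > 0:  # the vacated site becomes part of the surface
        w = a if weighted else 1
        fen_update(fen_b, s, w)
        d_b += w

    for d in range(6):
        if d == 0:
            if x == 0:
                continue
            nbx, nby, nbz = x - 1, y, z
        elif d == 1:
            if x == L - 1:
                continue
            nbx, nby, nbz = x + 1, y, z
        elif d == 2:
            if y == 0:
                continue
            nbx, nby, nbz = x, y - 1, z
        elif d == 3:
            if y == L - 1:
                continue
            nbx, nby, nbz = x, y + 1, z
        elif d == 4:
            if z == 0:
                continue
            nbx, nby, nbz = x, y, z - 1
        else:
            if z == L - 1:
                continue
            nbx, nby, nbz = x, y, z + 1
        nbi = (nbx * L + nby) * L + nbz
        old = adj[nbi]
        adj[nbi] = old - 1
        if occ[nbi]:
            # neighbour cell gained one empty face-neighbour
            e_old = _n_inlattice_neighbors(nbx, nby, nbz, L) - old
            if e_old < thr and e_old + 1 >= thr:
                fen_update(fen_n2, nbi, 1)
                d_n2 += 1
                d_n1 -= 1  # e_old == thr - 1 >= 1, so it was in N1
            elif e_old == 0:
                d_n1 += 1
        else:
            if weighted:
                fen_update(fen_b, nbi, -1)
                d_b -= 1
            elif old == 1:
                fen_update(fen_b, nbi, -1)
                d_b -= 1
    return d_n1, d_n2, d_b
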