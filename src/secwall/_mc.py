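"""Numba kernels for the periodic hard-disk Monte Carlo engine.

All kernels work on an (n, 2) float64 coordinate array in a periodic
square box of side ``L`` with non-penetration diameter ``2 * r_eff``.
Overlap tests use a cell list whose cells are at least one diameter
wide, so only the 3x3 neighbourhood of a cell needs checking.

Kernels are deterministic: every stochastic kernel seeds numba's
internal RNG from an explicit integer argument.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# max disks per cell; cells are < 2 diameters wide, so the true bound is ~9
_CELL_CAP = 28


@njit(cache=True)
def _wrap(x, L):
    return x - L * np.floor(x / L)


@njit(cache=True)
def _cell_grid(L, r_eff):
    """Number of cells per side; 0 signals 'use brute force'."""
    ncell = int(L / (2.0 * r_eff))
    if ncell < 4:
        return 0
    return ncell


@njit(cache=True)
def _build_cells(pos, L, ncell):
    n = pos.shape[0]
    count = np.zeros((ncell, ncell), dtype=np.int64)
    items = np.zeros((ncell, ncell, _CELL_CAP), dtype=np.int64)
    cell_of = np.zeros((n, 2), dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / L * ncell) % ncell
        cy = int(pos[i, 1] / L * ncell) % ncell
        items[cx, cy, count[cx, cy]] = i
        count[cx, cy] += 1
        cell_of[i, 0] = cx
        cell_of[i, 1] = cy
    return count, items, cell_of


@njit(cache=True)
def _overlaps_at(x, y, skip, pos, L, d2, count, items, ncell):
    """True if a disk centred at (x, y) overlaps any disk other than `skip`."""
    cx = int(x / L * ncell) % ncell
    cy = int(y / L * ncell) % ncell
    for ox in range(-1, 2):
        for oy in range(-1, 2):
            ax = (cx + ox) % ncell
            ay = (cy + oy) % ncell
            for k in range(count[ax, ay]):
                j = items[ax, ay, k]
                if j == skip:
                    continue
                dx = pos[j, 0] - x
                dy = pos[j, 1] - y
                dx -= L * np.rint(dx / L)
                dy -= L * np.rint(dy / L)
                if dx * dx + dy * dy < d2:
                    return True
    return False


@njit(cache=True)
def _overlaps_brute(x, y, skip, pos, L, d2):
    for j in range(pos.shape[0]):
        if j == skip:
            continue
        dx = pos[j, 0] - x
        dy = pos[j, 1] - y
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        if dx * dx + dy * dy < d2:
            return True
    return False


@njit(cache=True)
def rsa_fill(n, L, r_eff, seed, max_consecutive_failures):
    """Random sequential addition of n disks; returns (pos, n_placed).

    Gives up (returning the partial configuration) after
    ``max_consecutive_failures`` rejected insertions in a row.
    """
    np.random.seed(seed)
    pos = np.zeros((n, 2))
    d2 = 4.0 * r_eff * r_eff
    ncell = _cell_grid(L, r_eff)
    if ncell > 0:
        count = np.zeros((ncell, ncell), dtype=np.int64)
        items = np.zeros((ncell, ncell, _CELL_CAP), dtype=np.int64)
    else:
        count = np.zeros((1, 1), dtype=np.int64)
        items = np.zeros((1, 1, _CELL_CAP), dtype=np.int64)
    placed = 0
    fails = 0
    while placed < n:
        x = np.random.random() * L
        y = np.random.random() * L
        if ncell > 0:
            bad = _overlaps_at(x, y, -1, pos[:placed], L, d2, count, items, ncell)
        else:
            bad = _overlaps_brute(x, y, -1, pos[:placed], L, d2)
        if bad:
            fails += 1
            if fails >= max_consecutive_failures:
                return pos, placed
            continue
        pos[placed, 0] = x
        pos[placed, 1] = y
        if ncell > 0:
            cx = int(x / L * ncell) % ncell
            cy = int(y / L * ncell) % ncell
            items[cx, cy, count[cx, cy]] = placed
            count[cx, cy] += 1
        placed += 1
        fails = 0
    return pos, placed


@njit(cache=True)
def mc_sweeps(pos, L, r_eff, delta, n_sweeps, seed, tune, tune_interval):
    """Metropolis sweeps of single-disk uniform displacements.

    A sweep is n trial moves on uniformly chosen disks; a move is rejected
    on any overlap (hard-core potential: acceptance is purely geometric).
    With ``tune`` true, delta is rescaled every ``tune_interval`` sweeps
    toward a 30-50% acceptance window.  Returns (delta, acceptance_rate).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    d2 = 4.0 * r_eff * r_eff
    ncell = _cell_grid(L, r_eff)
    if ncell > 0:
        count, items, cell_of = _build_cells(pos, L, ncell)
    else:
        count = np.zeros((1, 1), dtype=np.int64)
        items = np.zeros((1, 1, _CELL_CAP), dtype=np.int64)
        cell_of = np.zeros((n, 2), dtype=np.int64)
    accepted = 0
    attempted = 0
    acc_window = 0
    att_window = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = int(np.random.random() * n)
            if i == n:
                i = n - 1
            x = pos[i, 0] + (2.0 * np.random.random() - 1.0) * delta
            y = pos[i, 1] + (2.0 * np.random.random() - 1.0) * delta
            x = _wrap(x, L)
            y = _wrap(y, L)
            attempted += 1
            att_window += 1
            if ncell > 0:
                bad = _overlaps_at(x, y, i, pos, L, d2, count, items, ncell)
            else:
                bad = _overlaps_brute(x, y, i, pos, L, d2)
            if bad:
                continue
            if ncell > 0:
                cx = int(x / L * ncell) % ncell
                cy = int(y / L * ncell) % ncell
                ox, oy = cell_of[i, 0], cell_of[i, 1]
                if cx != ox or cy != oy:
                    # remove i from its old cell (swap-with-last)
                    m = count[ox, oy]
                    for k in range(m):
                        if items[ox, oy, k] == i:
                            items[ox, oy, k] = items[ox, oy, m - 1]
                            break
                    count[ox, oy] = m - 1
                    items[cx, cy, count[cx, cy]] = i
                    count[cx, cy] += 1
                    cell_of[i, 0] = cx
                    cell_of[i, 1] = cy
            pos[i, 0] = x
            pos[i, 1] = y
            accepted += 1
            acc_window += 1
        if tune and (sweep + 1) % tune_interval == 0 and att_window > 0:
            rate = acc_window / att_window
            if rate < 0.30:
                delta *= 0.8
            elif rate > 0.50:
                delta = min(delta * 1.25, L / 4.0)
            acc_window = 0
            att_window = 0
    rate = accepted / attempted if attempted > 0 else 0.0
    return delta, rate


@njit(cache=True)
def min_pair_distance(pos, L):
    """Brute-force O(n²) minimum periodic pair distance."""
    n = pos.shape[0]
    best = L
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            d = np.sqrt(dx * dx + dy * dy)
            if d < best:
                best = d
    return best


@njit(cache=True)
def pair_histogram(pos, L, bin_width, n_bins):
    """Periodic minimum-image pair-distance histogram (counts each pair once)."""
    n = pos.shape[0]
    hist = np.zeros(n_bins, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            r = np.sqrt(dx * dx + dy * dy)
            b = int(r / bin_width)
            if b < n_bins:
                hist[b] += 1
    return hist


@njit(cache=True)
def lattice_surface_distances(pos, L, n_lat, radius):
    """Distance from each lattice point to the nearest disk surface.

    Lays an n_lat x n_lat square lattice over the box and returns, for the
    lattice points lying OUTSIDE every physical disk (the matrix phase),
    the distance to the nearest disk surface (nearest-centre distance
    minus ``radius``).  Points inside a disk get -1 sentinel.
    """
    spacing = L / n_lat
    out = np.empty(n_lat * n_lat)
    n = pos.shape[0]
    for iy in range(n_lat):
        for ix in range(n_lat):
            x = (ix + 0.5) * spacing
            y = (iy + 0.5) * spacing
            best2 = 1e300
            for j in range(n):
                dx = pos[j, 0] - x
                dy = pos[j, 1] - y
                dx -= L * np.rint(dx / L)
                dy -= L * np.rint(dy / L)
                d2 = dx * dx + dy * dy
                if d2 < best2:
                    best2 = d2
            d = np.sqrt(best2) - radius
            out[iy * n_lat + ix] = d if d > 0.0 else -1.0
    return out


@njit(cache=True)
def lattice_surface_distances_celled(pos, L, n_lat, radius, search_cap):
    """Cell-accelerated version of :func:`lattice_surface_distances`.

    ``search_cap`` (Å) bounds the nearest-surface distance of interest;
    matrix points farther than that from every disk are reported at the
    cap (sufficient for cumulative shell fractions up to the cap).
    """
    spacing = L / n_lat
    # cell width >= search diameter so a fixed neighbourhood suffices
    reach = radius + search_cap
    ncell = int(L / reach)
    if ncell < 3:
        return lattice_surface_distances(pos, L, n_lat, radius)
    count = np.zeros((ncell, ncell), dtype=np.int64)
    # disks per cell can be large here; use dynamic second pass sizing
    cap = 8
    cw = L / ncell
    est = int((cw + 2.0 * radius) * (cw + 2.0 * radius) / (2.0 * radius * radius)) + 4
    if est > cap:
        cap = est
    items = np.zeros((ncell, ncell, cap), dtype=np.int64)
    n = pos.shape[0]
    for i in range(n):
        cx = int(pos[i, 0] / L * ncell) % ncell
        cy = int(pos[i, 1] / L * ncell) % ncell
        if count[cx, cy] < cap:
            items[cx, cy, count[cx, cy]] = i
            count[cx, cy] += 1
        else:
            # capacity blown: fall back to the exact O(n) kernel
            return lattice_surface_distances(pos, L, n_lat, radius)
    out = np.empty(n_lat * n_lat)
    for iy in range(n_lat):
        for ix in range(n_lat):
            x = (ix + 0.5) * spacing
            y = (iy + 0.5) * spacing
            cx = int(x / L * ncell) % ncell
            cy = int(y / L * ncell) % ncell
            best2 = 1e300
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    ax = (cx + ox) % ncell
                    ay = (cy + oy) % ncell
                    for k in range(count[ax, ay]):
                        j = items[ax, ay, k]
                        dx = pos[j, 0] - x
                        dy = pos[j, 1] - y
                        dx -= L * np.rint(dx / L)
                        dy -= L * np.rint(dy / L)
                        d2 = dx * dx + dy * dy
                        if d2 < best2:
                            best2 = d2
            d = np.sqrt(best2) - radius
            if d <= 0.0:
                out[iy * n_lat + ix] = -1.0
            elif d > search_cap:
                out[iy * n_lat + ix] = search_cap
            else:
                out[iy * n_lat + ix] = d
    return out
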