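"""Numba kernel for the hexagonal-lattice progenitor cellular automaton.

State layout (N = width*height sites, two slots per site):

* ``ctype[N, 2]``  -1 empty slot, 0 progenitor, 1 differentiating
* ``geno[N, 2]``   0 wild type, 1 mutant
* ``clone[N, 2]``  induced-clone label, -1 unlabelled
* ``occ[N]``       site occupancy 0/1/2
* ``nbrs[N, 6]``   precomputed periodic hex neighbourhood

Event sampling is exact continuous-time (Gillespie). Four reaction
channels: division of a singly resident wild-type / mutant progenitor at
its genotype's lambda, stratification of a (always singly resident)
wild-type / mutant differentiating cell at its genotype's Gamma. Cells in
doubly occupied sites are division-blocked until the pair resolves; by
construction a doubly occupied site only ever holds two progenitors.

Resolution of a doubly occupied site: migrate one resident (uniform) to a
uniform empty neighbour when one exists; otherwise extrude one
differentiating resident (uniform) if any; otherwise the pair waits.
Resolution runs immediately after every division, and every
stratification offers the freed site to a uniform doubly occupied
neighbour, so extrusion and unblocking are event-driven, never polled.

RNG: numba's internal legacy stream, seeded once per run; the draw order
is fixed by the code path, so a seed fully determines the trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# reaction-channel codes
WT_P, MUT_P, WT_D, MUT_D = 0, 1, 2, 3


def hex_neighbours(width: int, height: int) -> np.ndarray:
    """Periodic 6-neighbourhood for an odd-r offset hexagonal grid.

    Site index is ``row * width + col``.
    """
    nbrs = np.empty((width * height, 6), dtype=np.int64)
    for row in range(height):
        for col in range(width):
            if row % 2 == 0:
                offs = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
            else:
                offs = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))
            for k, (dr, dc) in enumerate(offs):
                rr = (row + dr) % height
                cc = (col + dc) % width
                nbrs[row * width + col, k] = rr * width + cc
    return nbrs


@njit(cache=True)
def _cat_add(cat, cell, cat_items, cat_len, cell_cat, cell_pos):
    i = cat_len[cat]
    cat_items[cat, i] = cell
    cell_cat[cell] = cat
    cell_pos[cell] = i
    cat_len[cat] = i + 1


@njit(cache=True)
def _cat_remove(cell, cat_items, cat_len, cell_cat, cell_pos):
    cat = cell_cat[cell]
    i = cell_pos[cell]
    last = cat_len[cat] - 1
    moved = cat_items[cat, last]
    cat_items[cat, i] = moved
    cell_pos[moved] = i
    cat_len[cat] = last
    cell_cat[cell] = -1
    cell_pos[cell] = -1


@njit(cache=True)
def _channel_of(ct, g):
    # progenitor channels 0/1, differentiating 2/3, split by genotype
    if ct == 0:
        return MUT_P if g == 1 else WT_P
    return MUT_D if g == 1 else WT_D


@njit(cache=True)
def _resolve_double(site, occ, ctype, geno, clone, nbrs,
                    cat_items, cat_len, cell_cat, cell_pos):
    """Resolve one doubly occupied site. Returns 1 if a cell was extruded."""
    # empty neighbours first: migration
    n_empty = 0
    for k in range(6):
        if occ[nbrs[site, k]] == 0:
            n_empty += 1
    if n_empty > 0:
        pick = int(np.random.random() * n_empty)
        target = -1
        seen = 0
        for k in range(6):
            nb = nbrs[site, k]
            if occ[nb] == 0:
                if seen == pick:
                    target = nb
                    break
                seen += 1
        mover = 0 if np.random.random() < 0.5 else 1
        stay = 1 - mover
        # move into slot 0 of the empty site
        ctype[target, 0] = ctype[site, mover]
        geno[target, 0] = geno[site, mover]
        clone[target, 0] = clone[site, mover]
        occ[target] = 1
        # compact the stayer into slot 0
        if stay == 1:
            ctype[site, 0] = ctype[site, 1]
            geno[site, 0] = geno[site, 1]
            clone[site, 0] = clone[site, 1]
        ctype[site, 1] = -1
        occ[site] = 1
        # both cells are now singly resident -> schedulable
        _cat_add(_channel_of(ctype[target, 0], geno[target, 0]), target * 2,
                 cat_items, cat_len, cell_cat, cell_pos)
        _cat_add(_channel_of(ctype[site, 0], geno[site, 0]), site * 2,
                 cat_items, cat_len, cell_cat, cell_pos)
        return 0
    # no space: instant extrusion of a differentiating resident, if any
    n_diff = 0
    for k in range(2):
        if ctype[site, k] == 1:
            n_diff += 1
    if n_diff > 0:
        if n_diff == 2:
            out = 0 if np.random.random() < 0.5 else 1
        else:
            out = 0 if ctype[site, 0] == 1 else 1
        if out == 0:
            ctype[site, 0] = ctype[site, 1]
            geno[site, 0] = geno[site, 1]
            clone[site, 0] = clone[site, 1]
        ctype[site, 1] = -1
        occ[site] = 1
        _cat_add(_channel_of(ctype[site, 0], geno[site, 0]), site * 2,
                 cat_items, cat_len, cell_cat, cell_pos)
        return 1
    # two progenitors, no space: blocked pair persists
    return 0


@njit(cache=True)
def run_ca(width, height, duration, record_times, seed,
           occ, ctype, geno, clone, nbrs,
           lam_wt, gam_wt, r_wt, delta_wt,
           lam_mut, gam_mut, r_mut, delta_mut,
           crowding_multiplier):
    """Evolve the lattice in place; returns per-record-time snapshots."""
    np.random.seed(seed)
    n_sites = width * height
    n_rec = len(record_times)

    out_ctype = np.empty((n_rec, n_sites, 2), dtype=np.int8)
    out_geno = np.empty((n_rec, n_sites, 2), dtype=np.int8)
    out_clone = np.empty((n_rec, n_sites, 2), dtype=np.int32)
    out_doubles = np.zeros(n_rec, dtype=np.int64)
    out_extruded = np.zeros(n_rec, dtype=np.int64)
    out_stratified = np.zeros(n_rec, dtype=np.int64)

    # event-channel bookkeeping: cell id = site*2 + slot
    cat_items = np.empty((4, 2 * n_sites), dtype=np.int64)
    cat_len = np.zeros(4, dtype=np.int64)
    cell_cat = np.full(2 * n_sites, -1, dtype=np.int64)
    cell_pos = np.full(2 * n_sites, -1, dtype=np.int64)
    for s in range(n_sites):
        for k in range(2):
            if ctype[s, k] >= 0 and occ[s] == 1:
                _cat_add(_channel_of(ctype[s, k], geno[s, k]), s * 2 + k,
                         cat_items, cat_len, cell_cat, cell_pos)
        if occ[s] == 2 and (ctype[s, 0] == 1 or ctype[s, 1] == 1):
            # initial states must not hold mixed doubles; resolve them now
            _resolve_double(s, occ, ctype, geno, clone, nbrs,
                            cat_items, cat_len, cell_cat, cell_pos)

    t = 0.0
    rec_idx = 0
    n_extruded = 0
    n_stratified = 0
    rates = np.empty(4)
    while rec_idx < n_rec:
        rates[WT_P] = lam_wt * cat_len[WT_P]
        rates[MUT_P] = lam_mut * cat_len[MUT_P]
        rates[WT_D] = gam_wt * cat_len[WT_D]
        rates[MUT_D] = gam_mut * cat_len[MUT_D]
        total = rates[0] + rates[1] + rates[2] + rates[3]
        if total <= 0.0:
            t = duration + 1.0
        else:
            t += np.random.exponential(1.0 / total)
        # snapshot every record time passed by this waiting interval
        while rec_idx < n_rec and record_times[rec_idx] < t:
            for s in range(n_sites):
                for k in range(2):
                    out_ctype[rec_idx, s, k] = ctype[s, k]
                    out_geno[rec_idx, s, k] = geno[s, k]
                    out_clone[rec_idx, s, k] = clone[s, k]
            nd = 0
            for s in range(n_sites):
                if occ[s] == 2:
                    nd += 1
            out_doubles[rec_idx] = nd
            out_extruded[rec_idx] = n_extruded
            out_stratified[rec_idx] = n_stratified
            rec_idx += 1
        if rec_idx >= n_rec or t > duration:
            break

        u = np.random.random() * total
        ch = 0
        acc = rates[0]
        while u >= acc and ch < 3:
            ch += 1
            acc += rates[ch]
        cell = cat_items[ch, int(np.random.random() * cat_len[ch])]
        site = cell // 2
        slot = cell % 2

        if ch == WT_P or ch == MUT_P:
            # division of a singly resident progenitor
            g = geno[site, slot]
            if g == 1:
                delta = delta_mut
                n_double_nb = 0
                for k in range(6):
                    if occ[nbrs[site, k]] == 2:
                        n_double_nb += 1
                if n_double_nb >= 1:
                    delta = delta_mut * crowding_multiplier
                r = r_mut
            else:
                delta = delta_wt
                r = r_wt
            p_pp = r * (1.0 + delta)
            p_pd = 1.0 - 2.0 * r
            v = np.random.random()
            if v < p_pp:
                c0, c1 = 0, 0
            elif v < p_pp + p_pd:
                c0, c1 = 0, 1
            else:
                c0, c1 = 1, 1
            _cat_remove(cell, cat_items, cat_len, cell_cat, cell_pos)
            cl = clone[site, slot]
            ctype[site, 0] = c0
            ctype[site, 1] = c1
            geno[site, 0] = g
            geno[site, 1] = g
            clone[site, 0] = cl
            clone[site, 1] = cl
            occ[site] = 2
            n_extruded += _resolve_double(site, occ, ctype, geno, clone, nbrs,
                                          cat_items, cat_len, cell_cat, cell_pos)
        else:
            # stratification of a singly resident differentiating cell
            _cat_remove(cell, cat_items, cat_len, cell_cat, cell_pos)
            ctype[site, slot] = -1
            occ[site] = 0
            n_stratified += 1
            # offer the freed site to a doubly occupied neighbour
            n_dbl = 0
            for k in range(6):
                if occ[nbrs[site, k]] == 2:
                    n_dbl += 1
            if n_dbl > 0:
                pick = int(np.random.random() * n_dbl)
                seen = 0
                src = -1
                for k in range(6):
                    nb = nbrs[site, k]
                    if occ[nb] == 2:
                        if seen == pick:
                            src = nb
                            break
                        seen += 1
                mover = 0 if np.random.random() < 0.5 else 1
                stay = 1 - mover
                ctype[site, 0] = ctype[src, mover]
                geno[site, 0] = geno[src, mover]
                clone[site, 0] = clone[src, mover]
                ctype[site, 1] = -1
                occ[site] = 1
                if stay == 1:
                    ctype[src, 0] = ctype[src, 1]
                    geno[src, 0] = geno[src, 1]
                    clone[src, 0] = clone[src, 1]
                ctype[src, 1] = -1
                occ[src] = 1
                _cat_add(_channel_of(ctype[site, 0], geno[site, 0]), site * 2,
                         cat_items, cat_len, cell_cat, cell_pos)
                _cat_add(_channel_of(ctype[src, 0], geno[src, 0]), src * 2,
                         cat_items, cat_len, cell_cat, cell_pos)

    # runs that end with unrecorded times (all-extinct edge) get final state
    while rec_idx < n_rec:
        for s in range(n_sites):
            for k in range(2):
                out_ctype[rec_idx, s, k] = ctype[s, k]
                out_geno[rec_idx, s, k] = geno[s, k]
                out_clone[rec_idx, s, k] = clone[s, k]
        nd = 0
        for s in range(n_sites):
            if occ[s] == 2:
                nd += 1
        out_doubles[rec_idx] = nd
        out_extruded[rec_idx] = n_extruded
        out_stratified[rec_idx] = n_stratified
        rec_idx += 1

    return out_ctype, out_geno, out_clone, out_doubles, out_extruded, out_stratified
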