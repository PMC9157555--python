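"""Independent brute-force oracles used by unit and acceptance tests.

These re-derive expected results by direct enumeration, sharing no code
path with the implementation they check.
"""

from __future__ import annotations

import numpy as np

from forestinv.allometry import PowerModel


def brute_force_treetops(chm, window_factor=0.1, min_height=1.37):
    """Per-pixel variable-window local-maximum search by direct window scan.

    Applies the same published decision rules (>= everything in the
    circular window, strictly above at least one neighbor unless alone,
    first-in-row-major on plateaus) but by examining every pixel's window
    explicitly.  Returns a list of (i, j, height) pixel hits.
    """
    vals = chm.values
    ny, nx = vals.shape
    nodata = chm.nodata
    cell = chm.cell_size
    hits = []
    for i in range(ny):
        for j in range(nx):
            h = vals[i, j]
            if h == nodata or h <= min_height:
                continue
            r = max(h * window_factor, cell) / cell
            rc = int(np.floor(r + 1e-9))
            i0, i1 = max(i - rc, 0), min(i + rc, ny - 1)
            j0, j1 = max(j - rc, 0), min(j + rc, nx - 1)
            win = vals[i0 : i1 + 1, j0 : j1 + 1]
            ii, jj = np.mgrid[i0 : i1 + 1, j0 : j1 + 1]
            inside = ((ii - i) ** 2 + (jj - j) ** 2 <= r * r + 1e-9) & (win != nodata)
            neigh = win[inside]
            if (neigh > h).any():
                continue
            if neigh.size > 1 and not (neigh < h).any():
                continue
            eq = inside & (win == h)
            if (ii[eq] * nx + jj[eq]).min() < i * nx + j:
                continue
            hits.append((i, j, float(h)))
    return hits


def sequential_greedy_match(tops, stems, regional: PowerModel, radius: float = 4.0):
    """Smallest-difference-first matching by full re-scan each round.

    Each round enumerates every remaining (stem, top) pair within the
    radius and accepts the one with the smallest |extracted - regional|
    difference (ties: distance, stem id, tree id); both members leave the
    pool.  Returns a set of (stem_id, tree_id) pairs.
    """
    remaining_stems = list(range(len(stems)))
    remaining_tops = list(range(len(tops)))
    accepted = set()
    while True:
        best = None
        for si in remaining_stems:
            s = stems[si]
            for ti in remaining_tops:
                t = tops[ti]
                dist = float(np.hypot(t.x - s.x, t.y - s.y))
                if dist > radius:
                    continue
                cost = abs(s.dbh - regional.a * t.height**regional.b)
                key = (cost, dist, s.stem_id, t.tree_id)
                if best is None or key < best[0]:
                    best = (key, si, ti)
        if best is None:
            return accepted
        _, si, ti = best
        accepted.add((stems[si].stem_id, tops[ti].tree_id))
        remaining_stems.remove(si)
        remaining_tops.remove(ti)
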