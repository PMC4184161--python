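"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the dip oracle poses the
best-unimodal-CDF fit as a sequence of small linear programs, one per
candidate mode placement, and is exact for small samples.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(values) -> float:
    """Exact dip of a sample via linear programming.

    The dip is ``min_G sup_x |F_n(x) - G(x)|`` over unimodal CDFs ``G``
    (convex below the mode, concave above; convexity allows an upward jump
    exactly at the mode).  For a mode placed at a distinct data value the
    problem is a linear program in the CDF values at the data points, the
    left/right limits at the mode, and the band half-width ``d``:

    * at every non-mode point the CDF must sit within ``d`` of both step
      corners of the empirical CDF;
    * at the mode the left limit is constrained by the lower corner only and
      the right limit by the upper corner only (the jump absorbs the step);
    * values are monotone, convex up to the mode and concave after it
      (sign-constrained second differences over consecutive points).

    A mode strictly inside a gap between data values never improves on the
    better of the two adjacent at-value placements: in the gap the CDF must
    be continuous at the mode (a jump can only go up, and raising the
    concave side's start or lowering the convex side's end only tightens the
    slope requirements), and sliding the mode to the nearer data value
    relaxes the remaining constraints.  ``test_dip`` verifies this
    numerically with gap-mode LPs on random samples.  The result is floored
    at 1/(2n), the value conventionally reported for samples a unimodal CDF
    can match exactly.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n == 1 or x[0] == x[-1]:
        return 0.5 / n
    v, lo, hi = _distinct_corners(x)
    best = min(
        d
        for d in (_min_d_at_value(v, lo, hi, g) for g in range(v.size))
        if d is not None
    )
    return max(best, 0.5 / n)


def _distinct_corners(x_sorted):
    """Distinct values with the empirical CDF just left of / at each."""
    n = x_sorted.size
    v, counts = np.unique(x_sorted, return_counts=True)
    hi = np.cumsum(counts) / n
    lo = hi - counts / n
    return v, lo, hi


def dip_gap_mode(values, n_grid=60):
    """Best dip over modes placed strictly inside gaps (grid over positions).

    Support tool for validating that gap modes never beat at-value modes;
    grid-based, so approximate.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    v, lo, hi = _distinct_corners(x)
    best = np.inf
    for g in range(v.size - 1):
        for t in np.linspace(1e-3, 1 - 1e-3, n_grid):
            m = v[g] + t * (v[g + 1] - v[g])
            d = _min_d_gap(v, lo, hi, g, m)
            if d is not None:
                best = min(best, d)
    return best


def _lp_solve(nv, i_d, rows, rhs):
    c = np.zeros(nv)
    c[i_d] = 1.0
    res = linprog(
        c,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(None, None)] * (nv - 1) + [(0, None)],
        method="highs",
    )
    return float(res.x[i_d]) if res.success else None


def _min_d_at_value(v, lo, hi, g):
    """Minimal band half-width with the mode at distinct value ``g``.

    Variables: y_j (j != g), v_minus, v_plus, d.
    """
    G = v.size
    # variable indexing: 0..G-1 -> y_j for j != g, slot g -> v_plus
    # (the concave-side value at the mode); extra slot G -> v_minus; G+1 -> d
    i_minus, i_d = G, G + 1
    nv = G + 2
    rows, rhs = [], []

    def add(pairs, b):
        r = np.zeros(nv)
        for j, c in pairs:
            r[j] += c
        rows.append(r)
        rhs.append(b)

    for j in range(G):
        if j == g:
            add([(i_minus, 1.0), (i_d, -1.0)], lo[j])
            add([(i_minus, -1.0), (i_d, -1.0)], -lo[j])
            add([(j, 1.0), (i_d, -1.0)], hi[j])
            add([(j, -1.0), (i_d, -1.0)], -hi[j])
        else:
            add([(j, 1.0), (i_d, -1.0)], lo[j])   # y_j <= lo_j + d
            add([(j, -1.0), (i_d, -1.0)], -hi[j])  # y_j >= hi_j - d
    # monotone chain through the mode's two limits, bounded in [0, 1]
    chain = [j for j in range(g)] + [i_minus, g] + [j for j in range(g + 1, G)]
    for a, b in zip(chain, chain[1:]):
        add([(a, 1.0), (b, -1.0)], 0.0)
    add([(chain[0], -1.0)], 0.0)
    add([(chain[-1], 1.0)], 1.0)
    # convex side: points 0..g-1 then (v[g], v_minus)
    left = [(v[j], j) for j in range(g)] + [(v[g], i_minus)]
    _add_shape(add, left, convex=True)
    # concave side: (v[g], v_plus) then points g+1..G-1
    right = [(v[g], g)] + [(v[j], j) for j in range(g + 1, G)]
    _add_shape(add, right, convex=False)
    return _lp_solve(nv, i_d, rows, rhs)


def _min_d_gap(v, lo, hi, g, m):
    """Minimal band half-width with the mode fixed at ``m`` inside gap
    (v[g], v[g+1]); the CDF is continuous there with free value ``w``."""
    G = v.size
    i_w, i_d = G, G + 1
    nv = G + 2
    rows, rhs = [], []

    def add(pairs, b):
        r = np.zeros(nv)
        for j, c in pairs:
            r[j] += c
        rows.append(r)
        rhs.append(b)

    for j in range(G):
        add([(j, 1.0), (i_d, -1.0)], lo[j])
        add([(j, -1.0), (i_d, -1.0)], -hi[j])
    # gap band: F is constant hi[g] across the gap
    add([(i_w, 1.0), (i_d, -1.0)], hi[g])
    add([(i_w, -1.0), (i_d, -1.0)], -hi[g])
    chain = list(range(g + 1)) + [i_w] + list(range(g + 1, G))
    for a, b in zip(chain, chain[1:]):
        add([(a, 1.0), (b, -1.0)], 0.0)
    add([(chain[0], -1.0)], 0.0)
    add([(chain[-1], 1.0)], 1.0)
    left = [(v[j], j) for j in range(g + 1)] + [(m, i_w)]
    _add_shape(add, left, convex=True)
    right = [(m, i_w)] + [(v[j], j) for j in range(g + 1, G)]
    _add_shape(add, right, convex=False)
    return _lp_solve(nv, i_d, rows, rhs)


def _add_shape(add, pts, convex):
    """Sign-constrained second differences over consecutive point triples."""
    for (xa, ia), (xb, ib), (xc, ic) in zip(pts, pts[1:], pts[2:]):
        # convex: (yb-ya)(xc-xb) - (yc-yb)(xb-xa) <= 0 ; concave: >= 0
        s = 1.0 if convex else -1.0
        add(
            [
                (ib, s * ((xc - xb) + (xb - xa))),
                (ia, -s * (xc - xb)),
                (ic, -s * (xb - xa)),
            ],
            0.0,
        )


def bh_textbook(pvalues):
    """Step-up BH from the definition, element by element."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


def trimmed_mean_bruteforce(values, trim_fraction):
    """Trimmed mean discarding floor(trim*n) values from each tail."""
    s = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(trim_fraction * s.size))
    kept = s[k : s.size - k] if k > 0 else s
    return kept.mean()


def best_split_bruteforce(values):
    """Exhaustive 1-D two-group split minimising within-group variance.

    Returns the midpoint of the two group means at the best split.
    """
    s = np.sort(np.asarray(values, dtype=float))
    n = s.size
    best_ss, best_mid = np.inf, np.nan
    for k in range(1, n):
        a, b = s[:k], s[k:]
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if ss < best_ss:
            best_ss = ss
            best_mid = 0.5 * (a.mean() + b.mean())
    return best_mid
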