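"""Hartigan's dip statistic with Monte-Carlo null distributions.

The dip of a sample is the smallest sup-norm distance between the empirical
CDF and any unimodal CDF (convex up to a mode, concave after it, with an
arbitrary jump permitted at the mode itself).  Large dips indicate departure
from unimodality; the statistic is the workhorse behind the bimodal-marker
scan in :mod:`hlascore.discovery`.

Significance is assessed empirically: dips of many standard-normal samples of
the same size form the null distribution, and the p-value of an observed dip
is the proportion of null dips strictly greater than it.  Because the dip is
invariant under strictly increasing affine transforms, the choice of normal
parameters for the null is irrelevant.

Implementation notes
--------------------
The kernel is the classical iterative modal-interval algorithm.  Working in
units of 1/n with the step corners of the empirical CDF (lower corner ``i``
and upper corner ``i+1`` at the i-th order statistic, 0-based), it fits the
greatest convex minorant (GCM, lower convex hull of the lower corners) and
the least concave majorant (LCM, upper concave hull of the upper corners)
over the current candidate modal interval.  The largest vertical distance
between the two fitted curves, evaluated at their vertices, measures the
convex/concave tension still inside the interval; where it occurs defines a
tighter modal interval, and the CDF deviations over the regions abandoned to
the tails are accumulated.  Iteration stops when the interior tension no
longer exceeds the accumulated tail deviation; the dip is half that
deviation (in 1/n units), floored at 1, hence the familiar 1/(2n) lower
bound.  The kernel is numba-compiled for the Monte-Carlo null loop; ties are
handled exactly through the corner bookkeeping (no jittering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - numba is an optional accelerator
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # noqa: D103 - identity decorator fallback
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "DipResult",
    "NullDipDistribution",
    "EmpiricalPValue",
    "compute_dip",
    "simulate_null_dips",
    "get_null_distribution",
    "empirical_pvalue",
    "bh_adjust",
    "clear_null_cache",
]


@njit(cache=True)
def _gcm_interp(x, gv, P, p, j):
    """GCM value (in lower-corner index units) at data index j, lying in
    hull segment [gv[p], gv[p+1]] (index-wise)."""
    i0 = gv[p]
    if p + 1 >= P:
        return float(i0)
    i1 = gv[p + 1]
    if x[i1] > x[i0]:
        return i0 + (x[j] - x[i0]) * (i1 - i0) / (x[i1] - x[i0])
    return float(i0)


@njit(cache=True)
def _lcm_interp(x, lv, Q, q, j):
    """LCM value (in upper-corner index units) at data index j, lying in
    hull segment [lv[q], lv[q+1]] (index-wise)."""
    i0 = lv[q]
    if q + 1 >= Q:
        return float(i0 + 1)
    i1 = lv[q + 1]
    if x[i1] > x[i0]:
        return (i0 + 1) + (x[j] - x[i0]) * (i1 - i0) / (x[i1] - x[i0])
    return float(i1 + 1)


@njit(cache=True)
def _dip_sorted(x):
    """Dip of a sorted sample.  Returns (dip, lo, hi, degenerate)."""
    n = x.shape[0]
    if n == 1 or x[0] == x[n - 1]:
        return 0.5 / n, 0, n - 1, True

    low = 0
    high = n - 1
    best = 1.0  # accumulated tail deviation, units of 1/n; floor 1
    gv = np.empty(n, np.int64)  # GCM vertex indices, ascending
    lv = np.empty(n, np.int64)  # LCM vertex indices, ascending

    for _it in range(n + 2):
        if x[low] == x[high]:
            break  # modal region collapsed onto one value

        # GCM: lower convex hull of lower corners (x_i, i) on [low, high];
        # at tied x only the lowest corner can be a vertex
        P = 0
        for i in range(low, high + 1):
            if P > 0 and x[i] == x[gv[P - 1]]:
                continue
            while P >= 2 and (x[gv[P - 1]] - x[gv[P - 2]]) * (i - gv[P - 2]) - (
                gv[P - 1] - gv[P - 2]
            ) * (x[i] - x[gv[P - 2]]) <= 0.0:
                P -= 1
            gv[P] = i
            P += 1

        # LCM: upper concave hull of upper corners (x_i, i+1); at tied x
        # keep the highest corner
        Q = 0
        for i in range(low, high + 1):
            if Q > 0 and x[i] == x[lv[Q - 1]]:
                Q -= 1
            while Q >= 2 and (x[lv[Q - 1]] - x[lv[Q - 2]]) * (i - lv[Q - 2]) - (
                lv[Q - 1] - lv[Q - 2]
            ) * (x[i] - x[lv[Q - 2]]) >= 0.0:
                Q -= 1
            lv[Q] = i
            Q += 1

        # largest distance between the fitted curves, checked at vertices
        d = 1.0
        nl = low
        nh = high
        p = 0
        for q in range(Q):
            j = lv[q]
            while p + 1 < P and gv[p + 1] < j:
                p += 1
            dist = (j + 1) - _gcm_interp(x, gv, P, p, j)
            if dist > d:
                d = dist
                nl = gv[p]
                nh = j
        q = 0
        for p2 in range(P):
            j = gv[p2]
            while q + 1 < Q and lv[q + 1] < j:
                q += 1
            dist = _lcm_interp(x, lv, Q, q, j) - j
            if dist > d:
                d = dist
                nl = j
                nh = lv[q + 1] if q + 1 < Q else lv[q]

        if d <= best:
            break

        # deviations over the regions handed to the tails; the optimal CDF
        # follows the (vertically re-centred) hull fits there
        p = 0
        while p + 1 < P and gv[p + 1] <= nl:
            for jj in range(gv[p], gv[p + 1] + 1):
                dev = (jj + 1) - _gcm_interp(x, gv, P, p, jj)
                if dev > best:
                    best = dev
            p += 1
        q = Q - 1
        while q - 1 >= 0 and lv[q - 1] >= nh:
            for jj in range(lv[q - 1], lv[q] + 1):
                dev = _lcm_interp(x, lv, Q, q - 1, jj) - jj
                if dev > best:
                    best = dev
            q -= 1

        if nl == low and nh == high:
            break
        low = nl
        high = nh

    return best / (2.0 * n), low, high, False


@njit(cache=True)
def _dips_of_rows(rows):
    """Dip of every row of a (n_sims, n) matrix of *sorted* samples."""
    out = np.empty(rows.shape[0])
    for r in range(rows.shape[0]):
        d, _, _, _ = _dip_sorted(rows[r])
        out[r] = d
    return out


@dataclass(frozen=True)
class DipResult:
    """Dip statistic of one sample.

    ``modal_interval`` brackets the optimal mode placement with 0-based
    indices into the sorted sample; ``degenerate`` marks samples (n = 1 or
    all values tied) where the dip is pinned at its lower bound 1/(2n).
    """

    dip: float
    modal_interval: tuple[int, int]
    n: int
    degenerate: bool = False

    def __post_init__(self):
        lo, hi = self.modal_interval
        if not (0 <= lo <= hi <= self.n - 1):
            raise ValueError("modal_interval out of range")


def compute_dip(values) -> DipResult:
    """Hartigan's dip statistic of a sample.

    Parameters
    ----------
    values : array-like
        Sample values; sorted internally.  Must be finite and non-empty.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    xs = np.sort(x)
    dip, lo, hi, degen = _dip_sorted(xs)
    return DipResult(dip=float(dip), modal_interval=(int(lo), int(hi)), n=int(x.size), degenerate=bool(degen))


@dataclass(frozen=True)
class NullDipDistribution:
    """Monte-Carlo null distribution of the dip at sample size ``n``.

    ``dips`` holds one dip per simulated standard-normal sample.
    """

    n: int
    n_sims: int
    seed: int
    dips: np.ndarray = field(repr=False)

    def save(self, path) -> None:
        np.savez_compressed(path, n=self.n, n_sims=self.n_sims, seed=self.seed, dips=self.dips)

    @classmethod
    def load(cls, path) -> "NullDipDistribution":
        with np.load(path) as z:
            return cls(n=int(z["n"]), n_sims=int(z["n_sims"]), seed=int(z["seed"]), dips=z["dips"])


def simulate_null_dips(n: int, n_sims: int, seed: int) -> NullDipDistribution:
    """Simulate the null dip distribution for sample size ``n``.

    Draws ``n_sims`` independent standard-normal samples of size ``n`` and
    reduces each to its dip.  Reproducible for a fixed ``seed``.
    """
    if n < 2:
        raise ValueError(f"null simulation needs n >= 2, got n={n}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    dips = np.empty(n_sims)
    # chunked so memory stays bounded for large n_sims
    chunk = max(1, min(n_sims, 200_000 // max(n, 1)))
    done = 0
    while done < n_sims:
        k = min(chunk, n_sims - done)
        rows = np.sort(rng.standard_normal((k, n)), axis=1)
        dips[done : done + k] = _dips_of_rows(rows)
        done += k
    return NullDipDistribution(n=n, n_sims=n_sims, seed=seed, dips=dips)


_NULL_CACHE: dict[tuple[int, int, int], NullDipDistribution] = {}


def get_null_distribution(n: int, n_sims: int, seed: int) -> NullDipDistribution:
    """Cached :func:`simulate_null_dips`.

    One null serves every probe set of a dataset because all probes share the
    same sample count; re-simulating per probe would be wasteful.
    """
    key = (int(n), int(n_sims), int(seed))
    if key not in _NULL_CACHE:
        _NULL_CACHE[key] = simulate_null_dips(*key)
    return _NULL_CACHE[key]


def clear_null_cache() -> None:
    _NULL_CACHE.clear()


@dataclass(frozen=True)
class EmpiricalPValue:
    """Empirical p-value of an observed dip against a Monte-Carlo null."""

    observed_dip: float
    p: float
    n_sims: int
    count_greater: int

    def render(self) -> str:
        """Report-friendly rendering; a zero count reads '< 1/n_sims'."""
        if self.count_greater == 0:
            return f"< {1.0 / self.n_sims:.2e}"
        return f"{self.p:.3e}"


def empirical_pvalue(observed, null: NullDipDistribution) -> EmpiricalPValue:
    """Proportion of null dips strictly greater than the observed dip.

    ``observed`` may be a :class:`DipResult` (its sample size is checked
    against the null's) or a bare dip value.
    """
    if isinstance(observed, DipResult):
        if observed.n != null.n:
            raise ValueError(
                f"sample size mismatch: observed n={observed.n}, null n={null.n}"
            )
        dip = observed.dip
    else:
        dip = float(observed)
    count = int(np.sum(null.dips > dip))
    return EmpiricalPValue(
        observed_dip=float(dip),
        p=count / null.n_sims,
        n_sims=null.n_sims,
        count_greater=count,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sorts ascending, takes ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at
    1, and returns the adjusted values in the original order.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
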