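"""Shared nearest-neighbor machinery for the KSG-family estimators.

All estimators here work in the Chebyshev (max) norm. Neighbor searches
support a Theiler window: candidate neighbors within ``theiler`` samples in
time of the query point are excluded, both when determining the k-th
neighbor distance and when counting points inside that distance in marginal
subspaces. Counting is strict (< eps), the KSG convention; exact ties are
broken beforehand by a deterministic micro-jitter.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

__all__ = ["break_ties", "kth_distances", "count_within", "ksg_mi", "ksg_cmi"]

#: relative amplitude of the tie-breaking jitter (fraction of each
#: marginal's standard deviation)
JITTER_REL_AMP = 1e-10
#: fixed sub-seed of the jitter stream, so estimates are deterministic
DEFAULT_TIE_SEED = 0


def break_ties(
    arr: np.ndarray, tie_seed: int, rel_amp: float = JITTER_REL_AMP
) -> np.ndarray:
    """Add uniform micro-noise (amplitude ``rel_amp`` times the column SD) to
    each column so that exact value ties — under which kNN counts are
    ill-defined — occur with probability zero.

    The jitter stream of each column is seeded from ``tie_seed`` and a CRC of
    the column's bytes, so the noise is a deterministic function of the data:
    repeated calls give identical output and estimators built on it are
    invariant to argument order (``mi(x, y) == mi(y, x)`` exactly).
    """
    import zlib

    arr = np.atleast_2d(np.asarray(arr, dtype=float).T).T
    out = arr.copy()
    for j in range(arr.shape[1]):
        col = np.ascontiguousarray(arr[:, j])
        sd = col.std()
        amp = rel_amp * (sd if sd > 0 else 1.0)
        rng = np.random.default_rng([tie_seed, zlib.crc32(col.tobytes())])
        out[:, j] = col + rng.uniform(-amp, amp, size=col.size)
    return out


def kth_distances(joint: np.ndarray, k: int, theiler: int = 0) -> np.ndarray:
    """Chebyshev distance from each point to its k-th nearest neighbor,
    excluding the point itself and any point within ``theiler`` in time."""
    n = joint.shape[0]
    n_excluded = 1 + 2 * theiler
    if n <= k + n_excluded:
        raise ValueError(
            f"need more than k + 2*theiler + 1 = {k + n_excluded} points "
            f"for a k={k} neighbor search with theiler={theiler}, got {n}"
        )
    tree = cKDTree(joint)
    k_query = min(k + n_excluded, n)
    dist, idx = tree.query(joint, k=k_query, p=np.inf)
    rows = np.arange(n)[:, None]
    valid = np.abs(idx - rows) > theiler
    ranks = np.cumsum(valid, axis=1)
    hit = ranks == k
    if not np.all(hit.any(axis=1)):
        raise RuntimeError("neighbor query exhausted before k valid neighbors")
    pos = np.argmax(hit, axis=1)
    return dist[np.arange(n), pos]


def _theiler_correction(
    pts: np.ndarray, eps: np.ndarray, theiler: int
) -> np.ndarray:
    """Number of temporal neighbors (0 < |i-j| <= theiler) of each point that
    fall strictly inside its eps ball; subtracted from naive ball counts."""
    n = pts.shape[0]
    corr = np.zeros(n, dtype=np.int64)
    for off in range(1, theiler + 1):
        if off >= n:
            break
        d = np.max(np.abs(pts[off:] - pts[:-off]), axis=1)
        inside = d < eps[:-off]  # j = i + off inside ball of i
        corr[:-off] += inside
        inside_rev = d < eps[off:]  # j = i - off inside ball of i
        corr[off:] += inside_rev
    return corr


def count_within(pts: np.ndarray, eps: np.ndarray, theiler: int = 0) -> np.ndarray:
    """Count, for each point, the other points strictly within its Chebyshev
    ball of radius ``eps[i]``, excluding self and the Theiler window."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float).T).T
    n, dim = pts.shape
    if dim == 1:
        v = pts[:, 0]
        order = np.argsort(v, kind="mergesort")
        vs = v[order]
        hi = np.searchsorted(vs, v + eps, side="left")
        lo = np.searchsorted(vs, v - eps, side="right")
        counts = (hi - lo - 1).astype(np.int64)  # -1 removes self
    else:
        tree = cKDTree(pts)
        r = np.nextafter(eps, 0.0)  # strict inequality
        counts = tree.query_ball_point(pts, r, p=np.inf, return_length=True)
        counts = np.asarray(counts, dtype=np.int64) - 1
    if theiler > 0:
        counts -= _theiler_correction(pts, eps, theiler)
    return counts


def ksg_mi(
    x: np.ndarray, y: np.ndarray, k: int = 4, theiler: int = 0,
    tie_seed: int = DEFAULT_TIE_SEED,
) -> float:
    """KSG (algorithm 1) mutual information estimate in nats.

    ``x`` and ``y`` may be 1-D samples or 2-D state matrices with one row
    per time point.
    """
    x = break_ties(x, tie_seed)
    y = break_ties(y, tie_seed)
    n = x.shape[0]
    joint = np.hstack([x, y])
    eps = kth_distances(joint, k, theiler)
    n_x = count_within(x, eps, theiler)
    n_y = count_within(y, eps, theiler)
    return float(
        digamma(k) + digamma(n)
        - np.mean(digamma(n_x + 1) + digamma(n_y + 1))
    )


def ksg_cmi(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, k: int = 4,
    theiler: int = 0, tie_seed: int = DEFAULT_TIE_SEED,
) -> float:
    """Nearest-neighbor conditional mutual information I(a; b | c) in nats.

    Digamma-form estimator over neighbor counts projected into the (a,c),
    (b,c) and (c) subspaces of the joint (a,b,c) space — the conditional
    analogue of the KSG estimator used for transfer entropy.
    """
    a = break_ties(a, tie_seed)
    b = break_ties(b, tie_seed)
    c = break_ties(c, tie_seed)
    joint = np.hstack([a, b, c])
    eps = kth_distances(joint, k, theiler)
    n_ac = count_within(np.hstack([a, c]), eps, theiler)
    n_bc = count_within(np.hstack([b, c]), eps, theiler)
    n_c = count_within(c, eps, theiler)
    return float(
        digamma(k)
        - np.mean(digamma(n_ac + 1) + digamma(n_bc + 1) - digamma(n_c + 1))
    )
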