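"""Independent reference implementations used only as test oracles.

Each oracle follows the published definition of its quantity through a
different algorithm than the package implementation: dense Riemann
sampling instead of closed-form trapezoids for the SPIKE-distance,
candidate enumeration instead of a linear scan for bursts, exhaustive
partition search instead of greedy optimization for modularity, and
Monte-Carlo sampling instead of polygon unions for swept areas.
"""

from __future__ import annotations

import bisect

import numpy as np


# ---------------------------------------------------------------------------
# SPIKE-distance oracles


def _aug(times, T):
    return np.unique(np.concatenate(([0.0], np.asarray(times, float), [T])))


def _nearest(v, other):
    i = np.searchsorted(other, v)
    lo = other[np.clip(i - 1, 0, other.size - 1)]
    hi = other[np.clip(i, 0, other.size - 1)]
    return np.minimum(np.abs(v - lo), np.abs(v - hi))


def riemann_spike_distance(x1, x2, T, n_points: int = 100_000) -> float:
    """Dense Riemann-sum integration of the dissimilarity profile S(t).

    Sample points are allocated across the pooled inter-spike segments in
    proportion to segment length and S is evaluated at sub-interval
    midpoints, i.e. a plain midpoint Riemann sum per segment.
    """
    a1, a2 = _aug(x1, T), _aug(x2, T)
    pool = np.union1d(a1, a2)
    total = 0.0
    for a, b in zip(pool[:-1], pool[1:]):
        seg = b - a
        n_k = max(1, int(round(n_points * seg / T)))
        t = a + (np.arange(n_k) + 0.5) * (seg / n_k)

        def side(tr, other):
            i = np.searchsorted(tr, a, side="right") - 1
            tP, tF = tr[i], tr[i + 1]
            dP = _nearest(np.array([tP]), other)[0]
            dF = _nearest(np.array([tF]), other)[0]
            xisi = tF - tP
            return (dP * (tF - t) + dF * (t - tP)) / xisi, xisi

        s1, xisi1 = side(a1, a2)
        s2, xisi2 = side(a2, a1)
        S = (s1 * xisi2 + s2 * xisi1) / (2.0 * (0.5 * (xisi1 + xisi2)) ** 2)
        total += S.sum() * (seg / n_k)
    return total / T


def reference_spike_distance(x1, x2, T) -> float:
    """Scalar plain-Python implementation of the same metric.

    Uses bisect-based neighbour lookups and midpoint evaluation per
    pooled segment (the profile is linear there, so the midpoint value
    times the width integrates it exactly).
    """
    t1 = sorted({0.0, float(T), *map(float, x1)})
    t2 = sorted({0.0, float(T), *map(float, x2)})
    pool = sorted(set(t1) | set(t2))

    def nearest(v, tr):
        i = bisect.bisect_left(tr, v)
        cands = []
        if i > 0:
            cands.append(abs(v - tr[i - 1]))
        if i < len(tr):
            cands.append(abs(v - tr[i]))
        return min(cands)

    total = 0.0
    for a, b in zip(pool[:-1], pool[1:]):
        mid = 0.5 * (a + b)

        def s_side(tr, other):
            i = bisect.bisect_right(tr, a) - 1
            tP, tF = tr[i], tr[i + 1]
            dP, dF = nearest(tP, other), nearest(tF, other)
            xisi = tF - tP
            return (dP * (tF - mid) + dF * (mid - tP)) / xisi, xisi

        s1, xisi1 = s_side(t1, t2)
        s2, xisi2 = s_side(t2, t1)
        mean_isi = 0.5 * (xisi1 + xisi2)
        S_mid = (s1 * xisi2 + s2 * xisi1) / (2.0 * mean_isi * mean_isi)
        total += S_mid * (b - a)
    return total / T


# ---------------------------------------------------------------------------
# Burst-detection oracle


def brute_force_bursts(times, max_isi_start, max_isi_in, min_duration,
                       min_ibi, min_spikes):
    """Burst detection by exhaustive candidate-run enumeration.

    All time parameters in seconds.  Enumerates every contiguous spike
    run whose opening ISI is within ``max_isi_start`` and whose later
    ISIs are within ``max_isi_in``; repeatedly selects the leftmost
    (longest) candidate and discards overlapping ones; merges selections
    separated by less than ``min_ibi``; applies the duration and spike
    count minima.  Returns (start, end, n_spikes) tuples.
    """
    t = list(map(float, times))
    n = len(t)
    candidates = []
    for i in range(n - 1):
        if t[i + 1] - t[i] <= max_isi_start:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= max_isi_in:
                j += 1
            for jj in range(i + 1, j + 1):
                candidates.append((i, jj))
    selected = []
    while candidates:
        best = min(candidates, key=lambda r: (r[0], -r[1]))
        selected.append(best)
        candidates = [r for r in candidates if r[0] > best[1]]
    merged = []
    for a, b in sorted(selected):
        if merged and t[a] - t[merged[-1][1]] < min_ibi:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        if t[b] - t[a] >= min_duration and (b - a + 1) >= min_spikes:
            out.append((t[a], t[b], b - a + 1))
    return out


# ---------------------------------------------------------------------------
# Modularity oracle


def set_partitions(items):
    """All partitions of a list (Bell(n) of them; 4140 for n = 8)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield [[first]] + part


def modularity_matrix(W, partition) -> float:
    """Q of a partition from the weighted adjacency matrix directly."""
    W = np.asarray(W, dtype=float)
    m2 = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for block in partition:
        b = np.asarray(block, dtype=int)
        q += W[np.ix_(b, b)].sum() - (k[b].sum() ** 2) / m2
    return q / m2


def max_modularity_exhaustive(W):
    """Exhaustive-search modularity optimum over all node partitions."""
    n = np.asarray(W).shape[0]
    best_q, best_p = -np.inf, None
    for part in set_partitions(range(n)):
        q = modularity_matrix(W, part)
        if q > best_q:
            best_q, best_p = q, [sorted(b) for b in part]
    return best_q, best_p


# ---------------------------------------------------------------------------
# Swept-area oracle


def monte_carlo_swept_area(trajectories, tip_radius, n_points=200_000,
                           seed=0) -> float:
    """Monte-Carlo estimate of the union area of dilated trajectories."""
    segs = []
    for traj in trajectories:
        pts = np.atleast_2d(np.asarray(traj, dtype=float))
        if pts.shape[0] == 1:
            segs.append((pts[0], pts[0]))
        else:
            for a, b in zip(pts[:-1], pts[1:]):
                segs.append((a, b))
    allpts = np.vstack([np.vstack(s) for s in segs])
    lo = allpts.min(axis=0) - tip_radius
    hi = allpts.max(axis=0) + tip_radius
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    inside = np.zeros(n_points, dtype=bool)
    for a, b in segs:
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = ((pts - a) ** 2).sum(axis=1)
        else:
            s = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + s[:, None] * ab
            d2 = ((pts - proj) ** 2).sum(axis=1)
        inside |= d2 <= tip_radius**2
    box_area = np.prod(hi - lo)
    return float(inside.mean() * box_area)
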