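"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: plain Python loops,
no spatial indexing, direct textbook formulas.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# first-order features from a flat list of values
# ---------------------------------------------------------------------------


def brute_force_features(values, voxel_volume_mm3: float, n_bins: int = 64) -> dict:
    values = [float(v) for v in values]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sorted_vals = sorted(values)
    if n % 2 == 1:
        median = sorted_vals[n // 2]
    else:
        median = 0.5 * (sorted_vals[n // 2 - 1] + sorted_vals[n // 2])
    mtv = n * voxel_volume_mm3 / 1000.0

    lo, hi = min(values), max(values)
    counts = [0] * n_bins
    if lo == hi:
        counts[0] = n
        centers = [lo] * n_bins
    else:
        width = (hi - lo) / n_bins
        for v in values:
            idx = int((v - lo) // width)
            if idx >= n_bins:
                idx = n_bins - 1
            counts[idx] += 1
        centers = [lo + (i + 0.5) * width for i in range(n_bins)]
    p = [c / n for c in counts]

    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    uniformity = sum(pi * pi for pi in p)
    mu = sum(pi * c for pi, c in zip(p, centers))
    m2 = sum(pi * (c - mu) ** 2 for pi, c in zip(p, centers))
    if m2 == 0:
        skew, kurt = 0.0, 0.0
    else:
        m3 = sum(pi * (c - mu) ** 3 for pi, c in zip(p, centers))
        m4 = sum(pi * (c - mu) ** 4 for pi, c in zip(p, centers))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    return {
        "max_suv": max(values),
        "mean_suv": mean,
        "median_suv": median,
        "mtv_cm3": mtv,
        "tlg_g": mtv * mean,
        "cov_suv": math.sqrt(var) / mean,
        "kurtosis": kurt,
        "skewness": skew,
        "entropy_bits": entropy,
        "uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# Kruskal-Wallis H by the rank formula (no ties assumed by callers)
# ---------------------------------------------------------------------------


def brute_force_kruskal_h(groups) -> float:
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    order = sorted(range(n_total), key=lambda i: pooled[i])
    ranks = [0.0] * n_total
    for r, i in enumerate(order):
        ranks[i] = r + 1.0
    h = 0.0
    start = 0
    for g in groups:
        gr = ranks[start : start + len(g)]
        h += len(g) * (sum(gr) / len(g)) ** 2
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)


def brute_force_dunn_z(groups, i, j) -> float:
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    sorted_vals = sorted(pooled)
    # mid-ranks with ties
    def rank_of(v):
        lo = sum(1 for x in sorted_vals if x < v)
        eq = sum(1 for x in sorted_vals if x == v)
        return lo + (eq + 1) / 2.0

    mean_ranks = [sum(rank_of(v) for v in g) / len(g) for g in groups]
    tie = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie += t**3 - t
    var = (n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))) * (
        1.0 / len(groups[i]) + 1.0 / len(groups[j])
    )
    return (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Youden cutoff by O(n^2) confusion-matrix enumeration
# ---------------------------------------------------------------------------


def brute_force_youden(x, y):
    """(cutoff, J) maximizing |sens+spec-1| over both directions, lowest cutoff wins."""
    uniq = sorted(set(float(v) for v in x))
    best_cut, best_j = None, -2.0
    for a, b in zip(uniq[:-1], uniq[1:]):
        m = (a + b) / 2.0
        tp = fn = fp = tn = 0
        for xi, yi in zip(x, y):
            if yi == 1:
                if xi > m:
                    tp += 1
                else:
                    fn += 1
            else:
                if xi > m:
                    fp += 1
                else:
                    tn += 1
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        for jj in (j, -j):
            if jj > best_j + 1e-15:
                best_j, best_cut = jj, m
    return best_cut, best_j


# ---------------------------------------------------------------------------
# Cox partial likelihood for untied data, expanded literally
# ---------------------------------------------------------------------------


def cox_partial_loglik(beta, times, events, x) -> float:
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


# ---------------------------------------------------------------------------
# adaptive-threshold delineation without spatial indexing (BFS flood fill)
# ---------------------------------------------------------------------------


def _neighbors26(idx, shape):
    x, y, z = idx
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    yield nx, ny, nz


def _flood_fill(above, start):
    if not above[start]:
        return set()
    seen = {start}
    frontier = [start]
    while frontier:
        cur = frontier.pop()
        for nb in _neighbors26(cur, above.shape):
            if above[nb] and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return seen


def brute_force_delineate(
    values,
    spacing,
    seed_idx,
    core_fraction=0.70,
    weight=0.30,
    shell_inner=8.0,
    shell_outer=16.0,
    max_iter=20,
    local_max_radius=12.0,
):
    """Reference fixed-point delineation: flood fill + explicit distance loops."""
    values = np.asarray(values, dtype=float)
    shape = values.shape

    # local maximum near the seed
    best, anchor = -1.0, seed_idx
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if all(
                    abs(a - b) * s <= local_max_radius + 1e-9
                    for a, b, s in ((i, seed_idx[0], spacing[0]),
                                    (j, seed_idx[1], spacing[1]),
                                    (k, seed_idx[2], spacing[2]))
                ) and values[i, j, k] > best:
                    best, anchor = values[i, j, k], (i, j, k)

    mask = _flood_fill(values > 0.5 * best, anchor)
    threshold = 0.5 * best
    for _ in range(max_iter):
        coords = [np.array(c, dtype=float) * s for c, s in
                  zip(zip(*sorted(mask)), spacing)]
        mask_pts = np.stack(coords, axis=1)
        bg_vals = []
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if (i, j, k) in mask:
                        continue
                    p = np.array([i * spacing[0], j * spacing[1], k * spacing[2]])
                    d = np.sqrt(((mask_pts - p) ** 2).sum(axis=1)).min()
                    if shell_inner <= d <= shell_outer:
                        bg_vals.append(values[i, j, k])
        bg = float(np.mean(bg_vals))
        tumor_vals = [values[idx] for idx in mask]
        mx = max(tumor_vals)
        core = [v for v in tumor_vals if v > core_fraction * mx]
        threshold = weight * (sum(core) / len(core)) + bg
        hot = max(mask, key=lambda idx: values[idx])
        new_mask = _flood_fill(values > threshold, hot)
        if new_mask == mask:
            break
        mask = new_mask
    return mask, threshold
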