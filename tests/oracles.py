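"""Independent brute-force oracles used to validate the vectorized implementations.

Everything here is written as naive enumeration (explicit Python loops over
voxels, pairs, runs and zones) and deliberately shares no code with the
package internals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

DIRECTIONS_13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]

NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= v[ax] < shape[ax] for ax in range(3))


def brute_glcm(levels, mask, ng, offset):
    """Symmetric co-occurrence counts for one direction by pair enumeration."""
    mat = np.zeros((ng, ng), dtype=np.int64)
    for v in zip(*np.where(mask)):
        w = tuple(v[ax] + offset[ax] for ax in range(3))
        if _inside(mask.shape, w) and mask[w]:
            mat[levels[v] - 1, levels[w] - 1] += 1
            mat[levels[w] - 1, levels[v] - 1] += 1
    return mat


def brute_glrlm(levels, mask, ng, offset):
    """Run-length counts for one direction by walking every line."""
    max_len = max(mask.shape)
    mat = np.zeros((ng, max_len), dtype=np.int64)
    neg = tuple(-o for o in offset)
    for v in zip(*np.where(mask)):
        prev = tuple(v[ax] + neg[ax] for ax in range(3))
        # only start counting at the first voxel of a run
        if _inside(mask.shape, prev) and mask[prev] and levels[prev] == levels[v]:
            continue
        length = 1
        w = tuple(v[ax] + offset[ax] for ax in range(3))
        while _inside(mask.shape, w) and mask[w] and levels[w] == levels[v]:
            length += 1
            w = tuple(w[ax] + offset[ax] for ax in range(3))
        mat[levels[v] - 1, length - 1] += 1
    return mat[:, : max(1, int(np.max(np.where(mat.any(axis=0))[0], initial=0)) + 1)]


def brute_glszm(levels, mask, ng):
    """Size-zone counts via flood fill over 26-connected same-level zones."""
    visited = np.zeros(mask.shape, dtype=bool)
    sizes = []
    for v in zip(*np.where(mask)):
        if visited[v]:
            continue
        g = levels[v]
        stack = [v]
        visited[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = tuple(u[ax] + d[ax] for ax in range(3))
                if (
                    _inside(mask.shape, w)
                    and mask[w]
                    and not visited[w]
                    and levels[w] == g
                ):
                    visited[w] = True
                    stack.append(w)
        sizes.append((g, size))
    max_size = max(s for _, s in sizes)
    mat = np.zeros((ng, max_size), dtype=np.int64)
    for g, size in sizes:
        mat[g - 1, size - 1] += 1
    return mat


def brute_gldm(levels, mask, ng, alpha=0):
    """Dependence counts: 1 + number of 26-neighbors within |level diff| <= alpha."""
    deps = []
    for v in zip(*np.where(mask)):
        d = 1
        for off in NEIGHBORS_26:
            w = tuple(v[ax] + off[ax] for ax in range(3))
            if _inside(mask.shape, w) and mask[w] and abs(int(levels[w]) - int(levels[v])) <= alpha:
                d += 1
        deps.append((levels[v], d))
    nd = max(d for _, d in deps)
    mat = np.zeros((ng, nd), dtype=np.int64)
    for g, d in deps:
        mat[g - 1, d - 1] += 1
    return mat


def brute_ngtdm(levels, mask, ng):
    """Per-level counts n_i and summed |i - mean neighbor level| s_i."""
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng)
    for v in zip(*np.where(mask)):
        neigh = []
        for off in NEIGHBORS_26:
            w = tuple(v[ax] + off[ax] for ax in range(3))
            if _inside(mask.shape, w) and mask[w]:
                neigh.append(int(levels[w]))
        if not neigh:
            continue
        g = int(levels[v])
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(neigh) / len(neigh))
    return n, s


# --------------------------------------------------------------------------- ICC
def brute_icc_a1_ci(m, alpha=0.05):
    """McGraw & Wong exact F interval for ICC(A,1), transcribed independently.

    Mean squares come from explicit double loops over cells (no shared code
    with the package ANOVA).
    """
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ssr = ssc = sse = 0.0
    row = [m[i].sum() / k for i in range(n)]
    col = [m[:, j].sum() / n for j in range(k)]
    for i in range(n):
        ssr += k * (row[i] - grand) ** 2
    for j in range(k):
        ssc += n * (col[j] - grand) ** 2
    for i in range(n):
        for j in range(k):
            sse += (m[i, j] - row[i] - col[j] + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    a = (k * icc) / (n * (1 - icc))
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return icc, lower, upper, msr, msc, mse


# -------------------------------------------------------------------------- Ward
def brute_ward(points):
    """Agglomerative Ward clustering with explicit variance bookkeeping.

    Merge cost is the increase in total within-cluster sum of squared
    Euclidean distances to centroids; returns the merge heights (scipy
    convention: sqrt(2 * cost)) and the final two-cluster assignment.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    heights = []
    merges = []
    next_id = n

    def sse(members):
        pts = points[members]
        c = pts.mean(axis=0)
        return float(((pts - c) ** 2).sum())

    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                cost = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        cost, a, b = best
        heights.append(np.sqrt(2.0 * cost))
        merges.append((a, b, next_id))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    # reconstruct the 2-cluster cut: undo the last merge
    rebuild = {i: [i] for i in range(n)}
    for a, b, new in merges[:-1]:
        rebuild[new] = rebuild.pop(a) + rebuild.pop(b)
    assign = np.zeros(n, dtype=int)
    for cluster_idx, cid in enumerate(sorted(rebuild)):
        for m in rebuild[cid]:
            assign[m] = cluster_idx
    return np.array(heights), assign
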