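"""Independent brute-force oracles used by the feature and acceptance tests.

Everything here is deliberately naive (explicit voxel/pair enumeration,
breadth-first search) and shares no code with the implementation it checks.
"""

from itertools import combinations

import numpy as np


def surface_faces(mask):
    """Count exposed 6-neighbour faces by explicit per-voxel enumeration."""
    count = 0
    shape = mask.shape
    for i, j, k in np.argwhere(mask):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                count += 1
            elif not mask[ni, nj, nk]:
                count += 1
    return count


def components_26(mask):
    """26-connected components by breadth-first search."""
    seen = np.zeros(mask.shape, bool)
    comps = []
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[a] < mask.shape[a] for a in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(np.array(comp))
    return comps


def dmax_cm(mask, spacing):
    comps = components_26(mask)
    if len(comps) < 2:
        return 0.0
    cents = [c.mean(axis=0) * np.asarray(spacing) for c in comps]
    best = 0.0
    for i in range(len(cents)):
        for j in range(i + 1, len(cents)):
            best = max(best, float(np.sqrt(((cents[i] - cents[j]) ** 2).sum())))
    return best / 10.0


def exact_rank_sum_p(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        g1, g2 = pooled[sel], pooled[~sel]
        us.append(sum(1 for a in g1 for b in g2 if a > b))
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))
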