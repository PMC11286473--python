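"""Independent brute-force oracles for texture matrices and AUC.

These deliberately use naive voxel-by-voxel enumeration (pair listing,
run scanning, BFS flood fill, neighbourhood tallies) so they share no
code with the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np


def _in(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def bf_glcm(levels, mask, offset, n_levels):
    """Symmetric co-occurrence counts for one offset, by pair listing."""
    out = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for v in np.argwhere(mask):
        w = tuple(v + np.array(offset))
        if _in(shape, w) and mask[w]:
            a, b = levels[tuple(v)] - 1, levels[w] - 1
            out[a, b] += 1
            out[b, a] += 1
    return out


def bf_glrlm(levels, mask, direction, n_levels, max_len):
    """Run-length counts for one direction, by scanning from run starts."""
    out = np.zeros((n_levels, max_len), dtype=np.int64)
    shape = levels.shape
    d = np.array(direction)
    for v in np.argwhere(mask):
        prev = tuple(v - d)
        if _in(shape, prev) and mask[prev] and levels[prev] == levels[tuple(v)]:
            continue  # not a run start
        length = 1
        w = v + d
        while _in(shape, tuple(w)) and mask[tuple(w)] and levels[tuple(w)] == levels[tuple(v)]:
            length += 1
            w = w + d
        out[levels[tuple(v)] - 1, length - 1] += 1
    return out


def _neighbours26(v, shape):
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                w = (v[0] + dx, v[1] + dy, v[2] + dz)
                if _in(shape, w):
                    yield w


def bf_glszm(levels, mask, n_levels):
    """Zone sizes by BFS flood fill with 26-connectivity, per level."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in map(tuple, np.argwhere(mask)):
        if seen[v]:
            continue
        level = levels[v]
        stack, size = [v], 0
        seen[v] = True
        while stack:
            u = stack.pop()
            size += 1
            for w in _neighbours26(u, shape):
                if mask[w] and not seen[w] and levels[w] == level:
                    seen[w] = True
                    stack.append(w)
        zones.append((level, size))
    max_size = max(s for _, s in zones)
    out = np.zeros((n_levels, max_size), dtype=np.int64)
    for level, size in zones:
        out[level - 1, size - 1] += 1
    return out


def bf_gldm(levels, mask, n_levels, alpha=0):
    """Dependence counts: per voxel, matching 26-neighbours within alpha."""
    shape = levels.shape
    deps = []
    for v in map(tuple, np.argwhere(mask)):
        d = sum(
            1 for w in _neighbours26(v, shape)
            if mask[w] and abs(int(levels[w]) - int(levels[v])) <= alpha
        )
        deps.append((levels[v], d))
    max_dep = max(d for _, d in deps) + 1
    out = np.zeros((n_levels, max_dep), dtype=np.int64)
    for level, d in deps:
        out[level - 1, d] += 1
    return out


def bf_ngtdm(levels, mask, n_levels):
    """Per-level counts n_i and summed |level - neighbourhood mean| s_i."""
    shape = levels.shape
    n_i = np.zeros(n_levels, dtype=float)
    s_i = np.zeros(n_levels, dtype=float)
    for v in map(tuple, np.argwhere(mask)):
        nb = [levels[w] for w in _neighbours26(v, shape) if mask[w]]
        if not nb:
            continue
        n_i[levels[v] - 1] += 1
        s_i[levels[v] - 1] += abs(levels[v] - float(np.mean(nb)))
    return np.stack([n_i, s_i])


def bf_auc(y_true, scores, positive=1):
    """All-pairs comparison AUC, ties counted half."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == positive]
    neg = s[y != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_discretized(rng, shape, n_levels=3):
    """A random small levels/mask pair with a non-empty mask."""
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    levels[~mask] = 0
    return levels, mask
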