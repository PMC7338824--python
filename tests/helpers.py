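"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: pair counting by explicit
loops, exact null distributions by full enumeration, Spearman via ranks +
Pearson.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def glcm_features_bruteforce(patch, offsets, n_levels, symmetric=True):
    """Haralick 4-vector of a level patch by explicit pair enumeration.

    patch: 2D or 3D int array, 0 = invalid voxel.  Returns None when no
    offset yields a valid pair.
    """
    patch = np.asarray(patch)
    if patch.ndim == 2:
        patch = patch[:, :, None]
    offsets3 = [tuple(o) + (0,) * (3 - len(o)) for o in offsets]
    feats = []
    for off in offsets3:
        counts = {}
        nx, ny, nz = patch.shape
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    x2, y2, z2 = x + off[0], y + off[1], z + off[2]
                    if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                        continue
                    i, j = patch[x, y, z], patch[x2, y2, z2]
                    if i == 0 or j == 0:
                        continue
                    counts[(i, j)] = counts.get((i, j), 0) + 1
                    if symmetric:
                        counts[(j, i)] = counts.get((j, i), 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        energy = entropy = contrast = homog = 0.0
        for (i, j), c in counts.items():
            p = c / total
            energy += p * p
            entropy -= p * math.log2(p)
            contrast += (i - j) ** 2 * p
            homog += p / (1 + abs(i - j))
        feats.append((energy, entropy, contrast, homog))
    if not feats:
        return None
    return tuple(np.mean(feats, axis=0))


def mannwhitney_u(x, y):
    """U counting x>y pairs with ties 0.5, by explicit loops."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def mannwhitney_exact_p(x, y):
    """Exact two-sided MW p by enumerating all C(n1+n2, n1) group assignments.

    Two-sided as the doubled smaller tail (capped at 1), matching the exact
    null convention for the symmetric untied case.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mannwhitney_u(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(mannwhitney_u(g1, g2))
    us = np.array(us)
    eps = 1e-9
    lo = np.mean(us <= u_obs + eps)
    hi = np.mean(us >= u_obs - eps)
    return min(1.0, 2.0 * min(lo, hi))


def kendall_s_bruteforce(x, y):
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return s


def kendall_exact_p(x, y):
    """Exact two-sided Kendall p by enumerating all n! rank permutations."""
    n = len(x)
    s_obs = abs(kendall_s_bruteforce(x, y))
    hits = total = 0
    base = list(range(n))
    for perm in itertools.permutations(base):
        s = abs(kendall_s_bruteforce(base, perm))
        hits += s >= s_obs
        total += 1
    return hits / total


def spearman_bruteforce(x, y):
    """Spearman rho as Pearson correlation of average ranks."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def wcss(X, labels):
    """Within-cluster sum of squares (Lloyd's objective) for given labels."""
    X = np.asarray(X, dtype=float)
    total = 0.0
    for k in np.unique(labels):
        pts = X[labels == k]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def permutation_with_inversions(n, k):
    """A permutation of 0..n-1 with exactly k inversions (untied Kendall fixture)."""
    p, items = [], list(range(n))
    for i in range(n, 0, -1):
        maxrest = (i - 1) * (i - 2) // 2
        take = min(i - 1, max(0, k - maxrest))
        p.append(items.pop(take))
        k -= take
    assert k == 0
    return p
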