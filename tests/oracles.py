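"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths they check: surfaces are
found by explicit neighbour enumeration, distances by all-pairs scans, and
p-values by exhaustive enumeration of rank or sign assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def surface_pixels_bruteforce(mask2d: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels with a 4-connected background neighbour or on the border."""
    m = np.asarray(mask2d).astype(bool)
    H, W = m.shape
    out = []
    for r in range(H):
        for c in range(W):
            if not m[r, c]:
                continue
            if r == 0 or r == H - 1 or c == 0 or c == W - 1:
                out.append((r, c))
                continue
            if not (m[r - 1, c] and m[r + 1, c] and m[r, c - 1] and m[r, c + 1]):
                out.append((r, c))
    return out


def _directed(src, dst) -> list[float]:
    return [min(math.dist(a, b) for b in dst) for a in src]


def msd_hd95_bruteforce(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """All-pairs slice-wise MSD and HD95 with the centre-pixel convention."""
    H, W, D = a.shape
    center = [(H // 2, W // 2)]
    total, count, hd_vals = 0.0, 0, []
    for s in range(D):
        sa = surface_pixels_bruteforce(a[:, :, s])
        sb = surface_pixels_bruteforce(b[:, :, s])
        if not sa and not sb:
            continue
        sa = sa or center
        sb = sb or center
        fwd = _directed(sa, sb)
        bwd = _directed(sb, sa)
        total += sum(fwd) + sum(bwd)
        count += len(sa) + len(sb)
        hd_vals.append(max(np.percentile(fwd, 95), np.percentile(bwd, 95)))
    if count == 0:
        raise ValueError("both masks empty")
    return total / count, float(np.mean(hd_vals))


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = x + y
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}  # no ties expected

    def u_stat(group):
        rsum = sum(ranks[v] for v in group)
        return rsum - len(group) * (len(group) + 1) / 2

    u_obs = u_stat(x)
    mean_u = nx * ny / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        u = u_stat([pooled[i] for i in combo])
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2**n
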