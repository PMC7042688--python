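"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force grid
search on the simplex for the optimizer, and the pairwise-distance
within-group sums-of-squares formulation (with full label enumeration) for
the permutation MANOVA.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def simplex_grid(k: int, resolution: float) -> np.ndarray:
    """All simplex points with coordinates on a grid of the given step."""
    steps = round(1.0 / resolution)
    if k == 2:
        a = np.arange(steps + 1) / steps
        return np.column_stack([a, 1.0 - a])
    if k == 3:
        pts = []
        for i in range(steps + 1):
            for j in range(steps + 1 - i):
                pts.append((i / steps, j / steps, (steps - i - j) / steps))
        return np.array(pts)
    raise ValueError("grid oracle supports 2 or 3 species only")


def grid_search_optimum(y: np.ndarray, means: np.ndarray, resolution: float) -> tuple[float, np.ndarray]:
    """Best symmetrized-KL distance over the alpha grid, computed from scratch."""
    grid = simplex_grid(means.shape[0], resolution)
    mix = grid @ means
    mix = mix / mix.sum(axis=1, keepdims=True)
    mix = np.clip(mix, 1e-300, None)
    d = ((y[None, :] - mix) * (np.log(y)[None, :] - np.log(mix))).sum(axis=1)
    i = int(np.argmin(d))
    return float(d[i]), grid[i]


def anderson_one_way_F(d2: np.ndarray, labels) -> float:
    """Pseudo-F for a one-way design from pairwise squared distances.

    Uses the within-group sum-of-squares identity
    ``SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij^2`` — no Gower centering,
    no projection matrices.
    """
    labels = list(labels)
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ss_tot = d2[iu].sum() / n
    ss_w = 0.0
    groups = sorted(set(labels))
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_b = ss_tot - ss_w
    a = len(groups)
    if ss_w <= 0:
        return 0.0 if ss_b <= 0 else math.inf
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def exact_one_way_p(D: np.ndarray, labels) -> tuple[float, float]:
    """(F_obs, exact p) by enumerating every permutation of the labels.

    p includes the identity permutation in both numerator and denominator.
    """
    d2 = np.asarray(D, dtype=float) ** 2
    labels = list(labels)
    n = len(labels)
    F_obs = anderson_one_way_F(d2, labels)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if anderson_one_way_F(d2, [labels[i] for i in perm]) >= F_obs - 1e-12:
            count += 1
    return F_obs, count / total


def holm_by_hand(p) -> np.ndarray:
    """Literal step-down Holm, written as the textbook loop."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj
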