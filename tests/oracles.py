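"""Independent reference implementations used only to check the package.

Each function here re-derives a quantity by the most transparent route
available (direct formula evaluation, brute-force enumeration, explicit
pairwise counting) and deliberately shares no code with the implementation
it validates.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def tajima_d_direct(rows: list[str]) -> float | None:
    """Tajima's D by direct evaluation of the 1989 constants and formula.

    Columns containing '-' or 'N' are dropped entirely. Returns None when
    undefined (S = 0).
    """
    n = len(rows)
    L = len(rows[0])
    cols = [
        j for j in range(L) if all(r[j] not in "-N" for r in rows)
    ]
    S = sum(1 for j in cols if len({r[j] for r in rows}) > 1)
    if S == 0:
        return None
    # mean pairwise differences, summed over sites (k-hat)
    k_total = 0.0
    for a, b in combinations(rows, 2):
        k_total += sum(1 for j in cols if a[j] != b[j])
    k_hat = k_total / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def pairwise_pi_direct(rows: list[str]) -> float:
    """pi by explicit pairwise counting over gap/N-free columns."""
    n = len(rows)
    cols = [j for j in range(len(rows[0])) if all(r[j] not in "-N" for r in rows)]
    if not cols:
        return 0.0
    total = 0.0
    for a, b in combinations(rows, 2):
        total += sum(1 for j in cols if a[j] != b[j]) / len(cols)
    return total / (n * (n - 1) / 2)


def min_switches_exhaustive(states: str) -> int:
    """Minimum number of class switches over all valid segmentations.

    ``states`` uses 'A'/'B' for informative entries and any other character
    for uninformative ones. Every segmentation cuts the informative
    subsequence into contiguous homogeneous segments; enumerate all
    2^(k-1) cut patterns and keep the best valid one.
    """
    info = [c for c in states if c in "AB"]
    if not info:
        raise ValueError("no informative entries")
    k = len(info)
    best = None
    for mask in range(2 ** (k - 1)):
        # cut after position i when bit i is set
        segments = []
        start = 0
        for i in range(k - 1):
            if mask >> i & 1:
                segments.append(info[start : i + 1])
                start = i + 1
        segments.append(info[start:])
        if any(len(set(seg)) != 1 for seg in segments):
            continue
        if any(s1[0] == s2[0] for s1, s2 in zip(segments, segments[1:])):
            continue
        n_switches = len(segments) - 1
        if best is None or n_switches < best:
            best = n_switches
    assert best is not None  # the all-cuts segmentation is always valid
    return best


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix. Returns (newick, labels, matrix).

    Built by random agglomeration: each cluster tracks its newick fragment,
    member leaves, and each member's path length to the cluster root; a join
    fixes all cross-cluster leaf distances exactly.
    """
    labels = [f"t{i}" for i in range(1, n_leaves + 1)]
    clusters = [
        {"frag": lab, "members": {lab: 0.0}} for lab in labels
    ]
    dist = {lab: {} for lab in labels}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a = clusters.pop(int(j))
        b = clusters.pop(int(i))
        la = round(float(rng.uniform(0.05, 1.0)), 6)
        lb = round(float(rng.uniform(0.05, 1.0)), 6)
        for x, dx in a["members"].items():
            for y, dy in b["members"].items():
                dist[x][y] = dist[y][x] = dx + la + dy + lb
        merged = {
            "frag": f"({a['frag']}:{la},{b['frag']}:{lb})",
            "members": {
                **{x: dx + la for x, dx in a["members"].items()},
                **{y: dy + lb for y, dy in b["members"].items()},
            },
        }
        clusters.append(merged)
    newick = clusters[0]["frag"] + ";"
    mat = np.zeros((n_leaves, n_leaves))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                mat[i, j] = dist[x][y]
    return newick, labels, mat
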