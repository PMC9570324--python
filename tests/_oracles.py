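"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: brute-force window
matching for motif scans, exact rational enumeration for Fisher's test, and
random additive trees for neighbor joining.
"""

from __future__ import annotations

import random
from fractions import Fraction
from math import comb

import numpy as np

from methyloscan.mtase_repertoire import DistanceMatrix

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def brute_force_scan(sequence: str, pattern: str, methyl_offset: int,
                     circular: bool = False) -> set[tuple[int, str]]:
    """All (methyl_pos, strand) sites by direct window checks."""
    n, L = len(sequence), len(pattern)

    def matches(window: str, pat: str) -> bool:
        return all(w in IUPAC[p] for p, w in zip(pat, window))

    def window_at(s: int) -> str | None:
        if s + L <= n:
            return sequence[s: s + L]
        if circular:
            return sequence[s:] + sequence[: (s + L) % n]
        return None

    def revcomp(seq: str) -> str:
        return "".join(_RC.get(c, "X") for c in reversed(seq))

    sites = set()
    for s in range(n):
        window = window_at(s)
        if window is None:
            continue
        if matches(window, pattern):
            sites.add(((s + methyl_offset) % n, "+"))
        if matches(revcomp(window), pattern):
            sites.add(((s + L - 1 - methyl_offset) % n, "-"))
    return sites


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact enumeration of same-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = comb(r1, a) * comb(r2, c)
    total = sum(nums)
    return Fraction(sum(x for x in nums if x <= observed), total)


def random_additive_tree(n_leaves: int, rng: random.Random):
    """A random additive distance matrix plus nothing else.

    Built by sequential leaf attachment on an edge-list representation;
    distances are exact path sums over positive branch lengths.
    """
    # adjacency: node -> list of (node, length)
    adj: dict[int, list[tuple[int, float]]] = {0: [], 1: []}
    length = rng.uniform(0.5, 2.0)
    adj[0].append((1, length))
    adj[1].append((0, length))
    next_node = 2
    leaves = [0, 1]
    while len(leaves) < n_leaves:
        # split a random edge with a new internal node, hang a new leaf
        u = rng.choice(list(adj))
        v, bl = rng.choice(adj[u])
        mid, leaf = next_node, next_node + 1
        next_node += 2
        frac = rng.uniform(0.2, 0.8)
        adj[u] = [(x, l) for x, l in adj[u] if x != v] + [(mid, bl * frac)]
        adj[v] = [(x, l) for x, l in adj[v] if x != u] + [(mid, bl * (1 - frac))]
        hang = rng.uniform(0.5, 2.0)
        adj[mid] = [(u, bl * frac), (v, bl * (1 - frac)), (leaf, hang)]
        adj[leaf] = [(mid, hang)]
        leaves.append(leaf)

    def dist_from(src: int) -> dict[int, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, l in adj[x]:
                if y not in out:
                    out[y] = out[x] + l
                    stack.append(y)
        return out

    names = [f"L{i}" for i in range(len(leaves))]
    d = np.zeros((len(leaves), len(leaves)))
    for i, u in enumerate(leaves):
        du = dist_from(u)
        for j, v in enumerate(leaves):
            d[i, j] = du[v]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(ids=names, d=d)
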