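"""Independent oracles used by the test-suite.

These deliberately re-derive results by a different route than the package:
full Smith-Waterman dynamic programming (no seeding), bitmask subset
enumeration of maximal cliques, exhaustive DUST window scoring, and an
exact three-sequence alignment DP.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = {c: i for i, c in enumerate("ACGT")}


def enc(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.int64)


@njit(cache=False)
def _sw(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e9)
    F = np.full((n + 1, m + 1), -1e9)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def sw_score(a: str, b: str, match=1.0, mismatch=-2.0,
             gap_open=-5.0, gap_extend=-2.0) -> float:
    """Exhaustive local-alignment score, affine gaps (first gap base costs
    gap_open, each further base gap_extend)."""
    return float(_sw(enc(a), enc(b), match, mismatch, gap_open, gap_extend))


def brute_force_maximal_cliques(nodes: list, edges: set) -> set:
    """All maximal cliques (size >= 2) by bitmask subset enumeration."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]

    def is_clique(mask: int) -> bool:
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if (adj[i] & mask) != mask & ~(1 << i):
                return False
            m &= m - 1
        return True

    cliques = [mask for mask in range(1, 1 << n)
               if bin(mask).count("1") >= 2 and is_clique(mask)]
    maximal = set()
    for c in cliques:
        if not any(c != d and (c & d) == c for d in cliques):
            maximal.add(frozenset(nodes[i] for i in range(n) if c >> i & 1))
    return maximal


def dust_mask_bruteforce(seq: str, window: int, threshold: float) -> np.ndarray:
    """Mask by scoring every (start, end) window independently."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    trip = [seq[i:i + 3] for i in range(n - 2)]
    for start in range(n):
        for end in range(start + 4, min(start + window, n) + 1):
            t = trip[start:end - 2]
            if len(t) < 2:
                continue
            _, counts = np.unique(t, return_counts=True)
            score = np.sum(counts * (counts - 1) / 2) / (len(t) - 1)
            if score > threshold:
                mask[start:end] = True
    return mask


@njit(cache=False)
def _msa3(a, b, c):
    """Exact 3-sequence alignment minimising sum-of-pairs distance
    (substitution 1, gap-vs-char 1, gap-gap 0)."""
    INF = 1e18
    na, nb, nc = a.size, b.size, c.size
    D = np.full((na + 1, nb + 1, nc + 1), INF)
    D[0, 0, 0] = 0.0
    for i in range(na + 1):
        for j in range(nb + 1):
            for k in range(nc + 1):
                if i == 0 and j == 0 and k == 0:
                    continue
                best = INF
                if i > 0 and j > 0 and k > 0:
                    cost = (0.0 if a[i-1] == b[j-1] else 1.0) + \
                           (0.0 if a[i-1] == c[k-1] else 1.0) + \
                           (0.0 if b[j-1] == c[k-1] else 1.0)
                    v = D[i-1, j-1, k-1] + cost
                    best = v if v < best else best
                if i > 0 and j > 0:
                    cost = (0.0 if a[i-1] == b[j-1] else 1.0) + 2.0
                    v = D[i-1, j-1, k] + cost
                    best = v if v < best else best
                if i > 0 and k > 0:
                    cost = (0.0 if a[i-1] == c[k-1] else 1.0) + 2.0
                    v = D[i-1, j, k-1] + cost
                    best = v if v < best else best
                if j > 0 and k > 0:
                    cost = (0.0 if b[j-1] == c[k-1] else 1.0) + 2.0
                    v = D[i, j-1, k-1] + cost
                    best = v if v < best else best
                if i > 0:
                    v = D[i-1, j, k] + 2.0
                    best = v if v < best else best
                if j > 0:
                    v = D[i, j-1, k] + 2.0
                    best = v if v < best else best
                if k > 0:
                    v = D[i, j, k-1] + 2.0
                    best = v if v < best else best
                D[i, j, k] = best
    return D[na, nb, nc]


def optimal_3seq_sp_distance(a: str, b: str, c: str) -> float:
    return float(_msa3(enc(a), enc(b), enc(c)))


def msa_sp_distance(rows: list[str]) -> float:
    """Sum-of-pairs distance of a given MSA (sub 1, gap-vs-char 1, gap-gap 0)."""
    total = 0.0
    k = len(rows)
    for x in range(k):
        for y in range(x + 1, k):
            for cx, cy in zip(rows[x], rows[y]):
                if cx == "-" and cy == "-":
                    continue
                if cx == "-" or cy == "-":
                    total += 1.0
                elif cx != cy:
                    total += 1.0
    return total
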