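"""Independent brute-force oracles used by the test suite.

These deliberately recompute results by a different route than the library
(substring tests instead of core-scan bookkeeping, pairwise counts instead of
rank sums, naive fixpoint merging instead of a sweep) so agreement is
evidence, not tautology.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy import integrate, stats

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper().replace("U", "T")))


def naive_seed_sites(mirna_seq: str, utr: str) -> set[tuple[int, int, str]]:
    """All-substring seed-site detection: test every window against the four
    site-string definitions, then keep the strongest type per 6mer-core locus."""
    m = mirna_seq.upper().replace("U", "T")
    core6 = rc(m[1:7])
    s8 = rc(m[1:8]) + "A"
    s7m8 = rc(m[1:8])
    s7a1 = rc(m[1:7]) + "A"
    utr = utr.upper()
    occ = lambda s: {i for i in range(len(utr) - len(s) + 1) if utr[i:i + len(s)] == s}
    occ8, occ7m8, occ7a1, occ6 = occ(s8), occ(s7m8), occ(s7a1), occ(core6)
    out = set()
    for c in occ6:
        if c - 1 in occ8:
            out.add((c - 1, c + 7, "8mer"))
        elif c - 1 in occ7m8:
            out.add((c - 1, c + 6, "7mer-m8"))
        elif c in occ7a1:
            out.add((c, c + 7, "7mer-A1"))
        else:
            out.add((c, c + 6, "6mer"))
    return out


def naive_motif_count(seq: str, motif: str) -> int:
    return sum(seq[i:i + len(motif)] == motif for i in range(len(seq) - len(motif) + 1))


def pairwise_u(x, y) -> float:
    """U for x by direct pair counting (greater = 1, tie = 1/2)."""
    return float(sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y))


def enumerate_mw_p(x, y, alternative="two_sided") -> float:
    """Exact Mann-Whitney p by enumerating assignments, scoring each by
    direct pair counting on the pooled values (no ranks involved)."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = pairwise_u(x, y)
    center = n * m / 2
    eps = 1e-9
    count = 0
    for chosen in combinations(range(n + m), n):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(n + m) if i not in set(chosen)]
        u = pairwise_u(xs, ys)
        if alternative == "two_sided":
            count += abs(u - center) >= abs(u_obs - center) - eps
        elif alternative == "less":
            count += u <= u_obs + eps
        else:
            count += u >= u_obs - eps
    return count / comb(n + m, n)


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top          # rank of this p in ascending order
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj


def naive_merge_counts(intervals) -> int:
    """Number of connected overlap components by pairwise fixpoint merging."""
    groups = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if a[0] < b[1] and b[0] < a[1]:
                    groups[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return len(groups)


def normexp_conditional_mean(x, mu, sigma, alpha) -> float:
    """E[S | X = x] by numerical quadrature over the conditional density."""
    lo = max(0.0, x - mu - 8 * sigma)
    hi = x - mu + 8 * sigma
    if hi <= lo:
        hi = lo + 16 * sigma
    num = integrate.quad(
        lambda s: s * np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma),
        lo, hi, limit=400)[0]
    den = integrate.quad(
        lambda s: np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma),
        lo, hi, limit=400)[0]
    return num / den
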