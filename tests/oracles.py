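"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and the defining formulas,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math
from itertools import product

ALPHABET = "ACGT"
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def info_value(row) -> float:
    """Conservation Ci of one count row, from the defining formula."""
    total = sum(row)
    acc = 0.0
    for c in row:
        if c > 0:
            f = c / total
            acc += f * math.log(f)
    return (100.0 / math.log(4)) * (math.log(4) + acc)


def score_window(counts, s: str, pseudocount: float, core=None) -> float:
    """Information-weighted similarity, restricted to ``core`` positions if
    given, computed with explicit loops."""
    L = len(counts)
    positions = range(L) if core is None else core
    num = den = 0.0
    for i in positions:
        row = counts[i]
        total = sum(row)
        freqs = [(c + pseudocount * total) / (total * (1 + 4 * pseudocount)) for c in row]
        ci = info_value(row)
        num += ci * freqs[ALPHABET.index(s[i])]
        den += ci * max(freqs)
    return num / den


def best_core(counts, core_length: int = 4):
    """Consecutive positions with maximal summed Ci, first window on ties."""
    infos = [info_value(row) for row in counts]
    best, best_sum = 0, -1.0
    for start in range(len(counts) - core_length + 1):
        s = sum(infos[start : start + core_length])
        if s > best_sum + 1e-12:
            best, best_sum = start, s
    return list(range(best, best + core_length))


def naive_scan(counts, seq: str, pseudocount: float, core_cut: float, threshold: float):
    """All (start, strand, core_sim, matrix_sim) retained hits, both strands,
    by rescoring every window."""
    L = len(counts)
    core = best_core(counts)
    hits = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if any(c not in ALPHABET for c in window):
            continue
        for strand, w in (("+", window), ("-", revcomp(window))):
            cs = score_window(counts, w, pseudocount, core)
            ms = score_window(counts, w, pseudocount)
            if cs >= core_cut - 1e-9 and ms >= threshold - 1e-9:
                hits.append((start, strand, cs, ms))
    return sorted(hits)


def sw_local_score(a: str, b: str, sub, gap_open: int, gap_extend: int) -> float:
    """Affine-gap Smith-Waterman by explicit dynamic programming.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]  # best ending in match/mismatch
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + sub[a[i - 1], b[j - 1]])
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def exhaustive_best_window(hits, anchors, candidate_families, max_span):
    """Best anchored window by enumerating every hit-bounded interval
    (all O(n^2) start/end pairs): returns (families frozenset, span,
    hull_start) or None.

    ``hits`` are (start, end, family, id) tuples; ``anchors`` is the set of
    ids admissible as the window anchor.
    """
    anchor_keys = set(anchors)
    cand = [g for g in hits if g[2] in candidate_families]
    best = None
    for lo_hit in cand:
        for hi_hit in cand:
            lo, hi = lo_hit[0], hi_hit[1]
            if hi <= lo or hi - lo > max_span:
                continue
            inside = [g for g in cand if g[0] >= lo and g[1] <= hi]
            if not any(g[3] in anchor_keys for g in inside):
                continue
            fams = frozenset(g[2] for g in inside)
            hull_lo = min(g[0] for g in inside)
            hull_hi = max(g[1] for g in inside)
            key = (-len(fams), hull_hi - hull_lo, hull_lo)
            if best is None or key < best[0]:
                best = (key, fams, hull_hi - hull_lo, hull_lo)
    if best is None:
        return None
    return best[1], best[2], best[3]


def exhaustive_module_families(hits_by_species, anchor_family, max_span):
    """Largest family set coverable by an anchored window in every species,
    by explicit enumeration over all subsets; lexicographic min on ties.

    ``hits_by_species`` maps species -> list of (start, end, family) tuples.
    """
    common = None
    for hits in hits_by_species.values():
        fams = {h[2] for h in hits}
        common = fams if common is None else common & fams
    if not common or anchor_family not in common:
        return None

    def covered(hits, S) -> bool:
        for h in hits:
            lo, hi = h[0], h[0] + max_span
            inside = [g for g in hits if g[0] >= lo and g[1] <= hi]
            fams = {g[2] for g in inside}
            if anchor_family in fams and S <= fams:
                return True
        return False

    others = sorted(common - {anchor_family})
    best = None
    for mask in range(2 ** len(others)):
        S = {anchor_family} | {f for i, f in enumerate(others) if mask >> i & 1}
        if all(covered(hits, S) for hits in hits_by_species.values()):
            key = (-len(S), tuple(sorted(S)))
            if best is None or key < best[0]:
                best = (key, frozenset(S))
    return None if best is None else best[1]


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct pmf summation."""
    total = 0.0
    for x in range(k, n + 1):
        total += math.comb(n, x) * p**x * (1 - p) ** (n - x)
    return total
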