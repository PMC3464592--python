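"""Independent brute-force oracles used only by the tests.

Everything here is deliberately written by a different route than the
package implementation: plain dynamic programming or exhaustive
enumeration, no shared helpers.
"""

from __future__ import annotations

import itertools
import math

NEG_INF = float("-inf")

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE = sorted(c for c, aa in _CODE.items() if aa != "*")


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Per-position fraction of non-stop neighbours that are synonymous."""
    aa = _CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if _CODE[mutant] == "*":
                continue
            tot += 1
            syn += _CODE[mutant] == aa
        if tot:
            s += syn / tot
    return s, 3.0 - s


def ng86_diffs_oracle(a: str, b: str) -> tuple[float, float] | None:
    """Equal-weight pathway averaging with stop-crossing paths excluded."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if _CODE[nxt] == "*":
                ok = False
                break
            sd += _CODE[cur] == _CODE[nxt]
            nd += _CODE[cur] != _CODE[nxt]
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def affine_dp_oracle(a: str, b: str, score, gap_open: float, gap_extend: float,
                     local: bool) -> float:
    """Three-matrix affine-gap alignment DP; a gap of length L costs
    gap_open + (L - 1) * gap_extend (matching the aligner's convention)."""
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    M[0][0] = 0.0
    best = 0.0 if local else NEG_INF
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:
                X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            if j > 0:
                Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                              Y[i][j - 1] - gap_extend)
            if i > 0 and j > 0:
                diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = diag + score(a[i - 1], b[j - 1])
                if local:
                    M[i][j] = max(M[i][j], score(a[i - 1], b[j - 1]))
            if local:
                best = max(best, M[i][j] if (i and j) else 0.0)
    if local:
        return best
    return max(M[n][m], X[n][m], Y[n][m])


def global_enumeration_oracle(a: str, b: str, score, gap_open: float,
                              gap_extend: float) -> float:
    """Exhaustive recursion over all global alignments (tiny inputs only)."""

    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if state == "x" else gap_open
            options.append(-cost + rec(i + 1, j, "x"))
        if j < len(b):
            cost = gap_extend if state == "y" else gap_open
            options.append(-cost + rec(i, j + 1, "y"))
        return max(options)

    return rec(0, 0, "m")


def fisher_two_sided_oracle(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Integer binomial numerators with the standard 1e-7 relative tie
    tolerance; denominator C(N, n) applied once at the end.
    """
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    nums = {kk: math.comb(K, kk) * math.comb(N - K, n - kk)
            for kk in range(k_min, k_max + 1)}
    obs = nums[k]
    total = sum(num for num in nums.values() if num * 10**7 <= obs * (10**7 + 1))
    return min(1.0, total / math.comb(N, n))


def fisher_greater_oracle(k: int, n: int, K: int, N: int) -> float:
    k_max = min(n, K)
    total = sum(math.comb(K, kk) * math.comb(N - K, n - kk)
                for kk in range(k, k_max + 1))
    return total / math.comb(N, n)
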