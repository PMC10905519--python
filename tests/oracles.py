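"""Independent reference implementations used only to check the package.

Each oracle is written from the mathematical definition, deliberately not
sharing code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

MIN_LOOP = 3
PAIR_W = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def gotoh_local_score(a: str, b: str, match=1.0, mis=-1.0, open_=-2.0, ext=-1.0) -> float:
    """Naive affine-gap local alignment (Gotoh three-matrix DP); the first
    base of a gap costs ``open_``, each further base ``ext``."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e9)
    F = np.full((n + 1, m + 1), -1e9)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + ext)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + ext)
            s = match if a[i - 1] == b[j - 1] else mis
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def exhaustive_pairing_score(seq: str) -> int:
    """Maximum weighted non-crossing pairing (min loop 3) by exhaustive
    recursion on the leftmost position — no memoization, every structure
    is enumerated. Feasible for sequences up to ~14 nt."""
    r = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i < MIN_LOOP + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = PAIR_W.get((r[i], r[k]), 0)
            if w:
                best = max(best, w + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(r) - 1)


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_offtarget_scan(
    guide: str, genome_seq: str, max_mm: int, pam_tails=("GG", "AG")
) -> set[tuple[int, str, str]]:
    """All (protospacer_start, strand, protospacer+PAM) with a tolerated PAM
    and Hamming distance <= max_mm, scanning the forward sequence and its
    reverse complement separately."""
    L = len(genome_seq)
    hits: set[tuple[int, str, str]] = set()

    def scan(s: str, strand: str):
        for i in range(L - 23 + 1):
            if s[i + 21 : i + 23] not in pam_tails:
                continue
            proto = s[i : i + 20]
            site = s[i : i + 23]
            if "N" in site:
                continue
            mm = sum(1 for x, y in zip(guide, proto) if x != y)
            if mm <= max_mm:
                start = i if strand == "+" else L - (i + 20)
                hits.add((start, strand, site))

    scan(genome_seq, "+")
    scan(revcomp(genome_seq), "-")
    return hits


def kendall_tau_b_enumeration(x, y) -> float:
    """Tau-b from O(n^2) concordant/discordant pair enumeration."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


def spearman_via_midranks(x, y) -> float:
    """Pearson correlation of average ranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
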