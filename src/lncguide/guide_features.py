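"""The 27-feature registry for sgRNA on-target activity prediction.

Features cover GC partitions of the spacer, base composition with one-hot
position indicators (the PAM-proximal 20th base and the middle 10th base,
both reported discriminative for lncRNA guides), Wallace-rule melting
temperature proxies, and secondary-structure descriptors from a built-in
Nussinov-style folding engine (stem fraction, hairpins, free single-strand
run, seed accessibility, surrogate folding energy).

The registry is data-driven: FEATURE_NAMES fixes the order, and each name
maps to one extractor, so alternative feature definitions can be swapped in
without touching the model code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .target_scan import GUIDE_LEN

#: fixed, ordered names of the 27 features; file/column order is a contract.
FEATURE_NAMES: tuple[str, ...] = (
    "gc_whole",            # f1
    "gc_distal_1_10",      # f2
    "gc_proximal_11_20",   # f3
    "gc_tail_15_20",       # f4
    "freq_A",              # f5
    "freq_C",              # f6
    "freq_G",              # f7
    "freq_T",              # f8
    "pos20_is_A",          # f9
    "pos20_is_C",          # f10
    "pos20_is_G",          # f11
    "pos20_is_T",          # f12
    "pos10_is_A",          # f13
    "pos10_is_C",          # f14
    "pos10_is_G",          # f15
    "pos10_is_T",          # f16
    "tm_wallace_whole",    # f17
    "tm_wallace_13_20",    # f18
    "mfe_surrogate",       # f19
    "stem_fraction",       # f20
    "hairpin_count",       # f21
    "longest_unpaired_run",# f22
    "seed_unpaired_frac",  # f23
    "gg_count",            # f24
    "tt_count",            # f25
    "gc_skew",             # f26
    "purine_fraction",     # f27
)

N_FEATURES = len(FEATURE_NAMES)
_BASES = "ACGT"

# Nussinov surrogate pair scores; min hairpin loop of 3 nt.
PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
MIN_LOOP = 3


def _check_guide(guide: str) -> str:
    g = guide.upper()
    if len(g) != GUIDE_LEN or set(g) - set(_BASES):
        raise ValueError(f"need a {GUIDE_LEN}-nt ACGT guide, got {guide!r}")
    return g


@dataclass(frozen=True)
class FoldResult:
    """Secondary structure of a folded spacer.

    ``pair_list`` holds 0-based (i, j) index pairs, i < j, non-crossing;
    ``mfe`` is the negated total pair score (surrogate energy, <= 0).
    """

    pair_list: frozenset[tuple[int, int]]
    mfe: float
    hairpin_count: int
    longest_unpaired_run: int
    n: int


class FoldingEngine(Protocol):
    def fold(self, rna: str) -> FoldResult: ...


class NussinovEngine:
    """Maximum-weighted-pairing fold (GC=3, AU=2, GU=1, min loop 3).

    A thermodynamic engine (e.g. a nearest-neighbour model) can be plugged
    in behind the same contract; this built-in engine keeps the package
    self-contained and exactly testable by exhaustive enumeration.
    """

    def fold(self, rna: str) -> FoldResult:
        r = rna.upper().replace("T", "U")
        n = len(r)
        dp = np.zeros((n, n), dtype=np.int64)
        for span in range(MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = dp[i][j - 1]
                for k in range(i, j - MIN_LOOP):
                    w = PAIR_SCORE.get((r[k], r[j]), 0)
                    if w:
                        left = dp[i][k - 1] if k > i else 0
                        cand = left + w + dp[k + 1][j - 1]
                        if cand > best:
                            best = cand
                best = max(best, dp[i + 1][j] if i + 1 <= j else 0)
                dp[i][j] = best
        pairs: set[tuple[int, int]] = set()
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j:
                continue
            if dp[i][j] == dp[i][j - 1]:
                stack.append((i, j - 1))
                continue
            for k in range(i, j - MIN_LOOP):
                w = PAIR_SCORE.get((r[k], r[j]), 0)
                if not w:
                    continue
                left = dp[i][k - 1] if k > i else 0
                if left + w + dp[k + 1][j - 1] == dp[i][j]:
                    pairs.add((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
            else:  # pragma: no cover - dp[i][j-1] branch always matches otherwise
                stack.append((i, j - 1))
        return build_fold_result(pairs, n)


def build_fold_result(pairs: set[tuple[int, int]], n: int) -> FoldResult:
    """Derive the summary fields of a FoldResult from an explicit pair set."""
    paired = np.zeros(n, dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True
    # hairpin: a pair with no paired base strictly inside it
    hairpins = sum(
        1 for i, j in pairs if not any(paired[i + 1 : j])
    )
    longest = run = 0
    for p in paired:
        run = 0 if p else run + 1
        longest = max(longest, run)
    # surrogate energy needs the sequence-free score; recompute from weights
    return FoldResult(
        pair_list=frozenset(pairs),
        mfe=0.0,  # placeholder, overwritten by callers that know the sequence
        hairpin_count=hairpins,
        longest_unpaired_run=int(longest),
        n=n,
    )


def fold_guide(guide: str, engine: FoldingEngine | None = None) -> FoldResult:
    """Fold the spacer as RNA (T->U) and return its structure summary."""
    g = guide.upper()
    if set(g) - set("ACGTU"):
        raise ValueError(f"non-nucleotide characters in {guide!r}")
    eng = engine if engine is not None else NussinovEngine()
    fr = eng.fold(g)
    r = g.replace("T", "U")
    score = sum(PAIR_SCORE.get((r[i], r[j]), 0) for i, j in fr.pair_list)
    return FoldResult(fr.pair_list, -float(score), fr.hairpin_count,
                      fr.longest_unpaired_run, fr.n)


def gc_features(guide: str) -> tuple[float, float, float, float]:
    """GC fractions: whole spacer, PAM-distal half (1-10), PAM-proximal half
    (11-20) and the tail (15-20)."""
    g = _check_guide(guide)

    def gc(s: str) -> float:
        return (s.count("G") + s.count("C")) / len(s)

    return gc(g), gc(g[:10]), gc(g[10:]), gc(g[14:])


def composition_features(guide: str) -> tuple[float, ...]:
    """Mononucleotide frequencies plus one-hot identity of positions 20 and 10."""
    g = _check_guide(guide)
    freqs = tuple(g.count(b) / GUIDE_LEN for b in _BASES)
    hot20 = tuple(1.0 if g[19] == b else 0.0 for b in _BASES)
    hot10 = tuple(1.0 if g[9] == b else 0.0 for b in _BASES)
    return freqs + hot20 + hot10


def thermo_features(guide: str) -> tuple[float, float]:
    """Wallace-rule melting temperatures (2(A+T)+4(G+C) degC) of the whole
    spacer and of the PAM-proximal 13-20 window."""
    g = _check_guide(guide)

    def tm(s: str) -> float:
        gc = s.count("G") + s.count("C")
        return 2.0 * (len(s) - gc) + 4.0 * gc

    return tm(g), tm(g[12:])


def structure_features(fr: FoldResult) -> tuple[float, float, float, float, float]:
    """Surrogate energy, stem fraction, hairpin count, longest free
    single-strand run, and unpaired fraction of the seed (positions 11-20)."""
    paired = np.zeros(fr.n, dtype=bool)
    for i, j in fr.pair_list:
        paired[i] = paired[j] = True
    seed = paired[10:] if fr.n >= 11 else paired[:0]
    seed_unpaired = 1.0 if len(seed) == 0 else float(np.mean(~seed))
    return (
        fr.mfe,
        2.0 * len(fr.pair_list) / fr.n,
        float(fr.hairpin_count),
        float(fr.longest_unpaired_run),
        seed_unpaired,
    )


def motif_features(guide: str) -> tuple[float, float, float, float]:
    """GG/TT dinucleotide counts, GC skew (G-C)/(G+C), purine fraction."""
    g = _check_guide(guide)
    gg = sum(1 for i in range(GUIDE_LEN - 1) if g[i : i + 2] == "GG")
    tt = sum(1 for i in range(GUIDE_LEN - 1) if g[i : i + 2] == "TT")
    ng, nc = g.count("G"), g.count("C")
    skew = 0.0 if ng + nc == 0 else (ng - nc) / (ng + nc)
    purine = (g.count("A") + ng) / GUIDE_LEN
    return float(gg), float(tt), skew, purine


@dataclass(frozen=True)
class FeatureVector:
    guide_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(self.values)}")
        if not all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]


def extract_feature_vector(
    guide: str, engine: FoldingEngine | None = None, guide_id: str | None = None
) -> FeatureVector:
    """Concatenate the five feature groups in registry order (deterministic)."""
    g = _check_guide(guide)
    fr = fold_guide(g, engine)
    values = (
        gc_features(g)
        + composition_features(g)
        + thermo_features(g)
        + structure_features(fr)
        + motif_features(g)
    )
    return FeatureVector(guide_id or g, tuple(float(v) for v in values))


def feature_matrix(
    guides: list[str], engine: FoldingEngine | None = None
) -> np.ndarray:
    """(n_guides, 27) matrix in registry column order."""
    return np.array([extract_feature_vector(g, engine).values for g in guides])


def registry_hash() -> str:
    """Stable hash of the feature registry; stored in model archives so a
    model is never applied to a differently ordered feature set."""
    import hashlib

    return hashlib.sha256("|".join(FEATURE_NAMES).encode()).hexdigest()[:16]
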