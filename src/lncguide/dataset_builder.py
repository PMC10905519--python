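"""Labeled training-set construction.

Efficient lncRNA guides from screens lack experimentally validated
inefficient counterparts, so negatives are constructed artificially: every
PAM-anchored 20-mer in the +/-15-nt neighbourhood of an efficient guide is
scored against it by Smith-Waterman local alignment; sequences scoring
below the similarity threshold (default 15, i.e. <~75% identity under the
+1/-1/-2/-1 scheme) are labelled inefficient, while similar ones are
excluded as presumed-effective. Class imbalance is then repaired by SMOTE
interpolation inside the minority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .genome_io import reverse_complement
from .target_scan import GUIDE_LEN, PAM_LEN

LABELS = ("efficient", "inefficient")
PROVENANCES = ("observed", "artificial", "smote_synthetic")

#: default alignment scheme: identical 20-mers score 20, threshold 15 ~ 75% identity
DEFAULT_SW_SCHEME = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -1.0}
SIM_THRESHOLD = 15.0


@dataclass(frozen=True)
class GuideEntry:
    guide: str
    pam: str
    chrom: str
    start: int
    strand: str
    label: str
    provenance: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")


@dataclass
class LabeledGuideSet:
    entries: list[GuideEntry]
    mechanism: str = "CRISPRko"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in ("CRISPRko", "CRISPRi"):
            raise ValueError("mechanism must be CRISPRko or CRISPRi")
        keys = [(e.guide, e.chrom, e.start, e.strand, e.label) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (guide, coords, label) entries")

    def labels(self) -> np.ndarray:
        return np.array([1 if e.label == "efficient" else 0 for e in self.entries])

    def guides(self) -> list[str]:
        return [e.guide for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("guide\tpam\tchrom\tstart\tstrand\tlabel\tprovenance\n")
            for e in self.entries:
                fh.write(
                    f"{e.guide}\t{e.pam}\t{e.chrom}\t{e.start}\t{e.strand}\t"
                    f"{e.label}\t{e.provenance}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, mechanism: str = "CRISPRko") -> "LabeledGuideSet":
        expected = ["guide", "pam", "chrom", "start", "strand", "label", "provenance"]
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != expected:
                raise ValueError(f"{path}: header {header} != {expected}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 7:
                    raise ValueError(f"{path}:{lineno}: expected 7 columns")
                entries.append(
                    GuideEntry(f[0], f[1], f[2], int(f[3]), f[4], f[5], f[6])
                )
        return cls(entries, mechanism)


def _aligner(scheme: dict | None = None) -> Align.PairwiseAligner:
    sc = dict(DEFAULT_SW_SCHEME, **(scheme or {}))
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = sc["match"]
    a.mismatch_score = sc["mismatch"]
    a.open_gap_score = sc["gap_open"]
    a.extend_gap_score = sc["gap_extend"]
    return a


def smith_waterman_score(a: str, b: str, scheme: dict | None = None) -> float:
    """Optimal local-alignment score (affine gaps; first gap base costs
    ``gap_open``, each further base ``gap_extend``). Symmetric, >= 0."""
    if not a or not b:
        raise ValueError("empty sequence")
    for s in (a, b):
        if set(s.upper()) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in {s!r}")
    return float(_aligner(scheme).score(a.upper(), b.upper()))


def _pam_anchored_20mers(window: str) -> list[tuple[str, str, int, str]]:
    """All (guide, pam, offset, strand) with an NGG immediately 3' of a
    20-mer, on both strands of the window."""
    out = []
    w = window.upper()
    L = GUIDE_LEN + PAM_LEN
    for i in range(len(w) - L + 1):
        if w[i + 21 : i + 23] == "GG":
            g, p = w[i : i + 20], w[i + 20 : i + 23]
            if "N" not in g + p:
                out.append((g, p, i, "+"))
        if w[i : i + 2] == "CC":
            g = reverse_complement(w[i + 3 : i + 23])
            p = reverse_complement(w[i : i + 3])
            if "N" not in g + p:
                out.append((g, p, i + 3, "-"))
    return out


def generate_artificial_negatives(
    positives: list[tuple[str, str]],
    sim_threshold: float = SIM_THRESHOLD,
    scheme: dict | None = None,
    mechanism: str = "CRISPRko",
) -> LabeledGuideSet:
    """Artificial inefficient guides from the neighbourhoods of efficient ones.

    ``positives`` is a list of (efficient 20-nt guide, genomic window holding
    the guide with its +/-15-nt flanks, typically 50 nt). Every PAM-anchored
    20-mer in the window other than the positive itself is scored against the
    positive; scores below ``sim_threshold`` become inefficient/artificial
    entries, scores at or above it are excluded entirely as presumed
    effective-like. Deterministic; deduplicated across positives.
    """
    entries: list[GuideEntry] = []
    seen: set[str] = set()
    for idx, (pos_guide, window) in enumerate(positives):
        if len(window) < GUIDE_LEN + PAM_LEN:
            warnings.warn(
                f"positive {idx}: window shorter than {GUIDE_LEN + PAM_LEN} nt, skipped"
            )
            continue
        pg = pos_guide.upper()
        for g, pam, off, strand in _pam_anchored_20mers(window):
            if g == pg:
                continue
            score = smith_waterman_score(g, pg, scheme)
            if score < sim_threshold and g not in seen:
                seen.add(g)
                entries.append(
                    GuideEntry(g, pam, f"window{idx}", off, strand,
                               "inefficient", "artificial")
                )
    gs = LabeledGuideSet(entries, mechanism)
    gs.metadata = {
        "sim_threshold": sim_threshold,
        "sw_scheme": dict(DEFAULT_SW_SCHEME, **(scheme or {})),
    }
    return gs


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: upsample the minority class to the majority count.

    Each synthetic point lies on the segment between a minority sample and
    one of its k minority-class nearest neighbours (k capped at
    n_minority - 1). Majority rows pass through unchanged; deterministic
    given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE needs two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("need at least 2 minority samples for SMOTE")
    Xm = X[y == minority]
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    nbr_choice = rng.integers(1, k_eff + 1, size=n_new)
    u = rng.random(n_new)
    synth = Xm[base] + u[:, None] * (Xm[idx[base, nbr_choice]] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def stratified_kfold_split(
    y: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold index partition."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros((len(y), 1)), y)]
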