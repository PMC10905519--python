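"""Synthetic genomes, gene models and labeled guide sets with planted,
recoverable signal.

The default planted efficiency rule mirrors the signals reported for
lncRNA-specific guides — a terminal (position-20) guanine, a moderate GC
band, and weak self-folding — so that the full training pipeline has a
known ground truth to recover: a guide is efficient iff its 20th base is
G, its whole-spacer GC fraction lies in [0.4, 0.75], and its surrogate
folding energy is at least -12 (the weakly folded half of the background
distribution under the built-in engine's pairing scores). Every generator
is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dataset_builder import GuideEntry, LabeledGuideSet
from .genome_io import GeneModel, GenomeSequence
from .guide_features import FeatureVector, FoldingEngine, extract_feature_vector
from .target_scan import GUIDE_LEN, CandidateGuide, scan_pam_sites

#: registry feature names referenced by the default planted rule
DEFAULT_RULE_FEATURES = ("pos20_is_G", "gc_whole", "mfe_surrogate")

#: the three clauses of the default rule, one per planted feature
DEFAULT_RULE_CLAUSES: tuple[Callable[["FeatureVector"], bool], ...] = (
    lambda fv: fv["pos20_is_G"] == 1.0,
    lambda fv: 0.4 <= fv["gc_whole"] <= 0.75,
    lambda fv: fv["mfe_surrogate"] >= -12.0,
)


def default_planted_rule(fv: FeatureVector) -> bool:
    return all(clause(fv) for clause in DEFAULT_RULE_CLAUSES)


@dataclass
class SyntheticSpec:
    genome_length: int = 120_000
    gc_background: float = 0.5
    n_genes: int = 6
    planted_rule: Callable[[FeatureVector], bool] = default_planted_rule
    rule_features: tuple[str, ...] = DEFAULT_RULE_FEATURES
    #: optional clause decomposition of the rule; when given, negatives are
    #: drawn stratified across single-clause violators ("near misses") so
    #: that every clause is individually recoverable from the labels
    rule_clauses: tuple[Callable[[FeatureVector], bool], ...] | None = (
        DEFAULT_RULE_CLAUSES
    )
    label_noise: float = 0.05
    n_pos: int = 200
    n_neg: int = 200
    seed: int = 0
    gene_length_range: tuple[int, int] = (1500, 3000)
    margin: int = 2000  # genomic gap kept around genes

    def __post_init__(self) -> None:
        if not 0 < self.gc_background < 1:
            raise ValueError("gc_background must be in (0,1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.genome_length < (self.gene_length_range[1] + self.margin) * self.n_genes:
            raise ValueError("genome too short for requested genes")


def generate_toy_genome(spec: SyntheticSpec) -> tuple[GenomeSequence, list[GeneModel]]:
    """I.i.d. genome at the requested GC background with non-overlapping
    genes of alternating strand; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    p = [
        (1 - spec.gc_background) / 2,  # A
        spec.gc_background / 2,        # C
        spec.gc_background / 2,        # G
        (1 - spec.gc_background) / 2,  # T
    ]
    bases = rng.choice(np.array(list("ACGT")), size=spec.genome_length, p=p)
    genome = GenomeSequence("synth_chr1", "".join(bases))
    genes: list[GeneModel] = []
    cursor = spec.margin
    slot = (spec.genome_length - spec.margin) // max(spec.n_genes, 1)
    for i in range(spec.n_genes):
        length = int(rng.integers(*spec.gene_length_range))
        start = cursor + int(rng.integers(0, max(1, slot - length - spec.margin)))
        end = start + length
        if end + spec.margin > spec.genome_length:
            break
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"synth_gene{i+1}", genome.id, start, end, strand))
        cursor += slot
    return genome, genes


def generate_labeled_dataset(
    spec: SyntheticSpec, engine: FoldingEngine | None = None
) -> LabeledGuideSet:
    """Rejection-sample PAM-adjacent guides from the toy genome until
    ``n_pos`` satisfy the planted rule and ``n_neg`` violate it, then flip
    each label independently with probability ``label_noise``.

    The true rule's feature names and the pre-noise labels are recorded in
    the set's metadata.
    """
    genome, _ = generate_toy_genome(spec)
    rng = np.random.default_rng(spec.seed + 1)
    candidates = scan_pam_sites(genome)
    order = rng.permutation(len(candidates))
    pos: list[CandidateGuide] = []
    # near-miss buckets: negatives violating exactly one rule clause, so
    # each clause leaves an identifiable footprint in the labels; the
    # remainder of the negative quota comes from unrestricted violators
    n_clauses = len(spec.rule_clauses) if spec.rule_clauses else 0
    bucket_quota = spec.n_neg // (n_clauses + 1) if n_clauses else 0
    buckets: list[list[CandidateGuide]] = [[] for _ in range(n_clauses)]
    spill: list[CandidateGuide] = []
    seen: set[str] = set()

    def neg_done() -> bool:
        have = sum(min(len(b), bucket_quota) for b in buckets) + len(spill)
        return have >= spec.n_neg and all(
            len(b) >= bucket_quota for b in buckets
        )

    for idx in order:
        if len(pos) >= spec.n_pos and (not n_clauses or neg_done()) and (
            n_clauses or len(spill) >= spec.n_neg
        ):
            break
        c = candidates[idx]
        if c.guide in seen:
            continue
        seen.add(c.guide)
        fv = extract_feature_vector(c.guide, engine)
        if spec.planted_rule(fv):
            if len(pos) < spec.n_pos:
                pos.append(c)
        elif n_clauses:
            violated = [i for i, cl in enumerate(spec.rule_clauses) if not cl(fv)]
            if len(violated) == 1 and len(buckets[violated[0]]) < bucket_quota:
                buckets[violated[0]].append(c)
            elif len(spill) < spec.n_neg:
                spill.append(c)
        elif len(spill) < spec.n_neg:
            spill.append(c)
    neg: list[CandidateGuide] = []
    for b in buckets:
        neg.extend(b[:bucket_quota])
    neg.extend(spill[: spec.n_neg - len(neg)])
    if len(pos) < spec.n_pos or len(neg) < spec.n_neg:
        raise RuntimeError(
            f"genome exhausted: found {len(pos)}/{spec.n_pos} positives, "
            f"{len(neg)}/{spec.n_neg} negatives; enlarge genome_length"
        )
    entries: list[GuideEntry] = []
    true_labels: list[int] = []
    flips = rng.random(spec.n_pos + spec.n_neg) < spec.label_noise
    for j, (c, true_eff) in enumerate(
        [(c, True) for c in pos] + [(c, False) for c in neg]
    ):
        eff = true_eff ^ bool(flips[j])
        entries.append(
            GuideEntry(
                c.guide, c.pam, c.chrom, c.start, c.strand,
                "efficient" if eff else "inefficient", "observed",
            )
        )
        true_labels.append(int(true_eff))
    gs = LabeledGuideSet(entries, "CRISPRko")
    gs.metadata = {
        "rule_features": list(spec.rule_features),
        "label_noise": spec.label_noise,
        "seed": spec.seed,
        "true_labels": true_labels,
    }
    return gs


def plant_offtarget_decoys(
    genome: GenomeSequence,
    guide: str,
    mismatch_counts: list[int],
    genes: list[GeneModel] | None = None,
    seed: int = 0,
    pam: str = "TGG",
) -> tuple[GenomeSequence, list[tuple[int, int]]]:
    """Insert PAM-adjacent near-copies of ``guide`` at recorded positions.

    Each requested mismatch count produces one planted plus-strand site
    (mutated guide + NGG) written over intergenic sequence, avoiding gene
    intervals and the other planted sites. Returns the modified genome and
    the list of (position, mismatch_count) placements.
    """
    if not mismatch_counts:
        return genome, []
    rng = np.random.default_rng(seed)
    g = guide.upper()
    if len(g) != GUIDE_LEN:
        raise ValueError("guide must be 20 nt")
    occupied = [(m.start - 25, m.end + 25) for m in (genes or [])]
    seq = list(genome.seq)
    placements: list[tuple[int, int]] = []
    site_len = GUIDE_LEN + len(pam)
    for k in mismatch_counts:
        mutant = list(g)
        for pos in rng.choice(GUIDE_LEN, size=k, replace=False):
            alternatives = [b for b in "ACGT" if b != mutant[pos]]
            mutant[pos] = alternatives[int(rng.integers(3))]
        for _ in range(1000):
            p = int(rng.integers(0, len(seq) - site_len))
            span = (p - 5, p + site_len + 5)
            if any(span[0] < e and s < span[1] for s, e in occupied):
                continue
            occupied.append(span)
            seq[p : p + site_len] = list("".join(mutant) + pam)
            placements.append((p, k))
            break
        else:
            raise RuntimeError("could not place decoy away from genes")
    return GenomeSequence(genome.id, "".join(seq)), placements
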