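"""Mechanism-specific sgRNA design and composite ranking.

Every candidate receives three scores in [0,1] — calibrated on-target
probability, off-target specificity, and a genomic-location score — and a
composite in [-1,1]:

    composite = 2 * (w1*p_on + w2*specificity + w3*location) - 1

with default weights (0.5, 0.3, 0.2). CRISPRi designs single guides in the
promoter window of a gene (dCas9 blocks transcription most effectively
near the TSS, so core-promoter placement scores highest); CRISPRko designs
guide *pairs* in the gene body whose simultaneous cuts delete a large
fragment — for lncRNAs, whose function rarely depends on a reading frame,
small indels from a single cut are usually silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GeneModel, GenomeSequence, Region, extract_promoter
from .offtarget import (
    MismatchWeightTable,
    aggregate_offtarget_risk,
    enumerate_offtarget_sites,
)
from .ontarget_model import TrainedModel, predict_ontarget
from .guide_features import extract_feature_vector
from .target_scan import CandidateGuide, assign_genomic_context, scan_pam_sites

DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)

#: location preferences per mechanism (gene-body thirds refined below)
CRISPRI_LOCATION = {
    "core_promoter": 1.0,
    "promoter": 0.7,
    "gene_body": 0.3,
    "downstream": 0.1,
    "intergenic": 0.0,
}
CRISPRKO_LOCATION = {
    "promoter": 0.3,
    "core_promoter": 0.3,
    "downstream": 0.1,
    "intergenic": 0.1,
}
#: multipliers for the 5', middle and 3' thirds of the gene body (CRISPRko)
GENE_BODY_THIRD_FACTORS = (1.0, 0.9, 0.7)

#: paired-design distance defaults: hard filter and preferred band (bp)
DEFAULT_MIN_DEL, DEFAULT_MAX_DEL = 50, 2000
PREFERRED_BAND = (200, 1000)
DISTANCE_PENALTY_PER_BP = 5e-4


def location_score(c: CandidateGuide, mechanism: str, gene: GeneModel | None = None) -> float:
    """Score in [0,1] for the candidate's genomic placement under a
    mechanism. CRISPRko favours the gene body, graded 5'->3' by thirds;
    CRISPRi favours the (core) promoter."""
    if mechanism == "CRISPRi":
        return CRISPRI_LOCATION[c.context]
    if mechanism != "CRISPRko":
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if c.context != "gene_body":
        return CRISPRKO_LOCATION[c.context]
    if gene is None:
        return 1.0
    # fraction along the gene in transcription orientation
    if gene.strand == "+":
        frac = (c.cut_site - gene.start) / (gene.end - gene.start)
    else:
        frac = (gene.end - 1 - c.cut_site) / (gene.end - gene.start)
    third = min(2, int(3 * min(max(frac, 0.0), 0.999999)))
    return GENE_BODY_THIRD_FACTORS[third]


def composite_score(
    p_on: float,
    specificity: float,
    location: float,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Affine map of the weighted mean of the three [0,1] scores to [-1,1]."""
    for v, name in ((p_on, "p_on"), (specificity, "specificity"), (location, "location")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    w1, w2, w3 = weights
    if min(weights) < 0 or abs(w1 + w2 + w3 - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    return 2.0 * (w1 * p_on + w2 * specificity + w3 * location) - 1.0


@dataclass(frozen=True)
class ScoredGuide:
    candidate: CandidateGuide
    p_on: float
    specificity: float
    location: float
    composite: float


@dataclass(frozen=True)
class GuidePair:
    left: ScoredGuide
    right: ScoredGuide
    deletion_size: int
    pair_composite: float

    def __post_init__(self) -> None:
        if self.deletion_size <= 0:
            raise ValueError("deletion_size must be positive")


@dataclass
class DesignResult:
    mechanism: str
    entries: list  # ScoredGuide (CRISPRi) or GuidePair (CRISPRko)
    diagnostics: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


def _rank_key(sg: ScoredGuide):
    return (-sg.composite, -sg.p_on, sg.candidate.start)


def _score_candidates(
    candidates: list[CandidateGuide],
    mechanism: str,
    gene: GeneModel,
    genome: GenomeSequence,
    model: TrainedModel,
    table: MismatchWeightTable | None,
    max_mm: int,
    check_offtargets: bool,
) -> list[ScoredGuide]:
    out = []
    for c in candidates:
        _, p_on = predict_ontarget(model, extract_feature_vector(c.guide))
        if check_offtargets:
            hits = enumerate_offtarget_sites(
                c.guide, genome, table=table, max_mm=max_mm,
                ontarget=(c.start, c.strand),
            )
            spec = aggregate_offtarget_risk(hits)
        else:
            spec = 1.0
        loc = location_score(c, mechanism, gene)
        out.append(
            ScoredGuide(c, p_on, spec, loc, composite_score(p_on, spec, loc))
        )
    out.sort(key=_rank_key)
    return out


def design_single_crispri(
    gene: GeneModel,
    genome: GenomeSequence,
    model: TrainedModel,
    upstream_len: int = 1000,
    core_len_up: int = 100,
    core_len_down: int = 50,
    top_n: int = 20,
    table: MismatchWeightTable | None = None,
    max_mm: int = 3,
    check_offtargets: bool = True,
) -> DesignResult:
    """Single-guide CRISPRi design over the promoter window.

    Scans the interval from ``upstream_len`` bp upstream of the TSS through
    ``core_len_down`` bp into the gene (transcription orientation), scores
    every NGG candidate and returns the ``top_n`` by composite score.
    """
    if model.mechanism != "CRISPRi":
        raise ValueError("model is not a CRISPRi model")
    promoter, core = extract_promoter(
        gene, upstream_len, core_len_up, core_len_down, chrom_length=len(genome)
    )
    lo = min(promoter.start, core.start)
    hi = max(promoter.end, core.end)
    scan = Region(gene.chrom, max(0, lo - 0), min(len(genome), hi), gene.strand,
                  "promoter") if hi > lo else None
    result = DesignResult("CRISPRi", [], parameters={
        "upstream_len": upstream_len, "core_len_up": core_len_up,
        "core_len_down": core_len_down, "top_n": top_n, "max_mm": max_mm,
    })
    candidates = scan_pam_sites(genome, scan) if scan else []
    candidates = [
        assign_genomic_context(c, gene, promoter, core) for c in candidates
    ]
    if not candidates:
        result.diagnostics.append(
            f"gene {gene.gene_id}: no PAM candidates in promoter window"
        )
        return result
    scored = _score_candidates(
        candidates, "CRISPRi", gene, genome, model, table, max_mm, check_offtargets
    )
    result.entries = scored[:top_n]
    return result


def design_paired_crispko(
    gene: GeneModel,
    genome: GenomeSequence,
    model: TrainedModel,
    min_del: int = DEFAULT_MIN_DEL,
    max_del: int = DEFAULT_MAX_DEL,
    top_n: int = 20,
    table: MismatchWeightTable | None = None,
    max_mm: int = 3,
    check_offtargets: bool = True,
    preferred_band: tuple[int, int] = PREFERRED_BAND,
    penalty_per_bp: float = DISTANCE_PENALTY_PER_BP,
) -> DesignResult:
    """Paired-guide CRISPRko design over the gene body.

    Enumerates ordered candidate pairs (left cut upstream of right cut)
    with deletion size in [min_del, max_del]; the pair score is the mean of
    the two composites minus a linear penalty for deletion sizes outside
    the preferred band (zero inside it).
    """
    if model.mechanism != "CRISPRko":
        raise ValueError("model is not a CRISPRko model")
    body = Region(gene.chrom, gene.start, gene.end, gene.strand, "gene_body")
    candidates = [
        assign_genomic_context(c, gene)
        for c in scan_pam_sites(genome, body)
    ]
    candidates = [c for c in candidates if c.context == "gene_body"]
    result = DesignResult("CRISPRko", [], parameters={
        "min_del": min_del, "max_del": max_del, "top_n": top_n,
        "preferred_band": list(preferred_band),
        "penalty_per_bp": penalty_per_bp, "max_mm": max_mm,
    })
    if not candidates:
        result.diagnostics.append(f"gene {gene.gene_id}: no gene-body candidates")
        return result
    scored = _score_candidates(
        candidates, "CRISPRko", gene, genome, model, table, max_mm, check_offtargets
    )
    pairs: list[GuidePair] = []
    by_cut = sorted(scored, key=lambda s: s.candidate.cut_site)
    for i, left in enumerate(by_cut):
        for right in by_cut[i + 1 :]:
            d = right.candidate.cut_site - left.candidate.cut_site
            if d < min_del:
                continue
            if d > max_del:
                break
            penalty = 0.0
            if d < preferred_band[0]:
                penalty = penalty_per_bp * (preferred_band[0] - d)
            elif d > preferred_band[1]:
                penalty = penalty_per_bp * (d - preferred_band[1])
            pairs.append(
                GuidePair(
                    left, right, d,
                    (left.composite + right.composite) / 2.0 - penalty,
                )
            )
    if not pairs:
        result.diagnostics.append(
            f"gene {gene.gene_id}: no valid pair in [{min_del},{max_del}] bp; "
            f"{len(scored)} singleton candidates available"
        )
        result.parameters["singletons"] = [s.candidate.guide for s in scored[:top_n]]
        return result
    pairs.sort(
        key=lambda p: (-p.pair_composite, -max(p.left.p_on, p.right.p_on),
                       p.left.candidate.start)
    )
    result.entries = pairs[:top_n]
    return result


def write_design_tsv(result: DesignResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        if result.mechanism == "CRISPRi":
            fh.write(
                "guide\tpam\tchrom\tstart\tstrand\tcontext\t"
                "p_on\tspecificity\tlocation\tcomposite\n"
            )
            for sg in result.entries:
                c = sg.candidate
                fh.write(
                    f"{c.guide}\t{c.pam}\t{c.chrom}\t{c.start}\t{c.strand}\t"
                    f"{c.context}\t{sg.p_on:.4f}\t{sg.specificity:.4f}\t"
                    f"{sg.location:.4f}\t{sg.composite:.4f}\n"
                )
        else:
            fh.write(
                "left_guide\tleft_start\tright_guide\tright_start\tstrands\t"
                "deletion_size\tleft_composite\tright_composite\tpair_composite\n"
            )
            for p in result.entries:
                fh.write(
                    f"{p.left.candidate.guide}\t{p.left.candidate.start}\t"
                    f"{p.right.candidate.guide}\t{p.right.candidate.start}\t"
                    f"{p.left.candidate.strand}/{p.right.candidate.strand}\t"
                    f"{p.deletion_size}\t{p.left.composite:.4f}\t"
                    f"{p.right.composite:.4f}\t{p.pair_composite:.4f}\n"
                )


def write_design_bed(result: DesignResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        if result.mechanism == "CRISPRi":
            for sg in result.entries:
                c = sg.candidate
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.start + 20}\t{c.guide}\t"
                    f"{sg.composite:.4f}\t{c.strand}\n"
                )
        else:
            for p in result.entries:
                lo = p.left.candidate.start
                hi = p.right.candidate.start + 20
                fh.write(
                    f"{p.left.candidate.chrom}\t{lo}\t{hi}\t"
                    f"{p.left.candidate.guide}|{p.right.candidate.guide}\t"
                    f"{p.pair_composite:.4f}\t+\n"
                )
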