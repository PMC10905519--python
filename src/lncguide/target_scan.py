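"""Protospacer enumeration adjacent to NGG PAMs and genomic-context labelling.

Protospacer positions are numbered 1 (PAM-distal) .. 20 (PAM-proximal).
The SpCas9 blunt cut falls between protospacer positions 17 and 18, i.e.
3 bp 5' of the PAM; ``cut_site`` stores the genomic coordinate of the base
on the PAM side of that cut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from .genome_io import GeneModel, GenomeSequence, Region, reverse_complement

GUIDE_LEN = 20
PAM_LEN = 3

#: precedence for overlapping annotations, most mechanism-relevant first
CONTEXT_PRECEDENCE = ("core_promoter", "promoter", "gene_body", "downstream")


@dataclass(frozen=True)
class CandidateGuide:
    """A 20-nt protospacer with its NGG PAM and genomic placement.

    ``start`` is the genomic start of the protospacer (0-based half-open);
    the guide string is always given 5'->3' on the targeting strand, so for
    minus-strand candidates it is the reverse complement of the genomic
    plus-strand subsequence.
    """

    guide: str
    pam: str
    chrom: str
    start: int
    strand: str
    cut_site: int
    context: str = "intergenic"

    def __post_init__(self) -> None:
        if len(self.guide) != GUIDE_LEN:
            raise ValueError(f"protospacer must be {GUIDE_LEN} nt, got {len(self.guide)}")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")


def scan_pam_sites(
    seq: GenomeSequence, region: Region | None = None
) -> list[CandidateGuide]:
    """Enumerate all NGG-adjacent 20-mers on both strands.

    Candidates containing N anywhere in protospacer or PAM are discarded.
    Output order is deterministic: ascending genomic start, plus strand
    before minus at equal start. A window shorter than 23 nt yields an
    empty list.
    """
    s = seq.seq
    lo, hi = (region.start, region.end) if region is not None else (0, len(s))
    if not (0 <= lo <= hi <= len(s)):
        raise ValueError("region outside sequence bounds")
    out: list[CandidateGuide] = []
    for i in range(lo, hi - (GUIDE_LEN + PAM_LEN) + 1):
        # plus strand: protospacer [i, i+20), PAM [i+20, i+23) = NGG
        if s[i + 21 : i + 23] == "GG":
            guide = s[i : i + GUIDE_LEN]
            pam = s[i + GUIDE_LEN : i + GUIDE_LEN + PAM_LEN]
            if "N" not in guide and "N" not in pam:
                out.append(
                    CandidateGuide(guide, pam, seq.id, i, "+", cut_site=i + 17)
                )
        # minus strand: genomic CCN at [i, i+3), protospacer [i+3, i+23)
        if s[i : i + 2] == "CC":
            proto = s[i + PAM_LEN : i + PAM_LEN + GUIDE_LEN]
            pam_g = s[i : i + PAM_LEN]
            if "N" not in proto and "N" not in pam_g:
                out.append(
                    CandidateGuide(
                        reverse_complement(proto),
                        reverse_complement(pam_g),
                        seq.id,
                        i + PAM_LEN,
                        "-",
                        cut_site=i + PAM_LEN + 2,
                    )
                )
    out.sort(key=lambda c: (c.start, 0 if c.strand == "+" else 1))
    return out


def assign_genomic_context(
    c: CandidateGuide,
    gene: GeneModel,
    promoter: Region | None = None,
    core: Region | None = None,
    downstream: Region | None = None,
) -> CandidateGuide:
    """Label a candidate by cut-site membership with precedence
    core_promoter > promoter > gene_body > downstream > intergenic."""
    pos = c.cut_site
    if core is not None and core.chrom == c.chrom and core.contains(pos):
        label = "core_promoter"
    elif promoter is not None and promoter.chrom == c.chrom and promoter.contains(pos):
        label = "promoter"
    elif gene.chrom == c.chrom and gene.start <= pos < gene.end:
        label = "gene_body"
    elif downstream is not None and downstream.chrom == c.chrom and downstream.contains(pos):
        label = "downstream"
    else:
        label = "intergenic"
    return replace(c, context=label)


def write_candidates_bed(candidates: list[CandidateGuide], path: str | Path) -> None:
    """BED6 export: name = guide+PAM, score column is a 0 placeholder."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.start + GUIDE_LEN}\t"
                f"{c.guide}+{c.pam}\t0\t{c.strand}\n"
            )


def write_candidates_tsv(candidates: list[CandidateGuide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("guide\tpam\tchrom\tstart\tstrand\tcut_site\tcontext\n")
        for c in candidates:
            fh.write(
                f"{c.guide}\t{c.pam}\t{c.chrom}\t{c.start}\t{c.strand}\t"
                f"{c.cut_site}\t{c.context}\n"
            )
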