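"""Sequence and gene-model I/O with coordinate arithmetic.

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REGION_LABELS = ("core_promoter", "promoter", "gene_body", "downstream")


class GenomeIOError(ValueError):
    """Malformed sequence or annotation input."""


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase, map RNA U to T, and reject characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise GenomeIOError(
            f"record {record_id!r}: illegal characters {sorted(bad)} in sequence"
        )
    if not s:
        raise GenomeIOError(f"record {record_id!r}: empty sequence")
    return s


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}, always uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", sanitize_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand and transcription start site.

    ``tss`` is the genomic coordinate of the first transcribed base:
    ``start`` on the plus strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise GenomeIOError(
                f"gene {self.gene_id}: invalid interval [{self.start},{self.end})"
            )
        if self.tss == -1:
            object.__setattr__(
                self, "tss", self.start if self.strand == "+" else self.end - 1
            )
        if not (self.start <= self.tss < self.end):
            raise GenomeIOError(f"gene {self.gene_id}: tss outside gene interval")


@dataclass(frozen=True)
class Region:
    """A labelled genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise GenomeIOError(f"unknown region label {self.label!r}")
        if not self.start < self.end:
            raise GenomeIOError(
                f"region {self.label}: empty/inverted interval [{self.start},{self.end})"
            )
        if self.start < 0:
            raise GenomeIOError(f"region {self.label}: negative start {self.start}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA file; duplicate ids and empty files are errors."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records found")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise GenomeIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (involution, length preserving)."""
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise GenomeIOError(f"illegal characters {sorted(bad)} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


def _parse_gff3_row(line: str, lineno: int) -> GeneModel | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 9:
        raise GenomeIOError(f"GFF3 line {lineno}: expected 9 columns, got {len(fields)}")
    chrom, _source, _ftype, start, end, _score, strand, _phase, attrs = fields[:9]
    start1, end1 = int(start), int(end)
    if end1 < start1:
        raise GenomeIOError(f"GFF3 line {lineno}: end < start")
    gene_id = f"line{lineno}"
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv.startswith("ID="):
            gene_id = kv[3:]
            break
        if kv.startswith("gene_id="):
            gene_id = kv[8:]
    # GFF3 is 1-based inclusive -> 0-based half-open
    return GeneModel(gene_id, chrom, start1 - 1, end1, strand)


def _parse_bed_row(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise GenomeIOError(f"BED line {lineno}: need BED6 (6 columns)")
    chrom, start, end, name, _score, strand = fields[:6]
    return GeneModel(name, chrom, int(start), int(end), strand)


def read_annotation(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 or BED6, normalizing to 0-based half-open.

    Rows with ``end <= start`` or an unknown strand raise GenomeIOError with
    the offending line number.
    """
    if format not in ("gff3", "bed"):
        raise GenomeIOError(f"unknown annotation format {format!r}")
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if format == "gff3":
                model = _parse_gff3_row(line, lineno)
            else:
                model = _parse_bed_row(line, lineno)
            if model is not None:
                models.append(model)
    return models


def write_bed6(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n")


def extract_promoter(
    gene: GeneModel,
    upstream_len: int = 1000,
    core_len_up: int = 100,
    core_len_down: int = 50,
    chrom_length: int | None = None,
) -> tuple[Region, Region]:
    """Promoter and core-promoter windows around the TSS, in transcription
    orientation, clipped to chromosome bounds.

    The promoter spans ``[tss - upstream_len, tss)`` and the core promoter
    ``[tss - core_len_up, tss + core_len_down)``, both measured along the
    direction of transcription (so on the minus strand the promoter lies
    genomically downstream of the gene end).
    """
    if upstream_len <= 0:
        raise GenomeIOError("upstream_len must be positive (empty promoter rejected)")
    if not upstream_len >= core_len_up >= 0:
        raise GenomeIOError("require upstream_len >= core_len_up >= 0")
    tss = gene.tss
    if gene.strand == "+":
        prom = (tss - upstream_len, tss)
        core = (tss - core_len_up, tss + core_len_down)
    else:
        # transcription runs right->left; "upstream" is genomically rightward.
        prom = (tss + 1, tss + 1 + upstream_len)
        core = (tss + 1 - core_len_down, tss + 1 + core_len_up)
    bound = chrom_length if chrom_length is not None else float("inf")
    p_start, p_end = max(0, prom[0]), min(bound, prom[1])
    c_start, c_end = max(0, core[0]), min(bound, core[1])
    if p_start >= p_end or c_start >= c_end:
        raise GenomeIOError(
            f"gene {gene.gene_id}: promoter/core window empty after clipping"
        )
    return (
        Region(gene.chrom, int(p_start), int(p_end), gene.strand, "promoter"),
        Region(gene.chrom, int(c_start), int(c_end), gene.strand, "core_promoter"),
    )


def region_sequence(genome: GenomeSequence, region: Region) -> str:
    """Extract a region's sequence in transcription orientation."""
    s = genome.seq[region.start : region.end]
    return reverse_complement(s) if region.strand == "-" else s
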