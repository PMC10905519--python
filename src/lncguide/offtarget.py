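"""Off-target enumeration and CFD-style mismatch-weight scoring.

A potential off-target site is any PAM-adjacent (NGG or NAG) 20-mer within
a bounded Hamming distance of the guide. Each site is scored as the
product, over mismatched positions, of a position- and mismatch-type-
specific weight in [0,1], multiplied by a PAM weight — the cutting
frequency determination (CFD) scheme. Weights are read from a CSV table
(``position,rna,dna,weight``): positions 1 (PAM-distal) to 20
(PAM-proximal), rna in {A,C,G,U} (the guide base), dna the target-strand
base the guide faces (a match when dna is the Watson-Crick complement of
rna). PAM rows use position ``PAM`` with the motif in the ``rna`` column.

The bundled ``cfd_weights_synthetic.csv`` is a synthetic stand-in for the
published experimentally derived table (which cannot be redistributed
here): it encodes the established qualitative structure — near-complete
tolerance at PAM-distal positions falling to near-intolerance in the seed,
extra tolerance for rU:dG wobble pairings, NGG weight 1, NAG strongly
reduced, other PAMs inactive. A user holding the published supplement can
drop it in unchanged via the same schema.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

from .genome_io import GenomeSequence, reverse_complement
from .target_scan import GUIDE_LEN

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_OF_DNA = {"A": "A", "C": "C", "G": "G", "T": "U"}
_DATA_DIR = Path(__file__).parent / "data"

DEFAULT_PAM_WEIGHTS = {"NGG": 1.0, "NAG": 0.26, "other": 0.0}


class CFDTableError(ValueError):
    """Missing or malformed mismatch-weight table entries."""


@dataclass(frozen=True)
class MismatchWeightTable:
    """Complete map (position 1-20, rna base, target-strand dna base) ->
    weight for every non-complementary pairing, plus PAM motif weights."""

    weights: dict[tuple[int, str, str], float]
    pam_weights: dict[str, float]

    def __post_init__(self) -> None:
        for key in _all_mismatch_keys():
            if key not in self.weights:
                raise CFDTableError(f"mismatch weight missing for {key}")
        for key, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise CFDTableError(f"weight {w} for {key} outside [0,1]")
        if self.pam_weights.get("NGG") != 1.0:
            raise CFDTableError("NGG PAM weight must be 1.0")

    def mismatch_weight(self, position: int, rna: str, dna: str) -> float:
        try:
            return self.weights[(position, rna, dna)]
        except KeyError:
            raise CFDTableError(
                f"no weight for position {position}, r{rna}:d{dna}"
            ) from None

    def pam_weight(self, pam: str) -> float:
        p = pam.upper()
        if len(p) == 3 and p[1:] == "GG":
            return self.pam_weights["NGG"]
        if len(p) == 3 and p[1:] == "AG":
            return self.pam_weights["NAG"]
        return self.pam_weights["other"]


def _all_mismatch_keys():
    for pos in range(1, GUIDE_LEN + 1):
        for rna in "ACGU":
            for dna in "ACGT":
                # dna is the target-strand base; match when rna pairs with it
                if _RNA_OF_DNA[_COMP[dna]] == rna:
                    continue
                yield (pos, rna, dna)


def synthetic_cfd_table() -> MismatchWeightTable:
    """Synthetic stand-in mismatch-weight table (see module docstring).

    weight(p, r, d) = tolerance(p) * type_factor(r, d), where tolerance
    falls linearly from 0.9 at position 1 to 0.1 at position 20 and the
    type factor is 0.9 for the rU:dG wobble, 0.6 for rG:dA / rA:dC-like
    purine-purine/pyrimidine-pyrimidine apposition, 0.4 otherwise.
    """
    weights: dict[tuple[int, str, str], float] = {}
    purines_r, purines_d = set("AG"), set("AG")
    for pos, rna, dna in _all_mismatch_keys():
        tol = 0.9 - 0.8 * (pos - 1) / (GUIDE_LEN - 1)
        if (rna, dna) == ("U", "G"):
            f = 0.9
        elif (rna in purines_r) == (dna in purines_d):
            f = 0.6
        else:
            f = 0.4
        weights[(pos, rna, dna)] = round(tol * f, 4)
    return MismatchWeightTable(weights, dict(DEFAULT_PAM_WEIGHTS))


def uniform_toy_table(weight: float = 0.5) -> MismatchWeightTable:
    """Uniform-weight toy table for tests (every mismatch = ``weight``)."""
    return MismatchWeightTable(
        {k: weight for k in _all_mismatch_keys()}, dict(DEFAULT_PAM_WEIGHTS)
    )


def write_cfd_table(table: MismatchWeightTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "rna", "dna", "weight"])
        for (pos, rna, dna), wt in sorted(table.weights.items()):
            w.writerow([pos, rna, dna, wt])
        for motif, wt in table.pam_weights.items():
            w.writerow(["PAM", motif, "-", wt])


def read_cfd_table(path: str | Path) -> MismatchWeightTable:
    weights: dict[tuple[int, str, str], float] = {}
    pam: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["position", "rna", "dna", "weight"]:
            raise CFDTableError(f"{path}: bad header {reader.fieldnames}")
        for row in reader:
            if row["position"] == "PAM":
                pam[row["rna"]] = float(row["weight"])
            else:
                weights[(int(row["position"]), row["rna"], row["dna"])] = float(
                    row["weight"]
                )
    return MismatchWeightTable(weights, pam)


def load_default_table() -> MismatchWeightTable:
    return read_cfd_table(_DATA_DIR / "cfd_weights_synthetic.csv")


@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    start: int
    strand: str
    site_seq: str  # 20-nt protospacer + PAM on the targeting strand
    mismatch_list: tuple[tuple[int, str, str], ...]  # (position, guide base, site base)
    cfd: float


def cfd_score(
    guide: str, site_seq20: str, site_pam: str, table: MismatchWeightTable
) -> float:
    """Product of per-mismatch weights times the PAM weight; a perfect NGG
    match scores exactly 1.0. Raises on any missing table key."""
    g, s = guide.upper(), site_seq20.upper()
    if len(g) != GUIDE_LEN or len(s) != GUIDE_LEN:
        raise ValueError("guide and site must be 20 nt")
    score = table.pam_weight(site_pam)
    for i, (gb, sb) in enumerate(zip(g, s), start=1):
        if gb != sb:
            rna = _RNA_OF_DNA[gb]
            dna = _COMP[sb]  # base the guide RNA faces on the target strand
            score *= table.mismatch_weight(i, rna, dna)
    return score


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def enumerate_offtarget_sites(
    guide: str,
    genome: GenomeSequence,
    table: MismatchWeightTable | None = None,
    max_mm: int = 4,
    pams: tuple[str, ...] = ("NGG", "NAG"),
    ontarget: tuple[int, str] | None = None,
    include_ontarget: bool = False,
) -> list[OffTargetHit]:
    """Exhaustive scan for PAM-adjacent sites within ``max_mm`` mismatches.

    ``ontarget`` is the (start, strand) of the intended site, excluded from
    the hit list unless ``include_ontarget`` is set (used by tests to
    confirm the intended site scores 1.0).
    """
    if max_mm > 6:
        raise ValueError("max_mm must be <= 6")
    table = table or load_default_table()
    g = guide.upper()
    s = genome.seq
    tails = {p[1:] for p in pams}  # {"GG","AG"}
    rc_tails = {reverse_complement(t) for t in tails}  # e.g. {"CC","CT"}
    hits: list[OffTargetHit] = []

    def consider(proto: str, pam: str, start: int, strand: str) -> None:
        if "N" in proto or "N" in pam:
            return
        if _hamming(g, proto) > max_mm:
            return
        if not include_ontarget and ontarget is not None and (start, strand) == ontarget:
            return
        mm = tuple(
            (i + 1, g[i], proto[i]) for i in range(GUIDE_LEN) if g[i] != proto[i]
        )
        hits.append(
            OffTargetHit(genome.id, start, strand, proto + pam,
                         mm, cfd_score(g, proto, pam, table))
        )

    L = GUIDE_LEN + 3
    for i in range(len(s) - L + 1):
        if s[i + 21 : i + 23] in tails:
            consider(s[i : i + 20], s[i + 20 : i + 23], i, "+")
        if s[i : i + 2] in rc_tails:
            consider(
                reverse_complement(s[i + 3 : i + 23]),
                reverse_complement(s[i : i + 3]),
                i + 3,
                "-",
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def aggregate_offtarget_risk(hits: list[OffTargetHit], method: str = "inverse_sum") -> float:
    """Per-guide specificity in [0,1]: 1 with no hits, strictly decreasing
    as hits accumulate.

    ``inverse_sum`` (default): 1 / (1 + sum of CFD scores). ``mit_like``:
    100/(100 + 100*sum) — same shape, MIT-style scaling. ``max``:
    1 - max CFD.
    """
    total = sum(h.cfd for h in hits)
    if method == "inverse_sum":
        return 1.0 / (1.0 + total)
    if method == "mit_like":
        return 100.0 / (100.0 + 100.0 * total)
    if method == "max":
        return 1.0 - (max((h.cfd for h in hits), default=0.0))
    raise ValueError(f"unknown aggregation method {method!r}")


def write_hits_tsv(hits: list[OffTargetHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tstrand\tsite_seq\tn_mismatches\tmismatches\tcfd\n")
        for h in hits:
            mm = ";".join(f"{p}:{gb}>{sb}" for p, gb, sb in h.mismatch_list)
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.strand}\t{h.site_seq}\t"
                f"{len(h.mismatch_list)}\t{mm or '.'}\t{h.cfd:.6g}\n"
            )


def write_hits_bed(hits: list[OffTargetHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.start + GUIDE_LEN}\t"
                f"{h.site_seq}\t{h.cfd:.4f}\t{h.strand}\n"
            )
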