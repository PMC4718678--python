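"""Variant location and coding-effect annotation from GFF3 gene models.

Each variant receives exactly one location class with precedence
coding > 5'UTR > 3'UTR > intron > upstream/downstream > intergenic, where
upstream/downstream means within a configurable flank (default 5000 bp) of a
gene boundary, oriented by gene strand, and intergenic means farther than
the flank from every annotated gene.  Variants inside exons of non-coding
RNA genes are classed "coding" for cross-tab purposes.  Coding SNPs are
called synonymous or codon-change by strand-aware translation with the
standard genetic code; coding indels are frameshift when their length is not
a multiple of three, inframe-indel otherwise.

All coordinates are 1-based inclusive (GFF3 convention); a variant's
position is its first affected base, with deletions anchored at the first
deleted base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

LOCATION_PRECEDENCE = ("coding", "5'UTR", "3'UTR", "intron")

TRANSCRIPT_TYPES = ("mRNA", "transcript", "ncRNA", "lnc_RNA", "tRNA", "rRNA")

Interval = tuple[int, int]


@dataclass(frozen=True)
class Variant:
    """A biallelic variant anchored at its first affected base."""

    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"
    vtype: str = "SNP"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.vtype not in ("SNP", "indel"):
            raise ValueError("vtype must be 'SNP' or 'indel'")

    @property
    def span(self) -> Interval:
        """Affected reference interval (deletions cover the deleted bases)."""
        return self.pos, self.pos + max(len(self.ref) - 1, 0)


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


def _contains(intervals: Iterable[Interval], pos: int) -> bool:
    return any(a <= pos <= b for a, b in intervals)


def _derive_utrs(tx: Transcript) -> None:
    """Fill missing UTRs as the exonic stretches flanking the CDS."""
    if not tx.cds or (tx.utr5 or tx.utr3):
        return
    cds_start = min(a for a, _ in tx.cds)
    cds_end = max(b for _, b in tx.cds)
    left: list[Interval] = []
    right: list[Interval] = []
    for a, b in tx.exons:
        if a < cds_start:
            left.append((a, min(b, cds_start - 1)))
        if b > cds_end:
            right.append((max(a, cds_end + 1), b))
    if tx.strand == "+":
        tx.utr5, tx.utr3 = left, right
    else:
        tx.utr5, tx.utr3 = right, left


def read_gff3(path) -> list[GeneModel]:
    """Load gene models (gene -> transcripts -> exon/CDS/UTR) from GFF3."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type(("gene", "ncRNA_gene")):
        gene = GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            start=g.start, end=g.end,
        )
        for t in db.children(g, featuretype=TRANSCRIPT_TYPES, level=1):
            tx = Transcript(transcript_id=t.id, strand=t.strand)
            for child in db.children(t):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    tx.exons.append(iv)
                elif child.featuretype == "CDS":
                    tx.cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    tx.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    tx.utr3.append(iv)
            tx.exons.sort()
            tx.cds.sort()
            _derive_utrs(tx)
            gene.transcripts.append(tx)
        if not gene.transcripts:
            # bare gene with direct exon/CDS children
            tx = Transcript(transcript_id=g.id, strand=g.strand)
            for child in db.children(g):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    tx.exons.append(iv)
                elif child.featuretype == "CDS":
                    tx.cds.append(iv)
            tx.exons.sort()
            tx.cds.sort()
            _derive_utrs(tx)
            gene.transcripts.append(tx)
        genes.append(gene)
    return genes


def _class_within_gene(gene: GeneModel, pos: int) -> str:
    best = "intron"
    rank = {c: i for i, c in enumerate(LOCATION_PRECEDENCE)}
    for tx in gene.transcripts:
        if _contains(tx.cds, pos):
            cls = "coding"
        elif not tx.is_coding and _contains(tx.exons, pos):
            cls = "coding"  # ncRNA exon counts as coding in the cross-tab
        elif _contains(tx.utr5, pos):
            cls = "5'UTR"
        elif _contains(tx.utr3, pos):
            cls = "3'UTR"
        else:
            cls = "intron"
        if rank[cls] < rank[best]:
            best = cls
    return best


def _flank_side(gene: GeneModel, pos: int) -> tuple[int, str]:
    """(distance to nearest gene boundary, 'upstream'/'downstream')."""
    if pos < gene.start:
        dist = gene.start - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = pos - gene.end
        side = "downstream" if gene.strand == "+" else "upstream"
    return dist, side


def classify_location(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    flank: int = 5000,
) -> tuple[str, str | None, int]:
    """Location class, nearest gene and distance (0 inside a gene).

    Overlapping genes resolve to the highest-precedence class across genes.
    A variant within the flank of several genes follows the nearer gene; on
    an exact tie the upstream assignment wins.  Variants on a chromosome
    absent from the models are intergenic (with a warning).
    """
    pos = variant.pos
    on_chrom = [g for g in gene_models if g.chrom == variant.chrom]
    if not on_chrom:
        logger.debug("no gene models on %s; %s:%d classed intergenic",
                     variant.chrom, variant.chrom, pos)
        return "intergenic", None, -1
    inside = [g for g in on_chrom if g.start <= pos <= g.end]
    if inside:
        rank = {c: i for i, c in enumerate(LOCATION_PRECEDENCE)}
        best_gene = min(inside, key=lambda g: rank[_class_within_gene(g, pos)])
        return _class_within_gene(best_gene, pos), best_gene.gene_id, 0
    candidates = []
    for g in on_chrom:
        dist, side = _flank_side(g, pos)
        if dist <= flank:
            candidates.append((dist, 0 if side == "upstream" else 1, side, g))
    if candidates:
        dist, _, side, gene = min(candidates, key=lambda c: (c[0], c[1]))
        return side, gene.gene_id, dist
    dist, _, gene = min(((_flank_side(g, pos)[0], i, g) for i, g in enumerate(on_chrom)))
    return "intergenic", gene.gene_id, dist


def _coding_sequence(tx: Transcript, chrom_seq: str) -> str:
    parts = [chrom_seq[a - 1:b] for a, b in tx.cds]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _coding_offset(tx: Transcript, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS."""
    offset = 0
    for a, b in tx.cds:
        if a <= pos <= b:
            offset += pos - a
            if tx.strand == "-":
                total = sum(e - s + 1 for s, e in tx.cds)
                return total - 1 - offset
            return offset
        offset += b - a + 1
    return None


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def classify_effect(
    variant: Variant,
    transcript: Transcript,
    reference_seq: str,
) -> str:
    """Coding effect of a variant overlapping a transcript's CDS.

    SNP -> "synonymous" or "codon-change"; indel -> "frameshift" (length not
    a multiple of 3) or "inframe-indel".  A variant whose affected span
    crosses a CDS-interval boundary is classed "other".  For non-coding
    transcripts the exons stand in for the CDS with the frame anchored at
    the first exon base.
    """
    regions = transcript.cds if transcript.is_coding else transcript.exons
    if not regions:
        raise ValueError("transcript has neither CDS nor exons")
    span = variant.span
    within = [r for r in regions if r[0] <= span[0] and span[1] <= r[1]]
    if not within:
        if any(a <= span[0] <= b or a <= span[1] <= b for a, b in regions):
            logger.warning("variant %s:%d spans a coding-interval boundary",
                           variant.chrom, variant.pos)
            return "other"
        raise ValueError("variant does not overlap the transcript's coding regions")
    if variant.vtype == "indel":
        shift = abs(len(variant.ref) - len(variant.alt))
        if shift == 0:
            raise ValueError("indel with equal-length alleles")
        return "frameshift" if shift % 3 else "inframe-indel"
    work = Transcript(transcript.transcript_id, transcript.strand,
                      exons=sorted(transcript.exons), cds=sorted(regions))
    cds_seq = _coding_sequence(work, reference_seq)
    offset = _coding_offset(work, variant.pos)
    alt = variant.alt if transcript.strand == "+" else variant.alt.translate(COMPLEMENT)
    codon_idx, in_codon = divmod(offset, 3)
    codon = cds_seq[codon_idx * 3:codon_idx * 3 + 3]
    if len(codon) < 3:
        return "other"  # truncated terminal codon
    mutated = codon[:in_codon] + alt + codon[in_codon + 1:]
    if str(Seq(codon).translate()) == str(Seq(mutated).translate()):
        return "synonymous"
    return "codon-change"


def nearby_gene_report(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    window: int = 5000,
) -> list[tuple[str, int]]:
    """Genes with a boundary within ``window`` bp, with signed distances.

    Distance is measured to the nearest gene boundary; the sign follows gene
    orientation (negative = variant upstream of the gene, positive =
    downstream, 0 = inside the gene span).  Sorted by absolute distance.
    """
    report: list[tuple[str, int]] = []
    for g in gene_models:
        if g.chrom != variant.chrom:
            continue
        if g.start <= variant.pos <= g.end:
            report.append((g.gene_id, 0))
            continue
        dist, side = _flank_side(g, variant.pos)
        if dist <= window:
            report.append((g.gene_id, -dist if side == "upstream" else dist))
    return sorted(report, key=lambda r: abs(r[1]))


def annotate_variants(
    variants: Iterable[Variant],
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str] | None = None,
    flank: int = 5000,
) -> list[dict]:
    """Location class (and coding effect where applicable) for each variant."""
    gene_by_id = {g.gene_id: g for g in gene_models}
    known_chroms = {g.chrom for g in gene_models}
    warned: set[str] = set()
    rows = []
    for v in variants:
        if v.chrom not in known_chroms and v.chrom not in warned:
            logger.warning("no gene models on %s; its variants are intergenic",
                           v.chrom)
            warned.add(v.chrom)
        loc, gene_id, dist = classify_location(v, gene_models, flank=flank)
        effect = "none"
        if loc == "coding" and reference is not None and gene_id is not None:
            for tx in gene_by_id[gene_id].transcripts:
                regions = tx.cds if tx.is_coding else tx.exons
                if _contains(regions, v.pos):
                    effect = classify_effect(v, tx, reference[v.chrom])
                    break
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "vtype": v.vtype, "location": loc, "nearest_gene": gene_id,
            "distance": dist, "effect": effect,
        })
    return rows
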