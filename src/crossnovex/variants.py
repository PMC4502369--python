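"""Variant quality filtering, genomic-region classification and coding
consequences.

Quality filtering keeps variants with read depth > 5, genotype quality
> 20 and site quality > 80, all strict.  Region classification assigns
each SNV one class per overlapping gene — coding, splicing (within the
splice window of an intron boundary, 2 bp by default), UTR5/UTR3,
intronic, or strand-aware upstream/downstream within a flank of the gene
— and resolves multiple genes by precedence tier
(coding/splicing > UTR > intronic > up/downstream), joining distinct
classes of the winning tier into combined classes such as
``downstream+upstream``.

Consequence calling translates the reference and alternate codon
strand-aware.  A lost stop extends translation into the 3' UTR; the
extension annotation ``ext*N`` records the 1-based index of the first
in-frame downstream stop (``ext*?`` when the UTR contains none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import hgvs
from .genome import AnnotatedGenome, GeneModel, revcomp

GENOTYPES = ("hom_ref", "het", "hom_alt")

_TIERS = (
    ("coding", "splicing"),
    ("UTR5", "UTR3"),
    ("intronic",),
    ("upstream", "downstream"),
)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with genotype and quality annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "het"
    dp: int = 0
    gq: int = 0
    qual: float = 0.0
    qd: float | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide alleles are supported")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.dp < 0 or self.gq < 0 or self.qual < 0:
            raise ValueError("DP/GQ/QUAL must be nonnegative")


def filter_variants(
    variants: Iterable[VariantRecord],
    min_dp: int = 5,
    min_gq: int = 20,
    min_qual: float = 80.0,
) -> list[VariantRecord]:
    """Quality filter; every threshold is strict (DP of exactly 5 fails)."""
    return [
        v
        for v in variants
        if v.dp > min_dp and v.gq > min_gq and v.qual > min_qual
    ]


# ------------------------------------------------------- region classes


def _classify_for_gene(
    pos: int, gene: GeneModel, flank: int, splice_window: int
) -> str | None:
    span = gene.gene_span
    if span[0] <= pos <= span[1]:
        if any(lo <= pos <= hi for lo, hi in gene.cds):
            return "coding"
        for lo, hi in gene.introns:
            if lo <= pos <= hi:
                near_boundary = pos - lo < splice_window or hi - pos < splice_window
                return "splicing" if near_boundary else "intronic"
        if any(lo <= pos <= hi for lo, hi in gene.utr5):
            return "UTR5"
        if any(lo <= pos <= hi for lo, hi in gene.utr3):
            return "UTR3"
        # exonic but neither CDS nor annotated UTR: place by side of the CDS
        if gene.cds:
            before_cds = pos < gene.cds[0][0]
            if gene.strand == "+":
                return "UTR5" if before_cds else "UTR3"
            return "UTR3" if before_cds else "UTR5"
        return "intronic"  # non-coding gene body
    if span[0] - flank <= pos < span[0]:
        return "upstream" if gene.strand == "+" else "downstream"
    if span[1] < pos <= span[1] + flank:
        return "downstream" if gene.strand == "+" else "upstream"
    return None


def classify_region(
    variant: VariantRecord,
    annotation: Sequence[GeneModel],
    flank: int = 1000,
    splice_window: int = 2,
    known_chroms: Iterable[str] | None = None,
) -> str:
    """Region class of a variant against a gene-model set.

    Returns one class token, or a ``+``-joined combination when genes of
    the winning precedence tier disagree (e.g. ``downstream+upstream``
    between two flanking genes, ``UTR3+UTR5`` inside overlapping UTRs).
    """
    if known_chroms is not None and variant.chrom not in set(known_chroms):
        raise KeyError(f"unknown chromosome {variant.chrom!r}")
    per_gene = {
        klass
        for gene in annotation
        if gene.chrom == variant.chrom
        and (klass := _classify_for_gene(variant.pos, gene, flank, splice_window))
    }
    if not per_gene:
        return "intergenic"
    for tier in _TIERS:
        found = sorted(per_gene & set(tier), key=str.lower)
        if found:
            return "+".join(found)
    raise AssertionError("unreachable: class outside precedence tiers")


# -------------------------------------------------- coding consequences


@dataclass(frozen=True)
class Consequence:
    """Coding effect of an SNV with its HGVS rendering."""

    effect: str  # synonymous | nonsynonymous | stopgain | stoploss | unknown
    hgvs_c: str
    hgvs_p: str
    codon: int
    ext_length: int | str | None = None  # stoploss only; "?" if undetermined
    gene_id: str | None = None


def call_consequence_cds(
    cds_seq: str,
    utr3_seq: str,
    cds_pos: int,
    alt_base: str,
    gene_id: str | None = None,
) -> Consequence:
    """Consequence of substituting ``alt_base`` at CDS position ``cds_pos``.

    ``cds_seq`` runs 5'->3' on the coding strand, stop codon included;
    ``utr3_seq`` continues immediately after it.  The CDS should start
    with ATG, end with a stop and have length divisible by 3 — violations
    warn and the call proceeds best-effort.
    """
    cds_seq = cds_seq.upper()
    utr3_seq = utr3_seq.upper()
    if not 1 <= cds_pos <= len(cds_seq):
        raise ValueError(f"CDS position {cds_pos} outside 1..{len(cds_seq)}")
    if len(cds_seq) % 3:
        warnings.warn("CDS length not divisible by 3; frame read from base 1",
                      stacklevel=2)
    elif not cds_seq.startswith("ATG") or cds_seq[-3:] not in hgvs.STOP_CODONS:
        warnings.warn("CDS lacks start and/or terminal stop codon", stacklevel=2)
    codon_no, offset = hgvs.codon_index(cds_pos)
    codon_start = 3 * (codon_no - 1)
    ref_codon = cds_seq[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError("variant codon truncated by CDS end")
    alt_codon = ref_codon[:offset] + alt_base.upper() + ref_codon[offset + 1 :]
    ref_aa = hgvs.translate_codon(ref_codon)
    alt_aa = hgvs.translate_codon(alt_codon)
    hgvs_c = hgvs.format_hgvs_c(cds_pos, ref_codon[offset], alt_base)
    ext: int | str | None = None
    if ref_aa == alt_aa:
        effect = "synonymous"
        hgvs_p = hgvs.format_hgvs_p(ref_aa, codon_no, alt_aa)
    elif alt_aa == "*":
        effect = "stopgain"
        hgvs_p = hgvs.format_hgvs_p(ref_aa, codon_no, "*")
    elif ref_aa == "*":
        effect = "stoploss"
        downstream = cds_seq[codon_start + 3 :] + utr3_seq
        ext = _extension_length(downstream)
        hgvs_p = hgvs.format_hgvs_p("*", codon_no, alt_aa, ext)
        if ext is None:
            ext = "?"
    else:
        effect = "nonsynonymous"
        hgvs_p = hgvs.format_hgvs_p(ref_aa, codon_no, alt_aa)
    return Consequence(
        effect=effect, hgvs_c=hgvs_c, hgvs_p=hgvs_p, codon=codon_no,
        ext_length=ext, gene_id=gene_id,
    )


def _extension_length(downstream: str) -> int | None:
    """1-based index of the first in-frame stop in the read-through frame."""
    for i in range(0, len(downstream) - 2, 3):
        if downstream[i : i + 3] in hgvs.STOP_CODONS:
            return i // 3 + 1
    return None


# -------------------------------------------- genomic coordinate mapping


@dataclass
class CodingContext:
    """Strand-aware CDS + 3' UTR of one gene, with coordinate mapping."""

    gene: GeneModel
    cds_seq: str
    utr3_seq: str
    _cds_positions: list[int] = field(repr=False, default_factory=list)

    @classmethod
    def from_gene(cls, gene: GeneModel, genome: AnnotatedGenome) -> "CodingContext":
        if not gene.cds:
            raise ValueError(f"gene {gene.gene_id} has no CDS annotation")
        positions = [
            p for lo, hi in gene.cds for p in range(lo, hi + 1)
        ]
        cds_seq = "".join(genome.fetch(gene.chrom, lo, hi) for lo, hi in gene.cds)
        utr3_seq = "".join(
            genome.fetch(gene.chrom, lo, hi) for lo, hi in gene.utr3
        )
        if gene.strand == "-":
            positions = positions[::-1]
            cds_seq = revcomp(cds_seq)
            utr3_seq = revcomp(utr3_seq)
        return cls(gene=gene, cds_seq=cds_seq, utr3_seq=utr3_seq,
                   _cds_positions=positions)

    def cds_position(self, genomic_pos: int) -> int | None:
        try:
            return self._cds_positions.index(genomic_pos) + 1
        except ValueError:
            return None


def call_consequence(
    variant: VariantRecord,
    gene: GeneModel,
    genome: AnnotatedGenome,
) -> Consequence:
    """Genomic-coordinate consequence call (strand-aware allele handling)."""
    context = CodingContext.from_gene(gene, genome)
    cds_pos = context.cds_position(variant.pos)
    if cds_pos is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} is outside the CDS of "
            f"{gene.gene_id}; use classify_region for non-coding classes"
        )
    ref, alt = variant.ref, variant.alt
    if gene.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    expected = context.cds_seq[cds_pos - 1]
    if expected != ref.upper():
        warnings.warn(
            f"reference allele {variant.ref} disagrees with CDS base "
            f"{expected} at c.{cds_pos} of {gene.gene_id}",
            stacklevel=2,
        )
    return call_consequence_cds(
        context.cds_seq, context.utr3_seq, cds_pos, alt, gene_id=gene.gene_id
    )


# ------------------------------------------------------------ DE join


def intersect_with_de(
    annotated: Sequence[tuple[VariantRecord, Consequence]],
    de_results: pd.DataFrame,
) -> pd.DataFrame:
    """Nonsynonymous variants inside differentially expressed genes.

    ``de_results`` is a :func:`crossnovex.de.call_de` frame indexed by
    gene id.  Returns one row per nonsynonymous variant in a DE gene,
    labeled ``up_in_a``/``up_in_b`` by the sign of the gene's log2FC.
    """
    rows = []
    de = de_results[de_results.get("is_de", pd.Series(dtype=bool))]
    for variant, consequence in annotated:
        if consequence.effect != "nonsynonymous" or consequence.gene_id is None:
            continue
        if consequence.gene_id not in de.index:
            continue
        direction = "up_in_a" if de.loc[consequence.gene_id, "log2fc"] > 0 else "up_in_b"
        rows.append(
            (variant.chrom, variant.pos, variant.ref, variant.alt,
             consequence.gene_id, consequence.hgvs_p, direction)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene_id", "hgvs_p", "group"],
    )


# ---------------------------------------------------------------- VCF io


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF (QUAL column, FORMAT DP/GQ)."""
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue
            alt = rec.alts[0]
            if len(rec.ref) != 1 or len(alt) != 1:
                continue
            sample = rec.samples[0] if rec.samples else None
            gt = tuple(sample["GT"]) if sample else (0, 1)
            genotype = (
                "hom_ref" if gt == (0, 0)
                else "hom_alt" if gt == (1, 1)
                else "het"
            )
            qd = rec.info.get("QD")
            variants.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    genotype=genotype,
                    dp=int(sample["DP"]) if sample and "DP" in sample else 0,
                    gq=int(sample["GQ"]) if sample and "GQ" in sample else 0,
                    qual=float(rec.qual or 0.0),
                    qd=float(qd) if qd is not None else None,
                    id=rec.id,
                )
            )
    return variants


def write_vcf(
    variants: Sequence[VariantRecord],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write biallelic SNVs as VCF v4.2 with DP/GQ genotype fields."""
    gt_codes = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        handle.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom, length in (contigs or {}).items():
            handle.write(f"##contig=<ID={chrom},length={length}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = f"QD={v.qd:g}" if v.qd is not None else "."
            handle.write(
                f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t"
                f"{v.qual:g}\t.\t{info}\tGT:DP:GQ\t"
                f"{gt_codes[v.genotype]}:{v.dp}:{v.gq}\n"
            )


def consequences_to_frame(
    annotated: Sequence[tuple[VariantRecord, str, Consequence | None]],
) -> pd.DataFrame:
    """Summary table: one row per variant with class, gene and HGVS columns."""
    rows = []
    for variant, region_class, consequence in annotated:
        rows.append(
            {
                "Chr": variant.chrom,
                "Position": variant.pos,
                "Identifier": variant.id or "?",
                "Ref/Alt": f"{variant.ref}/{variant.alt}",
                "DP": variant.dp,
                "QD": variant.qd,
                "Quality": variant.qual,
                "Classification": region_class,
                "Gene": consequence.gene_id if consequence else "",
                "HGVS Coding": consequence.hgvs_c if consequence else "",
                "HGVS Protein": consequence.hgvs_p if consequence else "",
                "Effect": consequence.effect if consequence else "",
            }
        )
    return pd.DataFrame(rows)
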