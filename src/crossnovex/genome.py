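"""Genomes, gene models and their FASTA/GTF serialization.

Coordinates are 1-based inclusive throughout (GTF native).  A
:class:`GeneModel` stores the union of its exons; introns are the gaps
between consecutive union-exons, so exons and introns tile the gene span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of closed intervals: sorted, overlapping/adjacent runs merged.

    Adjacency (end + 1 == next start) merges, since the closed intervals
    cover contiguous bases.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [ivs[0]]
    for start, end in ivs[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def derive_introns(exons: Sequence[Interval], gene_span: Interval) -> list[Interval]:
    """Gaps between union-exons inside ``gene_span``.

    Exons are unioned first, so overlapping exon records collapse before
    gaps are measured; a single-exon gene has no introns.  An exon falling
    outside the span is a modelling error and raises ``ValueError``.
    """
    union = merge_intervals(exons)
    for exon in union:
        if not contains(gene_span, exon):
            raise ValueError(f"exon {exon} outside gene span {gene_span}")
    introns = []
    for (_, left_end), (right_start, _) in zip(union, union[1:]):
        if right_start > left_end + 1:
            introns.append((left_end + 1, right_start - 1))
    return introns


@dataclass
class GeneModel:
    """A gene with exon structure and optional CDS/UTR sub-annotation.

    ``exons`` are stored as their sorted union.  ``gene_span`` defaults to
    the hull of the exons, which guarantees exons and introns tile it.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    gene_span: Interval | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = merge_intervals(self.exons)
        hull = (self.exons[0][0], self.exons[-1][1])
        if self.gene_span is None:
            self.gene_span = hull
        elif not contains(self.gene_span, hull):
            raise ValueError(f"gene {self.gene_id}: exons exceed declared span")
        self.cds = merge_intervals(self.cds)
        self.utr5 = merge_intervals(self.utr5)
        self.utr3 = merge_intervals(self.utr3)

    @property
    def introns(self) -> list[Interval]:
        return derive_introns(self.exons, self.gene_span)

    @property
    def span(self) -> Interval:
        return self.gene_span


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus gene annotation."""

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    name: str = "genome"

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the closed interval [start, end] on ``chrom``."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        return seq[start - 1 : end]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return [g for g in self.genes if g.chrom == chrom]

    # ------------------------------------------------------------------ io
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gtf(self, path: str | Path) -> None:
        write_gtf(self.genes, path, source=self.name)

    @classmethod
    def from_files(
        cls, fasta: str | Path, gtf: str | Path | None = None, name: str = "genome"
    ) -> "AnnotatedGenome":
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        genes = read_gtf(gtf) if gtf is not None else []
        return cls(chromosomes=chroms, genes=genes, name=name)


# ---------------------------------------------------------------------- GTF

_FEATURE_FIELDS = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
}


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "crossnovex") -> None:
    with open(path, "w") as handle:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}";'
            rows: list[tuple[str, Interval]] = [("gene", gene.gene_span)]
            for feature, attr in _FEATURE_FIELDS.items():
                rows.extend((feature, iv) for iv in getattr(gene, attr))
            for feature, (start, end) in rows:
                handle.write(
                    f"{gene.chrom}\t{source}\t{feature}\t{start}\t{end}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (gene/exon/CDS/UTR features, ``gene_id`` attr).

    Parsing is delegated to :func:`pyranges.read_gtf`; pyranges stores
    0-based half-open starts, so starts gain 1 on conversion back to the
    1-based closed intervals used here.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if "gene_id" not in df.columns:
        raise ValueError(f"GTF {path} lacks gene_id attributes")
    per_gene: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        rec = per_gene.setdefault(
            row.gene_id,
            {"chrom": str(row.Chromosome), "strand": str(row.Strand),
             "exons": [], "cds": [], "utr5": [], "utr3": [], "span": None},
        )
        iv = (int(row.Start) + 1, int(row.End))
        if row.Feature == "gene":
            rec["span"] = iv
        elif row.Feature in _FEATURE_FIELDS:
            rec[_FEATURE_FIELDS[row.Feature]].append(iv)
    genes = []
    for gene_id, rec in per_gene.items():
        exons = rec["exons"] or ([rec["span"]] if rec["span"] else [])
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
                cds=rec["cds"],
                utr5=rec["utr5"],
                utr3=rec["utr3"],
                gene_span=rec["span"],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.gene_span[0], g.gene_id))
    return genes
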