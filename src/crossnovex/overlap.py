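"""Classify homology hits against target gene annotation.

Each hit interval is placed into exactly one of four classes:

* ``exonic`` — completely contained in a single union-exon;
* ``intronic`` — completely contained in a single intron;
* ``partial_exonic`` — overlaps >=1 bp of exon without complete inclusion
  (exon-intron straddles and overhangs past gene ends);
* ``intergenic`` — overlaps no gene span.

Strand is ignored: a conserved segment is evidence wherever it lands.
When a hit is simultaneously inside an exon of one gene and an intron of
an overlapping gene, the exonic call wins (exonic evidence is what feeds
the differential-expression step).  Hits spanning several genes carry a
``multi_gene`` flag and report the first gene by coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import GeneModel, contains, overlaps
from .homology import HomologyHit

CLASSES = ("exonic", "intronic", "partial_exonic", "intergenic")


@dataclass(frozen=True)
class HitClass:
    hit: HomologyHit
    klass: str
    gene_id: str | None = None
    multi_gene: bool = False

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if (self.klass == "intergenic") != (self.gene_id is None):
            raise ValueError("gene_id present iff hit is genic")


def classify_hit(
    hit: HomologyHit,
    annotation: Sequence[GeneModel],
    known_chroms: Iterable[str] | None = None,
) -> HitClass:
    """Assign the hit its annotation class (see module docstring).

    ``annotation`` is the gene set of the hit's target species;
    ``known_chroms`` (when given) validates the hit's chromosome name.
    """
    if known_chroms is not None and hit.target_chrom not in set(known_chroms):
        raise KeyError(f"hit on unknown chromosome {hit.target_chrom!r}")
    iv = hit.interval
    touching = [
        g
        for g in annotation
        if g.chrom == hit.target_chrom and overlaps(g.gene_span, iv)
    ]
    if not touching:
        return HitClass(hit=hit, klass="intergenic", gene_id=None)
    touching.sort(key=lambda g: (g.gene_span[0], g.gene_id))
    multi = len({g.gene_id for g in touching}) > 1
    for gene in touching:
        if any(contains(exon, iv) for exon in gene.exons):
            return HitClass(hit=hit, klass="exonic", gene_id=gene.gene_id,
                            multi_gene=multi)
    for gene in touching:
        if any(contains(intron, iv) for intron in gene.introns):
            return HitClass(hit=hit, klass="intronic", gene_id=gene.gene_id,
                            multi_gene=multi)
    # exon bases touched -> partial; genic but exon-free (possible only when a
    # declared span exceeds the exon hull) falls back to intronic
    first = touching[0]
    if any(
        overlaps(exon, iv) for gene in touching for exon in gene.exons
    ):
        return HitClass(hit=hit, klass="partial_exonic", gene_id=first.gene_id,
                        multi_gene=multi)
    return HitClass(hit=hit, klass="intronic", gene_id=first.gene_id,
                    multi_gene=multi)


def classify_hits(
    hits: Sequence[HomologyHit],
    annotations: dict[str, Sequence[GeneModel]],
) -> list[HitClass]:
    """Classify hits per species; ``annotations`` maps species -> genes."""
    out = []
    for hit in hits:
        genes = annotations.get(hit.target_species)
        if genes is None:
            raise KeyError(f"no annotation for species {hit.target_species!r}")
        out.append(classify_hit(hit, genes))
    return out


def class_counts(classified: Sequence[HitClass]) -> dict[str, int]:
    counts = {klass: 0 for klass in CLASSES}
    for hc in classified:
        counts[hc.klass] += 1
    return counts


def classified_to_frame(classified: Sequence[HitClass]) -> pd.DataFrame:
    from .homology import hits_to_frame

    df = hits_to_frame([hc.hit for hc in classified])
    df["klass"] = [hc.klass for hc in classified]
    df["gene_id"] = [hc.gene_id or "" for hc in classified]
    df["multi_gene"] = [hc.multi_gene for hc in classified]
    return df


def write_classified(classified: Sequence[HitClass], path: str | Path) -> None:
    classified_to_frame(classified).to_csv(path, sep="\t", index=False)
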