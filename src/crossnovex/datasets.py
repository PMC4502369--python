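"""Bundled worked examples.

``STOP_VARIANTS`` is a curated set of fifteen stop-affecting coding SNVs
observed in pig (Sus scrofa) testis/oviduct transcriptomes — eight gained
and seven lost stop codons — with their published HGVS coding and protein
renderings.  They serve as end-to-end worked examples for the consequence
caller: :func:`crossnovex.hgvs.build_context` reconstructs a minimal CDS
consistent with each row, and the caller must reproduce the printed
classification, codon index and extension length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class StopVariantRow:
    chrom: str
    pos: int
    identifier: str | None
    ref: str
    alt: str
    dp: int
    qd: int
    qual: int
    classification: str  # Stopgain | Stoploss
    gene: str
    exon: int
    hgvs_c: str
    hgvs_p: str


STOP_VARIANTS: tuple[StopVariantRow, ...] = (
    StopVariantRow("2", 77952555, None, "G", "A", 13, 19, 165, "Stopgain",
                   "DAZAP1", 5, "c.304C>T", "p.Gln102*"),
    StopVariantRow("4", 107810302, None, "C", "A", 46, 26, 1723, "Stopgain",
                   "MCL1", 2, "c.92C>A", "p.Ser31*"),
    StopVariantRow("7", 58576014, None, "G", "T", 38, 6, 248, "Stopgain",
                   "UNC45A", 18, "c.2320G>T", "p.Glu774*"),
    StopVariantRow("13", 1095554, None, "G", "A", 13, 8, 102, "Stopgain",
                   "ASTE1", 4, "c.146G>A", "p.Trp49*"),
    StopVariantRow("14", 33232916, None, "T", "A", 19, 8, 166, "Stopgain",
                   "P2RX4", 13, "c.1084A>T", "p.Lys362*"),
    StopVariantRow("14", 53029449, None, "A", "T", 129, 5, 784, "Stopgain",
                   "SNRPD3", 2, "c.22A>T", "p.Lys8*"),
    StopVariantRow("14", 122996299, None, "C", "A", 16, 6, 96, "Stopgain",
                   "PPRC1", 5, "c.1442C>A", "p.Ser481*"),
    StopVariantRow("16", 42659625, None, "C", "T", 13, 8, 105, "Stopgain",
                   "ERCC8", 4, "c.321G>A", "p.Trp107*"),
    StopVariantRow("7", 123586577, None, "T", "A", 11, 21, 254, "Stoploss",
                   "DICER1", 22, "c.4697A>T", "p.*1566Leuext*?"),
    StopVariantRow("8", 124953125, None, "A", "T", 14, 28, 391, "Stoploss",
                   "PPA2", 5, "c.332A>T", "p.*111Leuext*22"),
    StopVariantRow("14", 12523156, "rs81212863", "A", "G", 155, 32, 5198,
                   "Stoploss", "CLU", 3, "c.124T>C", "p.*42Argext*13"),
    StopVariantRow("14", 41268275, None, "A", "C", 40, 29, 1542, "Stoploss",
                   "OAS1", 6, "c.1076A>C", "p.*359Serext*8"),
    StopVariantRow("14", 88489098, "rs196953202", "T", "C", 49, 20, 671,
                   "Stoploss", "ANXA11", 13, "c.1324T>C", "p.*442Argext*10"),
    StopVariantRow("16", 65096704, None, "A", "C", 12, 28, 335, "Stoploss",
                   "MAT2B", 7, "c.976T>G", "p.*326Glyext*11"),
    StopVariantRow("X", 141373463, None, "T", "G", 94, 18, 2304, "Stoploss",
                   "CETN2", 6, "c.477A>C", "p.*159Cysext*22"),
)


def stop_variants_frame() -> pd.DataFrame:
    """The curated stop-variant table as a DataFrame."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(row) for row in STOP_VARIANTS])
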