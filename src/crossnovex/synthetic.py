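"""Synthetic fixtures with planted ground truth.

The generator emulates the inputs of a two-tissue (testis vs oviduct)
transcriptome study in a query species whose genome carries unannotated
transcribed segments:

* a query genome with annotated coding genes (exon/CDS/UTR structure)
  plus planted intergenic "novel segments";
* one or more target-species genomes, each carrying a copy of every
  segment — mutated by a per-base substitution probability — placed
  completely inside an exon, completely inside an intron, or
  intergenically, on either strand;
* negative-binomial count matrices with planted tissue-specific
  differential expression at two samples per group;
* coding variants with known region classes and consequences
  (synonymous, missense, stopgain, stoploss with finite extension and
  stoploss with no downstream in-frame stop), with quality values
  straddling the published DP/GQ/QUAL filter thresholds.

Mutations are substitutions only, so identity ratios and window
similarities have an exact binomial oracle.  Base composition is uniform
over A/C/G/T.  All randomness derives from ``FixtureConfig.seed`` through
named ``numpy`` child seeds, making outputs byte-identical per seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import FixtureConfig
from .expression import CountMatrix, TranscriptRecord, compute_fpkm
from .genome import AnnotatedGenome, GeneModel, Interval, merge_intervals, revcomp
from .variants import CodingContext, VariantRecord
from . import hgvs

BASES = np.frombuffer(b"ACGT", dtype="S1")

GROUP_A = "testis"
GROUP_B = "oviduct"

#: margin kept between a planted copy and the boundary of its host feature
PLACEMENT_MARGIN = 20
#: clear space demanded around genes so flank-based classes stay unambiguous
GENE_GAP = 3000


class FixtureCapacityError(RuntimeError):
    """Requested density of genes/segments does not fit the chromosomes."""


# ------------------------------------------------------------ truth types


@dataclass(frozen=True)
class PlantedOrtholog:
    segment_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    placement: str  # exonic | intronic | intergenic
    host_gene: str | None
    n_substitutions: int
    divergence: float


@dataclass(frozen=True)
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str
    effect: str | None = None
    gene_id: str | None = None
    ext_length: int | str | None = None
    passes_filters: bool = True


@dataclass
class GroundTruth:
    ortholog_map: list[PlantedOrtholog] = field(default_factory=list)
    de_labels: dict[str, str] = field(default_factory=dict)
    variant_truth: dict[str, VariantTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ortholog_map": [asdict(o) for o in self.ortholog_map],
            "de_labels": self.de_labels,
            "variant_truth": {k: asdict(v) for k, v in self.variant_truth.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class Fixture:
    """Everything one end-to-end run needs, with its ground truth."""

    config: FixtureConfig
    query: AnnotatedGenome
    targets: list[AnnotatedGenome]
    transcripts: list[TranscriptRecord]
    counts: CountMatrix
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.query.to_fasta(outdir / "query.fasta")
        self.query.to_gtf(outdir / "query.gtf")
        for target in self.targets:
            target.to_fasta(outdir / f"{target.name}.fasta")
            target.to_gtf(outdir / f"{target.name}.gtf")
        self.counts.to_tsv(outdir / "counts.tsv")
        self.truth.to_json(outdir / "ground_truth.json")


# --------------------------------------------------------------- helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


_NON_STOP = [
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in hgvs.STOP_CODONS
]


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + random stop; length 3*n_codons."""
    if n_codons < 3:
        raise ValueError("ORF needs >= 3 codons")
    body = rng.choice(np.array(_NON_STOP), size=n_codons - 2)
    stop = rng.choice(np.array(sorted(hgvs.STOP_CODONS)))
    return "ATG" + "".join(body) + str(stop)


def _stop_free_frame(rng: np.random.Generator, length: int) -> str:
    """Sequence of ``length`` bases with no stop codon in frame 0."""
    n = -(-length // 3)
    seq = "".join(rng.choice(np.array(_NON_STOP), size=n))
    return seq[:length]


def _transcript_to_genomic(
    exons: Sequence[Interval], strand: str, t_start: int, t_end: int
) -> list[Interval]:
    """Genomic intervals of transcript positions [t_start, t_end] (1-based)."""
    order = list(exons) if strand == "+" else list(exons)[::-1]
    out: list[Interval] = []
    t = 1
    for lo, hi in order:
        length = hi - lo + 1
        s, e = max(t_start, t), min(t_end, t + length - 1)
        if s <= e:
            if strand == "+":
                out.append((lo + (s - t), lo + (e - t)))
            else:
                out.append((hi - (e - t), hi - (s - t)))
        t += length
    return merge_intervals(out)


def _write_transcript(
    chrom_seq: bytearray, exons: Sequence[Interval], strand: str, transcript: str
) -> None:
    order = list(exons) if strand == "+" else list(exons)[::-1]
    t = 0
    for lo, hi in order:
        length = hi - lo + 1
        chunk = transcript[t : t + length]
        if strand == "-":
            chunk = revcomp(chunk)
        chrom_seq[lo - 1 : hi] = chunk.encode()
        t += length


@dataclass
class _CodingSpec:
    utr5: int
    n_codons: int
    utr3: int
    utr3_mode: str | None = None  # None | "stop_free" | "early_stop"
    early_stop_codon: int = 5

    @property
    def total(self) -> int:
        return self.utr5 + 3 * self.n_codons + self.utr3


def _build_coding_gene(
    gene_id: str,
    chrom: str,
    chrom_seq: bytearray,
    strand: str,
    exons: Sequence[Interval],
    spec: _CodingSpec,
    rng: np.random.Generator,
) -> GeneModel:
    """Write a coding transcript into the genome and return its model."""
    total = sum(hi - lo + 1 for lo, hi in exons)
    if total != spec.total:
        raise ValueError(f"{gene_id}: exons cover {total} bp, spec needs {spec.total}")
    utr5_seq = _random_seq(rng, spec.utr5)
    cds_seq = _random_orf(rng, spec.n_codons)
    if spec.utr3_mode == "stop_free":
        utr3_seq = _stop_free_frame(rng, spec.utr3)
    elif spec.utr3_mode == "early_stop":
        head = _stop_free_frame(rng, 3 * (spec.early_stop_codon - 1))
        tail = _random_seq(rng, spec.utr3 - len(head) - 3)
        utr3_seq = head + "TAA" + tail
    else:
        utr3_seq = _random_seq(rng, spec.utr3)
    transcript = utr5_seq + cds_seq + utr3_seq
    _write_transcript(chrom_seq, exons, strand, transcript)
    cds_lo = spec.utr5 + 1
    cds_hi = spec.utr5 + 3 * spec.n_codons
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=list(exons),
        cds=_transcript_to_genomic(exons, strand, cds_lo, cds_hi),
        utr5=_transcript_to_genomic(exons, strand, 1, spec.utr5) if spec.utr5 else [],
        utr3=_transcript_to_genomic(exons, strand, cds_hi + 1, spec.total),
    )


def _exon_layout(
    start: int, n_exons: int, total: int, intron_lengths: Sequence[int]
) -> list[Interval]:
    """Split ``total`` transcript bases over ``n_exons`` exons from ``start``."""
    base = total // n_exons
    sizes = [base] * n_exons
    sizes[-1] += total - base * n_exons
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + size - 1))
        pos += size
        if i < n_exons - 1:
            pos += intron_lengths[i % len(intron_lengths)]
    return exons


# ------------------------------------------------------------- generator


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Build the full fixture: genomes, transcripts, counts and truth."""
    names = [
        "query_seq", "query_genes", "targets", "segments", "counts", "variants",
    ]
    rngs = _rngs(config.seed, names)
    truth = GroundTruth()

    query = _build_query_genome(config, rngs["query_seq"], rngs["query_genes"])
    segments, transcripts = _plant_segments(config, query, rngs["segments"])
    targets = [
        _build_target_genome(config, i, segments, truth, rngs["targets"])
        for i in range(config.n_target_species)
    ]
    counts, labels = simulate_counts(
        config,
        [t.id for t in transcripts],
        lengths={t.id: t.length for t in transcripts},
        rng=rngs["counts"],
    )
    truth.de_labels = labels
    _attach_fpkm(transcripts, counts)
    return Fixture(
        config=config,
        query=query,
        targets=targets,
        transcripts=transcripts,
        counts=counts,
        truth=truth,
    )


def _build_query_genome(
    config: FixtureConfig,
    seq_rng: np.random.Generator,
    gene_rng: np.random.Generator,
) -> AnnotatedGenome:
    chroms = {
        f"chr{i + 1}": bytearray(
            _random_seq(seq_rng, config.chrom_length).encode()
        )
        for i in range(config.n_chromosomes)
    }
    genes: list[GeneModel] = []
    names = list(chroms)
    # special constructs live at the head of chr1
    genes.extend(_special_genes(chroms[names[0]], names[0], gene_rng))
    reserved_until = 16_000

    remaining = config.n_genes
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    counter = 0
    for chrom in names:
        cursor = reserved_until + GENE_GAP if chrom == names[0] else GENE_GAP
        for _ in range(min(per_chrom, remaining)):
            spec = _CodingSpec(
                utr5=int(gene_rng.integers(60, 121)),
                n_codons=int(gene_rng.integers(80, 161)),
                utr3=int(gene_rng.integers(90, 181)),
            )
            introns = [int(gene_rng.integers(250, 601))
                       for _ in range(config.exons_per_gene - 1)]
            exons = _exon_layout(cursor, config.exons_per_gene, spec.total, introns)
            if exons[-1][1] + GENE_GAP > config.chrom_length:
                raise FixtureCapacityError(
                    f"chromosome {chrom} too short for {config.n_genes} genes"
                )
            counter += 1
            strand = "+" if counter % 2 else "-"
            genes.append(
                _build_coding_gene(
                    f"gq{counter:04d}", chrom, chroms[chrom], strand, exons,
                    spec, gene_rng,
                )
            )
            cursor = exons[-1][1] + GENE_GAP
            remaining -= 1
        if remaining == 0:
            break
    if remaining:
        raise FixtureCapacityError("not enough chromosomes for requested genes")
    return AnnotatedGenome(
        chromosomes={c: bytes(s).decode() for c, s in chroms.items()},
        genes=sorted(genes, key=lambda g: (g.chrom, g.gene_span[0])),
        name="query",
    )


def _special_genes(
    chrom_seq: bytearray, chrom: str, rng: np.random.Generator
) -> list[GeneModel]:
    """Hand-placed gene models exercising combined region classes and
    stop-loss extension scenarios."""
    genes = []
    # coding+splicing: guest gene's CDS begins exactly at the host's intron
    s = 1000
    host_exons = [(s, s + 699), (s + 1300, s + 1999)]
    genes.append(
        _build_coding_gene("g_splice_host", chrom, chrom_seq, "+", host_exons,
                           _CodingSpec(utr5=100, n_codons=400, utr3=100), rng)
    )
    guest_exon = [(s + 700, s + 1100)]  # inside the host intron [s+700, s+1299]
    genes.append(
        _build_coding_gene("g_splice_guest", chrom, chrom_seq, "+", guest_exon,
                           _CodingSpec(utr5=0, n_codons=100, utr3=101), rng)
    )
    # UTR3+UTR5: two single-exon genes overlapping tail-to-head
    s = 5000
    genes.append(
        _build_coding_gene("g_utr_a", chrom, chrom_seq, "+", [(s, s + 599)],
                           _CodingSpec(utr5=100, n_codons=100, utr3=200), rng)
    )
    genes.append(
        _build_coding_gene("g_utr_b", chrom, chrom_seq, "+",
                           [(s + 500, s + 1099)],
                           _CodingSpec(utr5=100, n_codons=100, utr3=200), rng)
    )
    # downstream+upstream: two plus-strand genes 400 bp apart
    s = 8000
    genes.append(
        _build_coding_gene("g_pair_left", chrom, chrom_seq, "+", [(s, s + 599)],
                           _CodingSpec(utr5=100, n_codons=100, utr3=200), rng)
    )
    genes.append(
        _build_coding_gene("g_pair_right", chrom, chrom_seq, "+",
                           [(s + 1000, s + 1599)],
                           _CodingSpec(utr5=100, n_codons=100, utr3=200), rng)
    )
    # stop-loss scenarios: controlled 3' UTR reading frames
    s = 11_000
    genes.append(
        _build_coding_gene("g_stop_near", chrom, chrom_seq, "+", [(s, s + 629)],
                           _CodingSpec(utr5=90, n_codons=120, utr3=180,
                                       utr3_mode="early_stop"), rng)
    )
    s = 13_000
    genes.append(
        _build_coding_gene("g_stop_free", chrom, chrom_seq, "-", [(s, s + 629)],
                           _CodingSpec(utr5=90, n_codons=120, utr3=180,
                                       utr3_mode="stop_free"), rng)
    )
    return genes


def _intergenic_gaps(
    genome_genes: Sequence[GeneModel], chrom: str, chrom_length: int, margin: int
) -> list[Interval]:
    spans = merge_intervals(
        [g.gene_span for g in genome_genes if g.chrom == chrom]
    )
    gaps = []
    prev_end = 0
    for lo, hi in spans + [(chrom_length + 1, chrom_length + 1)]:
        if lo - prev_end - 1 >= 2 * margin:
            gaps.append((prev_end + 1 + margin, lo - 1 - margin))
        prev_end = max(prev_end, hi)
    return gaps


def _plant_segments(
    config: FixtureConfig,
    query: AnnotatedGenome,
    rng: np.random.Generator,
) -> tuple[list[dict], list[TranscriptRecord]]:
    """Choose intergenic segments of the query genome as novel transcripts."""
    lo_len, hi_len = config.segment_length
    segments: list[dict] = []
    chrom_names = list(query.chromosomes)
    gap_cursor: dict[str, list[Interval]] = {
        c: _intergenic_gaps(query.genes, c, config.chrom_length, 1500)
        for c in chrom_names
    }
    for i in range(config.n_novel_segments):
        length = int(rng.integers(lo_len, hi_len + 1))
        placed = False
        for attempt in range(len(chrom_names)):
            chrom = chrom_names[(i + attempt) % len(chrom_names)]
            gaps = [g for g in gap_cursor[chrom] if g[1] - g[0] + 1 >= length]
            if gaps:
                gap = gaps[0]
                start = gap[0]
                end = start + length - 1
                # shrink the gap so the next segment lands clear of this one
                gap_cursor[chrom] = [
                    g for g in gap_cursor[chrom] if g != gap
                ] + ([(end + 200, gap[1])] if gap[1] - end >= 400 else [])
                gap_cursor[chrom].sort()
                segments.append(
                    {
                        "id": f"seg{i + 1:03d}",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "sequence": query.fetch(chrom, start, end),
                    }
                )
                placed = True
                break
        if not placed:
            raise FixtureCapacityError(
                f"no intergenic space for segment {i + 1} (length {length})"
            )
    transcripts = [
        TranscriptRecord(
            id=s["id"], chrom=s["chrom"], start=s["start"], end=s["end"],
            strand="+", sequence=s["sequence"],
        )
        for s in segments
    ]
    return segments, transcripts


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each base independently with probability ``divergence``."""
    if divergence == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < divergence
    for idx in np.nonzero(mask)[0]:
        options = BASES[BASES != arr[idx]]
        arr[idx] = rng.choice(options)
    return arr.tobytes().decode(), int(mask.sum())


_PLACEMENTS = ("exonic", "intronic", "intergenic")


def _build_target_genome(
    config: FixtureConfig,
    species_index: int,
    segments: Sequence[dict],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> AnnotatedGenome:
    name = f"target{species_index + 1}"
    chroms = {
        f"chr{i + 1}": bytearray(
            _random_seq(rng, config.chrom_length).encode()
        )
        for i in range(config.n_chromosomes)
    }
    # target genes: long exons/introns so planted copies fit completely inside
    genes: list[GeneModel] = []
    chrom_names = list(chroms)
    exon_len, intron_len, n_exons = 900, 900, 3
    gene_total = n_exons * exon_len + (n_exons - 1) * intron_len
    genes_per_chrom = 2
    counter = 0
    for chrom in chrom_names:
        cursor = GENE_GAP
        for _ in range(genes_per_chrom):
            if cursor + gene_total + GENE_GAP > config.chrom_length:
                raise FixtureCapacityError(
                    f"{name}: chromosome too short for target genes"
                )
            exons = [
                (cursor + k * (exon_len + intron_len),
                 cursor + k * (exon_len + intron_len) + exon_len - 1)
                for k in range(n_exons)
            ]
            counter += 1
            genes.append(
                GeneModel(
                    gene_id=f"{name}_g{counter:03d}",
                    chrom=chrom,
                    strand="+" if counter % 2 else "-",
                    exons=exons,
                )
            )
            cursor = exons[-1][1] + GENE_GAP
    # plant each segment once, cycling placement classes and strands
    gaps = {
        c: _intergenic_gaps(genes, c, config.chrom_length, 1000)
        for c in chrom_names
    }
    host_exons = [(g, e) for g in genes for e in g.exons]
    host_introns = [(g, i) for g in genes for i in g.introns]
    used_slots: set[tuple[str, int]] = set()

    def _claim(slots, label, segment_id, offset):
        """First free slot, scanning from a segment-dependent offset."""
        if not slots:
            raise FixtureCapacityError(
                f"{name}: no {label} slot fits segment {segment_id}"
            )
        for k in range(len(slots)):
            slot = slots[(offset + k) % len(slots)]
            if slot[:2] not in used_slots:
                used_slots.add(slot[:2])
                return slot
        raise FixtureCapacityError(
            f"{name}: {label} slots exhausted at segment {segment_id}"
        )

    for i, segment in enumerate(segments):
        placement = _PLACEMENTS[i % 3]
        strand = "+" if (i + species_index) % 2 == 0 else "-"
        seq = segment["sequence"]
        mutated, n_sub = _mutate(seq, config.divergence, rng)
        planted = mutated if strand == "+" else revcomp(mutated)
        length = len(planted)
        if placement in ("exonic", "intronic"):
            pool = host_exons if placement == "exonic" else host_introns
            slots = [
                (g.chrom, iv[0], iv, g) for g, iv in pool
                if iv[1] - iv[0] + 1 >= length + 2 * PLACEMENT_MARGIN
            ]
            chrom, _, iv, gene = _claim(slots, placement, segment["id"], i)
            start = iv[0] + PLACEMENT_MARGIN
            host = gene.gene_id
        else:
            slots = [
                (c, g[0], g) for c in chrom_names for g in gaps[c]
                if g[1] - g[0] + 1 >= length + 2 * PLACEMENT_MARGIN
            ]
            chrom, _, gap = _claim(slots, "intergenic", segment["id"], i)
            start = gap[0] + PLACEMENT_MARGIN
            host = None
        end = start + length - 1
        chroms[chrom][start - 1 : end] = planted.encode()
        truth.ortholog_map.append(
            PlantedOrtholog(
                segment_id=segment["id"],
                species=name,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                placement=placement,
                host_gene=host,
                n_substitutions=n_sub,
                divergence=config.divergence,
            )
        )
    return AnnotatedGenome(
        chromosomes={c: bytes(s).decode() for c, s in chroms.items()},
        genes=genes,
        name=name,
    )


# ----------------------------------------------------------------- counts


def simulate_counts(
    config: FixtureConfig,
    features: Sequence[str],
    lengths: dict[str, int] | None = None,
    samples_per_group: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, dict[str, str]]:
    """NB count matrix over ``features`` with planted DE labels.

    The first ``config.n_de_features`` features alternate between the two
    tissue groups; group means of DE features differ by
    ``config.planted_log2fc`` on the log2 scale, null features share a
    common mean.  Dispersion 0 samples the Poisson limit.
    """
    if samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    if rng is None:
        rng = _rngs(config.seed, ["counts"])["counts"]
    samples = [f"{GROUP_A}_{i + 1}" for i in range(samples_per_group)] + [
        f"{GROUP_B}_{i + 1}" for i in range(samples_per_group)
    ]
    groups = {s: GROUP_A if s.startswith(GROUP_A) else GROUP_B for s in samples}
    labels: dict[str, str] = {}
    base_means = np.exp(rng.uniform(np.log(100.0), np.log(1000.0), len(features)))
    lib_sizes = rng.integers(900_000, 1_100_000, size=len(samples))
    matrix = np.zeros((len(features), len(samples)), dtype=np.int64)
    for fi, feature in enumerate(features):
        if fi < config.n_de_features:
            label = "up_in_a" if fi % 2 == 0 else "up_in_b"
        else:
            label = "null"
        labels[feature] = label
        fold = 2.0 ** config.planted_log2fc
        mean_a = base_means[fi] * (fold if label == "up_in_a" else 1.0)
        mean_b = base_means[fi] * (fold if label == "up_in_b" else 1.0)
        for si, sample in enumerate(samples):
            mean = mean_a if groups[sample] == GROUP_A else mean_b
            mean = mean * lib_sizes[si] / 1e6  # deeper libraries see more reads
            if config.nb_dispersion <= 0:
                matrix[fi, si] = rng.poisson(mean)
            else:
                lam = rng.gamma(1.0 / config.nb_dispersion,
                                config.nb_dispersion * mean)
                matrix[fi, si] = rng.poisson(lam)
    counts = CountMatrix(
        counts=pd.DataFrame(matrix, index=list(features), columns=samples),
        lengths=pd.Series(
            {f: (lengths or {}).get(f, 1000) for f in features}
        ),
        library_sizes=pd.Series(lib_sizes, index=samples),
        groups=groups,
    )
    return counts, labels


def _attach_fpkm(
    transcripts: Sequence[TranscriptRecord], counts: CountMatrix
) -> None:
    fpkm = compute_fpkm(counts)
    for t in transcripts:
        t.fpkm = {s: float(fpkm.loc[t.id, s]) for s in counts.samples}


# --------------------------------------------------------------- variants


def simulate_variants(
    genome: AnnotatedGenome,
    config: FixtureConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], GroundTruth]:
    """Plant SNVs with known region classes and coding consequences.

    Covers every region class (including the combined classes produced by
    overlapping or closely spaced genes) and every consequence kind; extra
    records straddle the DP/GQ/QUAL filter thresholds on both sides.
    """
    if rng is None:
        rng = _rngs(config.seed, ["variants"])["variants"]
    by_id = {g.gene_id: g for g in genome.genes}
    if not any(g.cds for g in genome.genes):
        raise ValueError("genome lacks CDS annotation")
    regular = [
        g for g in genome.genes
        if g.gene_id.startswith("gq") and g.cds and len(g.exons) > 1
    ]
    if len(regular) < 4:
        raise ValueError("fixture needs >= 4 regular multi-exon coding genes")

    truth = GroundTruth()
    variants: list[VariantRecord] = []

    def qualities(passing: bool = True) -> dict:
        if passing:
            return {
                "dp": int(rng.integers(10, 150)),
                "gq": int(rng.integers(30, 99)),
                "qual": float(rng.integers(100, 3000)),
                "qd": float(rng.integers(5, 35)),
            }
        return {}

    def add(pos, chrom, ref, alt, region, effect=None, gene_id=None,
            ext=None, genotype="het", passes=True, **quals) -> bool:
        key = f"{chrom}:{pos}"
        if key in truth.variant_truth:
            return False
        q = {**qualities(), **quals}
        record = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype, **q
        )
        variants.append(record)
        truth.variant_truth[key] = VariantTruth(
            chrom=chrom, pos=pos, ref=ref, alt=alt, region_class=region,
            effect=effect, gene_id=gene_id, ext_length=ext,
            passes_filters=passes,
        )
        return True

    # --- coding consequences on regular genes (both strands get used)
    _plant_coding(add, genome, regular[0], "synonymous", rng)
    _plant_coding(add, genome, regular[1], "nonsynonymous", rng)
    _plant_coding(add, genome, regular[2], "stopgain", rng)
    _plant_coding(add, genome, by_id["g_stop_near"], "stoploss", rng,
                  expected_ext=5)
    _plant_coding(add, genome, by_id["g_stop_free"], "stoploss", rng,
                  expected_ext="?")

    # --- non-coding region classes on regular genes
    gene = regular[3]
    intron = gene.introns[0]
    add(intron[0], gene.chrom, genome.fetch(gene.chrom, intron[0], intron[0]),
        _other_base(genome.fetch(gene.chrom, intron[0], intron[0])),
        "splicing", gene_id=gene.gene_id)
    mid = (intron[0] + intron[1]) // 2
    add(mid, gene.chrom, genome.fetch(gene.chrom, mid, mid),
        _other_base(genome.fetch(gene.chrom, mid, mid)),
        "intronic", gene_id=gene.gene_id)
    for region, ivs in (("UTR5", gene.utr5), ("UTR3", gene.utr3)):
        iv = ivs[0]
        pos = (iv[0] + iv[1]) // 2
        ref = genome.fetch(gene.chrom, pos, pos)
        add(pos, gene.chrom, ref, _other_base(ref), region,
            gene_id=gene.gene_id)
    span = gene.gene_span
    up = span[0] - 50 if gene.strand == "+" else span[1] + 50
    down = span[1] + 50 if gene.strand == "+" else span[0] - 50
    for pos, region in ((up, "upstream"), (down, "downstream")):
        ref = genome.fetch(gene.chrom, pos, pos)
        add(pos, gene.chrom, ref, _other_base(ref), region,
            gene_id=gene.gene_id)

    # --- combined classes from the special constructs
    guest = by_id["g_splice_guest"]
    pos = guest.cds[0][0] + 1  # 2nd CDS base == 2nd intron base of the host
    ref = genome.fetch(guest.chrom, pos, pos)
    add(pos, guest.chrom, ref, _other_base(ref), "coding+splicing",
        effect="nonsynonymous", gene_id=guest.gene_id)
    utr_a, utr_b = by_id["g_utr_a"], by_id["g_utr_b"]
    overlap_lo = max(utr_a.utr3[0][0], utr_b.utr5[0][0])
    overlap_hi = min(utr_a.utr3[0][1], utr_b.utr5[0][1])
    pos = (overlap_lo + overlap_hi) // 2
    ref = genome.fetch(utr_a.chrom, pos, pos)
    add(pos, utr_a.chrom, ref, _other_base(ref), "UTR3+UTR5",
        gene_id=utr_a.gene_id)
    left, right = by_id["g_pair_left"], by_id["g_pair_right"]
    pos = (left.gene_span[1] + right.gene_span[0]) // 2
    ref = genome.fetch(left.chrom, pos, pos)
    add(pos, left.chrom, ref, _other_base(ref), "downstream+upstream",
        gene_id=left.gene_id)

    # --- intergenic: center of a large gap
    for chrom in genome.chromosomes:
        gaps = _intergenic_gaps(
            genome.genes, chrom, len(genome.chromosomes[chrom]), 0
        )
        gaps = [g for g in gaps if g[1] - g[0] > 4000]
        if gaps:
            pos = (gaps[-1][0] + gaps[-1][1]) // 2
            ref = genome.fetch(chrom, pos, pos)
            add(pos, chrom, ref, _other_base(ref), "intergenic")
            break

    # --- quality-filter boundary records (region truth still exact)
    boundary = [
        ({"dp": 5}, False), ({"dp": 6}, True),
        ({"gq": 20}, False), ({"gq": 21}, True),
        ({"qual": 80.0}, False), ({"qual": 81.0}, True),
    ]
    chrom = regular[0].chrom
    gaps = [
        g for g in _intergenic_gaps(genome.genes, chrom,
                                    len(genome.chromosomes[chrom]), 0)
        if g[1] - g[0] > 4000
    ]
    base_pos = (gaps[-1][0] + gaps[-1][1]) // 2
    for i, (quals, passes) in enumerate(boundary):
        pos = base_pos + 10 * (i + 1)
        ref = genome.fetch(chrom, pos, pos)
        add(pos, chrom, ref, _other_base(ref), "intergenic", passes=passes,
            **quals)

    # --- pad with extra coding variants up to the configured count
    gi = 0
    while len(variants) < config.n_variants and gi < 20 * config.n_variants:
        gene = regular[gi % len(regular)]
        gi += 1
        effect = "nonsynonymous" if gi % 2 else "synonymous"
        try:
            _plant_coding(add, genome, gene, effect, rng, salt=gi)
        except LookupError:
            continue
    return variants, truth


def _other_base(base: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[base.upper()]


def _plant_coding(
    add,
    genome: AnnotatedGenome,
    gene: GeneModel,
    effect: str,
    rng: np.random.Generator,
    expected_ext: int | str | None = None,
    salt: int = 0,
) -> None:
    """Find a CDS position whose substitution yields ``effect`` and add it."""
    context = CodingContext.from_gene(gene, genome)
    cds = context.cds_seq
    n_codons = len(cds) // 3
    candidates = []
    codon_range = (
        [n_codons] if effect == "stoploss" else range(2, n_codons)
    )
    for codon_no in codon_range:
        start = 3 * (codon_no - 1)
        codon = cds[start : start + 3]
        ref_aa = hgvs.translate_codon(codon)
        for offset in range(3):
            for alt in "ACGT":
                if alt == codon[offset]:
                    continue
                mutated = codon[:offset] + alt + codon[offset + 1 :]
                alt_aa = hgvs.translate_codon(mutated)
                ok = (
                    (effect == "synonymous" and alt_aa == ref_aa and ref_aa != "*")
                    or (effect == "nonsynonymous"
                        and "*" not in (ref_aa, alt_aa) and alt_aa != ref_aa)
                    or (effect == "stopgain" and ref_aa != "*" and alt_aa == "*")
                    or (effect == "stoploss" and ref_aa == "*" and alt_aa != "*")
                )
                if ok:
                    candidates.append((start + offset + 1, alt))
    if not candidates:
        raise LookupError(f"no {effect} site in {gene.gene_id}")
    cds_pos, alt_cds = candidates[(salt * 7) % len(candidates)]
    genomic_pos = context._cds_positions[cds_pos - 1]
    ref = genome.fetch(gene.chrom, genomic_pos, genomic_pos)
    alt = alt_cds if gene.strand == "+" else revcomp(alt_cds)
    genotype = "het" if effect == "stopgain" else (
        "hom_alt" if effect == "stoploss" and rng.random() < 0.5 else "het"
    )
    region = "coding"
    add(genomic_pos, gene.chrom, ref, alt, region, effect=effect,
        gene_id=gene.gene_id, ext=expected_ext, genotype=genotype)
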