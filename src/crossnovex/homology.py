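"""Seed-and-extend ungapped homology search of transcripts against genomes.

A desk-scale local aligner in the BLAST family: exact k-mer seeds are
looked up in a target index and extended in both directions without gaps
under +1/-2 match/mismatch scoring with x-drop termination.  Overlapping
extensions on the same diagonal are merged, and alignments below a
minimum score are discarded (the usual significance proxy for a
seed-extend search; E-value statistics are out of scope).  Minus-strand
matches are found by reverse-complementing the query and are reported in
plus-strand target coordinates with a strand flag.

The downstream filter keeps hits whose identity ratio — matched positions
over alignment length — strictly exceeds 0.9; the comparison at the
boundary is exact rational, so 90/100 fails and 91/100 passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .expression import TranscriptRecord
from .genome import AnnotatedGenome, revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -2


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped local alignment of a query transcript to a target genome."""

    query_id: str
    target_species: str
    target_chrom: str
    target_start: int  # 1-based inclusive, plus strand
    target_end: int
    strand: str
    aln_length: int
    matches: int
    score: int
    query_start: int = 0  # 1-based on the original query orientation
    query_end: int = 0

    def __post_init__(self) -> None:
        if self.target_end < self.target_start:
            raise ValueError("target_end < target_start")
        if self.aln_length != self.target_end - self.target_start + 1:
            raise ValueError("aln_length inconsistent with target interval")
        if not 0 <= self.matches <= self.aln_length:
            raise ValueError("matches outside [0, aln_length]")

    @property
    def identity_ratio(self) -> float:
        return identity_ratio(self.matches, self.aln_length)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


def identity_ratio(matches: int, aln_length: int) -> float:
    """Matched positions over alignment length."""
    if aln_length <= 0:
        raise ValueError("aln_length must be positive")
    if not 0 <= matches <= aln_length:
        raise ValueError("matches outside [0, aln_length]")
    return matches / aln_length


def filter_hits(
    hits: Iterable[HomologyHit], min_identity: float = 0.9
) -> list[HomologyHit]:
    """Keep hits with identity ratio strictly above ``min_identity``.

    The threshold is compared as an exact rational (its decimal rendering),
    so an identity of exactly 90/100 fails a 0.9 cutoff regardless of
    floating-point representation.
    """
    threshold = Fraction(str(min_identity))
    return [
        h for h in hits if Fraction(h.matches, h.aln_length) > threshold
    ]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _extend(
    qseq: str, tseq: str, qpos: int, tpos: int, k: int, x_drop: int
) -> tuple[int, int]:
    """Maximal x-drop extension of a seed; returns target 0-based [lo, hi]."""
    # rightward from the last seed base
    score = best = 0
    best_right = tpos + k - 1
    q, t = qpos + k, tpos + k
    while q < len(qseq) and t < len(tseq):
        score += MATCH_SCORE if qseq[q] == tseq[t] else MISMATCH_SCORE
        if score > best:
            best, best_right = score, t
        elif best - score > x_drop:
            break
        q += 1
        t += 1
    # leftward from the first seed base
    score = best = 0
    best_left = tpos
    q, t = qpos - 1, tpos - 1
    while q >= 0 and t >= 0:
        score += MATCH_SCORE if qseq[q] == tseq[t] else MISMATCH_SCORE
        if score > best:
            best, best_left = score, t
        elif best - score > x_drop:
            break
        q -= 1
        t -= 1
    return best_left, best_right


def _count_matches(qseq: str, tseq: str, qlo: int, tlo: int, length: int) -> int:
    return sum(
        1 for i in range(length) if qseq[qlo + i] == tseq[tlo + i]
    )


def search(
    queries: Sequence[TranscriptRecord],
    target: AnnotatedGenome,
    k: int = 11,
    x_drop: int = 20,
    min_score: int = 25,
) -> list[HomologyHit]:
    """All merged maximal ungapped seed extensions of ``queries`` in ``target``.

    Queries shorter than ``k`` are skipped with a warning.  Output order is
    deterministic: (query id, chromosome, start, end, strand).
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    indexes = {
        chrom: _kmer_index(seq, k) for chrom, seq in target.chromosomes.items()
    }
    hits: list[HomologyHit] = []
    for query in queries:
        qlen = len(query.sequence)
        if qlen < k:
            warnings.warn(
                f"query {query.id} shorter than seed length {k}; skipped",
                stacklevel=2,
            )
            continue
        for strand in "+-":
            qseq = (
                query.sequence.upper()
                if strand == "+"
                else revcomp(query.sequence.upper())
            )
            for chrom, tseq in target.chromosomes.items():
                index = indexes[chrom]
                # seed positions grouped per diagonal (diag = tpos - qpos)
                seeds: dict[int, list[int]] = {}
                for qpos in range(qlen - k + 1):
                    for tpos in index.get(qseq[qpos : qpos + k], ()):
                        seeds.setdefault(tpos - qpos, []).append(tpos)
                for diag, positions in seeds.items():
                    intervals: list[tuple[int, int]] = []
                    covered = -1
                    for tpos in sorted(positions):
                        if tpos + k - 1 <= covered:
                            continue  # seed inside an extension already made
                        lo, hi = _extend(qseq, tseq, tpos - diag, tpos, k, x_drop)
                        intervals.append((lo, hi))
                        covered = hi
                    for lo, hi in _merge_overlapping(intervals):
                        hits.extend(
                            _make_hit(query, target, chrom, strand, qseq, tseq,
                                      diag, lo, hi, min_score)
                        )
    hits.sort(
        key=lambda h: (h.query_id, h.target_chrom, h.target_start,
                       h.target_end, h.strand)
    )
    return hits


def _merge_overlapping(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _make_hit(
    query: TranscriptRecord,
    target: AnnotatedGenome,
    chrom: str,
    strand: str,
    qseq: str,
    tseq: str,
    diag: int,
    lo: int,
    hi: int,
    min_score: int,
) -> list[HomologyHit]:
    length = hi - lo + 1
    matches = _count_matches(qseq, tseq, lo - diag, lo, length)
    score = matches * MATCH_SCORE + (length - matches) * MISMATCH_SCORE
    if score < min_score:
        return []
    q0, q1 = lo - diag, hi - diag  # 0-based on the searched orientation
    if strand == "-":
        qlen = len(qseq)
        q0, q1 = qlen - 1 - q1, qlen - 1 - q0
    return [
        HomologyHit(
            query_id=query.id,
            target_species=target.name,
            target_chrom=chrom,
            target_start=lo + 1,
            target_end=hi + 1,
            strand=strand,
            aln_length=length,
            matches=matches,
            score=score,
            query_start=q0 + 1,
            query_end=q1 + 1,
        )
    ]


# ------------------------------------------------------------------ tables

_HIT_COLUMNS = [
    "query_id", "species", "chrom", "start", "end", "strand",
    "aln_length", "matches", "identity",
]


def hits_to_frame(hits: Sequence[HomologyHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.query_id, h.target_species, h.target_chrom, h.target_start,
             h.target_end, h.strand, h.aln_length, h.matches, h.identity_ratio)
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )


def write_hits(hits: Sequence[HomologyHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_blast_tabular(path: str | Path, species: str) -> list[HomologyHit]:
    """Adapter for 12-column BLAST tabular output (outfmt 6).

    Lets externally produced hits replace the built-in aligner.  Gapped
    alignments are accepted as-is; ``matches`` is reconstructed from the
    percent-identity column.  Minus-strand hits arrive with sstart > send
    and are flipped to plus-strand coordinates.
    """
    names = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=names, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        start, end, strand = row.sstart, row.send, "+"
        if start > end:
            start, end, strand = end, start, "-"
        length = int(end) - int(start) + 1  # subject span (== length if ungapped)
        matches = min(round(row.pident / 100.0 * int(row.length)), length)
        score = matches * MATCH_SCORE + (length - matches) * MISMATCH_SCORE
        hits.append(
            HomologyHit(
                query_id=str(row.qseqid),
                target_species=species,
                target_chrom=str(row.sseqid),
                target_start=int(start),
                target_end=int(end),
                strand=strand,
                aln_length=length,
                matches=int(matches),
                score=int(score),
                query_start=int(min(row.qstart, row.qend)),
                query_end=int(max(row.qstart, row.qend)),
            )
        )
    return hits
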