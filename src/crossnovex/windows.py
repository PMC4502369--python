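"""Sliding-window similarity between two genomic regions, with rendering.

For a gene region attracting several homology hits, the window size is
set to the smallest hit length, both regions are cut into consecutive
non-overlapping chunks of that size (a trailing remainder shorter than
one window is dropped so all similarity denominators agree), and every
chunk of the query region is paired with its best-matching chunk of the
target region.  Similarity is ungapped positional identity, and pairs
below the similarity floor (0.3 by default, strict: exactly 0.3 is kept)
are omitted.

Rendering produces a deterministic SVG: query annotation above, target
annotation below, connector bars between paired chunks colored on a
linear red (floor) to green (1.0) spectrum, and optional log-FPKM
expression tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome import GeneModel
from .homology import HomologyHit


@dataclass
class Region:
    """A named sequence with its source interval (1-based inclusive)."""

    name: str
    sequence: str
    chrom: str = ""
    start: int = 1

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


@dataclass
class WindowComparison:
    window: int
    chunks_a: list[tuple[int, int]]  # source coordinates per chunk
    chunks_b: list[tuple[int, int]]
    pairs: list[tuple[int, int, float]]  # (index_a, index_b, similarity)
    omitted_below: float = 0.3
    region_a: str = "A"
    region_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.chunks_a[ia][0], self.chunks_b[ib][0], sim)
                for ia, ib, sim in self.pairs
            ],
            columns=["chunkA_start", "chunkB_start", "similarity"],
        )

    def write_pairs(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def chunk_similarity(a: str, b: str) -> float:
    """Fraction of positions with identical nucleotides.

    Case-insensitive; ``N`` matches nothing, not even another ``N``.
    """
    if len(a) != len(b):
        raise ValueError(f"chunk lengths differ ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("empty chunks")
    a, b = a.upper(), b.upper()
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return matches / len(a)


def _chunk(region: Region, window: int) -> tuple[list[str], list[tuple[int, int]]]:
    seqs, coords = [], []
    seq = region.sequence
    for offset in range(0, len(seq) - window + 1, window):
        seqs.append(seq[offset : offset + window])
        coords.append((region.start + offset, region.start + offset + window - 1))
    return seqs, coords


def compare_regions(
    region_a: Region,
    region_b: Region,
    hits: Sequence[HomologyHit],
    similarity_floor: float = 0.3,
    step: int | None = None,
    all_pairs: bool = False,
) -> WindowComparison:
    """Window comparison of two regions, window = smallest hit length.

    Every chunk pair is scored; by default each query chunk reports its
    best target partner (ties break to the lowest target index), matching
    a one-bar-per-segment visualization; ``all_pairs=True`` keeps every
    pair above the floor instead.  ``step`` overrides the non-overlapping
    tiling with a custom chunk stride (exploratory use).
    """
    if not hits:
        raise ValueError("at least one hit is required to define the window")
    window = min(h.aln_length for h in hits)
    for region in (region_a, region_b):
        if window > len(region.sequence):
            raise ValueError(
                f"window {window} exceeds region {region.name!r} "
                f"({len(region.sequence)} bp)"
            )
    if step is None:
        step = window
    seqs_a, coords_a = _chunk_strided(region_a, window, step)
    seqs_b, coords_b = _chunk_strided(region_b, window, step)
    floor = Fraction(str(similarity_floor))
    pairs: list[tuple[int, int, float]] = []
    for ia, ca in enumerate(seqs_a):
        scored = [
            (ib, _match_count(ca, cb)) for ib, cb in enumerate(seqs_b)
        ]
        if all_pairs:
            kept = [
                (ia, ib, m / window)
                for ib, m in scored
                if Fraction(m, window) >= floor
            ]
            pairs.extend(kept)
        else:
            best_ib, best_m = max(scored, key=lambda x: (x[1], -x[0]))
            if Fraction(best_m, window) >= floor:
                pairs.append((ia, best_ib, best_m / window))
    return WindowComparison(
        window=window,
        chunks_a=coords_a,
        chunks_b=coords_b,
        pairs=pairs,
        omitted_below=similarity_floor,
        region_a=region_a.name,
        region_b=region_b.name,
    )


def _chunk_strided(
    region: Region, window: int, step: int
) -> tuple[list[str], list[tuple[int, int]]]:
    if step == window:
        return _chunk(region, window)
    seqs, coords = [], []
    seq = region.sequence
    for offset in range(0, len(seq) - window + 1, step):
        seqs.append(seq[offset : offset + window])
        coords.append((region.start + offset, region.start + offset + window - 1))
    return seqs, coords


def _match_count(a: str, b: str) -> int:
    a, b = a.upper(), b.upper()
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


# ------------------------------------------------------------------ render

SVG_WIDTH = 1000
TRACK_HEIGHT = 18
BAR_TOP = 120
BAR_BOTTOM = 260


def similarity_color(similarity: float, floor: float = 0.3) -> str:
    """Hex color on the linear red (floor) -> green (1.0) spectrum."""
    span = 1.0 - floor
    f = 0.0 if span <= 0 else min(1.0, max(0.0, (similarity - floor) / span))
    red = round(255 * (1.0 - f))
    green = round(255 * f)
    return f"#{red:02x}{green:02x}00"


def render_region(
    comparison: WindowComparison,
    annotation_a: Sequence[GeneModel] = (),
    annotation_b: Sequence[GeneModel] = (),
    expression_tracks: Mapping[str, Sequence[float]] | None = None,
) -> str:
    """Deterministic SVG of a window comparison (query above, target below)."""
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{SVG_WIDTH}" '
        f'height="{BAR_BOTTOM + 80}">',
        f'<title>{comparison.region_a} vs {comparison.region_b}</title>',
    ]
    span_a = _span(comparison.chunks_a)
    span_b = _span(comparison.chunks_b)
    parts.append(_track_svg(comparison.chunks_a, span_a, BAR_TOP - TRACK_HEIGHT,
                            "track-a"))
    parts.append(_track_svg(comparison.chunks_b, span_b, BAR_BOTTOM, "track-b"))
    for genes, span, y in (
        (annotation_a, span_a, BAR_TOP - TRACK_HEIGHT - 24),
        (annotation_b, span_b, BAR_BOTTOM + TRACK_HEIGHT + 6),
    ):
        for gene in genes:
            for exon in gene.exons:
                x0, x1 = _scale(exon[0], span), _scale(exon[1], span)
                parts.append(
                    f'<rect class="exon" x="{x0:.1f}" y="{y}" '
                    f'width="{max(x1 - x0, 1.0):.1f}" height="10" fill="#444444"/>'
                )
    if expression_tracks:
        colors = {"A": "#cc0000", "B": "#0000cc"}
        for label in sorted(expression_tracks):
            values = expression_tracks[label]
            points = " ".join(
                f"{_scale(c[0], span_a):.1f},{BAR_TOP - TRACK_HEIGHT - 30 - 4 * v:.1f}"
                for c, v in zip(comparison.chunks_a, values)
            )
            color = colors.get(label, "#888888")
            parts.append(
                f'<polyline class="expr" fill="none" stroke="{color}" '
                f'points="{points}"/>'
            )
    for ia, ib, sim in comparison.pairs:
        ax0 = _scale(comparison.chunks_a[ia][0], span_a)
        ax1 = _scale(comparison.chunks_a[ia][1], span_a)
        bx0 = _scale(comparison.chunks_b[ib][0], span_b)
        bx1 = _scale(comparison.chunks_b[ib][1], span_b)
        color = similarity_color(sim, comparison.omitted_below)
        parts.append(
            f'<polygon class="pair" fill="{color}" fill-opacity="0.7" '
            f'points="{ax0:.1f},{BAR_TOP} {ax1:.1f},{BAR_TOP} '
            f'{bx1:.1f},{BAR_BOTTOM} {bx0:.1f},{BAR_BOTTOM}"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def _track_svg(
    chunks: Sequence[tuple[int, int]], span: tuple[int, int], y: int, css: str
) -> str:
    """A horizontal baseline with a tick per chunk boundary."""
    x0, x1 = _scale(span[0], span), _scale(span[1], span)
    parts = [
        f'<line class="{css}" x1="{x0:.1f}" y1="{y + TRACK_HEIGHT:.1f}" '
        f'x2="{x1:.1f}" y2="{y + TRACK_HEIGHT:.1f}" stroke="#000000"/>'
    ]
    for lo, _hi in chunks:
        x = _scale(lo, span)
        parts.append(
            f'<line class="{css}-tick" x1="{x:.1f}" y1="{y + TRACK_HEIGHT - 4:.1f}" '
            f'x2="{x:.1f}" y2="{y + TRACK_HEIGHT:.1f}" stroke="#000000"/>'
        )
    return "\n".join(parts)


def _span(chunks: Sequence[tuple[int, int]]) -> tuple[int, int]:
    if not chunks:
        return (1, 2)
    return (chunks[0][0], chunks[-1][1])


def _scale(pos: int, span: tuple[int, int]) -> float:
    lo, hi = span
    width = max(hi - lo, 1)
    return 40 + (SVG_WIDTH - 80) * (pos - lo) / width


def write_svg(svg: str, path: str | Path) -> None:
    Path(path).write_text(svg + "\n")
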