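"""FPKM computation, expression filters, and sample-level QC.

FPKM (fragments per kilobase of feature per million mapped reads) is
computed from raw counts as

    fpkm[f, s] = counts[f, s] * 1e9 / (library_size[s] * length[f])

with the library size the total mapped reads of the sample (not the
column sum of the matrix).  The filters follow the published thresholds
literally: a gene counts as expressed when its FPKM exceeds 0.2 strictly
in at least one sample; a novel-transcript candidate is kept when it is
strictly longer than 130 bp and reaches an FPKM of at least 5 (inclusive)
in at least one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class TranscriptRecord:
    """A novel-transcript candidate with coordinates, sequence and FPKM."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    fpkm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.id}: end < start")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"interval length {self.length}"
            )
        if any(v < 0 for v in self.fpkm.values()):
            raise ValueError(f"{self.id}: negative FPKM")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def max_fpkm(self) -> float:
        return max(self.fpkm.values(), default=0.0)


@dataclass
class CountMatrix:
    """Integer read counts (features x samples) with lengths and metadata.

    ``library_sizes`` are total mapped reads per sample and may exceed the
    column sums (reads counted outside the feature set still normalize).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.lengths.isna().any() or self.library_sizes.isna().any():
            raise ValueError("lengths/library sizes do not cover the matrix")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        library_sizes: Mapping[str, int],
        groups: Mapping[str, str] | None = None,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        lengths = df.pop("length")
        return cls(
            counts=df,
            lengths=lengths,
            library_sizes=pd.Series(library_sizes),
            groups=dict(groups or {}),
        )


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """FPKM table from a count matrix.

    Raises ``ValueError`` on zero feature lengths or library sizes, which
    would silently produce infinities.
    """
    lengths = counts.lengths.to_numpy(dtype=float)
    libsizes = counts.library_sizes.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (libsizes <= 0).any():
        raise ValueError("library sizes must be positive")
    scale = 1e9 / (libsizes[np.newaxis, :] * lengths[:, np.newaxis])
    return pd.DataFrame(
        counts.counts.to_numpy(dtype=float) * scale,
        index=counts.counts.index,
        columns=counts.counts.columns,
    )


def filter_expressed(fpkm: pd.DataFrame, threshold: float = 0.2) -> set[str]:
    """Features whose FPKM strictly exceeds ``threshold`` in >=1 sample."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if fpkm.empty:
        return set()
    mask = (fpkm > threshold).any(axis=1)
    return set(fpkm.index[mask])


def filter_novel_transcripts(
    transcripts: Sequence[TranscriptRecord],
    min_len: int = 130,
    min_fpkm: float = 5.0,
) -> list[TranscriptRecord]:
    """Novel-transcript candidate filter, order preserving.

    Length is strict (a 130 bp transcript fails a ``>130 bp`` rule) while
    the FPKM floor is inclusive (``at least 5`` in one sample keeps 5.0).
    """
    return [
        t for t in transcripts if t.length > min_len and t.max_fpkm >= min_fpkm
    ]


@dataclass
class SampleQC:
    """Pairwise sample correlations plus a UPGMA dendrogram."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    samples: list[str]

    def merge_order(self) -> list[tuple[frozenset[str], float]]:
        """Clusters in merge order as (member set, merge height)."""
        clusters: dict[int, frozenset[str]] = {
            i: frozenset([s]) for i, s in enumerate(self.samples)
        }
        out = []
        n = len(self.samples)
        for i, (a, b, height, _size) in enumerate(self.linkage):
            members = clusters[int(a)] | clusters[int(b)]
            clusters[n + i] = members
            out.append((members, float(height)))
        return out


def sample_qc(fpkm: pd.DataFrame, log_transform: bool = True) -> SampleQC:
    """Sample-level QC: Pearson correlation and UPGMA clustering.

    Correlation and distances are computed on log2(FPKM + 1) by default,
    the usual variance-stabilizing choice for RNA-seq QC; pass
    ``log_transform=False`` for raw FPKM.  A constant sample has an
    undefined Pearson correlation and is reported as NaN, never as 0.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("sample QC needs at least 2 samples")
    data = np.log2(fpkm + 1.0) if log_transform else fpkm
    corr = data.corr(method="pearson")  # pandas yields NaN for constant columns
    dist = pdist(data.to_numpy().T, metric="euclidean")
    linkage = hierarchy.linkage(dist, method="average")
    return SampleQC(correlation=corr, linkage=linkage, samples=list(data.columns))
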