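"""Configuration objects for the simulator and the pipeline.

``PipelineConfig`` carries every published filtering threshold of the
analysis (transcript length/FPKM floors, identity ratio, FDR and
fold-change cutoffs, window-similarity floor, variant quality filters);
``FixtureConfig`` carries only simulation knobs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic-fixture generator.

    Defaults give a small three-genome comparison (one query, two target
    species) that exercises every downstream stage in well under a minute:
    5 chromosomes of 200 kb, 40 genes, 12 planted novel segments.
    """

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 200_000
    n_genes: int = 40
    exons_per_gene: int = 4
    n_novel_segments: int = 12
    n_target_species: int = 2
    divergence: float = 0.05
    nb_dispersion: float = 0.1
    n_de_features: int = 4
    planted_log2fc: float = 3.0
    n_variants: int = 40
    segment_length: tuple[int, int] = (200, 600)

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        for name in (
            "n_chromosomes", "chrom_length", "n_genes", "exons_per_gene",
            "n_novel_segments", "n_target_species", "n_de_features", "n_variants",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PipelineConfig:
    """Published analysis thresholds, overridable per run.

    The strict/inclusive senses follow the published wording: transcript
    length strictly > ``min_len``; FPKM at least ``min_fpkm`` in one
    sample; identity strictly > ``min_identity``; hit-level DE strictly
    FDR < ``hit_fdr`` while gene-level DE is FDR <= ``gene_fdr`` with
    ``|log2FC| >= min_abs_log2fc``; chunk pairs below ``similarity_floor``
    are omitted; variant filters are strict on all three fields.
    """

    min_len: int = 130
    min_fpkm: float = 5.0
    expressed_fpkm: float = 0.2
    min_identity: float = 0.9
    hit_fdr: float = 0.01
    gene_fdr: float = 0.01
    min_abs_log2fc: float = 2.0
    similarity_floor: float = 0.3
    min_dp: int = 5
    min_gq: int = 20
    min_qual: float = 80.0
    flank: int = 1000
    splice_window: int = 2
    seed_length: int = 11
    x_drop: int = 20
    min_score: int = 25
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
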