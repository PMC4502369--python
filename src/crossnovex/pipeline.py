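"""End-to-end orchestration of the novel-transcript discovery pipeline.

Stage order: transcript filtering -> homology search against every target
genome -> identity filtering -> annotation-overlap classification ->
exact-test differential expression on features with exonic or intronic
hits -> window-similarity comparison (with SVG rendering) for every
target gene attracting more than one hit.  Each stage logs its input and
output row counts; a JSON manifest records the configuration and all
per-stage counts, so a rerun with the same seed and config reproduces it
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import de as de_mod
from .config import PipelineConfig
from .expression import filter_novel_transcripts
from .homology import filter_hits, search, write_hits
from .overlap import class_counts, classify_hits, write_classified
from .synthetic import GROUP_A, GROUP_B, Fixture
from .windows import Region, compare_regions, render_region, write_svg

logger = logging.getLogger("crossnovex.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    manifest: dict[str, Any]
    candidates: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    classified: list = field(default_factory=list)
    de_results: Any = None
    comparisons: dict = field(default_factory=dict)


def run_all(
    fixture: Fixture,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on a fixture; optionally write stage outputs."""
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stages": {},
    }
    result = PipelineResult(manifest=manifest)
    stage = "filter-transcripts"
    try:
        transcripts = fixture.transcripts
        candidates = filter_novel_transcripts(
            transcripts, min_len=config.min_len, min_fpkm=config.min_fpkm
        )
        _log_stage(manifest, stage, len(transcripts), len(candidates))
        result.candidates = candidates

        stage = "search"
        raw_hits = []
        for target in fixture.targets:
            raw_hits.extend(
                search(candidates, target, k=config.seed_length,
                       x_drop=config.x_drop, min_score=config.min_score)
            )
        kept = filter_hits(raw_hits, min_identity=config.min_identity)
        _log_stage(manifest, stage, len(raw_hits), len(kept))
        result.hits = kept
        if outdir is not None:
            write_hits(kept, outdir / "hits.tsv")

        stage = "classify"
        annotations = {t.name: t.genes for t in fixture.targets}
        classified = classify_hits(kept, annotations)
        counts_by_class = class_counts(classified)
        manifest["stages"]["classify"] = {
            "in": len(kept), "out": len(classified), **counts_by_class
        }
        result.classified = classified
        if outdir is not None:
            write_classified(classified, outdir / "classified.tsv")

        stage = "de-hits"
        de_features = sorted(
            {
                hc.hit.query_id
                for hc in classified
                if hc.klass in ("exonic", "intronic")
            }
        )
        counts = fixture.counts
        if de_features:
            sub = type(counts)(
                counts=counts.counts.loc[de_features],
                lengths=counts.lengths.loc[de_features],
                library_sizes=counts.library_sizes,
                groups=counts.groups,
            )
            de_results = de_mod.call_de(
                de_mod.de_table(sub, GROUP_A, GROUP_B),
                mode="hits", hit_fdr=config.hit_fdr,
            )
            n_de = int(de_results["is_de"].sum())
        else:
            de_results = None
            n_de = 0
        _log_stage(manifest, stage, len(de_features), n_de)
        result.de_results = de_results
        if outdir is not None and de_results is not None:
            de_results.to_csv(outdir / "de_hits.tsv", sep="\t",
                              index_label="feature")
        de_ids = (
            set(de_results.index[de_results["is_de"]]) if de_results is not None
            else set()
        )
        de_hit_alignments = [
            hc for hc in classified
            if hc.klass in ("exonic", "intronic") and hc.hit.query_id in de_ids
        ]
        unique_genes = {hc.gene_id for hc in de_hit_alignments if hc.gene_id}
        manifest["stages"]["de-hits"]["de_hit_alignments"] = len(de_hit_alignments)
        manifest["stages"]["de-hits"]["unique_genes"] = len(unique_genes)

        stage = "window-compare"
        comparisons = _window_stage(fixture, classified, config, outdir)
        _log_stage(manifest, stage, len(comparisons), len(comparisons))
        result.comparisons = comparisons
    except Exception as exc:  # noqa: BLE001 - stage attribution on any failure
        if outdir is not None:
            (outdir / "manifest.partial.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True)
            )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    if outdir is not None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
    return result


def _log_stage(manifest: dict, stage: str, n_in: int, n_out: int) -> None:
    logger.info("stage %s: %d -> %d", stage, n_in, n_out)
    manifest["stages"][stage] = {"in": n_in, "out": n_out}


def _window_stage(fixture, classified, config, outdir):
    """Window comparison per target gene with more than one hit."""
    by_gene: dict[tuple[str, str], list] = {}
    for hc in classified:
        if hc.gene_id:
            by_gene.setdefault((hc.hit.target_species, hc.gene_id), []).append(hc)
    genomes = {t.name: t for t in fixture.targets}
    segments = {t.id: t for t in fixture.transcripts}
    comparisons = {}
    for (species, gene_id), hcs in sorted(by_gene.items()):
        if len(hcs) < 2:
            continue
        target = genomes[species]
        gene = next(g for g in target.genes if g.gene_id == gene_id)
        span = gene.gene_span
        region_b = Region(
            name=f"{species}:{gene_id}",
            sequence=target.fetch(gene.chrom, span[0], span[1]),
            chrom=gene.chrom,
            start=span[0],
        )
        seg_ids = sorted({hc.hit.query_id for hc in hcs})
        first = segments[seg_ids[0]]
        region_a = Region(
            name=f"query:{'+'.join(seg_ids)}",
            sequence="".join(segments[s].sequence for s in seg_ids),
            chrom=first.chrom,
            start=first.start,
        )
        hits = [hc.hit for hc in hcs]
        comparison = compare_regions(
            region_a, region_b, hits, similarity_floor=config.similarity_floor
        )
        comparisons[(species, gene_id)] = comparison
        if outdir is not None:
            stem = f"window_{species}_{gene_id}"
            comparison.write_pairs(outdir / f"{stem}.tsv")
            write_svg(
                render_region(comparison, annotation_b=[gene]),
                outdir / f"{stem}.svg",
            )
    return comparisons
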