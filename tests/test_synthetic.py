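import dataclasses
import math

import numpy as np
import pytest

from crossnovex import FixtureConfig
from crossnovex.synthetic import (
    FixtureCapacityError,
    generate_fixture,
    simulate_counts,
    simulate_variants,
)
from crossnovex.variants import classify_region


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = FixtureConfig(seed=42, n_chromosomes=2, chrom_length=120_000,
                            n_genes=8, n_novel_segments=6)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        generate_fixture(cfg).write(out_a)
        generate_fixture(cfg).write(out_b)
        for name in ("query.fasta", "query.gtf", "target1.fasta",
                     "counts.tsv", "ground_truth.json"):
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_different_seeds_differ(self):
        base = dataclasses.replace(FixtureConfig(seed=1), n_chromosomes=1,
                                   chrom_length=60_000, n_genes=4,
                                   n_novel_segments=3)
        other = dataclasses.replace(base, seed=2)
        fx1, fx2 = generate_fixture(base), generate_fixture(other)
        assert fx1.query.chromosomes != fx2.query.chromosomes


class TestPlantedSegments:
    def test_zero_divergence_copies_are_exact_substrings(
        self, zero_divergence_fixture
    ):
        fx = zero_divergence_fixture
        targets = {t.name: t for t in fx.targets}
        from crossnovex.genome import revcomp

        sequences = {t.id: t.sequence for t in fx.transcripts}
        for planted in fx.truth.ortholog_map:
            copy = targets[planted.species].fetch(
                planted.chrom, planted.start, planted.end
            )
            if planted.strand == "-":
                copy = revcomp(copy)
            assert copy == sequences[planted.segment_id]
            assert planted.n_substitutions == 0

    def test_divergence_recoverable_within_binomial_bounds(self):
        cfg = dataclasses.replace(
            FixtureConfig(seed=9), divergence=0.05, segment_length=(300, 300),
            n_chromosomes=2, chrom_length=120_000, n_genes=8,
            n_novel_segments=6,
        )
        fx = generate_fixture(cfg)
        from crossnovex.genome import revcomp

        sequences = {t.id: t.sequence for t in fx.transcripts}
        targets = {t.name: t for t in fx.targets}
        for planted in fx.truth.ortholog_map:
            copy = targets[planted.species].fetch(
                planted.chrom, planted.start, planted.end
            )
            if planted.strand == "-":
                copy = revcomp(copy)
            source = sequences[planted.segment_id]
            mismatches = sum(1 for a, b in zip(source, copy) if a != b)
            n = len(source)
            # substitutions always change the base, so the mismatch count
            # equals the mask weight, distributed Binomial(n, divergence)
            assert mismatches == planted.n_substitutions
            sd = math.sqrt(n * 0.05 * 0.95)
            assert abs(mismatches - n * 0.05) <= 3 * sd

    def test_each_segment_planted_once_per_species(self, default_fixture):
        fx = default_fixture
        seen = {(o.species, o.segment_id) for o in fx.truth.ortholog_map}
        expected = {
            (t.name, s.id) for t in fx.targets for s in fx.transcripts
        }
        assert seen == expected
        assert len(fx.truth.ortholog_map) == len(expected)

    def test_all_placement_classes_covered(self, default_fixture):
        placements = {o.placement for o in default_fixture.truth.ortholog_map}
        assert placements == {"exonic", "intronic", "intergenic"}

    def test_capacity_error_when_segments_do_not_fit(self):
        cfg = dataclasses.replace(
            FixtureConfig(seed=0), n_chromosomes=1, chrom_length=30_000,
            n_genes=2, n_novel_segments=100,
        )
        with pytest.raises(FixtureCapacityError):
            generate_fixture(cfg)


class TestSimulateCounts:
    def test_poisson_limit_variance_matches_mean(self):
        cfg = dataclasses.replace(
            FixtureConfig(seed=10), nb_dispersion=0.0, n_de_features=0
        )
        counts, _ = simulate_counts(cfg, [f"f{i}" for i in range(1000)])
        # per-sample rates scale with library depth, so divide that out
        # before applying the Poisson variance == mean oracle
        depth = counts.library_sizes.to_numpy(float) / 1e6
        matrix = counts.counts.to_numpy(float) / depth
        mean = matrix.mean(axis=1)
        var = matrix.var(axis=1, ddof=1)
        ratio = var.sum() / mean.sum()
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_no_planted_fold_change_centers_log_ratio_at_zero(self):
        cfg = dataclasses.replace(
            FixtureConfig(seed=11), n_de_features=0, nb_dispersion=0.05
        )
        counts, labels = simulate_counts(cfg, [f"f{i}" for i in range(800)])
        assert set(labels.values()) == {"null"}
        depth = counts.library_sizes.to_numpy(float) / 1e6
        matrix = counts.counts.to_numpy(float) / depth
        log_ratio = np.log2(matrix[:, :2].mean(axis=1) + 0.5) - np.log2(
            matrix[:, 2:].mean(axis=1) + 0.5
        )
        assert abs(log_ratio.mean()) < 0.05

    def test_planted_fold_change_concentrates_near_target(self):
        cfg = dataclasses.replace(
            FixtureConfig(seed=12), n_de_features=400, planted_log2fc=2.0,
            nb_dispersion=0.02,
        )
        counts, labels = simulate_counts(cfg, [f"f{i}" for i in range(400)])
        depth = counts.library_sizes.to_numpy(float) / 1e6
        matrix = counts.counts.to_numpy(float) / depth
        up_a = [i for i, f in enumerate(counts.counts.index)
                if labels[f] == "up_in_a"]
        ratio = matrix[up_a, :2].mean() / matrix[up_a, 2:].mean()
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(FixtureConfig(), nb_dispersion=-0.1)

    def test_single_sample_groups_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(FixtureConfig(), ["f1"], samples_per_group=1)


class TestSimulateVariants:
    @pytest.fixture()
    def planted(self, default_fixture):
        variants, truth = simulate_variants(
            default_fixture.query, default_fixture.config
        )
        return default_fixture.query, variants, truth

    def test_every_consequence_kind_present(self, planted):
        _, _, truth = planted
        effects = {t.effect for t in truth.variant_truth.values() if t.effect}
        assert effects == {
            "synonymous", "nonsynonymous", "stopgain", "stoploss",
        }
        exts = {
            t.ext_length
            for t in truth.variant_truth.values()
            if t.effect == "stoploss"
        }
        assert "?" in exts  # a stop-loss with no downstream in-frame stop
        assert any(isinstance(e, int) for e in exts)

    def test_every_region_class_occurs(self, planted):
        _, _, truth = planted
        classes = {t.region_class for t in truth.variant_truth.values()}
        assert {
            "coding", "splicing", "coding+splicing", "UTR5", "UTR3",
            "UTR3+UTR5", "intronic", "intergenic", "upstream", "downstream",
            "downstream+upstream",
        } <= classes

    def test_quality_values_straddle_filter_thresholds(self, planted):
        _, variants, truth = planted
        keyed = {f"{v.chrom}:{v.pos}": v for v in variants}
        failing = [
            keyed[k] for k, t in truth.variant_truth.items()
            if not t.passes_filters
        ]
        passing = [
            keyed[k] for k, t in truth.variant_truth.items()
            if t.passes_filters
        ]
        assert any(v.dp == 5 for v in failing)
        assert any(v.gq == 20 for v in failing)
        assert any(v.qual == 80.0 for v in failing)
        assert len(passing) > len(failing)

    def test_region_truth_agrees_with_classifier(self, planted):
        genome, variants, truth = planted
        for v in variants:
            expected = truth.variant_truth[f"{v.chrom}:{v.pos}"].region_class
            got = classify_region(v, genome.genes_on(v.chrom))
            assert got == expected, (v.chrom, v.pos)

    def test_genome_without_cds_rejected(self):
        from crossnovex.genome import AnnotatedGenome, GeneModel

        bare = AnnotatedGenome(
            {"chr1": "ACGT" * 100},
            [GeneModel("g", "chr1", "+", exons=[(10, 50)])],
        )
        with pytest.raises(ValueError, match="CDS"):
            simulate_variants(bare, FixtureConfig())
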