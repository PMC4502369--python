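import math

import numpy as np
import pytest

from crossnovex.expression import TranscriptRecord
from crossnovex.genome import AnnotatedGenome, revcomp
from crossnovex.homology import (
    MATCH_SCORE,
    MISMATCH_SCORE,
    HomologyHit,
    filter_hits,
    identity_ratio,
    search,
)


def make_query(seq, qid="q1"):
    return TranscriptRecord(
        id=qid, chrom="q", start=1, end=len(seq), strand="+", sequence=seq
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIdentityRatio:
    def test_values(self):
        assert identity_ratio(90, 100) == pytest.approx(0.9)
        assert identity_ratio(100, 100) == 1.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            identity_ratio(1, 0)
        with pytest.raises(ValueError):
            identity_ratio(5, 4)


class TestFilterHits:
    def hit(self, matches, length):
        return HomologyHit(
            query_id="q", target_species="t", target_chrom="c",
            target_start=1, target_end=length, strand="+",
            aln_length=length, matches=matches, score=matches,
        )

    def test_exact_boundary_is_excluded(self):
        # 90/100 is exactly 0.9, and 'larger than 0.9' is strict
        assert filter_hits([self.hit(90, 100)]) == []
        assert len(filter_hits([self.hit(91, 100)])) == 1

    def test_empty_and_perfect(self):
        assert filter_hits([]) == []
        hits = [self.hit(50, 50), self.hit(80, 80)]
        assert filter_hits(hits) == hits


class TestSearch:
    def test_exact_substring_single_full_length_hit(self):
        rng = np.random.default_rng(1)
        target_seq = random_seq(rng, 3000)
        query_seq = target_seq[500:560]
        genome = AnnotatedGenome({"chr1": target_seq}, name="t")
        hits = search([make_query(query_seq)], genome)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.target_start, hit.target_end) == (501, 560)
        assert hit.identity_ratio == 1.0
        assert hit.aln_length == len(query_seq)
        assert hit.strand == "+"

    def test_no_shared_kmers_no_hits(self):
        genome = AnnotatedGenome({"chr1": "A" * 500}, name="t")
        hits = search([make_query("C" * 60)], genome)
        assert hits == []

    def test_minus_strand_copy_found_in_plus_coordinates(self):
        rng = np.random.default_rng(2)
        target_seq = random_seq(rng, 2000)
        query_seq = revcomp(target_seq[1000:1080])
        genome = AnnotatedGenome({"chr1": target_seq}, name="t")
        hits = search([make_query(query_seq)], genome)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].target_start, hits[0].target_end) == (1001, 1080)
        assert hits[0].identity_ratio == 1.0

    def test_query_shorter_than_seed_skipped_with_warning(self):
        genome = AnnotatedGenome({"chr1": "ACGTACGTACGT"}, name="t")
        with pytest.warns(UserWarning, match="shorter than seed"):
            assert search([make_query("ACGTA")], genome) == []

    def test_agrees_with_exhaustive_diagonal_scan(self):
        rng = np.random.default_rng(3)
        target_seq = random_seq(rng, 1500)
        # plant two diverged copies of a 55-mer, one per strand
        q = random_seq(rng, 55)
        diverged = list(q)
        for i in (10, 30):
            diverged[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[diverged[i]]
        copy = "".join(diverged)
        target_seq = target_seq[:200] + copy + target_seq[255:]
        target_seq = target_seq[:900] + revcomp(copy) + target_seq[955:]
        genome = AnnotatedGenome({"chr1": target_seq}, name="t")
        k, x_drop, min_score = 11, 20, 10
        got = search([make_query(q)], genome, k=k, x_drop=x_drop,
                     min_score=min_score)
        expected = brute_force_hits(q, target_seq, k, x_drop, min_score)
        assert {
            (h.target_start, h.target_end, h.strand, h.matches) for h in got
        } == expected

    def test_strand_symmetry_under_target_reverse_complement(self):
        rng = np.random.default_rng(4)
        target_seq = random_seq(rng, 2000)
        q = target_seq[300:380]
        length = len(target_seq)
        fwd = search([make_query(q)], AnnotatedGenome({"c": target_seq}, name="t"))
        rev = search(
            [make_query(q)], AnnotatedGenome({"c": revcomp(target_seq)}, name="t")
        )
        mirrored = {
            (length + 1 - h.target_end, length + 1 - h.target_start,
             "-" if h.strand == "+" else "+", h.matches, h.score)
            for h in rev
        }
        assert {
            (h.target_start, h.target_end, h.strand, h.matches, h.score)
            for h in fwd
        } == mirrored

    def test_planted_divergence_recovered_within_binomial_bounds(
        self, default_fixture
    ):
        hits = search(default_fixture.transcripts, default_fixture.targets[0])
        truth = {
            o.segment_id: o
            for o in default_fixture.truth.ortholog_map
            if o.species == default_fixture.targets[0].name
        }
        recovered = 0
        for o in truth.values():
            matched = [
                h for h in hits
                if h.query_id == o.segment_id and h.target_chrom == o.chrom
                and h.target_start >= o.start - 5 and h.target_end <= o.end + 5
            ]
            if not matched:
                continue
            recovered += 1
            best = max(matched, key=lambda h: h.aln_length)
            p = o.divergence
            sd = math.sqrt(p * (1 - p) / best.aln_length)
            assert abs((1 - best.identity_ratio) - p) <= 3 * sd + 2 / best.aln_length
        assert recovered >= 0.9 * len(truth)


def brute_force_hits(query, target_seq, k, x_drop, min_score):
    """Independent re-derivation: scan every ungapped offset on both strands."""
    results = set()
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        for diag in range(-(len(q) - 1), len(target_seq)):
            lo_q = max(0, -diag)
            hi_q = min(len(q), len(target_seq) - diag)
            if hi_q - lo_q < k:
                continue
            match = [q[i] == target_seq[i + diag] for i in range(lo_q, hi_q)]
            intervals = []
            for s in range(len(match) - k + 1):
                if all(match[s : s + k]):
                    intervals.append(
                        _xdrop(match, s, s + k - 1, x_drop)
                    )
            merged = []
            for lo, hi in sorted(set(intervals)):
                if merged and lo <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
                else:
                    merged.append((lo, hi))
            for lo, hi in merged:
                matches = sum(match[lo : hi + 1])
                length = hi - lo + 1
                score = matches * MATCH_SCORE + (length - matches) * MISMATCH_SCORE
                if score >= min_score:
                    t0 = lo_q + lo + diag
                    results.add((t0 + 1, t0 + length, strand, matches))
    return results


def _xdrop(match, seed_lo, seed_hi, x_drop):
    best, score, hi = 0, 0, seed_hi
    for j in range(seed_hi + 1, len(match)):
        score += MATCH_SCORE if match[j] else MISMATCH_SCORE
        if score > best:
            best, hi = score, j
        elif best - score > x_drop:
            break
    best, score, lo = 0, 0, seed_lo
    for j in range(seed_lo - 1, -1, -1):
        score += MATCH_SCORE if match[j] else MISMATCH_SCORE
        if score > best:
            best, lo = score, j
        elif best - score > x_drop:
            break
    return lo, hi
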