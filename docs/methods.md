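# Methods

This note records the models, defaults and numerical choices behind
`crossnovex`, and what the synthetic fixtures do and do not establish
about real data.

## Expression and filtering

FPKM is the simple closed form
`fpkm = count * 1e9 / (library_size * length)` with the library size the
sample's total mapped reads (a superset of the matrix column sum) and the
feature length the annotated exonic-union length where exons exist, else
the span length. No effective-length correction is applied; the
quantity is used only for thresholding, not for isoform inference.

Filter senses are literal and asymmetric on purpose: "expressed" means
FPKM strictly above 0.2 in at least one sample; novel-transcript
candidates need length strictly above 130 bp *and* FPKM of at least 5
(inclusive) in at least one sample. "At least one sample" is implemented
as the max over samples. The filters are idempotent.

Sample QC computes Pearson correlation and average-linkage (UPGMA)
hierarchical clustering on Euclidean distances, both on log2(FPKM + 1)
by default; the log transform is the standard variance stabilization for
RNA-seq QC and can be disabled (`log_transform=False`). A constant
sample has undefined correlation and is reported as NaN rather than 0.

## Homology search

The aligner is a deliberately small seed-and-extend local search:
exact k-mer seeds (k = 11), ungapped x-drop extension (match +1,
mismatch −2, x_drop = 20), extensions on one diagonal merged when they
overlap, and a minimum alignment score of 25 as the significance proxy
(E-value statistics are out of scope; at this score a chance hit in a
megabase-scale random genome is vanishingly rare). Ungapped alignment is
a deliberate match to the fixtures, which plant substitution-only
orthologs; gapped or spliced alignment is an extension point, and a
BLAST tabular (outfmt 6) adapter lets externally produced hits replace
the built-in aligner.

The identity ratio is matches over *alignment length* (a query-length
denominator is available via the hit fields); the > 0.9 filter compares
exact rationals so that 90/100 fails regardless of floating-point
representation. Minus-strand hits are found by reverse-complementing
the query and are reported in plus-strand target coordinates with a
strand flag, so downstream interval classification is strand-agnostic.

## Annotation overlap

Coordinates are 1-based inclusive end to end (GTF native); containment
tests are closed-interval. Gene spans default to the exon hull, which
guarantees exons and introns tile the span and makes the four-way
classification (exonic / intronic / partial-exonic / intergenic) a total
partition. When a hit is inside an exon of one gene and an intron of an
overlapping gene, the exonic call wins — exonic evidence is what feeds
the DE stage. Hits spanning several genes report the first gene by
coordinate with a `multi_gene` flag. UTR exons count as exons; the gene
span (not a transcript span) defines intergenic.

## Exact test and dispersion

The two-group test conditions on the pooled total of library-size-
equalized group sums (total-count scaling to the geometric-mean library
size; TMM-style robust normalization is out of scope). Under the null
each group sum is a sum of i.i.d. NB counts, so the group-A sum given
the total follows the NB-convolution conditional law — a
Dirichlet-multinomial form with per-group weights n/φ — reducing to the
binomial at φ = 0 with equal effective sizes. The two-sided p-value
sums the probabilities of all splits no likelier than the observed one
(float ties tolerated at 1e-10, so mirror-image outcomes count as
equally extreme); zero totals give p = 1 by convention. Group
pseudo-counts are rounded to integers after equalization; exactness
claims are made (and tested against exhaustive rational enumeration)
for the equal-size case.

The common dispersion is a pooled method of moments: with m and s² the
per-group sample mean and variance of normalized counts,
φ̂ = max(0, Σ(s² − m) / Σ m²), summed over features and groups. Two
choices matter here and were made deliberately:

* **Pool, then divide.** At 2 + 2 samples the per-feature ratio
  (s² − m)/m² is extremely right-skewed; robust summaries of it (e.g.
  its median) sit well below the true φ and make the exact test
  anticonservative. Pooling the moment equations first keeps the
  estimator nearly unbiased; measured on 2000-feature null fixtures
  with φ = 0.1 it recovers 0.095–0.102 and the raw p < 0.05 fraction
  stays near nominal.
* **Within groups.** Variances are taken within sample groups when
  group labels are available, so genuinely differential features do not
  inflate the estimate — their between-group difference never enters a
  within-group variance. With across-group moments, a fixture with a
  third of its features strongly DE had its common dispersion inflated
  enough to destroy power entirely.

"Minimum log fold-change of two" is read as |log₂FC| ≥ 2 (the
fold-change-software convention); group means are moderated by a prior
count of 0.5 before the log-ratio so zero groups stay finite. Hit-level
calls use FDR < 0.01 strictly; gene-level calls use FDR ≤ 0.01
inclusively — the two senses are kept distinct rather than unified
because each mode's published wording differs.

## Window similarity

The window equals the smallest hit length; both regions are tiled into
consecutive non-overlapping windows (a configurable stride exists for
exploration); a trailing remainder shorter than one window is dropped
rather than padded so all similarity denominators agree. Similarity is
ungapped positional identity, case-insensitive, with N matching nothing.
Every chunk pair is scored; the reported pairing is the best target
partner per query chunk (ties to the lowest target index), matching a
one-bar-per-segment visualization, with an all-pairs mode behind a
flag. Pairs strictly below 0.3 are omitted — exactly 0.3 is kept.
Minus-strand material should be reverse-complemented before chunking
(the pipeline does this via plus-strand hit coordinates). The SVG
renderer is hand-rolled precisely so identical inputs give identical
bytes; bar colors interpolate linearly from red at the floor to green
at 1.0.

## Variant annotation

Quality filters are strict on all three fields (DP > 5, GQ > 20,
QUAL > 80), each independently configurable; QD is parsed but not
filtered by default. Region classes use precedence tiers
coding/splicing > UTR > intronic > upstream/downstream; distinct
classes from different genes within the winning tier are joined into
combined classes (`coding+splicing`, `UTR3+UTR5`,
`downstream+upstream`). The splice window is 2 bp into the intron at
each boundary (the canonical GT/AG dinucleotides) and the
upstream/downstream flank is 1000 bp; both are configurable since
neither has a single field-wide convention. Exonic positions of a gene
without CDS annotation fall back to the gene-body (intronic) class.
Only biallelic SNVs are modelled.

Consequences translate the reference and alternate codon strand-aware
(genomic alleles are complemented for minus-strand genes). For a lost
stop, the extension length N in `ext*N` is the 1-based index of the
first in-frame stop codon downstream of the replaced stop, reading
through the 3′ UTR; if the UTR ends without an in-frame stop the length
is unknown (`ext*?`). Protein changes use three-letter codes with `*`
for stop (`p.Gln102*`, `p.*111Leuext*22`), synonymous changes render as
`p.Xxx123=`.

`hgvs.build_context` inverts this logic: given a printed coding change
and protein consequence it searches the 64 codons for a reference codon
consistent with both, pads the CDS with inert alanine codons, and for
stop-losses constructs a 3′ UTR whose first in-frame stop lies exactly
at the printed extension offset (or nowhere). This is how the curated
worked examples are replayed without any genome download.

## Synthetic fixtures

The generator emulates a two-tissue (testis/oviduct), two-samples-per-
group transcriptome study: a query genome with annotated coding genes,
planted intergenic novel segments, target genomes carrying one diverged
copy of each segment (exonic, intronic, or intergenic placement,
alternating strands), NB counts with planted fold-changes, and planted
variants covering every region class and consequence kind with quality
values straddling the filter thresholds on both sides.

Defaults: 5 chromosomes × 200 kb per genome, 40 query genes (4 exons
each), 2 target species, 12 segments of 200–600 bp, 5% divergence,
NB dispersion 0.1, library sizes 0.9–1.1 M, feature means log-uniform
on [100, 1000] (a realistic expressed-gene count range at this depth),
planted log₂FC 3.0, 40 variants. These sizes keep full-fixture
generation near one second and the complete suite under half a minute
while leaving every class populated several times over.

Deliberate simplifications, hence limits on what passing tests show
about real data: substitutions only (no indels — this is what gives
identity ratios and window similarities a clean binomial oracle);
uniform base composition (no GC bias or repeats, so seed statistics are
benign compared to real genomes); no read-level simulation, mapping
error, or multi-mapping; single-isoform genes; biallelic SNVs only.
Randomness derives from a single seed through named child seeds
(sequences, genes, targets, segments, counts, variants), so outputs are
byte-identical per seed; a capacity error is raised when the requested
gene/segment density cannot be placed.

## Numerical conventions

Threshold comparisons that sit on published boundaries (identity 0.9,
similarity 0.3) are done in exact rational arithmetic. The exact test
clamps p to [0, 1] and treats probability ties within 1e-10 as ties.
BH adjustment delegates to statsmodels. The UPGMA linkage delegates to
scipy. Dispersion estimates are floored at 0; an all-zero count matrix
warns and returns 0.
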