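# Methods

## Rationale and model

Retrotransposition-competent L1 elements occasionally mobilize the unique
sequence downstream of themselves (3′ transduction). An orphan transduction
(TD2) carries *only* that downstream sequence, so a capture design over the
first 5 kb downstream of each cataloged source element sees every such
event twice: once at the donor locus (normal coverage) and once wherever the
copy inserted. At the insertion locus two read-level signals arise from
paired-end data:

1. **discordant pairs** — one mate anchored at the insertion locus, the
   other mapping inside a donor's transduced region;
2. **clipped reads** — reads crossing the insertion breakpoint whose
   clipped extreme realigns inside a transduced region.

Both signals name the donor element (the barcode property), and clip
positions pin the breakpoint to base resolution up to the target-site
duplication (TSD) ambiguity.

## Coordinate conventions

0-based, half-open everywhere internally; BED I/O is native; VCF output is
1-based. A '+' element at (s, e) has its transduced region at (e, e + w);
a '−' element at (s − w, s), clipped at chromosome bounds; w = 5000 bp by
default.

## Caller

**Evidence scan.** One pass over a coordinate-sorted BAM. A pair is
discordant if not flagged properly paired, interchromosomal, or with
|template| > `max_insert` (default 1000 bp ≈ 3× a 350 bp insert). Soft
clips ≥ `min_clip_len` = 20 bp become clip evidence; shorter clips are not
unique within a ~620 kb target space. Hard clips are skipped (sequence not
recoverable from the primary record). Duplicates are kept but flagged, and
excluded from support counts.

**Clip realignment.** Clipped sequences are realigned to all transduced
regions on both strands with edlib infix (glocal) alignment; a hit needs
edit distance ≤ 0.1 × clip length (≥ 90 % identity). This replaces a
heuristic local aligner (BLAT-style) with a deterministic, exhaustive
search over the small target space; an independent Smith–Waterman oracle in
the test suite confirms that accepted/rejected clips match local-alignment
scoring with match +1 / mismatch −1 / gap −2 at a 0.8 × length score
threshold. Ties break to the lowest (chrom, pos).

**Clustering.** Single-linkage along the genome within
`cluster_gap_bp` = 500, in separate streams per evidence kind (discordant
vs clipped), anchor strand, and partner element (the donor region
containing the mate/supplementary coordinate). This equals transitive
closure of the pairwise predicate and is order-independent. Evidence whose
partner falls outside every transduced region is kept but flagged, never
silently dropped.

**Filters (annotate, don't delete).** `LOW_SUPPORT` (< 3 non-duplicate
reads — the validation standard for a true somatic event), `LOW_MAPQ`
(mean < 20), `DUPLICATES` (duplicate fraction > 0.5), `BLACKLIST`
(user-supplied intervals; no default list is shipped), `OFF_TARGET_PARTNER`,
and `ANCHOR_IN_DONOR_REGION` (anchor span inside any transduced region;
removes donor-locus self-signal and source-to-source insertions). PASS =
empty flag set; everything else is excluded from output but auditable.

**Metaclusters and breakpoints.** PASS clusters on one chromosome with the
same donor merge while their anchor spans lie within `meta_merge_bp` = 150.
Breakpoint: the modal clip position (ties → leftmost) when clip evidence
exists — accurate to within the TSD length — otherwise the inner edges of
the '+' and '−' discordant clusters, or a one-read-length extension when
only one side exists.

**Classification.** Strand class is PLUS/MINUS when all anchors map to one
strand, RECIPROCAL otherwise. A metacluster with discordant support whose
mates lie inside the donor window is typed TD2; a clipped sequence sharing
a 15-mer with the element's oriented 3′-terminal body sequence marks TD1
(the L1 body travelled too); clip-only metaclusters are AMBIGUOUS.

**Matched mode.** With a germline control, a call is demoted to
GERMLINE_SUPPORTED if ≥ 1 germline evidence read shares its donor element
and anchors within 150 bp of the breakpoint interval; otherwise SOMATIC.

Open parameters the source method leaves unstated (cluster gap, merge
distance, MAPQ cutoff, duplicate rule, realignment scoring) are exposed in
`CallerParams`/`ScanParams` with the defaults above.

## Simulator

The generator reproduces the benchmark construction, and its defaults are
the study conditions: 20 transduction sequences per element by uniform
random 3′ trimming (minimum product 100 bp — the floor is a package choice,
unstated upstream); insertion points drawn one-per-bin in 10 kb bins over
nuclear (non-chrM) chromosomes avoiding assembly gaps; inserts carrying a
TSD of 5–20 bp, a poly(A) tail of 10–60 bp, and, with probability 0.5, a 5′
truncation removing up to 20 % of the transduction (hallmark values follow
typical L1 insertion biology; the distributions are config-exposed);
insert strand 50/50; reads 150 bp paired-end with insert length
N(350, 35 bp) truncated at 2 × read length; VAF realized as the fraction of
fragments drawn from the insertion-bearing haplotype; uniform substitution
errors at 0.1 %. One insertion-bearing genome per seed is reused across
conditions; the depth series downsamples a single 150× / 50 % VAF
simulation pair-coherently, and the VAF series re-sequences the same genome
at the base depth.

**Aligned-emission mode.** Instead of writing FASTQ for an external
aligner, the simulator can map each read analytically through the insertion
coordinate map: maximal affine frames link modified-genome intervals to the
original reference (flanks, TSD copy) or to the donor window (transduction
core, including orientation flips); each read takes its longest
single-frame block as the primary alignment, soft-clipping the rest, with
mate fields, proper-pair flags and template lengths set consistently.
Poly(A)-only stretches are unmappable by construction. This makes the
benchmark deterministic and aligner-free; FASTQ mode remains for
integration with a real aligner. A capture option keeps only pairs with ≥ 1
mate overlapping a transduced region after mapping, mirroring both the
hybrid-capture assay and on-target post-filtering of the simulated BAMs.

**What the generator does not emulate.** Real repeat-rich genomes
(synthetic references are unique random sequence, so multi-mapping and
MAPQ-0 losses do not occur), aligner-specific clip placement, indels,
quality-dependent errors, PCR duplicates, FFPE fragmentation, and capture
efficiency gradients. Passing benchmarks therefore bound the *algorithmic*
error of the pipeline, not assay-level losses on real libraries; measured
recall on clean simulations is an upper bound on real-data recall,
especially at low VAF (see Limitations).

## Benchmark

Calls match truth greedily, nearest-first, one-to-one within 500 bp
(≈ one insert size, covering discordant-only breakpoint uncertainty), by
default also requiring donor-element identity — stricter than
coordinate-only intersection; a flag relaxes it. Precision = TP/(TP+FP),
recall = TP/(TP+FN); zero denominators are flagged rather than propagated
as NaN. On sparse truth sets the greedy count equals optimal bipartite
matching (asserted against a Hungarian oracle in tests).

The shipped acceptance study is scaled down: a ~5.4 Mb three-chromosome
synthetic genome with 10 source elements and 100–150 insertions, chosen so
the full depth and VAF sweeps run in minutes on one CPU while keeping
binomial uncertainty on a recall estimate near ±0.05 at 99 % confidence.

## Quantification

Activation score = PASS TD2 count / median per-base depth over the union of
transduced regions (coverage normalization); estimated total L1 activity =
6.33 × TD2 count, taking the published TD2-to-total regression slope as a
constant. "Active" = ≥ 1 PASS TD2 call — the only parameter-free
dichotomization — and "high activity" = score above the cohort median; both
are config-exposed. Group comparisons use the two-sided Wilcoxon rank-sum
test with midrank ties: exact null for group sizes ≤ 25 without ties,
otherwise the continuity-corrected normal approximation (verified against
exhaustive permutation for combined n ≤ 12). Gene overlap intersects the
breakpoint interval with gene intervals (half-open); recurrence counts
distinct samples per gene.

## Numerical and degenerate-input choices

All randomness flows from a single integer seed through
`numpy.random.Generator`; downsampling hashes (seed, read name) so mates
share their fate and reruns are bit-identical. Cluster and call outputs are
fully sorted, making results invariant to input record order. Degenerate
inputs: empty catalogs and empty BAMs produce empty outputs with warnings;
all-N donor windows are skipped; zero on-target coverage yields an
undefined (not zero, not NaN) activation score; regions clipped to zero
length at chromosome ends are retained but never match.

## Limitations

- Solo-L1 (TD0) insertions are invisible to the design and out of scope;
  TD1 recognition is a k-mer heuristic sufficient for the TD2-centric
  benchmark.
- Recall at low VAF on clean synthetic genomes saturates near 1 at high
  depth, because detection is limited only by binomial evidence counts;
  published low-VAF recall on real-style simulations is lower, reflecting
  losses (repeat mappability, aligner behavior, capture efficiency) that
  the generator deliberately does not model.
- The VAF estimate per call and the per-element activity matrix are
  simulation-oriented conveniences, not validated clinical measures.
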