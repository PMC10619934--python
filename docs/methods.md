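# Methods

## The gene-unit model

A 45S rRNA gene unit is modeled as an ordered, non-overlapping tiling of
regions: 25S, the 3'ETS repeat zone, the Sal-repeat array, the
spacer-promoter cluster, the gene promoter, the 5'ETS repeat zone, 18S,
ITS1, 5.8S and ITS2, with short conserved spacers between adjacent
variable zones. Unit coordinates are phased **anchor-first**: position 0
is the start of a conserved 25S subsequence (the anchor, default 500 bp).
A tandem array is phase-symmetric, and reads are segmented at anchor
hits, so this rotation of the conventional promoter-first diagram makes
segment boundaries coincide with unit boundaries. The I-PpoI cut site
is an offset inside the 25S; successive cut positions measure unit
lengths, and the anchor count is the gene count.

Four regions are variable-length elements (VLEs). A **subtype** is a
full permutation of VLE variant calls, one per variable region, held in
the catalog's registry. Coordinates are 0-based half-open internally
and 1-based inclusive in custom text outputs; bedGraph-like files keep
that format's own 0-based convention.

## Tokenization

1. **Segmentation.** All approximate anchor occurrences (edit distance
   ≤ 0.15 × anchor length, found by iterated best-hit search with
   masking) delimit unit segments, reported on the transcribed strand.
   Anchors on both strands mean a chimeric read and raise an error;
   reads with no anchor tokenize to nothing.
2. **Region extraction.** Each variable region is the span between its
   conserved flanks (200 bp of reference sequence on either side,
   matched at ≤ 0.25 divergence, scanning left to right). The flank
   divergence cap matters: for a 200-bp flank the best *random* infix
   match sits near 0.3 × length, so 0.25 leaves a gap between true
   matches (≈ 0.03–0.1 divergence on real error rates) and noise.
   Missing flanks (truncated units) yield a null region.
3. **Calling.** The catalog variant with minimum Levenshtein distance
   becomes the call; ties go to the earliest variant in catalog order
   and are flagged ambiguous. An optional maximum score turns distant
   matches into no-calls (off by default). Units with a call for every
   region are classified by exact registry lookup; classification never
   mutates the catalog unless registration is requested (new ids are
   max + 1).

All alignment in the package is unit-cost edit distance via edlib; there
is no scoring-matrix tuning anywhere.

## Catalog bootstrapping

When no catalog is supplied, one is built from the extracted region
subsequences: per region, sequences are binned by length
(single-linkage, gap > 20 bp), each bin's consensus is produced by
plurality-vote polishing of a median-length template (two rounds, so
template read errors — including indels — are voted away), and bins are
split recursively at columns where a minority base exceeds 20% of
aligned bases (diagnostic SNPs). Clusters under 5 members are
discarded; variant ids are assigned by descending cluster size. The
subtype registry starts empty and fills during tokenization.

## Landmarks and the locus map

Token k-grams are counted across reads for k = 2…12. A pattern is a
landmark candidate when its count is within ±40% of one genome copy and
supported by ≥ 5 occurrences. Two refinements proved necessary:

- **Span-corrected coverage.** A read witnesses a k-gram only if it
  spans k consecutive complete units, so the copy estimate divides by
  `coverage × Σ max(0, n_r − k + 1) / Σ n_r` over read unit counts
  rather than raw coverage; without this, single-copy trigrams at
  moderate coverage drift below the acceptance band and two-copy
  patterns drift into it.
- **Context purity.** Across reads, the token immediately left (and
  right) of a single-copy pattern is fixed; a candidate whose flanking
  token votes split below 70% majority is a multi-copy pattern that
  sampling noise pushed into the band, and is rejected. This removes
  the k-grams internal to homogeneous runs.

Minimal-k selection drops any pattern containing an already-selected
shorter one. Map building then collects pairwise offset votes from
reads containing two landmarks: the modal offset fixes each distance,
sub-80% agreement raises a conflict error, equal-support competing right
neighbours raise an ambiguity error naming the landmark, and a
breadth-first placement from the best-supported landmark produces
per-contig coordinates. Overlapping landmarks are merged at this stage
(the earlier landmark absorbs the later with its relative offset) —
overlap is only well-defined once coordinates exist, which is why the
merge lives in map construction rather than landmark discovery.
Landmark gaps are start-to-start distances in gene units. Disconnected
components come back as separate contig maps, mirroring the situation
where a homogeneous run longer than the read length cannot be walked
across; such runs are reconciled by `join_contigs`, which inserts the
number of units needed to match the subtype's read-abundance copy
estimate and records the join explicitly — never silently.

## Consensus ("tagged" assembly)

Each read's absolute position is the modal vote over all its landmark
occurrences (reads below 80% vote agreement are dropped as chimeras).
Per array position, placed complete units vote on the token; the winning
token's catalog sequence seeds a draft, and two rounds of plurality-vote
polishing against up to 40 covering read segments (globally aligned to
the draft; column ties resolve toward the draft, insertions require a
strict majority) yield the consensus. The original pipeline enforced
positional register during multiple alignment by inserting a unique
24-mer tag at every 25S; here the per-unit segmentation enforces the
same register directly, so tags are unnecessary — the per-unit anchored
alignment *is* the tag trick. A position covered by no complete unit
and not a declared join raises a coverage-gap error.

The polish depth cap (40) keeps the benchmark round trip under a minute
while leaving plurality votes with enormous margins at 3% error
(per-column error ≈ 1–2%, so 40-deep majorities essentially never flip).

## Validation statistic

`validate_assembly` compares coverage-normalized read k-gram counts
against assembly counts with a least-squares fit through the origin and
reports R² plus the signed residual table ("unaccounted copies"; a
positive residual means reads carry copies the assembly lacks). The
statistic is scale-dependent: with few units almost every pattern is
single-copy, the x-variance vanishes and Poisson noise dominates, so R²
is evaluated meaningfully at full locus scale (~900 units), where the
token-level read sampler (`simulate_token_reads`) supplies read sets
without the cost of base-level simulation.

## Downstream analytics

- **Homogeneity**: per 9-unit sliding window, the multiplicity of the
  modal subtype; an identity-to-center-unit mode is provided since the
  window statistic could be read either way.
- **Similarity matrix**: sparse (i, j) pairs where 3-unit VLE windows
  match exactly; transpose-symmetric by construction.
- **Anomaly scan**: units globally aligned to the reference; gap runs
  separated by ≤ 20 aligned bases coalesce (large-indel alignments are
  not unique and smear into interleaved micro-runs), and merged events
  ≥ 500 bp are reported with the dominant reference region label. The
  summed gap length, not the smeared span, is the event size.
- **Guide design**: all 20-mers 5' of an NGG PAM, both strands, present
  in ≥ 1 variant and absent at 0 mismatches from ≥ 1 other; no
  off-target or thermodynamic scoring. Cas9 cuts are blunt, 3 bp 5' of
  the PAM; fragment lengths always sum to the assembly length.
- **Per-unit variants / expression**: SNV sites from a minimal VCF
  (AF-filtered at > 0.001) are looked up through each unit's global
  alignment to the reference; RNA alt-allele frequencies are divided by
  the alt's assembly copy number (a carrier-fraction mode exists; copy
  count is the default reading of "occurrences in the assembly") and
  assigned at every carrier position, so summing a site's values over
  carriers returns its frequency exactly. Zero-carrier RNA alleles are
  reported as orphans, never plotted. RNA inputs are assumed already
  strand-filtered upstream.
- **Enrichment**: per region, per variant, call fractions in nucleolus
  vs nuclei token sets with pseudocount 1, compared as log2 ratios —
  chosen for exact antisymmetry under swapping the fractions and
  finiteness at zero counts. No significance testing.
- **Methylation**: site-weighted mean methylated fraction per context in
  500-bp windows at 250-bp steps (coverage-weighted mode optional);
  windows with < 5 sites at coverage ≥ 3 are emitted missing, mirroring
  regions too repetitive for unique mapping.

## The simulator

The generator emulates the structure the pipeline assumes, not nanopore
physics. Variable regions are head + motif×copies + tail (motif 45–90
bp, copy numbers spanning each region's length range), with one
same-length variant pair per region distinguished only by six planted
marker SNPs in the conserved context — the hard case for calling, and
the source of SNV sites for the expression module. Subtype 1 is the
all-reference permutation; subtype 2 carries each region's last variant
privately (no other subtype uses it), giving the silenced subtype
locus-specific VLEs as real NORs have. Arrays mix two pure homogeneous
runs with a geometrically skewed background and plant eight unique
background trigrams as guaranteed landmarks. Reads have log-normal
lengths (default mean 60 kbp, σ_log 0.55, max 300 kbp), uniform starts
overhanging the array ends (so edge units are covered), uniform strand,
and independent per-base errors split 40/30/30 between substitution,
insertion and deletion — no homopolymer or pore-specific structure.
Sorted-fraction token sets sample single units, with silenced subtypes
retained in the nucleolus set at 1/depletion (default 8). RNA site
frequencies are per-copy rate × block carrier count, so normalization
recovers the expressed block identically. Methylation sites are real
cytosines of the array DNA with their true CG/CHG/CHH context,
hypomethylated inside the expressed block.

What passing tests therefore show: the tokenizer, landmark logic,
consensus, and downstream arithmetic are correct under realistic
length/error/abundance regimes. What they cannot show: robustness to
systematic basecaller error profiles, homopolymer artifacts, real IGS
repeat microheterogeneity, or mapping biases in the short-read inputs —
those require the original instrument data.

## Benchmark scale and defaults

The round-trip benchmark simulates 120 units, 30 subtypes, two 8-unit
homogeneous runs, 8 planted landmark trigrams, 100× coverage, 60-kbp
mean reads at 3% error; it recovers the subtype sequence and gene count
exactly and ≥ 99.9% consensus identity in about a minute. Homogeneous
runs at this scale are kept spannable by the read-length tail
(an unspannable run is a legitimate outcome — it produces separate
contigs and an explicit join — but the benchmark exercises the
single-contig path; joining is tested separately). The full-scale
preset (894 units, 74 subtypes) is used for statistics that need locus
size, via token-level reads. Unit tests run a 40-unit, 30× version of
the same conditions.

Key defaults, with units: anchor length 500 bp, anchor divergence 0.15;
flank 200 bp, flank divergence 0.25; landmark k 2–12, copy tolerance
0.4, min support 5, context purity 0.7; map agreement 0.8, pair support
3; polish rounds 2, depth cap 40; bootstrap length tolerance 20 bp, SNP
fraction 0.2, min cluster 5; anomaly threshold 500 bp, merge gap 20 bp;
homogeneity window 9 units; similarity window 3 units; VCF frequency
floor 0.001; methylation window/step 500/250 bp; enrichment pseudocount
1. Coverage for copy estimates is total tokenized units divided by the
expected gene count (CLI `--expected-genes`), since a per-subtype
abundance estimate is not available before assembly.

## Known limitations

- Tandem arrays of a single repeat family only; no general assembler,
  no telomere/centromere junction resolution beyond terminal flags.
- Mixed-orientation reads are rejected, not split.
- Only SNV alleles in the expression module; indel alleles are ignored.
- The landmark copy filter assumes roughly uniform coverage; a strong
  local coverage dip can orphan a region of the map into its own contig
  (reported, not hidden).
- Variable regions are fixed by the gene model; novel variable regions
  are not discovered automatically.
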