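# Methods

This note documents the models and conventions behind `mtg4`: what each
analysis computes, the parameters that matter, what the simulators emulate,
and where genuinely open design choices were settled.

## G4 consensus scanning

The scanner implements the conservative quadruplex consensus of at least
four runs of at least three guanines separated by loops of 1–30 nt,
evaluated as the regular expression `(G{3,}[ACGTN]{1,30}){3,}G{3,}` with
standard engine semantics: matches are leftmost, greedy and
non-overlapping. Loops are unrestricted over the nucleotide alphabet and
may themselves contain guanines; the greedy engine decides which Gs count
as runs and which as loop residues, and `mtg4` recovers that exact
assignment by replaying the engine's backtracking order (repetitions
preferred over termination, longer runs before shorter, longer loops before
shorter) when reporting `g_runs` and `loop_lengths`. This reproduces a
literal regex computation rather than an idealized thermodynamic G4 model;
scoring schemes (G4Hunter-style), RNA folding and two-quartet quadruplexes
are out of scope.

Parameters (`ScanParams`): `min_run` = 3 nt, `min_runs` = 4,
`loop_min`/`loop_max` = 1/30 nt, `circular_extension` = 200 nt. For
circular genomes the scanned string is extended by `circular_extension`
past the origin and matches whose start maps beyond the genome length are
dropped, so an origin-spanning motif is counted exactly once. Because the
`{3,}` quantifiers are unbounded, a match can in principle outrun the
extension; the scanner then warns and re-scans with the extension doubled
until the longest match fits.

Two consequences of non-overlapping counting are worth knowing. First,
relaxing parameters does not always increase the count: widening `loop_max`
can fuse two neighbouring motifs into a single match (verified by test).
Second, the motif set of a circular genome is invariant under rotation of
the origin for well-separated motifs, but adjacent motifs at the origin
could in principle be re-segmented; the extension convention makes the
behaviour deterministic.

Strand handling: the reverse strand is scanned on the reverse complement
and mapped back to reference coordinates. For human mtDNA the deposited
reference strand is the C-rich light (L) strand, so the strand-to-transcript
table defaults to "+" → H-strand-templated transcripts and "−" →
L-strand-templated (G-rich) transcripts; the table is configurable for
genomes deposited in the opposite orientation.

The genome-size-normalized count is `count / (L / L̄)` with `L̄` the mean
genome length of the cohort under comparison (configurable), so genomes of
different sizes are comparable per unit of "average genome".

## Composition statistics

AT fraction excludes N from the denominator. GC skew (G−C)/(G+C) is
computed on the strand as given in the input record and is reported as
missing (NaN), never zero, when a sequence contains no G or C; the
complementary strand's skew is the negation. Sliding G-fraction tracks use
a 50-nt window advanced in 5-nt steps; on circular genomes windows wrap so
every position is covered, and windows containing N report the fraction
over non-N bases and carry a flag. Intervals are 0-based half-open
internally and 1-based inclusive in reports; an interval whose end precedes
its start denotes an origin-spanning region and has length
`L − start + 1 + end` (so 11900–11972 on a 16,569-nt genome is 73 nt, and
16569–2 is 3 nt).

## Composition-matched null model

The null asks whether a genome's G4 count is explained by length, AT
content and GC skew alone. Two generators are provided:

- **constraint** (default): base counts are solved from the three matched
  statistics — `n_AT = round(at·L)`, `n_G = round(n_GC·(1+skew)/2)` — and
  placed in uniformly random order. The A:T split is unconstrained by the
  matched statistics; the default preserves the template's A:T ratio (an
  even split is available) rather than inventing an AT-skew constraint.
  Conservation is exact up to one base of rounding.
- **permute**: a uniform permutation of the template's residues, conserving
  all four counts exactly; used where machine-exact conservation matters.

Each of the `n` replicates (default 10,000; the package uses hundreds to a
thousand in its own tests and acceptance runs to keep runtimes in seconds)
is scanned on both strands under the same circularity as the template.
Replicate `r` draws its generator from a child of the master seed, so runs
are reproducible and order-independent. The empirical p-value uses the
add-one convention `(1 + #{replicates ≥ observed}) / (n + 1)`, which is
never zero and is super-uniform under the null (verified by a one-sided
Kolmogorov–Smirnov check on null-drawn templates). The z-score is reported
as missing when the null distribution is degenerate (zero variance).

Cohort comparisons of AT fraction, GC skew or normalized G4 count between
two groups of genomes use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test: exact enumeration when both groups have ≤ 20 untied values,
tie-corrected normal approximation otherwise, and p = 1 for the degenerate
all-tied case. Dinucleotide-preserving shuffles and phylogenetic
corrections are deliberately not offered.

## Strand-specific coverage and metagene profiles

Coverage is kept per position and per template strand in reference
orientation and normalized by the total number of reads mapped to both
strands, so all downstream quantities are invariant to library size.
Pileups accept BAM/SAM (secondary/supplementary reads skipped, mapping
quality ≥ 10 by default — uniquely mapped input is assumed, the threshold
is a guard, not a multimapper filter) or per-strand BEDGraph pairs; aligned
positions are taken modulo the genome length so reads placed across the
circular origin count at both ends.

**Strand contribution**: for each strand, eligible positions exclude
annotated functional transcripts (gene/mRNA/rRNA/tRNA by default,
configurable) on that same strand and any position antisense to rRNA or
tRNA genes — the latter because antisense bleed-through from highly
expressed structural RNAs would otherwise contaminate the non-coding
signal. Normalized depth is summed per strand over its eligible positions
and expressed as fractions of the two-strand total (which sum to one
whenever eligible coverage is positive). Under the default human
convention the "−" track carries L-strand-templated transcription.

**Metagene profiles**: windows of ± `halfwidth` (default 500 nt) around
each motif center are taken on the motif's transcript strand (or the
complementary strand for the antisense profile) and oriented 5′→3′ along
the transcript, so negative offsets are always transcript-upstream.
Normalized depth is averaged across motifs per offset first, and the
treated/control ratio of the two aggregate profiles is then formed — the
aggregate-coverage convention of standard metagene tooling. The alternative
(averaging per-motif ratios) carries a ≈ +1/depth small-count bias that
distorts low-depth profiles; the aggregate form is unbiased and was chosen
as the default. Each side of the ratio is stabilized with a pseudocount,
by default 0.5 reads / `total_mapped` of its own library, which protects
zero-coverage control positions; with the pseudocount engaged exact scale
identities hold only approximately, so tests of exact identities pass
`pseudocount=0`. Windows wrap on circular genomes and are clipped (with
NaN-aware averaging) on linear ones. A 3′→5′ exonuclease stalling at a G4
leaves its signature as a treated/control excess at negative offsets —
upstream of the motif — which is the qualitative fingerprint the simulator
plants and the acceptance checks recover. Note that when one condition
gains a large amount of RNA, library-size normalization scales its whole
profile down; the upstream/downstream *contrast*, not the absolute level,
is the readout.

## Short-RNA reconstruction and tail calling

A read pair proves a full-length molecule only if its mates overlap: r2 is
reverse-complemented and the maximal 3′-of-r1 / 5′-of-rc(r2) overlap of at
least 5 nt with at most `max_mismatch` mismatches (default 0; the merge is
performed before alignment, so no tolerance is assumed) defines the merge;
shorter overlaps are rejections, not errors. Ties are resolved
deterministically: fewest mismatches first, then the longest overlap.

Merged molecules are located on the genome by exact search on both strands
of the circularized sequence. The non-templated 3′ suffix is found
conservatively: tail lengths are tried from zero upward, so the shortest
tail whose removal leaves a perfect genomic match wins and anything the
genome can template is attributed to the genome — a genomically templated
CCA is therefore never called as an addition. Suffixes map to the labels
none/C/CC/CCA/CCACCA/other; CCACCA is detected and reported even though it
is not expected in mitochondria, precisely so its absence is an observation
rather than a blind spot. Species are groups of identical
(5′ end, 3′ end, strand) after tail trimming; groups below `min_count`
(default 2 — the minimal support that excludes singleton artifacts)
are dropped, and species overlapping annotated tRNAs are flagged rather
than quantified, since ligation-based short-RNA libraries without
tRNA-specific treatment do not quantify tRNAs reliably.

## TAP-MS candidate filter

Abundance is the mean of the three replicate intensities divided by the
molecular weight (intensity/kDa); enrichment is the mean bait intensity
over the mean tag-only-control intensity. "Present" means nonzero intensity
in a replicate (zero is "not quantified" in label-free output). A candidate
passes when it is present in all three replicates of both baits, enriched
above the threshold (default 3) for both, and annotated mitochondrial.
The threshold comparison is strict (>) by default with a `>=` option, since
published wordings differ between "more than three-fold" and "at least
three-fold"; the boundary only matters for a protein sitting exactly at
3.0. A control mean of zero is imputed with the smallest nonzero intensity
anywhere in the table (global floor) and flagged — this avoids infinite
ratios while preserving ranking. All decisions are invariant to rescaling
the whole table and to replicate permutation. Candidates are ranked by the
weaker of their two bait enrichments, so a partner must co-purify with both
subunits to rank highly.

## Synthetic data

The generators are pure functions of a `SimConfig` (NumPy PCG64 streams
spawned from one master seed; the RNG algorithm is recorded in the ground
truth) and write down everything needed to verify downstream results.

- **Genomes**: backgrounds are drawn under the configured length, AT
  fraction and GC skew — defaults 16,569 nt, 0.556, −0.41, the human
  reference-strand values — then scrubbed of chance G4 consensus matches by
  composition-preserving base swaps, and `n_planted_g4` minimal-consensus
  motifs (G₃N G₃N G₃N G₃, 15 nt) are inserted at recorded, well-separated
  positions (default 7 motifs on the "−" strand). The clean-background
  guarantee makes false-positive expectations exactly zero for scanner
  tests; it is a test convenience, not a claim about real genomes, whose
  backgrounds contain chance consensus matches (the null model quantifies
  that). Planting and scrubbing preserve the global base counts exactly but
  locally reorganize the sequence, so background composition matches the
  configuration to one base of rounding only in the unplanted case.
- **Coverage**: independent per-position Poisson depth per strand (mean
  `coverage_depth`, default 50 reads/base); the decay-deficient condition
  multiplies the expected depth on the motif-carrying strand by
  `accumulation_factor` (default 5) over a window 10–350 nt upstream
  (transcript 5′ direction) of each motif center. The metagene preset uses
  80 anchors on a 60-kb genome: the per-offset standard error of the
  aggregate ratio is ≈ sqrt(2/depth)/sqrt(n_motifs) ≈ 2.2%, which keeps a
  control-vs-control profile inside a ±10% band across all 1,001 offsets
  while anchor spacing (≥ 700 nt) keeps one motif's upstream window out of
  its neighbours' scoring windows. The Poisson choice models shot noise
  only — no overdispersion, positional bias or fragment-length correlation —
  so passing tests demonstrate correct computation, not robustness to
  real-library artifacts.
- **Read pairs**: 2×75 nt reads (r1 the 5′ prefix, r2 the reverse
  complement of the 3′ suffix, clipped to the molecule) over species of
  60–90 nt with tails drawn from the configured mix (40% none, 50% CCA,
  10% CCACCA); tails are only planted where the genome does not continue
  with the tail's first base, so every planted tail is genuinely
  non-templated. A configurable number of species are exactly
  2·read_length − 4 nt long, making their true overlap 4 nt — rejected by
  construction — and the generator verifies that no coincidental ≥ 5-nt
  overlap exists for any pair, so merge outcomes are fully determined by
  the recorded truth.
- **TAP-MS tables**: log-normal intensities (σ = 0.15 replicate noise),
  7 planted partners enriched 5–20-fold for both baits, and decoy classes
  exercising each criterion: a missing bait replicate, non-mitochondrial
  proteins at 100-fold enrichment, and control-absent proteins whose bait
  signal sits at twice the imputation floor (enrichment 2 after imputation,
  below threshold). A sentinel intensity fixes the global floor
  deterministically.

## Problem sizes and numerical conventions

The package's own tests and acceptance runs use deliberately compact
configurations — 2–60 kb genomes, hundreds to a thousand null replicates,
10,000 read pairs, 200-protein tables — chosen so every check completes in
seconds while the statistics remain decisive (planted effects are ≥ 5σ
from their nulls). Degenerate inputs have defined behaviour throughout:
all-N sequences and empty tables raise; undefined GC skew and undefined
z-scores are reported missing rather than coerced to zero; merge failures
and unalignable species are return states, not exceptions. Exit codes of
the CLI distinguish usage (2), input validation (3) and runtime (4)
failures, and every primary TSV output carries a provenance header
(version, config hash, seed).

## Known limitations

- The scanner counts non-overlapping consensus placements; overlap-tolerant
  counting and thermodynamic plausibility are out of scope.
- The null model matches single-nucleotide composition only; dinucleotide
  structure (e.g. CpG-like effects) is not preserved.
- The coverage simulator does not model transcription units, processing
  sites or sequencing error; real-data metagene profiles will be noisier
  and can carry annotation-driven structure the simulator lacks.
- Tail calling assumes exact genomic match of the core; a sequencing error
  in the last core base would masquerade as a 1-nt tail (label "other" or
  "C"), which is why species-level calls aggregate over supporting reads.
- The TAP-MS filter nominates candidates; it performs no significance
  testing and inherits whatever protein inference the upstream
  quantification used.
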