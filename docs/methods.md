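# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and states what the bundled synthetic
conditions do and do not establish about real data.

## The analysis problem

Ribosomal DNA and similar multicopy loci are absent from standard
reference assemblies. The working strategy is to insert one canonical
repeat unit into a host chromosome (for mouse rDNA, a ~45.3-kb unit
added at the proximal end of the chromosome that carries rDNA
endogenously) and align all reads to the augmented build. Two
consequences drive the rest of the pipeline. First, partial copies of
the repeat dispersed through the genome (pseudogenes) make stretches of
the unit unreachable by uniquely aligning short reads, so a mappability
track is needed to say where signal can exist at all. Second, reads
from hundreds of genomic copies pile onto one inserted copy, so repeat
signal must be compared against single-copy chromatin through an
explicit statistic (the normalized tag density) rather than read
directly.

## Genome build

Coordinates are 0-based half-open everywhere inside the package;
1-based conventions appear only at file-format boundaries. The default
insertion position is offset 0 (prepend), which makes repeat-local and
build coordinates coincide; an explicit offset is accepted because the
exact junction used in any particular published build is a choice, not
a constant. The inserted unit is kept verbatim (including N characters)
and existing host sequence is never replaced. Feature coordinates
(coding region ending near 13.4 kb, intergenic spacer to the end of the
unit, a ~200-bp spacer promoter ~2 kb upstream of the transcription
start site) are configuration with sensible mouse-flavored defaults,
because published boundaries are approximate.

## Mappability

The repeat is tiled into k-mers at 1-bp intervals from both strands
(k = 36 by default, a historical short-read length). A tile counts as
uniquely aligning when the total number of occurrence loci of the tile
or its reverse complement, over all chromosomes of the build, is
exactly one. The built-in matcher is exact (0 mismatches) over a hash
index of all genomic k-mers: exact matching is deterministic and
oracle-checkable, and on real data a mismatch-tolerant aligner can only
reveal additional alignment loci, i.e. tighten uniqueness — externally
aligned tiles can be supplied through the SAM reader when that behavior
is wanted. Three conventions matter and are fixed here: tiles
containing N never match; a palindromic tile is one alignment per locus
regardless of which strand tiling produced it (an aligner reports one
alignment per locus); and each unique alignment contributes once per
(locus, strand).

Each unique hit is extended to the estimated fragment length
(ext = 200 bp) in the read's 3′ direction — a '+' hit at s covers
[s, s+200), a '−' hit whose tile occupies [s, s+36) covers
[s−164, s+36) — and the track counts fragments overlapping each base,
clipped at the repeat boundary (the build carries one linear copy; no
wraparound). At any interior base, 200 start positions per strand can
produce an overlapping fragment, so the ceiling is 400 ("100%
mappability"); the extension is to a *total* length of 200 bp because
that is the only reading consistent with this ceiling. A base is
declared mappable when its count strictly exceeds 25% of the ceiling
(> 100 of 400); summaries report mappable fractions for the whole unit
and per annotated feature. Full-assembly fractions for the real mouse
unit require the external genome and are deliberately not bundled; the
summarizer is validated on constructed tracks with hand-computable
fractions instead.

## Signal and peaks

Reads are collapsed to one per (chromosome, start, strand) — the
standard duplicate guard for single-end data — then each read is
notionally extended to the fragment size and represented by a Gaussian
kernel at the fragment center (center = start + 100 on '+',
start + read_length − 100 on '−', for 200-bp fragments). The track is

  signal(b) = Σᵢ exp(−(b − cᵢ)² / 2h²) / (√(2π) h),

with bandwidth h = 50 bp by default (a quarter of the fragment size,
concentrating kernel mass within one fragment length); each kernel
integrates to ~1 so the track sums to the fragment count. Kernels are
truncated at ±8h: at that radius the omitted tail is below 1e-14 of a
kernel's mass, so truncation is numerically invisible at double
precision while evaluation stays O(window) per fragment (integer
centers are evaluated exactly by discrete convolution). A tighter
radius (e.g. ±4h) would leave relative errors of order 1e-4 against
direct summation on realistic read densities, which is why the wider
default was chosen.

Input subtraction is per base with library-size scaling:
out = chip − (N_chip/N_input) · input, so identical ChIP and input
libraries cancel exactly; negative residuals are retained for faithful
visualization of depletion. Peaks are maximal runs of signal above
T = μ₀ + z·σ₀, where μ₀ = N/L and σ₀² = N(I₂/L − 1/L²) with
I₂ = 1/(2h√π) are the per-base mean and variance of the kernel density
of N fragments placed uniformly on a length-L region; a Monte-Carlo
background (≥20 seeded uniform placements) is available and agrees with
the analytic moments to well under 10% at typical scales. The default
z = 4 is conservative; peaks are called on the input-subtracted track
by default (configurable), where the background model based on the raw
fragment count is slightly conservative again because subtraction
centers the baseline near zero. Summits take the leftmost maximum of a
run; every output is deterministic given the inputs and seed.

## Normalized tag density

Peaks are assigned by summit position: inside the repeat interval, or
outside-but-on-the-host-chromosome (other chromosomes are excluded from
the denominator). The statistic is mean(inside intensities) /
mean(outside intensities), using summit height as intensity by default
(peak area is available behind a flag; the two orderings agree on the
synthetic designs tested). When either side has no peaks the result is
signaled as a distinct undefined condition rather than 0 or NaN — a
ratio against an empty denominator has no meaning and silently
propagating one would poison downstream tables.

## Binned profiles and comparison

The repeat is divided into 100-bp bins (the final bin may be short —
454 bins for a 45,309-bp unit) and the per-base median taken in each,
on the input-subtracted track by default. Pairs of samples are compared
by simple OLS; the reported score is the adjusted
R² = 1 − (1−R²)(n−1)/(n−2), which can be negative for anti-predictive
fits — the form that matches published locus-wide comparisons — with
the F-test p-value on (1, n−2) degrees of freedom. R², adjusted R² and
p are symmetric in the pair; slopes are not. Multi-sample score
matrices are ordered by hierarchical clustering with Euclidean distance
and complete linkage on the raw profile vectors (deterministic given
input order); constant profiles get NaN scores against others and are
flagged rather than dropped.

## Synthetic data: what it emulates and what it does not

The generator produces (a) an i.i.d. random host chromosome at a chosen
GC (default 42%, mammalian-like), with one full random repeat unit
(default 45,309 bp, the mouse unit length) prepended, and a configurable
number of pseudogenes — contiguous sub-intervals of the repeat (default
10% of its length) copied verbatim to non-overlapping random host
positions — so multi-mapping arises *structurally* and the mappability
module, not the simulator, decides uniqueness; and (b) read sets whose
fragment centers are uniform (input) or a mixture of uniform background
and Gaussian spread (s.d. 50 bp) around designed repeat-local sites
(ChIP), with coin-flip strands, PCR duplicates injected by re-emitting
existing reads, and a provenance label on every read. The standard
operating point used throughout testing is three equal-weight sites at
10/40/80% of the repeat, 30% enriched fraction, 50,000 reads, 10%
duplicate rate. Reads are emitted pre-aligned at their true coordinates
so the pipeline is testable without an aligner; a FASTQ writer supports
integration tests with a real one.

Deliberately not modeled: sequencing errors, GC bias, fragment-length
dispersion, chromatin accessibility structure in the background, and
the sequence divergence of real pseudogenes (copies are exact). Passing
tests therefore demonstrate the correctness of the computations and the
recoverability of designed signal under idealized noise — not that any
particular biological dataset will behave as cleanly. In particular,
real rDNA pseudogenes are diverged, so exact-copy pseudogenes are the
*harsher* case for mappability loss at a given copy length.

Two test-design notes. Because designed sites live inside the repeat
and the background is uniform, an input-subtracted track at z = 4
yields no peaks outside the repeat and the tag density is correctly
undefined; tag-density response tests therefore call peaks on the raw
ChIP track at z = 3, where host-chromosome background fluctuations
supply denominator peaks — mirroring real data, where the host
chromosome always yields peaks. And duplicate-removal counts are
checked against the set of distinct read positions rather than the
injected-duplicate label count alone, since independent background
reads occasionally collide at desk-scale genome sizes.

## Problem sizes

Bundled runs use a 150-kb host + 45.3-kb repeat for signal-stage work,
2.5–3-kb repeats on 8–9-kb hosts for mappability oracle comparisons
(where the brute-force string-scanning oracle is quadratic), and
24-kb/6-kb builds for end-to-end determinism runs. These sizes keep the
whole suite in tens of seconds while leaving every statistic in the
regime where its expected behavior is unambiguous.

## Known limitations

- The built-in uniqueness matcher is exact-match; mismatch-tolerant
  uniqueness (e.g. up to 2 mismatches) must come from an external
  aligner's SAM output.
- Single-end model only; no paired-end fragment inference, no
  CIGAR-aware duplicate marking, no broad-domain segmentation.
- The analytic background assumes uniform fragment placement; strongly
  structured backgrounds would need the Monte-Carlo mode with a custom
  placement model.
- One repeat unit per build; no liftover between assemblies.
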