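# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind asmkit, in the order a typical analysis meets them.

## Synthetic data model

The generators exist so that every analytical procedure in the package can
be exercised end-to-end on data whose ground truth is known. They emulate
the *statistical* structure the analyses rely on, not sequence biology.

**Genomes.** `simulate_genome` draws an i.i.d. background at a requested GC
(default 0.42, a typical grass-genome value) and plants repeat families as
`copy_count` near-identical copies of one random unit at uniformly drawn
non-overlapping positions, each copy independently mutated at `divergence`
substitutions per base. Repeats are abstract units: no transposable-element
structure, no tandem arrays, no homopolymer realism. Placement is by
rejection sampling; a family that cannot be placed after 10,000 attempts
raises an error naming the family rather than silently truncating.

**Read lengths.** Long-read length distributions are modelled log-normal.
Given a target mean and N50 the closed form

    sigma^2 = 2 ln(N50 / mean),    mu = ln(mean) − sigma^2 / 2

follows from matching the log-normal mean exp(mu + sigma²/2) and its
base-weighted median exp(mu + sigma²), which is the N50 in the large-n
limit. A target N50 equal to the mean yields the sigma = 0 constant-length
model (used for short-read emulation); below the mean there is no solution
and the fit errors. The log-normal is a stand-in: real basecalled runs are
typically heavier-tailed in ways a two-parameter family cannot capture.
Fitted to mean 33.7 kb / N50 62.6 kb it reproduces the observed ~6% of
reads above 100 kb, but puts ~33% of bases in those reads where real runs
of that scale report ~25% — a known mismatch of the stand-in, which is why
no test or reported quantity relies on the base-weighted tail.

**Reads.** `simulate_reads` draws uniform start positions and model
lengths, floors lengths at `min_length`, truncates at the genome end, and
stops at the first crossing of `coverage × genome_length` total bases.
Errors are i.i.d. substitutions; constant per-base qualities are emitted at
the Phred equivalent of the error rate (Q90 for error-free reads, an
arbitrary "effectively certain" sentinel). Reads come from the forward
strand: no downstream statistic in this package is strand-sensitive, and
the assembler is simpler for it. Two deliberate artifacts of the linear
(non-circular) layout: a coverage ramp of about one read length at the
genome's left edge, and length truncation against the genome's right end.
Both vanish as genome length grows past read length; tests that measure
length-distribution convergence therefore use genomes ~100× the mean read
length.

**Depth histograms.** `simulate_depth_histogram` samples a three-component
Poisson mixture: the primary depth, an allelic component at 0.5× holding
`allelic_fraction` of bases, and a collapsed component at 2× holding
`collapsed_fraction`. Real per-base depth along a genome is spatially
autocorrelated; the mixture samples independently, which makes the
histograms *cleaner* than reality — detection rates measured on them are
upper bounds (see Limitations).

**Anchor tables.** `simulate_anchor_table` assigns each contig one majority
chromosome (of seven, matching a ryegrass-like karyotype) and reassigns
engineered runs of consecutive genes to a neighboring chromosome label.
Gene positions are strictly increasing with jittered ~20 kb spacing.

Empty-output requests (coverage 0, zero bases) raise immediately: a
generator that silently returns nothing hides pipeline bugs.

## Read statistics and manipulation

Nx/Lx follow the prefix-sum definition with an inclusive threshold (the
smallest length whose cumulative sum *reaches* x% of the total). Mean read
quality averages per-base error probabilities before converting back to
Phred — the ONT convention, which is several Q units lower than the
arithmetic mean of Q values and is what "mean q-score" cutoffs refer to.
Both filter thresholds are inclusive: a read exactly 2 kb long or exactly
at the quality cutoff is kept, and reads without quality strings pass the
quality filter on length evidence alone.

Cutting applies offsets sequentially; an offset fires only when the current
remainder is *strictly longer* than it, so no zero-length fragment can
arise and total bases are conserved exactly (enforced, not assumed, in
`run_cut_series`). Coverage subsampling shuffles once (seeded) and stops at
the first crossing of the base target, so the overshoot is smaller than the
last read; requesting more coverage than available errors with the
achievable value. Coordinates are 0-based half-open throughout.

## k-mer analytics

Counting is canonical (lexicographic minimum of a k-mer and its reverse
complement) with k ≤ 31, each k-mer packed two bits per base into a uint64
and multiplicities obtained by a single sort. Windows containing non-ACGT
symbols are skipped. Inputs above a 200 Mb base budget are rejected with
instructions to raise the budget explicitly — this is an in-memory counter
for desk-scale work, not a disk-backed one. Default k = 21.

The noise threshold is the first local minimum scanning multiplicity
upward (first m with h(m) < h(m+1)); a monotone-decreasing histogram falls
back to 1 with a flag. Genome size is solid instances over peak depth. The
peak depth is found as a smoothed argmax refined to the fixed point of the
bin-mass centroid within a ±20% window: histogram bins are spatially
correlated along the genome (neighboring positions share covering reads),
so the raw argmax wanders by several multiplicity units on sub-megabase
genomes, and a bare integer argmax additionally carries a λ/⌊λ⌋ bias of up
to ~1/peak when the true depth falls between integers. `refine=False`
restores the plain argmax. The estimator assumes a haploid/homozygous
sample (e.g. a doubled haploid); a heterozygous half-depth peak would be
mistaken for noise or peak and inflate the estimate — out of the default
model and stated in the output metadata.

Completeness and spectra-comp intersect sorted code arrays; the spectra
matrix rows reproduce the read histogram exactly (conservation is tested),
and completeness equals 1 minus the solid 0×-column fraction by
construction.

## Assembly evaluation

Depth histograms from intervals use a per-target difference-array sweep, so
Σ depth·bases = Σ interval lengths holds as an exact integer identity.
Breadth is the fraction of bases at depth ≥ 1; "unique" mapping is the
caller's responsibility (PAF input can be thresholded on mapping quality).

Collapse detection smooths the histogram with a centered moving average
(window max(3, 5% of the occupied depth range), forced odd), takes the
primary mode as the smoothed argmax at depth ≥ 1 (depth 0 is uncovered
sequence, never a peak), and calls a secondary peak when a smoothed local
maximum falls inside the window [0.4, 0.6]× (allelic) or [1.8, 2.2]× of
the mode (collapsed) *and* the raw mass in that window is at least
`min_peak_fraction` (default 0.05) of the total. Both gates are needed: the
local-maximum test alone fires on tail noise, the mass test alone fires on
smooth shoulders. The windows capture ~76% of a Poisson secondary
component's mass at depth 30–120, so a component holding 10% of bases
presents ~7.5% window mass, comfortably above the default gate.

QV with zero observed errors reports the detection limit
−10·log₁₀(1/aligned) flagged as a lower bound — never infinity. Whether
indels count as errors is the upstream aligner-parsing choice; the function
consumes a single error-base count.

## The toy assembler

`greedy_assemble` is a deliberately small greedy exact-overlap unitigger
for error-free reads, built so the titration and cut experiments have a
deterministic, fast assembler whose failure mode is the one under study
(repeats longer than the spanned overlap). It is not a general-purpose
assembler; any callable mapping a ReadSet to contigs can be plugged into
the experiments instead.

Algorithm: duplicate sequences are dropped; contained reads are removed;
candidate suffix-prefix overlaps ≥ `min_overlap` (default 100, minimum 20)
are located by packed-seed lookup (seed length min(min_overlap, 31)) and
verified by full string comparison; unitigs follow *mutually unique
maximal* overlaps — read i joins j only when j is i's single best right
partner and i is j's single best left partner, and any tie halts extension.
Ties in maximal overlap are the signature of a repeat boundary, so exact
repeats longer than read length break contigs, while reads spanning a
short repeat carry extension straight through it (their true-neighbor
overlap dominates any repeat-induced one). Error-containing input is
refused up front (detected via generator metadata): overlap detection under
noise is an assembler-research problem, and approximate results here would
be misleading. Deterministic given input order; remaining ties break by
read id. With exact repeats and a coverage gap positioned exactly at a
repeat boundary a cross-copy join is theoretically possible; at the
coverages used in the experiments this is rare enough never to appear in
the seeded test runs, which verify every contig is an exact substring of
the source genome.

## Titration and saturation

`run_titration` subsamples nested coverage steps by default (lower
coverages are prefixes of one seeded shuffle), which removes between-row
sampling variance; independent sampling is a flag. `fit_saturation` fits
N50(c) = N_max(1 − e^{−c/τ}) by least squares (scipy `curve_fit`),
initialized at N_max = 1.1 × max observed N50 and τ = (coverage at
half-max)/ln 2, with positivity bounds; non-convergence raises carrying the
initialization and residuals. The exponential is the simplest
two-parameter saturating curve and is exact on model-generated data to
machine precision; a Michaelis–Menten alternative (`model="mm"`) is
available for comparison. The two published-style anchor points this curve
family is judged against (80% at ~52×, 90% at ~70×) are mutually
inconsistent with any single τ of either family — with τ = 32.3 the
exponential reproduces 52.0× at 80% but predicts 74.4× (not 70×) at 90% —
so the 90% figure should be read as model-dependent extrapolation, not a
measurable constant.

## Chimera detection

Majority chromosome is the plurality label of a contig's assigned genes
(ties broken toward the first-encountered label, with a warning).
Unassigned genes are skipped rather than run-breaking by default — they
carry no evidence either way; `strict_unassigned=True` makes any gap in
gene order break a run. `min_run = 5` encodes "more than four consecutive
foreign genes". Split coordinates are the midpoints between the bounding
genes of adjacent chromosome segments — the true breakpoint is only
localized to the inter-gene gap, and the midpoint is the minimax choice.
Splitting conserves bases exactly and emits an AGP-like provenance table.
The default checks chromosome assignment only; requiring the foreign run to
be collinear *in order* on the second chromosome would be stricter but
cannot be evaluated without the second genome's gene order, which the
anchor table does not carry.

## Pipeline and I/O

One run seed fans out to per-stage seeds via CRC32 of the stage name, so
stages are independently reproducible. TSV is tab-separated, UTF-8,
unquoted, `#` for comments; FASTQ is Phred+33. Logging goes to stderr and
never alters outputs.

## Problem sizes

The test suite and acceptance script run simulations at 50 kb–6 Mb genome
scale: large enough that edge artifacts are below the measured tolerances,
small enough to iterate comfortably on a single core. Cut-series and
read-length experiments use 400–500 kb repeat-rich genomes at 8–10×
coverage over 10 seeds per condition; genome-size recovery uses constant
150 bp reads (the short-read regime such estimates come from in practice)
over a 50–500 kb × 20–60× × k ∈ {17, 21} grid.

## Limitations

- The read simulator has no signal-level, homopolymer, or chimeric-read
  modelling, and no structural variation; its substitution-only errors make
  error-containing data *easier* than real ONT data.
- Depth-mixture histograms are cleaner than aligned real depth (no
  mappability structure, no autocorrelation), so detection rates measured
  on them are optimistic upper bounds.
- The k-mer counter is memory-bound by design; multi-Gb read sets need a
  disk-backed counter (Jellyfish-class tools), not this one.
- The genome-size estimator is haploid-only; heterozygous samples need a
  two-peak mixture model it does not implement.
- The toy assembler requires error-free reads and exact repeats behave
  adversarially only through overlap ties; real assemblers face a strictly
  harder problem, so absolute contiguity values from the experiments are
  not comparable to real assemblies — only orderings and trends are.
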