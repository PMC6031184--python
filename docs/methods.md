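# Methods

This note documents the models, conventions and numerical choices behind
the toolkit, and what its synthetic-data validation does and does not
demonstrate about real sequencing data.

## Panel model and coordinate conventions

BED input is 0-based half-open; every reported site position is 1-based
within the amplicon, counted along the **assayed bisulfite strand**. Each
amplicon declares exactly one assayed strand (top or bottom), matching how
bisulfite PCR primers select a strand; bottom-strand amplicons are
reverse-complemented on load so all internal logic is single-orientation.
Cytosine context is classified from the two downstream reference bases
(CG → CpG, C-H-G → CHG, C-H-H → CHH, H ∈ {A,C,T}); cytosines whose
downstream context is truncated or contains N are unclassifiable and
skipped.

Primer footprints (optional BED columns 7–8) are masked from both
methylation calling and conversion-rate denominators: primer bases are
synthetic oligonucleotide, not bisulfite-converted template, so counting
them would bias both statistics. Footprints default to 0 bp when
unannotated.

Amplicon lengths outside 100–600 bp are rejected; outside 200–450 bp a
warning is emitted (such PCRs amplify but sit outside the well-behaved
design range for 2x300 bp chemistry). Both ranges are configurable.

Capacity arithmetic is deliberately simple: loading factor = samples x
amplicons, covered region = amplicons x mean length, with a default
feasibility ceiling of 2500 — the loading factor beyond which benchtop
flow-cell dropout becomes material in practice.

## Read simulator

Per template fragment, each CpG draws its methylation state independently
with the profile probability; methylated cytosines are protected (read C),
unmethylated cytosines — CpG or otherwise — convert to T with probability
`conversion_efficiency`, i.i.d. per cytosine. Uniform base-call errors
substitute one of the three other bases. Fragments span the whole
amplicon; paired 300 bp mates read in from both ends and overlap whenever
the amplicon is shorter than 600 bp. Base qualities are constant (Q37)
with an option to lower mate 2's overlap qualities to exercise the
trimmer. A fixed seed yields byte-identical SAM output.

What this emulates: control-DNA titrations, incomplete conversion, depth-
limited sampling noise, PCR artifacts (below) and SNP-created CpGs. What
it does not: haplotype-correlated methylation, PCR duplicates and
amplification jackpots, indels, quality degradation along the read,
context-dependent conversion failure, chimeric reads. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling model, not robustness to every real-data pathology —
upstream tools (adapter trimming, bisulfite alignment) and the QC filters
carry that load in practice.

Synthetic panels place CpG and CHH sites on an A/T background with >= 4 bp
spacing, so contexts are exactly as designed and every G belongs to a CpG.
Default validation geometry: 7 amplicons x 5 CpGs x 20 CHH sites in
330 bp, the scale of a small validation panel, chosen to keep the full
pipeline runnable in seconds at 2000x depth.

PCR artifacts are injected as `n_reads` fully converted read pairs
differing from the clean template only at the artifact: an unconverted C
immediately followed by a G — the simplest construction reproducing the
observed signature (a spurious CpG at very low coverage and ~100%
apparent methylation). SNP-CpGs rewrite *all* templates of an amplicon to
carry the G allele with a per-fragment methylation draw, yielding the
contrasting signature (full coverage, intermediate methylation).

## Overlap trimming

The mate whose mean Phred quality over the mates' intersection is lower
loses its overlapping bases entirely (hard trim of that end); ties trim
mate 2, which is empirically the lower-quality read. Per-end hard trimming
was chosen over per-base masking so downstream counting needs no special
cases, and over per-base quality comparison for determinism and order
independence. After trimming, each reference position is covered at most
once per pair. Corner case: if one mate strictly contains the other and
the container is the lower-quality mate, removing only the overlap would
split it; the implementation drops the distal remainder as well, keeping
mates contiguous (retained bases are never altered). Indel-containing
alignments cannot be represented by the gapless pair container and are
skipped with a warning on SAM input.

## Methylation calling

At every non-masked cytosine of the assayed strand, read C increments the
methylated count and T the unmethylated count; bases below Phred 20 and
non-C/T bases (errors or variants) are ignored — the standard bisulfite
convention, since G/A carries no methylation information on the assayed
strand. Analysis is not restricted to reference CpGs: any non-reference
position where >= 1 quality-passing read shows C immediately followed by G
is emitted as a read-evidenced CpG. Its counts come only from reads
carrying the CpG pattern (C·G methylated, T·G unmethylated), which is what
separates the two possible origins downstream: artifact reads are the only
pattern carriers (low coverage, extreme methylation), while a SNP allele
puts the G on every template (full coverage, ordinary methylation). CpG
dinucleotides split across a mate boundary are not detected as evidence;
with full-length amplicon mates this affects no position.

A position can legitimately carry two records — its reference context
(e.g. CHH, feeding the conversion denominator) and a read-evidenced CpG —
so call tables are keyed by (sample, amplicon, pos, context).

The conversion rate of a sample x amplicon unit is Σ unmethylated / Σ
coverage over its CHH sites. CHG sites are reported but excluded from the
denominator: CHH is the context with essentially zero genuine methylation
in human DNA, so retained CHH cytosines cleanly measure conversion
failure, while CHG would add a context with residual biology. A unit with
zero CHH observations raises an explicit undefined-rate error.

## QC filters

- **Conversion >= 0.95** (strictly-below fails): incomplete conversion
  inflates every apparent methylation level in the unit, so the whole unit
  is dropped. Undefined rates fail with an explicit reason.
- **Artifacts**: a non-reference CpG is flagged iff coverage < 5% of the
  unit's median reference-CpG coverage *and* methylation <= 5% or >= 95%.
  The qualitative signature ("very low coverage, ~0 or ~100%") needed
  quantifying; both knobs are exposed (`artifact_cov_frac`,
  `artifact_extremity`) and the defaults were calibrated on simulated
  artifacts, where they achieve exact separation from simulated SNP-CpGs.
  Reference CpGs are never flagged.
- **Coverage >= 1000x** (strictly-below removed), applied to CpG-context
  records; CHH/CHG records survive as conversion evidence.

All three flag sets are computed on the input table and then combined, so
the retained set is independent of filter order. The summary counts a
sample x amplicon unit as passing iff its conversion passed and at least
one of its CpG sites survived the artifact and coverage filters.

An internal-control helper (`control_check`) compares a designated control
amplicon (e.g. an imprinted locus expected at ~50%) against its expected
level and warns on deviation beyond a tolerance (default 10 points);
deviation is advisory only, never an automatic sample failure.

## Titration statistics

All statistics are on the percent scale. Per CpG, ordinary least squares
of observed methylation (%) on expected level (%) gives slope, intercept
and R² (= squared Pearson correlation); designs need >= 3 distinct levels.
CpGs with zero observed variance get slope 0 and a missing R² and are
excluded from the per-amplicon mean. An amplicon is flagged nonlinear when
its mean R² < 0.98 or mean slope leaves [0.9, 1.1] — explicit, configurable
stand-ins for the qualitative judgement "nonlinear amplification".

Condition comparisons inner-join two call sets on (amplicon, pos[, level])
and report the mean |difference| in percentage points per amplicon and
overall; the statistic is symmetric. Replicate SDs use the n−1 denominator
per CpG x level cell; aggregates (mean, max) are taken over all cells, the
most granular consistent aggregation, since coarser averaging orders are
not uniquely defined.

With 99% conversion, observed methylation is 0.01 + 0.99·p — still exactly
linear in p — so titration R² is unaffected and the fitted slope ≈ 0.99;
this is visible in all simulated fits.

## Coverage bootstrap

Each methylation level is a finite population of N = 100,000 fragments
(round(p·N) methylated); a sequencing experiment at coverage c draws c
fragments without replacement, so the estimate's SD has the closed
hypergeometric form with finite-population correction — the analytic
oracle the empirical bootstrap (1000 subsets per cell, drawn via the
hypergeometric sampler) is tested against at 3x Monte-Carlo SE. Levels run
0–100% in 10-point steps; the coverage grid is 100, 200, then 200-steps to
2000, then 1000-steps to 5000 (the grid's middle section is stated
elliptically in the design it follows; this reading is the package's own,
and the cutoff rule below does not depend on it). Per-cell generators are
spawned from the master seed, so grids are reproducible and
order-independent.

The cost proxy is combined SD (sum over levels) divided by coverage. Under
the k/√c decay of the combined SD, the relative SD reduction per
additional 100x coverage is 50/c independent of k, so the recommended
cutoff is the smallest grid coverage with 50/c <= marginal gain; the 5%
default yields 1000x, and halving it to 2.5% yields 2000x. Degenerate
curves (no accuracy gradient, e.g. a single fully-(un)methylated level)
and rises beyond 3x propagated Monte-Carlo SE raise diagnostic errors
rather than returning a number.

## Validation problem sizes

The packaged validation studies use 7 amplicons x 5 CpGs: the titration
study simulates 5 levels x 2000 fragments (70,000 pairs) and the
replicate-design contrast 5 levels x (3x1000 + 3000) fragments (210,000
pairs); both finish in seconds. These sizes give per-site binomial noise
of ~1.1 pp at 2000x — small enough that per-amplicon mean R² >= 0.99 and a
sub-point condition difference are comfortably resolved, and large enough
that failures of the counting or trimming logic would be flagrant.

## Known limitations

- The simulator's independence assumptions (sites, fragments, conversion
  events) understate real-data correlation; variance estimates from
  simulation are therefore lower bounds on real technical variance.
- Artifact-filter defaults are calibrated on simulated artifacts; real
  panels may need the knobs adjusted (e.g. for amplicons with very uneven
  coverage).
- The caller ignores G/A bases rather than modelling SNPs at assayed
  cytosines; heterozygous C→T variants are indistinguishable from
  unmethylated cytosines, as in all bisulfite assays.
- Pyrosequencing replicate tables can be analysed with `replicate_sd`, but
  no pyrosequencing signal processing is included.
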