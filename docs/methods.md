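# Methods

This note documents the models, estimators and numerical choices behind
`slamkit`, what the synthetic benchmark does and does not emulate, and the
known limitations.

## Read-to-gene assignment

Coordinates are 0-based half-open everywhere internally; GTF input (1-based
closed) is converted on load. Only matched (M/=/X) bases enter the internal
alignment model: soft-clipped bases are dropped, and insertion/deletion bases
are excluded from T accounting, because a conversion is defined only at an
aligned reference position.

Default assignment is strict: a read counts for a gene iff every aligned
block lies within the gene's exon union and the read's transcription strand
matches the gene strand (`--strandedness antisense` inverts the convention
for reverse-stranded libraries). Reads acceptable to more than one gene are
ambiguous and dropped — fractional counting is deliberately confined to the
compat mode so that the default numbers are simple sums.

The GEDI/GrandSLAM compat mode adds four independently toggleable behaviors
(`--compat gedi` turns all four on; each `--compat-*` flag can override):
intronic classification of unspliced reads fully inside intron intervals;
lenient acceptance (≥ 50% of aligned bases on the gene's exons and every
splice junction matching an annotated junction of the gene); read weighting
w = 1/(nTr × geneCount), with nTr the alignment count (NH tag) and geneCount
the genes accepted for this alignment (the choice of "this alignment" over
"any alignment of the read" is ours; the distinction only matters for
multimappers spanning different loci); and paired-end position filtering
(discordant overlap bases dropped rather than resolved by quality). Compat
intronic reads are pooled with exonic reads for NTR estimation; the per-run
manifest reports category totals so they can be audited. Secondary
alignments are counted only when weighting is on, since without fractional
weights they would double-count fragments.

## Conversion counting

For each assigned read, every aligned position whose sense-strand reference
base is T is inspected; on minus-strand genes this is a reference A with
read G on the alignment strand. A position is usable iff it is not in the
SNP mask, not inside a trimmed window (windows are defined in sequencing
orientation: for a reverse alignment, stored offset q maps to cycle
L−1−q), has base quality ≥ `--min-base-qual` (default Phred 20 — end
artifacts motivate the variance trimmer precisely because they pass quality
filters, but ordinary quality filtering is still worthwhile), and is not an
N in either read or reference. Usable positions increment n_T, and k when
the sense-strand read base is C.

Trimmed and masked positions are excluded from the per-site pileup table as
well ("trim guards"), so SNP detection, the QC report and the NTR model all
see the same position universe. The site table records the full sense-base
composition at each T site, which provides the control substitution classes
(T>G, T>A) used for background-rate anchoring.

Overlapping mate pairs are merged into one countable fragment: a reference
position covered by both mates counts once, the higher-quality base winning
(ties to mate 1); under compat position filtering, discordant overlap
positions are excluded from both numerator and denominator.

## SNP detection

Sites with coverage ≥ `--snp-min-cov` (default 10) form a histogram of
mismatch fractions f = tc/coverage over 100 equal bins on [0, 1] (bin count
exposed as `--snp-bins`). Only sense-strand T sites enter: T>C SNPs are the
class that confounds the labeling signal. Bin counts are log1p-transformed
and min–max normalized; with x the normalized bin index, the knee bin
maximizes d = (1 − x) − y, the distance below the descending diagonal — the
standard knee-detection orientation for a decreasing curve, maximal just
after the error mass has decayed. The threshold is the knee bin's lower
edge, clamped to [0.10, 0.60]. Guardrails: fewer than 1,000 eligible sites,
knee strength ≤ 0.02, or a degenerate flat histogram (min–max span zero)
all fall back to the fixed threshold 0.22. Empty bins count as zero before
log1p. A user mask (BED, half-open, expanded per position; or VCF, SNV rows
only) is unioned with the detected mask when both are present, and
`--snp-threshold` bypasses detection entirely.

On the benchmark generator's SNP scenario (error sites at rate 0.005, het
sites at 0.5, coverage 50) the detected threshold separates the two
populations with full recall and ~0 false masks; the guardrails absorb
small or degenerate inputs.

## Variance-based auto-trim

Reads are partitioned round-robin (by input order) into `--trim-chunks`
chunks (default 10); the per-position conversion rate is computed per chunk,
and the sample SD across chunks with nonzero T coverage estimates the
sampling variability of the rate at each read cycle. Since that SD scales
like sqrt(rate/coverage), cycles with artifact-elevated rates stand out
regardless of base quality. The SD curve is smoothed by a centered moving
average (`--trim-window`, default 5; truncated at the edges).

A continuous piecewise-linear curve with m ∈ {2, 3, 4} segments is fitted to
the smoothed SD by exhaustive search over integer breakpoints (minimum
segment length 2). Parameterizing by node values at the knots makes the
inner problem linear: the normal equations are tridiagonal with entries
expressible in prefix sums, so every candidate breakpoint placement is
scored exactly in one vectorized batch. m is selected by
BIC = n·ln(RSS/n) + 2m·ln(n) (m+1 node values plus m−1 breakpoints; n =
positions with defined smoothed SD; RSS floored at 1e-20 to keep degenerate
exact fits finite). The fit is cross-checked in the test suite against
brute-force enumeration with an explicit design matrix.

Trim derivation: the central level is the mean smoothed SD over the fitted
segment containing the curve midpoint. An end is trimmed up to the position
where the fitted curve falls back below `--elevation-factor` (default 1.5)
times the central level, walking inward from the end while the fitted value
stays above threshold. We use the fitted curve's threshold crossing rather
than a raw breakpoint because smoothing spreads a sharp artifact boundary
into a ramp roughly half a window wide on each side: the crossing point sits
within a position or two of the true boundary, while the breakpoints
themselves can land several positions away on noisy curves. If the combined
trim would exceed half the read length the trim is rejected (zero trim, a
warning recorded in manifest and QC). With `--trim-scope first` (default)
the trim fitted on the first input file applies to all files; `per-file`
fits each independently. Manual `--trim5/--trim3` disable fitting.

On planted artifact windows of (5,0), (0,8) and (4,4) cycles at 5× the
baseline conversion rate (2,000 reads), the recovered trims fall within ±2
cycles of truth in ≥ 9 of 10 replicate seeds.

## Global conversion rates

The background is anchored by a control substitution class at sense T sites
(default T>G; `--rate-method control` pins p_old there): sequencing error is
substitution-class symmetric while labeling is T>C-specific. The default
(`--rate-method em`) then fits both rates by EM on the binomial mixture with
one mixing weight per gene and shared p_old/p_new, initialized at the
control rate. The per-gene parameterization matters: with a single pooled
mixing weight the profile likelihood in p_old is nearly flat (a pooled-rate
shift can be traded against the mixing weight), whereas genes with little
labeling pin p_old and strongly labeled genes pin p_new. It also captures
T>C-specific background (e.g. residual chemical conversion in unlabeled RNA
or unmasked variants) that no control class can see. Estimation fails
loudly — with advice to pass `--p-old/--p-new` — when there is no conversion
signal or the fitted rates collapse (p_new ≤ p_old).

## Per-gene NTR estimation

With rates fixed, the per-gene EM iterates responsibilities
γᵢ = πB(kᵢ;nᵢ,p_new) / [πB(kᵢ;nᵢ,p_new) + (1−π)B(kᵢ;nᵢ,p_old)] and
π ← Σwᵢγᵢ/Σwᵢ from π₀ = 0.1 until |Δπ| < 1e-8 (max 1,000 iterations);
reads are collapsed to unique (n, k) classes first. The observed-data
log-likelihood is non-decreasing across iterations (asserted in tests), and
the EM optimum agrees with an exhaustive 1e-3 grid search of the exact
log-likelihood to ≤ 1e-3 on every simulated gene. Reads with n = 0 carry no
information and are excluded throughout; a gene with no informative reads is
reported with the uniform Beta(1,1) posterior and `converged = false`.

Uncertainty: the reported Beta(α, β) is moment-matched to the exact
posterior of π under a uniform prior, computed on a 1,001-point grid of the
observed-data likelihood. The posterior mode coincides with the EM optimum,
so `ntr_map = (α−1)/(α+β−2)` tracks the EM point estimate; the quantiles
come from the fitted Beta's inverse CDF. We chose this over the
effective-count posterior Beta(1+Σwγ, 1+Σw(1−γ)) because the latter treats
soft assignments as if they were observed labels and is materially
overconfident when the binomial components overlap (at n ≈ 20,
p_new = 0.05, p_old = 0.001, its nominal 90% interval covers ≈ 70% in
simulation, versus ≈ 89% for the matched-posterior interval). The
effective-count variant remains available as `--posterior counts`. Boundary
conventions for the MAP: 0 when α ≤ 1 < β, 1 when β ≤ 1 < α, the mean when
both are ≤ 1.

A note on attainable accuracy: at the reference conditions (n ≈ 20 usable T
per read, p_new = 0.05), about 36% of genuinely new reads show zero
conversions and are indistinguishable from old reads, so per-gene estimates
at π near 1 fluctuate a few percent below the boundary and per-gene RMSE has
a Cramér–Rao floor of roughly 0.027 at 500 reads/gene. Recovery is therefore
assessed against each gene's realized new-read fraction — the sample
quantity the NTR estimates.

## Pipeline architecture

`slamkit run` is a two-pass offline requantifier. Pass 1 assigns reads and
builds the unmasked, untrimmed site table (pooled across input files) and
the chunked per-cycle conversion profile (per file). The SNP threshold/mask
and trim windows are then derived, and pass 2 recounts under them. Global
rates, per-gene NTR, the output table (native or GrandSLAM dialect), the
QC report (JSON always; single-file HTML with inline SVG on `--html`) and a
run manifest are produced at the end. The pipeline is deterministic: a
manifest replay reproduces the TSV and QC JSON byte-for-byte. Inputs are
held in memory per file, which is appropriate for the intended
moderate-size requantification runs rather than whole-flowcell streaming.

## Synthetic benchmark

The generator emits a uniform-composition genome (so ~25% of read bases sit
over reference T), genes of 1 kb with two 400 bp exons on random strands,
single-end 80 bp reads placed uniformly within exons (a paired mode with
overlapping 120 bp fragments exercises the overlap resolver), per-gene new
fractions drawn uniform or supplied, conversions at p_new = 0.05 (new) /
p_old = 0.001 (old), class-symmetric sequencing errors at 1e-3, SNPs planted
only at exonic sense-T sites at allele fractions 0.5 or 1.0, and optional
artifact windows where the conversion probability is replaced for all
reads. Defaults correspond to the reference scenario used in the acceptance
checks (20 genes × 500 reads, ~20 usable T per read). The ground truth
records every planted event down to individual substitutions, and replaying
it against the reference reproduces the emitted reads exactly.

What it does not emulate — and hence what passing tests do not establish
about real data: position-dependent quality ladders, PCR duplicates,
fragment-length and coverage biases, indels and clipping, multimapping,
intron-containing (nascent) reads, UMI structure, and any deviation of real
background chemistry from a uniform per-T conversion rate.

## Known limitations

- Single-timepoint NTR only; no kinetic (half-life) modeling and no
  hierarchical shrinkage across genes.
- The internal alignment model ignores soft-clip/indel bases rather than
  modeling them; padded/hard-clip edge cases are not handled beyond pysam's
  parsing.
- SNP detection is site-marginal (no genotype likelihoods, no multi-allelic
  handling); indel variants in VCF masks are skipped.
- The chunked-SD estimator behind auto-trim is one concrete choice of
  variance population; alternatives (e.g. across-sample SD) would need
  multiple inputs.
- Memory scales with input size per file (offline requantification scope).
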