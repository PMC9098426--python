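# Methods

## Scope and data model

`circsplice` starts at transcript-level abundance matrices (TPM and
counts, features × samples) bound to a sample sheet (condition, sampling
time in hours, replicate) and a transcript annotation (exon features with
gene, transcript and biotype attributes). Read-level processing (QC,
trimming, alignment, quantification) is upstream and out of scope, as are
figure rendering and ortholog mapping. Exon intervals are held 0-based
half-open internally; GTF I/O converts at the file boundary. Each matrix
carries a unit label (`counts`, `TPM`, `CPM`) that downstream stages
enforce: rhythm detection consumes unlogged CPM, PSI consumes TPM.

## Normalization

TMM factors follow the trimmed-mean-of-M-values recipe: against a
reference sample (the one whose upper-quartile count fraction is closest
to the mean, unless given), per-feature log2 count-fraction ratios M and
average log abundances A are formed over features positive in both
samples; 30% of M (15% per tail) and 5% of A (2.5% per tail) are
rank-trimmed, and the factor is 2 raised to the inverse-asymptotic-
variance weighted mean of the surviving M, with all factors rescaled to
geometric mean 1. Note that one established implementation trims the
stated fractions from *each* tail; we read the published fractions as
totals split across tails, and expose `logratio_trim`/`sum_trim` so
either convention is reachable. CPM divides counts by the TMM-scaled
library size times 1e-6. Features with mean CPM < 0.5 over all samples
of a dataset are removed and, by default, TMM and CPM are recomputed on
the retained features (`refresh_factors=False` reuses the pre-filter
factors instead — the two behaviours bracket an ambiguity in common
practice). Gene-level tables are plain per-sample sums of transcript
values.

## Rhythm detection

The primary test (`rank_umbrella`) is nonparametric, in the class of
umbrella-alternative rank tests used by RAIN. Sampling times are folded
modulo the period (default 24 h) into phase groups; with the default
design (16 points every 3 h over 45 h starting at 9 h) this gives 8
groups of 2. For each candidate peak group, the groups are rotated so
the antipodal (trough) group comes first, and a Mack–Wolfe umbrella
statistic counts concordant pairs rising to the peak and falling after
it (midranks score ties 0.5). Each candidate is standardized by the
tie-free Mack–Wolfe null moments and the test statistic is the maximum
over candidates. The null distribution is obtained by permuting the
sample values: exhaustively over all n! assignments when n ≤ 8, else by
`n_perm` seeded random permutations with the add-one estimate
p = (1 + #{T\* ≥ T}) / (1 + n_perm), whose floor is 1/(n_perm+1). An
exactly constant series returns p = 1 by convention. The statistic is a
rank functional, so p is invariant to strictly monotone transforms of
the series. This is a testable approximation of the same alternative
class as RAIN, not a re-implementation of its analytic null; a
parametric cross-check (`harmonic_F`, the F-test of the single-harmonic
cosinor model against an intercept) is provided.

Cosinor parameters come from least squares on
y = M + a·cos(ωt) + b·sin(ωt): A = √(a²+b²), φ = (τ/2π)·atan2(b,a) mod τ
(time of the fitted maximum, in sample-time coordinates, no ZT/CT
adjustment), rAMP = A/M on the linear CPM scale. φ is NaN when A = 0
(amplitudes below 1e-12 relative to the mesor are treated as zero).
A feature is rhythmic iff BH-adjusted q < `alpha_q` (0.05) **and**
rAMP ≥ `min_ramp` (0.1); BH is applied per matrix, i.e. per dataset and
condition. Acrophase histograms use 3-h bins [0,3),…,[21,24).

Gene-vs-transcript discordance classes: `both_rhythmic`, `gene_only`
(rhythmic gene, no rhythmic transcript), `transcripts_only` (the
converse), `neither`, computed from the per-level rhythmic flags on the
same samples.

## Local splicing events and PSI

The seven local modes are enumerated per gene from exon/junction
signatures, with strict (exact) boundary matching and strand semantics
in transcription direction; overlapping genes are processed
independently, and a signature's inclusion/total transcript sets are the
unions over all compatible transcripts, so more than two isoforms can
support one event. Inclusion conventions: SE — exon-containing form;
RI — intron-retaining form; A5/A3 — the form with the longer exonic
extension (shorter intron); MX — the form using the transcription-
upstream internal exon; AF/AL — the form whose terminal exon is more
distal from the shared exon. Overlapping alternative boundary exons are
required for A5/A3; non-overlapping terminal exons for AF/AL. Events are
exchanged as SUPPA-style `.ioe` tables keyed by deterministic ids
`gene;TYPE:chrom:coords:strand`.

Per sample, PSI = Σ TPM(inclusion) / Σ TPM(total), undefined when the
denominator is zero; mean PSI averages defined samples only, and events
with under 50% defined samples in a condition are excluded from that
condition's gene sets. "Spliced" means 0.1 < mean PSI < 0.9, strictly. A
gene is spliced by mode E when ≥ 1 of its type-E events is spliced;
comparing knockout to control per mode gives gain / loss / shared /
absent statuses, annotated with circadian-transcript and protein-coding
flags. Differential splicing per event is a two-sided Mann–Whitney U on
per-sample PSI between conditions (exact when both n ≤ 8 and tie-free,
else normal approximation with midrank tie correction; p = 1 when all
pooled values are identical; < 3 defined samples in either condition
marks the event untestable), significant at p < 0.05. A rank test across
time-course samples replaces an empirical between-replicate ΔPSI null
because the target design has 16 samples per condition and no replicate
pool; the decision rule (p < 0.05) is unchanged.

## Differential rhythmicity of isoform pairs

Within one condition, all unordered pairs of rhythmic transcripts of a
gene are tested. Both series are divided by their fitted mesor so pure
expression-level offsets cannot register as differential rhythmicity
(raw-scale testing is available via `standardize_mesor=False`); a joint
regression with pair-indicator interactions on the cosine/sine terms is
fit, and the F-test of equal harmonic coefficients (2 numerator df)
gives p. This replaces an ensemble meta-p with a single well-defined
test under the same FDR < 0.05 decision rule. The circular phase
difference Δφ = min(|φa−φb|, τ−|φa−φb|) ∈ [0, τ/2]; the amplitude ratio
is rAMP(b)/rAMP(a) with transcripts in lexicographic order, so swapping
the pair inverts it and leaves p and Δφ unchanged. Pairs with q < 0.05
and Δφ ≥ 3 h form the phase-shifted class, binned <3, [3,6), [6,9),
≥9 h (the last is [9,12] by the circular metric), and labelled with the
unordered biotype pair.

## Gene sets and enrichment

Curated sets load from 2-column TSV or GMT files (duplicates collapsed
with a warning). Over-representation is the upper-tail hypergeometric
probability P(X ≥ k) of the query/set overlap within a universe, BH-
corrected across sets; the default universe is the expressed genes after
filtering. The splicing-factor summary reports, per condition, the genes
with ≥ 1 rhythmic transcript (categorical matrix), rhythmic gene and
transcript counts, and the set of factors rhythmic in the reference but
in none of the comparison conditions. Hallmark association is a plain
membership join per result class. The shipped files under
`examples/gene_sets/` are miniature illustrative subsets, not curated
resources.

## Synthetic data generator

The generator emulates the target study design: 16 timepoints every 3 h
over 45 h starting at 9 h, one replicate per timepoint (configurable), a
reference condition plus knockout-like conditions. Each transcript
follows mesor·(1 + rAMP·cos(2π(t − φ)/τ)) with multiplicative log-normal
noise of unit mean and log-sd √log(1+cv²), so `noise_cv` is the
coefficient of variation on the linear scale. Counts are Poisson with
means proportional to TPM × summed exon length, scaled to a 1e6 library;
TPM matrices are *not* renormalized to a fixed column sum, so programmed
mesors are recovered exactly in the noise-free case. Condition effects:
rhythm loss (rAMP→0, mesor kept), phase shift, amplitude scaling,
expression knockout, and isoform switches that redistribute a gene's
total expected abundance across its transcripts by given fractions —
preserving the gene-level series exactly, which is what makes programmed
gains/losses and gene/transcript discordance analytically known. Toy
gene models realize each event mode with two transcripts on alternating
strands. Default simulation magnitudes used throughout the tests: mesor
20–80 (uniform), rAMP 0.3 for single-feature rhythm recovery, noise CV
0.1 (0.05/0.02 for the PSI and gain/loss scenarios, which probe ratio
accuracy rather than rhythm detection). Phase-shifted isoform-pair
scenarios use rAMP 0.5, the value of the package's two-transcript pair
fixtures: at rAMP 0.3 and CV 0.1 the cosinor information bound puts the
sd of a pairwise phase-difference estimate near 0.64 h on this grid, so
per-pair 1-h phase accuracy is not statistically reachable, while at
rAMP 0.5 it is (~0.38 h).

What the generator does not emulate: quantification uncertainty and
length biases beyond the fixed-length Poisson layer, overdispersion,
batch effects, correlated noise across timepoints, damping of rhythms
over the course, and realistic isoform-complexity distributions. Passing
tests therefore demonstrate correctness and calibration of the methods
under the stated noise model, not performance on real RNA-seq.

## Numerical and design notes

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); per-feature permutation streams are
  spawned from one `SeedSequence`, so results do not depend on feature
  order. Reruns are bit-identical, and matrices written as TSV parse
  back exactly (`float_precision="round_trip"`).
- BH q-values via `statsmodels`; hypergeometric tails via
  `scipy.stats.hypergeom`; Mann–Whitney via `scipy.stats.mannwhitneyu`.
- Degenerate inputs: constant series give p = 1 and φ = NaN; events with
  all-zero TPM give undefined PSI; empty matrices, unknown transcripts,
  mismatched keys and invalid configs raise immediately with context.
- Perfect model fits (zero residual) report p at the numerical floor
  rather than 0/0.
- The pipeline writes every stage table with fixed column order and
  `NA` for missing values; `manifest.json` records package version and
  all parameters, and orchestrated and stage-by-stage CLI execution
  produce byte-identical outputs.
- Problem sizes in the shipped checks (1000–2000 features for
  calibration runs, 40-gene gain/loss scenarios, 60-gene pair
  scenarios, 1000 permutations) were chosen as the smallest sizes at
  which the binomial noise of the measured rates is comfortably inside
  the asserted margins.

## Known limitations

- The umbrella permutation test approximates RAIN's alternative class
  but not its analytic null; p-value granularity is 1/(n_perm+1).
- PSI uses exact transcript quantification (no bootstrap uncertainty),
  so near-zero denominators are noisier than the flags suggest on real
  data.
- Differential rhythmicity assumes a shared sampling grid within a
  condition and a single harmonic; multi-harmonic waveforms dilute
  power.
- Cross-condition differential rhythmicity of the same transcript is
  covered by joining per-condition fits, not by a dedicated paired test.
- Period is fixed (default 24 h); no period scanning.
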