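# Methods

## Kinetic model

All estimation rests on first-order mRNA turnover. For one gene, let Y(t) be
the normalized abundance of metabolically labeled (4sU-marked) transcripts at
labeling time t, α the transcription rate (normalized counts/hour) and β the
degradation rate (1/hour):

    dY/dt = α − β·Y,    Y(0) = 0
    Y(t)  = Y_ss · (1 − e^(−β t)),    Y_ss = α/β
    HL    = ln 2 / β

Two consequences drive the pipeline. First, the initial slope of the
saturation curve equals α, so labeled abundance at an early time point (0.5 h)
divided by the labeling time estimates the transcription rate; the estimate is
biased low by exactly (1 − e^(−βt))/(βt), which is negligible for slow decay
and about −7% at a 2.3 h half-life. Second, on the log2 scale the steady
state decomposes as

    log2FC_SS = log2FC_TR + log2FC_HL,

so a half-life fold-change between genotypes can be measured as the
steady-state fold-change minus the transcription-rate fold-change ("ratio
method") without fitting any curve. The package implements both routes: the
ratio method for relative changes, and two-pass weighted nonlinear
least-squares saturation fits for absolute half-lives.

Cell division would add a dilution term β_growth to β; the default is 0
(post-mitotic neurons) and the generator exposes it as a knob only.

## Estimation procedures

**Saturation fit.** Pass 1 fits Y_ss·(1 − e^(−βt)) by unweighted bounded
least squares (β ∈ (1e-4, 50] /h, Y_ss > 0; initialisation Y_ss⁰ = max
observed value, β⁰ by inverting the saturation fraction at the earliest time
point; up to 5 seeded, jittered restarts). Pass 2 refits with working weights
1/Ŷ from the pass-1 curve, reflecting variance that grows with the mean.
Because counts are overdispersed (variance ≈ μ + φμ², so ∝ μ² at high
counts), 1/Y weights understate the variance growth and the textbook
covariance s²(JᵀWJ)⁻¹ undercovers (≈0.86 measured for Y_ss at 10
observations). Parameter covariances therefore use an HC3 leverage-corrected
sandwich, and intervals use t quantiles with n−2 degrees of freedom; measured
Y_ss coverage is then ≈0.93. The 50% interval uses t₀.₇₅; a
likelihood-profile option replaces the 95% interval when requested. Fits
pinned at the β upper bound (curves saturated before the first time point)
are flagged non-converged.

**Transcription-rate contrast.** Labeled counts are divided by the fly
spike-in sum of their sample (both are labeled, so the ratio reconstructs the
labeled fraction up to one constant), rescaled by the geometric-mean fly sum
to stay count-like, the 1 h sample is halved into a pseudo 0.5 h replicate
(flagged: it shares a plate and understates between-plate variance), the
0.5 h replicate block is quantile-normalized within genotype, and the
genotype contrast is the NB Wald test below. Steady-state samples are never
spike-in normalized; they get median-of-ratios size factors.

**NB fold-change.** Per gene, size-factor-normalized group means give the
log2 fold-change (pseudocount 0.5 per group sum stabilizes logs near zero); a
pooled method-of-moments NB dispersion (floored at 1e-8) feeds a delta-method
SE, a normal Wald p, and BH adjustment over tested genes. Genes with summed
raw counts below `min_counts` (default 20) across the two groups are removed
before testing. Shrinkage is deliberately omitted: downstream logic needs
only the (log2fc, lfcSE, padj) contract, and measured type-I error at
nominal 0.05 is ~0.04 on 4v4 Poisson nulls. At 2 replicates per group the
estimator is anti-conservative under strong overdispersion; the categorizer
conditions use ≥4 replicates.

**Direction labels and categories.** Human thresholds: TR up/down at
|log2FC_TR| > 1 with padj < 0.1; HL up/down at |log2FC_HL| > 1 with
Z_FC = |log2FC_HL| / √(lfcSE_A² + lfcSE_B²) strictly above the median Z_FC of
genes entering the HL test (ties fail). Mouse mode: TR ±0.1 with FDR < 0.1,
HL ±1 with p below its 20th percentile. Motif-analysis (transite) mode: TR
±0.5. Buffering categories are assigned with fixed precedence — TR_only
(steady state tracks transcription within 25%), full_buffered (TR significant,
SS not, HL opposite-signed), partial_buffered (TR and SS significant,
|SS| < |TR|, HL opposite), HL_only (TR not significant, HL label present),
concordant (TR significant, HL label same-signed), else unchanged. Full
buffering requires only an opposite-signed HL point estimate, not HL
significance; the mouse p-value quantile is taken over tested genes.

**Transcription-inhibition fits.** log2 fold-changes versus the 0 h point are
regressed on time through the origin; the half-life is −1/slope (hours)
and β = −slope·ln 2. A widely used alternative convention reads the log2
slope directly as β with HL = ln2/β; on the log2 scale those two differ by a
factor ln 2 and only the −1/slope form satisfies HL = time-to-half, so that
form is used throughout.

**Reliability filter and global shift.** For absolute summaries, genes must
have transcription rate and steady-state level above their bottom-10%
quantiles and a 50% CI width below 0.75 of the half-life estimate. Because
both filter levels are correlated with β (the slope factor and Y_ss = α/β),
the surviving gene set is slightly depleted of short-lived transcripts; on
simulations this shifts post-filter medians by roughly +2–3%, which the
recovery checks absorb within their 5% tolerance. Genotype medians and means
carry bootstrap CIs (500 resamples, seeded).

**Mouse subcellular proxy.** Nuclear or chromatin-associated abundance is
proportional to production, so the genotype × assay interaction — whole-cell
log2FC minus fraction log2FC — proxies the half-life change, computed as two
NB contrasts with SEs in quadrature. Multiple batches are analysed within
batch and combined by inverse variance.

**Sequence classifiers.** Features are overlapping k-mer frequencies per
possible window (N-containing windows excluded from numerator and
denominator), in-frame codon frequencies, region length, and optional
methylation fractions or the TR log2FC. The classifier is a 500-tree random
forest (√p features per split, seeded) on a stratified 75/25 split after
seeded downsampling of the majority class; accuracy is reported with a
Clopper–Pearson 95% CI plus ROC/PR curves. Because a single 500-gene test
set carries ~1.5-point binomial noise and a similar split-assignment noise,
an aggregated mean over several seeded splits is available and used for
headline accuracy numbers. The exhaustive dinucleotide-combination search
(16 + 120 + 560 models, shared split and seed) uses 200-tree forests with
min_samples_leaf = 5: with at most three features the forest variance
saturates far below 500 trees (subset accuracies agree within binomial
noise) and the full search runs in ~5 instead of ~15 minutes on one CPU.

**Motif enrichment.** Motifs (RNA alphabet transliterated U→T) are matched
exactly, counting overlapping sites; the tested unit is gene-level membership
(≥1 site in the 3ʹUTR). Each comparison contrasts a foreground against its
background minus the foreground with a two-sided Fisher exact test,
BH-adjusted across motifs within the comparison; depletion is an odds ratio
below 1. Comparisons pair buffered foregrounds with their transcription
stratum (TR_down ∧ HL_up vs TR_down; TR_up ∧ HL_down vs TR_up) and half-life-
only foregrounds with the TR_not stratum. The site-count filter removes
motifs whose foreground and background site totals are both below a
threshold; when unset, the smallest threshold is chosen such that surviving
p-values have no more mass in (0.9, 1] than in [0, 0.1] — one operational
reading of "unimodal and enriched at zero", recorded as a heuristic.

## The synthetic-data generator

The generator is first-class code: it defines the conditions under which the
pipeline's claims are tested.

**Kinetic truth.** Genotype-A degradation rates are lognormal around a
median half-life of 2.5 h (ln-scale sd 0.5). Transcription rates are
lognormal (ln-scale sd 1.0) and drawn **independently of β**: production and
decay are mechanistically separate processes, and the steady state is their
ratio. (The alternative — drawing Y_ss independently — silently makes α ∝ β,
which couples expression-level filters to half-life and distorts
median-recovery experiments.) Planted categories modify genotype B with a
random sign at |Δlog2| = 2 by default: TR_only shifts α; HL_only shifts β;
full_buffered shifts both equally (Y_ss invariant by construction);
partial_buffered offsets half the α shift; concordant shifts α and β in
opposite directions so the SS change exceeds the TR change. Default
proportions: 15% full, 6% partial, 10% HL-only, 9% TR-only, 60% unchanged.
A global half-life shift multiplies every genotype-B half-life (used for the
2.5 → 3.0 h median-shift experiments).

**Counts.** Each labeled library holds the labeled endogenous signal
Y_ss(1 − e^(−βt)), a fixed fly spike-in amount (20% of total steady-state
abundance, spread over 300 species — fly spike-in RNA is a transcriptome-
scale pool, so its per-sample sum has a small CV), yeast RNA only as a
configurable contamination fraction of the pull-down (default 1%), and an
ERCC-like ladder of 92 species spanning 4.4 decades. Reads are NB draws
(shared dispersion 0.02; Poisson at 0) around depth-proportional shares with
lognormal per-sample depth noise (sd 0.15); steady-state samples are
whole-cell (∝ Y_ss, no fly/yeast species). Defaults: 2 genotypes × 2
replicates × time points 0.5/1/4/8/24 h plus one steady-state sample per
replicate. A `linear_labeling` flag replaces the saturation curve by its
tangent α·t, removing decay during the pulse for exact-recovery experiments;
with the exact curve, the slope method's (1 − e^(−βt))/(βt) bias is present
and, at high depth, makes strong degradation-rate shifts register as small
significant TR changes — a real property of the slope approximation that the
categorization experiments sidestep by linearizing, while the bias itself is
asserted in closed form in the kinetics tests. A fraction-design simulator
emits whole-cell (∝ Y_ss) and nuclear/chromatin (∝ α) replicates with batch
structure for the mouse proxy mode.

**Sequences.** Gene bodies come from first-order Markov chains whose
transition matrices are exponentially tilted (±τ) on three planted
dinucleotides; CDS (length divisible by 3) and 3ʹUTR use the untilted chain,
and gene-body length (1–3 kb uniform) is independent of direction. τ is
calibrated by bisection against a normal approximation of the per-sequence
log-likelihood-ratio — exact per-step mean and variance from the chain,
lag autocovariances to 25, averaged over the length grid — so that an oracle
thresholding the true log-odds attains a configurable Bayes accuracy
(default 0.85; verified within binomial error empirically). Because rows of
a stochastic matrix sum to one, tilting a cell hands its row-mates an equal
and opposite aggregate signal: if two planted dinucleotides share a first
base (e.g. CA and CG), the complement pair in that row carries the same
combined information and the planted triple is **not** uniquely recoverable
by a combination search. The default planted set {CA, GC, AT} therefore uses
three distinct first bases (one planted cell per row), which leaves each
row-mate only ~⅓ of the per-feature signal and makes the planted triple the
uniquely best subset (measured margin ~2.4 accuracy points). Same-row sets
are allowed but trigger a warning.

**Motif planting** overwrites a uniform-position window of the 3ʹUTR with a
literal motif copy with the configured foreground/background probabilities,
preserving lengths and recording truth. **Small-RNA simulation** draws
miRNA baselines (lognormal, ln-sd 1.5), applies per-miRNA relative
fold-changes times a global per-cell scale to genotype B, and adds a 52-member
ladder spanning ~5 decades whose expectations are genotype-independent; all
species in a sample share its library-size factor. Ladder-sum normalization
therefore shares one noisy scale per sample (~0.11 log2 SE at 2v2
replicates with NB dispersion 0.05), which the scaled-median checks allow
for; depth (median-of-ratios) normalization cancels the global scale by
construction, which is exactly the contrast the absolute-scaling analysis
demonstrates.

**What the generator does not emulate.** No read-level artifacts (FASTQ,
alignment, positional bias), no 3ʹUTR isoform/APA structure, no
gene-length–expression coupling, no batch effects in the human design, no
real genome sequence composition, and NB noise with a single shared
dispersion rather than a mean–dispersion trend. Passing tests show the
estimators recover the truth of this model at realistic depths and noise;
they do not certify performance on real libraries, where unmodeled structure
(alignment bias, isoform switching, dispersion trends) can dominate.

## Problem sizes for the validation runs

Validation and the reproduction script use problem sizes chosen to make the
measured quantities stable: 1,000 genes (two genotypes) for kinetic
recovery at depth 2×10⁷ (mean 0.5 h counts far above the ≥50 floor; the
half-life information limit at dispersion 0.02 puts the median relative
error near 9–10%, so depth is set where the Poisson tail no longer adds to
it); 5,000 genes with 4 replicates for categorization; 3,000 genes for the
median-shift recovery; 2,000 sequences for the classifier and the full
696-subset search; 200 vs 2,000 genes for motif power, with 50 null
simulations; 400 miRNAs with the 52-spike ladder.

## Known limitations

* The NB Wald contrast is anti-conservative at 2 replicates with strong
  overdispersion (no shrinkage); conclusions at n=2 rest on the ratio
  decomposition, not on per-gene significance.
* The slope transcription-rate estimate inherits the (1 − e^(−βt))/(βt)
  bias; for genes with half-lives well under 1 h the TR and HL fold-changes
  partially alias, and at very high precision this registers as spurious
  concordant calls.
* The reliability filters select on expression levels correlated with β,
  shifting post-filter half-life medians by a few percent.
* The site-count filter's unimodality rule is one operationalization of an
  informal criterion; alternative rules change which borderline motifs
  survive.
* Pipeline outputs are deterministic given the config seed; forests and
  splits derive all randomness from it.
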