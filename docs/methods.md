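# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `cobind`, and what the synthetic-data validation does and
does not demonstrate.

## Coordinates, summits, and windows

All coordinates are 0-based half-open (BED convention); narrowPeak summit
offsets are converted to absolute positions on read (−1 means no summit).
Signal profiles are smoothed with a Gaussian kernel of standard deviation
`smoothing_bandwidth_bp` (default 10 bp), truncated at ±4σ and
renormalized to unit sum (`scipy.ndimage.gaussian_filter1d`, reflected
boundaries).  The smoothing literature sometimes quotes a "10 bp kernel" as
a window width rather than a σ; we interpret it as σ and expose it as a
parameter.  The summit is the position of maximal smoothed signal within
the peak, ties broken to the smallest coordinate; an all-zero peak keeps
its start as the summit with a logged warning rather than failing a run.
Summit windows are inclusive on both ends: summit ± half_width covers
2·half_width + 1 bases (301 bp at the default 150), clipped at zero.

Distance from a peak to a TSS is zero if the TSS lies inside the peak and
otherwise the gap to the nearer edge; "within 2 kb" is inclusive.
Upstream windows are strand-aware: upstream of a +-strand TSS is the lower
coordinates.

## Motif scanning with exact p-value thresholds

A motif is a position probability matrix over {A,C,G,T} with a 0-order
background (uniform by default, overridable with sequence-derived
frequencies) and a pseudocount: regularized probabilities are
(p + c)/(1 + 4c).  A window scores Σⱼ log₂(p_reg(baseⱼ)/bg(baseⱼ)) in
bits.

The score threshold for a per-window p-value (default 10⁻⁴) is computed
exactly: per-column scores are discretized at 10⁻³ bits and the null score
distribution of a single window is built by column-wise convolution over
the integer grid; the threshold is the smallest achievable score whose
tail probability is ≤ p.  Columns with zero regularized probability
contribute a separate −∞ mass; a column that is zero for every base is an
error directing the user to a positive pseudocount.  Because the threshold
lives on the discretized grid, *hit detection* also uses the discretized
per-column scores — otherwise windows whose exact-grid score sits on the
threshold (for near-consensus motifs this is an entire mismatch class)
would pass or fail depending on sub-grid rounding.  Reported hit scores
are the continuous log-likelihood ratios; reverse-strand hits carry the
+-strand start coordinate of their window.  Windows containing N are
skipped, overlapping hits are all reported (no greedy masking).

One boundary case is worth stating: the smallest score s with
P(score ≥ s) ≤ p can never be the minimum achievable score (its tail is
exactly 1), so as p → 1 the threshold descends to the second-lowest grid
point, admitting every window that beats the worst one.

Two per-peak score summaries exist: the thresholded hit list (used for
classification and enrichment) and the best raw window score regardless of
threshold (used for the crosslink-ratio correlations, where sub-threshold
motif quality is exactly the signal of interest).

A peak "has a TEAD motif" if either the TEAD monomer or the TEAD dimer
matrix has a hit at threshold.  The class label is the subset of
{AP-1, TEAD, STAT3} with at least one hit; the empty subset is `none`.

## Accessibility-matched controls and enrichment

Control regions are drawn from a DHS atlas so that their accessibility
Z-score distribution matches the bound DHSs exactly per bin (bin width 0.1
by default; the matching granularity of the original workflow is not
published, so it is a parameter).  Candidates intersecting any target peak
are excluded before sampling, and an explicit iterative-replacement pass
guarantees zero intersections in the output; sampling is without
replacement and deterministic given the seed.  The pre-condition is that
every occupied bound bin has enough non-excluded candidates — in synthetic
atlases this is ensured by giving the background a slightly heavier-tailed
Z distribution (SD 1.3 vs 1.0) than the bound sites.

Enrichment is a Pearson chi-square on the 2×2 has-motif × target/control
table, df = 1, without Yates continuity correction (large genomic tables;
a correction flag exists).  A zero control frequency is reported as an
infinite fold with a flag rather than an error.  Pairwise co-occurrence is
the ratio of joint-occurrence fractions.

For target-gene enrichment, the control gene set is drawn without
replacement from the *non-differential* remainder of the gene universe.
Drawing from the full universe lets genes appear in both columns of the
2×2 table, which correlates the columns and visibly mis-calibrates the
chi-square null; disjoint sampling restores uniform null p-values provided
the differential set is small relative to the universe (a few hundred
genes against ~20k protein-coding genes, the realistic regime — at
|diff|/|universe| ≈ 0.1 the finite-population correction already
underdisperses the statistic by ~10%).

## Paralog-specific sites

Differential binding between YAP and TAZ replicate counts uses a bespoke
negative-binomial Wald test rather than calling an external tool:
median-of-ratios size factors over all samples; per-peak method-of-moments
dispersion from within-condition moments, shared across conditions and
floored at 10⁻⁸; delta-method standard error of the log₂ fold change; BH
adjustment across peaks; calls at padj < 0.05 with the sign of the fold
change.  With three replicates per condition the raw per-peak dispersion
estimate is noisy enough to make the Wald test anti-conservative (the
reason dedicated tools shrink dispersions), so the default mode floors
each peak's dispersion at the across-peak median ("moderated"); the strict
per-peak estimator remains available (`dispersion_mode="per_peak"`).
Numerical parity with any external tool is not claimed.

Knockout confirmation operationalizes "reduced binding only in the
matching deletion line" as: signal below `drop_fraction` (default 0.5) of
the parental signal in the cognate knockout *and* at or above that
fraction in the other knockout.  The threshold is not published and is
exposed as a parameter; a zero parental signal is unconfirmable.

Crosslink ratios are log₂((s₁+ε)/(s₂+ε)) with pseudo-signal ε = 1 to
tolerate empty windows; ε compresses ratios when signals are comparable to
it, so Pearson r is only affine-invariant at ε = 0 (tested).  Degenerate
zero-variance inputs report r = 0 with a flag.

## Signatures and survival

Motif-class signatures contain the genes with at least one proximal
(within 2 kb of a TSS, inclusive) peak of the requested class.  The
exclusivity rule concerns AP-1 and TEAD only: `AP1_only` means an AP-1
motif without a TEAD motif irrespective of STAT3 content, mirrored for
`TEAD_only`; `AP1_and_TEAD` requires both.  A gene with several proximal
peaks may belong to several signatures, and the one-motif / multi-motif
sub-signatures may share genes for the same reason.

GSS is computed on raw TPM-like expression (a log2(x+1) mode exists; the
original scale is not published) with cohort means and sample standard
deviations (n−1), after removing genes with CV < 5% or CV > 85% or zero
mean.  The per-gene z-scores sum to zero over the cohort, so ΣGSS over
patients is zero to machine precision — a useful internal check.  GSS = 0
is assigned to the high-risk group (high iff GSS ≥ 0).

The Kaplan–Meier estimator and the two-group log-rank test are
implemented directly (product-limit with events processed before
censorings at tied times; hypergeometric expectation and variance at each
distinct event time, χ² with 1 df) and are cross-checked in the test suite
against `lifelines` to nine decimals.  The χ² p-value is asymptotic: on
toy cohorts of a handful of patients it differs from the exact permutation
p-value by construction, so the permutation-agreement check uses 40+40
fully-observed cohorts where the asymptotic and permutation answers
coincide to within Monte-Carlo error.

## The synthetic-data generator

`generate_dataset` produces, from one seed: uniform-background genomes;
peaks laid out on a regular grid (spacing ≥ ~1.4 kb so summit windows and
control DHSs never collide); a motif class per peak from a configurable
mixture (defaults: 22% AP-1-only, 22% TEAD-only, 10% STAT3-only, 22%
composite classes, 24% none); planted motif instances sampled from the
PWM (not fixed consensus, so score distributions are non-degenerate) at
offsets uniform within ±100 bp of the true summit; per-factor summits
jittered by N(0, 15 bp); Gaussian signal bumps with 5% multiplicative
noise; NB(200, 0.05) replicate counts with 125 planted YAP-specific and
450 TAZ-specific sites at log₂FC = 3 and matching knockout drops (residual
0.2 of parental, lognormal σ = 0.2 noise); a DHS atlas with bound
Z ~ N(2,1) and motifs planted in 5% of background sites; genes with TSSs
within ±1.5 kb of 70% of peaks plus unlinked distal genes; Gamma-
distributed expression (per-gene CV uniform on 0.15–0.5) in which
signature genes respond multiplicatively to a latent per-patient risk
(effect 0.4); and exponential survival in which patients whose planted GSS
is ≥ 0 carry the configured hazard ratio (default 2), with independent
exponential censoring calibrated approximately to the configured censoring
fraction (default 20%).

The built-in PWMs are idealized: width-13 matrices with consensus
probability 0.96 (the TEAD dimer: width 15 at 0.93).  These numbers are a
joint design: at the 10⁻⁴ threshold such a matrix admits exactly the
windows with ≤ 2 mismatches (≤ 3 for the dimer), so a PWM-sampled instance
passes with probability ≈ 0.98 (binomial tail) while the per-window false
hit rate is ~10⁻⁵, i.e. ~0.6% per motif family per 301-bp window.  That is
what makes ≥ 95% end-to-end class recovery achievable; real motifs are
shorter and weaker, and real class calls would be correspondingly noisier.

What passing the synthetic validation shows: every pipeline stage
implements its stated statistic correctly, recovers planted effects at the
expected power, and is bit-reproducible from a seed.  What it does not
show: robustness to real-data pathologies — non-uniform genomic background
and repeats, peak-length and GC confounding, overlapping peaks, batch
effects in counts, or violation of proportional hazards — none of which
the generator emulates.

## Pipeline

`run-all` executes summits → motif profiles → classes → matched controls →
enrichments → co-occupancy → specific sites → crosslink ratios → target
genes → signatures → survival, writing every intermediate as a TSV (floats
at six significant digits) and a `manifest.json` with parameters, derived
per-stage seeds (all descended from the root seed), and SHA-256 checksums
of every output, with paths stored relative to the output directory so
manifests from identical runs compare byte-equal.  Single-stage
subcommands recompute their prerequisites from the original inputs — with
a fixed seed this reproduces the persisted intermediates exactly, which is
the reproducibility contract.

Default problem sizes (1000 peaks on two 2-Mb chromosomes, 20k-site DHS
atlas, 400 patients) keep a full simulate + run-all cycle under ~15 s
while leaving every statistical check well-powered; the validation suite
scales cohorts up (n = 5000 peaks for distance/correlation recoveries,
10⁶ windows for scanner calibration) or down (tiny cohorts repeated 100×
for survival power) per analysis.

## Known limitations

- Exact threshold computation assumes a 0-order background; no
  higher-order models.
- The NB test's moderated dispersion is a pragmatic floor, not an
  empirical-Bayes shrinkage; very heterogeneous dispersion landscapes
  would deserve the latter.
- Matched controls match accessibility only (no GC or length matching,
  matching the original design).
- Censoring calibration in the generator is approximate (single average
  hazard), so realized censoring fractions deviate by a few percent.
- No Cox regression or multivariate adjustment; stratification is the
  univariate GSS split only.
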