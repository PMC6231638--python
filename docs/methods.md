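# Methods

This note documents the models, statistical procedures and design choices
behind `ripdecay`, and what the synthetic data do and do not establish.

## Scope and data model

The package implements the computational side of an RNP
co-immunoprecipitation (RNP-IP) target screen for an RNA-binding protein
and the downstream dissection of 3'UTR mRNA-instability elements:

1. calling target mRNAs from replicate IP+/IP-/total intensity tables;
2. correlating enrichment with 3'UTR sequence features;
3. estimating mRNA half-lives from transcription-shutoff time courses and
   mapping instability elements with deletion / linker-scanning construct
   panels;
4. quantifying protein-RNA binding from fractionated RNP-IP qPCR;
5. assessing local sequence similarity of candidate elements with a
   windowed-shuffle empirical significance test.

Sequences are stored in the RNA alphabet (T canonicalized to U on ingest).
All user-facing coordinates are 1-based inclusive, matching RefSeq-style
annotation; conversion to 0-based half-open indexing happens internally.
The stop codon belongs to the CDS, so the 3'UTR is everything strictly
after the CDS end.

## Synthetic data generators

The generators in `ripdecay.simulate` emulate every raw input and always
emit the planted ground truth next to the data.

**Noise model.** All noise is multiplicative log-normal — qPCR quantities
and array intensities are ratio-scale, strictly positive measurements. A
coefficient of variation `cv` parameterizes sigma via
`sigma^2 = ln(1 + cv^2)`, and factors are mean-one
(`mu = -sigma^2/2`), so expectations are preserved. The default
`noise_cv = 0.15` is an artifact choice of a realistic qPCR/array
measurement CV; the source data carry no quantitative noise estimate.

**Transcript universe.** Random transcripts with a short 5'UTR, a CDS of
100–500 codons and a 3'UTR drawn uniformly from 500–3000 bases (mean
~1.75 kb, matching the ~1.7 kb average UTR length of the screen's
annotation). Base composition is i.i.d. with `gc_content = 0.4` (3'UTRs
are AU-biased). A fraction of records (default 5%) receives
`motif_copies = 3` non-overlapping copies of a U-rich motif (default
`UUUAA`) written over the background UTR sequence — replacement rather
than insertion keeps lengths fixed; non-overlap is enforced by rejection
sampling.

**IP intensities.** The anti-tag beads adsorb non-selective background
with a composition mirroring total mRNA; this is modelled as
abundance-proportional capture (`background_capture`, default 5%). Planted
targets are additionally captured with gain `binding_gain_per_copy`
(default 1.6) per planted motif copy, i.e. a 3-copy target is
1.6^3 ≈ 4.1-fold enriched in expectation. Cellular abundances are
log-normal across transcripts. Default replicate structure is 2 IP+, 2
IP- and 1 total sample — the screen's own design.

**Decay panels.** First-order decay with additive element contributions:
each instability element contributes a rate `delta_lambda >= 0`, and a
construct's rate is `lambda0 + sum(contributions of elements it does not
edit away)`, with `lambda0 = ln2 / stable_halflife` (the empty reporter,
default 400 min). An element counts as removed when its interval overlaps
any edited interval. Abundance is `100 * exp(-lambda (t - t0))` with
per-point, per-pool noise; `t0` is the first sampled timepoint, mirroring
the convention that the first post-shutoff sample defines 100%.

**RNP-IP qPCR.** `pellet = input * recovery * bound_fraction * noise` and
`supernatant = input * recovery * (1 - bound_fraction) * noise`, so pellet
and supernatant sum exactly to `input * recovery` in the noise-free limit.

**What the simulations do not emulate.** Probe-level array structure,
probe-specific biases and RMA normalization; shared-transfection
correlations between replicates; deadenylation-then-decay biphasic
kinetics; secondary structure. Passing recovery tests therefore shows the
estimators are correct under the stated generative model, not that they
are robust to all artifacts of real arrays or qPCR.

## Enrichment calling

Per-sample log10 intensities are median-centered (the bead background
mirrors total mRNA, so a location shift per sample is the appropriate
normalization at transcript-summary level; probe-level RMA is out of
scope). Fold enrichment of IP+ is computed against IP- and against total;
by default a call requires `min_fold = 3` against **both** (a flag pools
the controls instead). Z-scores (per-sample standardization with sample
SD) and the Z-ratio — difference of mean z between conditions divided by
the SD of those differences over transcripts — are reported as a
complementary effect-size statistic.

The p-value is a two-sample unequal-variance (Welch) t-test of the IP+
replicates against all control samples (IP- and total pooled; after
centering both mirror the abundance profile). This is a declared
simplification of the original moderated-statistics analysis and is
exercised on synthetic data only. Benjamini-Hochberg adjustment is applied
**within the fold-passing candidate set**: only fold-passing transcripts
are eligible to be called, so they form the family actually tested, and
with 2–3 replicates a genome-wide BH family would squander the little
power the plain t-test has (the moderated analysis this replaces shares
variance information across transcripts instead). Non-candidates report
`p_adjusted = 1`.

The default `alpha = 0.5` on the adjusted p-value reproduces the screen's
published filter ("3-fold enrichment with an adjusted p-value < 0.5"): the
fold threshold does the selection and the p-value only removes the
noisiest candidates. Calls above `max_fold = 70` are flagged as outliers;
redundant probes per gene symbol collapse to the highest-fold
representative (the tie-break the source leaves unstated). Controls for
feature screens are a seeded uniform sample of non-enriched transcripts
(default n = 800).

Measured on the default recovery simulation (50 planted 4.1-fold targets
among 1000 transcripts, CV 0.1, 2+2+1 replicates), these choices recover
on average ~49/50 planted targets with no false calls, and the neutral
simulation yields essentially no calls (the fold gate dominates type-I
control).

## Sequence features and the correlation screen

Motif occurrences are counted with overlap (every start position tested)
on the sense strand only. Composition percentages are exact; empty
sequences are flagged `undefined` rather than silently zeroed.

The ARE-like score is a deliberately simple surrogate for pentamer-based
ARE scoring: each `AUUUA` occurrence scores 1, plus 0.5 if another
pentamer starts within 15 bases (clustering), plus 0.3 if the ±10-base
flank is ≥ 70% A/U (context). The ARED-like flag marks UTRs with at least
one pentamer inside a ≥ 60% A/U window of ±13 bases and reports the
longest chain of mutually overlapping pentamers. Both are configurable
and are *not* reimplementations of the published AREScore program or the
ARED database; no result in this package depends on matching their
printed values.

The screen computes Spearman's rho (average ranks for ties; p from the
t-approximation) between each feature and a continuous per-transcript
enrichment value — the measured fold enrichment for enriched *and*
control transcripts (controls keep their sub-threshold ratios). A binary
enriched/control indicator can be supplied instead by passing it as the
enrichment vector. Constant features are reported with an `undefined`
flag. Raw p-values are reported, matching the source's presentation.

## Half-life estimation and element calling

`ln(abundance)` is regressed on time by ordinary least squares;
`t_half = ln2 / (-slope)` (any log base gives the same half-life; natural
log is used internally). Two methods mirror the two published reporting
conventions:

* **pooled** (default): one regression over all points from all cell
  pools; the 95% Student-t CI on the slope is mapped through
  `s -> ln2/(-s)`. If the CI crosses zero slope the upper half-life bound
  is infinite. A non-negative fitted slope yields `t_half = inf` with a
  `stable` flag rather than a negative half-life.
* **per_pool**: independent fits per pool, reported as mean ± SD (the
  bounds stored in `ci95_low/high` are mean ∓ SD, matching the
  "average ± SD" convention).

The two agree exactly when pools are identical. Zero or negative
abundances are an error (no silent log of zero).

Element calling compares per-pool slopes of each mutant construct against
the wild-type with a two-sample two-tailed t-test (slopes, not
half-lives, are the directly regressed, approximately normal quantity; a
CI-overlap criterion is available as an alternative). A construct's
edited interval is an instability element iff the mutant half-life
exceeds the wild-type's and p < alpha (default 0.05). Adjacent
significant linker-scan intervals merge into one element (the source
reports joined coordinate ranges); the merged call keeps the worst member
p and the mean member half-life. Element spacing between two called
intervals is `start(later) - end(earlier) - 1` intervening bases under
1-based inclusive coordinates — the convention pinned by the published
30-base and 60-base spacings.

The 15-base linker `AGCAACGCGTAGCTC` and the `AGATCT` deletion marker are
recorded as constants for panel semantics; sequence reconstruction of
mutant UTRs is not needed for rate arithmetic and is not performed.

## RNP-IP qPCR arithmetic

`total = supernatant + pellet`; `recovery = total / input` is a QC
quantity (flagged outside 0.5–0.8, not an error); `percent bound =
pellet / total`; `relative enrichment = pct_bound(target) /
pct_bound(reference)`. Total, not input, is the denominator — input
serves only for recovery QC. Group comparisons use the two-tailed
homoscedastic t-test against the empty-vector construct (kept for
fidelity to the source's stated test; Welch available by flag). Fragment
binding profiles take the maximum enrichment among fragments covering a
base (conservative localization; mean by flag) and report peak intervals
above a caller-supplied threshold.

## Local alignment and shuffle significance

Default scoring is +5/−4 with affine gaps −12/−4 (a gap of length L costs
`gap_open + (L−1) * gap_extend`), the common DNA convention of the FASTA
program family; the exact defaults of the original PRSS-style analysis
are not printed in the source, so all scores are configurable and echoed
in outputs. The ungapped mode — the default for element-vs-element
comparisons, since "identities at the same position" implies no gaps —
finds the best diagonal segment exactly (Kadane's maximum-sum subarray
per diagonal; ties broken by earliest query start, then target start).
The gapped mode is standard Smith-Waterman/Gotoh.

Significance is empirical: the **target only** is shuffled (default 1000
times) within consecutive 10-base windows, preserving local composition;
the final short window is shuffled as-is. The add-one estimator
`p = (1 + #{shuffled score >= observed}) / (n + 1)` avoids zero p-values.
A Gumbel fit to the shuffled score sample provides an extrapolated tail
p-value below the empirical resolution, reported separately and labeled
extrapolated. For batch shuffle scoring the ungapped recurrence is
vectorized over shuffles (row-scan over query positions), which keeps
1000 shuffles of a 200-mer pair well under a second.

## Problem sizes used in the test suite

The recovery and calibration tests run at the study's own design points
(2+2+1 replicates, 3 cell pools, timepoints 0/60/120 min after shutoff,
1000-transcript universe) with seed counts chosen to keep the full suite
around half a minute: 500 half-life simulations, 100 panel seeds, 200
neutral-screen seeds, 500 oracle alignment pairs, and null calibrations
with 99–1000 shuffles. Empirical-p uniformity is checked at 99 shuffles ×
200 repetitions on 100-mers, which bounds the discreteness of the add-one
estimator well below the KS tolerance.

## Known limitations

* The enrichment statistics are valid for the synthetic generative model;
  no claim is made about probe-level array artifacts.
* Strictly first-order decay; biphasic (deadenylation-limited) kinetics
  will bias half-lives of the early phase.
* The ARE-like score and ARED-like flag are package-defined surrogates;
  their absolute values are not comparable to published ARE scores.
* `per_pool` CIs are descriptive (mean ± SD), not formal confidence
  intervals, by design.
* The Gumbel extrapolation assumes the shuffled-score sample is in the
  extreme-value regime; for very short sequences the empirical p is the
  trustworthy quantity.
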