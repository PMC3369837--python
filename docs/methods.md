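# Methods

This note documents the models, rules and numerical choices behind
`gcircuits`, the assumptions they rest on, and what the synthetic-cohort
tests do and do not demonstrate about real data.

## Copy-number model and state calling

Input profiles are **already-segmented** log2 ratios aligned to a shared,
sorted probe grid (`ProbeMap`); the package deliberately does not segment
raw data. Internally all genomic coordinates are 0-based half-open (BED
convention); any 1-based source must be converted at the boundary. Probes
with missing log2 are ignored inside smoothing windows and counted as
unaltered in the fBAC denominator — a conservative choice that keeps
denominators fixed across samples.

Two calling layers are deliberately separate:

* **Gain/loss** uses values smoothed in a midpoint-centred window
  (`window_bp` = 250 000 bp; windows never cross a chromosome) compared
  against a per-sample **sample-adaptive threshold** (SAT). GAIN where
  smoothed > +SAT, LOSS where < −SAT.
* **Amplification / homozygous deletion** uses the *unsmoothed* segmented
  values with fixed cutoffs `amp_log2` = +0.8 and `hd_log2` = −0.8
  (inclusive), and only maximal runs of at least `min_focal_probes` = 4
  consecutive probes qualify ("longer than three consecutive probes"
  read as ≥ 4; configurable). Shorter excursions remain GAIN/LOSS. The
  extreme state always wins (AMP over GAIN, HD over LOSS).

**SAT estimator.** The SAT concept is a per-sample noise-calibrated
threshold; this package defines it as

    SAT = max(multiplier × 1.4826 × MAD(d), floor),   d = Δ/√2,

where Δ are probe-to-probe first differences within chromosomes,
multiplier = 2.5 and floor = 0.05 (all configurable). One refinement
matters on segmented input: probes sharing a segment produce
*exact-zero* differences that carry no noise information and would
collapse the MAD, so zero differences are dropped before the MAD is
taken. On data with probe-level scatter this changes nothing; on
piecewise-constant segmented data the estimator then tracks the
segment-to-segment scatter (breakpoint steps), which is the quantity a
noise threshold should track there. A fully degenerate profile (no
non-zero differences) falls back to the floor.

**Amplicon merging.** Same-chromosome FGAs whose genomic gap is
< `merge_gap_bp` = 1 Mbp count as one amplicon; nFGA is the merged count.

**Arm events.** An arm is gained (lost) when strictly more than
`arm_probe_fraction` = 50 % of its probes are in a gained (lost) state;
if both directions qualify the larger fraction wins and ties give none.

## Recurrent-region discovery (peak-and-extend)

Per-probe support counts are accumulated per chromosome from per-sample
events (FGA/HD) or deleted-probe masks (MRD; deletion of *any* depth,
i.e. LOSS or HD states). Every maximal constant run that is a strict
local maximum and reaches the kind's minimum support (FGA 3, HD 2,
MRD 15 — the minimum applies to the peak itself) becomes a **core**;
plateaus form a single core spanning the plateau. Cores extend outwards
to the maximal contiguous run with support ≥ max − 2 (max − 1 for HDs),
never crossing a chromosome end. Two local maxima inside one extended
run each keep their own region; only regions identical in (core,
extended) are deduplicated.

Post-processing order: arm-scale MRD suppression (an MRD covering
strictly more than `mrd_max_arm_fraction` = 50 % of any arm is dropped —
the arm-level call represents it), then MRD/HD overlap resolution (an
MRD intersecting HD extended boundaries is replaced by those HD regions;
one MRD overlapping several HDs yields all of them), then germline-CNV
masking (a region is removed when CNV intervals cover strictly more than
`cnv_overlap_max` = 50 % of its extended genomic span — the cutoff is
this package's choice, as is treating an absent CNV file as "keep all,
warn").

Support peaks produced by overlapping passenger deletions *inside* a
recurrent whole-arm loss can survive suppression when the peak is
narrow; this mirrors the practical difficulty of defining minimal
regions on arms that are lost wholesale, and is why arm-level features
exist alongside MRDs.

The binary alteration matrix marks a sample as carrying a region feature
when any of its events (or deleted runs, for MRDs) intersects the
region's extended interval; arm and mutation features are appended
as given. FGA/HD features rarer than `mds_min_freq` = 5 % are flagged
and excluded from MDS embedding but retained everywhere else.

## Complexity metrics

* **nFGA** — merged amplicon count (above).
* **fBAC** — fraction of probes in any non-neutral state; AMP/HD probes
  count as altered (they are extreme gains/losses), missing probes count
  in the denominator.
* **CIN score** — mean over signature genes of gene-wise z-scored
  normalized expression. Signature gene lists are configuration inputs;
  the synthetic tests use the generator's known subtype-effect genes as
  the signature, which is exactly what a published chromosome-instability
  signature is for its cohort.
* **TP53/MDM2 status** — altered iff TP53 mutated OR an FGA intersects
  the configured MDM2 probe interval OR MDM2 expression falls in the
  high category (default: top decile — the published rank-plot threshold
  is not a printed number, so the quantile is configurable). A sample
  missing any input is "unknown".
* **IHC score** — intensity (0–3) × fraction of positive nuclei (10 %
  grid) × 100, averaged over 1–2 cores; range 0–300. The ×100 keeps the
  familiar 0–300 clinical scale.
* Group comparisons: Wilcoxon rank-sum (exact null for ≤ 25 per group,
  normal approximation beyond), one-way ANOVA, Welch t, Pearson r.

## Expression pipeline and subtyping

Normalization order: per-gene geometric-mean scaling of each later
labeling batch onto the reference batch (geometric means over positive
entries; genes with no positive reference value are dropped with a
warning) → background subtraction (default 0; the original background
method is unspecified) → negatives capped to 0 → +30 intensity constant
→ quantile normalization → log2 → SD > 0.25 filter (strict).

Quantile normalization assigns the across-sample mean of sorted values
by sorted position (no tie-averaging), which makes "all columns share
one sorted vector" exact and the operation idempotent.

Clustering: distance = 1 − Pearson correlation between sample columns;
Ward linkage with ward.D2 semantics on those dissimilarities (scipy's
`linkage(..., "ward")` on the condensed matrix); the tree is cut at k
(default 5, a conventional choice, not internally selected) and at 2 for
the MS split. Cluster labels are ordered by decreasing mean FGFR3
expression when that gene is present (else by size) — a convention so
that "HC1"/"MS1" is the FGFR3-high, genomically simple end. A constant
sample column makes correlation undefined and is an error.

Gene categorization partitions samples by ordered thresholds (values or
rank quantiles); a sample exactly at a boundary goes to the *lower*
category, so e.g. the median sample of an odd-length vector is "low".

Differential expression is a plain gene-wise Welch t with Bonferroni
control — a deliberately simple, documented substitute for
moderated-statistic packages, with the same interface (t, p, adjusted p,
direction, significance); genes with zero variance in both groups report
p = 1 and are flagged. Bonferroni uses m = number of genes tested.

## Association tests, MDS and networks

Pairwise co-occurrence uses one-sided hypergeometric tails, matching the
positive/negative-association language of circuit analysis:
p⁺ = P(X ≥ overlap), p⁻ = P(X ≤ overlap) for
X ~ Hypergeometric(N, K_a, K_b), accumulated from exact log-pmf terms
(gammaln + logsumexp) so that tiny tails keep full precision. Both tails
of every tested pair enter a single Bonferroni family (m = 2 × number of
pairs, recorded in the output); features with empty margins are excluded
with a warning. Fisher's exact test (two-sided) serves the
feature-versus-subtype-group contrasts.

MDS embeds *features* (aberrations), not samples, using Jaccard
distances between carrier sets and classical (Torgerson) scaling —
double-centre −D²/2 and eigendecompose; numerically-zero eigenvalues are
floored so coincident features get identical coordinates. The network
keeps nodes incident to at least one Bonferroni-significant edge; its
connected components are the reported circuits.

## Survival

Kaplan–Meier product-limit estimation and the k-group log-rank test are
delegated to lifelines behind the module surface; disease-specific
death is the event and every other exit is censoring. Ties between an
event and a censoring at the same time follow the standard
events-first convention. Grouping modes: nFGA 0 vs ≥ 1, CIN score ≤
median vs > median (median sample to the lower group), or custom labels.
No follow-up truncation is applied.

## Synthetic cohort: what it emulates, and what it does not

Defaults: 146 samples on 3000 probes (4 chromosomes × 750 probes,
100 kb spacing, 40 %/60 % p/q arms). Groups: circuit-A-like 40 %,
circuit-B-like 30 %, keratinized-like 12 %, background 18 %. Planted
events (carrier fractions within the indicated groups): a CDKN2A-like
HD (−1.6, 50 % of A, nested strictly inside A), a 9q-like whole-arm
loss (−0.5, 85 % of A), a CCND1-like FGA (+1.4, 35 % of A), a 6p22-like
FGA (+1.5, 80 % of B), an RB1-like HD (−1.5, 60 % of B), a 5p-like arm
gain (+0.5, 80 % of B / 50 % of keratinized), further arm losses for the
complex groups, and two hemizygous MRDs (−0.5) shared across the complex
groups. These fractions were chosen once so every planted region clears
its support minimum with margin and the complex (MS2) groups carry the
larger genomic burden, as complex tumors do.

Noise is **per segment**: baseline chromosomes split into on average 8
random segments, each receiving one Gaussian offset (sd 0.08); planted
and passenger events get one offset each. This respects the fact that
the pipeline's input is segmented data — probe-level jitter would
misrepresent it — and it is exactly the regime the zero-difference-
dropping SAT refinement handles. Passenger events (per sample: Poisson
0.05 focal amps, 0.01 focal HDs, 0.3 broad ±0.45 segments) supply
realistic nuisance structure; their rates were set from collision
probabilities so that recurrent passenger pile-ups are rare, not absent.

Expression is generated on the raw intensity scale: per-gene log-normal
baselines (log2 mean 7, sd 1.5), a 1.0-log2 separation between the MS
classes on 150 genes, a 0.75-log2 keratin program on 40 genes, ±1.2-log2
marker-gene effects (FGFR3, CCND1, RB1, PTEN, CDKN2A, E2F3, MDM2),
gene-level noise sd 0.5, a ×1.3 multiplicative second-batch factor,
additive intensity noise and a subtracted background offset that
produces genuine negative values for the capping step to handle.
Survival is exponential with hazards 0.004/month (simple groups),
0.015 (circuit B) and 0.035 (keratinized), with independent exponential
censoring calibrated to a 30 % censored fraction.

The generator's two-way expression truth (MS1 = circuit-A + background,
MS2 = circuit-B + keratinized) is what the k = 2 cut can recover; the
background group is expression-silent by design, so four-way group
recovery from expression alone is not expected and not claimed.

**Limitations.** The grid is ~10× coarser than a tiling BAC array and
has 4 synthetic chromosomes, so arm events weigh more in fBAC than real
arms would; segment noise is homoscedastic; expression effects are
additive log-normal with no gene–gene correlation beyond group
structure; mutations are independent Bernoulli draws given the group;
survival has proportional hazards by construction. Passing the
planted-truth tests therefore shows the *rules* are implemented
correctly and are recoverable under realistic noise — not that the
defaults reproduce any particular real cohort's numbers.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 50 random ≤ 100-probe /
≤ 10-sample fixtures against exhaustive interval enumeration; 20 default
cohorts (146 × 3000) for planted-region, network and subtype recovery;
all hypergeometric configurations with N ≤ 12 against carrier-placement
enumeration (1651 tail checks, tolerance 1e−12); 200 null seeds for
log-rank calibration (n = 50 per group, 30 % censoring); and 100 null +
100 power seeds for the differential-expression substitute (2000 genes,
n = 15 per group, 2-log2 planted shifts). These sizes keep the whole
verification run in well under a minute per stage on one CPU while
leaving the binomial error of the estimated rates small.
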