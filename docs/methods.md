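# Methods

This note documents the models and procedures `sarcnv` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## Coordinates and input handling

All intervals are held internally as 0-based half-open (BED semantics).
Public SEG exports are frequently 1-based closed, so the segment reader
takes an explicit `dialect` argument and normalizes on input; there is no
guessing. Chromosome names are normalized by stripping a leading `chr`,
since public annotation and segment files mix both styles. Duplicate gene
symbols in the annotation keep the longest interval (identical duplicates
collapse silently); this is a tie rule, not a merge — overlapping isoform
footprints are out of scope.

## Segment-to-gene aggregation

A gene's value in a sample is the overlap-length weighted mean of the log2
ratios of all that sample's segments intersecting the gene. Length
weighting is the least-surprising estimator of the gene's average copy
state when a breakpoint falls inside a gene; for the common case of a gene
fully covered by a single segment it reduces to that segment's value
exactly. Genes with no overlapping segment in a sample are missing, and
missing entries are excluded from every downstream denominator (per-gene
sample counts are therefore gene-specific). Cytobands are assigned by gene
midpoint: a gene straddling a band boundary gets a single deterministic
label rather than two fractional ones.

## Five-level discretization

Discretization is relative, not absolute: thresholds are the 5th, 15th,
85th and 95th percentiles (type-7 linear interpolation between order
statistics, the default estimator across scientific software) of the
pooled gene x sample distribution of one cohort/platform. Pooling per
platform absorbs scale differences between array generations; thresholds
are never shared across cohorts. Codes are +2 above p95, +1 in (p85, p95],
-1 in [p05, p15), -2 below p05, else 0 — boundary ties resolve toward the
milder code, fixing the mixed boundary wording a reader might otherwise
implement either way. Gain calls pool +1/+2 and loss calls -1/-2; the
+-2 vs +-1 distinction is retained in the matrix (useful for display) but
not in frequencies.

A consequence worth stating plainly: by construction ~15% of pooled
entries are coded as gains and ~15% as losses *whatever the data look
like*. The scheme is meaningful for chromosomally unstable tumor genomes,
where the tails really are aberrations; on a flat diploid genome it
manufactures calls out of noise. The synthetic cohort scenario below is
designed with this in mind.

## Frequencies

Gene frequency = calls / non-missing samples for that gene. Band frequency
= total calls over member genes / summed per-gene non-missing counts; with
complete data the denominator is samples x genes and the band frequency
equals the arithmetic mean of member-gene frequencies exactly. The
summed-denominator form is the natural generalization when genes have
unequal missingness. The healthy background (DGV-style records) counts
distinct individuals with at least one overlapping gain (loss) record per
gene, divided by the declared population size; repeated records from one
individual do not inflate the frequency. Tumor and healthy frequencies are
reported side by side without a statistical test — recurrence significance
(GISTIC-style) is a non-goal.

Cohort comparison aligns gene-level tables on the intersection of gene
universes and reports the set of genes whose alteration frequency
(max of amp, del) reaches a caller-supplied floor in every cohort
simultaneously.

## Clustering

Clustering consumes the continuous matrix (codes are a display layer),
optionally restricted to the k genes of largest sample standard deviation
(ties break by annotation order). Distances are 1 - Pearson r (range
[0, 2], 0 iff perfectly correlated) or Euclidean, computed over
pairwise-complete observations; a pair with fewer than two shared
observations is an error naming the pair. The agglomeration itself is
implemented directly (average/UPGMA or complete linkage) so tie-breaking
is fully specified: among equally close pairs, the lexicographically
smallest cluster-id pair merges first. Tests cross-check the merge trees
against SciPy's reference agglomeration on tie-free data. Trees export as
Newick with branch lengths equal to parent merge height minus child merge
height.

## Dose-response AUC

The drug-response model imposes exactly one constraint: viability is
nonincreasing in log2 concentration. The fit is the L2 projection of the
observed viabilities onto the nonincreasing cone — isotonic regression by
pool-adjacent-violators (scikit-learn's implementation, with an exact
pass-through for already-feasible input) — and the sensitivity summary is
the trapezoidal integral of the fitted curve over the observed log2 grid.
This keeps the estimator deterministic and testable (the projection is
verified against exhaustive level-set enumeration) while preserving the
defining monotonicity property; no parametric curve family or smoothing
bandwidth is assumed, and EC50-style logistic fitting is deliberately out
of scope. AUC is unnormalized area (viability x log2-concentration units)
over the tested window; `normalized=True` divides by the window span.
Curves need at least 4 points with strictly increasing concentrations;
viabilities above 1 are retained (treated wells can outgrow controls),
negative viabilities are clipped to 0 with a warning.

## Biomarker calling

For each (gene, drug) pair with at least 3 shared cell lines, Pearson r is
computed between continuous gene-level CNV and AUC, with the two-sided
p-value from t = r sqrt((n-2)/(1-r^2)) on n-2 df (p = 0 exactly at
|r| = 1). Calls: sensitive iff r < -0.35 and p < 0.05; non_sensitive iff
r > 0.35 and p < 0.05; otherwise none. The thresholds apply to raw
p-values; Benjamini-Hochberg q-values are reported in the output for
transparency but do not change calls. Amplification correlating with lower
AUC (less drug needed to inhibit growth) gives negative r, hence
"sensitive". Cell-line names are matched case-insensitively with
punctuation stripped, absorbing the naming drift between CNV and screening
resources. Pairs with constant CNV or constant AUC are skipped, not fatal.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` tiles each chromosome of a desk-scale genome (default:
200 genes across 4 chromosomes and 12 bands) with segments of exponential
length (mean 3 Mb, floor 50 kb) and baseline log2 ratios ~ N(0, 0.2), a
noise scale typical of segmented SNP-array data. Each planted event
(region, amp/del, population frequency, shift) is applied to an
independent Bernoulli subset of samples; event edges act as breakpoints,
so segments never straddle a planted-region boundary and the shift is
confined to the region — mirroring how real CNV edges appear as
segmentation breakpoints.

The default tumor scenario (`tumor_cohort_spec`) plants one target
amplification (10 genes, 5% of the genome, shift +1.0) at the requested
frequency plus background "filler" aberrations: an amplified block on
chromosome 2 whose carrier frequency is set so the expected amplified
share of gene x sample entries stays near 12.5% regardless of the target
frequency, and a deleted block on chromosome 3 at 60% frequency. This
constant aberration burden is the study condition the quantile scheme
assumes (see above): it places p85 in the gap between diploid noise and
shifted entries, so planted frequencies are recoverable to binomial
accuracy. What the generator does not emulate: probe-level noise, GC
waves, focal/broad event mixtures, subclonal (fractional) shifts, or
correlated breakpoints between samples — so passing recovery tests show
the pipeline arithmetic is right under the stated model, not that the
thresholds are optimal for any particular real platform.

`simulate_cellline_panel` draws standard-normal gene-level CNV for each
line, then builds each 16-point, 2-fold-dilution dose-response curve as a
logistic in log2 concentration (half-viability at the potency parameter,
one log2 unit of steepness) whose potency is solved by bisection so the
trapezoidal AUC equals baseline + slope x CNV + N(0, noise) for planted
(gene, drug) links — AUC noiseless construction is exact to ~1e-12 —
and baseline + noise for unlinked pairs. With unit-variance CNV, a slope
s and noise sd sqrt(1 - s^2) give a population CNV-AUC correlation of
exactly s, which is how the power conditions (true r = -0.7, n = 27) are
constructed. Targets are clipped into 1-99% of the achievable AUC range;
defaults keep them far from the clip.

All generators draw from a single `numpy.random.Generator` per call and
emit byte-identical text for identical spec + seed.

## Packaged fixtures

The three study tables (63-gene recurrent panel with per-cohort amp/del
frequencies, 27 cell lines, 206-profile cohort annotation) are transcribed
tables shipped with the package and verified against SHA-256 checksums on
load. The panel table's source layout lost the column positions of the
per-sarcoma support flags for rows flagged in fewer than three cohorts;
those rows carry the flag count (`n_sarcoma_flags`) with the per-cohort
columns left missing rather than guessed. One row (IGF2) has a blank
frequency cell in the source; it is stored as missing.

## Problem sizes

Defaults are desk scale by design: 200-gene genomes, cohorts of tens to
200 samples, 27-line panels with 16-dose curves, 100-instance oracle
sweeps and 200-repetition power estimates. These sizes give sub-minute
test runs while leaving every statistical conclusion (binomial recovery
bands, calibration bands, power >= 90%) comfortably resolved.

## Known limitations

- The pipeline starts at segmented data; CNV calling from probe
  intensities, normalization of raw arrays, and liftover between genome
  builds are out of scope.
- Quantile discretization is rank-based per cohort; absolute copy-number
  states (ploidy, purity) are not modeled.
- Band assignment by midpoint attributes a boundary-straddling gene to a
  single band.
- Biomarker calling is univariate per (gene, drug); multivariate or
  regularized drug-response models are out of scope.
- The cohort comparison reports overlap sets; it attaches no significance
  to them.
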