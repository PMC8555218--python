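# Methods

## Problem setting

Copy-number variants (CNVs) in targeted panels and exomes are called from
read depth: a deletion halves and a duplication multiplies the expected
number of reads over a capture target (ROI). Depth-based callers are
sensitive to three interacting choices — which cohort samples form the
reference baseline, which low-coverage targets/samples to discard, and how
much evidence an event must accumulate before the segmentation model leaves
the normal state. The right settings are assay-specific. `panelcnv`
implements the full loop for tuning them without wet-lab truth data: call
the cohort with default parameters, build an *in silico* validation set
from the concordance of several independent callers, grid-search the three
parameters against that set to maximise sensitivity, and re-call with the
winning configuration.

## The depth caller

For each test sample the caller:

1. **Selects a reference set.** Candidates are the other samples in the
   batch, minus anything in the test sample's family group (a CNV shared
   within a family would otherwise be absorbed into the baseline).
   Candidates must reach a Pearson correlation of at least
   `min_correlation` (default 0.98) with the test sample's raw count
   profile over active ROIs; survivors are ranked by correlation and capped
   at 10, since reference sets beyond ~5–10 samples add noise rather than
   signal. A sample with no qualifying reference is a no-call for the whole
   batch. Correlation is computed on raw counts; whether to log-transform
   first is a genuinely open choice and raw counts keep the filter
   sensitive to the depth profile the ratios are actually built from.

2. **Applies coverage QC.** An ROI whose median count across samples falls
   below `min_coverage` (default 100) is dropped; a sample whose median
   count across the full pre-drop target falls below the same threshold is
   marked no-call. Both filters can be switched off independently.

3. **Computes reads ratios.** With library sizes `T_s` (total count over
   active ROIs), `ratio[r] = (count[test,r]/T_test) / median_j(count[j,r]/T_j)`
   over the reference `j`. An ROI whose reference median is zero is a
   no-call for that sample. On diploid regions the ratio estimates CN/2.

4. **Segments per chromosome** with a 3-state hidden Markov model
   (deletion / normal / duplication) with Gaussian emissions at ratio means
   0.5 / 1.0 / 1.5. The per-ROI emission SD is the spread of the reference
   samples' own normalised ratios at that ROI, floored at 0.05, so noisy
   targets are automatically down-weighted. Transitions out of normal into
   either event state carry probability `transition_prob` (default 0.01 —
   a deliberately conservative default); event states return to normal
   with probability 1/3 (expected event length 3 ROIs, not optimised) and
   hop directly between deletion and duplication with probability 1e-6.
   The initial distribution is (t, 1−2t, t). The most likely path is found
   by Viterbi dynamic programming, checked in the test suite against
   exhaustive enumeration of all 3^L paths on short chromosomes.

5. **Merges and annotates.** Maximal runs of consecutive same-state
   non-normal ROIs become one call spanning the first ROI's start to the
   last ROI's end. The call's reads ratio is the run mean, and the copy
   number comes from fixed bands: ≤0.1 → 0; (0.1, 0.8] → 1; (0.8, 1.2] → 2;
   (1.2, 1.8] → 3; (1.8, 2.2] → 4; above 2.2, twice the ratio rounded
   half-up (the band value is clamped to ≥3 right at the duplication
   boundary, where naive rounding would produce 2).

**Batching.** With at least 5 samples of each sex, females and males are
called separately, so sex-chromosome baselines are internally consistent.
Below that, all samples form a single batch and X/Y calls carry an
`unreliable` flag. A `batch2` mode keeps autosomes mixed and splits only
X/Y by sex. Sexes missing from the sample sheet are inferred from coverage:
male when the mean chrY count is ≥ 0.25× the autosomal median and the mean
chrX count is ≤ 0.75× of it, female when chrY is below the quarter
threshold; the ambiguous corner resolves to female with a warning. The
rule compares chromosome means against the autosomal median, so it assumes
capture efficiency is not wildly skewed between chromosomes; with known
sexes on the sample sheet no inference runs. Samples carrying real X/Y
CNVs are intrinsically ambiguous for any coverage-based rule.

## The in silico validation set

External call sets enter as normalised 5-column BED (chrom, start, end,
DEL|DUP, sample). Callers that report nothing anywhere are discarded; at
least two usable call sets are required. Within each (sample, type,
chromosome) stratum, calls are grouped into connected overlap components.
A component becomes a validated CNV when every retained caller contributes
a call and the mutual intersection (choosing, per caller, the fragment
that maximises it; ties to the leftmost) satisfies two filters:

- it covers at least 60% of at least **one** contributing call (the
  fraction is configurable; the one-caller reading is the literal one and
  the least restrictive), and
- it is at least as long as the mean ROI size of the target (configurable).

The validated span is the intersection — the most conservative choice —
clipped to the target footprint. Validated spans are then union-merged
into disjoint validated regions, and every (sample, region) pair receives
a state: the sample's validated call type where one overlaps, otherwise
NORMAL. These states are the truth the optimiser scores against; by
construction they cover only regions where some CNV was concordantly
observed, which keeps the negatives informative (same locus, other
samples) rather than trivially empty genome.

## Parameter optimisation

The grid holds up to 22 candidate values per parameter and must contain
each parameter's default, so the search can never select something worse
than the default configuration. The default grid spans correlation
0.80–0.99 (12 values), coverage 20–200 (10), and transition probability
1e-5–0.2 (10, log-spaced), i.e. 1200 combinations. Each combination runs
the full caller; calls are projected onto validated regions × samples
(no-calls count as NORMAL, see below) and scored. The objective is
sensitivity; ties break by F-score (so a call-everything configuration
cannot win), then specificity, then proximity to the defaults measured as
L2 distance on grid rank indices, then grid order. `full_grid` search is
the default; a `coordinate` mode sweeps one axis at a time (two passes)
for large grids and can only match, never beat, the full grid. Both are
deterministic, so re-running an identical configuration reproduces the
identical result table.

## Benchmarking

Evaluation is per (sample, region) unit, each unit scored independently:
agreement on a non-normal type is a true positive, agreement on normal a
true negative, a predicted CNV on a validated-normal unit a false
positive, and a missed or wrong-type validated CNV a false negative.
Wrong-type overlaps count as a single miss by default (one label per
unit); a double-count option (FN+FP) exists. No-call units are counted as
negatives by default (`as_normal`): in a diagnostic workflow an abstention
leaves the region unconfirmed, so a validated CNV hidden under a no-call
is a miss. The `excluded` policy removes them from the universe instead.
Reported metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV
TP/(TP+FP), NPV TN/(TN+FN), and F-score, the harmonic mean of PPV and
sensitivity; any ratio with a zero denominator is reported as null.

## Synthetic cohorts

The generator emulates the depth structure of capture experiments at desk
scale. Defaults: 40 samples (half female, two sibling pairs), 280
autosomal ROIs across four autosomes plus 15 chrX and 5 chrY targets of
100–400 bp; mean depth 150× with a truncated-normal per-sample library
factor (CV 0.1) and a lognormal per-ROI capture efficiency (sdlog 1.2, so
target depths span roughly two orders of magnitude as real capture data
does — this shared efficiency profile is what makes inter-sample
correlations high, exactly the property the correlation filter exploits).
Counts are negative-binomial with dispersion 50 (depth CV ≈ 0.15 at
150×), mean proportional to copy number over the diploid baseline, so a
hemizygous male chrX target sits at ~0.5× and female chrY at zero. Events
arrive per sample at Poisson rate 1, cover a geometric number of
consecutive ROIs (mean 2, so about half span a single ROI — the hard case
that exercises the transition-probability axis), are deletions with
probability 0.6 (10% of autosomal deletions homozygous), and never overlap
within a sample or violate sex-chromosome ploidy. Everything derives from
one seed.

Surrogate external callers are modelled as truth plus noise — per-event
dropout, boundary jitter in ROI units (anchored so a jittered call still
touches its source event, as a real caller's boundary error does), and
random 1–2 ROI false calls per (sample, ROI) unit — so consensus tests
isolate the consensus logic from caller quality.

Deliberately not modelled: GC/mappability structure, read-level noise,
allele fractions/mosaicism, recurrent artefact loci shared across callers.
The last point matters for interpretation: consensus specificity against
truth is excellent here partly because surrogate false calls are
independent across callers; correlated artefacts in real data could
survive the consensus.

At the default (exome-like) conditions, inter-sample correlations straddle
the 0.98 default threshold and many single-ROI events fall below the
evidence demanded by the default transition probability, so
default-parameter sensitivity is low and optimisation has real headroom —
the regime where tuning is worth doing. The test suite also uses a
tighter "panel" scenario (dispersion 300, depth 200×) where the defaults
already recall most well-displaced events.

## Numerical and design notes

- Coordinates are 0-based half-open everywhere, including all BED I/O.
  Overlapping targets in the input BED are union-merged with a warning.
  Chromosome names are taken verbatim; no "chr"-prefix harmonisation.
- Viterbi runs in log space; ties are broken toward the lower state index
  (DEL < NORMAL < DUP), a measure-zero event for continuous ratios.
- The external-caller log2 adapter maps diploid log2 ratios through bands
  ≤ −2 → CN0, (−2, −0.4] → CN1, up to +0.32 → CN2, then doubling with
  rounding (clamped to ≥3 inside the duplication band). The duplication
  threshold is not part of the deletion-band convention and is configurable;
  +0.32 ≈ the CN3 lower bound. For haploid regions the ratio is shifted
  down one doubling before banding, which makes the band value equal the
  haploid copy number directly.
- Sample medians for QC are evaluated on the pre-drop target, so the
  sample filter does not depend on which ROIs the ROI filter removed.
- A merged evaluation region touched by both a DEL and a DUP call of one
  sample (adjacent runs) takes the type with the larger overlap; only
  calls of opposite type overlapping each other are a contract violation.
- Test problem sizes: consensus and optimisation checks use 30-sample,
  300-ROI cohorts over 10 seeds with a reduced 5×4×6 grid; end-to-end
  determinism uses 25 samples and a 2×2×2 grid. These sizes were chosen to
  keep the full suite in the low minutes while leaving every mechanism
  (batching, QC, reference selection, segmentation, consensus, search)
  fully exercised.

## Known limitations

- The caller's Gaussian emission on the ratio scale is a simplification;
  exact read-count likelihoods (beta-binomial) would weight low-coverage
  ROIs more faithfully. The optimiser only needs parameter sensitivity,
  which the Gaussian model preserves.
- With one- or two-sample reference sets the per-ROI SD estimate collapses
  to the 0.05 floor and the caller over-calls; in practice the correlation
  threshold (or its optimised value) governs whether such fragile
  references occur.
- The copy-number bands assume a diploid baseline; on male sex chromosomes
  (called against male references) the printed copy number is the band
  value, not a ploidy-adjusted one.
- The validation set inherits the intersection's conservatism: its
  sensitivity against real truth is intentionally low, and optimising
  against it emphasises recovering concordant events, not every event.
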