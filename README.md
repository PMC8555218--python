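# panelcnv

Read-depth copy-number variant (CNV) calling for targeted panels and
exomes, with self-contained parameter tuning: the pipeline builds an *in
silico* validation set from the concordance of independent CNV callers and
grid-searches its own caller's parameters against it to maximise
sensitivity — no MLPA or array truth data required.

It is aimed at diagnostic and research labs running capture-based cohorts
(tens of samples, hundreds to thousands of targets) who need a depth
caller tuned to *their* assay, plus the benchmarking machinery to say how
well it does.

## What it computes

For a test sample $s$ with reference set $R$ (the ≤10 best-correlated,
unrelated cohort samples), the per-target reads ratio is

$$r_j = \frac{c_{sj}/T_s}{\operatorname{median}_{k \in R}\; c_{kj}/T_k},$$

with $c_{sj}$ the read count of sample $s$ on target $j$ and $T_s$ its
library size. On diploid regions $r_j \approx \mathrm{CN}/2$. The ratio
track is segmented per chromosome by a 3-state HMM (deletion / normal /
duplication; Gaussian emissions at means 0.5 / 1.0 / 1.5 with per-target
SD estimated from the reference spread) and consecutive non-normal
targets are merged into calls annotated with a mean reads ratio and an
integer copy number from fixed bands (≤0.1 → 0, …, (1.2, 1.8] → 3, >2.2 →
2·ratio rounded).

Three parameters drive sensitivity and are grid-optimised against the
validation set: the reference-correlation floor, the median-coverage
floor, and the HMM's normal→event transition probability. The validation
set itself is the mutual intersection of ≥2 callers' calls (same sample,
same type) covering ≥60% of at least one contributing call and at least
the mean target size. Benchmarking is per (sample, target-region) unit
with sensitivity, specificity, PPV, NPV and F-score; no-calls count as
negatives, as a diagnostic workflow would treat them.

See `docs/methods.md` for the model, assumptions and design choices.

## Worked example

Simulate a 30-sample cohort (300 targets, embedded DEL/DUP events) plus
three surrogate external call sets, then run the whole pipeline:

```sh
panelcnv simulate --out-dir demo --seed 7 --n-samples 30 --surrogate-callers 3
# simulated 30 samples x 300 ROIs, 22 truth events -> demo

cat > demo/grid.yaml <<EOF
correlation: [0.90, 0.94, 0.98]
coverage: [20, 60, 100]
transition: [0.001, 0.01, 0.1]
EOF

panelcnv batch --target demo/target.bed --coverage demo/coverage.tsv \
    --samples demo/samples.tsv \
    --calls demo/caller1.bed --calls demo/caller2.bed --calls demo/caller3.bed \
    --grid demo/grid.yaml --seed 7 --out-dir demo/run
# done: 142 final calls; best params CallerParams(min_correlation=0.94,
#   min_coverage=100, transition_prob=0.1); metrics {'sensitivity': 1.0, ...}
```

The run directory contains the default-parameter calls, the validated
call set and its per-sample states, the full per-combination grid table
(`grid_results.tsv`), the winning parameters:

```
$ cat demo/run/best_params.yaml
min_correlation: 0.94
min_coverage: 100
transition_prob: 0.1
```

and the final, fully annotated calls (chrom, start, end, type, sample,
reads ratio, copy number):

```
$ head -3 demo/run/final_calls.bed
chr1	23872	24222	DUP	S005	1.420	3
chr1	23872	24222	DEL	S023	0.659	1
chr1	25862	25978	DUP	S006	1.403	3
```

Reading the numbers: the optimiser moved the correlation floor from 0.98
down to 0.94 (the exome-like simulated cohort has inter-sample
correlations straddling 0.98, so the default no-calls many samples) and
the transition probability up from 0.01 to 0.1 (single-target events need
a laxer entry cost to be called). `metrics.tsv` scores the final calls
against the validated regions; a run's `MANIFEST.tsv` checksums every
artifact, and re-running with the same inputs and seed reproduces it byte
for byte. Every stage is also available as its own subcommand
(`simulate`, `call`, `consensus`, `optimize`, `benchmark`).

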