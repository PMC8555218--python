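"""Read-depth CNV caller for capture panels.

The caller follows the classic panel recipe: for each test sample pick a
reference set of well-correlated, unrelated cohort samples; form per-ROI
reads ratios (library-size-normalised test depth over the median normalised
reference depth); segment the ratio track per chromosome with a 3-state
hidden Markov model (deletion / normal / duplication, ratio means 0.5 / 1.0
/ 1.5); and merge consecutive non-normal ROIs into events annotated with a
mean reads ratio and an integer copy number.

Three knobs drive sensitivity and are the targets of grid optimisation
(:mod:`panelcnv.optimize`):

``min_correlation``
    Pearson-correlation floor for a cohort sample to enter a test sample's
    reference set (and for the test sample itself to be callable).
``min_coverage``
    Median read-count floor below which an ROI is dropped, or a sample is
    marked no-call, before ratio computation.
``transition_prob``
    HMM probability of leaving the normal state for deletion or
    duplication; lower values demand stronger per-event evidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    CallSet,
    CNVCall,
    CNVType,
    GenomicInterval,
    ROI,
    Sample,
    Sex,
    State,
    is_sex_chromosome,
)

__all__ = [
    "CallerParams",
    "CoverageMatrix",
    "Batch",
    "BatchPlan",
    "infer_sex",
    "plan_batches",
    "apply_qc_filters",
    "select_reference",
    "compute_ratios",
    "estimate_emission_sd",
    "viterbi_segment",
    "merge_calls",
    "map_ratio_to_cn",
    "call_cohort",
]

MAX_REFERENCE_SIZE = 10  # reference sets larger than ~10 add noise, not signal
SD_FLOOR = 0.05
DWELL_EXIT_PROB = 1.0 / 3.0  # DEL/DUP -> NORMAL; expected event length 3 ROIs
CROSS_STATE_PROB = 1e-6  # direct DEL <-> DUP hop


@dataclass(frozen=True)
class CallerParams:
    """The three tunable caller parameters (defaults: 0.98 / 100 / 0.01)."""

    min_correlation: float = 0.98
    min_coverage: float = 100.0
    transition_prob: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.min_correlation < 1.0) or not math.isfinite(self.min_correlation):
            raise ValueError(f"min_correlation must be in (0, 1): {self.min_correlation}")
        if self.min_coverage < 0 or not math.isfinite(self.min_coverage):
            raise ValueError(f"min_coverage must be nonnegative: {self.min_coverage}")
        if not (0.0 < self.transition_prob < 0.5) or not math.isfinite(self.transition_prob):
            raise ValueError(f"transition_prob must be in (0, 0.5): {self.transition_prob}")


@dataclass
class CoverageMatrix:
    """Read counts indexed (sample, ROI) plus QC bookkeeping.

    ``dropped_rois`` and ``nocall_samples`` record QC casualties with a
    human-readable reason; active ROIs/samples are the complement.
    """

    counts: np.ndarray  # shape (n_samples, n_rois), nonnegative integers
    samples: list[Sample]
    rois: list[ROI]
    dropped_rois: dict[str, str] = field(default_factory=dict)  # roi key -> reason
    nocall_samples: dict[str, str] = field(default_factory=dict)  # sample name -> reason

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.rois)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.rois)} ROIs"
            )
        if (self.counts < 0).any():
            raise ValueError("read counts must be nonnegative")

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def sample_index(self, name: str) -> int:
        try:
            return self.sample_names.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def active_roi_indices(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.rois) if r.key not in self.dropped_rois],
            dtype=np.intp,
        )

    def active_sample_names(self) -> list[str]:
        return [s.name for s in self.samples if s.name not in self.nocall_samples]

    def with_sexes(self, sexes: dict[str, Sex]) -> "CoverageMatrix":
        new_samples = [
            replace(s, sex=sexes.get(s.name, s.sex)) for s in self.samples
        ]
        return replace(self, samples=new_samples)


@dataclass(frozen=True)
class Batch:
    label: str
    sample_names: tuple[str, ...]
    chroms: tuple[str, ...]
    sex_calls_unreliable: bool = False


@dataclass(frozen=True)
class BatchPlan:
    batches: tuple[Batch, ...]

    def validate(self, samples: Sequence[Sample], chroms: Sequence[str]) -> None:
        seen: dict[tuple[str, str], str] = {}
        for b in self.batches:
            for s in b.sample_names:
                for c in b.chroms:
                    if (s, c) in seen:
                        raise ValueError(
                            f"(sample {s}, {c}) covered by batches {seen[(s, c)]} and {b.label}"
                        )
                    seen[(s, c)] = b.label
        expected = {(s.name, c) for s in samples for c in chroms}
        if set(seen) != expected:
            missing = expected - set(seen)
            raise ValueError(f"batch plan leaves {len(missing)} (sample, chrom) pairs uncovered")


def infer_sex(matrix: CoverageMatrix) -> CoverageMatrix:
    """Resolve UNKNOWN sample sexes from sex-chromosome coverage.

    A sample is called male when its mean chrY ROI count is at least a
    quarter of its autosomal median AND its mean chrX count is at most
    three quarters of the autosomal median; it is female when chrY coverage
    falls below the quarter threshold.  The ambiguous corner (Y present but
    X not depleted) resolves to female with a warning.  Samples with a sex
    already on the sample sheet are left untouched.
    """
    unknown = [s.name for s in matrix.samples if s.sex == Sex.UNKNOWN]
    if not unknown:
        return matrix
    x_idx = [i for i, r in enumerate(matrix.rois) if r.chrom.lower().removeprefix("chr") == "x"]
    y_idx = [i for i, r in enumerate(matrix.rois) if r.chrom.lower().removeprefix("chr") == "y"]
    aut_idx = [i for i, r in enumerate(matrix.rois) if not is_sex_chromosome(r.chrom)]
    if not (x_idx or y_idx):
        raise ValueError(
            f"samples {unknown} have unknown sex but the target has no sex-chromosome "
            "ROIs; provide explicit sexes in the sample sheet"
        )
    if not aut_idx:
        raise ValueError("cannot infer sex without autosomal ROIs for baseline coverage")
    sexes: dict[str, Sex] = {}
    for name in unknown:
        i = matrix.sample_index(name)
        aut_median = float(np.median(matrix.counts[i, aut_idx]))
        if aut_median <= 0:
            raise ValueError(f"sample {name} has zero autosomal coverage; cannot infer sex")
        y_mean = float(np.mean(matrix.counts[i, y_idx])) if y_idx else 0.0
        x_mean = float(np.mean(matrix.counts[i, x_idx])) if x_idx else 0.0
        if y_mean >= 0.25 * aut_median and (not x_idx or x_mean <= 0.75 * aut_median):
            sexes[name] = Sex.M
        elif y_mean < 0.25 * aut_median:
            sexes[name] = Sex.F
        else:
            warnings.warn(
                f"ambiguous sex-chromosome coverage for {name} "
                f"(Y present, X not depleted); resolving to F",
                stacklevel=2,
            )
            sexes[name] = Sex.F
    return matrix.with_sexes(sexes)


def plan_batches(
    samples: Sequence[Sample], rois: Sequence[ROI], mode: str = "default"
) -> BatchPlan:
    """Split the cohort into calling batches.

    default: with >=5 samples of each sex, females and males are called
    separately over all chromosomes (reliable sex-chromosome calling);
    otherwise all samples go in one batch and sex-chromosome calls are
    flagged unreliable.  batch2: autosomes in one mixed batch, X/Y split by
    sex (requires >=5 of each sex, falling back to the single batch).
    single: one mixed batch regardless of sex counts.
    """
    if not samples:
        raise ValueError("cannot plan batches for zero samples")
    if mode not in ("default", "batch2", "single"):
        raise ValueError(f"unknown batch mode {mode!r}")
    chroms = tuple(dict.fromkeys(r.chrom for r in rois))
    sex_chroms = tuple(c for c in chroms if is_sex_chromosome(c))
    autosomes = tuple(c for c in chroms if not is_sex_chromosome(c))
    females = tuple(s.name for s in samples if s.sex == Sex.F)
    males = tuple(s.name for s in samples if s.sex == Sex.M)
    everyone = tuple(s.name for s in samples)
    both_sexes_ok = len(females) >= 5 and len(males) >= 5

    def single_batch() -> BatchPlan:
        return BatchPlan(
            (
                Batch(
                    "all",
                    everyone,
                    chroms,
                    sex_calls_unreliable=bool(sex_chroms),
                ),
            )
        )

    if mode == "single":
        return single_batch()
    if mode == "default":
        if not both_sexes_ok:
            return single_batch()
        if len(females) + len(males) != len(everyone):
            raise ValueError("sex-split batching requires resolved sexes for every sample")
        return BatchPlan(
            (
                Batch("female", females, chroms),
                Batch("male", males, chroms),
            )
        )
    # batch2: mixed autosomal batch, per-sex batches on X/Y only
    if not both_sexes_ok:
        return single_batch()
    if len(females) + len(males) != len(everyone):
        raise ValueError("sex-split batching requires resolved sexes for every sample")
    batches = [Batch("autosomes", everyone, autosomes)]
    if sex_chroms:
        batches.append(Batch("sex-female", females, sex_chroms))
        batches.append(Batch("sex-male", males, sex_chroms))
    return BatchPlan(tuple(batches))


def apply_qc_filters(
    matrix: CoverageMatrix,
    params: CallerParams,
    drop_low_coverage_rois: bool = True,
    drop_low_coverage_samples: bool = True,
) -> CoverageMatrix:
    """Drop ROIs whose median count across samples falls below
    ``min_coverage`` and mark no-call any sample whose median count across
    ROIs does the same.

    Both filters are individually toggleable.  Sample medians are measured
    over the full (pre-drop) target.
    """
    dropped = dict(matrix.dropped_rois)
    nocall = dict(matrix.nocall_samples)
    if drop_low_coverage_rois:
        roi_medians = np.median(matrix.counts, axis=0)
        for j, roi in enumerate(matrix.rois):
            if roi_medians[j] < params.min_coverage and roi.key not in dropped:
                dropped[roi.key] = (
                    f"median coverage {roi_medians[j]:.1f} < {params.min_coverage:g}"
                )
    if drop_low_coverage_samples:
        sample_medians = np.median(matrix.counts, axis=1)
        for i, s in enumerate(matrix.samples):
            if sample_medians[i] < params.min_coverage and s.name not in nocall:
                nocall[s.name] = (
                    f"median coverage {sample_medians[i]:.1f} < {params.min_coverage:g}"
                )
    if len(dropped) == len(matrix.rois):
        raise ValueError(
            f"every ROI fell below min_coverage {params.min_coverage:g}; unusable batch"
        )
    return replace(matrix, dropped_rois=dropped, nocall_samples=nocall)


def _correlations(matrix: CoverageMatrix, test_idx: int, cand_idx: Sequence[int], roi_idx: np.ndarray) -> np.ndarray:
    """Pearson correlation of raw count profiles over the active ROIs."""
    test = matrix.counts[test_idx, roi_idx].astype(float)
    out = np.empty(len(cand_idx))
    for k, j in enumerate(cand_idx):
        cand = matrix.counts[j, roi_idx].astype(float)
        if test.std() == 0 or cand.std() == 0:
            out[k] = 0.0
        else:
            out[k] = float(np.corrcoef(test, cand)[0, 1])
    return out


def select_reference(
    test: str,
    matrix: CoverageMatrix,
    params: CallerParams,
    batch_samples: Sequence[str],
    roi_idx: Optional[np.ndarray] = None,
    apply_correlation_filter: bool = True,
) -> Optional[list[str]]:
    """Pick the reference set for one test sample, or None for no-call.

    Candidates are the batch minus the test sample and its relatives.
    Those with Pearson correlation >= ``min_correlation`` are kept, sorted
    by descending correlation, and truncated to 10 (reference sets beyond
    5-10 samples do not help).  Returns None when nothing passes: the test
    sample is uncallable in this batch.
    """
    if test not in batch_samples:
        raise ValueError(f"test sample {test!r} not in batch")
    if roi_idx is None:
        roi_idx = matrix.active_roi_indices()
    test_idx = matrix.sample_index(test)
    test_family = matrix.samples[test_idx].family
    cand_names = [
        n
        for n in batch_samples
        if n != test
        and n not in matrix.nocall_samples
        and not (
            test_family is not None
            and matrix.samples[matrix.sample_index(n)].family == test_family
        )
    ]
    if not cand_names:
        return None
    cand_idx = [matrix.sample_index(n) for n in cand_names]
    corr = _correlations(matrix, test_idx, cand_idx, roi_idx)
    if apply_correlation_filter:
        keep = [(c, n) for c, n in zip(corr, cand_names) if c >= params.min_correlation]
    else:
        keep = list(zip(corr, cand_names))
    if not keep:
        return None
    keep.sort(key=lambda t: (-t[0], t[1]))
    return [n for _, n in keep[:MAX_REFERENCE_SIZE]]


def compute_ratios(
    test: str,
    reference: Sequence[str],
    matrix: CoverageMatrix,
    roi_idx: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI reads ratios for one test sample against its reference.

    ratio[r] = (count[test, r] / T_test) / median_j(count[j, r] / T_j),
    with T_s the sample's total count over the active ROIs.  Returns
    (ratios, valid) aligned to ``roi_idx``; ``valid`` is False where the
    reference median is zero (the unit becomes a no-call, ratio NaN).
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    if roi_idx is None:
        roi_idx = matrix.active_roi_indices()
    test_idx = matrix.sample_index(test)
    ref_idx = [matrix.sample_index(n) for n in reference]
    test_counts = matrix.counts[test_idx, roi_idx].astype(float)
    t_test = test_counts.sum()
    if t_test <= 0:
        raise ValueError(f"sample {test} has zero total coverage over active ROIs")
    ref_counts = matrix.counts[np.ix_(ref_idx, roi_idx)].astype(float)
    ref_totals = ref_counts.sum(axis=1, keepdims=True)
    if (ref_totals <= 0).any():
        raise ValueError("a reference sample has zero total coverage")
    ref_norm = ref_counts / ref_totals
    ref_median = np.median(ref_norm, axis=0)
    valid = ref_median > 0
    ratios = np.full(len(roi_idx), np.nan)
    ratios[valid] = (test_counts[valid] / t_test) / ref_median[valid]
    return ratios, valid


def estimate_emission_sd(
    reference: Sequence[str],
    matrix: CoverageMatrix,
    roi_idx: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-ROI emission SD: the spread of the reference samples' own
    normalised ratios at that ROI, floored at 0.05.

    Each reference sample's ratio is its normalised count over the
    leave-nothing-out reference median, so a noisy ROI shows a wide spread
    and is trusted less during segmentation.
    """
    if roi_idx is None:
        roi_idx = matrix.active_roi_indices()
    ref_idx = [matrix.sample_index(n) for n in reference]
    ref_counts = matrix.counts[np.ix_(ref_idx, roi_idx)].astype(float)
    ref_totals = ref_counts.sum(axis=1, keepdims=True)
    ref_norm = ref_counts / ref_totals
    ref_median = np.median(ref_norm, axis=0)
    # invalid (zero-median) ROIs become no-calls upstream; a placeholder
    # ratio of 1.0 keeps the std computation warning-free
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_ratios = np.where(ref_median > 0, ref_norm / ref_median, 1.0)
    if len(ref_idx) > 1:
        sd = np.std(ref_ratios, axis=0, ddof=1)
    else:
        sd = np.zeros(len(roi_idx))
    sd = np.where(np.isfinite(sd), sd, 0.0)
    return np.maximum(sd, SD_FLOOR)


_STATE_ORDER = (State.DEL, State.NORMAL, State.DUP)
_STATE_MEANS = np.array([0.5, 1.0, 1.5])


def _log_transitions(t: float, q: float = DWELL_EXIT_PROB, eps: float = CROSS_STATE_PROB) -> np.ndarray:
    trans = np.array(
        [
            [1.0 - q - eps, q, eps],  # DEL -> (DEL, NORMAL, DUP)
            [t, 1.0 - 2.0 * t, t],  # NORMAL
            [eps, q, 1.0 - q - eps],  # DUP
        ]
    )
    return np.log(trans)


def viterbi_segment(
    ratios: np.ndarray,
    params: CallerParams,
    sd: np.ndarray,
) -> list[State]:
    """Most-likely DEL/NORMAL/DUP path for one chromosome's ratio track.

    Three-state HMM with Gaussian emissions around ratio means 0.5 / 1.0 /
    1.5 (per-ROI SD), initial distribution (t, 1-2t, t), and transitions
    parameterised by ``transition_prob`` t for entering an event state;
    event states exit back to normal with probability 1/3 (expected dwell
    3 ROIs) and hop directly between DEL and DUP with probability 1e-6.
    """
    ratios = np.asarray(ratios, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if ratios.size == 0:
        return []
    if not np.isfinite(ratios).all():
        raise ValueError("ratios must be finite for segmentation")
    if (sd <= 0).any():
        raise ValueError("emission SDs must be positive")
    t = params.transition_prob
    log_init = np.log(np.array([t, 1.0 - 2.0 * t, t]))
    log_trans = _log_transitions(t)
    # log N(ratio | mean_k, sd_r), vectorised over ROIs x states
    diffs = ratios[:, None] - _STATE_MEANS[None, :]
    log_emit = -0.5 * (diffs / sd[:, None]) ** 2 - np.log(sd)[:, None] - 0.5 * math.log(2 * math.pi)

    n = len(ratios)
    back = np.zeros((n, 3), dtype=np.int8)
    score = log_init + log_emit[0]
    lt = log_trans
    for i in range(1, n):
        cand = score[:, None] + lt  # (from, to)
        best_from = np.argmax(cand, axis=0)
        back[i] = best_from
        score = cand[best_from, np.arange(3)] + log_emit[i]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return [_STATE_ORDER[k] for k in path]


def map_ratio_to_cn(reads_ratio: float) -> int:
    """Map a reads ratio to an integer copy number via fixed bands:
    <=0.1 -> 0; (0.1, 0.8] -> 1; (0.8, 1.2] -> 2; (1.2, 1.8] -> 3;
    (1.8, 2.2] -> 4; above 2.2 -> ratio x 2 rounded half-up."""
    if reads_ratio < 0 or not math.isfinite(reads_ratio):
        raise ValueError(f"reads ratio must be a finite nonnegative real: {reads_ratio}")
    if reads_ratio <= 0.1:
        return 0
    if reads_ratio <= 0.8:
        return 1
    if reads_ratio <= 1.2:
        return 2
    if reads_ratio <= 1.8:
        return 3
    if reads_ratio <= 2.2:
        return 4
    return int(math.floor(reads_ratio * 2.0 + 0.5))


def merge_calls(
    states: Sequence[State],
    rois: Sequence[ROI],
    ratios: Sequence[float],
    sample: str,
    unreliable: bool = False,
) -> list[CNVCall]:
    """Collapse maximal runs of consecutive same-state non-NORMAL ROIs into
    CNV calls spanning the first ROI's start to the last ROI's end, with
    reads ratio the mean over the run."""
    if not (len(states) == len(rois) == len(ratios)):
        raise ValueError("states, rois and ratios must be aligned")
    calls: list[CNVCall] = []
    i = 0
    n = len(states)
    while i < n:
        st = states[i]
        if st == State.NORMAL:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and states[j + 1] == st
            and rois[j + 1].chrom == rois[i].chrom
        ):
            j += 1
        run_ratio = float(np.mean(np.asarray(ratios[i : j + 1], dtype=float)))
        calls.append(
            CNVCall(
                interval=GenomicInterval(
                    rois[i].chrom, rois[i].interval.start, rois[j].interval.end
                ),
                type=CNVType.DEL if st == State.DEL else CNVType.DUP,
                sample=sample,
                reads_ratio=run_ratio,
                copy_number=map_ratio_to_cn(run_ratio),
                unreliable=unreliable,
            )
        )
        i = j + 1
    return calls


def call_cohort(
    matrix: CoverageMatrix,
    params: CallerParams = CallerParams(),
    mode: str = "default",
    drop_low_coverage_rois: bool = True,
    drop_low_coverage_samples: bool = True,
    apply_correlation_filter: bool = True,
) -> CallSet:
    """Run the full caller over a cohort: batching, QC, reference
    selection, ratio computation, HMM segmentation and call merging.

    The returned CallSet's ``nocall_units`` covers dropped ROIs, low-
    coverage samples, correlation-filtered samples and zero-reference
    ROIs.  A failure inside one batch aborts that batch only.
    """
    matrix = infer_sex(matrix)
    plan = plan_batches(matrix.samples, matrix.rois, mode)
    try:
        matrix = apply_qc_filters(
            matrix,
            params,
            drop_low_coverage_rois=drop_low_coverage_rois,
            drop_low_coverage_samples=drop_low_coverage_samples,
        )
    except ValueError:
        # every ROI dropped: the whole cohort is a no-call, not a crash
        all_units = {(s.name, r.key) for s in matrix.samples for r in matrix.rois}
        return CallSet(caller_name="panelcnv", calls=[], nocall_units=all_units)

    calls: list[CNVCall] = []
    nocall_units: set[tuple[str, str]] = set()
    for s in matrix.samples:
        for key in matrix.dropped_rois:
            nocall_units.add((s.name, key))
    active_keys = [r.key for r in matrix.rois if r.key not in matrix.dropped_rois]
    for name in matrix.nocall_samples:
        for key in active_keys:
            nocall_units.add((name, key))

    sex_by_name = {s.name: s.sex for s in matrix.samples}
    roi_by_index = {i: r for i, r in enumerate(matrix.rois)}
    active = matrix.active_roi_indices()

    for batch in plan.batches:
        batch_roi_idx = np.array(
            [i for i in active if roi_by_index[i].chrom in batch.chroms], dtype=np.intp
        )
        if batch_roi_idx.size == 0:
            continue
        batch_keys = [matrix.rois[i].key for i in batch_roi_idx]
        callable_samples = [
            n for n in batch.sample_names if n not in matrix.nocall_samples
        ]
        for test in callable_samples:
            try:
                reference = select_reference(
                    test,
                    matrix,
                    params,
                    callable_samples,
                    roi_idx=batch_roi_idx,
                    apply_correlation_filter=apply_correlation_filter,
                )
            except ValueError:
                reference = None
            if reference is None:
                nocall_units.update((test, k) for k in batch_keys)
                continue
            try:
                ratios, valid = compute_ratios(test, reference, matrix, roi_idx=batch_roi_idx)
            except ValueError:
                nocall_units.update((test, k) for k in batch_keys)
                continue
            sd = estimate_emission_sd(reference, matrix, roi_idx=batch_roi_idx)
            nocall_units.update(
                (test, matrix.rois[i].key)
                for i, ok in zip(batch_roi_idx, valid)
                if not ok
            )
            # segment each chromosome independently over its valid ROIs
            for chrom in batch.chroms:
                sel = [
                    k
                    for k, i in enumerate(batch_roi_idx)
                    if roi_by_index[i].chrom == chrom and valid[k]
                ]
                if not sel:
                    continue
                chrom_ratios = ratios[sel]
                chrom_sd = sd[sel]
                chrom_rois = [roi_by_index[batch_roi_idx[k]] for k in sel]
                states = viterbi_segment(chrom_ratios, params, chrom_sd)
                unreliable = batch.sex_calls_unreliable and is_sex_chromosome(chrom)
                calls.extend(
                    merge_calls(states, chrom_rois, chrom_ratios, test, unreliable=unreliable)
                )
    _ = sex_by_name  # sexes resolved above; retained for future CN polarity rules
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.sample, c.type.value))
    return CallSet(caller_name="panelcnv", calls=calls, nocall_units=nocall_units)
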