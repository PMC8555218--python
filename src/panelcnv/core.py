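"""Domain types and interval arithmetic shared by every pipeline stage.

Coordinates are 0-based half-open throughout, matching the BED standard:
an interval ``start=100, end=200`` covers bases 100..199 and has length 100.
Chromosome names are taken verbatim from input files; no "chr"-prefix
harmonisation is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Sex",
    "CNVType",
    "State",
    "GenomicInterval",
    "ROI",
    "Sample",
    "CNVCall",
    "CallSet",
    "StateMatrix",
    "overlap_length",
    "mean_roi_size",
    "expected_ploidy",
    "is_sex_chromosome",
    "merge_intervals",
    "sort_rois",
]


class Sex(str, Enum):
    """Sample sex code; UNKNOWN must be resolved by inference before the
    caller touches sex chromosomes."""

    F = "F"
    M = "M"
    UNKNOWN = "U"


class CNVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"


class State(str, Enum):
    """Per-(sample, region) copy-number state used in benchmarking."""

    DEL = "DEL"
    NORMAL = "NORMAL"
    DUP = "DUP"
    NOCALL = "NOCALL"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


@dataclass(frozen=True)
class ROI:
    """One capture target region (typically an exon), the atomic unit of
    calling and evaluation.  ``index`` is the ordinal of the ROI within its
    chromosome after sorting by start."""

    interval: GenomicInterval
    name: str
    index: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def key(self) -> str:
        return self.interval.key


@dataclass(frozen=True)
class Sample:
    """A cohort member.  ``family`` groups related individuals that must be
    kept out of each other's reference sets."""

    name: str
    sex: Sex = Sex.UNKNOWN
    family: Optional[str] = None


@dataclass(frozen=True)
class CNVCall:
    """One deletion or duplication event in one sample.

    ``reads_ratio`` and ``copy_number`` are populated for final calls made by
    the internal depth caller; calls imported from external call sets carry
    only span, type and sample.  ``unreliable`` flags sex-chromosome calls
    made in a mixed-sex single batch.
    """

    interval: GenomicInterval
    type: CNVType
    sample: str
    reads_ratio: Optional[float] = None
    copy_number: Optional[int] = None
    unreliable: bool = False

    def with_span(self, start: int, end: int) -> "CNVCall":
        return replace(self, interval=GenomicInterval(self.interval.chrom, start, end))


@dataclass
class CallSet:
    """A named collection of CNV calls plus the (sample, ROI) units the
    caller abstained on."""

    caller_name: str
    calls: list[CNVCall] = field(default_factory=list)
    nocall_units: set[tuple[str, str]] = field(default_factory=set)  # (sample, roi key)

    def __len__(self) -> int:
        return len(self.calls)

    def is_empty(self) -> bool:
        return len(self.calls) == 0

    def calls_for(self, sample: str) -> list[CNVCall]:
        return [c for c in self.calls if c.sample == sample]

    def validate(self) -> None:
        """Reject same-sample, same-type overlapping calls."""
        by_key: dict[tuple[str, CNVType, str], list[CNVCall]] = {}
        for c in self.calls:
            by_key.setdefault((c.sample, c.type, c.interval.chrom), []).append(c)
        for (sample, cnv_type, _), group in by_key.items():
            group = sorted(group, key=lambda c: c.interval.start)
            for a, b in zip(group, group[1:]):
                if a.interval.overlaps(b.interval):
                    raise ValueError(
                        f"overlapping {cnv_type.value} calls for sample {sample}: "
                        f"{a.interval} and {b.interval}"
                    )


class StateMatrix:
    """Copy-number states on a fixed universe of (sample, region-key) units.

    The universe is explicit: confusion counting requires two matrices to
    agree on exactly the same units.
    """

    def __init__(
        self,
        samples: Sequence[str],
        region_keys: Sequence[str],
        states: Optional[Mapping[tuple[str, str], State]] = None,
        default: State = State.NORMAL,
    ) -> None:
        self.samples = list(samples)
        self.region_keys = list(region_keys)
        self._units = {(s, r) for s in self.samples for r in self.region_keys}
        self._states: dict[tuple[str, str], State] = {
            u: default for u in sorted(self._units)
        }
        if states:
            for unit, state in states.items():
                self[unit] = state

    @property
    def units(self) -> set[tuple[str, str]]:
        return set(self._units)

    def __getitem__(self, unit: tuple[str, str]) -> State:
        return self._states[unit]

    def __setitem__(self, unit: tuple[str, str], state: State) -> None:
        if unit not in self._units:
            raise KeyError(f"unit {unit} outside the state-matrix universe")
        self._states[unit] = State(state)

    def items(self) -> Iterable[tuple[tuple[str, str], State]]:
        return self._states.items()

    def drop_units(self, units: Iterable[tuple[str, str]]) -> None:
        for u in set(units):
            self._units.discard(u)
            self._states.pop(u, None)

    def __len__(self) -> int:
        return len(self._units)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two half-open intervals (0 when the
    chromosomes differ or the spans are disjoint/adjacent)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def mean_roi_size(rois: Sequence[ROI]) -> float:
    """Arithmetic mean target length; the default minimum size a consensus
    call must reach to enter the validation set."""
    if not rois:
        raise ValueError("target file contains no ROIs; cannot compute mean size")
    return sum(r.interval.length() for r in rois) / len(rois)


def is_sex_chromosome(chrom: str) -> bool:
    c = chrom.lower().removeprefix("chr")
    return c in ("x", "y")


def expected_ploidy(chrom: str, sex: Sex) -> int:
    """Expected copy number of a chromosome given sample sex.

    Autosomes are diploid; chrX is 2/1 and chrY 0/1 in females/males.
    """
    c = chrom.lower().removeprefix("chr")
    if c == "x":
        if sex == Sex.UNKNOWN:
            raise ValueError("sex must be inferred before calling on chrX")
        return 2 if sex == Sex.F else 1
    if c == "y":
        if sex == Sex.UNKNOWN:
            raise ValueError("sex must be inferred before calling on chrY")
        return 0 if sex == Sex.F else 1
    return 2


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping (not merely adjacent) spans on the
    same chromosome are merged; output sorted by (chrom, start)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def sort_rois(intervals_and_names: Sequence[tuple[GenomicInterval, str]]) -> list[ROI]:
    """Sort target intervals by (chrom, start), assign per-chromosome ordinal
    indices, and merge overlapping targets with a warning.

    Overlapping capture targets would make per-ROI states ambiguous, so the
    union replaces them (the merged ROI keeps the first contributor's name).
    """
    ordered = sorted(intervals_and_names, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    collapsed: list[tuple[GenomicInterval, str]] = []
    n_merged = 0
    for iv, name in ordered:
        if collapsed and collapsed[-1][0].chrom == iv.chrom and iv.start < collapsed[-1][0].end:
            prev_iv, prev_name = collapsed[-1]
            collapsed[-1] = (
                GenomicInterval(iv.chrom, prev_iv.start, max(prev_iv.end, iv.end)),
                prev_name,
            )
            n_merged += 1
        else:
            collapsed.append((iv, name))
    if n_merged:
        warnings.warn(
            f"merged {n_merged} overlapping target region(s); per-ROI states must be unambiguous",
            stacklevel=2,
        )
    rois: list[ROI] = []
    counter: dict[str, int] = {}
    for iv, name in collapsed:
        idx = counter.get(iv.chrom, 0)
        counter[iv.chrom] = idx + 1
        rois.append(ROI(interval=iv, name=name, index=idx))
    return rois
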