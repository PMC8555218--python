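"""Readers and writers for every on-disk artifact, plus adapters that
normalise external caller output (log2 ratios, integer copy numbers) to the
common DEL/NORMAL/DUP vocabulary.

Formats
-------
- Target BED: >=3 tab-separated columns, 0-based half-open, no header;
  column 4 (when present) names the ROI.
- Call BED (external or internal): 5 columns — chrom, start, end, DEL|DUP,
  sample.
- Final call BED: 7 columns — the 5 above plus reads ratio (3 decimals) and
  integer copy number.
- Coverage matrix TSV: header row ``roi<TAB>sample1<TAB>...``; one row per
  ROI keyed "chrom:start-end" (ROI name accepted as fallback).
- Sample sheet TSV: header ``sample<TAB>sex<TAB>family``; sex tokens F/M/U;
  empty family means unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import math

import numpy as np
import pandas as pd

from .core import (
    CallSet,
    CNVCall,
    CNVType,
    GenomicInterval,
    ROI,
    Sample,
    Sex,
    State,
    expected_ploidy,
    sort_rois,
)

PathLike = Union[str, Path]

__all__ = [
    "AdapterConfig",
    "read_target_bed",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_callset_bed",
    "write_callset_bed",
    "write_final_bed",
    "read_final_bed",
    "read_coverage_matrix",
    "write_coverage_matrix",
    "cn_to_type",
    "log2_to_cn",
]


@dataclass(frozen=True)
class AdapterConfig:
    """Thresholds for converting external log2 depth ratios to integer copy
    numbers.

    Deletion bands: log2 <= del_log2_cn0 maps to CN0 and
    del_log2_cn0 < log2 <= del_log2_cn1 to CN1 (stricter than the common
    -1.1 single cut, so only deep losses become CN0).  The duplication
    threshold is the lower log2 bound for calling CN >= 3; +0.32 is just
    below log2(3/2).
    """

    del_log2_cn0: float = -2.0
    del_log2_cn1: float = -0.4
    dup_log2_min: float = 0.32

    def __post_init__(self) -> None:
        if not (self.del_log2_cn0 < self.del_log2_cn1 < 0 < self.dup_log2_min):
            raise ValueError(
                "adapter thresholds must satisfy del_cn0 < del_cn1 < 0 < dup_min"
            )


def _parse_error(path: PathLike, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_target_bed(path: PathLike) -> list[ROI]:
    """Load capture targets from a BED file into sorted, indexed ROIs.

    The 4th column is used as the ROI name when present, otherwise
    "chrom:start-end".  Overlapping targets are merged (with a warning) by
    :func:`panelcnv.core.sort_rois`.
    """
    entries: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise _parse_error(path, lineno, f"non-integer coordinates: {exc}") from None
            if end <= start:
                raise _parse_error(path, lineno, f"end ({end}) must exceed start ({start})")
            name = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            entries.append((GenomicInterval(chrom, start, end), name))
    if not entries:
        raise ValueError(f"{path}: target BED contains no usable regions")
    return sort_rois(entries)


def read_sample_sheet(path: PathLike) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns 'sample' and 'sex'")
    samples: list[Sample] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = row["sample"].strip()
        if not name:
            raise ValueError(f"{path}: empty sample name on data row {i + 1}")
        if name in seen:
            raise ValueError(f"{path}: duplicate sample name {name!r}")
        seen.add(name)
        token = row["sex"].strip().upper()
        try:
            sex = Sex(token) if token else Sex.UNKNOWN
        except ValueError:
            raise ValueError(f"{path}: unknown sex token {token!r} for sample {name}") from None
        family = row.get("family", "") if "family" in df.columns else ""
        family = family.strip() or None
        samples.append(Sample(name=name, sex=sex, family=family))
    return samples


def write_sample_sheet(samples: Sequence[Sample], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsex\tfamily\n")
        for s in samples:
            fh.write(f"{s.name}\t{s.sex.value}\t{s.family or ''}\n")


def read_callset_bed(path: PathLike, caller_name: str) -> CallSet:
    """Load a normalised 5-column call BED (chrom, start, end, DEL|DUP,
    sample) produced by any external caller.

    An empty file is a valid CallSet with zero calls; downstream consensus
    discards it and falls back to the remaining callers.
    """
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise _parse_error(path, lineno, f"expected 5 tab-separated columns, got {len(fields)}")
            chrom, start_s, end_s, type_s, sample = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise _parse_error(path, lineno, f"non-integer coordinates: {exc}") from None
            try:
                cnv_type = CNVType(type_s)
            except ValueError:
                raise _parse_error(
                    path, lineno, f"unknown CNV type token {type_s!r} (expected DEL or DUP)"
                ) from None
            calls.append(
                CNVCall(interval=GenomicInterval(chrom, start, end), type=cnv_type, sample=sample)
            )
    return CallSet(caller_name=caller_name, calls=calls)


def write_callset_bed(callset: CallSet, path: PathLike) -> None:
    """Write the 5-column normalised call BED, sorted by (chrom, start, sample)."""
    ordered = sorted(callset.calls, key=lambda c: (c.interval.chrom, c.interval.start, c.sample))
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.type.value}\t{c.sample}\n"
            )


def write_final_bed(callset: CallSet, path: PathLike) -> None:
    """Write final, fully annotated calls: 7 columns adding reads ratio
    (printed with 3 decimals) and integer copy number."""
    for c in callset.calls:
        if c.reads_ratio is None or c.copy_number is None:
            raise ValueError(
                f"final call {c.interval} ({c.sample}) lacks reads_ratio/copy_number; "
                "final calls must be fully annotated"
            )
    ordered = sorted(callset.calls, key=lambda c: (c.interval.chrom, c.interval.start, c.sample))
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.type.value}\t"
                f"{c.sample}\t{c.reads_ratio:.3f}\t{c.copy_number}\n"
            )


def read_final_bed(path: PathLike, caller_name: str = "final") -> CallSet:
    calls: list[CNVCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise _parse_error(path, lineno, f"expected 7 columns, got {len(fields)}")
            chrom, start_s, end_s, type_s, sample, ratio_s, cn_s = fields[:7]
            calls.append(
                CNVCall(
                    interval=GenomicInterval(chrom, int(start_s), int(end_s)),
                    type=CNVType(type_s),
                    sample=sample,
                    reads_ratio=float(ratio_s),
                    copy_number=int(cn_s),
                )
            )
    return CallSet(caller_name=caller_name, calls=calls)


def read_coverage_matrix(path: PathLike, rois: Sequence[ROI], samples: Sequence[Sample]):
    """Load the per-ROI x per-sample read-count TSV and align it to the
    target/sample order.

    Rows are keyed by "chrom:start-end" (primary) or ROI name (fallback);
    every (ROI, sample) cell must be present and a nonnegative integer.
    Returns a :class:`panelcnv.caller.CoverageMatrix`.
    """
    from .caller import CoverageMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_names = [s.name for s in samples]
    missing_cols = [n for n in sample_names if n not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: coverage matrix lacks columns for samples {missing_cols}")
    by_key = {r.key: r for r in rois}
    by_name = {r.name: r for r in rois}
    row_for_roi: dict[str, str] = {}
    for row_key in df.index.astype(str):
        roi = by_key.get(row_key) or by_name.get(row_key)
        if roi is None:
            raise ValueError(f"{path}: row {row_key!r} does not match any target ROI")
        if roi.key in row_for_roi:
            raise ValueError(f"{path}: duplicate row for ROI {roi.key}")
        row_for_roi[roi.key] = row_key
    absent = [r.key for r in rois if r.key not in row_for_roi]
    if absent:
        raise ValueError(f"{path}: coverage matrix missing rows for ROIs {absent[:5]}")
    ordered = df.loc[[row_for_roi[r.key] for r in rois], sample_names]
    values = ordered.to_numpy()
    if np.isnan(values.astype(float)).any():
        raise ValueError(f"{path}: coverage matrix has missing cells")
    counts = values.astype(float)
    if (counts < 0).any():
        raise ValueError(f"{path}: negative read counts are not allowed")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError(f"{path}: read counts must be integers")
    # counts transposed to (sample, ROI) orientation
    return CoverageMatrix(counts=counts.T.astype(np.int64), samples=list(samples), rois=list(rois))


def write_coverage_matrix(matrix, path: PathLike) -> None:
    df = pd.DataFrame(
        matrix.counts.T,
        index=pd.Index([r.key for r in matrix.rois], name="roi"),
        columns=[s.name for s in matrix.samples],
    )
    df.to_csv(path, sep="\t")


def cn_to_type(cn: int, chrom: str, sex: Sex) -> State:
    """Convert an integer copy number to DEL/NORMAL/DUP relative to the
    expected ploidy of (chromosome, sex)."""
    if cn < 0:
        raise ValueError("copy number must be nonnegative")
    ploidy = expected_ploidy(chrom, sex)
    if ploidy == 0:
        raise ValueError(f"no expected copies of {chrom} for sex {sex.value}; cannot classify CN")
    if cn < ploidy:
        return State.DEL
    if cn > ploidy:
        return State.DUP
    return State.NORMAL


def log2_to_cn(log2_ratio: float, cfg: AdapterConfig = AdapterConfig(), ploidy: int = 2) -> int:
    """Convert an external caller's log2 depth ratio to an integer copy
    number using the banded thresholds in ``cfg``.

    For haploid regions (ploidy 1, e.g. male chrX against a male reference)
    the ratio is shifted down one doubling before banding: a copy-n haploid
    segment has log2(n), which lands on the diploid scale at log2(n/2), so
    the diploid band value equals the haploid copy number directly
    (log2 = 0 -> CN1, log2 = 1 -> CN2, deep loss -> CN0).
    """
    if not math.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    if ploidy not in (1, 2):
        raise ValueError("adapter supports ploidy 1 or 2 only")
    shifted = log2_ratio if ploidy == 2 else log2_ratio - 1.0
    if shifted <= cfg.del_log2_cn0:
        return 0
    if shifted <= cfg.del_log2_cn1:
        return 1
    if shifted < cfg.dup_log2_min:
        return 2
    # inside the duplication band the copy number is at least 3 even when
    # rounding 2 * 2**log2 would land on 2 (possible right at the bound)
    return max(3, int(math.floor(2.0 * 2.0 ** shifted + 0.5)))
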