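"""In silico validation set from the concordance of independent callers.

A CNV enters the validation set when every retained caller reports an
overlapping event of the same type in the same sample, the mutual
intersection covers at least 60% of at least one contributing call, and
the intersection is no shorter than the mean target-ROI size.  Callers
that report nothing anywhere are discarded (two concordant callers
suffice); fewer than two usable callers is an error.

The validated regions (union footprint of validated calls) then get a
per-sample state: the sample's validated call type where one exists,
NORMAL otherwise.  That sample x region state table is the truth the
parameter optimiser scores against.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    CallSet,
    CNVCall,
    CNVType,
    GenomicInterval,
    ROI,
    Sample,
    State,
    StateMatrix,
    mean_roi_size,
    merge_intervals,
    overlap_length,
)

__all__ = ["ValidationSet", "build_validation_calls", "attach_normal_states"]

DEFAULT_OVERLAP_FRACTION = 0.60


@dataclass
class ValidationSet:
    """In silico validated CNVs plus per-sample normal-state assignments
    over the validated regions."""

    validated_calls: list[CNVCall]
    validated_regions: list[GenomicInterval]
    states: StateMatrix  # samples x validated-region keys
    min_size_used: float
    overlap_fraction_used: float = DEFAULT_OVERLAP_FRACTION

    def is_empty(self) -> bool:
        return not self.validated_calls


def _clip_to_roi_footprint(
    iv: GenomicInterval, footprint: Sequence[GenomicInterval]
) -> Optional[GenomicInterval]:
    """Clip an interval to the union of target regions; None if disjoint."""
    pieces = [
        GenomicInterval(iv.chrom, max(iv.start, f.start), min(iv.end, f.end))
        for f in footprint
        if f.chrom == iv.chrom and overlap_length(iv, f) > 0
    ]
    if not pieces:
        return None
    return GenomicInterval(iv.chrom, min(p.start for p in pieces), max(p.end for p in pieces))


def build_validation_calls(
    callsets: Sequence[CallSet],
    rois: Sequence[ROI],
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    min_size: Optional[float] = None,
) -> list[CNVCall]:
    """Intersect >=2 normalised call sets into in silico validated CNVs.

    Within each (sample, type, chromosome) stratum, calls from all retained
    callsets are grouped into connected overlap components.  A component
    yields a validated call when every callset contributes at least one
    call; the validated span is the mutual intersection, choosing per
    callset the fragment that maximises it (tie -> leftmost).  The
    intersection must reach ``overlap_fraction`` of at least one
    contributing call and ``min_size`` (default: mean ROI length).
    """
    retained = [cs for cs in callsets if not cs.is_empty()]
    discarded = [cs.caller_name for cs in callsets if cs.is_empty()]
    if discarded:
        warnings.warn(
            f"caller(s) {discarded} reported no CNV in any sample; "
            f"consensus falls back to the remaining {len(retained)}",
            stacklevel=2,
        )
    if len(retained) < 2:
        raise ValueError(
            f"consensus needs at least 2 non-empty call sets, got {len(retained)}"
        )
    if min_size is None:
        min_size = mean_roi_size(rois)
    footprint = merge_intervals(r.interval for r in rois)

    # stable, order-independent caller ordering
    retained = sorted(retained, key=lambda cs: cs.caller_name)
    strata: dict[tuple[str, CNVType, str], dict[str, list[CNVCall]]] = {}
    for cs in retained:
        for call in cs.calls:
            key = (call.sample, call.type, call.interval.chrom)
            strata.setdefault(key, {}).setdefault(cs.caller_name, []).append(call)

    validated: list[CNVCall] = []
    for (sample, cnv_type, chrom) in sorted(
        strata, key=lambda k: (k[2], k[0], k[1].value)
    ):
        per_caller = strata[(sample, cnv_type, chrom)]
        if len(per_caller) < len(retained):
            continue  # some caller saw nothing here at all
        # connected overlap components over the union of all calls
        all_calls = sorted(
            (c for calls in per_caller.values() for c in calls),
            key=lambda c: (c.interval.start, c.interval.end),
        )
        components: list[list[CNVCall]] = []
        comp_end = -1
        for c in all_calls:
            if components and c.interval.start < comp_end:
                components[-1].append(c)
                comp_end = max(comp_end, c.interval.end)
            else:
                components.append([c])
                comp_end = c.interval.end
        for comp in components:
            by_caller: dict[str, list[CNVCall]] = {}
            for cs in retained:
                members = [c for c in comp if c in per_caller.get(cs.caller_name, [])]
                if members:
                    by_caller[cs.caller_name] = members
            if len(by_caller) < len(retained):
                continue
            best: Optional[tuple[int, int, tuple[CNVCall, ...]]] = None
            for combo in itertools.product(*(by_caller[cs.caller_name] for cs in retained)):
                start = max(c.interval.start for c in combo)
                end = min(c.interval.end for c in combo)
                inter_len = end - start
                if inter_len <= 0:
                    continue
                cand = (inter_len, -start, combo)
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
            if best is None:
                continue
            inter_len, neg_start, combo = best
            start = -neg_start
            end = start + inter_len
            frac_ok = any(
                inter_len >= overlap_fraction * c.interval.length() for c in combo
            )
            if not frac_ok or inter_len < min_size:
                continue
            clipped = _clip_to_roi_footprint(GenomicInterval(chrom, start, end), footprint)
            if clipped is None:
                continue
            validated.append(CNVCall(interval=clipped, type=cnv_type, sample=sample))
    validated.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.sample, c.type.value))
    return validated


def attach_normal_states(
    validated: Sequence[CNVCall],
    samples: Sequence[Sample],
    rois: Sequence[ROI],
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    min_size_used: Optional[float] = None,
) -> ValidationSet:
    """Assemble the full ValidationSet: merge validated call spans into
    disjoint validated regions and assign every (sample, region) a state —
    the sample's validated call type where one overlaps, else NORMAL."""
    if min_size_used is None:
        min_size_used = mean_roi_size(rois)
    if not validated:
        warnings.warn(
            "zero validated CNVs: the validation set is empty and parameter "
            "optimization is impossible",
            stacklevel=2,
        )
        return ValidationSet(
            validated_calls=[],
            validated_regions=[],
            states=StateMatrix([s.name for s in samples], []),
            min_size_used=min_size_used,
            overlap_fraction_used=overlap_fraction,
        )
    regions = merge_intervals(c.interval for c in validated)
    region_keys = [r.key for r in regions]
    states = StateMatrix([s.name for s in samples], region_keys, default=State.NORMAL)
    for region in regions:
        overlapping = [c for c in validated if overlap_length(c.interval, region) > 0]
        per_sample: dict[str, CNVCall] = {}
        for c in overlapping:
            prev = per_sample.get(c.sample)
            if prev is None or overlap_length(c.interval, region) > overlap_length(
                prev.interval, region
            ):
                per_sample[c.sample] = c
        for sample_name, call in per_sample.items():
            if sample_name in states.samples:
                states[(sample_name, region.key)] = (
                    State.DEL if call.type == CNVType.DEL else State.DUP
                )
    return ValidationSet(
        validated_calls=list(validated),
        validated_regions=regions,
        states=states,
        min_size_used=min_size_used,
        overlap_fraction_used=overlap_fraction,
    )
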