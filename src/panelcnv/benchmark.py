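"""Per-region confusion counting and the five panel-benchmark metrics.

Every (sample, region) unit is scored independently.  A unit is a true
positive when predicted and validated states agree on a non-normal type,
a true negative when both are normal, a false positive when a CNV is
predicted on a validated-normal unit, and a false negative when a
validated CNV is missed — including the wrong-type case (validated DEL,
predicted DUP), which counts as a miss rather than a miss plus a false
alarm (configurable).

No-calls are counted among the negatives by default (``as_normal``): in a
diagnostic setting an abstention still leaves the region unconfirmed, so
a validated CNV under a no-call is a false negative.  The ``excluded``
policy removes no-call units from the universe instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import (
    CallSet,
    CNVType,
    GenomicInterval,
    State,
    StateMatrix,
    overlap_length,
)

__all__ = [
    "ConfusionCounts",
    "MetricsResult",
    "states_from_calls",
    "confusion",
    "metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsResult:
    """Sensitivity, specificity, PPV, NPV and F-score; None where the
    denominator is zero."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f_score: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f_score": self.f_score,
        }


def states_from_calls(
    calls: CallSet,
    samples: Sequence[str],
    regions: Sequence[GenomicInterval],
    nocall_policy: str = "as_normal",
    rois_by_key: Optional[dict[str, GenomicInterval]] = None,
) -> StateMatrix:
    """Project a call set onto a fixed (sample x region) universe.

    A unit gets DEL/DUP when a call of that type and sample overlaps the
    region, NORMAL otherwise.  Units the caller abstained on (its
    ``nocall_units``, keyed by ROI) become NOCALL first, then the policy
    maps them: ``as_normal`` relabels them NORMAL, ``excluded`` removes
    them from the universe.  A sample with both a DEL and a DUP call on
    one unit violates the call-set contract and raises.
    """
    if nocall_policy not in ("as_normal", "excluded"):
        raise ValueError(f"unknown nocall policy {nocall_policy!r}")
    region_keys = [r.key for r in regions]
    sm = StateMatrix(samples, region_keys, default=State.NORMAL)
    by_sample: dict[str, list] = {}
    for c in calls.calls:
        by_sample.setdefault(c.sample, []).append(c)
    for region in regions:
        for sample in samples:
            hits = [
                c
                for c in by_sample.get(sample, [])
                if overlap_length(c.interval, region) > 0
            ]
            types = {c.type for c in hits}
            if CNVType.DEL in types and CNVType.DUP in types:
                # adjacent DEL and DUP runs may both touch a long merged
                # region; that is fine — but calls overlapping EACH OTHER
                # with opposite types violate the call-set contract
                dels = [c for c in hits if c.type == CNVType.DEL]
                dups = [c for c in hits if c.type == CNVType.DUP]
                if any(overlap_length(a.interval, b.interval) > 0
                       for a in dels for b in dups):
                    raise ValueError(
                        f"sample {sample} has overlapping DEL and DUP calls at {region}"
                    )
                del_ov = sum(overlap_length(c.interval, region) for c in dels)
                dup_ov = sum(overlap_length(c.interval, region) for c in dups)
                # the unit takes the dominant type; ties go to the deletion
                sm[(sample, region.key)] = State.DEL if del_ov >= dup_ov else State.DUP
            elif CNVType.DEL in types:
                sm[(sample, region.key)] = State.DEL
            elif CNVType.DUP in types:
                sm[(sample, region.key)] = State.DUP

    # map per-ROI no-call units onto the evaluation regions
    nocall_hits: set[tuple[str, str]] = set()
    if calls.nocall_units:
        roi_ivs = rois_by_key or {}
        for (sample, roi_key) in calls.nocall_units:
            if sample not in sm.samples:
                continue
            iv = roi_ivs.get(roi_key)
            if iv is None:
                try:
                    chrom, span = roi_key.rsplit(":", 1)
                    start_s, end_s = span.split("-")
                    iv = GenomicInterval(chrom, int(start_s), int(end_s))
                except ValueError:
                    continue
            for region in regions:
                if overlap_length(iv, region) > 0:
                    unit = (sample, region.key)
                    # a real call on the region wins over a partial no-call
                    if sm[unit] == State.NORMAL:
                        nocall_hits.add(unit)
    if nocall_policy == "excluded":
        sm.drop_units(nocall_hits)
    else:
        for unit in nocall_hits:
            sm[unit] = State.NORMAL
    return sm


def confusion(
    predicted: StateMatrix,
    truth: StateMatrix,
    wrong_type_double_counts: bool = False,
) -> ConfusionCounts:
    """Tally per-unit agreement between predicted and validated states.

    The two matrices must share an identical universe.  A wrong-type
    overlap (truth DEL, predicted DUP) is one FN by default; with
    ``wrong_type_double_counts`` it is one FN plus one FP.
    """
    if predicted.units != truth.units:
        diff = predicted.units ^ truth.units
        raise ValueError(
            f"state-matrix universes differ on {len(diff)} unit(s), e.g. {sorted(diff)[:3]}"
        )
    tp = tn = fp = fn = 0
    for unit, truth_state in truth.items():
        pred = predicted[unit]
        if pred == State.NOCALL:
            pred = State.NORMAL
        if truth_state == State.NOCALL:
            truth_state = State.NORMAL
        if truth_state == State.NORMAL:
            if pred == State.NORMAL:
                tn += 1
            else:
                fp += 1
        else:
            if pred == truth_state:
                tp += 1
            else:
                fn += 1
                if wrong_type_double_counts and pred != State.NORMAL:
                    fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsResult:
    """The five standard ratios from a confusion quadruple; F-score is the
    harmonic mean of PPV and sensitivity."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty universe")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f = None
    else:
        f = 2.0 * ppv * sens / (ppv + sens)
    return MetricsResult(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f_score=f)
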