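"""Synthetic capture-panel cohorts with known CNV truth.

The generator emulates the depth structure of a targeted/exome capture
experiment at desk scale: a few hundred ROIs across several autosomes plus
chrX/chrY, per-sample library-size factors, per-ROI capture efficiencies,
and negative-binomially overdispersed read counts whose mean scales with
the (sample, ROI) copy number over expected ploidy.  Multi- and single-ROI
DEL/DUP events are embedded per sample at a Poisson rate.

``perturb_calls`` fabricates surrogate external call sets by corrupting
the truth with per-event dropout, boundary jitter and random false calls —
the discordance one sees between real callers — so the consensus logic can
be exercised in isolation from caller quality.

It does not attempt GC/mappability realism, read-level simulation or
mosaicism; see the methods note for what that implies for test coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .caller import CoverageMatrix
from .core import (
    CallSet,
    CNVCall,
    CNVType,
    GenomicInterval,
    ROI,
    Sample,
    Sex,
    expected_ploidy,
    is_sex_chromosome,
)

__all__ = ["SimConfig", "CallerErrorProfile", "simulate_cohort", "perturb_calls"]

_AUTOSOMES = ("chr1", "chr2", "chr3", "chr4")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation settings.

    Defaults describe a mid-sized diagnostic panel run: 40 samples (half
    female), 280 autosomal + 15 chrX + 5 chrY targets of 100-400 bp,
    150x mean depth with ~10% library-size spread, lognormal capture
    efficiency (sdlog 1.2, so target depths span roughly two orders of
    magnitude as real capture does, and the shared efficiency profile
    dominates inter-sample correlation), negative-binomial dispersion 50
    (depth CV ~0.15 at 150x), one embedded event per sample on average with
    geometric length (mean 2 ROIs, so roughly half the events span a
    single ROI), 60% deletions, and two sibling pairs.
    """

    n_samples: int = 40
    sex_ratio: float = 0.5  # fraction female
    n_rois_autosomal: int = 280
    n_rois_x: int = 15
    n_rois_y: int = 5
    roi_length_range: tuple[int, int] = (100, 400)
    mean_depth: float = 150.0
    depth_sample_cv: float = 0.1
    capture_efficiency_sdlog: float = 1.2
    dispersion: float = 50.0
    events_per_sample_rate: float = 1.0
    event_length_geometric_p: float = 0.5
    del_fraction: float = 0.6
    n_families: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if not (0.0 <= self.del_fraction <= 1.0):
            raise ValueError("del_fraction must be in [0, 1]")
        for name in ("mean_depth", "dispersion", "event_length_geometric_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.events_per_sample_rate < 0:
            raise ValueError("events_per_sample_rate must be nonnegative")


@dataclass(frozen=True)
class CallerErrorProfile:
    """Error model for one surrogate external caller: per-event dropout,
    per-(sample, ROI) false-call rate, and boundary jitter in ROI units."""

    fn_rate: float = 0.1
    fp_rate: float = 0.01
    boundary_jitter: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fn_rate <= 1.0 and 0.0 <= self.fp_rate <= 1.0):
            raise ValueError("error rates must be in [0, 1]")
        if self.boundary_jitter < 0:
            raise ValueError("boundary jitter must be nonnegative")


def _layout_rois(cfg: SimConfig, rng: np.random.Generator) -> list[ROI]:
    chrom_counts: list[tuple[str, int]] = []
    per_aut = cfg.n_rois_autosomal // len(_AUTOSOMES)
    extra = cfg.n_rois_autosomal - per_aut * len(_AUTOSOMES)
    for i, chrom in enumerate(_AUTOSOMES):
        chrom_counts.append((chrom, per_aut + (1 if i < extra else 0)))
    if cfg.n_rois_x:
        chrom_counts.append(("chrX", cfg.n_rois_x))
    if cfg.n_rois_y:
        chrom_counts.append(("chrY", cfg.n_rois_y))
    rois: list[ROI] = []
    lo, hi = cfg.roi_length_range
    for chrom, n in chrom_counts:
        pos = 10_000
        for idx in range(n):
            length = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(200, 5_000))
            start = pos + gap
            end = start + length
            rois.append(
                ROI(GenomicInterval(chrom, start, end), name=f"{chrom}_roi{idx:04d}", index=idx)
            )
            pos = end
    return rois


def _make_samples(cfg: SimConfig, rng: np.random.Generator) -> list[Sample]:
    n_f = int(round(cfg.n_samples * cfg.sex_ratio))
    sexes = [Sex.F] * n_f + [Sex.M] * (cfg.n_samples - n_f)
    rng.shuffle(sexes)  # type: ignore[arg-type]
    samples = []
    # families are sibling pairs over the first 2*n_families samples
    for i in range(cfg.n_samples):
        family = f"fam{i // 2}" if i < 2 * cfg.n_families else None
        samples.append(Sample(name=f"S{i + 1:03d}", sex=sexes[i], family=family))
    return samples


def _place_events(
    cfg: SimConfig,
    rois: Sequence[ROI],
    samples: Sequence[Sample],
    rng: np.random.Generator,
) -> tuple[list[CNVCall], np.ndarray]:
    """Embed non-overlapping DEL/DUP events; returns (truth calls, CN matrix)."""
    roi_idx_by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(rois):
        roi_idx_by_chrom.setdefault(r.chrom, []).append(i)
    cn = np.zeros((len(samples), len(rois)), dtype=np.int16)
    for si, s in enumerate(samples):
        for ri, r in enumerate(rois):
            cn[si, ri] = expected_ploidy(r.chrom, s.sex)
    truth: list[CNVCall] = []
    for si, s in enumerate(samples):
        n_events = int(rng.poisson(cfg.events_per_sample_rate))
        occupied: set[int] = set()
        for _ in range(n_events):
            placed = False
            for _attempt in range(100):
                # geometric length with support {1, 2, ...}: mean 1/p, so at
                # p=0.5 roughly half of the events cover a single ROI
                length = int(rng.geometric(cfg.event_length_geometric_p))
                chrom = str(rng.choice(sorted(roi_idx_by_chrom)))
                ploidy = expected_ploidy(chrom, s.sex)
                if ploidy == 0:
                    continue  # no chrY events in females
                chrom_rois = roi_idx_by_chrom[chrom]
                if length > len(chrom_rois):
                    continue
                start_pos = int(rng.integers(0, len(chrom_rois) - length + 1))
                span = chrom_rois[start_pos : start_pos + length]
                if any(i in occupied for i in span):
                    continue
                is_del = rng.random() < cfg.del_fraction
                if is_del:
                    if ploidy == 1:
                        event_cn = 0
                    else:
                        event_cn = 0 if rng.random() < 0.10 else 1
                    cnv_type = CNVType.DEL
                else:
                    event_cn = ploidy + 1
                    cnv_type = CNVType.DUP
                for i in span:
                    cn[si, i] = event_cn
                occupied.update(span)
                truth.append(
                    CNVCall(
                        interval=GenomicInterval(
                            chrom, rois[span[0]].interval.start, rois[span[-1]].interval.end
                        ),
                        type=cnv_type,
                        sample=s.name,
                        copy_number=event_cn,
                        reads_ratio=event_cn / ploidy,
                    )
                )
                placed = True
                break
            if not placed:
                warnings.warn(
                    f"could not place an event for {s.name} after 100 retries; skipped",
                    stacklevel=2,
                )
    truth.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.sample))
    return truth, cn


def simulate_cohort(cfg: SimConfig) -> tuple[list[ROI], CoverageMatrix, CallSet, list[Sample]]:
    """Generate (target ROIs, coverage matrix, truth call set, samples).

    count[s, r] ~ NegBin(mean = mean_depth * d_s * e_r * CN[s, r] / ploidy,
    size = dispersion), with d_s a truncated-normal library factor and e_r
    a lognormal capture efficiency.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rois = _layout_rois(cfg, rng)
    samples = _make_samples(cfg, rng)
    depth_factor = np.maximum(
        rng.normal(1.0, cfg.depth_sample_cv, size=len(samples)), 0.2
    )
    efficiency = rng.lognormal(0.0, cfg.capture_efficiency_sdlog, size=len(rois))
    truth, cn = _place_events(cfg, rois, samples, rng)
    # depth scales with copy number against the diploid baseline, so a
    # hemizygous male chrX target sits at ~0.5x and female chrY at zero
    mu = (
        cfg.mean_depth
        * depth_factor[:, None]
        * efficiency[None, :]
        * (cn.astype(float) / 2.0)
    )
    counts = np.zeros_like(mu, dtype=np.int64)
    positive = mu > 0
    size = cfg.dispersion
    p = size / (size + mu[positive])
    counts[positive] = rng.negative_binomial(size, p)
    matrix = CoverageMatrix(counts=counts, samples=samples, rois=rois)
    truth_set = CallSet(caller_name="truth", calls=truth)
    return rois, matrix, truth_set, samples


def perturb_calls(
    truth: CallSet,
    profile: CallerErrorProfile,
    rois: Sequence[ROI],
    samples: Sequence[Sample],
    caller_name: str = "surrogate",
) -> CallSet:
    """Corrupt a truth call set into a plausible external caller's output.

    Each truth event survives with probability 1 - fn_rate; survivors'
    boundaries shift by a uniform +/- jitter in ROI units (clipped to the
    chromosome's targets).  False 1-2 ROI events with random type are
    inserted at ``fp_rate`` per (sample, ROI) unit, skipping units already
    covered for that sample.  Deterministic given ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    roi_idx_by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(rois):
        roi_idx_by_chrom.setdefault(r.chrom, []).append(i)
    calls: list[CNVCall] = []
    covered: dict[str, set[int]] = {s.name: set() for s in samples}

    def roi_span_indices(iv: GenomicInterval) -> list[int]:
        return [
            i
            for i in roi_idx_by_chrom.get(iv.chrom, [])
            if rois[i].interval.start < iv.end and rois[i].interval.end > iv.start
        ]

    for call in truth.calls:
        if rng.random() < profile.fn_rate:
            continue
        span = roi_span_indices(call.interval)
        if not span:
            continue
        chrom_rois = roi_idx_by_chrom[call.interval.chrom]
        first = chrom_rois.index(span[0])
        last = chrom_rois.index(span[-1])
        orig_first, orig_last = first, last
        if profile.boundary_jitter:
            j = profile.boundary_jitter
            first += int(rng.integers(-j, j + 1))
            last += int(rng.integers(-j, j + 1))
            # boundary error stays anchored on the event's depth signal:
            # the jittered span must keep at least one true ROI
            first = min(first, orig_last)
            last = max(last, orig_first)
        first = max(0, min(first, len(chrom_rois) - 1))
        last = max(first, min(last, len(chrom_rois) - 1))
        new_span = chrom_rois[first : last + 1]
        calls.append(
            CNVCall(
                interval=GenomicInterval(
                    call.interval.chrom,
                    rois[new_span[0]].interval.start,
                    rois[new_span[-1]].interval.end,
                ),
                type=call.type,
                sample=call.sample,
            )
        )
        covered[call.sample].update(new_span)

    if profile.fp_rate > 0:
        for s in samples:
            for i, r in enumerate(rois):
                if rng.random() >= profile.fp_rate:
                    continue
                if i in covered[s.name]:
                    continue
                length = int(rng.integers(1, 3))
                chrom_rois = roi_idx_by_chrom[r.chrom]
                pos = chrom_rois.index(i)
                span = chrom_rois[pos : pos + length]
                if any(k in covered[s.name] for k in span):
                    span = [i]
                cnv_type = CNVType.DEL if rng.random() < 0.5 else CNVType.DUP
                calls.append(
                    CNVCall(
                        interval=GenomicInterval(
                            r.chrom,
                            rois[span[0]].interval.start,
                            rois[span[-1]].interval.end,
                        ),
                        type=cnv_type,
                        sample=s.name,
                    )
                )
                covered[s.name].update(span)
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.sample, c.type.value))
    return CallSet(caller_name=caller_name, calls=calls)
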