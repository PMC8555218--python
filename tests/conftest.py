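"""Shared fixtures: tiny deterministic cohorts, and independent oracles
(exhaustive HMM path enumeration) used to cross-check the implementation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from panelcnv.caller import CallerParams
from panelcnv.core import GenomicInterval, ROI, Sample, Sex
from panelcnv.simulate import SimConfig, simulate_cohort


def exhaustive_viterbi(ratios, params: CallerParams, sd):
    """Brute-force most-likely path: score every one of the 3^L state
    sequences directly from the model densities.  Independent of the
    dynamic-programming implementation under test."""
    from panelcnv.caller import _STATE_MEANS, _STATE_ORDER, _log_transitions

    ratios = np.asarray(ratios, dtype=float)
    sd = np.asarray(sd, dtype=float)
    L = len(ratios)
    assert 1 <= L <= 10, "exhaustive enumeration is only feasible for short tracks"
    t = params.transition_prob
    log_init = np.log(np.array([t, 1.0 - 2.0 * t, t]))
    log_trans = _log_transitions(t)
    log_emit = (
        -0.5 * ((ratios[:, None] - _STATE_MEANS[None, :]) / sd[:, None]) ** 2
        - np.log(sd)[:, None]
        - 0.5 * np.log(2 * np.pi)
    )
    paths = np.array(list(itertools.product(range(3), repeat=L)), dtype=np.intp)
    scores = log_init[paths[:, 0]] + log_emit[np.arange(L), paths].sum(axis=1)
    if L > 1:
        scores = scores + log_trans[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    best = paths[int(np.argmax(scores))]
    return [_STATE_ORDER[k] for k in best]


@pytest.fixture(scope="session")
def viterbi_oracle():
    return exhaustive_viterbi


@pytest.fixture
def tiny_rois() -> list[ROI]:
    """Ten 100-bp ROIs on chr1 with 100-bp gaps."""
    return [
        ROI(GenomicInterval("chr1", 1000 + 200 * i, 1100 + 200 * i), f"roi{i}", i)
        for i in range(10)
    ]


@pytest.fixture
def trio_samples() -> list[Sample]:
    return [
        Sample("S1", Sex.F),
        Sample("S2", Sex.M),
        Sample("S3", Sex.F),
    ]


@pytest.fixture(scope="session")
def panel_cohort():
    """A high-quality panel-like cohort: tight counts so inter-sample
    correlations clear the default 0.98 threshold and the caller operates
    in its intended regime."""
    cfg = SimConfig(seed=11, n_samples=30, dispersion=300.0, mean_depth=200.0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the generator's default (exome-like) conditions."""
    return simulate_cohort(SimConfig(seed=7))
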