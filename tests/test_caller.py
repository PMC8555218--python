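"""The depth caller: sex inference, batching, QC filters, reference
selection, ratio computation, HMM segmentation, call merging and the
ratio-to-copy-number map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelcnv.caller import (
    CallerParams,
    CoverageMatrix,
    apply_qc_filters,
    call_cohort,
    compute_ratios,
    estimate_emission_sd,
    infer_sex,
    map_ratio_to_cn,
    merge_calls,
    plan_batches,
    select_reference,
    viterbi_segment,
)
from panelcnv.core import (
    CNVType,
    GenomicInterval,
    ROI,
    Sample,
    Sex,
    State,
    overlap_length,
)
from panelcnv.simulate import SimConfig, simulate_cohort

from conftest import exhaustive_viterbi


def make_rois(n, chrom="chr1", length=100, gap=100, name_prefix="r"):
    return [
        ROI(GenomicInterval(chrom, 1000 + (length + gap) * i, 1000 + (length + gap) * i + length),
            f"{name_prefix}{i}", i)
        for i in range(n)
    ]


def flat_matrix(n_samples, n_rois, value=200, sex=Sex.F):
    rois = make_rois(n_rois)
    samples = [Sample(f"S{i}", sex) for i in range(n_samples)]
    counts = np.full((n_samples, n_rois), value, dtype=np.int64)
    return CoverageMatrix(counts=counts, samples=samples, rois=rois)


class TestCallerParams:
    @pytest.mark.parametrize("kwargs", [
        {"min_correlation": 0.0}, {"min_correlation": 1.0},
        {"min_coverage": -1.0}, {"transition_prob": 0.0}, {"transition_prob": 0.5},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CallerParams(**kwargs)


class TestInferSex:
    def _cohort(self, seed):
        # tight counts with near-uniform capture efficiency: the mean/median
        # comparisons of the inference rule assume no heavy efficiency tail;
        # event-free, because a sample with an X/Y CNV has no single truth
        cfg = SimConfig(seed=seed, n_samples=12, capture_efficiency_sdlog=0.2,
                        dispersion=300.0, events_per_sample_rate=0.0)
        rois, matrix, truth, samples = simulate_cohort(cfg)
        return matrix

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_simulated_sexes(self, seed):
        matrix = self._cohort(seed)
        true_sexes = {s.name: s.sex for s in matrix.samples}
        blinded = matrix.with_sexes({s.name: Sex.UNKNOWN for s in matrix.samples})
        inferred = infer_sex(blinded)
        assert {s.name: s.sex for s in inferred.samples} == true_sexes

    def test_noop_when_all_sexes_known(self):
        matrix = self._cohort(99)
        out = infer_sex(matrix)
        assert out.samples == matrix.samples

    def test_error_without_sex_chromosome_rois(self):
        m = flat_matrix(4, 10)
        blinded = m.with_sexes({s.name: Sex.UNKNOWN for s in m.samples})
        with pytest.raises(ValueError, match="explicit sexes"):
            infer_sex(blinded)


class TestPlanBatches:
    def _samples(self, n_f, n_m):
        return ([Sample(f"F{i}", Sex.F) for i in range(n_f)]
                + [Sample(f"M{i}", Sex.M) for i in range(n_m)])

    def _rois(self):
        return (make_rois(5, "chr1") + make_rois(3, "chrX", name_prefix="x")
                + make_rois(2, "chrY", name_prefix="y"))

    def test_sex_split_with_enough_of_each(self):
        plan = plan_batches(self._samples(6, 6), self._rois(), "default")
        assert len(plan.batches) == 2
        labels = {b.label: b for b in plan.batches}
        assert len(labels["female"].sample_names) == 6
        assert not labels["female"].sex_calls_unreliable
        plan.validate(self._samples(6, 6), ["chr1", "chrX", "chrY"])

    def test_single_batch_fallback_below_five(self):
        plan = plan_batches(self._samples(3, 9), self._rois(), "default")
        assert len(plan.batches) == 1
        assert plan.batches[0].sex_calls_unreliable
        assert len(plan.batches[0].sample_names) == 12

    def test_batch2_mode_three_batches(self):
        plan = plan_batches(self._samples(6, 6), self._rois(), "batch2")
        assert len(plan.batches) == 3
        labels = [b.label for b in plan.batches]
        assert labels == ["autosomes", "sex-female", "sex-male"]
        auto = plan.batches[0]
        assert set(auto.chroms) == {"chr1"} and len(auto.sample_names) == 12
        plan.validate(self._samples(6, 6), ["chr1", "chrX", "chrY"])

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            plan_batches([], self._rois(), "default")


class TestQcFilters:
    def test_low_coverage_roi_dropped(self):
        m = flat_matrix(3, 4, value=200)
        m.counts[:, 2] = [10, 12, 8]
        out = apply_qc_filters(m, CallerParams())
        assert set(out.dropped_rois) == {m.rois[2].key}
        assert not out.nocall_samples

    def test_sample_median_150_retained(self):
        m = flat_matrix(3, 4, value=150)
        out = apply_qc_filters(m, CallerParams())
        assert not out.nocall_samples

    def test_matches_brute_force_median_oracle(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(0, 400, size=(50, 30))
        rois = make_rois(30)
        samples = [Sample(f"S{i}", Sex.F) for i in range(50)]
        m = CoverageMatrix(counts=counts, samples=samples, rois=rois)
        params = CallerParams(min_coverage=150.0)
        out = apply_qc_filters(m, params)
        # independent per-row/per-column median tally
        exp_drop = {rois[j].key for j in range(30)
                    if sorted(counts[:, j])[24:26][0] + sorted(counts[:, j])[24:26][1]
                    < 2 * 150.0}
        exp_nocall = {samples[i].name for i in range(50)
                      if sorted(counts[i, :])[14] + sorted(counts[i, :])[15] < 2 * 150.0}
        assert set(out.dropped_rois) == exp_drop
        assert set(out.nocall_samples) == exp_nocall

    def test_filters_toggleable(self):
        m = flat_matrix(3, 4, value=10)
        out = apply_qc_filters(m, CallerParams(), drop_low_coverage_rois=False,
                               drop_low_coverage_samples=False)
        assert not out.dropped_rois and not out.nocall_samples

    def test_all_rois_dropped_is_an_error(self):
        m = flat_matrix(3, 4, value=10)
        with pytest.raises(ValueError, match="unusable"):
            apply_qc_filters(m, CallerParams())

    def test_raising_min_coverage_grows_drop_set(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(50, 400, size=(20, 40))
        m = CoverageMatrix(counts=counts, samples=[Sample(f"S{i}", Sex.F) for i in range(20)],
                           rois=make_rois(40))
        previous: set = set()
        for cov in [60, 100, 150, 200, 250]:
            dropped = set(apply_qc_filters(m, CallerParams(min_coverage=cov),
                                           drop_low_coverage_samples=False).dropped_rois)
            assert previous <= dropped
            previous = dropped


class TestSelectReference:
    def test_truncated_to_ten(self):
        m = flat_matrix(13, 20)
        # identical profiles modulo tiny jitter so correlations are 1.0
        rng = np.random.default_rng(0)
        base = rng.integers(150, 400, size=20)
        m.counts[:] = base
        ref = select_reference("S0", m, CallerParams(), m.sample_names)
        assert ref is not None and len(ref) == 10

    def test_all_low_correlation_is_nocall(self):
        rng = np.random.default_rng(1)
        m = flat_matrix(6, 60)
        m.counts = rng.integers(100, 1000, size=(6, 60))  # uncorrelated noise
        assert select_reference("S0", m, CallerParams(min_correlation=0.98),
                                m.sample_names) is None

    def test_relatives_always_excluded(self):
        rois = make_rois(30)
        rng = np.random.default_rng(2)
        base = rng.integers(200, 2000, size=30)
        samples = [Sample("S0", Sex.F, family="famA"), Sample("S1", Sex.F, family="famA"),
                   Sample("S2", Sex.F), Sample("S3", Sex.F)]
        counts = np.tile(base, (4, 1))
        m = CoverageMatrix(counts=counts, samples=samples, rois=rois)
        ref = select_reference("S0", m, CallerParams(), m.sample_names)
        assert ref is not None and "S1" not in ref and set(ref) == {"S2", "S3"}

    def test_raising_threshold_only_shrinks_reference(self):
        cfg = SimConfig(seed=21, n_samples=15, dispersion=300.0, mean_depth=200.0)
        _, matrix, _, _ = simulate_cohort(cfg)
        names = matrix.sample_names
        previous = None
        for corr in [0.999, 0.99, 0.95, 0.90, 0.80]:  # descending strictness
            ref = select_reference(names[0], matrix, CallerParams(min_correlation=corr), names)
            current = set(ref or [])
            if previous is not None:
                assert previous <= current or len(current) == 10
            previous = current


class TestComputeRatios:
    def test_identity_when_test_equals_references(self):
        m = flat_matrix(5, 12, value=300)
        ratios, valid = compute_ratios("S0", ["S1", "S2", "S3"], m)
        assert valid.all()
        np.testing.assert_allclose(ratios, 1.0)

    def test_global_halving_cancels_under_normalization(self):
        m = flat_matrix(5, 12, value=300)
        m.counts[0] //= 2  # whole-genome halving: invisible after normalization
        ratios, _ = compute_ratios("S0", ["S1", "S2", "S3"], m)
        np.testing.assert_allclose(ratios, 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_focal_heterozygous_deletion_shows_half_ratio(self, seed):
        cfg = SimConfig(seed=1000 + seed, n_samples=12, n_rois_autosomal=300,
                        n_rois_x=0, n_rois_y=0, events_per_sample_rate=0.0,
                        dispersion=500.0, mean_depth=500.0,
                        capture_efficiency_sdlog=0.2)
        rois, matrix, _, samples = simulate_cohort(cfg)
        # engineer a CN1 deletion over 3 ROIs of sample 0
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, 290))
        matrix.counts[0, start:start + 3] = matrix.counts[0, start:start + 3] // 2
        reference = [s.name for s in samples[1:11]]
        ratios, valid = compute_ratios(samples[0].name, reference, matrix)
        assert valid.all()
        # per-ROI within 3 sigma of the count noise; run mean much tighter
        np.testing.assert_allclose(ratios[start:start + 3], 0.5, atol=0.15)
        assert abs(ratios[start:start + 3].mean() - 0.5) < 0.1
        mask = np.ones(300, bool)
        mask[start:start + 3] = False
        assert np.quantile(np.abs(ratios[mask] - 1.0), 0.99) < 0.3

    def test_zero_reference_median_marks_nocall(self):
        m = flat_matrix(4, 10, value=200)
        m.counts[1:, 4] = 0
        ratios, valid = compute_ratios("S0", ["S1", "S2", "S3"], m)
        assert not valid[4] and np.isnan(ratios[4])
        assert valid[[i for i in range(10) if i != 4]].all()


class TestViterbi:
    def test_flat_track_is_all_normal(self):
        params = CallerParams(transition_prob=0.4 - 1e-9)
        states = viterbi_segment(np.ones(12), params, np.full(12, 0.1))
        assert states == [State.NORMAL] * 12

    def test_textbook_deletion_run(self):
        ratios = np.array([1.0, 1.0, 0.5, 0.5, 0.5, 1.0])
        params = CallerParams(transition_prob=0.01)
        sd = np.full(6, 0.1)
        expected = [State.NORMAL, State.NORMAL, State.DEL, State.DEL, State.DEL, State.NORMAL]
        assert viterbi_segment(ratios, params, sd) == expected
        assert exhaustive_viterbi(ratios, params, sd) == expected

    def test_singleton_and_empty_tracks(self):
        params = CallerParams()
        assert viterbi_segment(np.array([0.5]), CallerParams(transition_prob=0.4 - 1e-9),
                               np.array([0.05])) == [State.DEL]
        assert viterbi_segment(np.array([]), params, np.array([])) == []

    def test_transition_prob_gates_single_roi_excursions(self):
        # a borderline one-ROI dip: called DEL at lax t, absorbed at strict t
        ratios = np.array([1.0, 1.0, 0.68, 1.0, 1.0])
        sd = np.full(5, 0.1)
        states_by_t = {}
        for t in [0.1, 0.03, 0.01, 1e-3, 1e-4, 1e-6]:
            params = CallerParams(transition_prob=t)
            path = viterbi_segment(ratios, params, sd)
            assert path == exhaustive_viterbi(ratios, params, sd)
            states_by_t[t] = path[2]
        assert states_by_t[0.1] == State.DEL
        assert states_by_t[1e-6] == State.NORMAL

    @given(st.integers(1, 10), st.integers(0, 2 ** 31 - 1),
           st.sampled_from([1e-4, 1e-2, 0.1, 0.3]))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_enumeration(self, length, seed, t):
        rng = np.random.default_rng(seed)
        ratios = rng.uniform(0.0, 2.5, size=length)
        sd = rng.uniform(0.05, 0.4, size=length)
        params = CallerParams(transition_prob=t)
        assert viterbi_segment(ratios, params, sd) == exhaustive_viterbi(ratios, params, sd)


class TestMapRatioToCn:
    @pytest.mark.parametrize("ratio, cn", [
        (0.05, 0), (0.1, 0),            # CN0 band, boundary inclusive
        (0.11, 1), (0.5, 1), (0.8, 1),  # CN1
        (0.81, 2), (1.0, 2), (1.2, 2),  # CN2
        (1.21, 3), (1.5, 3), (1.8, 3),  # CN3
        (1.81, 4), (2.0, 4), (2.2, 4),  # CN4
        (2.21, 4), (2.3, 5), (2.5, 5), (3.0, 6), (4.9, 10),  # doubling rule
    ])
    def test_band_table(self, ratio, cn):
        assert map_ratio_to_cn(ratio) == cn

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            map_ratio_to_cn(-0.1)

    def test_non_decreasing(self):
        grid = np.linspace(0.0, 6.0, 1201)
        cns = [map_ratio_to_cn(float(r)) for r in grid]
        assert all(a <= b for a, b in zip(cns, cns[1:]))


class TestMergeCalls:
    def test_del_run_becomes_one_call(self):
        rois = make_rois(4)
        states = [State.NORMAL, State.DEL, State.DEL, State.NORMAL]
        ratios = [1.0, 0.48, 0.52, 1.0]
        calls = merge_calls(states, rois, ratios, "S1")
        assert len(calls) == 1
        c = calls[0]
        assert c.type == CNVType.DEL
        assert (c.interval.start, c.interval.end) == (rois[1].interval.start, rois[2].interval.end)
        assert c.reads_ratio == pytest.approx(0.5)
        assert c.copy_number == 1
        assert c.sample == "S1"

    def test_all_normal_yields_nothing(self):
        rois = make_rois(3)
        assert merge_calls([State.NORMAL] * 3, rois, [1.0] * 3, "S1") == []

    def test_adjacent_del_and_dup_runs_stay_separate(self):
        rois = make_rois(4)
        states = [State.DEL, State.DEL, State.DUP, State.DUP]
        ratios = [0.5, 0.5, 1.5, 1.5]
        calls = merge_calls(states, rois, ratios, "S1")
        assert [c.type for c in calls] == [CNVType.DEL, CNVType.DUP]
        assert calls[0].interval.end == rois[1].interval.end
        assert calls[1].interval.start == rois[2].interval.start


def _event_displacement_ok(event, rois, matrix, n_sd=3.0):
    """Oracle: event ROIs are active and the expected ratio displacement
    exceeds n_sd times the cohort's empirical per-ROI ratio spread."""
    idx = [i for i, r in enumerate(rois)
           if r.chrom == event.interval.chrom
           and overlap_length(r.interval, event.interval) > 0]
    if any(rois[i].key in matrix.dropped_rois for i in idx):
        return False
    norm = matrix.counts.astype(float)
    norm /= norm.sum(axis=1, keepdims=True)
    med = np.median(norm, axis=0)
    if (med[idx] <= 0).any():
        return False
    spread = np.std(norm[:, idx] / med[idx], axis=0, ddof=1)
    displacement = abs(event.reads_ratio - 1.0)
    return bool((displacement > n_sd * np.maximum(spread, 0.05)).all())


class TestCallCohort:
    @pytest.mark.parametrize("seed", range(10))
    def test_recall_of_well_displaced_events(self, seed):
        cfg = SimConfig(seed=3000 + seed, n_samples=30, dispersion=300.0, mean_depth=200.0)
        rois, matrix, truth, samples = simulate_cohort(cfg)
        callset = call_cohort(matrix, CallerParams())
        filtered = apply_qc_filters(matrix, CallerParams())
        strong = [t for t in truth.calls
                  if _event_displacement_ok(t, rois, filtered)
                  and not all((t.sample, r.key) in callset.nocall_units
                              for r in rois if overlap_length(r.interval, t.interval) > 0)]
        if not strong:
            pytest.skip("no strongly displaced callable events this seed")
        hits = sum(
            1 for t in strong
            if any(c.sample == t.sample and c.type == t.type
                   and overlap_length(c.interval, t.interval) > 0 for c in callset.calls))
        assert hits / len(strong) >= 0.8

    @pytest.mark.parametrize("seed", range(5))
    def test_null_cohort_false_positive_rate(self, seed):
        cfg = SimConfig(seed=4000 + seed, n_samples=30, events_per_sample_rate=0.0,
                        dispersion=300.0, mean_depth=200.0)
        rois, matrix, truth, samples = simulate_cohort(cfg)
        assert truth.is_empty()
        callset = call_cohort(matrix, CallerParams())
        fp_units = set()
        for c in callset.calls:
            for r in rois:
                if overlap_length(r.interval, c.interval) > 0:
                    fp_units.add((c.sample, r.key))
        universe = len(samples) * len(rois) - len(callset.nocall_units)
        assert universe > 0
        assert len(fp_units) / universe <= 0.01

    def test_correlation_failed_sample_is_fully_nocall(self):
        cfg = SimConfig(seed=5, n_samples=12, dispersion=300.0, mean_depth=200.0,
                        n_rois_x=0, n_rois_y=0)
        rois, matrix, truth, samples = simulate_cohort(cfg)
        # scramble one sample so it correlates with nobody
        rng = np.random.default_rng(0)
        matrix.counts[3] = rng.permutation(matrix.counts[3])
        victim = samples[3].name
        callset = call_cohort(matrix, CallerParams(min_correlation=0.98), mode="single")
        assert not [c for c in callset.calls if c.sample == victim]
        active_keys = {r.key for r in rois} - set(
            apply_qc_filters(matrix, CallerParams()).dropped_rois)
        assert {(victim, k) for k in active_keys} <= callset.nocall_units

    def test_deterministic_given_identical_inputs(self, panel_cohort):
        rois, matrix, truth, samples = panel_cohort
        a = call_cohort(matrix, CallerParams())
        b = call_cohort(matrix, CallerParams())
        assert a.calls == b.calls and a.nocall_units == b.nocall_units
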