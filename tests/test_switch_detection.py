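import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chronoswitch import switch_detection as sd
from chronoswitch.switch_detection import (
    SwitchEvent,
    SwitchThresholds,
    add_noise,
    filter_switches,
    find_crossings,
    interval_mean_difference,
    score_gene,
    series_correlation,
    smooth_series,
    switch_magnitude,
    switch_probability,
    switch_pvalue,
)
from chronoswitch.synthetic_data import SimulationConfig, simulate_profiles


class TestAddNoise:
    def test_zero_amount_is_identity(self, small_matrix):
        out = add_noise(small_matrix, 0.0, seed=1)
        assert np.array_equal(out.values, small_matrix.values)

    def test_noise_bounded_by_amount(self, small_matrix):
        out = add_noise(small_matrix, 2.0, seed=1)
        high = small_matrix.values >= 2
        assert np.all(np.abs(out.values - small_matrix.values)[high] < 2)

    def test_clamped_at_zero(self, small_matrix):
        m = small_matrix
        m.values[:] = 0.1
        out = add_noise(m, 2.0, seed=0)
        assert np.all(out.values >= 0)

    def test_same_seed_same_output(self, small_matrix):
        a = add_noise(small_matrix, 2.0, seed=7)
        b = add_noise(small_matrix, 2.0, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_negative_amount_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            add_noise(small_matrix, -1.0, seed=0)


class TestSmoothSeries:
    times = np.arange(0.0, 31.0, 3.0)

    def test_constant_reproduced(self):
        out = smooth_series(self.times, np.full(11, 7.0), degree=4)
        assert np.allclose(out, 7.0, rtol=1e-8)

    def test_exact_quartic_reproduced(self):
        y = 0.01 * self.times**4 - 0.3 * self.times**2 + 2 * self.times + 5
        assert np.allclose(smooth_series(self.times, y, 4), y, rtol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_series([0, 1, 2], [1, 2, 3], degree=4)

    def test_smoothing_reduces_noise_on_planted_signal(self):
        rng = np.random.default_rng(42)
        clean = 10 + 5 * np.sin(2 * np.pi * self.times / 24)
        noisy = clean + rng.uniform(-2, 2, size=clean.size)
        fitted = smooth_series(self.times, noisy, 4)
        assert np.sum((fitted - clean) ** 2) <= np.sum((noisy - clean) ** 2)


class TestFindCrossings:
    def test_linear_interpolation_root(self):
        out = find_crossings([0.0, 3.0], [1.0, 3.0], [3.0, 1.0])
        assert len(out) == 1
        t, before, after = out[0]
        assert t == pytest.approx(1.5)
        assert before == (0,) and after == (1,)

    def test_no_reversal_no_crossing(self):
        assert find_crossings([0, 1, 2], [5, 6, 5], [1, 2, 1]) == []

    def test_zero_touch_same_sign_is_not_a_crossing(self):
        # difference 1, 0, 1: touches zero without reversing
        assert find_crossings([0, 1, 2], [2, 1, 2], [1, 1, 1]) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_crossings([0, 1], [1, 2], [1, 2, 3])

    def test_consecutive_crossings_partition_samples(self):
        # difference +,+,-,-,+ : crossings between (1,2) and (3,4)
        d = np.array([1.0, 1.0, -1.0, -1.0, 1.0])
        out = find_crossings([0, 1, 2, 3, 4], d, np.zeros(5))
        assert [(c[1], c[2]) for c in out] == [
            ((0, 1), (2, 3)), ((2, 3), (4,)),
        ]


class TestMetrics:
    def test_interval_mean_difference_examples(self):
        assert interval_mean_difference([5, 7], [1, 3], [0, 1]) == 4.0
        assert interval_mean_difference([2, 2], [2, 2], [0, 1]) == 0.0
        # absolute values, not signed
        assert interval_mean_difference([1, 5], [3, 3], [0, 1]) == 2.0

    def test_magnitude_is_sum_of_interval_differences(self):
        si, sj = [5, 7, 1, 3], [1, 3, 5, 7]
        assert switch_magnitude(si, sj, [0, 1], [2, 3]) == 8.0
        assert switch_magnitude([1, 1], [1, 1], [0], [1]) == 0.0

    def test_magnitude_linear_in_separation(self):
        si = np.array([5.0, 7, 1, 3])
        sj = np.array([1.0, 3, 5, 7])
        mid = (si + sj) / 2
        s1 = switch_magnitude(si, sj, [0, 1], [2, 3])
        s2 = switch_magnitude(mid + 2 * (si - mid), mid + 2 * (sj - mid),
                              [0, 1], [2, 3])
        assert s2 == pytest.approx(2 * s1)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_magnitude_matches_naive_double_loop(self, seed):
        """S2 equals direct summation of per-sample absolute differences."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        si = rng.uniform(0, 100, n)
        sj = rng.uniform(0, 100, n)
        cut = int(rng.integers(2, n - 1))
        i1, i2 = list(range(cut)), list(range(cut, n))
        naive = sum(abs(si[m] - sj[m]) for m in i1) / len(i1) \
            + sum(abs(si[m] - sj[m]) for m in i2) / len(i2)
        assert switch_magnitude(si, sj, i1, i2) == pytest.approx(
            naive, rel=1e-12)

    def test_probability_counts_consistent_samples(self):
        # perfectly consistent
        assert switch_probability([3, 3, 1, 1], [1, 1, 3, 3], [0, 1], [2, 3]) == 1.0
        # 3 of 4 consistent
        assert switch_probability([3, 1, 1, 1], [1, 3, 3, 3], [0, 1], [2, 3]) == 0.75
        # fully reversed
        assert switch_probability([1, 1, 3, 3], [3, 3, 1, 1], [0, 1], [2, 3]) == 0.0

    def test_probability_ties_count_as_inconsistent(self):
        assert switch_probability([2, 2], [2, 1], [0], [1]) == 0.0

    def test_pvalue_closed_form(self):
        # differences [3,4,5]: t = 4/(1/sqrt(3)), df=2
        si, sj = [3.0, 4.0, 5.0, 0, 0, 0], [0.0, 0, 0, 3, 4, 5]
        p = switch_pvalue(si, sj, [0, 1, 2], [3, 4, 5])
        t = 4 / (1 / np.sqrt(3))
        expected = 2 * stats.t.sf(t, df=2)
        assert p == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(0.0202, abs=1e-4)

    def test_pvalue_mean_zero_is_one(self):
        si, sj = [1.0, 2, 3, 5, 5, 5], [2.0, 2, 2, 1, 1, 1]
        # I1 differences [-1, 0, 1] -> p 1; I2 differences [4,4,4] -> p 0
        assert switch_pvalue(si, sj, [0, 1, 2], [3, 4, 5]) == 1.0

    def test_pvalue_max_rule(self):
        si = [10.0, 11, 12, 1, 2, 30]
        sj = [0.0, 0, 0, 3, 3, 3]
        p1 = switch_pvalue(si, sj, [0, 1, 2], [0, 1, 2])
        p2 = switch_pvalue(si, sj, [3, 4, 5], [3, 4, 5])
        assert switch_pvalue(si, sj, [0, 1, 2], [3, 4, 5]) == max(p1, p2)

    def test_pvalue_zero_variance_nonzero_mean(self):
        assert switch_pvalue([5, 5, 1, 1], [1, 1, 5, 5], [0, 1], [2, 3]) == 0.0

    def test_pvalue_undersized_interval_rejected(self):
        with pytest.raises(ValueError):
            switch_pvalue([1, 2], [0, 0], [0], [1])

    def test_correlation_examples(self):
        assert series_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert series_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert series_correlation([1, 0, -1, 0], [0, 1, 0, -1]) == pytest.approx(
            0.0, abs=1e-12)

    def test_correlation_constant_series_defined_as_zero(self):
        assert series_correlation([1, 1, 1], [1, 2, 3]) == 0.0


class TestScoreGene:
    def test_single_isoform_gene_returns_empty(self, small_matrix):
        m = small_matrix
        m.tx2gene["GB.T2"] = "GC"  # GB now single-isoform... still two genes
        single = {t: g for t, g in m.tx2gene.items()}
        assert score_gene(m, "GC") == []

    def test_unknown_gene_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            score_gene(small_matrix, "NOPE")

    def test_planted_antiphase_pair_recovered(self, small_matrix):
        events = score_gene(small_matrix, "GA", use_smoothing=False)
        # sin(pi t/12 + pi/3) zeros at t = 8 and 20 inside (0, 30); linear
        # interpolation between 3 h samples localises them to ~0.05 h
        found = sorted(e.switch_time for e in events)
        assert len(found) == 2
        assert found[0] == pytest.approx(8.0, abs=0.1)
        assert found[1] == pytest.approx(20.0, abs=0.1)
        assert all(e.prob == 1.0 for e in events)
        # iso_i is dominant before each crossing
        assert events[0].iso_i == "GA.T1"
        assert events[1].iso_i == "GA.T2"

    def test_three_isoforms_enumerate_three_pairs(self):
        from chronoswitch.io_formats import TimeCourseMatrix

        times = np.arange(0.0, 31.0, 3.0)
        rng = np.random.default_rng(0)
        m = TimeCourseMatrix(
            transcript_ids=["T1", "T2", "T3"],
            times=times,
            values=rng.uniform(1, 10, (3, 11)),
            tx2gene={"T1": "G", "T2": "G", "T3": "G"},
        )
        events = score_gene(m, "G", use_smoothing=False)
        pairs = {frozenset((e.iso_i, e.iso_j)) for e in events}
        assert len(pairs) <= 3  # at most the 3 unordered pairs
        # and the enumeration visits all 3 pairs (crossings or not)
        assert len(list(__import__("itertools").combinations(["T1", "T2", "T3"], 2))) == 3


def _event(**kw):
    base = dict(gene_id="G", iso_i="A", iso_j="B", switch_time=15.0,
                interval_before=(0, 1), interval_after=(2, 3),
                prob=1.0, diff=5.0, pval=1e-5, cor=-0.9)
    base.update(kw)
    return SwitchEvent(**base)


class TestFilterSwitches:
    def test_empty_input(self):
        assert filter_switches([], SwitchThresholds()) == []

    def test_diff_below_cutoff_removed(self):
        kept = filter_switches([_event(diff=0.9)], SwitchThresholds())
        assert kept == []

    def test_passing_event_kept_in_order(self):
        evs = [_event(switch_time=5.0), _event(switch_time=25.0)]
        assert filter_switches(evs, SwitchThresholds()) == evs

    def test_time_window_is_inclusive(self):
        th = SwitchThresholds()
        assert filter_switches([_event(switch_time=30.0)], th)
        assert not filter_switches([_event(switch_time=30.01)], th)

    def test_nan_pvalue_fails(self):
        assert filter_switches([_event(pval=float("nan"))]) == []

    def test_antiphase_pair_passes_default_correlation_gate(self):
        assert filter_switches([_event(cor=-1.0)], SwitchThresholds())

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_tightening_any_threshold_gives_subset(self, seed):
        rng = np.random.default_rng(seed)
        events = [
            _event(prob=rng.uniform(0, 1), diff=rng.uniform(0, 3),
                   pval=10 ** rng.uniform(-6, 0), cor=rng.uniform(-1, 1),
                   switch_time=rng.uniform(-5, 35))
            for _ in range(30)
        ]
        th = SwitchThresholds(
            prob_min=rng.uniform(0, 1), diff_min=rng.uniform(0, 2),
            pval_max=10 ** rng.uniform(-4, 0), cor_min=rng.uniform(0, 1),
            time_lower=0.0, time_upper=rng.uniform(10, 30))
        knob = rng.integers(0, 5)
        from dataclasses import replace

        tighter = [
            replace(th, prob_min=min(1.0, th.prob_min + 0.2)),
            replace(th, diff_min=th.diff_min + 0.5),
            replace(th, pval_max=th.pval_max / 10),
            replace(th, cor_min=min(1.0, th.cor_min + 0.2)),
            replace(th, time_upper=th.time_upper - 5),
        ][knob]
        loose = filter_switches(events, th)
        tight = filter_switches(events, tighter)
        assert set(id(e) for e in tight) <= set(id(e) for e in loose)


class TestAntisymmetry:
    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_swapping_isoforms_flips_prob_and_keeps_diff(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        si = rng.uniform(0, 20, n)
        sj = rng.uniform(0, 20, n)
        i1, i2 = [0, 1, 2, 3], [4, 5, 6, 7]
        assert switch_magnitude(si, sj, i1, i2) == switch_magnitude(
            sj, si, i1, i2)
        assert switch_pvalue(si, sj, i1, i2) == pytest.approx(
            switch_pvalue(sj, si, i1, i2))
        assert abs(series_correlation(si, sj)) == pytest.approx(
            abs(series_correlation(sj, si)))
        p = switch_probability(si, sj, i1, i2)
        q = switch_probability(sj, si, i1, i2)
        assert p + q == pytest.approx(1.0)  # tie-free with prob. 1


class TestRecoveryAndSpecificity:
    def test_noise_free_crossing_within_half_sampling_interval(self):
        cfg = SimulationConfig(n_genes=10, fraction_switching=1.0,
                               single_isoform_fraction=0.0,
                               noise_amount=0.0, seed=5)
        matrix, truth = simulate_profiles(cfg)
        events = [e for g in matrix.genes()
                  for e in score_gene(matrix, g)]
        for sw in truth.switches:
            for tc in sw.crossing_times:
                hits = [e for e in events
                        if {e.iso_i, e.iso_j} == {sw.iso_a, sw.iso_b}
                        and abs(e.switch_time - tc) <= 1.5]
                assert hits, f"crossing at {tc} not recovered"

    def test_step_switches_pass_full_filter(self):
        """Step-shaped reversals (constant separation per flank) pass the
        complete cutoff cascade at the study noise level."""
        recovered = planted = 0
        for seed in range(10):
            cfg = SimulationConfig(n_genes=10, fraction_switching=1.0,
                                   single_isoform_fraction=0.0,
                                   noise_amount=2.0, seed=seed,
                                   profile_archetype="step")
            matrix, truth = simulate_profiles(cfg)
            events = [e for g in matrix.genes() for e in score_gene(matrix, g)]
            kept = filter_switches(events)
            for sw in truth.switches:
                for tc in sw.crossing_times:
                    planted += 1
                    if any({e.iso_i, e.iso_j} == {sw.iso_a, sw.iso_b}
                           and abs(e.switch_time - tc) <= 1.5 for e in kept):
                        recovered += 1
        assert planted >= 90
        assert recovered / planted >= 0.9

    def test_proportional_pairs_yield_no_filtered_events_noise_free(self):
        cfg = SimulationConfig(n_genes=15, fraction_switching=0.0,
                               single_isoform_fraction=0.0,
                               noise_amount=0.0, seed=2)
        matrix, _ = simulate_profiles(cfg)
        events = [e for g in matrix.genes() for e in score_gene(matrix, g)]
        assert filter_switches(events) == []

    def test_module_is_deterministic(self, small_matrix):
        a = score_gene(add_noise(small_matrix, 2.0, 3), "GA")
        b = score_gene(add_noise(small_matrix, 2.0, 3), "GA")
        assert a == b
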