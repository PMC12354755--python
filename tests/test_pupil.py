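import numpy as np
import pandas as pd
import pytest

from rlpupil.pupil import (
    FilterConfig,
    PupilTrace,
    cluster_permutation_test,
    derivative_matrix,
    interpolate_blinks,
    preprocess_session,
    preprocess_traces,
    read_traces,
    temporal_derivative,
    write_traces,
    zscore_within,
)
from rlpupil.synth import SyntheticPupilSpec, generate_task_schedule, generate_pupil_dataset

FS = 500.0


def _trace(diameter, trial=0, participant="p0", drug="placebo", condition="gain"):
    n = len(diameter)
    t = np.arange(n) / FS
    return PupilTrace(
        participant_id=participant,
        drug_state=drug,
        condition=condition,
        trial=trial,
        time=t,
        diameter=np.asarray(diameter, dtype=float),
        t_stimulus_on=3.5,
        t_outcome_on=4.5,
    )


def _n(seconds):
    return int(round(seconds * FS))


def _session_trace(value=5.0, trial=0, **kw):
    # 3.5 s fixation + 1.0 s stimulus + 2.5 s outcome
    return _trace(np.full(_n(7.0), value), trial=trial, **kw)


class TestInterpolateBlinks:
    def test_constant_trace_gap_filled_exactly(self):
        d = np.full(_n(7.0), 5.0)
        d[1000 : 1000 + _n(0.4)] = np.nan
        fixed, discarded = interpolate_blinks(_trace(d))
        assert not discarded
        assert np.all(fixed.diameter == 5.0)

    def test_600ms_gap_discards(self):
        d = np.full(_n(7.0), 5.0)
        d[1000 : 1000 + _n(0.6)] = np.nan
        fixed, discarded = interpolate_blinks(_trace(d))
        assert discarded
        assert np.isnan(fixed.diameter).any()  # samples untouched

    def test_exactly_500ms_gap_discards(self):
        d = np.full(_n(7.0), 5.0)
        d[1000 : 1000 + _n(0.5)] = np.nan
        _, discarded = interpolate_blinks(_trace(d))
        assert discarded

    def test_ramp_gap_filled_on_the_line(self):
        slope = 2.0
        t = np.arange(_n(7.0)) / FS
        d = 1.0 + slope * t
        d[1000 : 1000 + _n(0.4)] = np.nan
        fixed, _ = interpolate_blinks(_trace(d))
        expected = 1.0 + slope * t[1000 : 1000 + _n(0.4)]
        assert np.allclose(fixed.diameter[1000 : 1000 + _n(0.4)], expected, atol=1e-9)

    def test_non_missing_samples_never_altered(self):
        rng = np.random.default_rng(0)
        d = rng.normal(5, 1, _n(7.0))
        d[200:300] = np.nan
        d[2000:2100] = np.nan
        original = d.copy()
        fixed, _ = interpolate_blinks(_trace(d))
        valid = ~np.isnan(original)
        assert np.array_equal(fixed.diameter[valid], original[valid])

    def test_boundary_blink_one_sided_anchor(self):
        d = np.full(_n(7.0), 5.0)
        d[: _n(0.3)] = np.nan
        fixed, discarded = interpolate_blinks(_trace(d))
        assert not discarded
        assert np.all(fixed.diameter == 5.0)


class TestPreprocessSession:
    def test_constant_traces_correct_to_zero(self):
        traces = [_session_trace(value=7.0, trial=k) for k in range(6)]
        matrix = preprocess_session(traces)
        assert np.abs(matrix.values).max() < 1e-9
        assert len(matrix.excluded) == 0  # zero SD -> no exclusion

    def test_baseline_outlier_flagged(self):
        rng = np.random.default_rng(1)
        traces = []
        for k in range(12):
            value = 5.0 + 0.01 * rng.standard_normal()
            traces.append(_session_trace(value=value, trial=k))
        traces.append(_session_trace(value=50.0, trial=12))  # huge baseline
        matrix = preprocess_session(traces)
        assert list(matrix.excluded["trial"]) == [12]
        assert list(matrix.excluded["reason"]) == ["baseline-outlier"]

    def test_exclusion_fraction_matches_normal_tail(self):
        # baselines ~ N(0,1): expect ~4.6% of trials outside +/- 2 SD
        rng = np.random.default_rng(2)
        excluded = total = 0
        for session in range(60):
            traces = [
                _session_trace(value=float(rng.standard_normal()), trial=k,
                               participant=f"p{session}")
                for k in range(40)
            ]
            m = preprocess_session(traces)
            excluded += len(m.excluded)
            total += 40
        frac = excluded / total
        assert 0.02 < frac < 0.08

    def test_short_fixation_rejected(self):
        tr = _session_trace()
        tr.t_stimulus_on = 0.3
        tr.t_outcome_on = 0.6
        with pytest.raises(ValueError, match="fixation"):
            preprocess_session([tr])

    def test_nan_input_rejected(self):
        d = np.full(_n(7.0), 5.0)
        d[100] = np.nan
        with pytest.raises(ValueError, match="blink"):
            preprocess_session([_trace(d)])

    def test_order_faithful(self):
        rng = np.random.default_rng(3)
        traces = [
            _session_trace(value=float(rng.normal(5, 0.1)), trial=k) for k in range(10)
        ]
        m1 = preprocess_session(traces)
        m2 = preprocess_session(traces[::-1])
        key = lambda m: m.index["trial"].to_numpy()
        order1 = np.argsort(key(m1))
        order2 = np.argsort(key(m2))
        assert np.allclose(m1.values[order1], m2.values[order2])

    def test_noiseless_baseline_recovers_tonic_exactly(self):
        spec = SyntheticPupilSpec(
            noise_sd=0.0, blink_rate=0.0, phasic_amplitude=0.0,
            constriction_amplitude=0.0,
            tonic_baseline={"placebo": 4321.0},
        )
        schedule = generate_task_schedule(rng_seed=0)
        traces = generate_pupil_dataset(spec, schedule, rng_seed=1)
        matrix = preprocess_traces(traces)
        assert np.median(matrix.baselines) == pytest.approx(4321.0, abs=1e-9)

    def test_long_blink_trials_in_exclusion_ledger(self):
        spec = SyntheticPupilSpec(noise_sd=1.0, blink_rate=0.3, long_blink_prob=0.5)
        schedule = generate_task_schedule(rng_seed=2)
        traces = generate_pupil_dataset(spec, schedule, rng_seed=3)
        matrix = preprocess_traces(traces)
        assert (matrix.excluded["reason"] == "long-blink").any()
        assert len(matrix.index) + len(matrix.excluded) == 96


class TestTemporalDerivative:
    def test_quoted_example(self):
        assert temporal_derivative(np.array([1.0, 3.0, 2.0])).tolist() == [2.0, -1.0]

    def test_constant_gives_zeros(self):
        assert np.all(temporal_derivative(np.full(10, 4.2)) == 0)

    def test_ramp_gives_constant(self):
        x = np.arange(10) * 0.25
        assert np.allclose(temporal_derivative(x), 0.25)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            temporal_derivative(np.array([1.0]))


class TestZscoreWithin:
    def _matrix(self, blocks):
        from rlpupil.pupil.preprocess import PupilTrialMatrix

        values, rows = [], []
        for (pid, drug), mat in blocks.items():
            for k, row in enumerate(mat):
                values.append(row)
                rows.append(
                    {"participant_id": pid, "drug_state": drug,
                     "condition": "gain", "trial": k}
                )
        values = np.asarray(values, dtype=float)
        return PupilTrialMatrix(
            values=values,
            times=np.arange(values.shape[1]) * 0.002,
            index=pd.DataFrame(rows),
            baselines=np.zeros(len(values)),
        )

    def test_group_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        m = self._matrix({("p0", "placebo"): rng.normal(3, 2, (5, 20))})
        z = zscore_within(m)
        assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_hand_computed_example(self):
        m = self._matrix({("p0", "placebo"): np.array([[1.0], [2.0], [3.0]])})
        z = zscore_within(m)
        assert np.allclose(z.values.ravel(), [-1.0, 0.0, 1.0])  # ddof=1 SD

    def test_groups_are_independent(self):
        m = self._matrix(
            {
                ("p0", "placebo"): np.array([[1.0], [2.0], [3.0]]),
                ("p0", "atomoxetine"): np.array([[101.0], [102.0], [103.0]]),
            }
        )
        z = zscore_within(m)
        assert np.allclose(z.values[:3].ravel(), z.values[3:].ravel())

    def test_zero_variance_group_rejected(self):
        m = self._matrix({("p0", "placebo"): np.ones((3, 4))})
        with pytest.raises(ValueError, match="zero variance"):
            zscore_within(m)


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((10, 100))
        result = cluster_permutation_test(a, a.copy(), n_permutations=100, rng_seed=0)
        assert result.clusters == []

    def test_p_value_floor(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((12, 200))
        b = a - 3.0  # massive uniform effect
        result = cluster_permutation_test(a, b, n_permutations=200, rng_seed=1)
        assert result.clusters
        for c in result.clusters:
            assert c.p_value >= 1.0 / 201.0

    def test_injected_effect_detected_with_overlap(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((18, 500))
        b = rng.standard_normal((18, 500))
        b[:, 150:250] -= 1.0
        result = cluster_permutation_test(a, b, n_permutations=500, rng_seed=2)
        sig = result.significant()
        assert sig
        assert any(c.start_ms < 250 and c.end_ms >= 150 for c in sig)
        assert all(c.direction == "positive" for c in sig)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((2, 10)), np.zeros((2, 10)))

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((5, 10)), np.zeros((6, 10)))

    def test_participant_relabelling_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((9, 80))
        b = rng.standard_normal((9, 80))
        b[:, 30:50] -= 1.2
        r1 = cluster_permutation_test(a, b, n_permutations=300, rng_seed=3)
        perm = rng.permutation(9)
        r2 = cluster_permutation_test(a[perm], b[perm], n_permutations=300, rng_seed=3)
        assert [c.start_ms for c in r1.clusters] == [c.start_ms for c in r2.clusters]
        assert [c.cluster_mass for c in r1.clusters] == pytest.approx(
            [c.cluster_mass for c in r2.clusters]
        )

    def test_times_ms_labels_clusters(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((10, 50))
        b = a.copy()
        b[:, 10:20] -= 2.0
        times = np.arange(50) * 2.0  # 500 Hz in ms
        result = cluster_permutation_test(
            a, b, n_permutations=200, rng_seed=4, times_ms=times
        )
        sig = result.significant()
        assert sig and sig[0].start_ms == pytest.approx(20.0)


class TestTraceIO:
    def test_round_trip_preserves_missing(self, tmp_path):
        spec = SyntheticPupilSpec(noise_sd=2.0, blink_rate=0.3)
        schedule = generate_task_schedule(rng_seed=10)
        traces = generate_pupil_dataset(spec, schedule, rng_seed=11)[:10]
        path = tmp_path / "traces.csv"
        write_traces(traces, path)
        loaded = read_traces(path)
        assert len(loaded) == len(traces)
        by_key = {tr.key(): tr for tr in loaded}
        for tr in traces:
            other = by_key[tr.key()]
            assert np.allclose(tr.time, other.time)
            assert np.array_equal(np.isnan(tr.diameter), np.isnan(other.diameter))
            valid = ~np.isnan(tr.diameter)
            assert np.allclose(tr.diameter[valid], other.diameter[valid])
            assert other.t_outcome_on == pytest.approx(tr.t_outcome_on, abs=0.003)
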