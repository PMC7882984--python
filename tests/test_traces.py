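import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoresp import synth, traces


class TestWashout:
    @pytest.mark.parametrize("volume,flow,expected", [
        (2.6, 2000.0, 3.9),
        (2.6, 2500.0, 3.1),
        (1.0, 1000.0, np.log(20)),
    ])
    def test_known_equilibration_times(self, volume, flow, expected):
        assert traces.washout_t95(volume, flow) == pytest.approx(expected,
                                                                 abs=0.05)

    @given(st.floats(0.1, 50), st.floats(100, 10000), st.floats(1.1, 10))
    def test_homogeneity(self, volume, flow, c):
        base = traces.washout_t95(volume, flow)
        assert traces.washout_t95(c * volume, c * flow) == pytest.approx(base)
        assert traces.washout_t95(volume, c * flow) == pytest.approx(base / c)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            traces.washout_t95(0.0, 2000.0)
        with pytest.raises(ValueError):
            traces.washout_t95(2.6, -1.0)


def _trace_with_baselines(n=4000, base_s=400, drift_total=0.0, ref=0.2095):
    t = np.arange(n, dtype=float)
    v = np.full(n, ref) + drift_total * t / (n - 1)
    segments = [(0.0, float(base_s)), (float(n - base_s), float(n))]
    return t, v, segments


class TestDriftCorrection:
    def test_clean_trace_unchanged(self):
        t, v, segs = _trace_with_baselines()
        out = traces.correct_drift(t, v, segs, 0.2095)
        assert np.allclose(out, v, atol=1e-12)

    def test_affine_drift_removed_exactly(self):
        # analyzer drifting +0.0005 O2 fraction over the run
        t, v, segs = _trace_with_baselines(drift_total=5e-4)
        out = traces.correct_drift(t, v, segs, 0.2095)
        for s, e in segs:
            mask = (t >= s) & (t < e)
            assert abs(out[mask].mean() - 0.2095) < 1e-6

    def test_idempotent(self):
        t, v, segs = _trace_with_baselines(drift_total=3e-4)
        once = traces.correct_drift(t, v, segs, 0.2095)
        twice = traces.correct_drift(t, once, segs, 0.2095)
        assert np.allclose(once, twice, atol=1e-12)

    @given(st.floats(-1e-3, 1e-3), st.floats(-1e-3, 1e-3))
    def test_exact_for_any_affine_drift(self, offset, total):
        t, v, segs = _trace_with_baselines()
        drifted = v + offset + total * t / t[-1]
        out = traces.correct_drift(t, drifted, segs, 0.2095)
        assert np.allclose(out, v, atol=1e-9)

    def test_single_baseline_rejected(self):
        t, v, _ = _trace_with_baselines()
        with pytest.raises(ValueError):
            traces.correct_drift(t, v, [(0.0, 400.0)], 0.2095)


def _oracle_window(x, w):
    """Exhaustive stable-window scan (independent of the implementation)."""
    best_i, best_v = 0, np.inf
    for i in range(len(x) - w + 1):
        v = np.var(x[i:i + w])
        if v < best_v - 1e-15:
            best_i, best_v = i, v
    return best_i, best_v


class TestStableWindow:
    def test_constant_trace_picks_earliest(self):
        start, var = traces.find_stable_window(np.full(900, 0.2), 300)
        assert start == 0
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_noise_burst_pushes_window_to_quiet_half(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 5e-4, 450), rng.normal(0, 5e-6, 450)])
        start, var = traces.find_stable_window(x, 300)
        oi, ov = _oracle_window(x, 300)
        assert start >= 450
        assert start == oi
        assert var == pytest.approx(ov, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.208, 1e-4, 700) + 1e-4 * np.sin(
            np.arange(700) / rng.integers(20, 120))
        start, var = traces.find_stable_window(x, 300)
        oi, ov = _oracle_window(x, 300)
        assert var == pytest.approx(ov, rel=1e-9)
        assert start == oi

    def test_short_step_rejected(self):
        with pytest.raises(ValueError):
            traces.find_stable_window(np.zeros(299), 300)


class TestSensorAgreement:
    def test_identical_pairs(self):
        assert traces.sensor_agreement([40, 42], [40, 42]) == (0.0, 0.0)

    def test_constant_offset(self):
        mean, sd = traces.sensor_agreement([40, 42, 44], [40.2, 42.2, 44.2])
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_calibration_style_offset_with_noise(self):
        rng = np.random.default_rng(0)
        core = np.repeat(np.arange(40, 47, 2.0), 8)
        ref = core + 0.2 + rng.normal(0, 0.05, core.size)
        mean, sd = traces.sensor_agreement(core, ref)
        assert mean == pytest.approx(0.2, abs=0.05)
        assert sd < 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            traces.sensor_agreement([40.0], [40.2])


class TestSummarizeSession:
    def test_truncated_run_keeps_completed_steps_only(self):
        from conftest import zero_variance_population
        pop = zero_variance_population()
        pop.tb_base_C = 44.2
        pop.psi_tb_C = 30.0
        bird = synth.sample_birds(1, pop, seed=0)[0]
        session = synth.simulate_session(bird, noise=synth.SessionNoise.zero())
        assert session.truth["truncated"]
        summary, excl = traces.summarize_session(session)
        completed = session.steps[session.steps.completed]
        assert set(summary.step_index) == set(completed.step_index)
        assert any("truncated" in e["reason"] for e in excl)

    def test_restless_session_yields_empty_summary(self, noiseless_session):
        """Steps without 5 min of calm chamber data are all excluded."""
        short = synth.RespirometrySession(
            bird_id=noiseless_session.bird_id,
            data=noiseless_session.data,
            steps=noiseless_session.steps.assign(
                end_s=noiseless_session.steps.start_s + 200),
            mass_g=noiseless_session.mass_g,
            flow_ml_min=noiseless_session.flow_ml_min,
            chamber_volume_L=noiseless_session.chamber_volume_L,
            fasted_min=noiseless_session.fasted_min,
            rq=noiseless_session.rq, seed=None,
            truth=noiseless_session.truth)
        summary, excl = traces.summarize_session(short)
        assert summary.empty
        assert len(excl) == len(short.steps)

    def test_windows_are_traceable(self, noiseless_session):
        summary, _ = traces.summarize_session(noiseless_session)
        assert ((summary.window_end_s - summary.window_start_s) == 300).all()
        for row in summary.itertuples():
            step = noiseless_session.steps.iloc[row.step_index]
            assert step.start_s <= row.window_start_s < row.window_end_s <= step.end_s
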