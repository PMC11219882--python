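import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclequant import phasecall as pc
from cyclequant import simulate as sim


def cycle_waveform(g1s=50, sg2=100, end=115, plateau=3000.0,
                   halvings_per_frame=1.0, rise_per_frame=360.0):
    """Noiseless degron-reporter waveform with known transition frames."""
    f = np.arange(end + 1, dtype=float)
    v = np.full(end + 1, plateau)
    decay = plateau * 0.5 ** (halvings_per_frame * (f - g1s))
    v[f > g1s] = decay[f > g1s]
    v[v < 1.0] = 0.0
    rise = np.minimum(plateau, rise_per_frame * (f - sg2))
    v[f >= sg2] = np.maximum(v[f >= sg2], rise[f >= sg2])
    return v


class TestNormalizeTrace:
    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(100, 4000, 50)
        n1, s1 = pc.normalize_trace(v)
        n2, s2 = pc.normalize_trace(3.7 * v + 250.0)
        np.testing.assert_allclose(n1, n2, atol=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_constant_trace(self):
        n, s = pc.normalize_trace(np.full(20, 123.0))
        assert (n == 0).all()
        assert s == 0.0

    def test_plateau_normalizes_high(self):
        v = cycle_waveform()
        n, _ = pc.normalize_trace(v)
        assert n[10:45].min() >= 0.9

    def test_order_preserved(self):
        v = np.array([5.0, 1.0, 3.0, 9.0, 2.0, 8.0])
        n, _ = pc.normalize_trace(v)
        assert list(np.argsort(n)) == list(np.argsort(v))

    def test_too_short(self):
        with pytest.raises(ValueError):
            pc.normalize_trace(np.ones(3))


class TestCallG1s:
    def test_one_halving_per_frame_returns_51(self):
        # decay at one halving per frame from frame 50: first frame at or
        # below half the plateau is 51
        v = cycle_waveform(g1s=50, halvings_per_frame=1.0)
        idx, plateau = pc.call_g1s(v)
        assert idx == 51
        assert plateau == pytest.approx(1.0, abs=0.05)

    def test_constant_trace_no_call(self):
        idx, _ = pc.call_g1s(np.full(50, 2000.0))
        assert idx is None

    def test_affine_invariance(self):
        v = cycle_waveform()
        i1, _ = pc.call_g1s(v)
        i2, _ = pc.call_g1s(0.1 * v + 777.0)
        assert i1 == i2

    def test_g2_rise_does_not_shift_reference(self):
        # the running-maximum plateau ignores the later G2 re-rise
        v = cycle_waveform(g1s=40, sg2=80, end=120, rise_per_frame=500.0)
        idx, _ = pc.call_g1s(v)
        assert idx == 41


class TestCallSg2:
    def test_noiseless_rise_within_one_frame(self):
        v = cycle_waveform(g1s=50, sg2=100, end=115)
        g1s, plateau = pc.call_g1s(v)
        idx = pc.call_sg2(v, g1s, plateau)
        assert idx is not None
        assert abs(idx - 100) <= 1

    def test_flat_after_g1s_no_call(self):
        v = cycle_waveform(g1s=50, sg2=100, end=115)
        v[100:] = v[99]  # never rises again
        g1s, plateau = pc.call_g1s(v)
        assert pc.call_sg2(v, g1s, plateau) is None

    def test_single_frame_spike_not_called(self):
        v = cycle_waveform(g1s=50, sg2=100, end=115)
        v[70] = 900.0  # isolated spike during S, well above delta
        g1s, plateau = pc.call_g1s(v)
        idx = pc.call_sg2(v, g1s, plateau)
        assert abs(idx - 100) <= 1  # spike at 70 ignored


class TestPhaseLengths:
    def test_arithmetic(self):
        calls = pc.phase_lengths(30, 80, 116, 131, frame_interval=10.0)
        assert calls.g1_h == pytest.approx(50 / 6)
        assert calls.s_h == pytest.approx(6.0)
        assert calls.g2m_h == pytest.approx(2.5)
        assert calls.total_h == pytest.approx(101 / 6)
        assert calls.g1_h + calls.s_h + calls.g2m_h == pytest.approx(
            calls.total_h)

    def test_degenerate_ordering_errors(self):
        with pytest.raises(ValueError):
            pc.phase_lengths(30, 80, 80, 131, 10.0)

    def test_batch_sum_identity(self, trace_cfg, trace_lineage, trace_traces):
        cc = trace_lineage.completed_cycles()
        checked = 0
        for r in cc.head(30).itertuples():
            ct = sim.cycle_trace(trace_lineage, trace_traces, int(r.cell_id))
            calls = pc.call_cycle(ct["venus_mean"].to_numpy(),
                                  int(r.birth_frame), trace_cfg.frame_interval)
            if calls.ok:
                assert calls.g1_h + calls.s_h + calls.g2m_h == pytest.approx(
                    calls.total_h)
                checked += 1
        assert checked >= 25


class TestRecovery:
    def test_noiseless_recovery_within_one_frame(self, trace_cfg,
                                                 trace_lineage, trace_traces):
        cc = trace_lineage.completed_cycles()
        assert len(cc) >= 30
        for r in cc.itertuples():
            ct = sim.cycle_trace(trace_lineage, trace_traces, int(r.cell_id))
            calls = pc.call_cycle(ct["venus_mean"].to_numpy(),
                                  int(r.birth_frame), trace_cfg.frame_interval)
            assert calls.ok
            assert abs(calls.g1s_frame - r.g1s_frame) <= 1
            assert abs(calls.sg2_frame - r.sg2_frame) <= 1

    def test_noisy_recovery_median_error(self, trace_cfg, trace_lineage,
                                         trace_traces):
        noisy = sim.apply_trace_noise(trace_traces, trace_cfg, seed=21)
        errs_g1s, errs_sg2 = [], []
        for r in trace_lineage.completed_cycles().itertuples():
            ct = sim.cycle_trace(trace_lineage, noisy, int(r.cell_id))
            calls = pc.call_cycle(ct["venus_mean"].to_numpy(),
                                  int(r.birth_frame), trace_cfg.frame_interval)
            if calls.ok:
                errs_g1s.append(abs(calls.g1s_frame - r.g1s_frame))
                errs_sg2.append(abs(calls.sg2_frame - r.sg2_frame))
        assert len(errs_g1s) >= 30
        assert np.median(errs_g1s) <= 1.0
        assert np.median(errs_sg2) <= 1.0

    def test_noise_monotonicity(self, trace_cfg, trace_lineage, trace_traces):
        # the median absolute transition error never improves with noise
        cc = trace_lineage.completed_cycles()
        medians = []
        for mult in (0.0, 0.05, 0.15, 0.4):
            import dataclasses
            cfg = dataclasses.replace(
                trace_cfg, noise_mult_sigma=mult,
                noise_read_sigma=trace_cfg.noise_read_sigma * (
                    mult / 0.03 if mult else 0.0))
            noisy = sim.apply_trace_noise(trace_traces, cfg, seed=33)
            errs = []
            for r in cc.itertuples():
                ct = sim.cycle_trace(trace_lineage, noisy, int(r.cell_id))
                calls = pc.call_cycle(ct["venus_mean"].to_numpy(),
                                      int(r.birth_frame),
                                      trace_cfg.frame_interval)
                if calls.ok:
                    errs.append(abs(calls.g1s_frame - r.g1s_frame))
                    errs.append(abs(calls.sg2_frame - r.sg2_frame))
            medians.append(np.median(errs))
        assert all(b >= a for a, b in zip(medians, medians[1:]))


class TestFucciCycle:
    def test_recovery_inside_window(self):
        cfg = sim.SimConfig(construct="PIP_FUCCI", n_founders=8,
                            duration=2880, seed=13)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        n_frames = lin.n_frames
        checked = 0
        for r in lin.completed_cycles().itertuples():
            ct = sim.cycle_trace(lin, traces, int(r.cell_id))
            frames = ct["frame"].to_numpy()
            v = np.zeros(n_frames)
            c = np.zeros(n_frames)
            v[frames] = ct["venus_mean"].to_numpy()
            c[frames] = ct["red_mean"].to_numpy()
            res = pc.call_fucci_cycle(v, c, n_frames, cfg.frame_interval,
                                      start_frame=int(r.birth_frame))
            if res.excluded_reason is not None:
                continue
            assert res.calls.ok
            assert abs(res.calls.g1s_frame - r.g1s_frame) <= 1
            assert abs(res.calls.sg2_frame - r.sg2_frame) <= 1
            assert res.calls.end_frame == r.division_frame
            checked += 1
        assert checked >= 10

    def test_too_early_exclusion(self):
        v = np.zeros(300)
        c = np.zeros(300)
        res = pc.call_fucci_cycle(v, c, 300, 10.0, start_frame=24)  # 4 h
        assert res.excluded_reason == pc.TOO_EARLY

    def test_too_late_exclusion(self):
        v = np.zeros(300)
        c = np.zeros(300)
        res = pc.call_fucci_cycle(v, c, 300, 10.0, start_frame=186)
        # 299 - 186 = 113 frames = 18.8 h < 20 h before the end
        assert res.excluded_reason == pc.TOO_LATE

    def test_boundary_inclusions(self):
        v = np.zeros(300)
        c = np.zeros(300)
        res = pc.call_fucci_cycle(v, c, 300, 10.0, start_frame=30)  # 5 h
        assert res.excluded_reason != pc.TOO_EARLY
        res = pc.call_fucci_cycle(v, c, 300, 10.0, start_frame=179)  # 20 h
        assert res.excluded_reason != pc.TOO_LATE


class TestClassifySnapshot:
    BG = (200.0, 30.0)

    def _nuclei(self, rows):
        return pd.DataFrame(rows, columns=["venus_mean", "red_mean"])

    def test_class_mapping(self):
        nuclei = self._nuclei([(4000.0, 210.0),   # G1/G0
                               (205.0, 3000.0),   # S
                               (4000.0, 3000.0),  # G2/M
                               (210.0, 190.0)])   # indeterminate
        table, fr = pc.classify_snapshot(nuclei, self.BG, self.BG, k=3)
        assert list(table["phase_class"]) == ["G1/G0", "S", "G2/M",
                                              "indeterminate"]
        assert fr["n_indeterminate"] == 1
        assert fr["G1/G0"] + fr["S"] + fr["G2/M"] == pytest.approx(1.0)

    def test_fold_indeterminate_into_s(self):
        nuclei = self._nuclei([(210.0, 190.0)])
        table, _ = pc.classify_snapshot(nuclei, self.BG, self.BG, k=3,
                                        fold_indeterminate_into_s=True)
        assert list(table["phase_class"]) == ["S"]

    def test_empty(self):
        table, fr = pc.classify_snapshot(self._nuclei([]), self.BG, self.BG)
        assert table.empty and fr == {}

    def test_monte_carlo_mix_recovery(self):
        mix = {"G1": 0.6, "S": 0.3, "G2M": 0.1}
        cfg = sim.SimConfig(seed=17)
        n = 500
        nuclei = sim.sample_snapshot(cfg, mix, n)
        _, fr = pc.classify_snapshot(nuclei, self.BG, self.BG, k=3)
        # recovered fractions within binomial 95% bounds of the generator mix
        for cls, p in (("G1/G0", 0.6), ("S", 0.3), ("G2/M", 0.1)):
            bound = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(fr[cls] - p) <= bound

    def test_background_model(self):
        rng = np.random.default_rng(5)
        img = rng.normal(200, 30, (64, 64))
        labels = np.zeros((64, 64), dtype=int)
        labels[10:20, 10:20] = 1
        img[labels == 1] = 5000
        med, mad = pc.background_model(img, labels)
        assert med == pytest.approx(200, abs=5)
        assert mad == pytest.approx(20, abs=5)


@settings(max_examples=30, deadline=None)
@given(st.floats(0.01, 100.0), st.floats(-1000.0, 1000.0),
       st.integers(0, 2**31 - 1))
def test_calls_affine_invariant(scale, shift, seed):
    rng = np.random.default_rng(seed)
    v = cycle_waveform() + rng.normal(0, 20, 116)
    v = np.clip(v, 0, None)
    c1 = pc.call_cycle(v, 0, 10.0)
    c2 = pc.call_cycle(scale * v + shift, 0, 10.0)
    assert c1.g1s_frame == c2.g1s_frame
    assert c1.sg2_frame == c2.sg2_frame
    assert c1.flags == c2.flags
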