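import numpy as np
import pandas as pd
import pytest

from cyclequant import Construct, SimConfig
from cyclequant import simulate as sim


class TestSampleLineage:
    def test_zero_dispersion_limit(self):
        # with no spread every completed G1 equals the configured median
        cfg = SimConfig(n_founders=5, duration=2880, seed=2,
                        phase_dispersions={"G1": 0.0, "S": 0.0, "G2M": 0.0})
        lin = sim.sample_lineage(cfg)
        cc = lin.completed_cycles()
        assert len(cc) > 0
        g1_minutes = (cc["g1s_frame"] - cc["birth_frame"]) * cfg.frame_interval
        # both boundaries round independently: up to half a frame each
        assert np.all(np.abs(g1_minutes - 8.3 * 60)
                      <= cfg.frame_interval + 1e-9)

    def test_determinism(self):
        cfg = SimConfig(n_founders=6, duration=1440, seed=11)
        a = sim.sample_lineage(cfg)
        b = sim.sample_lineage(cfg)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.positions, b.positions)

    def test_phase_sum_identity(self, small_lineage):
        cc = small_lineage.completed_cycles()
        total = cc["division_frame"] - cc["birth_frame"]
        parts = ((cc["g1s_frame"] - cc["birth_frame"])
                 + (cc["sg2_frame"] - cc["g1s_frame"])
                 + (cc["division_frame"] - cc["sg2_frame"]))
        assert (parts == total).all()

    def test_ordering_invariant(self, small_lineage):
        cc = small_lineage.completed_cycles()
        assert (cc["birth_frame"] < cc["g1s_frame"]).all()
        assert (cc["g1s_frame"] < cc["sg2_frame"]).all()
        assert (cc["sg2_frame"] < cc["division_frame"]).all()

    def test_daughter_birth_equals_parent_division(self, small_lineage):
        cells = small_lineage.cells.set_index("cell_id")
        kids = cells[cells["parent_id"] >= 0]
        for r in kids.itertuples():
            assert r.birth_frame == cells.loc[r.parent_id, "division_frame"]

    def test_degenerate_config_errors(self):
        cfg = SimConfig(n_founders=0)
        with pytest.raises(ValueError):
            sim.sample_lineage(cfg)

    def test_monte_carlo_phase_quantiles(self):
        # 10k draws must land on the configured lognormal quantiles
        cfg = SimConfig(seed=5)
        draws = sim.sample_phase_durations(cfg, 10_000)
        med = draws["G1"].median()
        q1, q3 = draws["G1"].quantile([0.25, 0.75])
        assert med == pytest.approx(8.3, rel=0.02)
        assert q1 == pytest.approx(6.2, rel=0.05)
        assert q3 == pytest.approx(11.3, rel=0.05)


class TestReporterTraces:
    def test_decay_below_half_next_frame(self, trace_cfg, trace_lineage,
                                         trace_traces):
        # exponential decay: one frame after G1/S the signal is <= half
        cc = trace_lineage.completed_cycles()
        merged = trace_traces.merge(
            cc[["cell_id", "g1s_frame"]], on="cell_id")
        after = merged[merged["frame"] == merged["g1s_frame"] + 1]
        assert len(after) > 0
        assert (after["venus_mean"] <= 0.5 * trace_cfg.venus_plateau).all()

    def test_h2a_spike_exceeds_slope_threshold(self, trace_cfg, trace_lineage,
                                               trace_traces):
        cc = trace_lineage.completed_cycles()
        for cell_id in cc["cell_id"].head(10):
            ct = sim.cycle_trace(trace_lineage, trace_traces, int(cell_id))
            diffs = np.abs(np.diff(ct["red_max"].to_numpy()))
            assert diffs.max() > 300.0

    def test_spike_is_per_cycle_maximum(self, trace_lineage, trace_traces):
        cc = trace_lineage.completed_cycles()
        for cell_id in cc["cell_id"].head(10):
            ct = sim.cycle_trace(trace_lineage, trace_traces, int(cell_id))
            red = ct["red_mean"].to_numpy()
            # spikes sit at both cycle boundaries; interior stays below
            assert red[1:-1].max() < max(red[0], red[-1])

    def test_fucci_early_s_gap(self):
        cfg = SimConfig(construct=Construct.PIP_FUCCI, n_founders=8,
                        duration=2160, seed=9)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        delay = int(cfg.cherry_onset_delay / cfg.frame_interval)
        cc = lin.completed_cycles()
        checked = 0
        for r in cc.itertuples():
            ct = sim.cycle_trace(lin, traces, int(r.cell_id)).set_index("frame")
            span_min = (r.division_frame - r.g1s_frame) * cfg.frame_interval
            cherry_plateau = cfg.cherry_ramp_rate * span_min
            for f in range(r.g1s_frame + 1, r.g1s_frame + delay + 1):
                assert ct.loc[f, "venus_mean"] < 0.1 * cfg.venus_plateau
                assert ct.loc[f, "red_mean"] < 0.1 * cherry_plateau
                checked += 1
        assert checked > 0

    def test_fucci_division_drop(self):
        cfg = SimConfig(construct=Construct.PIP_FUCCI, n_founders=8,
                        duration=2160, seed=9)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        for r in lin.completed_cycles().head(8).itertuples():
            ct = sim.cycle_trace(lin, traces, int(r.cell_id))
            red = ct["red_mean"].to_numpy()
            assert red[-1] <= 0.1 * red[-2]  # >= 90% drop in one frame

    def test_short_cycles_flagged_unusable(self):
        cfg = SimConfig(n_founders=2, duration=120, seed=4,
                        phase_medians={"G1": 0.05, "S": 0.05, "G2M": 0.05},
                        phase_dispersions={"G1": 0.0, "S": 0.0, "G2M": 0.0})
        lin = sim.sample_lineage(cfg)
        assert not lin.cells["usable"].any()
        traces = sim.reporter_traces(lin, cfg)
        assert traces.empty


class TestRenderMovie:
    def test_empty_scene(self):
        cfg = SimConfig(n_founders=1, duration=100, image_size=(64, 64),
                        seed=1, noise_mult_sigma=0.0, noise_read_sigma=0.0)
        lin = sim.sample_lineage(cfg)
        # drop all cells: empty positions and traces
        lin.positions = lin.positions.iloc[0:0]
        movie = sim.render_movie(lin, sim.reporter_traces(lin, cfg).iloc[0:0],
                                 cfg)
        assert (movie.labels == 0).all()
        assert (movie.venus == int(cfg.background_level)).all()

    def test_noiseless_peak_closed_form(self):
        cfg = SimConfig(n_founders=1, duration=100, image_size=(64, 64),
                        seed=1, noise_mult_sigma=0.0, noise_read_sigma=0.0,
                        motion_sigma=0.0)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        movie = sim.render_movie(lin, traces, cfg)
        p = lin.positions.iloc[0]
        t0 = traces[(traces["cell_id"] == p["cell_id"])
                    & (traces["frame"] == p["frame"])].iloc[0]
        px = movie.venus[int(p["frame"]), int(round(p["y_um"])),
                         int(round(p["x_um"]))]
        # pixel-center offset keeps the sampled value within a few percent
        expected = cfg.background_level + t0["venus_mean"]
        assert abs(float(px) - expected) <= 0.05 * expected

    def test_label_count_matches_live_cells(self, small_lineage, small_movie):
        for f in (0, 50, 100):
            n_live = (small_lineage.positions["frame"] == f).sum()
            n_labels = len(np.unique(small_movie.labels[f])) - 1
            assert n_labels == n_live

    def test_render_determinism(self):
        cfg = SimConfig(n_founders=3, duration=200, image_size=(64, 64),
                        seed=6)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        a = sim.render_movie(lin, traces, cfg)
        b = sim.render_movie(lin, traces, cfg)
        assert np.array_equal(a.venus, b.venus)
        assert np.array_equal(a.red, b.red)
        assert np.array_equal(a.labels, b.labels)


class TestWriteFixture:
    def test_round_trip(self, tmp_path):
        from cyclequant import io
        cfg = SimConfig(n_founders=3, duration=300, image_size=(64, 64),
                        seed=8)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        movie = sim.render_movie(lin, traces, cfg)
        files = sim.write_fixture(lin, traces, movie, cfg, tmp_path / "fx")
        labels_back = io.read_labels(files["labels"])
        assert np.array_equal(labels_back, movie.labels)
        venus_back = io.read_stack(files["venus"])
        assert np.array_equal(venus_back, movie.venus)
        cfg_back = SimConfig.from_yaml(files["config"])
        assert cfg_back.seed == cfg.seed
        assert cfg_back.phase_medians == cfg.phase_medians

    def test_truth_table_row_counts(self, tmp_path):
        cfg = SimConfig(n_founders=3, duration=300, image_size=(64, 64),
                        seed=8)
        lin = sim.sample_lineage(cfg)
        traces = sim.reporter_traces(lin, cfg)
        files = sim.write_fixture(lin, traces, None, cfg, tmp_path / "fx")
        pos = pd.read_csv(files["truth_positions"])
        assert len(pos) == len(lin.positions)  # sum over cells x frames alive
        cells = pd.read_csv(files["truth_cells"])
        assert len(cells) == len(lin.cells)


class TestTraceNoise:
    def test_noise_deterministic(self, small_cfg, small_traces):
        a = sim.apply_trace_noise(small_traces, small_cfg, seed=5)
        b = sim.apply_trace_noise(small_traces, small_cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_nonnegative(self, small_cfg, small_traces):
        noisy = sim.apply_trace_noise(small_traces, small_cfg, seed=5)
        assert (noisy[["venus_mean", "red_mean"]] >= 0).all().all()
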