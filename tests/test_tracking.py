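import numpy as np
import pytest
from hypothesis import given, strategies as st

from axotrace import (ConfigurationError, Kymograph, TransportSimConfig,
                      simulate_transport)
from axotrace.tracking import (ANTEROGRADE, MOTILE, RETROGRADE, STATIONARY,
                               UNCLASSIFIED, RunRuleConfig, Track,
                               assign_direction, classify_stationary,
                               diffusion_bound, extract_tracks, segment_track)
from conftest import random_walk_track
from _oracles import brute_force_segment

DT = 1.0


def make_track(positions, track_id=0):
    positions = np.asarray(positions, dtype=float)
    return Track(track_id, np.arange(len(positions)), positions)


class TestDiffusionBound:
    def test_printed_values(self):
        # D = 0.01 um^2/s over t = 50 s -> exactly 1.0 um
        assert diffusion_bound(0.01, 50.0) == pytest.approx(1.0)

    def test_zero(self):
        assert diffusion_bound(0.0, 123.0) == 0.0

    @given(st.floats(1e-6, 10.0), st.floats(1e-6, 1e4))
    def test_sqrt_scaling(self, D, t):
        assert diffusion_bound(4 * D, t) == pytest.approx(2 * diffusion_bound(D, t))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diffusion_bound(-0.01, 50.0)
        with pytest.raises(ValueError):
            diffusion_bound(0.01, -1.0)


class TestRunRuleConfig:
    def test_default_threshold_dominates_diffusion(self):
        rules = RunRuleConfig()
        assert rules.run_threshold >= diffusion_bound(rules.diffusion_coeff,
                                                      rules.diffusion_horizon)

    def test_threshold_below_bound_rejected(self):
        with pytest.raises(ConfigurationError):
            RunRuleConfig(run_threshold=0.5, diffusion_coeff=0.01,
                          diffusion_horizon=50.0, stationary_threshold=0.5)


class TestSegmentTrack:
    def test_monotone_run(self, rules):
        track = make_track(np.arange(11, dtype=float))  # 10 um over 10 s
        runs, pauses = segment_track(track, rules, DT)
        assert len(runs) == 1 and not pauses
        assert runs[0].direction == ANTEROGRADE
        assert runs[0].displacement_um == pytest.approx(10.0)
        assert runs[0].mean_speed_um_s == pytest.approx(1.0)

    def test_below_threshold_not_emitted(self, rules):
        track = make_track(np.cumsum([0.0] + [0.49] * 10))  # 4.9 um
        runs, _ = segment_track(track, rules, DT)
        assert runs == []

    def test_exactly_at_threshold_emitted(self, rules):
        track = make_track(np.cumsum([0.0] + [0.5] * 10))  # 5.0 um
        runs, _ = segment_track(track, rules, DT)
        assert len(runs) == 1
        assert runs[0].displacement_um == pytest.approx(5.0)

    def test_run_stall_reversal_example(self, rules):
        # 6 um anterograde, 5-frame stall, 7 um retrograde
        positions = list(np.arange(7.0)) + [6.0] * 4 + list(np.arange(5.0, -2.0, -1.0))
        runs, pauses = segment_track(make_track(positions), rules, DT)
        assert [r.direction for r in runs] == [ANTEROGRADE, RETROGRADE]
        assert runs[0].displacement_um == pytest.approx(6.0)
        assert runs[1].displacement_um == pytest.approx(7.0)
        assert len(pauses) == 1
        assert pauses[0].direction == ANTEROGRADE

    def test_short_stall_does_not_terminate(self, rules):
        # 3-frame stall (2 zero steps) is below the 4-frame rule
        positions = list(np.arange(4.0)) + [3.0] * 2 + list(np.arange(4.0, 8.0))
        runs, pauses = segment_track(make_track(positions), rules, DT)
        assert len(runs) == 1 and not pauses
        assert runs[0].displacement_um == pytest.approx(7.0)
        # stalled frames excluded from duration: 7 of the 9 steps move
        assert runs[0].duration_s == pytest.approx(7.0)

    def test_requires_two_points(self, rules):
        with pytest.raises(ValueError):
            segment_track(make_track([1.0]), rules, DT)

    def test_gap_split(self, rules, caplog):
        frames = np.concatenate([np.arange(10), np.arange(30, 40)])
        positions = np.concatenate([np.arange(10.0), np.arange(10.0)])
        track = Track(0, frames, positions)
        runs, _ = segment_track(track, rules, DT)
        assert len(runs) == 2  # two 9-um pieces, not one 39-frame run

    def test_matches_brute_force_on_battery(self, rules):
        rng = np.random.default_rng(99)
        for trial in range(250):
            n = int(rng.integers(5, 31))
            x = random_walk_track(rng, n, rules.same_position_tol)
            runs, pauses = segment_track(make_track(x), rules, DT)
            oruns, opauses = brute_force_segment(
                x, DT, rules.same_position_tol, rules.pause_min_frames,
                rules.run_threshold)
            got = [(r.direction, r.start_frame, r.end_frame,
                    round(r.displacement_um, 9), round(r.duration_s, 9))
                   for r in runs]
            want = [(d, a, b, round(disp, 9), round(dur, 9))
                    for d, a, b, disp, dur in oruns]
            assert got == want, f"trial {trial}"
            assert [(p.start_frame, p.end_frame, round(p.duration_s, 9))
                    for p in pauses] == [(a, b, round(dur, 9))
                                         for a, b, dur in opauses]

    def test_time_reversal_flips_directions(self, rules):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = random_walk_track(rng, int(rng.integers(6, 40)),
                                  rules.same_position_tol)
            fwd, _ = segment_track(make_track(x), rules, DT)
            rev, _ = segment_track(make_track(x[::-1]), rules, DT)
            flip = {ANTEROGRADE: RETROGRADE, RETROGRADE: ANTEROGRADE}
            fwd_set = sorted((flip[r.direction], round(r.displacement_um, 9),
                              round(r.duration_s, 9)) for r in fwd)
            rev_set = sorted((r.direction, round(r.displacement_um, 9),
                              round(r.duration_s, 9)) for r in rev)
            assert fwd_set == rev_set

    def test_idempotent(self, rules):
        x = random_walk_track(np.random.default_rng(1), 25, rules.same_position_tol)
        first = segment_track(make_track(x), rules, DT)
        second = segment_track(make_track(x), rules, DT)
        assert repr(first) == repr(second)

    def test_emitted_runs_respect_threshold(self, rules):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = random_walk_track(rng, 40, rules.same_position_tol)
            runs, _ = segment_track(make_track(x), rules, DT)
            for r in runs:
                assert r.displacement_um >= rules.run_threshold


class TestClassifyStationary:
    def test_constant_track(self, rules):
        track = make_track([5.0] * 50)
        assert classify_stationary(track, rules, 50.0, DT) == STATIONARY

    def test_boundary_4p9_vs_5p0(self, rules):
        base = make_track(np.cumsum([0.0] + [0.49] * 10 + [0.0] * 40))
        assert classify_stationary(base, rules, 50.0, DT) == STATIONARY
        moved = make_track(np.cumsum([0.0] + [0.5] * 10 + [0.0] * 40))
        assert classify_stationary(moved, rules, 50.0, DT) == MOTILE

    def test_short_quiet_track_unclassified(self, rules):
        track = make_track([3.0] * 10)
        assert classify_stationary(track, rules, 100.0, DT) == UNCLASSIFIED

    def test_short_fast_track_is_motile(self, rules):
        # motility is falsifiable even on a short observation
        track = make_track(np.arange(0.0, 8.0))
        assert classify_stationary(track, rules, 100.0, DT) == MOTILE

    def test_planted_fraction_recovered_exactly(self, rules):
        cfg = TransportSimConfig(n_particles=20, stationary_fraction=0.5,
                                 n_frames=120, seed=42)
        _, truth = simulate_transport(cfg, render=False)
        classes = [classify_stationary(tr, rules, cfg.duration_s, cfg.frame_interval)
                   for tr in truth.tracks()]
        frac = classes.count(STATIONARY) / len(classes)
        assert frac == pytest.approx(0.5)


class TestAssignDirection:
    def test_positive_is_anterograde(self):
        assert assign_direction(2.0) == ANTEROGRADE
        assert assign_direction(-2.0) == RETROGRADE

    def test_mirrored_orientation_flips(self):
        assert assign_direction(2.0, away_from_soma_positive=False) == RETROGRADE

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            assign_direction(0.0)

    def test_agrees_with_ground_truth_on_noiseless_tracks(self, rules):
        cfg = TransportSimConfig(n_particles=6, stationary_fraction=0.0,
                                 n_frames=100, seed=17)
        _, truth = simulate_transport(cfg, render=False)
        true_runs = truth.run_table()
        directed = true_runs[true_runs.displacement_um >= rules.run_threshold]
        got = []
        for tr in truth.tracks():
            runs, _ = segment_track(tr, rules, cfg.frame_interval)
            got += [r.direction for r in runs]
        assert sorted(got) == sorted(directed["direction"])


def _kymograph_from_lines(lines, n_frames=40, n_cols=80, pixel_size=0.16, dt=1.0):
    """Noiseless kymograph with Gaussian-profile lines col = x0 + v*frame."""
    data = np.zeros((n_frames, n_cols))
    cols = np.arange(n_cols, dtype=float)
    for x0, v in lines:
        for f in range(n_frames):
            c = x0 + v * f
            data[f] += 100.0 * np.exp(-0.5 * ((cols - c) / 1.2) ** 2)
    return Kymograph(data, pixel_size, dt)


class TestExtractTracks:
    def test_single_line_single_track(self):
        kym = _kymograph_from_lines([(10.0, 1.0)])
        tracks = extract_tracks(kym, min_frames=5)
        assert len(tracks) == 1
        expected = kym.column_to_um(10.0 + np.arange(40))
        np.testing.assert_allclose(tracks[0].positions_um, expected, atol=0.5 * 0.16)

    def test_two_parallel_lines_two_tracks(self):
        kym = _kymograph_from_lines([(10.0, 0.5), (40.0, 0.5)])
        tracks = extract_tracks(kym, min_frames=5)
        assert len(tracks) == 2
        starts = sorted(t.positions_um[0] for t in tracks)
        assert starts[0] == pytest.approx(kym.column_to_um(10.0), abs=0.1)
        assert starts[1] == pytest.approx(kym.column_to_um(40.0), abs=0.1)

    def test_empty_kymograph(self):
        kym = Kymograph(np.zeros((0, 0)), 0.16, 1.0)
        assert extract_tracks(kym) == []

    def test_ground_truth_points_recovered(self):
        from axotrace import AxonPath, build_kymograph

        cfg = TransportSimConfig(n_particles=4, n_frames=100, snr=12.0, seed=52)
        stack, truth = simulate_transport(cfg)
        # precondition of the oracle: particles stay well separated
        wide = truth.trajectories.pivot(index="frame", columns="particle_id",
                                        values="position_um").to_numpy()
        for i in range(wide.shape[1]):
            for j in range(i + 1, wide.shape[1]):
                assert np.abs(wide[:, i] - wide[:, j]).min() > 1.5
        kym = build_kymograph(stack, AxonPath(stack.axon_path_vertices()))
        tracks = extract_tracks(kym)
        correct = total = 0
        for pid in truth.particle_ids():
            true_pos = truth.positions(pid)
            best, best_err = None, np.inf
            for tr in tracks:
                err = np.median(np.abs(tr.positions_um - true_pos[tr.frames]))
                if err < best_err:
                    best, best_err = tr, err
            total += len(true_pos)
            if best is not None:
                match = np.abs(best.positions_um - true_pos[best.frames]) < 0.5
                correct += int(match.sum())
        assert correct / total >= 0.95
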