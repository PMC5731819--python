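"""Interval detection from traces and spot detection from image stacks."""

import numpy as np
import pytest

from smswitch.acquisition import LabelModel, TraceSet, make_schedule, render_movie, render_traces
from smswitch.detection import (
    DetectionParams,
    Interval,
    SpotParams,
    detect_intervals,
    detect_spots,
    detect_traceset,
)
from smswitch.kinetics import StateTrajectory


def make_trace(n, on_runs, bg=20.0, amp=10.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.full(n, bg) + (rng.normal(0, noise, n) if noise else 0.0)
    for a, b in on_runs:
        x[a : b + 1] += amp
    return x


class TestDetectIntervals:
    def test_flat_noisy_background_gives_no_intervals(self):
        x = make_trace(500, [], noise=1.0, seed=1)
        assert detect_intervals(x) == []

    def test_noiseless_step_gives_exact_interval_and_dwell(self):
        x = make_trace(1000, [(100, 150)])
        ivs = detect_intervals(x, period=0.66)
        assert len(ivs) == 1
        iv = ivs[0]
        assert (iv.start_frame, iv.end_frame) == (100, 150)
        assert iv.dwell == pytest.approx(51 * 0.66)
        assert not iv.censored

    def test_censor_flags_at_movie_edges(self):
        x = make_trace(200, [(0, 10), (190, 199)])
        ivs = detect_intervals(x)
        assert ivs[0].left_censored and not ivs[0].right_censored
        assert ivs[1].right_censored and not ivs[1].left_censored

    def test_constant_trace_returns_degenerate_doubly_censored_interval(self):
        with pytest.warns(UserWarning, match="constant trace"):
            ivs = detect_intervals(np.full(50, 30.0))
        assert len(ivs) == 1
        assert ivs[0].degenerate and ivs[0].left_censored and ivs[0].right_censored

    def test_gap_bridging_and_min_length(self):
        x = make_trace(100, [(10, 14), (16, 20)])  # 1-frame gap
        ivs = detect_intervals(x, DetectionParams(max_gap=1))
        assert [(iv.start_frame, iv.end_frame) for iv in ivs] == [(10, 20)]
        ivs = detect_intervals(x, DetectionParams(max_gap=0))
        assert [(iv.start_frame, iv.end_frame) for iv in ivs] == [(10, 14), (16, 20)]
        ivs = detect_intervals(x, DetectionParams(max_gap=0, min_length=6))
        assert ivs == []

    def test_raising_min_length_never_increases_interval_count(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            runs = []
            t = 5
            while t < 180:
                ln = rng.integers(1, 6)
                runs.append((t, min(179, t + ln - 1)))
                t += ln + rng.integers(3, 15)
            x = make_trace(200, runs, noise=1.0, seed=trial)
            counts = [
                len(detect_intervals(x, DetectionParams(min_length=m)))
                for m in (1, 2, 3, 5)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_idempotence_on_reconstructed_trace(self):
        rng = np.random.default_rng(8)
        x = make_trace(300, [(20, 40), (80, 81), (150, 220)], noise=1.0, seed=9)
        first = detect_intervals(x, period=0.44)
        recon = np.full(300, 20.0)
        for iv in first:
            recon[iv.start_frame : iv.end_frame + 1] += 10.0
        recon += rng.normal(0, 1.0, 300)
        second = detect_intervals(recon, period=0.44)
        assert [(iv.start_frame, iv.end_frame) for iv in first] == [
            (iv.start_frame, iv.end_frame) for iv in second
        ]

    def test_explicit_background_stats_handle_saturated_traces(self):
        # occupancy ~90%: per-trace median sits on the signal level
        x = make_trace(200, [(0, 179)], noise=0.5, seed=3)
        assert detect_intervals(x) == []  # median/MAD is fooled
        ivs = detect_intervals(
            x, DetectionParams(background_median=20.0, background_sd=0.5)
        )
        assert [(iv.start_frame, iv.end_frame) for iv in ivs] == [(0, 179)]

    def test_round_trip_recovers_ground_truth_events(self):
        # SNR 10 traces from ~1000 ground-truth events of >= 3 frames:
        # >= 99% recovered with both endpoints within +/- 1 frame
        sched = make_schedule(1, n_frames=400)
        per = sched.cycle_period
        rng = np.random.default_rng(12)
        trajs, truth = [], []
        for m in range(260):
            t, segs, events = 0.0, [], []
            while t < sched.duration:
                # occupancy ~15%: at high occupancy the per-trace MAD is
                # inflated by the signal itself and thresholds drift upward
                gap = rng.exponential(60 * per) + 20 * per
                on = rng.uniform(3 * per, 25 * per)
                a, b = t + gap, min(t + gap + on, sched.duration)
                if a >= sched.duration:
                    break
                segs.append((t, a, frozenset()))
                segs.append((a, b, frozenset({"x"})))
                events.append((a, b))
                t = b
            segs.append((t, sched.duration, frozenset()))
            if segs[-1][0] == segs[-1][1]:
                segs.pop()
            trajs.append(StateTrajectory(m, sched.duration, segs))
            truth.append(events)
        lm = LabelModel(channel_of={"x": 0}, p_label={"x": 1.0},
                        brightness={"x": 10.0}, background=20.0, noise_sd=1.0)
        ts = render_traces(trajs, sched, lm, seed=13)
        ivs = detect_traceset(ts)
        by_mol = {}
        for iv in ivs:
            by_mol.setdefault(iv.molecule_id, []).append(iv)
        n_total = n_good = 0
        for m, events in enumerate(truth):
            got = by_mol.get(m, [])
            for a, b in events:
                if b - a < 3 * per:
                    continue
                n_total += 1
                a_f = int(np.ceil(a / per))
                b_f = int(np.floor(b / per - 1e-9))
                ok = any(
                    abs(iv.start_frame - a_f) <= 1 and abs(iv.end_frame - b_f) <= 1
                    for iv in got
                )
                n_good += ok
        assert n_total > 900
        assert n_good / n_total >= 0.99

    def test_censored_fraction_follows_exponential_survival(self):
        # a species bound from t=0 with lifetime tau is right-censored with
        # probability exp(-T/tau)
        sched = make_schedule(1, n_frames=300)
        T = sched.duration
        for tau in (T / 2, T):
            rng = np.random.default_rng(int(tau * 1000))
            n = 800
            cens = 0
            trajs = []
            for m in range(n):
                d = rng.exponential(tau)
                end = min(d, T)
                segs = [(0.0, end, frozenset({"x"}))]
                if end < T:
                    segs.append((end, T, frozenset()))
                trajs.append(StateTrajectory(m, T, segs))
            lm = LabelModel(channel_of={"x": 0}, p_label={"x": 1.0},
                            brightness={"x": 10.0}, background=20.0, noise_sd=1.0)
            ts = render_traces(trajs, sched, lm, seed=int(tau))
            # traces are nearly always-on: threshold off the known background
            ivs = detect_traceset(
                ts, DetectionParams(background_median=20.0, background_sd=1.0))
            frac = np.mean([iv.right_censored for iv in ivs])
            expected = np.exp(-T / tau)
            se = np.sqrt(expected * (1 - expected) / len(ivs))
            assert abs(frac - expected) < 3 * se


class TestDetectSpots:
    def test_blank_stack_has_no_spots(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(10, 1, size=(5, 64, 64))
        pos, traces = detect_spots(stack)
        assert len(pos) == 0

    def test_round_trip_field_recall_and_no_false_positives(self):
        sched = make_schedule(1, n_frames=6)
        n_mol = 150
        rng = np.random.default_rng(17)
        # rejection-sample positions at >= 5 px spacing on a 200 px field
        pts = []
        while len(pts) < n_mol:
            cand = rng.uniform(8, 192, size=2)
            if all(np.hypot(*(cand - p)) >= 5.0 for p in pts):
                pts.append(cand)
        pos = np.array(pts)
        inten = np.full((n_mol, 1, 6), 400.0)
        ts = TraceSet(inten, sched, np.arange(n_mol))
        stacks, _, _ = render_movie(ts, psf_sigma=1.2, image_size=(200, 200),
                                    molecule_positions=pos, seed=3,
                                    background=10.0, noise_sd=1.0)
        found, traces = detect_spots(stacks[0], SpotParams(exclusion_radius=4.0))
        # every true position matched within 1 px, nothing spurious
        d = np.hypot(*(pos[:, None, :] - found[None, :, :]).transpose(2, 0, 1))
        assert (d.min(axis=1) <= 1.0).mean() >= 0.99
        assert len(found) <= n_mol
        assert traces.shape[1] == 6

    def test_two_overlapping_molecules_never_double_counted(self):
        sched = make_schedule(1, n_frames=3)
        ts = TraceSet(np.full((2, 1, 3), 300.0), sched, np.arange(2))
        stacks, _, _ = render_movie(
            ts, psf_sigma=1.5, image_size=(64, 64),
            molecule_positions=np.array([[30.0, 30.0], [31.0, 30.0]]),
            seed=0, background=10.0, noise_sd=1.0,
        )
        found, _ = detect_spots(stacks[0], SpotParams(exclusion_radius=4.0))
        assert len(found) <= 1
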