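"""Event classification: co-arrival, loading/unloading, exchange, label efficiency."""

import numpy as np
import pytest
from scipy import stats

from smswitch.detection import Interval
from smswitch.events import (
    classify_coarrival,
    classify_exchange,
    classify_loading,
    classify_unloading,
    estimate_label_efficiency,
    lag_statistics,
)
from smswitch.kinetics import RateSet, build_scheme, occupancy_runs, simulate_many

PER = 0.44


def iv(start, end, *, ch=0, mol=0, left=False, right=False, period=PER):
    return Interval(mol, ch, start, end, period, left_censored=left, right_censored=right)


def intervals_from_trajs(trajs, species, period, *, ch=0, n_frames=None):
    """Frame-quantized ground-truth intervals (ideal detection)."""
    out = []
    for tr in trajs:
        last = int(tr.duration / period) - 1 if n_frames is None else n_frames - 1
        for a, b in occupancy_runs(tr, species):
            a_f = int(np.ceil(a / period - 1e-12))
            b_f = int(np.floor(b / period - 1e-12))
            b_f = min(b_f, last)
            if b_f < a_f:
                continue
            out.append(
                Interval(tr.molecule_id, ch, a_f, b_f, period,
                         left_censored=(a_f == 0), right_censored=(b_f == last))
            )
    return out


class TestCoarrival:
    @pytest.mark.parametrize("delta,expected", [(0, True), (1, True), (2, False)])
    def test_adjacent_frame_tolerance(self, delta, expected):
        a = iv(10, 20, ch=0)
        b = iv(10 + delta, 25, ch=1)
        assert classify_coarrival(a, b) is expected
        assert classify_coarrival(b, a) is expected  # symmetric

    def test_same_channel_rejected(self):
        with pytest.raises(ValueError):
            classify_coarrival(iv(0, 1, ch=0), iv(0, 1, ch=0))


class TestLoading:
    def test_coarriving_pair_with_persistent_clamp(self):
        loader = [iv(10, 12, ch=0)]
        clamp = [iv(10, 899, ch=1, right=True)]
        (ev,) = classify_loading(loader, clamp)
        assert ev.kind == "loading"
        assert ev.extra["loader_dwell"] == pytest.approx(3 * PER)
        assert ev.extra["clamp_persists"] and not ev.extra["co_release"]

    def test_co_release_is_flagged(self):
        loader = [iv(10, 14, ch=0)]
        clamp = [iv(11, 15, ch=1)]
        (ev,) = classify_loading(loader, clamp)
        assert ev.kind == "loading" and ev.extra["co_release"]

    def test_unpaired_loader_is_solo(self):
        evs = classify_loading([iv(10, 12, ch=0)], [iv(50, 60, ch=1)])
        assert [e.kind for e in evs] == ["solo"]


class TestUnloading:
    def test_productive_lag_in_frames(self):
        clamp = [iv(0, 106, ch=1, left=True)]
        loader = [iv(100, 116, ch=0)]
        (ev,) = classify_unloading(loader, clamp)
        assert ev.kind == "unloading_productive"
        assert ev.lag == pytest.approx(6 * PER)

    def test_outliving_clamp_is_nonproductive(self):
        clamp = [iv(0, 899, ch=1, left=True, right=True)]
        loader = [iv(100, 104, ch=0)]
        (ev,) = classify_unloading(loader, clamp)
        assert ev.kind == "unloading_nonproductive"

    def test_loader_without_clamp_is_solo(self):
        (ev,) = classify_unloading([iv(100, 104, ch=0)], [])
        assert ev.kind == "solo"

    def test_branch_probability_recovered_from_simulation(self):
        rates = {"loader": RateSet.from_arrival(0.2, 0.0)}
        scheme = build_scheme("unloading", rates, p_productive=0.47)
        trajs = simulate_many(scheme, 600.0, 2500, seed=99)
        loaders = intervals_from_trajs(trajs, "loader", PER, ch=0)
        clamps = intervals_from_trajs(trajs, "clamp", PER, ch=1)
        evs = classify_unloading(loaders, clamps)
        n_p = sum(e.kind == "unloading_productive" for e in evs)
        n_n = sum(e.kind == "unloading_nonproductive" for e in evs)
        assert n_p + n_n >= 2000
        frac = n_p / (n_p + n_n)
        se = np.sqrt(0.47 * 0.53 / (n_p + n_n))
        assert abs(frac - 0.47) < 3 * se


class TestExchange:
    def test_disjoint_pair_is_switch_with_gap_lag(self):
        summary, evs = classify_exchange(
            [iv(10, 40, ch=0)], [iv(45, 60, ch=1)], species_a="A", species_b="B")
        (ev,) = evs
        assert ev.kind == "switch" and ev.order == "A->B"
        assert ev.lag == pytest.approx(4 * PER)
        assert summary.n_ab == 1 and summary.n_pairs == 1

    def test_overlapping_pair_is_colocalization(self):
        summary, evs = classify_exchange(
            [iv(10, 40, ch=0)], [iv(30, 60, ch=1)], species_a="A", species_b="B")
        (ev,) = evs
        assert ev.kind == "colocalization"
        assert ev.duration == pytest.approx(11 * PER)
        assert ev.extra["first_in"] == "A" and ev.extra["first_out"] == "A"

    def test_same_channel_overlap_is_malformed(self):
        with pytest.raises(ValueError, match="overlapping same-channel"):
            classify_exchange([iv(0, 10, ch=0), iv(5, 20, ch=0)], [])

    def test_every_cross_pair_classified_once_and_percentages_sum(self):
        rng = np.random.default_rng(3)
        ivs_a, ivs_b = [], []
        for mol in range(50):
            t = 0
            for _ in range(rng.integers(2, 6)):
                ln = rng.integers(1, 20)
                which = rng.random() < 0.5
                (ivs_a if which else ivs_b).append(
                    iv(t, t + ln, ch=0 if which else 1, mol=mol))
                t += ln + rng.integers(1, 15)
        summary, evs = classify_exchange(ivs_a, ivs_b)
        assert summary.n_ab + summary.n_ba + summary.n_coloc == summary.n_pairs
        if summary.n_pairs:
            assert summary.pct_ab + summary.pct_ba + summary.pct_coloc == pytest.approx(100.0)
        assert sum(e.kind in ("switch", "colocalization") for e in evs) == summary.n_pairs

    def test_symmetric_competition_gives_even_switch_directions(self):
        # fully exchangeable species (equal kon and koff): switch directions
        # are 50/50 by symmetry.  (With unequal koff the direction split is
        # close to even but not exactly so.)
        rates = {
            "pol3": RateSet.from_arrival(1 / 20.3, 1 / 15.0),
            "pol4": RateSet.from_arrival(1 / 20.3, 1 / 15.0),
        }
        scheme = build_scheme("competition", rates)
        trajs = simulate_many(scheme, 660.0, 800, seed=17)
        per = 0.086
        a = intervals_from_trajs(trajs, "pol3", per, ch=0)
        b = intervals_from_trajs(trajs, "pol4", per, ch=1)
        summary, _ = classify_exchange(a, b, species_a="pol3", species_b="pol4")
        n = summary.n_ab + summary.n_ba
        se = np.sqrt(0.25 / n)
        assert abs(summary.n_ab / n - 0.5) < 3 * se

    def test_switch_lag_recovers_installed_arrival_rate(self):
        # one bound polymerase, the competitor arriving at rate 1/20.3:
        # the release-to-arrival lag distribution has mean 20.3 s
        rates = {
            "pol3": RateSet(kon_per_conc=0.0, koff=1 / 15.7, conc=0.0),
            "pol4": RateSet.from_arrival(1 / 20.3, 1 / 14.2),
        }
        scheme = build_scheme("competition", rates, initial=("pol3",))
        trajs = simulate_many(scheme, 660.0, 3000, seed=23)
        per = 0.66
        a = intervals_from_trajs(trajs, "pol3", per, ch=0)
        b = intervals_from_trajs(trajs, "pol4", per, ch=1)
        _, evs = classify_exchange(a, b, species_a="pol3", species_b="pol4")
        lags = [e.lag for e in evs if e.kind == "switch" and e.order == "pol3->pol4"]
        lags = np.array(lags)
        se = lags.std(ddof=1) / np.sqrt(lags.size)
        assert lags.size > 1500
        assert abs(lags.mean() - 20.3) < 2 * se

    def test_first_in_first_out_independence_in_co_occupancy(self):
        # independent arrival/departure: which species entered first carries
        # no information about which leaves first (no stable ternary complex)
        rates = {
            "pol3": RateSet.from_arrival(1 / 10.0, 1 / 15.7),
            "pol4": RateSet.from_arrival(1 / 10.0, 1 / 14.2),
        }
        scheme = build_scheme("competition", rates)
        pvals = []
        for seed in (31, 32, 33):
            trajs = simulate_many(scheme, 660.0, 500, seed=seed)
            per = 0.66
            a = intervals_from_trajs(trajs, "pol3", per, ch=0)
            b = intervals_from_trajs(trajs, "pol4", per, ch=1)
            summary, _ = classify_exchange(a, b, species_a="pol3", species_b="pol4")
            table = summary.first_in_out
            assert table.sum() > 300
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert sum(p > 0.01 for p in pvals) >= 2

    def test_coloc_duration_matches_independence_prediction(self):
        from smswitch.kinetics import expected_coloc_duration

        rates = {
            "pol3": RateSet.from_arrival(1 / 8.0, 1 / 15.7),
            "pol4": RateSet.from_arrival(1 / 8.0, 1 / 14.2),
        }
        scheme = build_scheme("competition", rates)
        trajs = simulate_many(scheme, 660.0, 600, seed=37)
        per = 0.086  # fine frames: overlap quantization bias << sem
        a = intervals_from_trajs(trajs, "pol3", per, ch=0)
        b = intervals_from_trajs(trajs, "pol4", per, ch=1)
        summary, _ = classify_exchange(a, b, species_a="pol3", species_b="pol4")
        expected = expected_coloc_duration(15.7, 14.2)
        assert abs(summary.coloc_duration_mean - expected) < 2.5 * summary.coloc_duration_sem

    def test_tau_complex_tethering_makes_pol3_first_in(self):
        # with Pol IIIcore delivered by the tau clamp loader it rebinds the
        # clamp almost immediately after each departure; at the camera's
        # frame resolution those sub-second gaps are invisible, so in nearly
        # every observed co-localization Pol IIIcore is the resident species
        # and Pol IV arrives second
        from smswitch.acquisition import LabelModel, make_schedule, render_traces
        from smswitch.detection import DetectionParams, detect_traceset

        rates = {
            "pol3": RateSet.from_arrival(10.0, 1 / 14.8),
            "pol4": RateSet.from_arrival(1 / 20.3, 1 / 14.2),
        }
        scheme = build_scheme("tau_complex", rates)
        sched = make_schedule(3, n_frames=1000)
        trajs = simulate_many(scheme, sched.duration, 300, seed=41)
        lm = LabelModel(channel_of={"pol3": 0, "pol4": 1},
                        p_label={"pol3": 1.0, "pol4": 1.0},
                        background=20.0, noise_sd=1.0)
        ts = render_traces(trajs, sched, lm, seed=42)
        # pol3 occupies its channel almost continuously: use the known
        # camera background rather than the per-trace median
        ivs = detect_traceset(
            ts, DetectionParams(background_median=20.0, background_sd=1.0))
        a = [v for v in ivs if v.channel == 0]
        b = [v for v in ivs if v.channel == 1]
        summary, evs = classify_exchange(a, b, species_a="pol3", species_b="pol4")
        colocs = [e for e in evs if e.kind == "colocalization"
                  and e.extra["first_in"] != "tie"]
        assert len(colocs) > 200
        frac = np.mean([e.extra["first_in"] == "pol3" for e in colocs])
        assert frac > 0.90


class TestLabelEfficiency:
    def test_simple_counts(self):
        p_a, se_a, p_b, se_b = estimate_label_efficiency(100, 50, 50)
        assert p_a == pytest.approx(2 / 3, abs=1e-9)
        assert p_b == pytest.approx(2 / 3, abs=1e-9)
        assert se_a > 0

    def test_perfect_labeling(self):
        p_a, _, p_b, _ = estimate_label_efficiency(500, 0, 0)
        assert p_a == 1.0 and p_b == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            estimate_label_efficiency(0, 10, 0)

    def test_estimator_consistency_on_simulated_draws(self):
        rng = np.random.default_rng(5)
        n = 5000
        alpha = rng.random(n) < 0.67
        eps = rng.random(n) < 0.71
        n_both = int((alpha & eps).sum())
        n_a = int((alpha & ~eps).sum())
        n_b = int((~alpha & eps).sum())
        p_a, se_a, p_b, se_b = estimate_label_efficiency(n_both, n_a, n_b)
        assert abs(p_a - 0.67) < 2 * se_a
        assert abs(p_b - 0.71) < 2 * se_b


class TestLagStatistics:
    def test_mean_and_sem(self):
        from smswitch.events import EventRecord

        evs = [EventRecord("switch", 0, ("A", "B"), order="A->B", lag=v)
               for v in (2.0, 4.0, 6.0)]
        df = lag_statistics(evs)
        row = df.iloc[0]
        assert row["lag_mean_s"] == pytest.approx(4.0)
        assert row["lag_sem_s"] == pytest.approx(1.1547, abs=1e-4)

    def test_censored_only_selection_is_empty(self):
        from smswitch.events import EventRecord

        evs = [EventRecord("switch", 0, ("A", "B"), order="A->B", lag=2.0, censored=True)]
        df = lag_statistics(evs)
        assert df.empty
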