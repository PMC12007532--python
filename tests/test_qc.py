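"""Quality control: CoV screening, trial repair, robustness re-analyses."""

import numpy as np
import pytest

from fnirs_nfb.core import HbRecording
from fnirs_nfb.online import ThresholdState, run_closed_loop
from fnirs_nfb.qc import (
    bandpass_001_009,
    bandpass_series,
    coefficient_of_variation,
    common_average_reference,
    detect_bad_channels,
    has_flatline,
    interpolate_bad_trials,
    offline_reanalysis,
    reinclude_channel,
    remove_outlier_samples,
)
from fnirs_nfb.simulate import SimScenario, simulate_recording


class TestCov:
    def test_definition(self):
        assert coefficient_of_variation([9.5, 10.0, 10.5]) == pytest.approx(5.0)

    def test_constant_series_is_zero(self):
        assert coefficient_of_variation(np.full(100, 7.0)) == 0.0

    def test_direct_arithmetic(self):
        x = np.array([9.0, 10.0, 11.0])
        assert coefficient_of_variation(x) == pytest.approx(
            100 * np.std(x, ddof=1) / 10.0)

    def test_zero_mean_is_undefined(self):
        assert np.isnan(coefficient_of_variation([-1.0, 1.0]))


def _recording(series_map, fs=10.0):
    """Build a recording from {channel: (hbo, hbr)}; first half left."""
    channels = list(series_map)
    hemis = ["left" if ch.startswith("L") else "right" for ch in channels]
    hbo = np.column_stack([series_map[ch][0] for ch in channels])
    hbr = np.column_stack([series_map[ch][1] for ch in channels])
    fb = next(ch for ch in channels if ch.startswith("R"))
    return HbRecording(fs, channels, hemis, fb, hbo, hbr)


def _noisy(rng, n, mean, sd):
    x = rng.normal(0, 1, n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestBadChannelDetector:
    def test_flatline_boundary(self, rng):
        n = 600
        good = _noisy(rng, n, 10.0, 0.3)
        twelve = good.copy()
        twelve[100:112] = twelve[100]       # 12 identical samples -> flagged
        nine = good.copy()
        nine[200:209] = nine[200]           # 9 identical samples -> below 1 s
        assert has_flatline(twelve)
        assert not has_flatline(nine)

    def test_cov_above_ten_percent_excluded(self, rng):
        n = 600
        rec = _recording({
            "L01": (_noisy(rng, n, 10, 0.3), _noisy(rng, n, 10, 0.3)),
            "R01": (_noisy(rng, n, 10, 1.1), _noisy(rng, n, 10, 0.3)),
        })
        rep = detect_bad_channels(rec)
        assert rep.excluded_channels() == ["R01"]
        assert "cov_hbo" in rep.channels.set_index("channel").loc["R01", "reason"]

    def test_full_sensitivity_and_specificity(self, rng):
        """Every injected defect is caught; every clean channel passes."""
        n = 1200
        clean = {f"L{i:02d}": (_noisy(rng, n, 10, 0.3), _noisy(rng, n, 10, 0.35))
                 for i in range(1, 7)}
        high_cov = (_noisy(rng, n, 10, 1.5), _noisy(rng, n, 10, 0.3))
        cov_gap = (_noisy(rng, n, 10, 0.8), _noisy(rng, n, 10, 0.1))
        flat_o = _noisy(rng, n, 10, 0.3)
        flat_o[500:515] = flat_o[500]
        flatline = (flat_o, _noisy(rng, n, 10, 0.3))
        rec = _recording({**clean, "R01": high_cov, "R02": cov_gap,
                          "R03": flatline,
                          "R04": (_noisy(rng, n, 10, 0.3), _noisy(rng, n, 10, 0.3))})
        rep = detect_bad_channels(rec)
        assert set(rep.excluded_channels()) == {"R01", "R02", "R03"}

    def test_reinclusion_audit_path(self, rng):
        n = 600
        rec = _recording({
            "L01": (_noisy(rng, n, 10, 0.3), _noisy(rng, n, 10, 0.3)),
            "R01": (_noisy(rng, n, 10, 1.5), _noisy(rng, n, 10, 0.3)),
        })
        rep = detect_bad_channels(rec)
        with pytest.raises(ValueError, match="justification"):
            reinclude_channel(rep, "R01", "  ")
        with pytest.raises(ValueError, match="not excluded"):
            reinclude_channel(rep, "L01", "looks fine")
        rep = reinclude_channel(rep, "R01", "spike-driven CoV, correctable")
        rep = reinclude_channel(rep, "R01", "again")   # idempotent
        assert rep.excluded_channels() == []
        assert len(rep.audit) == 1


class TestTrialRepair:
    def test_interpolation_of_middle_trial(self):
        trials = [np.full(300, 2.0)] * 7
        out = interpolate_bad_trials(trials, 3)
        assert np.all(out == 2.0)

    def test_first_trial_uses_following_neighbors_only(self):
        trials = [np.full(10, v) for v in [9.0, 1.0, 2.0, 3.0, 99.0]]
        out = interpolate_bad_trials(trials, 0)
        assert np.allclose(out, (1 + 2 + 3) / 3)

    def test_six_neighbor_mean(self):
        trials = [np.full(10, v) for v in [1, 2, 3, 0, 4, 5, 6]]
        out = interpolate_bad_trials(trials, 3)
        assert np.allclose(out, 3.5)

    def test_no_neighbors_raises(self):
        with pytest.raises(ValueError, match="neighbor"):
            interpolate_bad_trials([np.zeros(5)], 0)

    def test_single_outlier_locf(self):
        x = np.zeros(300)
        x[150] = 100.0
        out, n = remove_outlier_samples(x)
        assert n == 1
        assert out[150] == 0.0
        assert np.all(out == 0.0)

    def test_clean_trial_unchanged(self, rng):
        x = rng.normal(0, 1, 300)
        x = np.clip(x, -2.5, 2.5)
        out, n = remove_outlier_samples(x)
        assert n == 0
        assert np.array_equal(out, x)

    def test_consecutive_outliers_share_last_retained_value(self):
        x = np.concatenate([np.zeros(100), [0.5], [50.0, 60.0], np.zeros(100)])
        out, n = remove_outlier_samples(x)
        assert n == 2
        assert out[101] == 0.5 and out[102] == 0.5

    def test_leading_outlier_takes_next_retained(self):
        x = np.concatenate([[80.0], np.zeros(200), [0.25]])
        out, n = remove_outlier_samples(x)
        assert n == 1
        assert out[0] == 0.0

    def test_replaced_count_monotone_in_injected_outliers(self, rng):
        base = rng.normal(0, 1, 300)
        counts = []
        for k in (0, 2, 5, 9):
            x = base.copy()
            x[10:10 + k] = 40.0
            counts.append(remove_outlier_samples(x)[1])
        assert counts == sorted(counts)


class TestBandpass:
    def test_cardiac_probe_attenuated_20db(self):
        t = np.arange(0, 300, 0.1)
        y = bandpass_series(np.sin(2 * np.pi * 1.0 * t))
        assert np.max(np.abs(y[500:-500])) < 0.1   # >= 20 dB down

    def test_passband_preserved(self):
        t = np.arange(0, 2000, 0.1)
        y = bandpass_series(np.sin(2 * np.pi * 0.05 * t))
        mid = y[5000:-5000]
        assert (mid.max() - mid.min()) / 2 == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        y = bandpass_series(np.full(4000, 3.0))
        assert np.max(np.abs(y[1000:-1000])) < 1e-6

    def test_zero_phase_no_lag(self, rng):
        t = np.arange(0, 1000, 0.1)
        clean = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass_series(clean + 0.5 * np.sin(2 * np.pi * 1.0 * t)
                            + 0.1 * rng.normal(size=t.size))
        a = clean[2000:-2000] - clean[2000:-2000].mean()
        b = y[2000:-2000] - y[2000:-2000].mean()
        xc = np.correlate(a, b, mode="full")
        lag = int(np.argmax(xc)) - (a.size - 1)
        assert lag == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            bandpass_series(np.zeros(10))

    def test_recording_wrapper_filters_all_channels(self, rng):
        rec = _recording({
            "L01": (rng.normal(10, 1, 800), rng.normal(10, 1, 800)),
            "R01": (rng.normal(10, 1, 800), rng.normal(10, 1, 800)),
        })
        out = bandpass_001_009(rec)
        assert out.hbo.shape == rec.hbo.shape
        assert abs(out.hbo.mean()) < 0.5    # DC gone


class TestCar:
    def test_identical_channels_cancel(self):
        n = 100
        x = np.tile(np.sin(np.arange(n) / 5.0)[:, None], (1, 4))
        rec = HbRecording(10.0, ["L01", "L02", "R01", "R02"],
                          ["left", "left", "right", "right"], "R01", x, x)
        out = common_average_reference(rec)
        assert np.allclose(out.hbo, 0.0)

    def test_zero_reference_leaves_feedback_unchanged(self, rng):
        n = 100
        fb = rng.normal(size=n)
        hbo = np.column_stack([np.zeros(n), np.zeros(n), fb])
        rec = HbRecording(10.0, ["L01", "L02", "R01"],
                          ["left", "left", "right"], "R01", hbo, hbo.copy())
        out = common_average_reference(rec)
        assert np.array_equal(out.hbo[:, 0], fb)

    def test_equal_count_reference_levels(self):
        n = 50
        cols = [np.full(n, 1.0), np.full(n, 3.0), np.full(n, 5.0)]
        rec = HbRecording(10.0, ["L01", "L02", "R01"],
                          ["left", "left", "right"], "R01",
                          np.column_stack(cols), np.column_stack(cols))
        out = common_average_reference(rec)
        assert np.allclose(out.hbo, 3.0)    # 5 - mean(1, 3)

    def test_linearity(self, rng):
        n = 200
        def make():
            hbo = rng.normal(size=(n, 4))
            return HbRecording(10.0, ["L01", "L02", "R01", "R02"],
                               ["left", "left", "right", "right"], "R01",
                               hbo, rng.normal(size=(n, 4)))
        x, y = make(), make()
        a, b = 2.5, -1.5
        combo = HbRecording(10.0, x.channels, x.hemispheres, "R01",
                            a * x.hbo + b * y.hbo, a * x.hbr + b * y.hbr)
        got = common_average_reference(combo)
        want_o = (a * common_average_reference(x).hbo
                  + b * common_average_reference(y).hbo)
        assert np.allclose(got.hbo, want_o)

    def test_left_hemisphere_required(self, rng):
        rec = HbRecording(10.0, ["R01", "R02"], ["right", "right"], "R01",
                          rng.normal(size=(50, 2)), rng.normal(size=(50, 2)))
        with pytest.raises(ValueError, match="left"):
            common_average_reference(rec)


class TestOfflineReanalysis:
    def test_replication_matches_online_engine(self, short_schedule):
        scen = SimScenario(
            regulation_amplitudes=(0.6,) * short_schedule.n_runs,
            channels_per_hemisphere=2, seed=11, feedback_channel="R01",
        )
        rec, _ = simulate_recording(short_schedule, scen)
        traces, _, _ = run_closed_loop(rec, short_schedule, "up",
                                       ThresholdState(T=1.0))
        online_medians = np.array([np.median(t.feedback_signal) for t in traces])
        table = offline_reanalysis(rec, short_schedule, "up", "replication")
        assert np.allclose(table["trial_median"].to_numpy(), online_medians,
                           atol=1e-6)

    def test_bandpass_variant_suppresses_cardiac_contamination(self, short_schedule):
        base = dict(
            regulation_amplitudes=(0.6,) * short_schedule.n_runs,
            drift_slope=0.0, noise_sd=0.03, channels_per_hemisphere=1,
            feedback_channel="R01", seed=12,
        )
        clean, _ = simulate_recording(
            short_schedule, SimScenario(physio_amplitudes={}, **base))
        contam, _ = simulate_recording(
            short_schedule, SimScenario(physio_amplitudes={"cardiac": 3.0}, **base))

        def medians(rec, variant):
            return offline_reanalysis(rec, short_schedule, "up",
                                      variant)["trial_median"].to_numpy()

        # each variant normalizes to its own baseline SD, so compare the
        # contamination-induced *relative* error within each variant
        def rel_err(variant):
            c = medians(contam, variant)
            o = medians(clean, variant)
            return np.mean(np.abs(c - o) / np.abs(o))

        assert rel_err("robust1") < rel_err("replication")

    def test_car_variant_cancels_common_mode(self, short_schedule, rng):
        scen = SimScenario(
            regulation_amplitudes=(0.6,) * short_schedule.n_runs,
            physio_amplitudes={}, drift_slope=0.0, noise_sd=0.03,
            channels_per_hemisphere=22, seed=13,
        )
        rec, _ = simulate_recording(short_schedule, scen)
        common = 2.0 * np.sin(2 * np.pi * 0.04 * rec.time)
        dirty = rec.copy_with(hbo=rec.hbo + common[:, None],
                              hbr=rec.hbr + common[:, None])
        clean_r2 = offline_reanalysis(rec, short_schedule, "up", "robust2")
        dirty_r2 = offline_reanalysis(dirty, short_schedule, "up", "robust2")
        # CAR removes an identical additive series from every channel exactly
        assert np.allclose(dirty_r2["trial_median"], clean_r2["trial_median"],
                           atol=1e-9)
        ref = offline_reanalysis(rec, short_schedule, "up", "replication")
        assert np.allclose(dirty_r2["trial_median"], ref["trial_median"],
                           rtol=0.15, atol=0.5)

    def test_unknown_variant_rejected(self, short_schedule, rng):
        rec = _recording({"L01": (rng.normal(10, 1, 600), rng.normal(10, 1, 600)),
                          "R01": (rng.normal(10, 1, 600), rng.normal(10, 1, 600))})
        with pytest.raises(ValueError, match="variant"):
            offline_reanalysis(rec, short_schedule, "up", "bogus")
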