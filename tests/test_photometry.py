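import numpy as np
import pandas as pd
import pytest

from nremlink import photometry as ph
from nremlink.errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    InvalidArgumentError,
)

from conftest import make_hypnogram

FS = 400.0


def trace(samples, fs=FS):
    return ph.PhotometryTrace(np.asarray(samples, dtype=float), fs=fs)


class TestDff:
    def test_constant_trace_is_zero(self):
        dff = ph.compute_dff(trace(np.full(1000, 3.7)))
        assert np.all(dff.samples == 0.0)

    def test_double_baseline_gives_one(self):
        x = np.ones(1001)
        x[500] = 2.0
        dff = ph.compute_dff(trace(x))
        assert dff.samples[500] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1.0, 3.0, 777)
        dff = ph.compute_dff(trace(x))
        f_m = sorted(x)[len(x) // 2]  # odd length: middle of sorted values
        expected = (x - f_m) / f_m
        np.testing.assert_allclose(dff.samples, expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1.0, 2.0, 500)
        a = ph.compute_dff(trace(x)).samples
        b = ph.compute_dff(trace(7.3 * x)).samples
        np.testing.assert_allclose(a, b)

    def test_zero_baseline_raises(self):
        with pytest.raises(DegenerateBaselineError):
            ph.compute_dff(trace(np.zeros(100)))

    def test_pre_stimulus_mode(self):
        x = np.concatenate([np.full(400, 2.0), np.full(400, 4.0)])
        dff = ph.compute_dff(trace(x), baseline_mode="pre", pre_window=1.0, event_time=1.0)
        assert dff.f_m == 2.0
        assert dff.samples[-1] == pytest.approx(1.0)


class TestDetrend:
    def test_exact_quadratic_removed(self):
        t = np.arange(0, 700, 1 / 10.0)
        x = 5.0 + 0.01 * t - 1e-5 * t**2
        out = ph.detrend_baseline(ph.PhotometryTrace(x, fs=10.0), degree=2)
        assert np.ptp(out.samples) < 1e-9 * np.ptp(x)

    def test_constant_unchanged(self):
        x = np.full(700 * 10, 2.0)
        out = ph.detrend_baseline(ph.PhotometryTrace(x, fs=10.0), degree=2)
        np.testing.assert_allclose(out.samples, x)

    def test_short_trace_passthrough(self):
        x = np.linspace(1, 2, 100)
        out = ph.detrend_baseline(ph.PhotometryTrace(x, fs=10.0), degree=2)
        np.testing.assert_array_equal(out.samples, x)

    def test_transient_amplitudes_preserved(self, desk_config, rest_hypnogram):
        """Amplitudes after polynomial detrend match an oracle that subtracts
        the known drift."""
        from dataclasses import replace

        from nremlink.synthetic_data import synth_photometry

        cfg = replace(desk_config, noise_sd=0.0)
        raw, events = synth_photometry(rest_hypnogram, cfg, seed=4)
        det = ph.detrend_baseline(raw, degree=2)
        t = raw.times
        drift = np.polynomial.polynomial.polyval(t, np.asarray(cfg.drift_coeffs))
        oracle = raw.samples - drift + np.median(raw.samples)
        # compare peak heights at true event times
        idx = (events["time_s"] * FS).astype(int).to_numpy()
        base = np.median(det.samples)
        obase = np.median(oracle)
        a = det.samples[idx] - base
        b = oracle[idx] - obase
        assert np.all(np.abs(a - b) <= 0.05 * np.abs(b) + 1e-3)


class TestQuietPeriod:
    def test_constructed_minimum_found(self):
        rng = np.random.default_rng(2)
        n = int(1000 * FS)
        x = rng.normal(0, 0.1, n)
        i0 = int(300 * FS)
        i1 = i0 + int(250 * FS)
        x[i0:i1] = 0.0  # perfectly flat NREM segment
        hyp = make_hypnogram("N" * 200)
        dff = ph.DffTrace(x, fs=FS)
        s, e, sd = ph.find_quiet_period(dff, hyp)
        assert s == pytest.approx(300.0, abs=0.5)
        assert e - s == pytest.approx(250.0, abs=1 / FS)

    def test_all_wake_raises(self):
        x = np.zeros(int(300 * FS))
        hyp = make_hypnogram("W" * 60)
        with pytest.raises(InsufficientDataError):
            ph.find_quiet_period(ph.DffTrace(x, fs=FS), hyp)

    def test_interval_length_contract(self):
        x = np.random.default_rng(3).normal(0, 1, int(600 * FS))
        hyp = make_hypnogram("N" * 120)
        s, e, _ = ph.find_quiet_period(ph.DffTrace(x, fs=FS), hyp)
        assert e - s == pytest.approx(250.0, abs=1.5 / FS)


def gaussian_bump(center, sigma, amp, n, fs):
    t = np.arange(n) / fs
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def brute_force_transients(x, fs, quiet_sd, prominence_mult=3.0, min_halfwidth=1.5):
    """Independent oracle: exhaustive local-max scan plus direct prominence
    and half-prominence-width computation."""
    found = []
    for i in range(1, len(x) - 1):
        if not (x[i] > x[i - 1] and x[i] >= x[i + 1]):
            continue
        # walk left/right to the first higher point; prominence base is the
        # minimum in between
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        left_base = min(left_min, x[: i + 1].min()) if j < 0 else left_min
        right_min = x[i]
        j = i + 1
        while j < len(x) and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        right_base = min(right_min, x[i:].min()) if j >= len(x) else right_min
        prom = x[i] - max(left_base, right_base)
        if prom <= prominence_mult * quiet_sd:
            continue
        # half-prominence width with linear interpolation at the crossings
        half = x[i] - 0.5 * prom
        a = i
        while a > 0 and x[a - 1] > half:
            a -= 1
        left_pos = float(a)
        if a > 0:  # interpolate between a-1 (below) and a (above)
            left_pos = a - (x[a] - half) / (x[a] - x[a - 1])
        b = i
        while b < len(x) - 1 and x[b + 1] > half:
            b += 1
        right_pos = float(b)
        if b < len(x) - 1:
            right_pos = b + (x[b] - half) / (x[b] - x[b + 1])
        width = (right_pos - left_pos) / fs
        if width >= min_halfwidth:
            found.append(i)
    return found


class TestDetectTransients:
    def test_flat_trace_no_transients(self):
        dff = ph.DffTrace(np.zeros(4000), fs=FS)
        assert len(ph.detect_transients(dff, quiet_sd=0.01)) == 0

    def test_single_wide_bump_detected(self):
        x = gaussian_bump(5.0, 1.5, 0.05, 4000, FS)  # half-width ~3.5 s
        dff = ph.DffTrace(x, fs=FS)
        tr = ph.detect_transients(dff, quiet_sd=0.01, smooth_s=None)
        assert len(tr) == 1
        assert tr.iloc[0]["peak_time_s"] == pytest.approx(5.0, abs=0.01)

    def test_narrow_bump_rejected(self):
        # same amplitude, half-width ~0.5 s -> filtered out
        x = gaussian_bump(5.0, 0.2, 0.05, 4000, FS)
        dff = ph.DffTrace(x, fs=FS)
        assert len(ph.detect_transients(dff, quiet_sd=0.01, smooth_s=None)) == 0

    def test_invalid_quiet_sd(self):
        with pytest.raises(InvalidArgumentError):
            ph.detect_transients(ph.DffTrace(np.zeros(100), fs=FS), quiet_sd=0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fs = 20.0  # coarse grid keeps the oracle O(n^2) cheap
        n = 8000
        x = rng.normal(0, 0.004, n)
        for _ in range(12):
            c = rng.uniform(20, n / fs - 20)
            x += gaussian_bump(c, rng.uniform(0.3, 2.0), rng.uniform(0.02, 0.1), n, fs)
        dff = ph.DffTrace(x, fs=fs)
        got = ph.detect_transients(dff, quiet_sd=0.005, smooth_s=None, max_extent=1e9)
        expected = brute_force_transients(x, fs, quiet_sd=0.005)
        got_idx = ((got["peak_time_s"]) * fs).round().astype(int).tolist()
        assert got_idx == expected

    def test_recovery_on_synthetic(self, desk_config, rest_hypnogram):
        from nremlink.synthetic_data import synth_photometry

        raw, events = synth_photometry(rest_hypnogram, desk_config, seed=7)
        dff = ph.compute_dff(ph.detrend_baseline(raw))
        _, _, qsd = ph.find_quiet_period(dff, rest_hypnogram)
        tr = ph.detect_transients(dff, qsd, hypnogram=rest_hypnogram)
        big = events[events["amplitude"] >= 5 * desk_config.noise_sd]
        det = tr["peak_time_s"].to_numpy()
        sens = np.mean([np.any(np.abs(det - t) <= 0.5) for t in big["time_s"]])
        fdr = np.mean(
            [~np.any(np.abs(events["time_s"].to_numpy() - t) <= 0.5) for t in det]
        )
        assert sens >= 0.9
        assert fdr <= 0.1


class TestStateSummary:
    def test_no_transients(self):
        dff = ph.DffTrace(np.zeros(4000), fs=FS)
        hyp = make_hypnogram("NN")
        out = ph.state_activity_summary(
            ph.detect_transients(dff, 0.01), dff, hyp
        )
        assert all(out[s]["n_transients"] == 0 for s in "WNR")
        assert all(out[s]["cumulative_integral"] == 0 for s in "WNR")

    def test_rem_only_transients(self):
        tr = pd.DataFrame(
            {"peak_time_s": [7.0], "amplitude": [0.1], "half_width_s": [2.0],
             "start_s": [6.0], "end_s": [9.0], "state": ["R"]}
        )
        dff = ph.DffTrace(np.zeros(int(10 * FS)), fs=FS)
        out = ph.state_activity_summary(tr, dff, make_hypnogram("NR"))
        assert out["N"]["n_transients"] == 0
        assert out["R"]["n_transients"] == 1

    def test_counts_partition_total(self, desk_config, rest_hypnogram):
        from nremlink.synthetic_data import synth_photometry

        raw, _ = synth_photometry(rest_hypnogram, desk_config, seed=8)
        dff = ph.compute_dff(ph.detrend_baseline(raw))
        _, _, qsd = ph.find_quiet_period(dff, rest_hypnogram)
        tr = ph.detect_transients(dff, qsd, hypnogram=rest_hypnogram)
        out = ph.state_activity_summary(tr, dff, rest_hypnogram)
        assert sum(out[s]["n_transients"] for s in "WNR") == len(tr)

    def test_nrem_integral_dominates_at_equal_rates(self, desk_config):
        """180 min NREM vs 20 min REM at equal rates/amplitudes -> NREM
        cumulative integral larger (expected ratio 9:1)."""
        from dataclasses import replace

        from nremlink.synthetic_data import synth_photometry

        cfg = replace(
            desk_config,
            transient_rates={"W": 0.0, "N": 2.0, "R": 2.0},
            transient_amp_params={"W": (0.1, 0.01), "N": (0.1, 0.01), "R": (0.1, 0.01)},
        )
        n_n = int(180 * 60 / 5)
        n_r = int(20 * 60 / 5)
        hyp = make_hypnogram("N" * n_n + "R" * n_r)
        ratios = []
        for seed in range(3):
            raw, _ = synth_photometry(hyp, cfg, seed=seed)
            dff = ph.compute_dff(ph.detrend_baseline(raw))
            _, _, qsd = ph.find_quiet_period(dff, hyp)
            tr = ph.detect_transients(dff, qsd, hypnogram=hyp)
            out = ph.state_activity_summary(tr, dff, hyp)
            ratios.append(
                out["N"]["cumulative_integral"] / out["R"]["cumulative_integral"]
            )
        assert np.mean(ratios) > 3.0
        assert all(r > 1.0 for r in ratios)


class TestStandardize:
    def frame(self):
        return pd.DataFrame(
            {
                "mouse": [0] * 4 + [1] * 4,
                "day": [0, 1, 2, 3] * 2,
                "mean_amplitude": [1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 4.0, 2.0],
            }
        )

    def test_per_mouse_mean_zero(self):
        out = ph.standardize_across_animals(self.frame())
        for _, g in out.groupby("mouse"):
            assert g["standardized"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_linear_trend_removed(self):
        out = ph.standardize_across_animals(self.frame())
        g = out[out["mouse"] == 0]
        np.testing.assert_allclose(g["standardized"], 0.0, atol=1e-12)

    def test_matches_hand_oracle(self):
        df = pd.DataFrame(
            {"mouse": [0] * 4, "day": [0, 1, 2, 3], "mean_amplitude": [1.0, 2.0, 2.0, 5.0]}
        )
        v = df["mean_amplitude"].to_numpy()
        z = (v - v.mean()) / v.std()
        day = df["day"].to_numpy(dtype=float)
        coef = np.polynomial.polynomial.polyfit(day, z, 1)
        resid = z - np.polynomial.polynomial.polyval(day, coef)
        out = ph.standardize_across_animals(df)
        np.testing.assert_allclose(out["standardized"], resid, atol=1e-12)

    def test_single_day_raises(self):
        df = pd.DataFrame({"mouse": [0], "day": [0], "mean_amplitude": [1.0]})
        with pytest.raises(InsufficientDataError):
            ph.standardize_across_animals(df)


class TestAlignToEvents:
    def test_constant_trace(self):
        dff = ph.DffTrace(np.full(int(60 * FS), 0.3), fs=FS)
        out = ph.align_to_events(dff, [10.0, 20.0, 30.0], window=(1.0, 2.0))
        np.testing.assert_allclose(out["mean"], 0.3)
        np.testing.assert_allclose(out["sem"], 0.0)

    def test_single_event_mean_is_snippet(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, int(30 * FS))
        dff = ph.DffTrace(x, fs=FS)
        out = ph.align_to_events(dff, [10.0], window=(1.0, 1.0))
        np.testing.assert_array_equal(out["mean"], out["snippets"][0])

    def test_partial_windows_dropped(self):
        dff = ph.DffTrace(np.zeros(int(10 * FS)), fs=FS)
        out = ph.align_to_events(dff, [0.1, 5.0], window=(1.0, 1.0))
        assert out["n_dropped"] == 1
        assert out["snippets"].shape[0] == 1

    def test_no_events_raises(self):
        dff = ph.DffTrace(np.zeros(int(2 * FS)), fs=FS)
        with pytest.raises(InsufficientDataError):
            ph.align_to_events(dff, [100.0], window=(1.0, 1.0))

    def test_step_mean_and_sem_shrink(self):
        rng = np.random.default_rng(6)
        fs = 50.0
        n = int(2000 * fs)
        x = rng.normal(0, 0.5, n)
        events = np.arange(10, 1990, 19.9)[:100]
        for t in events:
            x[int(t * fs) :] += 0.0  # noise only; plant step at each event
            i = int(t * fs)
            x[i : i + int(2 * fs)] += 1.0
        dff = ph.DffTrace(x, fs=fs)
        out = ph.align_to_events(dff, events, window=(1.0, 1.0))
        pre = out["mean"][: int(0.8 * fs)].mean()
        post = out["mean"][int(1.2 * fs) :].mean()
        assert post - pre > 0.8
        assert out["sem"].max() < 0.2  # ~0.5/sqrt(100) plus margin
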