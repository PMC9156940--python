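"""Fluorescence normalization (dF/F), detrending, transient detection and
per-vigilance-state activity summaries.

dF/F = (F_r - F_m) / F_m with a median baseline F_m taken either from the
whole recording or a pre-event window. Transients are local maxima whose
topographic prominence exceeds a multiple of the SD of a "quiet" NREM window
and whose half-prominence width is at least 1.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateBaselineError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .sleep_scoring import Hypnogram


@dataclass
class PhotometryTrace:
    """Raw fluorescence samples at a fixed rate."""

    samples: np.ndarray
    fs: float = 400.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be > 0")
        if self.samples.size == 0:
            raise InvalidArgumentError("trace is empty")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class DffTrace:
    """Baseline-normalized fluorescence."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    baseline_mode: str = "whole"
    f_m: float = np.nan

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


def compute_dff(
    raw: PhotometryTrace,
    baseline_mode: str = "whole",
    pre_window: float | None = None,
    event_time: float | None = None,
) -> DffTrace:
    """(F_r - F_m)/F_m with F_m the median of the whole recording or of the
    ``pre_window`` seconds before ``event_time``."""
    if baseline_mode == "whole":
        f_m = float(np.median(raw.samples))
    elif baseline_mode == "pre":
        if pre_window is None or event_time is None:
            raise InvalidArgumentError("pre mode requires pre_window and event_time")
        t = raw.times
        m = (t >= event_time - pre_window) & (t < event_time)
        if not np.any(m):
            raise InsufficientDataError("pre-stimulus window contains no samples")
        f_m = float(np.median(raw.samples[m]))
    else:
        raise InvalidArgumentError(f"unknown baseline_mode {baseline_mode!r}")
    if f_m == 0:
        raise DegenerateBaselineError("median baseline is zero")
    return DffTrace(
        samples=(raw.samples - f_m) / f_m,
        fs=raw.fs,
        t0=raw.t0,
        baseline_mode=baseline_mode,
        f_m=f_m,
    )


def detrend_baseline(
    raw: PhotometryTrace, degree: int = 2, min_duration: float = 600.0
) -> PhotometryTrace:
    """Fit-and-subtract a least-squares polynomial; the pre-fit median is
    added back so dF/F stays well scaled. Short traces pass through."""
    if degree < 1:
        raise InvalidArgumentError("degree must be >= 1")
    if raw.duration <= min_duration:
        return PhotometryTrace(raw.samples.copy(), fs=raw.fs, t0=raw.t0)
    t = raw.times
    poly = np.polynomial.Polynomial.fit(t, raw.samples, deg=degree)
    detrended = raw.samples - poly(t) + float(np.median(raw.samples))
    return PhotometryTrace(detrended, fs=raw.fs, t0=raw.t0)


def _smooth(x: np.ndarray, fs: float, smooth_s: float | None) -> np.ndarray:
    """Boxcar low-pass; GCaMP transients are slow relative to the 400 Hz
    acquisition, so smoothing suppresses sample noise without touching the
    >= 1.5 s features of interest."""
    if not smooth_s:
        return x
    n = max(int(round(smooth_s * fs)), 1)
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def find_quiet_period(
    dff: DffTrace,
    hypnogram: Hypnogram,
    length: float = 250.0,
    smooth_s: float | None = 0.1,
) -> tuple[float, float, float]:
    """NREM-contained window of ``length`` seconds minimizing the signal SD.

    Returns (start_s, end_s, sd) where sd calibrates transient detection;
    the SD is measured on the same smoothed signal used by
    :func:`detect_transients` (pass the same ``smooth_s`` to both).
    """
    n_win = int(round(length * dff.fs))
    x = _smooth(dff.samples, dff.fs, smooth_s)
    if n_win > x.size:
        raise InsufficientDataError("trace shorter than the quiet-period length")
    is_nrem = hypnogram.sample_labels(dff.fs) == "N"
    if is_nrem.size != x.size:  # tolerate off-by-a-few sample count mismatches
        m = min(is_nrem.size, x.size)
        is_nrem, x = is_nrem[:m], x[:m]
    # rolling mean/SD via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cn = np.concatenate([[0], np.cumsum(is_nrem.astype(int))])
    starts = np.arange(x.size - n_win + 1)
    full_nrem = (cn[starts + n_win] - cn[starts]) == n_win
    if not np.any(full_nrem):
        raise InsufficientDataError(
            f"no fully-NREM window of {length} s available"
        )
    mean = (c1[starts + n_win] - c1[starts]) / n_win
    var = (c2[starts + n_win] - c2[starts]) / n_win - mean**2
    var = np.where(full_nrem, var, np.inf)
    i = int(np.argmin(var))
    sd = float(np.sqrt(max(var[i], 0.0)))
    start_s = dff.t0 + i / dff.fs
    return start_s, start_s + n_win / dff.fs, sd


def detect_transients(
    dff: DffTrace,
    quiet_sd: float,
    prominence_mult: float = 3.0,
    min_halfwidth: float = 1.5,
    hypnogram: Hypnogram | None = None,
    max_extent: float = 10.0,
    smooth_s: float | None = 0.1,
) -> pd.DataFrame:
    """Prominence-thresholded peak detection with a half-width filter.

    Peaks need topographic prominence > ``prominence_mult * quiet_sd``; width
    is measured at half prominence and peaks narrower than ``min_halfwidth``
    seconds are discarded. The extent of each transient is its prominence
    base interval, clipped to +-``max_extent`` s around the peak and truncated
    at the inter-peak minimum when neighbors overlap.

    Returns a DataFrame with columns peak_time_s, amplitude, half_width_s,
    start_s, end_s and (if a hypnogram is given) state.
    """
    if quiet_sd <= 0:
        raise InvalidArgumentError("quiet_sd must be > 0")
    x = _smooth(dff.samples, dff.fs, smooth_s)
    fs = dff.fs
    peaks, props = signal.find_peaks(x, prominence=prominence_mult * quiet_sd)
    if peaks.size == 0:
        return _empty_transients(hypnogram is not None)
    widths, _, _, _ = signal.peak_widths(x, peaks, rel_height=0.5)
    keep = widths / fs >= min_halfwidth
    peaks = peaks[keep]
    if peaks.size == 0:
        return _empty_transients(hypnogram is not None)
    widths = widths[keep]
    prom = props["prominences"][keep]
    left = props["left_bases"][keep]
    right = props["right_bases"][keep]

    max_ext = int(round(max_extent * fs))
    left = np.maximum(left, peaks - max_ext)
    right = np.minimum(right, peaks + max_ext)
    # truncate overlapping extents at the minimum between adjacent peaks
    for j in range(peaks.size - 1):
        if right[j] > left[j + 1]:
            lo, hi = peaks[j], peaks[j + 1]
            cut = lo + int(np.argmin(x[lo : hi + 1]))
            right[j] = min(right[j], cut)
            left[j + 1] = max(left[j + 1], cut)

    t0, times = dff.t0, None
    out = pd.DataFrame(
        {
            "peak_time_s": t0 + peaks / fs,
            "amplitude": prom,
            "half_width_s": widths / fs,
            "start_s": t0 + left / fs,
            "end_s": t0 + right / fs,
        }
    )
    if hypnogram is not None:
        out["state"] = hypnogram.state_at(out["peak_time_s"].to_numpy())
    return out


def _empty_transients(with_state: bool) -> pd.DataFrame:
    cols = ["peak_time_s", "amplitude", "half_width_s", "start_s", "end_s"]
    if with_state:
        cols.append("state")
    return pd.DataFrame({c: pd.Series(dtype=float if c != "state" else object) for c in cols})


def state_activity_summary(
    transients: pd.DataFrame,
    dff: DffTrace,
    hypnogram: Hypnogram,
) -> dict[str, dict[str, float]]:
    """Per-state transient counts, rates, mean amplitudes and cumulative
    integrals (trapezoidal integral of baseline-subtracted dF/F over each
    transient extent, summed within the state of the transient peak)."""
    if hypnogram.n_epochs == 0:
        raise InvalidArgumentError("empty hypnogram")
    if "state" not in transients.columns and len(transients):
        transients = transients.copy()
        transients["state"] = hypnogram.state_at(transients["peak_time_s"].to_numpy())
    x = dff.samples
    fs = dff.fs
    state_time_min = {
        s: np.sum(hypnogram.labels == s) * hypnogram.epoch_len / 60.0
        for s in ("W", "N", "R")
    }
    out = {}
    for s in ("W", "N", "R"):
        sel = transients[transients["state"] == s] if len(transients) else transients
        integral = 0.0
        for _, tr in sel.iterrows():
            i0 = int(round((tr["start_s"] - dff.t0) * fs))
            i1 = int(round((tr["end_s"] - dff.t0) * fs))
            i0, i1 = max(i0, 0), min(i1, x.size - 1)
            if i1 <= i0:
                continue
            seg = x[i0 : i1 + 1]
            base = np.linspace(seg[0], seg[-1], seg.size)
            integral += max(float(np.trapezoid(seg - base, dx=1.0 / fs)), 0.0)
        minutes = state_time_min[s]
        out[s] = {
            "n_transients": int(len(sel)),
            "rate_per_min": float(len(sel) / minutes) if minutes > 0 else np.nan,
            "mean_amplitude": float(sel["amplitude"].mean()) if len(sel) else np.nan,
            "cumulative_integral": integral,
            "state_minutes": minutes,
        }
    return out


def standardize_across_animals(
    summaries: pd.DataFrame,
    value_col: str = "mean_amplitude",
    pooled: bool = False,
) -> pd.DataFrame:
    """Standardized per mouse-day activity: z-score ``value_col`` (within each
    mouse, or pooled), then remove a per-mouse least-squares linear trend in
    day index. Adds a ``standardized`` column."""
    required = {"mouse", "day", value_col}
    if not required.issubset(summaries.columns):
        raise InvalidArgumentError(f"summaries must have columns {sorted(required)}")
    df = summaries.copy()
    if df.groupby("mouse")["day"].nunique().min() < 2:
        raise InsufficientDataError("need at least 2 days per mouse")
    if pooled:
        v = df[value_col].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise InsufficientDataError("zero variance in activity values")
        df["_z"] = (v - v.mean()) / sd
    else:
        def _z(g):
            v = g.to_numpy(dtype=float)
            sd = v.std()
            if sd == 0:
                return pd.Series(np.zeros_like(v), index=g.index)
            return pd.Series((v - v.mean()) / sd, index=g.index)

        df["_z"] = df.groupby("mouse")[value_col].transform(_z)

    def _detrend(g: pd.DataFrame) -> pd.Series:
        day = g["day"].to_numpy(dtype=float)
        z = g["_z"].to_numpy(dtype=float)
        coef = np.polynomial.polynomial.polyfit(day, z, 1)
        return pd.Series(z - np.polynomial.polynomial.polyval(day, coef), index=g.index)

    parts = [ _detrend(g) for _, g in df.groupby("mouse") ]
    df["standardized"] = pd.concat(parts).reindex(df.index)
    return df.drop(columns=["_z"])


def align_to_events(
    dff: DffTrace,
    event_times: np.ndarray,
    window: tuple[float, float] = (2.0, 5.0),
) -> dict:
    """Event-aligned snippets with pointwise mean and SEM.

    ``window`` is (pre, post) in seconds; events whose window falls partly
    outside the trace are dropped (their count is reported).
    """
    pre, post = window
    n_pre = int(round(pre * dff.fs))
    n_post = int(round(post * dff.fs))
    snippets = []
    dropped = 0
    for t in np.asarray(event_times, dtype=float):
        i = int(round((t - dff.t0) * dff.fs))
        if i - n_pre < 0 or i + n_post > dff.samples.size:
            dropped += 1
            continue
        snippets.append(dff.samples[i - n_pre : i + n_post])
    if not snippets:
        raise InsufficientDataError("no events with a full window inside the trace")
    mat = np.vstack(snippets)
    mean = mat.mean(axis=0)
    sem = (
        mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros_like(mean)
    )
    t = (np.arange(-n_pre, n_post)) / dff.fs
    return {"times": t, "snippets": mat, "mean": mean, "sem": sem, "n_dropped": dropped}
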