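"""Vigilance-state scoring from EEG/EMG in fixed epochs.

States are labeled ``W`` (wake), ``N`` (NREM) and ``R`` (REM).  Scoring uses a
rule-based classifier on per-epoch band powers and EMG tone: wake is high
muscle tone, NREM is delta-dominant (1-4 Hz) EEG with reduced tone, REM is
theta-dominant (4-10 Hz) EEG with muscle atonia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import CalibrationError, InsufficientDataError, InvalidArgumentError

STATES = ("W", "N", "R")

DELTA_BAND = (1.0, 4.0)
THETA_BAND = (4.0, 10.0)
TOTAL_BAND = (0.5, 25.0)

#: default decision thresholds (see classify_epochs)
DEFAULT_DELTA_THRESHOLD = 0.45
DEFAULT_THETA_RATIO_THRESHOLD = 1.5


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels on a fixed epoch grid."""

    labels: np.ndarray
    epoch_len: float = 5.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.epoch_len <= 0:
            raise InvalidArgumentError("epoch_len must be > 0")
        if self.labels.size == 0:
            raise InvalidArgumentError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise InvalidArgumentError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    @property
    def epoch_starts(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_epochs) * self.epoch_len

    def state_at(self, t) -> np.ndarray:
        """State label at time(s) ``t`` (clipped to the record)."""
        t = np.asarray(t, dtype=float)
        idx = np.floor((t - self.start_time) / self.epoch_len).astype(int)
        idx = np.clip(idx, 0, self.n_epochs - 1)
        return self.labels[idx]

    def sample_labels(self, fs: float) -> np.ndarray:
        """Labels expanded to a per-sample grid at rate ``fs``."""
        n = int(round(self.duration * fs))
        t = self.start_time + (np.arange(n) + 0.5) / fs
        return self.state_at(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_start_s": self.epoch_starts, "state": self.labels}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, epoch_len: float | None = None) -> "Hypnogram":
        starts = np.asarray(df["epoch_start_s"], dtype=float)
        if epoch_len is None:
            if starts.size < 2:
                raise InvalidArgumentError("cannot infer epoch_len from one row")
            epoch_len = float(np.median(np.diff(starts)))
        return cls(np.asarray(df["state"]), epoch_len=epoch_len, start_time=float(starts[0]))


@dataclass
class ScoringThresholds:
    """Explicit decision thresholds for classify_epochs."""

    emg_threshold: float
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    theta_ratio_threshold: float = DEFAULT_THETA_RATIO_THRESHOLD
    atonia_threshold: float = field(default=np.nan)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    m = (freqs >= lo) & (freqs <= hi)
    if not np.any(m):
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def compute_epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    epoch_len: float = 5.0,
) -> pd.DataFrame:
    """Per-epoch delta/theta/total EEG band power (Welch) and EMG RMS.

    Epochs that would overrun the traces are dropped.
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if eeg.shape != emg.shape:
        raise InvalidArgumentError("EEG and EMG traces must have the same length")
    if fs < 20:
        raise InvalidArgumentError("fs must be >= 20 Hz to resolve the 10 Hz band edge")
    spe = int(round(epoch_len * fs))
    n_epochs = eeg.size // spe
    if n_epochs == 0:
        raise InvalidArgumentError("trace shorter than one epoch")
    nperseg = min(spe, 256)
    rows = []
    for i in range(n_epochs):
        seg = eeg[i * spe : (i + 1) * spe]
        freqs, psd = signal.welch(seg, fs=fs, nperseg=nperseg)
        eseg = emg[i * spe : (i + 1) * spe]
        rows.append(
            (
                _band_power(freqs, psd, DELTA_BAND),
                _band_power(freqs, psd, THETA_BAND),
                _band_power(freqs, psd, TOTAL_BAND),
                float(np.sqrt(np.mean(eseg**2))),
            )
        )
    return pd.DataFrame(
        rows, columns=["delta_power", "theta_power", "total_power", "emg_rms"]
    )


def _otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing the between-class variance of a 1-D sample."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best, best_t = -np.inf, v[0]
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, n):
        w0 = k / n
        w1 = 1 - w0
        m0 = csum[k - 1] / k
        m1 = (total - csum[k - 1]) / (n - k)
        between = w0 * w1 * (m0 - m1) ** 2
        if between > best:
            best = between
            best_t = 0.5 * (v[k - 1] + v[k])
    return float(best_t)


def calibrate_thresholds(features: pd.DataFrame) -> ScoringThresholds:
    """Auto thresholds: EMG split via Otsu on log RMS; atonia from NREM candidates."""
    emg = np.asarray(features["emg_rms"], dtype=float)
    if np.ptp(emg) < 1e-12 or emg.size < 4:
        raise CalibrationError("EMG features are degenerate; cannot auto-calibrate")
    log_emg = np.log(emg + 1e-12)
    emg_threshold = float(np.exp(_otsu_threshold(log_emg)))
    delta_frac = features["delta_power"] / features["total_power"].replace(0, np.nan)
    nrem_candidates = emg[(emg <= emg_threshold) & (delta_frac > DEFAULT_DELTA_THRESHOLD)]
    if nrem_candidates.size == 0:
        nrem_candidates = emg[emg <= emg_threshold]
    if nrem_candidates.size == 0:
        raise CalibrationError("no sub-threshold EMG epochs; cannot calibrate atonia")
    atonia = float(np.percentile(nrem_candidates, 25))
    return ScoringThresholds(
        emg_threshold=emg_threshold,
        atonia_threshold=atonia,
    )


def classify_epochs(
    features: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
    epoch_len: float = 5.0,
    smooth_islands: bool = True,
) -> Hypnogram:
    """Rule-based scoring.

    Precedence: wake if EMG RMS above threshold; else NREM if the delta
    fraction of total power exceeds the delta threshold; else REM if the
    theta/delta ratio exceeds its threshold under atonia. Remaining epochs
    inherit the previous label (first epoch defaults to wake), and
    single-epoch islands are absorbed into the preceding bout.
    """
    if len(features) == 0:
        raise InvalidArgumentError("features are empty")
    thr = thresholds if thresholds is not None else calibrate_thresholds(features)
    delta = np.asarray(features["delta_power"], dtype=float)
    theta = np.asarray(features["theta_power"], dtype=float)
    total = np.asarray(features["total_power"], dtype=float)
    emg = np.asarray(features["emg_rms"], dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        delta_frac = np.where(total > 0, delta / total, 0.0)
        theta_ratio = np.where(delta > 0, theta / delta, np.inf)

    atonia = thr.atonia_threshold
    if np.isnan(atonia):
        atonia = thr.emg_threshold

    labels = np.full(len(features), "?", dtype="<U1")
    labels[emg > thr.emg_threshold] = "W"
    undecided = labels == "?"
    labels[undecided & (delta_frac > thr.delta_threshold)] = "N"
    undecided = labels == "?"
    labels[undecided & (theta_ratio > thr.theta_ratio_threshold) & (emg < atonia)] = "R"

    # unclassifiable epochs inherit the previous label; first defaults to wake
    prev = "W"
    for i in range(labels.size):
        if labels[i] == "?":
            labels[i] = prev
        else:
            prev = labels[i]

    if smooth_islands and labels.size > 2:
        labels = _absorb_islands(labels)
    return Hypnogram(labels, epoch_len=epoch_len)


def _absorb_islands(labels: np.ndarray) -> np.ndarray:
    """Length-1 runs are absorbed into the preceding bout (first run: following)."""
    out = labels.copy()
    runs = _runs(out)
    for j, (state, start, length) in enumerate(runs):
        if length == 1:
            if j > 0:
                out[start] = out[start - 1]
            elif len(runs) > 1:
                out[start] = runs[1][0]
    return out


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append((str(labels[start]), start, i - start))
            start = i
    return runs


def extract_bouts(hypnogram: Hypnogram) -> pd.DataFrame:
    """Maximal runs of identical labels: columns state, start_s, duration_s."""
    rows = [
        (state, hypnogram.start_time + start * hypnogram.epoch_len, length * hypnogram.epoch_len)
        for state, start, length in _runs(hypnogram.labels)
    ]
    return pd.DataFrame(rows, columns=["state", "start_s", "duration_s"])


def state_occupancy(hypnogram: Hypnogram) -> dict[str, float]:
    """Fraction of epochs in each state; missing states report 0."""
    n = hypnogram.n_epochs
    return {s: float(np.sum(hypnogram.labels == s)) / n for s in STATES}


def spectral_profile(
    eeg: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    state: str,
    band: tuple[float, float] = TOTAL_BAND,
    resolution: float = 0.2,
) -> pd.DataFrame:
    """Mean per-epoch periodogram over one state, normalized to unit in-band power.

    Returns columns ``frequency_hz`` and ``relative_power`` (sums to 1).
    """
    eeg = np.asarray(eeg, dtype=float)
    mask = hypnogram.labels == state
    if not np.any(mask):
        raise InsufficientDataError(f"state {state!r} absent from hypnogram")
    spe = int(round(hypnogram.epoch_len * fs))
    nfft = max(spe, int(round(fs / resolution)))
    acc = None
    count = 0
    for i in np.flatnonzero(mask):
        seg = eeg[i * spe : (i + 1) * spe]
        if seg.size < spe:
            continue
        freqs, psd = signal.periodogram(seg, fs=fs, nfft=nfft)
        acc = psd if acc is None else acc + psd
        count += 1
    if count == 0:
        raise InsufficientDataError(f"no complete epochs for state {state!r}")
    psd = acc / count
    sel = (freqs >= band[0]) & (freqs <= band[1])
    rel = psd[sel] / psd[sel].sum()
    return pd.DataFrame({"frequency_hz": freqs[sel], "relative_power": rel})


def emg_rms_by_state(features: pd.DataFrame, hypnogram: Hypnogram) -> dict[str, float]:
    """Mean epoch EMG RMS per state; absent states are omitted (not 0)."""
    if len(features) != hypnogram.n_epochs:
        raise InvalidArgumentError(
            f"features ({len(features)}) and hypnogram ({hypnogram.n_epochs}) length mismatch"
        )
    emg = np.asarray(features["emg_rms"], dtype=float)
    out = {}
    for s in STATES:
        m = hypnogram.labels == s
        if np.any(m):
            out[s] = float(np.mean(emg[m]))
    return out
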