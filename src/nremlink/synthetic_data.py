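"""Ground-truth-labeled synthetic multimodal datasets.

Generates, per mouse and day, a rest recording (semi-Markov hypnogram,
state-dependent EEG/EMG, photometry with Poisson transients) and next-day
maze trials whose slow-vs-fast port-visit mixture is coupled to the preceding
night's standardized NREM transient amplitude. Everything flows from one
seeded generator; sub-streams are split deterministically by
(mouse, day, modality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidArgumentError
from .maze_behavior import MazeGeometry, Trajectory
from .photometry import PhotometryTrace, standardize_across_animals
from .sleep_scoring import Hypnogram

# state-sequence grammar: Wake -> NREM; NREM -> {Wake, REM}; REM -> {Wake, NREM}
P_NREM_TO_REM = 0.35
P_REM_TO_NREM = 0.6

# GCaMP6s-like double-exponential transient kernel
TAU_RISE = 0.2
TAU_DECAY = 2.0

CRUISE_SPEED = 12.0  # cm/s locomotion between waypoints


@dataclass
class SimConfig:
    seed: int = 0
    n_mice: int = 4
    n_days: int = 4
    trials_per_day: int = 5
    rest_duration: float = 4 * 3600.0
    trial_duration: float = 60.0
    epoch_len: float = 5.0
    eeg_fs: float = 100.0
    photo_fs: float = 400.0
    track_fs: float = 10.0
    state_dwell_params: dict = field(
        default_factory=lambda: {
            "W": {"mean": 240.0, "max": 1200.0},
            "N": {"mean": 480.0, "max": 2400.0},
            "R": {"mean": 90.0, "max": 120.0},
        }
    )
    rem_latency_min: float = 3600.0
    transient_rates: dict = field(
        default_factory=lambda: {"W": 4.0, "N": 2.0, "R": 10.0}
    )  # events/min
    transient_amp_params: dict = field(
        default_factory=lambda: {"W": (0.08, 0.02), "N": (0.08, 0.02), "R": (0.12, 0.02)}
    )  # dF/F mean, SD
    drift_coeffs: tuple = (1.0, -2e-5)  # polynomial in t, low order first
    transient_min_sep: float = 3.5  # s; closer Poisson draws fuse and are thinned
    noise_sd: float = 0.01
    arena_diameter: float = 120.0
    n_ports: int = 8
    coupling: float = 0.0
    slow_speed_mu: float = 5.0
    fast_speed_mu: float = 25.0
    speed_sigma: float = 0.8
    position_jitter: float = 0.08  # cm, Gaussian jitter on sampled nose positions
    include_eeg: bool = True
    object_session_duration: float = 600.0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "trial_duration", "epoch_len", "eeg_fs",
                     "photo_fs", "track_fs", "arena_diameter"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        for name in ("n_mice", "n_days", "trials_per_day", "n_ports"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        if any(r < 0 for r in self.transient_rates.values()):
            raise InvalidArgumentError("transient rates must be >= 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    def geometry(self, correct_port: int = 0) -> MazeGeometry:
        return MazeGeometry(
            arena_diameter=self.arena_diameter,
            n_ports=self.n_ports,
            correct_port=correct_port,
        )


def _rng(seed, *key) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(config: SimConfig, duration: float, seed) -> Hypnogram:
    """Semi-Markov Wake/NREM/REM bout sequence tiled onto the epoch grid.

    Dwell times are truncated exponentials (never shorter than one epoch);
    REM is forbidden before ``rem_latency_min`` seconds from record start.
    """
    if duration < config.epoch_len:
        raise InvalidArgumentError("duration must cover at least one epoch")
    rng = _rng(seed)
    bouts = []  # (state, start, dur)
    t, state = 0.0, "W"
    while t < duration:
        p = config.state_dwell_params[state]
        dwell = min(max(rng.exponential(p["mean"]), config.epoch_len), p["max"])
        bouts.append((state, t, dwell))
        t += dwell
        if state == "W":
            state = "N"
        elif state == "N":
            allow_rem = t >= config.rem_latency_min
            state = "R" if (allow_rem and rng.random() < P_NREM_TO_REM) else "W"
        else:  # REM
            state = "N" if rng.random() < P_REM_TO_NREM else "W"
    n_epochs = int(duration // config.epoch_len)
    starts = np.arange(n_epochs) * config.epoch_len
    labels = np.empty(n_epochs, dtype="<U1")
    bi = 0
    for i, es in enumerate(starts):
        while bi + 1 < len(bouts) and bouts[bi][1] + bouts[bi][2] <= es:
            bi += 1
        labels[i] = bouts[bi][0]
    return Hypnogram(labels, epoch_len=config.epoch_len)


# ---------------------------------------------------------------------------
# EEG / EMG
# ---------------------------------------------------------------------------

# per-state component amplitudes: (delta, theta, broadband) and EMG SD
EEG_WEIGHTS = {"W": (0.4, 0.4, 1.0), "N": (3.0, 0.5, 0.5), "R": (0.4, 2.0, 0.4)}
EMG_SD = {"W": 1.0, "N": 0.1, "R": 0.02}


def _band_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.999)
    sos = signal.butter(4, [lo, hi], btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / (x.std() + 1e-12)


def synth_eeg_emg(
    hypnogram: Hypnogram, config: SimConfig, seed
) -> tuple[np.ndarray, np.ndarray]:
    """State-weighted band-limited EEG noise plus state-scaled EMG noise.

    Full-length delta/theta/broadband components are cross-faded by
    per-sample state envelopes, avoiding per-epoch filter edge artifacts.
    """
    rng = _rng(seed)
    fs = config.eeg_fs
    n = int(round(hypnogram.duration * fs))
    delta = _band_noise(n, fs, (1.0, 4.0), rng)
    theta = _band_noise(n, fs, (4.0, 10.0), rng)
    broad = _band_noise(n, fs, (0.5, 25.0), rng)
    states = hypnogram.sample_labels(fs)
    wd = np.empty(n)
    wt = np.empty(n)
    wb = np.empty(n)
    emg_sd = np.empty(n)
    for s, (a, b, c) in EEG_WEIGHTS.items():
        m = states == s
        wd[m], wt[m], wb[m] = a, b, c
        emg_sd[m] = EMG_SD[s]
    eeg = wd * delta + wt * theta + wb * broad
    eeg += config.noise_sd * rng.standard_normal(n)
    emg = emg_sd * rng.standard_normal(n) + config.noise_sd * rng.standard_normal(n)
    return eeg, emg


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def _transient_kernel(fs: float, length_s: float = 15.0) -> tuple[np.ndarray, float]:
    """Unit-peak double-exponential kernel and its peak latency (s)."""
    t = np.arange(0.0, length_s, 1.0 / fs)
    k = np.exp(-t / TAU_DECAY) - np.exp(-t / TAU_RISE)
    return k / k.max(), float(t[np.argmax(k)])


def synth_photometry(
    hypnogram: Hypnogram, config: SimConfig, seed
) -> tuple[PhotometryTrace, pd.DataFrame]:
    """Poisson transients (state-dependent rate/amplitude) on a drifting
    baseline with white noise. Returns the raw trace and the true event list
    (columns time_s [kernel peak time], onset_s, amplitude, state)."""
    rng = _rng(seed)
    fs = config.photo_fs
    n = int(round(hypnogram.duration * fs))
    t = np.arange(n) / fs
    trace = np.polynomial.polynomial.polyval(t, np.asarray(config.drift_coeffs))
    kernel, peak_lag = _transient_kernel(fs)
    events = []
    for state, start, dur in _bout_iter(hypnogram):
        rate = config.transient_rates[state] / 60.0
        n_ev = rng.poisson(rate * dur)
        times = np.sort(start + rng.random(n_ev) * dur)
        if config.transient_min_sep > 0 and times.size > 1:
            kept = [times[0]]
            for x in times[1:]:
                if x - kept[-1] >= config.transient_min_sep:
                    kept.append(x)
            times = np.asarray(kept)
        mu, sd = config.transient_amp_params[state]
        n_ev = times.size
        amps = np.maximum(rng.normal(mu, sd, n_ev), 0.2 * mu)
        for et, amp in zip(times, amps):
            i = int(round(et * fs))
            j = min(i + kernel.size, n)
            if j > i:
                trace[i:j] += amp * kernel[: j - i]
                events.append((et + peak_lag, et, amp, state))
    if config.noise_sd > 0:
        trace = trace + config.noise_sd * rng.standard_normal(n)
    ev = pd.DataFrame(events, columns=["time_s", "onset_s", "amplitude", "state"])
    return PhotometryTrace(trace, fs=fs), ev


def _bout_iter(hyp: Hypnogram):
    labels = hyp.labels
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            yield str(labels[start]), start * hyp.epoch_len, (i - start) * hyp.epoch_len
            start = i


# ---------------------------------------------------------------------------
# maze trajectories
# ---------------------------------------------------------------------------

class _Path:
    """Piecewise constant-speed waypoint path."""

    def __init__(self, start_xy, t0: float = 0.0):
        self.ts = [float(t0)]
        self.pts = [np.asarray(start_xy, dtype=float)]

    @property
    def t(self) -> float:
        return self.ts[-1]

    @property
    def cur(self) -> np.ndarray:
        return self.pts[-1]

    def goto(self, p, speed: float) -> None:
        p = np.asarray(p, dtype=float)
        d = float(np.hypot(*(p - self.cur)))
        if d < 1e-9:
            return
        self.ts.append(self.t + d / speed)
        self.pts.append(p)

    def hold(self, duration: float) -> None:
        self.ts.append(self.t + duration)
        self.pts.append(self.cur.copy())

    def sample(self, fs: float, n_frames: int) -> np.ndarray:
        t = np.arange(n_frames) / fs
        pts = np.vstack(self.pts)
        x = np.interp(t, self.ts, pts[:, 0])
        y = np.interp(t, self.ts, pts[:, 1])
        return np.column_stack([x, y])


def _polar(r: float, ang_rad: float) -> np.ndarray:
    return np.array([r * np.cos(ang_rad), r * np.sin(ang_rad)])


def _arc(path: _Path, r: float, a0: float, a1: float, speed: float, step_deg: float = 6.0):
    """Append knots along a circular arc (radians) at constant speed."""
    n = max(int(abs(a1 - a0) / np.deg2rad(step_deg)), 1)
    for a in np.linspace(a0, a1, n + 1)[1:]:
        path.goto(_polar(r, a), speed)


def _add_visit(
    path: _Path, geom: MazeGeometry, port: int, v: float, slow: bool, rng
) -> float:
    """Append a controlled-speed port visit; returns the true zone-entry time.

    The nose moves at constant speed ``v`` from 0.7 s before zone entry until
    3.0 s after, covering the -0.5..2.5 s visit-speed window with margin.
    """
    bearing = np.deg2rad(geom.port_angles_deg[port]) + np.deg2rad(rng.uniform(-2.0, 2.0))
    r_in = geom.zone_r_inner
    pre = _polar(r_in - 0.7 * v, bearing)
    path.goto(pre, CRUISE_SPEED)
    entry_point = _polar(r_in + 0.2, bearing)
    path.goto(entry_point, v)
    t_entry = path.t - 0.2 / v  # crossing of r_in happened just before the knot
    need = 3.0 * v  # post-entry constant-speed path length
    sweep_dir = 1.0 if rng.random() < 0.5 else -1.0
    if slow:
        # slow investigative visit: short radial step then a gentle arc
        # inside the zone annulus (sweep capped clear of neighboring wedges)
        path.goto(_polar(r_in + 2.5, bearing), v)
        arc_r = r_in + 3.0
        port_gap = np.deg2rad(360.0 / geom.n_ports - 2 * geom.zone_half_angle_deg - 4.0)
        sweep = min((need - 2.3) / arc_r, port_gap)
        _arc(path, arc_r, bearing, bearing + sweep_dir * sweep, v, step_deg=3.0)
        # linger: keep investigating near the port after the speed window,
        # drifting further from the wedge so the zone is not re-entered
        linger = rng.uniform(2.0, 4.0)
        t_end = path.t + linger
        a = bearing + sweep_dir * sweep
        a_max = port_gap
        rr = arc_r
        while path.t < t_end:
            if abs(a - bearing) < a_max:
                a += sweep_dir * np.deg2rad(3.0)
            rr = np.clip(rr + rng.uniform(-1.5, 1.0), geom.zone_r_inner - 6.0,
                         geom.zone_r_outer - 1.0)
            path.goto(_polar(rr, a), 3.0)
        path.goto(_polar(r_in - 4.0, bearing + sweep_dir * sweep), v)
    else:
        # fast pass-and-go: radial to mid-zone, arc out of the wedge, spiral
        # back toward the center
        mid = 0.5 * (geom.zone_r_inner + geom.zone_r_outer)
        path.goto(_polar(mid, bearing), v)
        used = mid - (r_in + 0.2)
        sweep = np.deg2rad(24.0)
        _arc(path, mid, bearing, bearing + sweep_dir * sweep, v, step_deg=6.0)
        used += mid * sweep
        a = bearing + sweep_dir * sweep
        r = mid
        while used < need:
            r = max(r - 9.0, 12.0)
            a += sweep_dir * np.deg2rad(14.0)
            leg = _polar(r, a)
            used += float(np.hypot(*(leg - path.cur)))
            path.goto(leg, v)
    # settle back toward the center region
    path.goto(_polar(rng.uniform(8.0, 18.0), rng.uniform(0, 2 * np.pi)), CRUISE_SPEED)
    return t_entry


def _enter_pod(path: _Path, geom: MazeGeometry) -> None:
    """Approach the correct pod from outside the port zones and cross the
    door line (outer zone radius inside the wedge)."""
    bearing = np.deg2rad(geom.port_angles_deg[geom.correct_port])
    off = np.deg2rad(geom.zone_half_angle_deg + 4.0)
    r_door = geom.zone_r_outer + 1.2
    path.goto(_polar(r_door, bearing + off), CRUISE_SPEED)
    _arc(path, r_door, bearing + off, bearing, 8.0, step_deg=2.0)


def _finish_trajectory(
    path: _Path, config: SimConfig, n_frames: int, rng, meta: dict
) -> Trajectory:
    fs = config.track_fs
    nose = path.sample(fs, n_frames)
    nose += rng.normal(0.0, config.position_jitter, nose.shape)
    # heading from smoothed displacement; center/tail 2 cm behind nose
    disp = np.gradient(nose, axis=0)
    norm = np.hypot(disp[:, 0], disp[:, 1])
    ok = norm > 1e-6
    u = np.zeros_like(disp)
    u[ok] = disp[ok] / norm[ok, None]
    last = np.array([1.0, 0.0])
    for i in range(n_frames):  # carry heading through pauses
        if ok[i]:
            last = u[i]
        else:
            u[i] = last
    center = nose - 2.0 * u
    tail = nose - 4.0 * u
    lim = config.arena_diameter / 2.0 - 1e-6
    for arr in (nose, center, tail):
        r = np.hypot(arr[:, 0], arr[:, 1])
        over = r > lim
        if np.any(over):
            arr[over] *= (lim / r[over])[:, None]
    # body elongates during locomotion: area shrinks with speed
    speed = norm * fs
    area = 9.0 - 0.12 * np.minimum(speed, 25.0) + 0.08 * rng.standard_normal(n_frames)
    t = np.arange(n_frames) / fs
    return Trajectory(
        time=t, nose=nose, center=center, tail=tail, area=area, fs=fs, **meta
    )


def synth_maze_session(
    drive: float,
    config: SimConfig,
    trial_duration: float | None = None,
    seed=0,
    geometry: MazeGeometry | None = None,
    **meta,
) -> tuple[Trajectory, pd.DataFrame]:
    """One maze trial: alternating locomotion, pauses and port visits whose
    motif is slow with probability ``logistic(drive)``; ends with entry into
    the correct pod. Returns the trajectory and true per-visit labels
    (columns port, entry_time_s, motif, target_speed)."""
    if trial_duration is None:
        trial_duration = config.trial_duration
    if trial_duration <= 0:
        raise InvalidArgumentError("trial_duration must be > 0")
    rng = _rng(seed)
    geom = geometry if geometry is not None else config.geometry()
    n_frames = int(round(trial_duration * config.track_fs))
    visit_budget = 12.0
    if trial_duration < visit_budget:
        raise InvalidArgumentError(
            f"trial_duration {trial_duration} s too short to contain one port visit"
        )
    p_slow = 1.0 / (1.0 + np.exp(-drive))
    path = _Path(_polar(rng.uniform(0, 3.0), rng.uniform(0, 2 * np.pi)))
    path.hold(0.5)
    visits = []
    while path.t < trial_duration - 2.0 * visit_budget:
        port = int(rng.integers(geom.n_ports))
        slow = rng.random() < p_slow
        mu = config.slow_speed_mu if slow else config.fast_speed_mu
        v = max(rng.normal(mu, config.speed_sigma), 1.0)
        t_entry = _add_visit(path, geom, port, v, slow, rng)
        visits.append((port, t_entry, "slow" if slow else "fast", v))
        if rng.random() < 0.5:
            path.hold(rng.uniform(0.5, 1.5))
    _enter_pod(path, geom)
    path.hold(max(trial_duration - path.t, 0.1))
    traj = _finish_trajectory(path, config, n_frames, rng, meta)
    truth = pd.DataFrame(
        visits, columns=["port", "entry_time_s", "motif", "target_speed"]
    )
    return traj, truth


def synth_object_session(
    preference: float,
    config: SimConfig,
    seed=0,
    duration: float | None = None,
    object_centers: np.ndarray | None = None,
    **meta,
) -> tuple[Trajectory, np.ndarray]:
    """Object-arena session whose expected novel-object share of object-zone
    dwell equals ``preference`` (novel object = index 0). Bout choices are
    self-balancing, keeping the realized ratio close to the target."""
    if not 0.0 <= preference <= 1.0:
        raise InvalidArgumentError("preference must be in [0, 1]")
    if duration is None:
        duration = config.object_session_duration
    rng = _rng(seed)
    centers = (
        np.array([[20.0, 0.0], [-20.0, 0.0]])
        if object_centers is None
        else np.asarray(object_centers, dtype=float)
    )
    n_frames = int(round(duration * config.track_fs))
    path = _Path(np.array([0.0, -10.0]))
    dwell = np.zeros(2)

    def _safe_goto(target: np.ndarray) -> None:
        """Route around object perimeters so wandering never counts as dwell."""
        for c in centers:
            p0, p1 = path.cur, target
            seg = p1 - p0
            L = np.hypot(*seg)
            if L < 1e-9:
                continue
            u = seg / L
            s = np.clip(np.dot(c - p0, u), 0.0, L)
            closest = p0 + s * u
            if np.hypot(*(c - closest)) < 5.0:
                perp = np.array([-u[1], u[0]])
                side = perp if np.dot(perp, closest - c) >= 0 else -perp
                path.goto(c + 9.0 * side, CRUISE_SPEED)
        path.goto(target, CRUISE_SPEED)

    while path.t < duration:
        # wander (clear of both object zones)
        target = rng.uniform(-28, 28, size=2)
        while min(np.hypot(*(target - c)) for c in centers) < 8.0:
            target = rng.uniform(-28, 28, size=2)
        _safe_goto(target)
        if path.t >= duration:
            break
        # self-balancing object choice
        total = dwell.sum()
        if preference in (0.0, 1.0):
            k = 0 if preference == 1.0 else 1
        elif total == 0:
            k = 0 if rng.random() < preference else 1
        else:
            p_eff = np.clip(preference + 2.0 * (preference - dwell[0] / total), 0, 1)
            k = 0 if rng.random() < p_eff else 1
        c = centers[k]
        bout = rng.uniform(3.0, 5.0)
        approach = c + np.array([0.0, -6.0])
        _safe_goto(approach)
        path.goto(c + np.array([1.2, 0.0]), CRUISE_SPEED)
        t_start = path.t
        a = 0.0
        while path.t - t_start < bout:
            a += np.deg2rad(40.0)
            path.goto(c + 1.2 * np.array([np.cos(a), np.sin(a)]), 2.5)
        dwell[k] += path.t - t_start
    traj = _finish_trajectory(path, config, n_frames, rng, meta)
    return traj, centers


# ---------------------------------------------------------------------------
# multi-day experiment
# ---------------------------------------------------------------------------

def synth_multiday_experiment(config: SimConfig) -> tuple[dict, dict]:
    """Full multi-mouse, multi-day dataset with planted sleep-behavior coupling.

    Day-``d`` trials (d >= 1) are driven by
    ``coupling * standardized NREM transient amplitude`` of the day ``d-1``
    rest; day-0 trials have zero drive. Returns ``(dataset, ground_truth)``.
    """
    rests: dict[tuple[int, int], dict] = {}
    act_rows = []
    for m in range(config.n_mice):
        for d in range(config.n_days):
            hyp = simulate_hypnogram(
                config, config.rest_duration, _rng(config.seed, m, d, 0)
            )
            rec: dict = {"hypnogram": hyp}
            if config.include_eeg:
                eeg, emg = synth_eeg_emg(hyp, config, _rng(config.seed, m, d, 1))
                rec["eeg"], rec["emg"] = eeg, emg
            trace, events = synth_photometry(hyp, config, _rng(config.seed, m, d, 2))
            rec["photometry"] = trace
            rec["true_events"] = events
            rests[(m, d)] = rec
            for state, col in (("N", "nrem"), ("R", "rem")):
                sel = events[events["state"] == state]
                act_rows.append(
                    {
                        "mouse": m,
                        "day": d,
                        "state": col,
                        "mean_amplitude": float(sel["amplitude"].mean())
                        if len(sel)
                        else 0.0,
                    }
                )
    act = pd.DataFrame(act_rows)
    activity = {}
    for state in ("nrem", "rem"):
        sub = act[act["state"] == state][["mouse", "day", "mean_amplitude"]]
        activity[state] = standardize_across_animals(sub.reset_index(drop=True))

    nrem_std = activity["nrem"].set_index(["mouse", "day"])["standardized"]
    trials: dict[tuple[int, int, int], Trajectory] = {}
    visit_frames = []
    drives: dict[tuple[int, int], float] = {}
    for m in range(config.n_mice):
        for d in range(config.n_days):
            drive = (
                config.coupling * float(nrem_std.loc[(m, d - 1)]) if d > 0 else 0.0
            )
            drives[(m, d)] = drive
            for k in range(config.trials_per_day):
                traj, truth = synth_maze_session(
                    drive,
                    config,
                    config.trial_duration,
                    seed=_rng(config.seed, m, d, 3 + k),
                    mouse_id=m,
                    day=d,
                    trial_id=k,
                )
                trials[(m, d, k)] = traj
                truth = truth.assign(mouse=m, day=d, trial=k)
                visit_frames.append(truth)
    visits = (
        pd.concat(visit_frames, ignore_index=True)
        if visit_frames
        else pd.DataFrame(
            columns=["port", "entry_time_s", "motif", "target_speed", "mouse", "day", "trial"]
        )
    )
    dataset = {"rests": rests, "trials": trials, "config": replace(config)}
    ground_truth = {
        "true_visits": visits,
        "true_nrem_activity": activity["nrem"],
        "true_rem_activity": activity["rem"],
        "true_coupling": config.coupling,
        "drives": drives,
    }
    return dataset, ground_truth
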