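"""Maze and object-arena behavioral metrics from 10 Hz tracking tables.

Port zones are annular wedges (between ``zone_r_inner`` and ``zone_r_outer``
from the maze center, within ``zone_half_angle_deg`` of a port bearing); a
port visit opens when the nose first satisfies the zone predicate, and the
visit speed is the mean absolute nose speed from -0.5 s to +2.5 s around
entry. Visit speeds are bimodal (slow investigative vs fast pass-and-go) and
are modeled with a BIC-selected Gaussian mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import (
    InsufficientDataError,
    InsufficientVarianceError,
    InvalidArgumentError,
    InvalidReferenceError,
    UndefinedRatioError,
)

VISIT_WINDOW = (-0.5, 2.5)  # seconds around port entry


@dataclass
class MazeGeometry:
    arena_diameter: float = 120.0
    n_ports: int = 8
    port_angles_deg: np.ndarray | None = None
    zone_r_inner: float = 50.0
    zone_r_outer: float = 58.0
    zone_half_angle_deg: float = 6.0
    correct_port: int = 0
    pod_perimeter: float = 3.0

    def __post_init__(self) -> None:
        if self.port_angles_deg is None:
            self.port_angles_deg = np.arange(self.n_ports) * 360.0 / self.n_ports
        self.port_angles_deg = np.asarray(self.port_angles_deg, dtype=float)
        if not (0 < self.zone_r_inner < self.zone_r_outer <= self.arena_radius):
            raise InvalidArgumentError(
                "need 0 < zone_r_inner < zone_r_outer <= arena radius"
            )
        if len(np.unique(np.mod(self.port_angles_deg, 360.0))) != len(self.port_angles_deg):
            raise InvalidArgumentError("port angles must be distinct")
        if not 0 <= self.correct_port < len(self.port_angles_deg):
            raise InvalidArgumentError("correct_port out of range")

    @property
    def arena_radius(self) -> float:
        return self.arena_diameter / 2.0

    def port_xy(self, port: int, radius: float | None = None) -> np.ndarray:
        r = self.arena_radius if radius is None else radius
        a = np.deg2rad(self.port_angles_deg[port])
        return np.array([r * np.cos(a), r * np.sin(a)])

    def pod_center(self, port: int | None = None) -> np.ndarray:
        """Pods sit at the arena edge, just outside the port zones."""
        return self.port_xy(self.correct_port if port is None else port)


@dataclass
class Trajectory:
    """10 Hz tracking: nose/center/tail coordinates (cm, maze-center origin)
    and body area, with trial provenance."""

    time: np.ndarray
    nose: np.ndarray
    center: np.ndarray
    tail: np.ndarray
    area: np.ndarray
    fs: float = 10.0
    mouse_id: int | None = None
    day: int | None = None
    trial_id: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("nose", "center", "tail"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise InvalidArgumentError(f"{name} must be (n, 2)")
            setattr(self, name, arr)
        self.area = np.asarray(self.area, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise InvalidArgumentError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.time,
                "nose_x": self.nose[:, 0],
                "nose_y": self.nose[:, 1],
                "center_x": self.center[:, 0],
                "center_y": self.center[:, 1],
                "tail_x": self.tail[:, 0],
                "tail_y": self.tail[:, 1],
                "area": self.area,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float = 10.0, **meta) -> "Trajectory":
        return cls(
            time=df["time_s"].to_numpy(),
            nose=df[["nose_x", "nose_y"]].to_numpy(),
            center=df[["center_x", "center_y"]].to_numpy(),
            tail=df[["tail_x", "tail_y"]].to_numpy(),
            area=df["area"].to_numpy(),
            fs=fs,
            **meta,
        )


def _point_speed(xy: np.ndarray, fs: float, smoothing: int) -> np.ndarray:
    if xy.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 samples")
    v = np.empty_like(xy)
    v[1:-1] = (xy[2:] - xy[:-2]) * (fs / 2.0)
    v[0] = (xy[1] - xy[0]) * fs
    v[-1] = (xy[-1] - xy[-2]) * fs
    speed = np.hypot(v[:, 0], v[:, 1])
    if smoothing and smoothing > 1:
        kernel = np.ones(smoothing) / smoothing
        pad = smoothing // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="valid")[: speed.size]
    return speed


def nose_speed(traj: Trajectory, smoothing: int = 3) -> np.ndarray:
    """Absolute nose speed (cm/s): central differences, boxcar smoothed."""
    return _point_speed(traj.nose, traj.fs, smoothing)


def center_speed(traj: Trajectory, smoothing: int = 3) -> np.ndarray:
    return _point_speed(traj.center, traj.fs, smoothing)


def _zone_port(nose: np.ndarray, geom: MazeGeometry) -> np.ndarray:
    """Per-frame port index whose zone contains the nose, or -1."""
    r = np.hypot(nose[:, 0], nose[:, 1])
    ang = np.rad2deg(np.arctan2(nose[:, 1], nose[:, 0]))
    in_ring = (r >= geom.zone_r_inner) & (r <= geom.zone_r_outer)
    out = np.full(nose.shape[0], -1, dtype=int)
    for p, pa in enumerate(geom.port_angles_deg):
        d = np.abs((ang - pa + 180.0) % 360.0 - 180.0)
        m = in_ring & (d <= geom.zone_half_angle_deg)
        out[m] = p
    return out


def detect_port_entries(
    traj: Trajectory, geom: MazeGeometry, merge_gap: float = 0.5
) -> pd.DataFrame:
    """Port visits: a visit opens at the first frame the nose satisfies the
    zone predicate; re-entries to the same port within ``merge_gap`` seconds
    of exit merge into the same visit.

    Returns columns port, entry_time_s, entry_frame, exit_time_s.
    """
    zone = _zone_port(traj.nose, geom)
    visits: list[list] = []
    for i in range(traj.n_frames):
        p = zone[i]
        if p < 0:
            continue
        if (
            visits
            and visits[-1][0] == p
            and traj.time[i] - visits[-1][3] <= merge_gap
        ):
            visits[-1][3] = traj.time[i]
        else:
            visits.append([p, traj.time[i], i, traj.time[i]])
    return pd.DataFrame(
        visits, columns=["port", "entry_time_s", "entry_frame", "exit_time_s"]
    )


def port_visit_speed(
    traj: Trajectory,
    entry_time: float,
    window: tuple[float, float] = VISIT_WINDOW,
    smoothing: int = 3,
) -> float | None:
    """Mean absolute nose speed over [entry+window[0], entry+window[1]]
    (inclusive endpoints). Returns None when the window is truncated."""
    lo = entry_time + window[0]
    hi = entry_time + window[1]
    if lo < traj.time[0] - 1e-9 or hi > traj.time[-1] + 1e-9:
        return None
    speed = nose_speed(traj, smoothing=smoothing)
    m = (traj.time >= lo - 1e-9) & (traj.time <= hi + 1e-9)
    return float(np.mean(speed[m]))


def compute_port_visits(traj: Trajectory, geom: MazeGeometry) -> pd.DataFrame:
    """Port entries annotated with visit speed; truncated-window visits are
    flagged motif='unassigned' and carry NaN speed."""
    visits = detect_port_entries(traj, geom)
    speeds, motifs = [], []
    for _, v in visits.iterrows():
        s = port_visit_speed(traj, v["entry_time_s"])
        speeds.append(np.nan if s is None else s)
        motifs.append("unassigned")
    visits["visit_speed"] = speeds
    visits["motif"] = motifs
    return visits


@dataclass
class SpeedMixture:
    """BIC-selected Gaussian mixture over port-visit speeds."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    selected_k: int
    bics: dict[int, float] = field(default_factory=dict)

    @property
    def boundary(self) -> float | None:
        """Posterior decision boundary between the two slowest components."""
        if self.selected_k < 2:
            return None
        grid = np.linspace(self.means[0], self.means[1], 2001)
        post = self._posterior(grid)
        cross = np.argmax(post[:, 1] > post[:, 0])
        return float(grid[cross])

    def _posterior(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dens = np.stack(
            [
                w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
                for m, s, w in zip(self.means, self.sds, self.weights)
            ],
            axis=1,
        )
        return dens / dens.sum(axis=1, keepdims=True)

    def assign(self, speeds: np.ndarray) -> np.ndarray:
        """'slow'/'fast' labels by posterior (components ordered by mean).
        With k selected != 2 the two extreme components are used."""
        post = self._posterior(speeds)
        if self.selected_k == 1:
            return np.array(["slow"] * len(np.atleast_1d(speeds)))
        slow_like = post[:, 0]
        fast_like = post[:, -1]
        return np.where(slow_like >= fast_like, "slow", "fast")


def fit_speed_mixture(
    speeds: np.ndarray,
    k_candidates: tuple[int, ...] = (1, 2, 3),
    seed: int = 0,
) -> SpeedMixture:
    """EM Gaussian-mixture fits for each candidate k; k minimizing BIC wins."""
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size < 20:
        raise InsufficientDataError("need at least 20 visit speeds")
    if np.ptp(speeds) < 1e-9:
        raise InsufficientVarianceError("speeds are identical; mixture is degenerate")
    X = speeds.reshape(-1, 1)
    bics, fits = {}, {}
    for k in k_candidates:
        gm = GaussianMixture(
            n_components=k, n_init=3, random_state=seed, covariance_type="full"
        ).fit(X)
        bics[k] = float(gm.bic(X))
        fits[k] = gm
    best_k = min(bics, key=bics.get)
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    return SpeedMixture(
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        weights=gm.weights_[order],
        selected_k=best_k,
        bics=bics,
    )


def _pod_entry_frame(traj: Trajectory, geom: MazeGeometry) -> int | None:
    """First frame the nose crosses the outer zone radius outward within the
    correct-port wedge (the pod 'door line')."""
    r = np.hypot(traj.nose[:, 0], traj.nose[:, 1])
    ang = np.rad2deg(np.arctan2(traj.nose[:, 1], traj.nose[:, 0]))
    pa = geom.port_angles_deg[geom.correct_port]
    d = np.abs((ang - pa + 180.0) % 360.0 - 180.0)
    beyond = (r > geom.zone_r_outer) & (d <= geom.zone_half_angle_deg)
    idx = np.flatnonzero(beyond)
    return int(idx[0]) if idx.size else None


def correct_pod_visits(
    traj: Trajectory, geom: MazeGeometry, heading_frames: int = 3
) -> dict[str, int]:
    """Approaches into the pod perimeter classified as entry vs no-entry.

    An approach starts when the nose enters the ``pod_perimeter`` around the
    correct pod. It ends in *entry* if the nose crosses the pod door line
    (outer zone radius, within the wedge); it ends *without entry* if the
    nose exits the perimeter or turns away from the pod (heading deviating
    more than 90 degrees from the nose-to-pod bearing for 2+ consecutive
    frames).
    """
    pod = geom.pod_center()
    nose = traj.nose
    dist = np.hypot(nose[:, 0] - pod[0], nose[:, 1] - pod[1])
    inside = dist <= geom.pod_perimeter
    r = np.hypot(nose[:, 0], nose[:, 1])
    ang = np.rad2deg(np.arctan2(nose[:, 1], nose[:, 0]))
    pa = geom.port_angles_deg[geom.correct_port]
    wedge = np.abs((ang - pa + 180.0) % 360.0 - 180.0) <= geom.zone_half_angle_deg
    door = (r > geom.zone_r_outer) & wedge

    heading = np.zeros_like(nose)
    k = heading_frames
    heading[k:] = nose[k:] - nose[:-k]
    to_pod = pod[None, :] - nose
    dot = np.sum(heading * to_pod, axis=1)
    away = (
        (np.hypot(heading[:, 0], heading[:, 1]) > 1e-9)
        & (dot < 0)
    )

    counts = {"with_entry": 0, "without_entry": 0}
    i = 0
    n = traj.n_frames
    while i < n:
        if not inside[i]:
            i += 1
            continue
        # approach run
        j = i
        outcome = None
        away_streak = 0
        while j < n and inside[j]:
            if door[j]:
                outcome = "with_entry"
                break
            away_streak = away_streak + 1 if away[j] else 0
            if away_streak >= 2:
                outcome = "without_entry"
                break
            j += 1
        if outcome is None:
            outcome = "without_entry"  # exited the perimeter
        counts[outcome] += 1
        # skip the rest of this inside-run
        while j < n and inside[j]:
            j += 1
        i = j
        if outcome == "with_entry":
            break
    return counts


def path_length(xy: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


def trial_metrics(
    traj: Trajectory,
    geom: MazeGeometry,
    reference: "Trajectory | float | None" = None,
    first_trial: "Trajectory | float | None" = None,
) -> dict[str, float]:
    """Per-trial distance/velocity metrics.

    distance_to_escape: cumulative center path length up to pod entry (whole
    trial on timeout). normalized_distance: divided by the reference trial's
    distance. mean_velocity: mean center speed up to entry. velocity_ratio:
    relative to the first trial's mean velocity. ``reference`` and
    ``first_trial`` accept a Trajectory or a precomputed scalar.
    """
    entry = _pod_entry_frame(traj, geom)
    end = traj.n_frames if entry is None else entry + 1
    dist = path_length(traj.center[:end])
    speed = center_speed(traj)
    mean_v = float(np.mean(speed[:end]))
    out = {
        "distance_to_escape": dist,
        "mean_velocity": mean_v,
        "escaped": entry is not None,
        "escape_time_s": np.nan if entry is None else float(traj.time[entry]),
    }
    if reference is not None:
        ref_dist = (
            trial_metrics(reference, geom)["distance_to_escape"]
            if isinstance(reference, Trajectory)
            else float(reference)
        )
        if ref_dist <= 0:
            raise InvalidReferenceError("reference distance must be > 0")
        out["normalized_distance"] = dist / ref_dist
    if first_trial is not None:
        first_v = (
            trial_metrics(first_trial, geom)["mean_velocity"]
            if isinstance(first_trial, Trajectory)
            else float(first_trial)
        )
        if first_v <= 0:
            raise InvalidReferenceError("first-trial velocity must be > 0")
        out["velocity_ratio"] = mean_v / first_v
    return out


def object_dwell_times(
    traj: Trajectory,
    object_centers: np.ndarray,
    perimeter: float = 2.0,
) -> np.ndarray:
    """Seconds the nose spends within ``perimeter`` cm of each object center."""
    centers = np.asarray(object_centers, dtype=float).reshape(-1, 2)
    dt = 1.0 / traj.fs
    out = np.zeros(centers.shape[0])
    for k, c in enumerate(centers):
        d = np.hypot(traj.nose[:, 0] - c[0], traj.nose[:, 1] - c[1])
        out[k] = np.sum(d <= perimeter) * dt
    return out


def novelty_preference(
    traj: Trajectory,
    object_centers: np.ndarray,
    perimeter: float = 2.0,
    novel_index: int = 0,
) -> float:
    """time_novel / (time_novel + time_familiar); exploration is nose within
    the object perimeter."""
    dwell = object_dwell_times(traj, object_centers, perimeter)
    if dwell.size != 2:
        raise InvalidArgumentError("exactly two object centers required")
    total = dwell.sum()
    if total == 0:
        raise UndefinedRatioError("no object exploration time")
    return float(dwell[novel_index] / total)


def occupancy_map(
    traj: Trajectory, geom: MazeGeometry, bin_cm: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D dwell-time histogram (seconds per bin) of the center point."""
    if bin_cm <= 0:
        raise InvalidArgumentError("bin size must be > 0")
    r = geom.arena_radius
    edges = np.arange(-r, r + bin_cm, bin_cm)
    h, xe, ye = np.histogram2d(
        traj.center[:, 0], traj.center[:, 1], bins=(edges, edges)
    )
    return h / traj.fs, xe, ye
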