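"""Plain-text readers/writers for traces, hypnograms and tracking tables.

Traces are single-column CSV files with a JSON sidecar ({fs, units, t0});
hypnograms are CSV (epoch_start_s, state); tracking tables are CSV with the
frame/time/nose/center/tail/area columns produced by the generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .maze_behavior import Trajectory
from .photometry import PhotometryTrace
from .sleep_scoring import Hypnogram


def write_trace(prefix: str | Path, samples: np.ndarray, fs: float,
                units: str = "au", t0: float = 0.0) -> Path:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    np.savetxt(csv_path, np.asarray(samples, dtype=float), fmt="%.10g")
    prefix.with_suffix(".json").write_text(
        json.dumps({"fs": fs, "units": units, "t0": t0})
    )
    return csv_path


def read_trace(prefix: str | Path) -> PhotometryTrace:
    prefix = Path(prefix)
    if prefix.suffix:
        prefix = prefix.with_suffix("")
    samples = np.loadtxt(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return PhotometryTrace(samples, fs=meta["fs"], t0=meta.get("t0", 0.0))


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    hyp.to_frame().to_csv(path, index=False)
    return path


def read_hypnogram(path: str | Path, epoch_len: float | None = None) -> Hypnogram:
    return Hypnogram.from_frame(pd.read_csv(path), epoch_len=epoch_len)


def write_tracking(path: str | Path, traj: Trajectory) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(path, index=False)
    return path


def read_tracking(
    path: str | Path,
    fs: float = 10.0,
    column_map: dict[str, str] | None = None,
    **meta,
) -> Trajectory:
    """Read a tracking CSV; ``column_map`` renames external column names to
    the canonical ones (import shim for third-party tables)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return Trajectory.from_frame(df, fs=fs, **meta)
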