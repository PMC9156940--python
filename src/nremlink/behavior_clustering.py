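"""Temporally regularized VAE + self-organizing-map clustering of trajectory
windows.

Each 10 s window (100 time steps x 7 features at 10 Hz) is encoded into a
4-dimensional Gaussian latent; a SOM codebook over the latent space assigns
every window to one of ``som_rows x som_cols`` (default 36) behavioral
clusters. Training jointly optimizes reconstruction (Gaussian ELBO), a SOM
assignment/commitment loss with neighborhood smoothing, a latent temporal
smoothness penalty between consecutive windows, and a one-step linear latent
forecasting loss.

Implemented in numpy with hand-written backpropagation so that training is
deterministic given a seed and runs on a single CPU at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidStateError,
    TrainingError,
)
from .maze_behavior import MazeGeometry, Trajectory

FEATURE_NAMES = (
    "center_x",
    "center_y",
    "nose_rel_x",
    "nose_rel_y",
    "tail_rel_x",
    "tail_rel_y",
    "area",
)


@dataclass
class ClusterConfig:
    latent_dim: int = 4
    som_rows: int = 6
    som_cols: int = 6
    hidden: int = 128
    window_s: float = 10.0
    step_s: float = 1.0
    batch_size: int = 100
    epochs: int = 30
    lr: float = 1e-2
    patience: int = 5
    kl_weight: float = 1.0
    som_weight: float = 1.0
    smooth_weight: float = 0.1
    predict_weight: float = 0.1
    val_frac: float = 0.15
    som_lr: float = 0.5
    som_sigma0: float = 2.0
    som_sigma_min: float = 0.5
    min_samples: int = 500
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return self.som_rows * self.som_cols


@dataclass
class WindowedSamples:
    """N x L x 7 window array with per-sample provenance."""

    X: np.ndarray
    provenance: pd.DataFrame  # columns mouse, day, trial, start_s

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3 or self.X.shape[2] != len(FEATURE_NAMES):
            raise InvalidArgumentError("X must be (N, L, 7)")
        if len(self.provenance) != self.X.shape[0]:
            raise InvalidArgumentError("provenance must have one row per sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def trial_keys(self) -> pd.DataFrame:
        return self.provenance[["mouse", "day", "trial"]].drop_duplicates()

    def successor_pairs(self, step_s: float) -> np.ndarray:
        """Indices (i, j) of consecutive windows within the same trial."""
        p = self.provenance
        pairs = []
        key = list(zip(p["mouse"], p["day"], p["trial"]))
        start = p["start_s"].to_numpy()
        order = np.lexsort((start, [k[2] for k in key], [k[1] for k in key], [k[0] for k in key]))
        for a, b in zip(order[:-1], order[1:]):
            if key[a] == key[b] and abs(start[b] - start[a] - step_s) < 1e-6:
                pairs.append((a, b))
        return np.asarray(pairs, dtype=int).reshape(-1, 2)


def featurize(traj: Trajectory, geom: MazeGeometry | None = None) -> np.ndarray:
    """7-feature series at the tracking rate: maze-center-referenced center
    coordinates, nose and tail relative to center, and body area."""
    return np.column_stack(
        [
            traj.center[:, 0],
            traj.center[:, 1],
            traj.nose[:, 0] - traj.center[:, 0],
            traj.nose[:, 1] - traj.center[:, 1],
            traj.tail[:, 0] - traj.center[:, 0],
            traj.tail[:, 1] - traj.center[:, 1],
            traj.area,
        ]
    )


def window(
    series: np.ndarray,
    fs: float = 10.0,
    window_s: float = 10.0,
    step_s: float = 1.0,
    meta: dict | None = None,
) -> WindowedSamples:
    """Overlapping windows of ``window_s`` seconds every ``step_s`` seconds;
    the trailing partial window is dropped."""
    series = np.asarray(series, dtype=float)
    L = int(round(window_s * fs))
    step = max(int(round(step_s * fs)), 1)
    n = series.shape[0]
    meta = meta or {}
    starts = list(range(0, n - L + 1, step))
    X = np.stack([series[s : s + L] for s in starts]) if starts else np.empty((0, L, 7))
    prov = pd.DataFrame(
        {
            "mouse": meta.get("mouse", 0),
            "day": meta.get("day", 0),
            "trial": meta.get("trial", 0),
            "start_s": [s / fs for s in starts],
        }
    )
    return WindowedSamples(X, prov)


def build_windows(
    trajectories: list[Trajectory],
    config: ClusterConfig | None = None,
) -> WindowedSamples:
    """Featurize and window a list of trajectories into one sample set."""
    config = config or ClusterConfig()
    parts_X, parts_p = [], []
    for traj in trajectories:
        w = window(
            featurize(traj),
            fs=traj.fs,
            window_s=config.window_s,
            step_s=config.step_s,
            meta={
                "mouse": traj.mouse_id or 0,
                "day": traj.day or 0,
                "trial": traj.trial_id or 0,
            },
        )
        if w.n_samples:
            parts_X.append(w.X)
            parts_p.append(w.provenance)
    if not parts_X:
        raise InsufficientDataError("no complete windows in input trajectories")
    return WindowedSamples(np.concatenate(parts_X), pd.concat(parts_p, ignore_index=True))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


class ClusterModel:
    """Trained VAE+SOM: network parameters, feature standardization constants
    and the SOM codebook."""

    def __init__(self, config: ClusterConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.codebook: np.ndarray | None = None
        self.feat_mean: np.ndarray | None = None
        self.feat_sd: np.ndarray | None = None
        self.trained = False
        self.val_mse = np.nan
        self.history: list[dict] = []

    # -- initialization ----------------------------------------------------
    def init_params(self, input_dim: int, rng: np.random.Generator) -> None:
        c = self.config
        H, L = c.hidden, c.latent_dim

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        self.params = {
            "W1": glorot(input_dim, H), "b1": np.zeros(H),
            "Wm": glorot(H, L), "bm": np.zeros(L),
            "Wv": glorot(H, L), "bv": np.full(L, -2.0),
            "W4": glorot(L, H), "b4": np.zeros(H),
            "W5": glorot(H, input_dim), "b5": np.zeros(input_dim),
            "Wp": np.eye(L) + 0.01 * rng.standard_normal((L, L)), "bp": np.zeros(L),
        }
        self.codebook = 0.5 * rng.standard_normal((c.n_clusters, L))
        self.grid = _grid_coords(c.som_rows, c.som_cols)

    # -- forward -----------------------------------------------------------
    def standardize(self, X: np.ndarray) -> np.ndarray:
        flat = X.reshape(X.shape[0], -1)
        mean = np.tile(self.feat_mean, X.shape[1])
        sd = np.tile(self.feat_sd, X.shape[1])
        return (flat - mean) / sd

    def destandardize(self, flat: np.ndarray, L_steps: int) -> np.ndarray:
        mean = np.tile(self.feat_mean, L_steps)
        sd = np.tile(self.feat_sd, L_steps)
        return (flat * sd + mean).reshape(flat.shape[0], L_steps, len(FEATURE_NAMES))

    def encode(self, x: np.ndarray):
        p = self.params
        h = np.tanh(x @ p["W1"] + p["b1"])
        mu = h @ p["Wm"] + p["bm"]
        lv = np.clip(h @ p["Wv"] + p["bv"], -8.0, 8.0)
        return h, mu, lv

    def decode(self, z: np.ndarray):
        p = self.params
        hd = np.tanh(z @ p["W4"] + p["b4"])
        return hd, hd @ p["W5"] + p["b5"]

    def bmu(self, mu: np.ndarray) -> np.ndarray:
        d = ((mu[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "params.npz", **self.params)
        np.savez(
            d / "state.npz",
            codebook=self.codebook,
            feat_mean=self.feat_mean,
            feat_sd=self.feat_sd,
        )
        meta = {"config": asdict(self.config), "val_mse": float(self.val_mse),
                "trained": self.trained}
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ClusterModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        model = cls(ClusterConfig(**meta["config"]))
        model.params = dict(np.load(d / "params.npz"))
        state = np.load(d / "state.npz")
        model.codebook = state["codebook"]
        model.feat_mean = state["feat_mean"]
        model.feat_sd = state["feat_sd"]
        model.trained = meta["trained"]
        model.val_mse = meta["val_mse"]
        model.grid = _grid_coords(model.config.som_rows, model.config.som_cols)
        return model


def _adam_update(params, grads, m, v, t, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    for k, g in grads.items():
        m[k] = beta1 * m[k] + (1 - beta1) * g
        v[k] = beta2 * v[k] + (1 - beta2) * g * g
        mhat = m[k] / (1 - beta1**t)
        vhat = v[k] / (1 - beta2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_cluster_model(
    samples: WindowedSamples, config: ClusterConfig | None = None
) -> ClusterModel:
    """Train the VAE+SOM on windowed samples (85/15 train/validation split at
    trial granularity, early stopping on validation reconstruction error)."""
    config = config or ClusterConfig()
    if samples.n_samples < config.min_samples:
        raise InsufficientDataError(
            f"need >= {config.min_samples} samples, got {samples.n_samples}"
        )
    rng = np.random.default_rng(config.seed)
    model = ClusterModel(config)

    # feature standardization constants from the full training pool
    flat_feats = samples.X.reshape(-1, len(FEATURE_NAMES))
    model.feat_mean = flat_feats.mean(axis=0)
    model.feat_sd = np.maximum(flat_feats.std(axis=0), 1e-9)

    Xs = model.standardize(samples.X)
    D = Xs.shape[1]
    model.init_params(D, rng)
    p = model.params

    # split by trial to avoid leakage between overlapping windows
    trials = samples.trial_keys.reset_index(drop=True)
    n_val_trials = max(int(round(config.val_frac * len(trials))), 1)
    perm = rng.permutation(len(trials))
    val_trials = set(map(tuple, trials.iloc[perm[:n_val_trials]].to_numpy()))
    key_arr = list(
        zip(samples.provenance["mouse"], samples.provenance["day"], samples.provenance["trial"])
    )
    is_val = np.array([k in val_trials for k in key_arr])
    train_idx = np.flatnonzero(~is_val)
    val_idx = np.flatnonzero(is_val)
    if train_idx.size == 0 or val_idx.size == 0:
        raise InsufficientDataError("train/validation split left an empty side")

    pairs = samples.successor_pairs(config.step_s)
    pair_ok = ~is_val[pairs[:, 0]] & ~is_val[pairs[:, 1]] if pairs.size else np.array([], bool)
    train_pairs = pairs[pair_ok] if pairs.size else pairs
    succ = np.full(samples.n_samples, -1, dtype=int)
    if train_pairs.size:
        succ[train_pairs[:, 0]] = train_pairs[:, 1]

    m_adam = {k: np.zeros_like(v) for k, v in p.items()}
    v_adam = {k: np.zeros_like(v) for k, v in p.items()}
    step = 0
    best_val = np.inf
    best_params = None
    best_codebook = None
    bad_epochs = 0
    n_batches = max(train_idx.size // config.batch_size, 1)
    c = config

    for epoch in range(c.epochs):
        frac = epoch / max(c.epochs - 1, 1)
        sigma = c.som_sigma0 + (c.som_sigma_min - c.som_sigma0) * frac
        som_lr = c.som_lr * (1.0 - 0.9 * frac)
        order = rng.permutation(train_idx)
        ep_loss = 0.0
        for b in range(n_batches):
            idx = order[b * c.batch_size : (b + 1) * c.batch_size]
            if idx.size == 0:
                continue
            x = Xs[idx]
            B = x.shape[0]
            h, mu, lv = model.encode(x)
            eps_z = rng.standard_normal(mu.shape)
            z = mu + np.exp(0.5 * lv) * eps_z
            hd, xo = model.decode(z)

            grads = {k: np.zeros_like(v) for k, v in p.items()}
            # reconstruction (per-element MSE)
            dxo = 2.0 * (xo - x) / (B * D)
            loss = float(np.mean((xo - x) ** 2))
            # KL
            kl = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0) / B
            loss += c.kl_weight * kl / D
            dmu = (c.kl_weight / D) * mu / B
            dlv = (c.kl_weight / D) * 0.5 * (np.exp(lv) - 1.0) / B
            # SOM commitment with neighborhood smoothing (codebook frozen
            # w.r.t. encoder gradient)
            bmu = model.bmu(mu)
            zq = model.codebook[bmu]
            som_term = np.sum((mu - zq) ** 2) / (B * c.latent_dim)
            loss += c.som_weight * som_term
            dmu = dmu + c.som_weight * 2.0 * (mu - zq) / (B * c.latent_dim)
            # temporal smoothness + one-step forecast on successor pairs
            has_next = succ[idx] >= 0
            if np.any(has_next) and (c.smooth_weight > 0 or c.predict_weight > 0):
                ii = np.flatnonzero(has_next)
                x2 = Xs[succ[idx[ii]]]
                h2, mu2, lv2 = model.encode(x2)
                P = ii.size
                diff = mu[ii] - mu2
                loss += c.smooth_weight * np.sum(diff**2) / (P * c.latent_dim)
                g = c.smooth_weight * 2.0 * diff / (P * c.latent_dim)
                dmu2 = -g
                dmu[ii] += g
                pred = mu[ii] @ p["Wp"] + p["bp"]
                perr = pred - mu2  # mu2 treated as target (no gradient)
                loss += c.predict_weight * np.sum(perr**2) / (P * c.latent_dim)
                dpred = c.predict_weight * 2.0 * perr / (P * c.latent_dim)
                grads["Wp"] += mu[ii].T @ dpred
                grads["bp"] += dpred.sum(axis=0)
                dmu[ii] += dpred @ p["Wp"].T
                # backprop the successor encoder pass (smoothness only)
                dh2 = dmu2 @ p["Wm"].T
                da2 = (1.0 - h2**2) * dh2
                grads["W1"] += x2.T @ da2
                grads["b1"] += da2.sum(axis=0)
                grads["Wm"] += h2.T @ dmu2
                grads["bm"] += dmu2.sum(axis=0)

            # decoder backprop
            grads["W5"] += hd.T @ dxo
            grads["b5"] += dxo.sum(axis=0)
            dhd = dxo @ p["W5"].T
            dzin = (1.0 - hd**2) * dhd
            grads["W4"] += z.T @ dzin
            grads["b4"] += dzin.sum(axis=0)
            dz = dzin @ p["W4"].T
            dmu = dmu + dz
            dlv = dlv + dz * eps_z * 0.5 * np.exp(0.5 * lv)
            # encoder backprop
            dh = dmu @ p["Wm"].T + dlv @ p["Wv"].T
            da = (1.0 - h**2) * dh
            grads["W1"] += x.T @ da
            grads["b1"] += da.sum(axis=0)
            grads["Wm"] += h.T @ dmu
            grads["bm"] += dmu.sum(axis=0)
            grads["Wv"] += h.T @ dlv
            grads["bv"] += dlv.sum(axis=0)

            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            step += 1
            _adam_update(p, grads, m_adam, v_adam, step, c.lr)

            # SOM codebook update (classic neighborhood-weighted pull)
            gd = ((model.grid[bmu][:, None, :] - model.grid[None, :, :]) ** 2).sum(axis=2)
            hnb = np.exp(-gd / (2.0 * sigma**2))  # (B, K)
            wk = hnb.sum(axis=0)  # per-node neighborhood mass
            target = (hnb.T @ mu) / (wk[:, None] + 1e-9)
            eta = som_lr * wk / (wk.max() + 1e-9)
            model.codebook += eta[:, None] * (target - model.codebook)

            ep_loss += loss

        # validation reconstruction error (deterministic: z = mu)
        _, vmu, _ = model.encode(Xs[val_idx])
        _, vxo = model.decode(vmu)
        val_mse = float(np.mean((vxo - Xs[val_idx]) ** 2))
        model.history.append(
            {"epoch": epoch, "train_loss": ep_loss / n_batches, "val_mse": val_mse}
        )
        if val_mse < best_val - 1e-6:
            best_val = val_mse
            best_params = {k: v.copy() for k, v in p.items()}
            best_codebook = model.codebook.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > c.patience:
                break

    if best_params is not None:
        model.params = best_params
        model.codebook = best_codebook
    model.val_mse = best_val
    model.trained = True
    return model


@dataclass
class ClusterMap:
    """Per-window cluster labels plus per-trial occupancy vectors."""

    labels: np.ndarray
    provenance: pd.DataFrame
    n_clusters: int

    def occupancy(self) -> pd.DataFrame:
        """Per-trial fraction of windows in each cluster (rows on the simplex)."""
        df = self.provenance.copy()
        df["label"] = self.labels
        rows = []
        for (mouse, day, trial), g in df.groupby(["mouse", "day", "trial"]):
            counts = np.bincount(g["label"], minlength=self.n_clusters).astype(float)
            occ = counts / counts.sum()
            rows.append({"mouse": mouse, "day": day, "trial": trial,
                         **{f"occ_{k}": occ[k] for k in range(self.n_clusters)}})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        df = self.provenance.copy()
        df["label"] = self.labels
        return df


def assign_clusters(model: ClusterModel, samples: WindowedSamples) -> ClusterMap:
    """Label each window with its nearest SOM codebook node (posterior mean)."""
    if not model.trained:
        raise InvalidStateError("model is not trained")
    if samples.X.shape[2] != len(FEATURE_NAMES):
        raise InvalidArgumentError("feature count mismatch")
    Xs = model.standardize(samples.X)
    _, mu, _ = model.encode(Xs)
    labels = model.bmu(mu)
    return ClusterMap(labels=labels, provenance=samples.provenance.copy(),
                      n_clusters=model.config.n_clusters)


def reconstruct(model: ClusterModel, samples: WindowedSamples):
    """Decode each window from its latent mean.

    Returns (reconstructions in original units, per-sample standardized MSE,
    aggregate standardized MSE).
    """
    if not model.trained:
        raise InvalidStateError("model is not trained")
    Xs = model.standardize(samples.X)
    _, mu, _ = model.encode(Xs)
    _, xo = model.decode(mu)
    per_sample = np.mean((xo - Xs) ** 2, axis=1)
    rec = model.destandardize(xo, samples.X.shape[1])
    return rec, per_sample, float(per_sample.mean())
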