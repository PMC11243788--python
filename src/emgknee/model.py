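"""Attention-based GRU encoder-decoder knee-angle estimator.

Architecture: a single-layer GRU encoder consumes the ordered 20-sample EMG
segments of one gait cycle (M = (L/20) x n_channels encoder steps); at each
of the L decoder steps a Bahdanau attention block scores every encoder
state against the previous decoder state,

    score(j, t) = Va' tanh(Ua s(t-1) + Wa h(j)),
    alpha(j, t) = softmax_j score(j, t),
    c(t)        = sum_j alpha(j, t) h(j),

and a GRU decoder cell consumes [y(t-1); c(t)] to produce s(t); the knee
angle on the normalized [0, 1] scale is sigmoid(w's(t) + b), de-normalized
to degrees with the training-set angle bounds.  The attention-free baseline
replaces c(t) by the final encoder state h(M) at every step.

Training is full-batch ADAM on binary cross-entropy over min-max-normalized
angles (MSE available via config), with teacher forcing, stopping when the
free-running training RMSE drops below 15 degrees or after 10,000 epochs.

The module follows the Model/Results convention: ``KneeAngleGRU(dataset,
config).fit()`` returns a ``KneeAngleGRUResults`` with the parameters,
history, ``summary()`` and estimation/evaluation methods.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _autodiff as ad
from ._autodiff import Tensor
from .gait import (GaitCycle, GaitCycleDataset, NormStats, SegmentSequence,
                   dataset_arrays, segment)
from . import metrics as mx

__all__ = [
    "GruAmConfig", "KneeAngleGRU", "KneeAngleGRUResults",
    "alignment_score", "attention_weights", "context_vector",
    "train", "gru_baseline_config",
]


# -- attention primitives (pure numpy; mirrored inside the taped forward) ---

def alignment_score(va: np.ndarray, ua: np.ndarray, wa: np.ndarray,
                    s_prev: np.ndarray, h_j: np.ndarray) -> float:
    """Bahdanau alignment score Va' tanh(Ua s_prev + Wa h_j)."""
    va = np.atleast_1d(np.asarray(va, dtype=float))
    ua = np.atleast_2d(np.asarray(ua, dtype=float))
    wa = np.atleast_2d(np.asarray(wa, dtype=float))
    s_prev = np.atleast_1d(np.asarray(s_prev, dtype=float))
    h_j = np.atleast_1d(np.asarray(h_j, dtype=float))
    pre = s_prev @ ua + h_j @ wa
    if pre.shape[-1] != va.shape[0]:
        raise ValueError("attention dimensions are inconsistent")
    return float(np.tanh(pre) @ va)


def attention_weights(scores) -> np.ndarray:
    """Softmax normalization of alignment scores over encoder steps."""
    s = np.asarray(scores, dtype=float).ravel()
    if s.size < 1:
        raise ValueError("need at least one score")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite alignment score")
    z = np.exp(s - s.max())
    return z / z.sum()


def context_vector(weights, encoder_states) -> np.ndarray:
    """Attention-weighted sum of encoder hidden states."""
    w = np.asarray(weights, dtype=float).ravel()
    h = np.atleast_2d(np.asarray(encoder_states, dtype=float))
    if w.size != h.shape[0]:
        raise ValueError(f"{w.size} weights for {h.shape[0]} encoder states")
    return w @ h


# -- configuration ----------------------------------------------------------

@dataclass(frozen=True)
class GruAmConfig:
    """Hyperparameters of the estimator and its training loop."""

    hidden_size: int = 100
    attn_size: int | None = 64        # alignment-model width
    segment_window: int = 20
    L: int = 100
    use_attention: bool = True
    loss: str = "bce"                 # "bce" (published choice) or "mse"
    learning_rate: float = 1e-3
    rmse_stop: float = 15.0           # degrees, on the training set
    max_epochs: int = 10000
    seed: int = 0
    # free-running decoding during training matches the inference regime and
    # avoids exposure bias (teacher forcing trains a one-step-ahead predictor
    # that degrades sharply when fed its own outputs)
    teacher_forcing: bool = False

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.rmse_stop <= 0:
            raise ValueError("rmse_stop must be positive")
        if self.loss not in ("bce", "mse"):
            raise ValueError("loss must be 'bce' or 'mse'")

    @property
    def attention_size(self) -> int:
        """Width of the Bahdanau alignment model (defaults to 64)."""
        return self.attn_size if self.attn_size is not None else self.hidden_size


def gru_baseline_config(cfg: GruAmConfig) -> GruAmConfig:
    """The matched attention-free arm: identical except use_attention."""
    d = asdict(cfg)
    d["use_attention"] = False
    return GruAmConfig(**d)


# -- parameters -------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(cfg: GruAmConfig, input_dim: int) -> dict[str, np.ndarray]:
    """Seeded Glorot-uniform initialization of all trainable weights."""
    rng = np.random.default_rng(cfg.seed)
    H, A = cfg.hidden_size, cfg.attention_size
    params: dict[str, np.ndarray] = {}
    for prefix, in_dim in (("enc", input_dim), ("dec", 1 + H)):
        for gate in ("z", "r", "n"):
            params[f"{prefix}_W{gate}"] = _glorot(rng, (in_dim, H))
            params[f"{prefix}_U{gate}"] = _glorot(rng, (H, H))
            params[f"{prefix}_b{gate}"] = np.zeros(H)
    if cfg.use_attention:
        params["att_Wa"] = _glorot(rng, (H, A))
        params["att_Ua"] = _glorot(rng, (H, A))
        params["att_Va"] = _glorot(rng, (A, 1))
    params["out_W"] = _glorot(rng, (H, 1))
    params["out_b"] = np.zeros(1)
    return params


def n_params(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


# -- GRU cell ---------------------------------------------------------------

def gru_cell_np(p: dict, prefix: str, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    z = _sig(x @ p[f"{prefix}_Wz"] + h @ p[f"{prefix}_Uz"] + p[f"{prefix}_bz"])
    r = _sig(x @ p[f"{prefix}_Wr"] + h @ p[f"{prefix}_Ur"] + p[f"{prefix}_br"])
    n = np.tanh(x @ p[f"{prefix}_Wn"] + (r * h) @ p[f"{prefix}_Un"]
                + p[f"{prefix}_bn"])
    return (1.0 - z) * n + z * h


def _sig(x: np.ndarray) -> np.ndarray:
    return ad._sigmoid(x)


def _gru_cell_tape(P: dict[str, Tensor], prefix: str, x: Tensor,
                   h: Tensor) -> Tensor:
    z = ad.sigmoid(ad.add(ad.add(ad.matmul(x, P[f"{prefix}_Wz"]),
                                 ad.matmul(h, P[f"{prefix}_Uz"])),
                          P[f"{prefix}_bz"]))
    r = ad.sigmoid(ad.add(ad.add(ad.matmul(x, P[f"{prefix}_Wr"]),
                                 ad.matmul(h, P[f"{prefix}_Ur"])),
                          P[f"{prefix}_br"]))
    n = ad.tanh(ad.add(ad.add(ad.matmul(x, P[f"{prefix}_Wn"]),
                              ad.matmul(ad.mul(r, h), P[f"{prefix}_Un"])),
                       P[f"{prefix}_bn"]))
    one_minus_z = ad.sub(Tensor(1.0), z)
    return ad.add(ad.mul(one_minus_z, n), ad.mul(z, h))


# -- forward passes ---------------------------------------------------------

def forward_infer(params: dict, X: np.ndarray, cfg: GruAmConfig) -> np.ndarray:
    """Free-running inference: (n, M, w) segments -> (n, L) normalized angle."""
    n, M, _ = X.shape
    H = cfg.hidden_size
    h = np.zeros((n, H))
    Hs = np.empty((n, M, H))
    for j in range(M):
        h = gru_cell_np(params, "enc", X[:, j, :], h)
        Hs[:, j, :] = h
    s = h
    h_final = h
    if cfg.use_attention:
        WaH = Hs @ params["att_Wa"]
    y_prev = np.zeros((n, 1))
    out = np.empty((n, cfg.L))
    for t in range(cfg.L):
        if cfg.use_attention:
            u = s @ params["att_Ua"]
            scores = (np.tanh(WaH + u[:, None, :]) @ params["att_Va"])[:, :, 0]
            zmax = scores.max(axis=1, keepdims=True)
            e = np.exp(scores - zmax)
            alpha = e / e.sum(axis=1, keepdims=True)
            c = np.einsum("nm,nmh->nh", alpha, Hs)
        else:
            c = h_final
        s = gru_cell_np(params, "dec", np.concatenate([y_prev, c], axis=1), s)
        y = _sig(s @ params["out_W"] + params["out_b"])
        out[:, t] = y[:, 0]
        y_prev = y
    return out


def training_loss(P: dict[str, Tensor], X: np.ndarray, Y: np.ndarray,
                  cfg: GruAmConfig) -> Tensor:
    """Taped (differentiable) forward pass and loss, teacher forced."""
    n, M, _ = X.shape
    h: Tensor = Tensor(np.zeros((n, cfg.hidden_size)))
    hs: list[Tensor] = []
    for j in range(M):
        h = _gru_cell_tape(P, "enc", Tensor(X[:, j, :]), h)
        hs.append(h)
    s = hs[-1]
    h_final = hs[-1]
    if cfg.use_attention:
        Hs = ad.stack(hs, axis=1)                       # (n, M, H)
        WaH = ad.matmul(Hs, P["att_Wa"])                # (n, M, A)
    logits: list[Tensor] = []
    y_prev: Tensor = Tensor(np.zeros((n, 1)))
    for t in range(cfg.L):
        if cfg.use_attention:
            u = ad.reshape(ad.matmul(s, P["att_Ua"]), (n, 1, cfg.attention_size))
            e = ad.tanh(ad.add(WaH, u))
            scores = ad.reshape(ad.matmul(e, P["att_Va"]), (n, M))
            alpha = ad.softmax(scores, axis=1)
            c = ad.tsum(ad.mul(Hs, ad.reshape(alpha, (n, M, 1))), axis=1)
        else:
            c = h_final
        s = _gru_cell_tape(P, "dec", ad.concat([y_prev, c], axis=1), s)
        logit = ad.add(ad.matmul(s, P["out_W"]), P["out_b"])
        logits.append(logit)
        if cfg.teacher_forcing:
            y_prev = Tensor(Y[:, t:t + 1])
        else:
            y_prev = ad.sigmoid(logit)
    all_logits = ad.concat(logits, axis=1)               # (n, L)
    if cfg.loss == "bce":
        return ad.bce_with_logits(all_logits, Y)
    return ad.tmean(ad.square(ad.sub(ad.sigmoid(all_logits), Tensor(Y))))


class _Adam:
    """Plain ADAM on a dict of ndarrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


# -- model / results --------------------------------------------------------

class KneeAngleGRU:
    """Knee-angle estimation model over a segmented gait-cycle dataset."""

    def __init__(self, dataset: GaitCycleDataset, config: GruAmConfig | None = None):
        self.dataset = dataset
        self.config = config or GruAmConfig()
        if not dataset.train_cycles:
            raise ValueError("dataset has no training cycles")
        if dataset.L % self.config.segment_window != 0:
            raise ValueError("cycle length not divisible by segment window")

    @property
    def M(self) -> int:
        return (self.dataset.L // self.config.segment_window) * \
            len(self.dataset.channels)

    def fit(self, start_params: dict | None = None,
            max_epochs: int | None = None,
            rmse_stop: float | None = None) -> "KneeAngleGRUResults":
        """ADAM-optimize the configured loss; stop at RMSE < rmse_stop
        (free-running, degrees, training set) or at the epoch budget."""
        cfg = self.config
        max_epochs = cfg.max_epochs if max_epochs is None else max_epochs
        rmse_stop = cfg.rmse_stop if rmse_stop is None else rmse_stop
        stats = self.dataset.stats
        X, Y = dataset_arrays(self.dataset.train_cycles, stats,
                              cfg.segment_window)
        params = ({k: v.copy() for k, v in start_params.items()}
                  if start_params is not None
                  else init_params(cfg, cfg.segment_window))
        opt = _Adam(params, cfg.learning_rate)
        truth_deg = stats.denorm_angle(Y)
        history: list[dict] = []
        stop_reason = "max_epochs" if max_epochs > 0 else "no_epochs"
        for epoch in range(1, max_epochs + 1):
            P = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
            loss = training_loss(P, X, Y, cfg)
            loss.backward()
            opt.step(params, {k: P[k].grad for k in params})
            pred_deg = stats.denorm_angle(forward_infer(params, X, cfg))
            train_rmse = float(np.sqrt(np.mean((pred_deg - truth_deg) ** 2)))
            history.append({"epoch": epoch, "loss": float(loss.data),
                            "train_rmse_deg": train_rmse})
            if train_rmse < rmse_stop:
                stop_reason = "rmse"
                break
        return KneeAngleGRUResults(
            params=params, config=cfg, stats=stats,
            channels=list(self.dataset.channels), L=self.dataset.L,
            history=pd.DataFrame(history,
                                 columns=["epoch", "loss", "train_rmse_deg"]),
            stop_reason=stop_reason)


@dataclass
class KneeAngleGRUResults:
    """A fitted (or initialized) estimator with its training history."""

    params: dict
    config: GruAmConfig
    stats: NormStats
    channels: list[str]
    L: int
    history: pd.DataFrame
    stop_reason: str = "untrained"
    meta: dict = field(default_factory=dict)

    # -- estimation --------------------------------------------------------
    def _check_channels(self, channels) -> None:
        if list(channels) != list(self.channels):
            missing = set(self.channels) - set(channels)
            extra = set(channels) - set(self.channels)
            raise ValueError(
                f"channel mismatch: missing {sorted(missing)}, "
                f"extra {sorted(extra)} (expected order {self.channels})")

    def estimate_cycle(self, seq: SegmentSequence | GaitCycle) -> np.ndarray:
        """Estimate one cycle's knee-angle trajectory in degrees (L samples)."""
        if isinstance(seq, GaitCycle):
            cyc = seq
            self._check_channels(cyc.channels)
            norm = GaitCycle(start=cyc.start, end=cyc.end,
                             channels=list(cyc.channels),
                             emg=self.stats.norm_emg(cyc.emg), angle=cyc.angle,
                             emg_times=cyc.emg_times,
                             angle_times=cyc.angle_times, normalized=True)
            seq = segment(norm, self.config.segment_window)
            X = seq.segments[None, :, :]
        else:
            self._check_channels(seq.channels)
            # segments are time-window-major / channel-minor
            n_ch = len(seq.channels)
            ch_idx = np.arange(len(seq)) % n_ch
            span = np.where(self.stats.ch_max > self.stats.ch_min,
                            self.stats.ch_max - self.stats.ch_min, 1.0)
            segs = (seq.segments - self.stats.ch_min[ch_idx][:, None]) / \
                span[ch_idx][:, None]
            X = segs[None, :, :]
        y = forward_infer(self.params, X, self.config)[0]
        return self.stats.denorm_angle(y)

    def predict(self, cycles: list[GaitCycle]) -> np.ndarray:
        """Estimate many cycles at once -> (n, L) degrees."""
        for c in cycles:
            self._check_channels(c.channels)
        X, _ = dataset_arrays(cycles, self.stats, self.config.segment_window)
        return self.stats.denorm_angle(forward_infer(X=X, params=self.params,
                                                     cfg=self.config))

    def evaluate(self, cycles: list[GaitCycle],
                 snr_mode: str = "literal") -> pd.DataFrame:
        """Per-stride RMSE/CC/SNR/NRMSE against each cycle's measured angle."""
        preds = self.predict(cycles)
        rows = []
        for i, (cyc, est) in enumerate(zip(cycles, preds)):
            sm = mx.stride_metrics(cyc.angle, est, snr_mode=snr_mode)
            rows.append({"stride": i, "rmse": sm.rmse, "cc": sm.cc,
                         "snr": sm.snr, "nrmse": sm.nrmse})
        return pd.DataFrame(rows)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_params(self) -> int:
        return n_params(self.params)

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def refit(self, cycles: list[GaitCycle], max_epochs: int | None = None,
              rmse_stop: float | None = None) -> "KneeAngleGRUResults":
        """Warm-started continuation of training on new cycles.

        Normalization statistics travel with the model (they are part of
        the estimator, not of the new data)."""
        from .gait import GaitCycleDataset as _DS
        ds = _DS(cycles=list(cycles), split=["train"] * len(cycles),
                 stats=self.stats, train_frac=1.0, seed=self.config.seed)
        model = KneeAngleGRU(ds, self.config)
        res = model.fit(start_params=self.params, max_epochs=max_epochs,
                        rmse_stop=rmse_stop)
        res.meta = dict(self.meta)
        return res

    def summary(self) -> str:
        cfg = self.config
        name = "GRU-AM" if cfg.use_attention else "GRU (no attention)"
        lines = [
            "Knee-angle estimator results",
            "=" * 60,
            f"Model:              {name}",
            f"Channels ({len(self.channels)}):       {', '.join(self.channels)}",
            f"Encoder steps M:    {(self.L // cfg.segment_window) * len(self.channels)}",
            f"Decoder steps L:    {self.L}",
            f"Hidden size:        {cfg.hidden_size}",
            f"Trainable params:   {self.n_params}",
            f"Loss:               {cfg.loss}",
            f"Epochs run:         {self.n_epochs}",
            f"Stop reason:        {self.stop_reason}",
        ]
        if self.n_epochs:
            last = self.history.iloc[-1]
            lines += [f"Final loss:         {last['loss']:.6f}",
                      f"Final train RMSE:   {last['train_rmse_deg']:.2f} deg"]
        if self.meta:
            lines += [f"Meta:               {self.meta}"]
        lines.append(
            f"Angle bounds:       [{self.stats.angle_min:.2f}, "
            f"{self.stats.angle_max:.2f}] deg")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> Path:
        """Parameter blob (npz) plus a plain-text YAML sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.params)
        cfg_dict = asdict(self.config)
        sidecar = {
            "channels": list(self.channels),
            "L": int(self.L),
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                yaml.safe_dump(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "stats": {"ch_min": self.stats.ch_min.tolist(),
                      "ch_max": self.stats.ch_max.tolist(),
                      "angle_min": self.stats.angle_min,
                      "angle_max": self.stats.angle_max},
            "stop_reason": self.stop_reason,
            "meta": dict(self.meta),
        }
        with open(directory / "model.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)
        self.history.to_csv(directory / "history.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory) -> "KneeAngleGRUResults":
        directory = Path(directory)
        with open(directory / "model.yaml", encoding="utf-8") as fh:
            sidecar = yaml.safe_load(fh)
        with np.load(directory / "params.npz") as blob:
            params = {k: blob[k].copy() for k in blob.files}
        st = sidecar["stats"]
        stats = NormStats(ch_min=np.array(st["ch_min"]),
                          ch_max=np.array(st["ch_max"]),
                          angle_min=float(st["angle_min"]),
                          angle_max=float(st["angle_max"]))
        history = pd.read_csv(directory / "history.csv")
        return cls(params=params, config=GruAmConfig(**sidecar["config"]),
                   stats=stats, channels=list(sidecar["channels"]),
                   L=int(sidecar["L"]), history=history,
                   stop_reason=sidecar.get("stop_reason", "loaded"),
                   meta=dict(sidecar.get("meta", {})))


def train(dataset: GaitCycleDataset,
          config: GruAmConfig | None = None) -> KneeAngleGRUResults:
    """Convenience wrapper: build the model and fit it."""
    return KneeAngleGRU(dataset, config).fit()
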