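"""Feedforward neural GRF estimators (direct and hybrid).

The direct estimator maps the nine 10 Hz-low-passed free-acceleration
channels (3 sensors × 3 axes) at one time sample to the 3-axis GRF in BW
at that sample; the hybrid estimator additionally receives the physical
vertical-GRF estimate as a tenth input. Networks are multilayer
perceptrons (two hidden layers of 100 ReLU units, joint MSE over the three
axes) trained with Adam, batch size 250, for at most 1000 epochs with
early stopping once the validation loss has not improved for 100 epochs;
the weights from the best validation epoch are restored.

The trainer is written directly on NumPy (no deep-learning framework is
required at run time) and can optimize several ensemble members in one
batched pass, which is how the leave-one-subject-out driver uses it.
Inputs are z-scored with statistics from the training rows only; targets
stay in BW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .physical import PhysicalParams, estimate_vertical_grf
from .preprocess import ANN_INPUT_FILTER, butter_filter
from .types import (EstimateSource, GrfEstimate, SensorId, Trial)

_SENSOR_ORDER = (SensorId.PELVIS, SensorId.TIBIA_LEFT, SensorId.TIBIA_RIGHT)


@dataclass
class TrainConfig:
    hidden_layers: int = 2
    neurons_per_layer: int = 100
    epochs: int = 1000
    batch_size: int = 250
    patience_epochs: int = 100
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    #: cap on rows used for the per-epoch validation loss (None = all rows);
    #: a fixed random subset is drawn once per member before training.
    max_val_rows: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_layers", "neurons_per_layer", "epochs",
                     "batch_size", "patience_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedEstimator:
    """A fitted network plus everything needed to reproduce its inference."""

    kind: EstimateSource                  # direct | hybrid
    weights: list                         # [W0, b0, W1, b1, ...]
    norm_mean: np.ndarray                 # (d,) training-set feature means
    norm_sd: np.ndarray                   # (d,) training-set feature sds
    history: dict                         # {"train_loss": [...], "val_loss": [...]}
    best_epoch: int                       # 1-based epoch with minimum val loss
    best_val_loss: float
    config: TrainConfig

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[-2]


def build_features(trial: Trial, kind, physical: Optional[GrfEstimate] = None,
                   w: int = 0, params: PhysicalParams = PhysicalParams(),
                   ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Assemble the feature matrix (and targets, if force is present).

    Channels are filtered over the full trial before the stride window is
    cut; a symmetric context window ``w`` replicates each channel at lags
    −w..+w with edge replication at the window boundaries. The hybrid kind
    appends one column: the physical vertical estimate in BW (computed from
    the trial if not supplied).
    """
    kind = EstimateSource(kind)
    if kind not in (EstimateSource.DIRECT, EstimateSource.HYBRID):
        raise ValueError(f"estimator kind must be direct or hybrid, got {kind}")
    if trial.stride_window is None:
        raise ValueError("trial has no stride window; run preprocessing first")
    a, b = trial.stride_window
    chans = np.column_stack([trial.sensor(sid).acc for sid in _SENSOR_ORDER])
    filt = butter_filter(chans, ANN_INPUT_FILTER, trial.rate_hz)[a:b]
    if w < 0:
        raise ValueError("context window w must be >= 0")
    if w == 0:
        X = filt
    else:
        cols = []
        for lag in range(-w, w + 1):
            idx = np.clip(np.arange(filt.shape[0]) + lag, 0, filt.shape[0] - 1)
            cols.append(filt[idx])
        X = np.column_stack(cols)
    if kind is EstimateSource.HYBRID:
        if physical is None:
            physical = estimate_vertical_grf(trial, params)
        if physical.n_samples == trial.n_samples:
            phys_col = physical.vertical[a:b]
        elif physical.n_samples == b - a:
            phys_col = physical.vertical
        else:
            raise ValueError("physical estimate is not aligned to the trial "
                             "or its stride window")
        X = np.column_stack([X, phys_col])
    Y = None
    if trial.force is not None:
        if not trial.is_synchronized:
            raise ValueError("force stream is not synchronized to the sensors")
        Y = trial.force.grf[a:b] / trial.subject.bodyweight_n
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X, Y


def _layer_sizes(d: int, cfg: TrainConfig) -> List[int]:
    return [d] + [cfg.neurons_per_layer] * cfg.hidden_layers + [3]


def _init_weights(M: int, sizes: Sequence[int],
                  rng: np.random.Generator) -> list:
    """He-initialized weights for M stacked members, float32."""
    params = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / a)
        params.append((rng.standard_normal((M, a, b)) * scale).astype(np.float32))
        params.append(np.zeros((M, 1, b), dtype=np.float32))
    return params


def _forward_stacked(params: list, x: np.ndarray) -> np.ndarray:
    """Forward pass for stacked members; x is (M, n, d)."""
    h = x
    n_layers = len(params) // 2
    for li in range(n_layers):
        h = h @ params[2 * li] + params[2 * li + 1]
        if li < n_layers - 1:
            np.maximum(h, 0.0, out=h)
    return h


def _val_losses(params: list, X: np.ndarray, Y: np.ndarray,
                val_idx: List[np.ndarray], mu: np.ndarray, sd: np.ndarray,
                chunk: int = 16384) -> np.ndarray:
    M = len(val_idx)
    out = np.empty(M)
    for m in range(M):
        idx = val_idx[m]
        sq_sum = 0.0
        pm = [p[m:m + 1] for p in params]
        for s in range(0, len(idx), chunk):
            ii = idx[s:s + chunk]
            xb = ((X[ii] - mu[m]) / sd[m]).astype(np.float32)[None]
            pred = _forward_stacked(pm, xb)[0]
            sq_sum += float(((pred - Y[ii]) ** 2).sum())
        out[m] = sq_sum / (len(idx) * 3)
    return out


def train_members(X: np.ndarray, Y: np.ndarray,
                  train_idx: List[np.ndarray], val_idx: List[np.ndarray],
                  cfg: TrainConfig,
                  kind=EstimateSource.DIRECT) -> List[TrainedEstimator]:
    """Train one network per (train, validation) row split, batched.

    ``X``/``Y`` are the pooled feature/target rows; each member sees only
    its own index arrays. All members share the epoch schedule (a member
    whose training set is exhausted reshuffles and continues within the
    epoch); early stopping and best-weight restoration are tracked per
    member. Deterministic given ``cfg.seed`` and a fixed thread count.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    Y = np.ascontiguousarray(Y, dtype=np.float32)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature/target row counts differ")
    M = len(train_idx)
    if M == 0 or len(val_idx) != M:
        raise ValueError("need one validation index set per training index set")
    for m in range(M):
        if len(val_idx[m]) == 0:
            raise ValueError(f"member {m}: empty validation set")
        if len(train_idx[m]) < cfg.batch_size:
            raise ValueError(f"member {m}: fewer training rows than one batch")
    d = X.shape[1]
    rng = np.random.default_rng(cfg.seed)

    mu = np.empty((M, 1, d), dtype=np.float32)
    sd = np.empty((M, 1, d), dtype=np.float32)
    for m in range(M):
        rows = X[train_idx[m]]
        mu[m, 0] = rows.mean(axis=0)
        sd[m, 0] = rows.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("constant feature column: zero normalization sd")

    eff_val_idx = []
    for m in range(M):
        idx = np.asarray(val_idx[m])
        if cfg.max_val_rows is not None and len(idx) > cfg.max_val_rows:
            idx = rng.choice(idx, size=cfg.max_val_rows, replace=False)
        eff_val_idx.append(np.sort(idx))

    sizes = _layer_sizes(d, cfg)
    params = _init_weights(M, sizes, rng)
    m1 = [np.zeros_like(p) for p in params]
    v2 = [np.zeros_like(p) for p in params]
    b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
    batch = cfg.batch_size
    steps_per_epoch = max(int(np.ceil(max(len(t) for t in train_idx) / batch)), 1)

    perms = [rng.permutation(train_idx[m]) for m in range(M)]
    pos = [0] * M
    active = np.ones(M, dtype=bool)
    best_val = np.full(M, np.inf)
    best_epoch = np.zeros(M, dtype=int)
    best_params = [[p[m].copy() for p in params] for m in range(M)]
    history = [{"train_loss": [], "val_loss": []} for _ in range(M)]
    adam_t = 0

    for epoch in range(1, cfg.epochs + 1):
        epoch_sq = np.zeros(M)
        epoch_n = 0
        for _ in range(steps_per_epoch):
            rows = np.empty((M, batch), dtype=np.intp)
            for m in range(M):
                if pos[m] + batch > len(perms[m]):
                    perms[m] = rng.permutation(train_idx[m])
                    pos[m] = 0
                rows[m] = perms[m][pos[m]:pos[m] + batch]
                pos[m] += batch
            x = (X[rows] - mu) / sd
            y = Y[rows]
            # forward with cached activations
            acts = [x]
            h = x
            n_layers = len(params) // 2
            for li in range(n_layers):
                h = h @ params[2 * li] + params[2 * li + 1]
                if li < n_layers - 1:
                    np.maximum(h, 0.0, out=h)
                acts.append(h)
            diff = acts[-1] - y
            epoch_sq += (diff.astype(np.float64) ** 2).sum(axis=(1, 2))
            epoch_n += batch * 3
            g = diff * np.float32(2.0 / (batch * 3))
            grads = [None] * len(params)
            for li in range(n_layers - 1, -1, -1):
                grads[2 * li] = np.matmul(acts[li].transpose(0, 2, 1), g)
                grads[2 * li + 1] = g.sum(axis=1, keepdims=True)
                if li > 0:
                    g = np.matmul(g, params[2 * li].transpose(0, 2, 1))
                    g[acts[li] <= 0] = 0.0
            adam_t += 1
            lr_t = (cfg.learning_rate
                    * np.sqrt(1.0 - b2 ** adam_t) / (1.0 - b1 ** adam_t))
            lr_mask = np.float32(lr_t) * active.astype(np.float32)[:, None, None]
            for p, gr, mo, vo in zip(params, grads, m1, v2):
                mo *= b1
                mo += (1 - b1) * gr
                vo *= b2
                vo += (1 - b2) * gr * gr
                p -= lr_mask * mo / (np.sqrt(vo) + eps)
        vloss = _val_losses(params, X, Y, eff_val_idx, mu, sd)
        if not np.all(np.isfinite(vloss[active])):
            bad = int(np.flatnonzero(active & ~np.isfinite(vloss))[0])
            raise RuntimeError(f"member {bad}: non-finite validation loss at "
                               f"epoch {epoch} (diverged)")
        tloss = epoch_sq / epoch_n
        for m in range(M):
            if not active[m]:
                continue
            history[m]["train_loss"].append(float(tloss[m]))
            history[m]["val_loss"].append(float(vloss[m]))
            if vloss[m] < best_val[m]:
                best_val[m] = vloss[m]
                best_epoch[m] = epoch
                best_params[m] = [p[m].copy() for p in params]
            if epoch - best_epoch[m] >= cfg.patience_epochs:
                active[m] = False
        if not active.any():
            break

    out = []
    for m in range(M):
        out.append(TrainedEstimator(
            kind=EstimateSource(kind),
            weights=[p[None] for p in best_params[m]],
            norm_mean=mu[m, 0].astype(float),
            norm_sd=sd[m, 0].astype(float),
            history=history[m],
            best_epoch=int(best_epoch[m]),
            best_val_loss=float(best_val[m]),
            config=cfg,
        ))
    return out


def train(features: np.ndarray, targets: np.ndarray,
          val_features: np.ndarray, val_targets: np.ndarray,
          cfg: TrainConfig, kind=EstimateSource.DIRECT) -> TrainedEstimator:
    """Train a single estimator on explicit train/validation matrices.

    The caller is responsible for drawing validation rows from different
    subjects than the training rows.
    """
    features = np.asarray(features, dtype=np.float32)
    val_features = np.asarray(val_features, dtype=np.float32)
    if val_features.shape[0] == 0:
        raise ValueError("empty validation set")
    if features.shape[1] != val_features.shape[1]:
        raise ValueError("train/validation feature dimensions differ")
    X = np.vstack([features, val_features])
    Y = np.vstack([np.asarray(targets, dtype=np.float32),
                   np.asarray(val_targets, dtype=np.float32)])
    n_tr = features.shape[0]
    return train_members(X, Y, [np.arange(n_tr)],
                         [np.arange(n_tr, X.shape[0])], cfg, kind=kind)[0]


def predict(est: TrainedEstimator, features: np.ndarray,
            rate_hz: float = 240.0) -> GrfEstimate:
    """Per-sample 3-axis GRF prediction in BW (no temporal smoothing)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != est.n_features:
        raise ValueError(f"feature columns ({features.shape[1] if features.ndim == 2 else '?'}) "
                         f"do not match the trained network ({est.n_features})")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite feature values")
    x = ((features - est.norm_mean) / est.norm_sd).astype(np.float32)[None]
    pred = _forward_stacked(est.weights, x)[0].astype(float)
    return GrfEstimate(pred, est.kind, rate_hz=rate_hz)
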