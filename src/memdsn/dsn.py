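"""Lifelong-learning classifier with a dynamically scalable network (DSN).

The model is a shared ReLU trunk plus one binary (one-vs-rest) head per
learned class.  Classes arrive as a stream of tasks; for task t only the
current task's data is available, so instead of retraining from scratch the
model is trained under

    minimize_{W_t}  L(W_t; W_{t-1}, D_t) + lambda * Omega(W_t)

with three phases per task:

1. *Selective retraining* — a new head is added and only parameters not yet
   frozen by earlier tasks are trained (weighted binary cross-entropy with an
   element-wise L1 penalty).  From the second task on this is just the new
   head: the trunk is frozen.
2. *Expansion* — if the held-out loss after phase 1 exceeds the threshold
   tau, ``expand_units`` fresh units are appended to every hidden layer and
   trained together with the new head under a group-sparse (per-unit L2)
   penalty; units whose incoming weights collapse below 1e-6 are pruned.
   Old units never receive input from new units, so earlier heads are
   unaffected by growth.
3. *Freeze* — every parameter touched this task is timestamped and never
   trained again, which prevents catastrophic forgetting exactly: earlier
   heads' scores on fixed inputs are bit-for-bit reproducible.

Prediction is argmax over the per-class head probabilities (ties to the
lowest class index).

Everything is plain float64 numpy with minibatch SGD (fixed learning rate,
classical momentum), so runs are deterministic for a fixed seed on one
platform.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from memdsn.errors import ConfigurationError, FormatError

_MAGIC = b"MEMDSN\x00"
_VERSION = 1

#: timestamp sentinel for structurally-zero weights (old unit <- new unit)
_STRUCTURAL = -1
#: timestamp for parameters created but not yet frozen
_FRESH = 0


@dataclass
class DSNConfig:
    """Hyperparameters of the dynamically scalable network.

    ``expand_threshold`` (tau) is the held-out loss above which a task
    triggers expansion by ``expand_units`` units per hidden layer;
    ``reg_weight`` (lambda) scales the sparsity penalty (element-wise L1 in
    selective retraining, per-unit group L2 during expansion).  Inverse-
    frequency class weighting is on by default because one-vs-rest tasks are
    heavily imbalanced (membrane-protein classes range over two orders of
    magnitude in size).
    """

    hidden_sizes: list[int] = field(default_factory=lambda: [128, 64])
    expand_units: int = 16
    expand_threshold: float = 0.15
    reg_weight: float = 1e-4
    reg_kind: str = "l1"
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    seed: int = 0
    class_weighting: str = "inverse-frequency"

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ConfigurationError("hidden_sizes must be non-empty")
        if any(h < 1 for h in self.hidden_sizes):
            raise ConfigurationError("hidden sizes must be positive")
        if self.expand_units < 0 or self.expand_threshold < 0 or self.reg_weight < 0:
            raise ConfigurationError("expand_units, expand_threshold, reg_weight must be >= 0")
        if self.reg_kind not in ("l1", "l2"):
            raise ConfigurationError("reg_kind must be 'l1' or 'l2'")
        if self.class_weighting not in ("none", "inverse-frequency"):
            raise ConfigurationError("class_weighting must be 'none' or 'inverse-frequency'")
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ConfigurationError("epochs, batch_size, learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ConfigurationError("momentum must be in [0, 1)")


@dataclass
class TrainReport:
    """Observability record of one task's training (which branches ran)."""

    task_index: int
    pre_expansion_loss: float
    expanded: bool
    units_added: int
    final_loss: float
    pruned_units: int
    seed_used: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


class _Layer:
    """One trunk layer: W (out x in), bias b, and per-parameter timestamps."""

    __slots__ = ("W", "b", "W_ts", "b_ts")

    def __init__(self, W: np.ndarray, b: np.ndarray, W_ts: np.ndarray, b_ts: np.ndarray):
        self.W, self.b, self.W_ts, self.b_ts = W, b, W_ts, b_ts


class _Head:
    """A binary head reading the first ``width`` units of the last trunk layer."""

    __slots__ = ("w", "b", "width", "task")

    def __init__(self, w: np.ndarray, b: float, width: int, task: int):
        self.w, self.b, self.width, self.task = w, float(b), width, task


@dataclass
class DSNModel:
    config: DSNConfig
    input_dim: int
    layers: list[_Layer] = field(default_factory=list)
    heads: list[_Head] = field(default_factory=list)
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None
    history: list[TrainReport] = field(default_factory=list)

    @property
    def n_tasks(self) -> int:
        return len(self.heads)

    @property
    def n_parameters(self) -> int:
        n = sum(l.W.size + l.b.size for l in self.layers)
        n += sum(h.w.size + 1 for h in self.heads)
        return n

    def layer_widths(self) -> list[int]:
        return [l.W.shape[0] for l in self.layers]

    def trunk_forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations after each layer, for standardized-input X (n, d)."""
        Z = (X - self.scaler_mean) / self.scaler_sd
        acts = [Z]
        h = Z
        for layer in self.layers:
            h = np.maximum(h @ layer.W.T + layer.b, 0.0)
            acts.append(h)
        return acts

    def head_logits(self, h_last: np.ndarray) -> np.ndarray:
        """(n, n_heads) logit matrix; each head reads only its creation-time width."""
        out = np.empty((h_last.shape[0], len(self.heads)))
        for k, head in enumerate(self.heads):
            out[:, k] = h_last[:, : head.width] @ head.w + head.b
        return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> float:
    eps = 1e-12
    terms = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    if w is not None:
        terms = terms * w
    return float(terms.mean())


def init_model(cfg: DSNConfig, input_dim: int) -> DSNModel:
    """A trunk with ``cfg.hidden_sizes`` layers, zero heads, He-style
    deterministic initialization from ``cfg.seed``."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    layers = []
    fan_in = input_dim
    for width in cfg.hidden_sizes:
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(width, fan_in))
        b = np.zeros(width)
        layers.append(_Layer(W, b, np.full(W.shape, _FRESH, dtype=np.int64),
                             np.full(b.shape, _FRESH, dtype=np.int64)))
        fan_in = width
    return DSNModel(config=cfg, input_dim=input_dim, layers=layers)


def _class_weights(y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return np.ones_like(y, dtype=float)
    n = len(y)
    n_pos = max(int(y.sum()), 1)
    n_neg = max(n - int(y.sum()), 1)
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


def _holdout_split(y: np.ndarray, rng: np.random.Generator, frac: float = 0.2):
    """Stratified train/validation index split (at least one positive held out
    when possible)."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    val = []
    for idx in (idx_pos, idx_neg):
        perm = rng.permutation(idx)
        k = max(1, int(round(frac * len(idx)))) if len(idx) > 1 else 0
        val.append(perm[:k])
    val_idx = np.sort(np.concatenate(val))
    mask = np.ones(len(y), bool)
    mask[val_idx] = False
    return np.flatnonzero(mask), val_idx


def _train_phase(
    model: DSNModel,
    X: np.ndarray,
    y: np.ndarray,
    sample_w: np.ndarray,
    cfg: DSNConfig,
    rng: np.random.Generator,
    group_rows: list[np.ndarray] | None,
) -> None:
    """Minibatch SGD on the newest head plus all timestamp-0 trunk parameters.

    ``group_rows`` (one boolean row mask per layer) switches the penalty from
    element-wise L1/L2 to a group-sparse per-row L2 on those rows (expansion
    phase)."""
    head = model.heads[-1]
    lam = cfg.reg_weight
    lr = cfg.learning_rate
    mu = cfg.momentum
    masks = [(l.W_ts == _FRESH, l.b_ts == _FRESH) for l in model.layers]
    vel = {
        "layers": [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in model.layers],
        "head": (np.zeros_like(head.w), 0.0),
    }
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            Xb, yb, wb = X[batch], y[batch], sample_w[batch]
            acts = model.trunk_forward(Xb)
            h_last = acts[-1]
            logit = h_last[:, : head.width] @ head.w + head.b
            p = _sigmoid(logit)
            dlogit = wb * (p - yb) / len(batch)
            # head gradients
            g_w = h_last[:, : head.width].T @ dlogit
            g_b = dlogit.sum()
            if group_rows is None:
                if cfg.reg_kind == "l1":
                    g_w = g_w + lam * np.sign(head.w)
                else:
                    g_w = g_w + lam * head.w
            else:
                g_w = g_w + lam * head.w  # mild l2 keeps the head bounded
            # backprop into trunk (only needed where something is trainable)
            delta = np.zeros_like(h_last)
            delta[:, : head.width] = np.outer(dlogit, head.w)
            for li in range(len(model.layers) - 1, -1, -1):
                layer = model.layers[li]
                m_W, m_b = masks[li]
                delta = delta * (acts[li + 1] > 0)
                delta_prev = delta @ layer.W if li > 0 else None
                if m_W.any() or m_b.any():
                    g_W = delta.T @ acts[li]
                    if group_rows is None:
                        if cfg.reg_kind == "l1":
                            g_W = g_W + lam * np.sign(layer.W)
                        else:
                            g_W = g_W + lam * layer.W
                    else:
                        rows = group_rows[li]
                        norms = np.linalg.norm(layer.W[rows], axis=1, keepdims=True) + 1e-12
                        g_W = g_W.copy()
                        g_W[rows] += lam * layer.W[rows] / norms
                    vW, vb = vel["layers"][li]
                    vW *= mu
                    vW += np.where(m_W, g_W, 0.0)
                    vb *= mu
                    vb += np.where(m_b, delta.sum(axis=0), 0.0)
                    layer.W -= lr * vW
                    layer.b -= lr * vb
                delta = delta_prev
            vw, vb_h = vel["head"]
            vw *= mu
            vw += g_w
            vb_h = mu * vb_h + g_b
            vel["head"] = (vw, vb_h)
            head.w -= lr * vw
            head.b -= lr * vb_h


def _val_loss(model: DSNModel, X: np.ndarray, y: np.ndarray) -> float:
    h_last = model.trunk_forward(X)[-1]
    head = model.heads[-1]
    p = _sigmoid(h_last[:, : head.width] @ head.w + head.b)
    return _bce(p, y)


def _expand(model: DSNModel, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Append k units to every hidden layer.  New units read the full previous
    layer; old units get frozen zero weights to new inputs, so old-unit
    activations — and therefore old heads — are unchanged.  Returns per-layer
    boolean masks marking the new rows."""
    new_rows = []
    for li, layer in enumerate(model.layers):
        old_out, old_in = layer.W.shape
        in_grow = k if li > 0 else 0
        W = np.zeros((old_out + k, old_in + in_grow))
        W_ts = np.full(W.shape, _STRUCTURAL, dtype=np.int64)
        W[:old_out, :old_in] = layer.W
        W_ts[:old_out, :old_in] = layer.W_ts
        W[old_out:, :] = rng.normal(0.0, np.sqrt(2.0 / (old_in + in_grow)), size=(k, old_in + in_grow))
        W_ts[old_out:, :] = _FRESH
        b = np.concatenate([layer.b, np.zeros(k)])
        b_ts = np.concatenate([layer.b_ts, np.full(k, _FRESH, dtype=np.int64)])
        layer.W, layer.b, layer.W_ts, layer.b_ts = W, b, W_ts, b_ts
        rows = np.zeros(old_out + k, bool)
        rows[old_out:] = True
        new_rows.append(rows)
    # widen the newest head over the grown last layer
    head = model.heads[-1]
    k_last = int(new_rows[-1].sum())
    head.w = np.concatenate([head.w, rng.normal(0.0, 0.01, size=k_last)])
    head.width += k_last
    return new_rows


def _prune(model: DSNModel, new_rows: list[np.ndarray], tol: float = 1e-6) -> int:
    """Drop newly-added units whose incoming weights collapsed below ``tol``."""
    pruned = 0
    for li, layer in enumerate(model.layers):
        rows = new_rows[li]
        norms = np.linalg.norm(layer.W, axis=1)
        drop = rows & (norms < tol)
        if not drop.any():
            continue
        keep = ~drop
        pruned += int(drop.sum())
        layer.W, layer.b = layer.W[keep], layer.b[keep]
        layer.W_ts, layer.b_ts = layer.W_ts[keep], layer.b_ts[keep]
        new_rows[li] = rows[keep]
        if li + 1 < len(model.layers):
            nxt = model.layers[li + 1]
            nxt.W, nxt.W_ts = nxt.W[:, keep], nxt.W_ts[:, keep]
        else:
            head = model.heads[-1]
            head.w = head.w[keep[: head.width]]
            head.width = int(keep[: head.width].sum())
    return pruned


def train_task(model: DSNModel, X: np.ndarray, y: np.ndarray, cfg: DSNConfig | None = None):
    """Learn one new class from binary-labelled features.

    ``X`` is (n, input_dim); ``y`` is 1 for members of the new class and 0
    for the task's own negatives (earlier tasks' data is assumed gone).
    Returns ``(model, TrainReport)``; the model is modified in place and all
    parameters of earlier tasks are bit-identical afterwards.
    """
    cfg = cfg or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(f"features must be (n, {model.input_dim}), got {X.shape}")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if int(y.sum()) < 2:
        raise ValueError("a task needs at least 2 positive examples")

    task_index = model.n_tasks + 1
    seed_used = int(np.random.default_rng([cfg.seed, task_index]).integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed_used)

    if model.scaler_mean is None:  # first task fixes the input standardization
        model.scaler_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        model.scaler_sd = np.where(sd == 0, 1.0, sd)

    train_idx, val_idx = _holdout_split(y, rng)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    sample_w = _class_weights(ytr, cfg.class_weighting)

    width = model.layers[-1].W.shape[0]
    head = _Head(rng.normal(0.0, 0.01, size=width), 0.0, width, task_index)
    model.heads.append(head)

    # Phase 1: selective retraining of unfrozen parameters + the new head
    _train_phase(model, Xtr, ytr, sample_w, cfg, rng, group_rows=None)
    pre_loss = _val_loss(model, Xval, yval)

    expanded = pre_loss > cfg.expand_threshold and cfg.expand_units > 0
    units_added = 0
    pruned = 0
    final_loss = pre_loss
    if expanded:
        # Phase 2: grow capacity and train only the new units + new head
        new_rows = _expand(model, cfg.expand_units, rng)
        units_added = cfg.expand_units * len(model.layers)
        _train_phase(model, Xtr, ytr, sample_w, cfg, rng, group_rows=new_rows)
        pruned = _prune(model, new_rows)
        final_loss = _val_loss(model, Xval, yval)

    # Phase 3: freeze everything touched this task
    for layer in model.layers:
        layer.W_ts[layer.W_ts == _FRESH] = task_index
        layer.b_ts[layer.b_ts == _FRESH] = task_index

    report = TrainReport(
        task_index=task_index,
        pre_expansion_loss=float(pre_loss),
        expanded=bool(expanded),
        units_added=int(units_added),
        final_loss=float(final_loss),
        pruned_units=int(pruned),
        seed_used=seed_used,
    )
    model.history.append(report)
    return model, report


def predict(model: DSNModel, features: np.ndarray):
    """Class prediction by argmax over per-head probabilities.

    Accepts one feature vector (returns ``(class_index, scores)``) or an
    (n, d) batch (returns ``(classes, score_matrix)``).  Class indices are
    1-based in head order; ties break to the lowest class index.
    """
    if not model.heads:
        raise RuntimeError("model has no trained heads")
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise ValueError(f"features must have dimension {model.input_dim}, got {X.shape[1]}")
    scores = _sigmoid(model.head_logits(model.trunk_forward(X)[-1]))
    classes = scores.argmax(axis=1) + 1
    if single:
        return int(classes[0]), scores[0]
    return classes, scores


# ---------------------------------------------------------------------------
# model container: JSON header + raw little-endian payload


def _array_specs(model: DSNModel):
    arrays = [("scaler_mean", model.scaler_mean), ("scaler_sd", model.scaler_sd)]
    for i, l in enumerate(model.layers):
        arrays += [(f"layer{i}.W", l.W), (f"layer{i}.b", l.b),
                   (f"layer{i}.W_ts", l.W_ts), (f"layer{i}.b_ts", l.b_ts)]
    for i, h in enumerate(model.heads):
        arrays.append((f"head{i}.w", h.w))
    return [(n, a) for n, a in arrays if a is not None]


def save_model(model: DSNModel, path: str | Path) -> None:
    """Versioned container: magic + JSON header (config, structure, head
    metadata, training history) followed by the raw float64/int64 payload."""
    arrays = _array_specs(model)
    header = {
        "version": _VERSION,
        "config": asdict(model.config),
        "input_dim": model.input_dim,
        "n_layers": len(model.layers),
        "heads": [{"width": h.width, "task": h.task, "b": h.b} for h in model.heads],
        "history": [asdict(r) for r in model.history],
        "arrays": [{"name": n, "dtype": str(a.dtype), "shape": list(a.shape)} for n, a in arrays],
    }
    hdr = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<HI", _VERSION, len(hdr)))
        fh.write(hdr)
        for _, a in arrays:
            fh.write(np.ascontiguousarray(a).tobytes())


def load_model(path: str | Path) -> DSNModel:
    """Inverse of :func:`save_model`; raises :class:`FormatError` on a bad
    magic, a version mismatch, or a truncated payload."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < len(_MAGIC) + 6 or blob[: len(_MAGIC)] != _MAGIC:
        raise FormatError(f"{path}: not a memdsn model file")
    off = len(_MAGIC)
    version, hlen = struct.unpack_from("<HI", blob, off)
    off += 6
    if version != _VERSION:
        raise FormatError(f"{path}: unsupported model version {version}")
    try:
        header = json.loads(blob[off : off + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: corrupt model header") from exc
    off += hlen
    data = {}
    for spec in header["arrays"]:
        a = np.zeros(spec["shape"], dtype=spec["dtype"])
        nbytes = a.nbytes
        if off + nbytes > len(blob):
            raise FormatError(f"{path}: truncated payload at array {spec['name']!r}")
        data[spec["name"]] = np.frombuffer(blob[off : off + nbytes], dtype=spec["dtype"]).reshape(spec["shape"]).copy()
        off += nbytes
    if off != len(blob):
        raise FormatError(f"{path}: {len(blob) - off} trailing bytes")

    model = DSNModel(config=DSNConfig(**header["config"]), input_dim=header["input_dim"])
    model.scaler_mean = data.get("scaler_mean")
    model.scaler_sd = data.get("scaler_sd")
    for i in range(header["n_layers"]):
        model.layers.append(
            _Layer(data[f"layer{i}.W"], data[f"layer{i}.b"],
                   data[f"layer{i}.W_ts"], data[f"layer{i}.b_ts"])
        )
    for i, hmeta in enumerate(header["heads"]):
        model.heads.append(_Head(data[f"head{i}.w"], hmeta["b"], hmeta["width"], hmeta["task"]))
    model.history = [TrainReport(**r) for r in header["history"]]
    return model
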