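"""Multi-task glenohumeral classifier: shared encoder, projection, four heads.

One convolutional encoder condenses the GH crop; a non-linear projection
maps its pooled features into a shared latent space; four parallel softmax
heads predict osteophyte severity (3 classes), joint-space condition (3),
humeroscapular alignment (2) and implant type (2). Training minimises the
sum over tasks of class-weighted cross-entropies, with per-class weights
inversely proportional to training-set frequency:
``w_c = (1/N_c) / sum_i (1/N_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam, Conv3d, Linear, Module, Tensor

__all__ = [
    "TaskSpec",
    "CaseLabels",
    "TASK_NAMES",
    "compute_class_weights",
    "default_task_specs",
    "multitask_loss",
    "build_arthronet",
    "ArthroNet",
    "train_classifier",
    "ClsTrainingResult",
]

TASK_NAMES = ("OS", "JS", "HSA", "IT")
_TASK_CLASSES = {"OS": 3, "JS": 3, "HSA": 2, "IT": 2}


def compute_class_weights(counts) -> np.ndarray:
    """Normalised inverse-frequency weights: ``(1/N_c) / sum_i (1/N_i)``.

    Smaller classes receive larger weights; the weights sum to one.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("counts must be a 1-D array with >= 2 classes")
    if np.any(counts <= 0):
        raise ValueError("every class count must be > 0 (weight undefined otherwise)")
    inv = 1.0 / counts
    return inv / inv.sum()


@dataclass
class TaskSpec:
    name: str
    n_classes: int
    class_weights: np.ndarray

    def __post_init__(self):
        if self.name not in _TASK_CLASSES:
            raise ValueError(f"unknown task {self.name!r}; expected one of {TASK_NAMES}")
        if self.n_classes != _TASK_CLASSES[self.name]:
            raise ValueError(
                f"task {self.name} has {_TASK_CLASSES[self.name]} classes, "
                f"got {self.n_classes}"
            )
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if self.class_weights.size != self.n_classes or np.any(self.class_weights <= 0):
            raise ValueError("class_weights must be positive, one per class")
        if not np.isclose(self.class_weights.sum(), 1.0):
            raise ValueError("class_weights must sum to 1")


@dataclass
class CaseLabels:
    os: int
    js: int
    hsa: int
    implant: int  # 0 reverse, 1 anatomical

    def __post_init__(self):
        if self.os not in (0, 1, 2) or self.js not in (0, 1, 2):
            raise ValueError("os and js grades must be in {0,1,2}")
        if self.hsa not in (0, 1) or self.implant not in (0, 1):
            raise ValueError("hsa and implant must be in {0,1}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.os, self.js, self.hsa, self.implant)


def default_task_specs(labels: list[CaseLabels],
                       smooth_zeros: bool = False) -> list[TaskSpec]:
    """Task specs with weights derived from observed per-class counts.

    With ``smooth_zeros`` an unobserved class (in a task that still shows at
    least two classes) gets an add-one count so its weight is defined.
    """
    specs = []
    arr = np.array([l.as_tuple() for l in labels])
    for t, name in enumerate(TASK_NAMES):
        n_cls = _TASK_CLASSES[name]
        counts = np.bincount(arr[:, t], minlength=n_cls)
        if np.any(counts == 0):
            if not smooth_zeros or (counts > 0).sum() < 2:
                raise ValueError(
                    f"task {name}: a class is unobserved in the training data")
            counts = counts + 1
        specs.append(TaskSpec(name, n_cls, compute_class_weights(counts)))
    return specs


def multitask_loss(head_probs, labels, specs: list[TaskSpec]) -> Tensor:
    """Sum over tasks of class-weighted cross-entropy.

    ``head_probs`` is a list of (N, n_classes) probability tensors (or a
    single case's vectors); each task term is ``-sum_n w_{y_n} log p_{n,y_n}``
    normalised by the batch mass ``sum_n w_{y_n}`` of the true classes.
    """
    if isinstance(labels, CaseLabels):
        labels = [labels]
    lab = np.array([l.as_tuple() for l in labels])
    total = None
    eps = 1e-12
    for t, spec in enumerate(specs):
        probs = head_probs[t]
        p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))
        if p.data.ndim == 1:
            p = p.reshape(1, -1)
        y = lab[:, t]
        if np.any(y < 0) or np.any(y >= spec.n_classes):
            raise ValueError(f"label out of range for task {spec.name}")
        onehot = np.eye(spec.n_classes, dtype=p.data.dtype)[y]
        w = spec.class_weights[y].astype(p.data.dtype)  # (N,)
        picked = (p.clip(eps, 1.0) * onehot).sum(axis=1)
        term = (picked.log() * (-w)).sum() * (1.0 / float(w.sum()))
        total = term if total is None else total + term
    return total


class ArthroNet(Module):
    """Shared conv encoder + projection + four softmax heads."""

    def __init__(self, specs: list[TaskSpec],
                 encoder_channels: tuple[int, ...] = (8, 16, 32),
                 projection_width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.specs = specs
        chans = (1,) + tuple(encoder_channels)
        self.convs = [Conv3d(chans[i], chans[i + 1], 3, stride=2, rng=rng)
                      for i in range(len(encoder_channels))]
        self.depth = len(encoder_channels)
        self.projection = Linear(encoder_channels[-1], projection_width, rng=rng)
        self.heads = [Linear(projection_width, s.n_classes, rng=rng) for s in specs]

    def forward(self, x) -> list[Tensor]:
        """Map (N, 1, D, H, W) crops to four (N, n_classes) probability rows."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        if any(s % 2**self.depth for s in t.data.shape[2:]):
            raise ValueError(
                f"crop shape {t.data.shape[2:]} incompatible with encoder depth "
                f"{self.depth} (must be divisible by {2**self.depth})"
            )
        h = t
        for conv in self.convs:
            h = conv(h).relu()
        h = h.mean(axis=(2, 3, 4))  # global average pooling -> (N, C)
        z = self.projection(h).relu()
        return [head(z).softmax(axis=1) for head in self.heads]

    __call__ = forward


def build_arthronet(specs: list[TaskSpec], encoder_channels=(8, 16, 32),
                    projection_width: int = 64, seed: int = 0) -> ArthroNet:
    return ArthroNet(specs, encoder_channels, projection_width, seed=seed)


def save_checkpoint(model: ArthroNet, path) -> None:
    """Single-file checkpoint with task specs and encoder widths embedded."""
    import json

    meta = {
        "specs": [{"name": s.name, "n_classes": s.n_classes,
                   "class_weights": s.class_weights.tolist()}
                  for s in model.specs],
        "encoder_channels": [c.weight.data.shape[0] for c in model.convs],
        "projection_width": model.projection.weight.data.shape[1],
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path) -> ArthroNet:
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    specs = [TaskSpec(s["name"], s["n_classes"], np.asarray(s["class_weights"]))
             for s in meta["specs"]]
    model = build_arthronet(specs, tuple(meta["encoder_channels"]),
                            meta["projection_width"])
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model


@dataclass
class ClsTrainingResult:
    model: ArthroNet
    history: pd.DataFrame
    stopped_epoch: int
    best_val_loss: float
    best_state: dict = field(repr=False, default=None)


def _normalise_crop(crop: np.ndarray) -> np.ndarray:
    return np.asarray(crop, dtype=float) / 1200.0 - 0.5


def predict_tasks(model: ArthroNet, crops) -> np.ndarray:
    """Hard per-task predictions, shape (N, 4)."""
    x = _normalise_crop(np.stack(crops))[:, None]
    x = x.astype(model.parameters()[0].data.dtype)
    preds = []
    for i in range(0, x.shape[0], 8):
        probs = model(x[i:i + 8])
        preds.append(np.stack([p.data.argmax(axis=1) for p in probs], axis=1))
    return np.concatenate(preds, axis=0)


def train_classifier(
    train_data: list[tuple[np.ndarray, CaseLabels]],
    val_data: list[tuple[np.ndarray, CaseLabels]],
    specs: list[TaskSpec] | None = None,
    encoder_channels=(8, 16, 32),
    projection_width: int = 64,
    lr: float = 3e-3,
    max_epochs: int = 60,
    patience: int = 8,
    batch_size: int = 4,
    seed: int = 0,
    dtype=np.float32,
) -> ClsTrainingResult:
    """Train the multi-task classifier with early stopping on validation loss.

    Every task must show at least two classes in the training data. History
    records the training loss and per-task validation accuracy per epoch.
    """
    if len(train_data) < 2 or len(val_data) < 1:
        raise ValueError("need >= 2 training and >= 1 validation cases")
    labels = [lab for _, lab in train_data]
    arr = np.array([l.as_tuple() for l in labels])
    for t, name in enumerate(TASK_NAMES):
        if np.unique(arr[:, t]).size < 2:
            raise ValueError(f"task {name} has a single observed class in training data")
    if specs is None:
        specs = default_task_specs(labels, smooth_zeros=True)

    rng = np.random.default_rng(seed)
    model = build_arthronet(specs, encoder_channels, projection_width,
                            seed=int(rng.integers(2**31 - 1))).astype(dtype)
    opt = Adam(model.parameters(), lr=lr)

    x_train = _normalise_crop(np.stack([c for c, _ in train_data]))[:, None].astype(dtype)
    x_val = _normalise_crop(np.stack([c for c, _ in val_data]))[:, None].astype(dtype)
    y_val = [lab for _, lab in val_data]
    y_val_arr = np.array([l.as_tuple() for l in y_val])

    rows = []
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(train_data))
        ep_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            probs = model(x_train[idx])
            loss = multitask_loss(probs, [labels[i] for i in idx], specs)
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        # validation
        v_losses, v_preds = [], []
        for start in range(0, len(val_data), batch_size):
            sl = slice(start, start + batch_size)
            probs = model(x_val[sl])
            v_losses.append(float(multitask_loss(probs, y_val[sl], specs).data))
            v_preds.append(np.stack([p.data.argmax(axis=1) for p in probs], axis=1))
        v_preds = np.concatenate(v_preds, axis=0)
        val_loss = float(np.mean(v_losses))
        row = {"epoch": epoch, "train_loss": float(np.mean(ep_losses)),
               "val_loss": val_loss}
        for t, name in enumerate(TASK_NAMES):
            row[f"val_acc_{name}"] = float((v_preds[:, t] == y_val_arr[:, t]).mean())
        rows.append(row)
        if val_loss < best_val:
            best_val, since_best = val_loss, 0
            best_state = model.state_dict()
        else:
            since_best += 1
            if since_best > patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return ClsTrainingResult(model=model, history=pd.DataFrame(rows),
                             stopped_epoch=len(rows), best_val_loss=best_val,
                             best_state=best_state)
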