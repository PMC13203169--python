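"""Edge-aware dual-decoder segmentation network and its losses.

The network extends a 3-D U-Net with two parallel decoder branches sharing
one encoder: a region branch producing per-class softmax probabilities and
an edge branch producing per-foreground-class boundary probabilities
through a pyramidal multi-scale module. Edge features are fused
unidirectionally into the region decoder at every resolution.

Training combines a region loss — class-weighted soft Dice blended with a
distance-weighted cross-entropy, where each voxel's weight is
``DWM = exp(-EDT)`` and EDT is the unsigned Euclidean distance to the class
boundary — and an edge loss blending forward and reverse distance-weighted
cross-entropies. Both losses are zero at a perfect prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam, Conv3d, Module, Tensor, concat, upsample2
from .volumes import LabelVolume

__all__ = [
    "ArchConfig",
    "LossConfig",
    "compute_distance_weight_map",
    "extract_edge_labels",
    "inverse_frequency_weights",
    "region_loss",
    "edge_loss",
    "build_cel_unet",
    "CELUNet",
    "train_segmentation",
    "SegTrainingResult",
    "predict_labels",
]

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class ArchConfig:
    depth: int = 3
    base_channels: int = 8
    in_channels: int = 1
    n_classes: int = 3
    pyramid_levels: int = 3
    max_channel_factor: int = 4
    edge_branch: bool = True
    fuse_edges: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid channel/class configuration")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class LossConfig:
    """Balance and weighting knobs of the region/edge losses.

    alpha blends soft Dice against distance-weighted cross-entropy in the
    region loss; beta blends forward against reverse cross-entropy in the
    edge loss; class_weights (k_c) default to inverse relative frequency
    normalised to sum to one; epsilon clips probabilities before logs.
    """

    alpha: float = 0.5
    beta: float = 0.5
    class_weights: dict[int, float] | None = None
    epsilon: float = 1e-7
    normalize: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.class_weights is not None and any(
            w <= 0 for w in self.class_weights.values()
        ):
            raise ValueError("class weights must be strictly positive")


# ---------------------------------------------------------------------------
# distance-weighted maps and edge ground truth
# ---------------------------------------------------------------------------

def _class_boundary(mask: np.ndarray) -> np.ndarray:
    """One-voxel-thick 6-connectivity boundary: in-class voxels with a
    6-neighbour outside the class (the grid border counts as outside)."""
    eroded = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    return mask & ~eroded


def extract_edge_labels(labels: LabelVolume | np.ndarray) -> LabelVolume:
    """Per-class boundary voxels, labelled with their class id."""
    arr = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    spacing = labels.spacing if isinstance(labels, LabelVolume) else (1.0, 1.0, 1.0)
    out = np.zeros_like(arr, dtype=np.int16)
    for c in np.unique(arr):
        if c == 0:
            continue
        out[_class_boundary(arr == c)] = c
    return LabelVolume(out, spacing)


def compute_distance_weight_map(
    labels: LabelVolume | np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    classes: tuple[int, ...] = (1, 2),
    voxel_units: bool = True,
) -> dict[int, np.ndarray]:
    """``DWM = exp(-EDT)`` per class, EDT the unsigned Euclidean distance to
    the nearest boundary voxel of the class region.

    Distances are in voxel units by default; pass ``voxel_units=False`` with
    a spacing to measure in mm. Values lie in (0, 1] and equal 1 exactly on
    boundary voxels.
    """
    arr = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    if spacing is None and isinstance(labels, LabelVolume):
        spacing = labels.spacing
    out: dict[int, np.ndarray] = {}
    for c in classes:
        mask = arr == c
        if not mask.any():
            raise ValueError(f"class {c} absent from label volume")
        boundary = _class_boundary(mask)
        sampling = None if voxel_units else spacing
        edt = ndimage.distance_transform_edt(~boundary, sampling=sampling)
        out[c] = np.exp(-edt)
    return out


def inverse_frequency_weights(truth_onehot: np.ndarray) -> np.ndarray:
    """Per-class inverse relative frequency, normalised to sum to one."""
    counts = truth_onehot.reshape(truth_onehot.shape[0], -1).sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("every class must be present to derive frequency weights")
    inv = 1.0 / counts
    return inv / inv.sum()


def _prepare(pred, truth, dwm, cfg: LossConfig, n_classes: int):
    pred_t = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=float))
    truth = np.asarray(truth)
    if not np.issubdtype(truth.dtype, np.floating):
        truth = truth.astype(float)
    if pred_t.data.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_t.data.shape} vs truth {truth.shape}"
        )
    if not np.all(np.isfinite(pred_t.data)) or not np.all(np.isfinite(truth)):
        raise ValueError("non-finite values in loss inputs")
    if dwm is None:
        w = np.ones_like(truth)
    elif isinstance(dwm, dict):
        w = np.stack([np.asarray(dwm[c]) for c in sorted(dwm)], axis=0)
    else:
        w = np.asarray(dwm)
    w = w.astype(truth.dtype, copy=False)
    if w.shape != truth.shape:
        raise ValueError(f"weight map shape {w.shape} does not match truth {truth.shape}")
    if cfg.class_weights is not None:
        kc = np.array([cfg.class_weights[c] for c in sorted(cfg.class_weights)], dtype=float)
        if kc.size != truth.shape[0]:
            raise ValueError("class_weights must cover every channel")
    else:
        kc = inverse_frequency_weights(truth)
    return pred_t, truth, w, kc.astype(truth.dtype)


def _kc_shape(kc: np.ndarray, ndim: int) -> np.ndarray:
    return kc.reshape((kc.size,) + (1,) * (ndim - 1))


def region_loss(pred, truth_onehot, dwm, cfg: LossConfig | None = None) -> Tensor:
    """``alpha * (1 - D) + (1 - alpha) * C`` with D the class-weighted soft
    Dice and C the DWM- and class-weighted cross-entropy (normalised by the
    total applied weight unless ``cfg.normalize`` is off)."""
    cfg = cfg or LossConfig()
    pred_t, truth, w, kc = _prepare(pred, truth_onehot, dwm, cfg, None)
    p = pred_t.clip(cfg.epsilon, 1.0 - cfg.epsilon)
    axes = tuple(range(1, truth.ndim))

    inter = (p * truth).sum(axis=axes)
    denom = p.sum(axis=axes) + Tensor(truth.sum(axis=axes))
    dice_c = (2.0 * inter) / denom
    kc_norm = kc / kc.sum()
    dice = (dice_c * kc_norm).sum()

    kw = _kc_shape(kc, truth.ndim)
    ce_terms = (p.log() * (-(kw * w * truth))).sum()
    if cfg.normalize:
        total_w = float((kw * w * truth).sum())
        ce = ce_terms * (1.0 / total_w) if total_w > 0 else ce_terms
    else:
        ce = ce_terms
    return cfg.alpha * (1.0 - dice) + (1.0 - cfg.alpha) * ce


def edge_loss(pred_edges, truth_edges, dwm, cfg: LossConfig | None = None) -> Tensor:
    """``beta * C + (1 - beta) * C_hat``: forward plus reverse
    distance-weighted cross-entropy over per-class edge probabilities."""
    cfg = cfg or LossConfig()
    pred_t, truth, w, kc = _prepare(pred_edges, truth_edges, dwm, cfg, None)
    p = pred_t.clip(cfg.epsilon, 1.0 - cfg.epsilon)
    kw = _kc_shape(kc, truth.ndim)

    fwd_w = kw * w * truth
    fwd_terms = (p.log() * (-fwd_w)).sum()
    rev_w = kw * w * (1.0 - truth)
    rev_terms = ((1.0 - p).log() * (-rev_w)).sum()
    if cfg.normalize:
        fs, rs = float(fwd_w.sum()), float(rev_w.sum())
        fwd = fwd_terms * (1.0 / fs) if fs > 0 else fwd_terms
        rev = rev_terms * (1.0 / rs) if rs > 0 else rev_terms
    else:
        fwd, rev = fwd_terms, rev_terms
    return cfg.beta * fwd + (1.0 - cfg.beta) * rev


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _ConvBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        self.c1 = Conv3d(in_ch, out_ch, 3, rng=rng)
        self.c2 = Conv3d(out_ch, out_ch, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class CELUNet(Module):
    """Dual-decoder 3-D U-Net; see module docstring."""

    def __init__(self, cfg: ArchConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d = cfg.depth
        chans = [min(cfg.base_channels * 2**i, cfg.base_channels * cfg.max_channel_factor)
                 for i in range(d + 1)]
        self.chans = chans

        self.enc = [_ConvBlock(cfg.in_channels if i == 0 else chans[i], chans[i], rng)
                    for i in range(d)]
        self.down = [Conv3d(chans[i], chans[i + 1], 3, stride=2, rng=rng) for i in range(d)]
        self.bottleneck = _ConvBlock(chans[d], chans[d], rng)

        if cfg.edge_branch:
            self.edge_dec = [
                _ConvBlock(chans[i + 1] + chans[i], chans[i], rng) for i in range(d)
            ]
            n_levels = min(cfg.pyramid_levels, d)
            self.pyramid_levels_used = n_levels
            n_edge_out = cfg.n_classes - 1
            self.pyr = [Conv3d(chans[i], n_edge_out, 1, rng=rng) for i in range(n_levels)]
        else:
            self.edge_dec, self.pyr = [], []
            self.pyramid_levels_used = 0

        fuse = cfg.edge_branch and cfg.fuse_edges
        self.reg_dec = [
            _ConvBlock(chans[i + 1] + chans[i] + (chans[i] if fuse else 0), chans[i], rng)
            for i in range(d)
        ]
        self.reg_head = Conv3d(chans[0], cfg.n_classes, 1, rng=rng)

    def _check_shape(self, x: np.ndarray) -> None:
        if any(s % 2**self.cfg.depth for s in x.shape[2:]):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} not divisible by 2^depth "
                f"({2**self.cfg.depth})"
            )

    def forward(self, x) -> tuple[Tensor, Tensor | None]:
        """Map (N, 1, D, H, W) to (region_probs, edge_probs)."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        self._check_shape(t.data)
        cfg = self.cfg
        skips = []
        h = t
        for i in range(cfg.depth):
            h = self.enc[i](h)
            skips.append(h)
            h = self.down[i](h).relu()
        h = self.bottleneck(h)

        edge_feats: list[Tensor | None] = [None] * cfg.depth
        if cfg.edge_branch:
            e = h
            for i in reversed(range(cfg.depth)):
                e = self.edge_dec[i](concat([upsample2(e), skips[i]], axis=1))
                edge_feats[i] = e
            # pyramidal multi-scale aggregation of edge logits
            logits = None
            for lvl in range(self.pyramid_levels_used):
                le = self.pyr[lvl](edge_feats[lvl])
                for _ in range(lvl):
                    le = upsample2(le)
                logits = le if logits is None else logits + le
            edge_probs = logits.sigmoid()
        else:
            edge_probs = None

        r = h
        for i in reversed(range(cfg.depth)):
            parts = [upsample2(r), skips[i]]
            if cfg.edge_branch and cfg.fuse_edges:
                parts.append(edge_feats[i])
            r = self.reg_dec[i](concat(parts, axis=1))
        region_probs = self.reg_head(r).softmax(axis=1)
        return region_probs, edge_probs

    __call__ = forward


def build_cel_unet(cfg: ArchConfig, seed: int = 0) -> CELUNet:
    return CELUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainingResult:
    model: CELUNet
    history: pd.DataFrame
    stopped_epoch: int
    best_val_loss: float
    best_state: dict = field(repr=False, default=None)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[labels].transpose(3, 0, 1, 2)


def _normalise_image(img: np.ndarray) -> np.ndarray:
    return img / 1200.0 - 0.5


def _foreground_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    scores = []
    for c in range(1, n_classes):
        a, b = pred == c, truth == c
        denom = a.sum() + b.sum()
        scores.append(2.0 * (a & b).sum() / denom if denom else 1.0)
    return float(np.mean(scores))


def train_segmentation(
    train_cases,
    val_cases,
    arch: ArchConfig | None = None,
    loss_cfg: LossConfig | None = None,
    lr: float = 3e-3,
    max_epochs: int = 30,
    patience: int = 5,
    seed: int = 0,
    dtype=np.float32,
) -> SegTrainingResult:
    """Train a CEL-UNet on phantom cases with early stopping.

    Per-epoch history records the mean region loss, mean edge loss,
    validation total loss and validation foreground Dice. Stops when the
    validation loss fails to improve for ``patience`` consecutive epochs.
    Deterministic given ``seed`` and fixed BLAS threading.
    """
    if len(train_cases) < 2 or len(val_cases) < 1:
        raise ValueError("need >= 2 training and >= 1 validation cases")
    arch = arch or ArchConfig()
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(seed)
    model = build_cel_unet(arch, seed=int(rng.integers(2**31 - 1))).astype(dtype)
    opt = Adam(model.parameters(), lr=lr)

    def prep(case):
        img = _normalise_image(case.image.data)[None, None].astype(dtype)
        truth = _one_hot(case.labels.data, arch.n_classes).astype(dtype)
        dwm_all = compute_distance_weight_map(case.labels, classes=tuple(range(arch.n_classes)))
        dwm_region = np.stack([dwm_all[c] for c in range(arch.n_classes)], axis=0).astype(dtype)
        edges = extract_edge_labels(case.labels).data
        edge_truth = np.stack([(edges == c) for c in range(1, arch.n_classes)], axis=0).astype(dtype)
        dwm_edge = np.stack([dwm_all[c] for c in range(1, arch.n_classes)], axis=0).astype(dtype)
        return img, truth, dwm_region, edge_truth, dwm_edge, case.labels.data

    train = [prep(c) for c in train_cases]
    val = [prep(c) for c in val_cases]

    def losses(batch, update: bool):
        img, truth, dwm_r, e_truth, dwm_e, _ = batch
        region_probs, edge_probs = model(img)
        lr_t = region_loss(region_probs[0], truth, dwm_r, loss_cfg)
        if edge_probs is not None:
            le_t = edge_loss(edge_probs[0], e_truth, dwm_e, loss_cfg)
            total = lr_t + le_t
        else:
            le_t = None
            total = lr_t
        if update:
            model.zero_grad()
            total.backward()
            opt.step()
        return (float(lr_t.data), float(le_t.data) if le_t is not None else 0.0,
                region_probs)

    rows = []
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(max_epochs):
        order = rng.permutation(len(train))
        tr_r, tr_e = [], []
        for idx in order:
            l_r, l_e, _ = losses(train[idx], update=True)
            tr_r.append(l_r)
            tr_e.append(l_e)
        v_losses, v_dice = [], []
        for batch in val:
            l_r, l_e, probs = losses(batch, update=False)
            v_losses.append(l_r + l_e)
            pred = probs.data[0].argmax(axis=0)
            v_dice.append(_foreground_dice(pred, batch[5], arch.n_classes))
        val_loss = float(np.mean(v_losses))
        rows.append({
            "epoch": epoch,
            "loss_region": float(np.mean(tr_r)),
            "loss_edge": float(np.mean(tr_e)),
            "val_loss": val_loss,
            "val_dice": float(np.mean(v_dice)),
        })
        if val_loss < best_val:
            best_val, since_best = val_loss, 0
            best_state = model.state_dict()
        else:
            since_best += 1
            if since_best > patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return SegTrainingResult(
        model=model,
        history=pd.DataFrame(rows),
        stopped_epoch=len(rows),
        best_val_loss=best_val,
        best_state=best_state,
    )


def save_checkpoint(model: CELUNet, path) -> None:
    """Single-file checkpoint with the architecture config embedded."""
    import dataclasses
    import json

    meta = json.dumps(dataclasses.asdict(model.cfg))
    np.savez(path, __arch__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> CELUNet:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = ArchConfig(**json.loads(str(data["__arch__"])))
    model = build_cel_unet(cfg)
    state = {k: data[k] for k in data.files if k != "__arch__"}
    model.load_state_dict(state)
    return model


def predict_labels(model: CELUNet, image, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Segment a volume: argmax over the region branch's class probabilities."""
    from .volumes import VoxelVolume

    if isinstance(image, VoxelVolume):
        spacing = image.spacing
        image = image.data
    img = _normalise_image(np.asarray(image, dtype=float))[None, None]
    img = img.astype(model.parameters()[0].data.dtype)
    region_probs, _ = model(img)
    return LabelVolume(region_probs.data[0].argmax(axis=0).astype(np.int16), spacing)
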