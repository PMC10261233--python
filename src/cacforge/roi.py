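"""Region-of-interest networks: heart segmentation and CAC slice selection.

Analysis is restricted to the heart before any calcium quantification.
Two small residual networks handle this:

* a 3-D residual CNN producing a per-voxel heart probability, trained
  with a soft Dice loss on patches; its thresholded output is cleaned up
  to a single connected, hole-free component;
* a 2-D residual classifier scoring each axial heart-cropped slice for
  the presence of visible calcium, trained with cross-entropy; slices
  outside the heart's z-extent are forced negative.

Both are intentionally tiny (a few thousand parameters): on the phantom
contrast (heart tissue ~30-60 HU vs. 0 HU body and -800 HU lungs, bright
calcium) that capacity is sufficient, and training stays in CPU minutes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .volume import CTVolume

#: full CT window mapped to the network input range [-1, 1]; used by the
#: decomposition networks, whose residual maps convert back to HU through it
HU_WINDOW = (-1000.0, 3000.0)

#: soft-tissue window for the ROI networks: the heart/body/lung contrast
#: (~45 vs 0 vs -800 HU) is invisible at the full CT window's scale
ROI_HU_WINDOW = (-200.0, 200.0)


def normalize_hu(hu: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    x = (np.asarray(hu, dtype=np.float32) - lo) / (hi - lo)
    return np.clip(x, 0.0, 1.0) * 2.0 - 1.0


def denormalize_to_hu(x: np.ndarray, window: tuple[float, float] = HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return (np.asarray(x, dtype=np.float64) + 1.0) / 2.0 * (hi - lo) + lo


# ---------------------------------------------------------------------------
# Heart segmentation (3-D)
# ---------------------------------------------------------------------------

@dataclass
class SegConfig:
    epochs: int = 1  # kept for API symmetry; steps is the unit that matters
    steps: int = 250
    lr: float = 2e-3
    patch_size: tuple[int, int, int] = (16, 32, 32)  # (z, y, x)
    batch: int = 2
    channels: int = 8
    seed: int = 0


class HeartSegNet(nn.Module):
    """conv(1->c) -> residual block -> conv(c->1) -> sigmoid."""

    def __init__(self, rng, channels: int):
        self.inc = nn.Conv3d(rng, 1, channels)
        self.res = nn.ResBlock3d(rng, channels)
        self.out = nn.Conv3d(rng, channels, 1)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.inc(x).relu()
        h = self.res(h).relu()
        return self.out(h).sigmoid()


@dataclass
class HeartSegmenter:
    net: HeartSegNet
    config: SegConfig
    loss_log: list

    def save(self, path):
        nn.save_checkpoint(path, self.net, {"kind": "heart_seg", **_cfg_dict(self.config)})

    @classmethod
    def load(cls, path):
        config, arrays = nn.load_checkpoint(path)
        if config.pop("kind", None) != "heart_seg":
            raise ValueError(f"{path} is not a heart segmentation checkpoint")
        cfg = SegConfig(**{k: _untuple(v) for k, v in config.items()})
        net = HeartSegNet(np.random.default_rng(0), cfg.channels)
        net.load_state_arrays(arrays)
        return cls(net=net, config=cfg, loss_log=[])


def _cfg_dict(cfg):
    d = asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _untuple(v):
    return tuple(v) if isinstance(v, list) else v


def _dice_loss(pred: nn.Tensor, target: np.ndarray, eps: float = 1.0) -> nn.Tensor:
    t = nn.Tensor(target)
    inter = (pred * t).sum()
    denom = pred.sum() + t.sum()
    # 1 - 2|P.T|/(|P|+|T|), smoothed
    return 1.0 - (2.0 * inter + eps) * _reciprocal(denom + eps)


def _seg_loss(pred: nn.Tensor, target: np.ndarray) -> nn.Tensor:
    """Soft Dice plus voxel-wise cross-entropy.

    Dice alone is degenerate on foreground-dominated patches (predicting
    foreground everywhere scores well); the cross-entropy term keeps the
    background suppressed.
    """
    t = nn.Tensor(target)
    bce = -(t * pred.log() + (1.0 - t) * (1.0 - pred).log()).mean()
    return _dice_loss(pred, target) + bce


def _reciprocal(x: nn.Tensor) -> nn.Tensor:
    """1/x for a positive scalar tensor (via exp(-log x))."""
    # simple and differentiable: d(1/x) = -1/x^2
    inv = 1.0 / x.data

    def backward(g):
        x._accum(-g * inv * inv)

    return x._child(inv, (x,), backward)


def train_heart_segmenter(cases, config: SegConfig | None = None) -> HeartSegmenter:
    """Train the heart segmentation network on (volume, truth mask) pairs.

    ``cases`` is a list of ``(CTVolume, bool mask)`` on a common analysis
    grid. Training samples random patches, balanced to contain heart
    voxels most of the time. Fully deterministic for a fixed seed.
    """
    cfg = config or SegConfig()
    cases = list(cases)
    if len(cases) == 0:
        raise ValueError("empty training set")
    for _, mask in cases:
        if not np.asarray(mask).any():
            raise ValueError("a training case has an all-background heart mask")
    rng = np.random.default_rng(cfg.seed)
    net = HeartSegNet(rng, cfg.channels)
    opt = nn.Adam(net.parameters(), lr=cfg.lr)
    vols = [normalize_hu(v.voxels, ROI_HU_WINDOW) for v, _ in cases]
    masks = [np.asarray(m, dtype=np.float32) for _, m in cases]
    fg_idx = [np.argwhere(m > 0) for m in masks]
    pz, py, px = cfg.patch_size
    loss_log = []
    for step in range(cfg.steps):
        xs, ts = [], []
        for _ in range(cfg.batch):
            ci = int(rng.integers(len(cases)))
            vol, msk = vols[ci], masks[ci]
            nz, ny, nx = vol.shape
            # bias sampling toward the heart so Dice has foreground signal
            if rng.random() < 0.5:
                zc, yc, xc = fg_idx[ci][rng.integers(len(fg_idx[ci]))]
            else:
                zc = rng.integers(nz)
                yc = rng.integers(ny)
                xc = rng.integers(nx)
            z0 = int(np.clip(zc - pz // 2, 0, max(0, nz - pz)))
            y0 = int(np.clip(yc - py // 2, 0, max(0, ny - py)))
            x0 = int(np.clip(xc - px // 2, 0, max(0, nx - px)))
            xs.append(vol[z0 : z0 + pz, y0 : y0 + py, x0 : x0 + px])
            ts.append(msk[z0 : z0 + pz, y0 : y0 + py, x0 : x0 + px])
        x = nn.Tensor(np.stack(xs)[:, None])
        t = np.stack(ts)[:, None]
        pred = net(x)
        loss = _seg_loss(pred, t)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite segmentation loss at step {step}")
        net.zero_grad()
        loss.backward()
        opt.step()
        loss_log.append(float(loss.data))
    return HeartSegmenter(net=net, config=cfg, loss_log=loss_log)


def segment_heart(volume: CTVolume, model: HeartSegmenter, threshold: float = 0.5) -> np.ndarray:
    """Segment the heart; returns a single-component, hole-filled bool mask.

    Raises if the thresholded prediction is empty (unusable segmentation).
    """
    x = normalize_hu(volume.voxels, ROI_HU_WINDOW)[None, None]
    with nn.no_grad():
        prob = model.net(nn.Tensor(x)).data[0, 0]
    mask = prob > threshold
    if not mask.any():
        raise RuntimeError(f"heart segmentation produced an empty mask for {volume.patient_id!r}")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# Slice classification (2-D)
# ---------------------------------------------------------------------------

@dataclass
class ClsConfig:
    steps: int = 1500
    lr: float = 1e-3
    crop: int = 64
    batch: int = 16
    channels: int = 8
    seed: int = 0
    #: random flip/rotation/translation augmentation; the small training
    #: sets overfit badly without it and miss faint lesions held out
    augment: bool = True
    augment_shift: int = 4
    #: linear lr decay to 10% over the second half of training
    lr_decay: bool = True


class SliceClsNet(nn.Module):
    """Strided residual encoder + global pooling + linear head."""

    def __init__(self, rng, channels: int):
        c = channels
        self.c1 = nn.Conv2d(rng, 1, c, stride=2)
        self.c2 = nn.Conv2d(rng, c, 2 * c, stride=2)
        self.res = nn.ResBlock2d(rng, 2 * c)
        self.head = nn.Dense(rng, 2 * c, 1)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.c1(x).leaky_relu()
        h = self.c2(h).leaky_relu()
        h = self.res(h).leaky_relu()
        return self.head(nn.global_max_pool(h)).sigmoid()


@dataclass
class SliceClassifier:
    net: SliceClsNet
    config: ClsConfig
    loss_log: list

    def save(self, path):
        nn.save_checkpoint(path, self.net, {"kind": "slice_cls", **_cfg_dict(self.config)})

    @classmethod
    def load(cls, path):
        config, arrays = nn.load_checkpoint(path)
        if config.pop("kind", None) != "slice_cls":
            raise ValueError(f"{path} is not a slice classifier checkpoint")
        cfg = ClsConfig(**{k: _untuple(v) for k, v in config.items()})
        net = SliceClsNet(np.random.default_rng(0), cfg.channels)
        net.load_state_arrays(arrays)
        return cls(net=net, config=cfg, loss_log=[])


@dataclass
class SliceLabels:
    probabilities: np.ndarray  # (n_slices,) in [0, 1]
    threshold: float = 0.5

    @property
    def positive(self) -> np.ndarray:
        return self.probabilities > self.threshold

    def __len__(self) -> int:
        return len(self.probabilities)


def heart_crop_slices(
    volume: CTVolume,
    heart_mask: np.ndarray,
    crop: int = 64,
    window: tuple[float, float] = HU_WINDOW,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Normalized ``crop x crop`` in-plane windows centred on the heart.

    The window is clipped to the volume and padded with air where it
    overhangs; returns an ``(n_slices, crop, crop)`` float32 array.
    """
    heart_mask = np.asarray(heart_mask, dtype=bool)
    if heart_mask.shape != volume.shape:
        raise ValueError("heart mask is not on the volume grid")
    if heart_mask.any():
        _, ys, xs = np.nonzero(heart_mask)
        yc = int(round(ys.mean()))
        xc = int(round(xs.mean()))
    else:
        yc = volume.shape[1] // 2
        xc = volume.shape[2] // 2
    nz, ny, nx = volume.shape
    y0, x0 = yc - crop // 2, xc - crop // 2
    out = np.full((nz, crop, crop), -1000.0, dtype=np.float32)
    ys0, ys1 = max(0, y0), min(ny, y0 + crop)
    xs0, xs1 = max(0, x0), min(nx, x0 + crop)
    out[:, ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = volume.voxels[:, ys0:ys1, xs0:xs1]
    return normalize_hu(out, window), (y0, x0)


def _augment_batch(batch, shift, rng):
    """Random flips, right-angle rotations and small translations."""
    out = []
    for s in batch:
        if rng.random() < 0.5:
            s = s[::-1]
        if rng.random() < 0.5:
            s = s[:, ::-1]
        s = np.rot90(s, int(rng.integers(4)))
        dy, dx = rng.integers(-shift, shift + 1, 2)
        s = np.roll(np.roll(s, dy, 0), dx, 1)
        out.append(s)
    return np.stack(out)


def train_slice_classifier(slices, labels, config: ClsConfig | None = None) -> SliceClassifier:
    """Train the CAC-presence slice classifier.

    ``slices``: (n, crop, crop) normalized array; ``labels``: (n,) binary.
    Batches are drawn class-balanced and augmented with flips, rotations
    and small shifts; both classes must be present.
    """
    cfg = config or ClsConfig()
    slices = np.asarray(slices, dtype=np.float32)
    labels = np.asarray(labels).astype(bool)
    if slices.ndim != 3 or len(slices) != len(labels):
        raise ValueError("slices must be (n, h, w) with one label per slice")
    pos_idx = np.nonzero(labels)[0]
    neg_idx = np.nonzero(~labels)[0]
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present in the training data")
    rng = np.random.default_rng(cfg.seed)
    net = SliceClsNet(rng, cfg.channels)
    opt = nn.Adam(net.parameters(), lr=cfg.lr)
    loss_log = []
    half = cfg.batch // 2
    for step in range(cfg.steps):
        if cfg.lr_decay and step > cfg.steps // 2:
            opt.lr = cfg.lr * (1.0 - 0.9 * (step - cfg.steps // 2) / max(1, cfg.steps // 2))
        idx = np.concatenate(
            [rng.choice(pos_idx, half), rng.choice(neg_idx, cfg.batch - half)]
        )
        xb = slices[idx]
        if cfg.augment:
            xb = _augment_batch(xb, cfg.augment_shift, rng)
        x = nn.Tensor(xb[:, None])
        y = labels[idx].astype(np.float32)[:, None]
        p = net(x)
        # binary cross-entropy
        loss = -(nn.Tensor(y) * p.log() + nn.Tensor(1.0 - y) * (1.0 - p).log()).mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite classifier loss at step {step}")
        net.zero_grad()
        loss.backward()
        opt.step()
        loss_log.append(float(loss.data))
    return SliceClassifier(net=net, config=cfg, loss_log=loss_log)


def classify_slices(
    volume: CTVolume, heart_mask: np.ndarray, model: SliceClassifier
) -> SliceLabels:
    """Score each axial slice for visible CAC; outside-heart slices are negative."""
    heart_mask = np.asarray(heart_mask, dtype=bool)
    if heart_mask.shape != volume.shape:
        raise ValueError("heart mask grid does not match the volume")
    crops, _ = heart_crop_slices(volume, heart_mask, crop=model.config.crop, window=ROI_HU_WINDOW)
    with nn.no_grad():
        probs = model.net(nn.Tensor(crops[:, None])).data[:, 0]
    in_heart = heart_mask.any(axis=(1, 2))
    probs = np.where(in_heart, probs, 0.0)
    return SliceLabels(probabilities=probs.astype(float))
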