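"""Unpaired calcium decomposition with a CycleGAN.

An axial slice containing coronary calcium is decomposed into a
synthetic calcium-free counterpart plus a nonnegative CAC-map, without
any paired training data. Two residual generators translate between the
*CAC* and *noCAC* slice domains:

* the removing generator predicts a CAC-map and **subtracts** it from
  its input, and
* the synthesizing generator predicts a CAC-map and **adds** it,

so the decomposition identity ``input = counterpart + map`` holds
bit-exactly by construction, and map nonnegativity is architectural (the
map passes through a softplus). Two patch discriminators judge whether
translated slices look like real members of the target domain; training
uses least-squares adversarial losses plus an L1 cycle-consistency term
in both directions.

Networks operate in normalized intensity space (a soft-tissue-to-400-HU
window mapped to [-1, 1]); maps are converted back to HU before scoring.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .roi import SliceLabels, heart_crop_slices, normalize_hu
from .volume import CTVolume

#: intensity window for the decomposition networks: covers the degraded
#: lesion intensities of thick-slice scans (which rarely exceed ~300 HU)
#: while keeping lesion/tissue contrast a large fraction of the input range
DEC_HU_WINDOW = (-200.0, 400.0)

#: normalized units -> HU for additive quantities (window width / 2)
MAP_SCALE_HU = (DEC_HU_WINDOW[1] - DEC_HU_WINDOW[0]) / 2.0


@dataclass
class CycleGANConfig:
    iterations: int = 3000
    lr: float = 1e-4
    batch: int = 4
    crop: int = 64
    cycle_weight: float = 10.0
    channels: int = 12
    seed: int = 0
    log_every: int = 100
    #: keep lr constant for the first half, then decay linearly to
    #: lr_final_fraction * lr — stabilizes the adversarial equilibrium
    lr_final_fraction: float = 0.05
    #: weight of the identity terms: the removing generator should leave
    #: calcium-free slices untouched (zero map), and symmetrically the
    #: synthesizing generator should not alter slices already with CAC
    identity_weight: float = 5.0
    #: exponential moving average of generator weights used at inference;
    #: smooths the oscillation of the adversarial equilibrium
    ema_decay: float = 0.998


class ResidualGenerator(nn.Module):
    """Predicts a nonnegative residual map from a slice.

    The map passes through a softplus, so nonnegativity is architectural;
    the output bias starts strongly negative so that initial maps are
    near zero without the dead-gradient failure a hard ReLU output has.
    """

    def __init__(self, rng, channels: int):
        self.inc = nn.Conv2d(rng, 1, channels)
        self.res1 = nn.ResBlock2d(rng, channels)
        self.res2 = nn.ResBlock2d(rng, channels)
        self.out = nn.Conv2d(rng, channels, 1)
        self.out.b.data = np.full(1, -4.0, dtype=np.float32)

    def map(self, x: nn.Tensor) -> nn.Tensor:
        h = self.inc(x).relu()
        h = self.res1(h).relu()
        h = self.res2(h).relu()
        return self.out(h).softplus()  # nonnegativity is architectural


class PatchDiscriminator(nn.Module):
    """Strided convolutional critic with patch-wise real/fake outputs.

    ``score`` aggregates the patch map into one slice-level score with
    the extremum appropriate for the domain: calcium evidence is
    localized, so membership of the CAC domain is judged by the
    *strongest* patch (max), while a single contaminated patch betrays a
    fake calcium-free slice, so the noCAC domain is judged by the
    *weakest* patch (min). Plain per-patch averaging drowns the sparse
    lesion signal among the many indistinguishable tissue patches.
    """

    def __init__(self, rng, channels: int):
        c = channels
        self.c1 = nn.Conv2d(rng, 1, c, stride=2)
        self.c2 = nn.Conv2d(rng, c, 2 * c, stride=2)
        self.c3 = nn.Conv2d(rng, 2 * c, 1)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.c1(x).leaky_relu()
        h = self.c2(h).leaky_relu()
        return self.c3(h)

    def score(self, x: nn.Tensor, aggregate: str) -> nn.Tensor:
        patches = self(x)
        if aggregate == "max":
            return nn.global_max_pool(patches)
        if aggregate == "min":
            return nn.global_min_pool(patches)
        raise ValueError(f"unknown aggregate {aggregate!r}")


@dataclass
class DecompositionModel:
    g_rem: ResidualGenerator
    g_syn: ResidualGenerator
    d_cac: PatchDiscriminator
    d_nocac: PatchDiscriminator
    config: CycleGANConfig
    loss_log: list = field(default_factory=list)

    def save(self, path):
        import json
        from pathlib import Path

        nets = {"g_rem": self.g_rem, "g_syn": self.g_syn, "d_cac": self.d_cac, "d_nocac": self.d_nocac}
        arrays = {}
        for name, net in nets.items():
            for i, a in enumerate(net.state_arrays()):
                arrays[f"{name}_{i}"] = a
        cfg = {"kind": "cyclegan", **asdict(self.config)}
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path):
        import json
        from pathlib import Path

        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"model checkpoint not found: {path}")
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config"]).decode())
            if cfg.pop("kind", None) != "cyclegan":
                raise ValueError(f"{path} is not a decomposition checkpoint")
            config = CycleGANConfig(**cfg)
            rng = np.random.default_rng(0)
            model = cls(
                g_rem=ResidualGenerator(rng, config.channels),
                g_syn=ResidualGenerator(rng, config.channels),
                d_cac=PatchDiscriminator(rng, config.channels),
                d_nocac=PatchDiscriminator(rng, config.channels),
                config=config,
            )
            for name, net in (
                ("g_rem", model.g_rem), ("g_syn", model.g_syn),
                ("d_cac", model.d_cac), ("d_nocac", model.d_nocac),
            ):
                n = len(net.parameters())
                net.load_state_arrays([data[f"{name}_{i}"] for i in range(n)])
        return model


def _mse_to(x: nn.Tensor, target: float) -> nn.Tensor:
    return (x - target).square().mean()


def train_cyclegan(cac_slices, nocac_slices, config: CycleGANConfig | None = None) -> DecompositionModel:
    """Train the decomposition CycleGAN on unpaired normalized slices.

    ``cac_slices`` and ``nocac_slices`` are ``(n, crop, crop)`` arrays in
    normalized intensity space, typically heart-cropped axial slices
    assigned to the two domains by per-slice CAC labels. Generator and
    discriminator parameters are updated alternately with Adam; the loss
    log records (iteration, d_loss, g_adv, g_cycle, g_identity).
    Deterministic for a fixed seed.
    """
    cfg = config or CycleGANConfig()
    cac = np.asarray(cac_slices, dtype=np.float32)
    nocac = np.asarray(nocac_slices, dtype=np.float32)
    if len(cac) == 0 or len(nocac) == 0:
        raise ValueError("both domains must be non-empty")
    if cac.ndim != 3 or nocac.ndim != 3:
        raise ValueError("slices must be (n, h, w) arrays")
    rng = np.random.default_rng(cfg.seed)
    model = DecompositionModel(
        g_rem=ResidualGenerator(rng, cfg.channels),
        g_syn=ResidualGenerator(rng, cfg.channels),
        d_cac=PatchDiscriminator(rng, cfg.channels),
        d_nocac=PatchDiscriminator(rng, cfg.channels),
        config=cfg,
    )
    g_opt = nn.Adam([*model.g_rem.parameters(), *model.g_syn.parameters()], lr=cfg.lr)
    d_opt = nn.Adam([*model.d_cac.parameters(), *model.d_nocac.parameters()], lr=cfg.lr)
    g_params = [*model.g_rem.parameters(), *model.g_syn.parameters()]
    ema = [p.data.copy() for p in g_params]

    half = cfg.iterations // 2
    for it in range(cfg.iterations):
        if it >= half and cfg.iterations > half:
            frac = (it - half) / max(1, cfg.iterations - half)
            lr_now = cfg.lr * (1.0 - (1.0 - cfg.lr_final_fraction) * frac)
            g_opt.lr = lr_now
            d_opt.lr = lr_now
        b = cfg.batch
        cac_batch = cac[rng.integers(len(cac), size=b)][:, None]
        nocac_batch = nocac[rng.integers(len(nocac), size=b)][:, None]
        x_cac = nn.Tensor(cac_batch)
        x_nocac = nn.Tensor(nocac_batch)

        # --- generator update (g_rem runs once on [cac | nocac]: first half
        # is the removal map, second half the identity map)
        map_both = model.g_rem.map(nn.Tensor(np.concatenate([cac_batch, nocac_batch])))
        map_rem = map_both.narrow(0, b)
        fake_nocac = x_cac - map_rem
        map_syn = model.g_syn.map(x_nocac)
        fake_cac = x_nocac + map_syn
        rec_cac = fake_nocac + model.g_syn.map(fake_nocac)
        rec_nocac = fake_cac - model.g_rem.map(fake_cac)
        # dense per-patch term plus slice-level extremum term: the patch
        # term gives gradients everywhere, the extremum focuses on the
        # sparse lesion evidence
        g_adv = (
            _mse_to(model.d_nocac(fake_nocac), 1.0)
            + _mse_to(model.d_cac(fake_cac), 1.0)
            + _mse_to(model.d_nocac.score(fake_nocac, "min"), 1.0)
            + _mse_to(model.d_cac.score(fake_cac, "max"), 1.0)
        )
        g_cycle = (rec_cac - x_cac).abs().mean() + (rec_nocac - x_nocac).abs().mean()
        # identity: removing from a clean slice should produce no map
        g_ident = map_both.narrow(b, 2 * b).abs().mean()
        g_loss = g_adv + cfg.cycle_weight * g_cycle + cfg.identity_weight * g_ident
        if not np.isfinite(g_loss.data):
            raise RuntimeError(f"non-finite generator loss at iteration {it}")
        model.g_rem.zero_grad()
        model.g_syn.zero_grad()
        g_loss.backward()
        g_opt.step()
        for e, p in zip(ema, g_params):
            e *= cfg.ema_decay
            e += (1.0 - cfg.ema_decay) * p.data

        # --- discriminator update (detached fakes, batched with reals:
        # first half real -> target 1, second half fake -> target 0)
        patch_tgt = np.zeros((2 * b, 1, 1, 1), dtype=np.float32)
        patch_tgt[:b] = 1.0
        score_tgt = patch_tgt[:, :, 0, 0]
        d_loss = nn.Tensor(0.0)
        for disc, real_b, fake_t, agg in (
            (model.d_nocac, nocac_batch, fake_nocac, "min"),
            (model.d_cac, cac_batch, fake_cac, "max"),
        ):
            patches = disc(nn.Tensor(np.concatenate([real_b, fake_t.data])))
            pooled = nn.global_max_pool(patches) if agg == "max" else nn.global_min_pool(patches)
            d_loss = d_loss + 2.0 * (
                (patches - patch_tgt).square().mean() + (pooled - score_tgt).square().mean()
            )
        if not np.isfinite(d_loss.data):
            raise RuntimeError(f"non-finite discriminator loss at iteration {it}")
        model.d_cac.zero_grad()
        model.d_nocac.zero_grad()
        d_loss.backward()
        d_opt.step()

        if it % cfg.log_every == 0 or it == cfg.iterations - 1:
            model.loss_log.append(
                (it, float(d_loss.data), float(g_adv.data), float(g_cycle.data), float(g_ident.data))
            )
    # ship the EMA generators: the time-averaged weights are what inference uses
    for e, p in zip(ema, g_params):
        p.data = e.astype(np.float32)
    return model


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def remove_cac(slice_2d: np.ndarray, model: DecompositionModel):
    """Decompose a normalized slice: returns ``(nocac_slice, cac_map)``.

    The identity ``slice == nocac_slice + cac_map`` holds exactly and the
    map is nonnegative everywhere.
    """
    x = np.asarray(slice_2d, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {x.shape}")
    with nn.no_grad():
        cac_map = model.g_rem.map(nn.Tensor(x[None, None])).data[0, 0]
    return x - cac_map, cac_map


def synthesize_cac(slice_2d: np.ndarray, model: DecompositionModel):
    """Inverse translation: returns ``(cac_slice, cac_map)`` with
    ``cac_slice == slice + cac_map`` exact and the map nonnegative."""
    x = np.asarray(slice_2d, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {x.shape}")
    with nn.no_grad():
        cac_map = model.g_syn.map(nn.Tensor(x[None, None])).data[0, 0]
    return x + cac_map, cac_map


def decompose_volume(
    volume: CTVolume,
    heart_mask: np.ndarray,
    labels: SliceLabels,
    model: DecompositionModel,
) -> np.ndarray:
    """Per-voxel CAC-map (HU) for a whole volume.

    Only slices labelled CAC-positive are passed through the removing
    generator (on the heart-centred crop); negative slices get all-zero
    planes, and the result is masked to the heart. Returns a float array
    on the volume grid, nonnegative, zero outside the heart.
    """
    heart_mask = np.asarray(heart_mask, dtype=bool)
    if heart_mask.shape != volume.shape:
        raise ValueError("heart mask grid does not match the volume")
    if len(labels) != volume.n_slices:
        raise ValueError(
            f"slice labels ({len(labels)}) do not match slice count ({volume.n_slices})"
        )
    crops, (y0, x0) = heart_crop_slices(volume, heart_mask, crop=model.config.crop, window=DEC_HU_WINDOW)
    nz, ny, nx = volume.shape
    crop = model.config.crop
    out = np.zeros(volume.shape, dtype=np.float64)
    pos = np.nonzero(labels.positive)[0]
    if len(pos):
        with nn.no_grad():
            maps = model.g_rem.map(nn.Tensor(crops[pos][:, None])).data[:, 0]
        ys0, ys1 = max(0, y0), min(ny, y0 + crop)
        xs0, xs1 = max(0, x0), min(nx, x0 + crop)
        for z, m in zip(pos, maps):
            out[z, ys0:ys1, xs0:xs1] = m[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
    out *= MAP_SCALE_HU  # normalized residual -> HU
    out[~heart_mask] = 0.0
    return out
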