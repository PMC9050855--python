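"""Dense-block U-Net for voxelwise aliased/not-aliased classification.

Each 3D volume (one cardiac frame, one velocity direction) of an aliased
field is a separate input.  Volumes are normalized to ``[-1, 1)`` by dividing
by their venc — the wrap operation is scale-free in these units, so one model
serves any venc — and center-cropped in-plane; the network assigns every
voxel one of two classes via a softmax head, and the per-volume masks are
compiled into the full 5-axis aliased-voxel mask.

The architecture is a U-Net whose convolutional stages are dense blocks
(small convolutions whose outputs are concatenated to their inputs), with
in-plane-only pooling so variable slab counts need no padding, concatenation
skip connections, and a two-channel softmax head.  Training minimizes a
composite of voxelwise softmax cross-entropy and a smoothed soft-Dice loss
(see :data:`DICE_SMOOTH` for why the loss smoothing differs from the
evaluation Dice's 1e-5 stabilizer); aliasing is re-simulated afresh every
epoch at venc fractions drawn uniformly from [0.40, 0.70].
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .aliasing import WrapSpec, wrap_velocity
from .core import VelocityField
from .metrics import dice

__all__ = [
    "CnnConfig",
    "CropInfo",
    "center_crop",
    "uncrop",
    "DenseUNet",
    "build_model",
    "composite_loss",
    "train",
    "predict",
    "TrainingRecord",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyperparameters.

    The class defaults are the full-scale profile (in-plane crop 128x96,
    learning rate 1e-4, dropout 0.1, batch size 1; 400 epochs there take days
    on CPU, so the default epoch count is a desk-scale 30).
    :meth:`tiny` is the small preset used for desk-scale experiments and tests.
    """

    crop_xy: tuple[int, int] = (128, 96)
    levels: int = 4
    dense_layers: int = 4
    growth: int = 12
    init_channels: int = 12
    width: int = 24  # channels after the 1x1 compression following each block
    kernel: tuple[int, int, int] = (3, 3, 3)
    dropout: float = 0.1
    learning_rate: float = 1e-4
    lr_decay: str = "constant"  # "constant" or "hold-cosine" (constant for the
    # first half of the run, then cosine decay to 10%)
    batch_size: int = 1
    epochs: int = 30
    wraps_per_dataset_per_epoch: int = 4
    venc_fraction_range: tuple[float, float] = (0.40, 0.70)
    seed: int = 0

    def __post_init__(self) -> None:
        f = 2 ** (self.levels - 1)
        if self.crop_xy[0] % f or self.crop_xy[1] % f:
            raise ValueError(
                f"crop dims {self.crop_xy} must be divisible by 2^(levels-1) = {f}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.levels < 1 or self.dense_layers < 1 or self.growth < 1:
            raise ValueError("levels, dense_layers and growth must be positive")
        if self.lr_decay not in ("constant", "hold-cosine"):
            raise ValueError(f"unknown lr_decay {self.lr_decay!r}")
        lo, hi = self.venc_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("venc_fraction_range must satisfy 0 < lo <= hi < 1")

    @classmethod
    def tiny(cls, **overrides) -> "CnnConfig":
        """Small desk-scale preset: a 2-level net with in-plane kernels on
        48x32 crops, sized so training finishes in minutes on one core."""
        kw = dict(
            crop_xy=(48, 32),
            levels=2,
            dense_layers=2,
            growth=6,
            init_channels=6,
            width=12,
            kernel=(3, 3, 1),
            epochs=10,
            learning_rate=3e-3,
            lr_decay="hold-cosine",
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# cropping


@dataclass(frozen=True)
class CropInfo:
    """Bookkeeping to re-embed a cropped/padded volume exactly."""

    in_shape: tuple[int, int]
    offsets: tuple[int, int]  # voxels removed from the low side (cropping)
    pad: tuple[int, int]  # voxels of zero padding added per side (low side gets the extra)


def _crop_1d(n: int, c: int) -> tuple[int, int]:
    """(low offset removed, low padding added) to take n -> c symmetrically."""
    if n >= c:
        return ((n - c) + 1) // 2, 0
    return 0, ((c - n) + 1) // 2


def center_crop(volume: np.ndarray, crop_xy: tuple[int, int]) -> tuple[np.ndarray, CropInfo]:
    """Center-crop (or zero-pad) the in-plane dims of a 3D volume.

    Output in-plane shape equals ``crop_xy``; cropping/padding is symmetric
    about the array center, with the extra voxel on the low side when the
    difference is odd.  The returned :class:`CropInfo` allows exact
    re-embedding via :func:`uncrop`.
    """
    nx, ny = volume.shape[:2]
    cx, cy = int(crop_xy[0]), int(crop_xy[1])
    ox, px = _crop_1d(nx, cx)
    oy, py = _crop_1d(ny, cy)
    out = volume[ox : ox + cx, oy : oy + cy]
    if px or py:
        hx = cx - volume.shape[0] - px if px else 0
        hy = cy - volume.shape[1] - py if py else 0
        out = np.pad(out, ((px, hx), (py, hy)) + ((0, 0),) * (volume.ndim - 2))
    return out, CropInfo((nx, ny), (ox, oy), (px, py))


def uncrop(cropped: np.ndarray, info: CropInfo, fill=0) -> np.ndarray:
    """Embed a cropped volume back at its original in-plane size.

    Padding regions are discarded; regions removed by the crop are ``fill``.
    """
    nx, ny = info.in_shape
    cx, cy = cropped.shape[:2]
    px, py = info.pad
    core = cropped[px : px + min(nx, cx), py : py + min(ny, cy)]
    out = np.full((nx, ny) + cropped.shape[2:], fill, dtype=cropped.dtype)
    ox, oy = info.offsets
    out[ox : ox + core.shape[0], oy : oy + core.shape[1]] = core
    return out


# ---------------------------------------------------------------------------
# model


class DenseUNet:
    """Encoder–decoder of dense blocks with in-plane pooling.

    Structure per encoder level: dense block -> 1x1 compression -> pool
    (skip connections tap the compressed features).  The decoder mirrors this
    with nearest upsampling and concatenation skips.  The head is a 1x1
    convolution to two channels, zero-initialized with a background-favoring
    bias, so an untrained model predicts "not aliased" everywhere.
    """

    def __init__(self, config: CnnConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        k = config.kernel
        L, w = config.levels, config.width
        self.conv_in = nn.Conv3d(1, config.init_channels, k, rng)
        self.act_in = nn.ReLU()
        self.enc_blocks, self.enc_comp, self.enc_act = [], [], []
        c = config.init_channels
        for _ in range(L):
            blk = nn.DenseBlock(c, config.dense_layers, config.growth, k, config.dropout, rng)
            self.enc_blocks.append(blk)
            self.enc_comp.append(nn.Conv3d(blk.c_out, w, (1, 1, 1), rng))
            self.enc_act.append(nn.ReLU())
            c = w
        self.pools = [nn.MaxPool2x2() for _ in range(L - 1)]
        self.ups = [nn.Upsample2x2() for _ in range(L - 1)]
        self.dec_blocks, self.dec_comp, self.dec_act = [], [], []
        for _ in range(L - 1):
            blk = nn.DenseBlock(2 * w, config.dense_layers, config.growth, k, config.dropout, rng)
            self.dec_blocks.append(blk)
            self.dec_comp.append(nn.Conv3d(blk.c_out, w, (1, 1, 1), rng))
            self.dec_act.append(nn.ReLU())
        self.head = nn.Conv3d(
            w, 2, (1, 1, 1), rng, zero_init=True, bias_init=np.array([1.0, -1.0])
        )

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = self.conv_in.params()
        for blk, comp in zip(self.enc_blocks, self.enc_comp):
            ps += blk.params() + comp.params()
        for blk, comp in zip(self.dec_blocks, self.dec_comp):
            ps += blk.params() + comp.params()
        return ps + self.head.params()

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def checksum(self) -> str:
        return nn.checksum(self.params())

    # -- forward / backward ------------------------------------------------
    def forward(self, volume: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape ``volume.shape + (2,)`` for a 3D input volume."""
        x = np.ascontiguousarray(volume, dtype=np.float32)[..., None]
        h = self.act_in.forward(self.conv_in.forward(x, train), train)
        skips = []
        L = self.config.levels
        for i in range(L):
            h = self.enc_blocks[i].forward(h, train)
            h = self.enc_act[i].forward(self.enc_comp[i].forward(h, train), train)
            if i < L - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for i in reversed(range(L - 1)):
            h = self.ups[i].forward(h, train)
            h = np.concatenate([skips[i], h], axis=-1)
            h = self.dec_blocks[i].forward(h, train)
            h = self.dec_act[i].forward(self.dec_comp[i].forward(h, train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        L = self.config.levels
        w = self.config.width
        dh = self.head.backward(dlogits.astype(np.float32, copy=False))
        dskips: dict[int, np.ndarray] = {}
        for i in range(L - 1):
            dh = self.dec_comp[i].backward(self.dec_act[i].backward(dh))
            dh = self.dec_blocks[i].backward(dh)
            dskips[i] = dh[..., :w]
            dh = self.ups[i].backward(dh[..., w:])
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                dh = self.pools[i].backward(dh) + dskips[i]
            dh = self.enc_comp[i].backward(self.enc_act[i].backward(dh))
            dh = self.enc_blocks[i].backward(dh)
        self.conv_in.backward(self.act_in.backward(dh))

    def predict_volume(self, volume: np.ndarray) -> np.ndarray:
        """Boolean aliased-voxel mask for one (cropped, normalized) volume."""
        logits = self.forward(volume, train=False)
        return logits[..., 1] > logits[..., 0]


def build_model(config: CnnConfig) -> DenseUNet:
    """Construct a seeded :class:`DenseUNet`; identical configs (same seed)
    yield bit-identical initial weights."""
    return DenseUNet(config)


# ---------------------------------------------------------------------------
# loss


#: smoothing constant of the soft-Dice *loss*.  The evaluation Dice uses the
#: tiny 1e-5 stabilizer, but reusing that in the loss makes empty-truth
#: volumes a needle-sharp optimum whose gradient grows like 1/eps as the
#: foreground probability mass vanishes — those gradients (from the many
#: aliasing-free diastolic volumes) swamp the foreground signal and collapse
#: the network to all-background.  The conventional unit smooth term keeps
#: empty-truth volumes well defined with bounded gradients.
DICE_SMOOTH = 1.0


def composite_loss(prob_fg: np.ndarray, truth: np.ndarray) -> float:
    """Cross-entropy + (1 - soft Dice) of a foreground-probability volume.

    ``prob_fg`` holds per-voxel probabilities of the "aliased" class; the
    background probability is its complement.  The soft-Dice term is
    smoothed with :data:`DICE_SMOOTH` so an all-background prediction on an
    empty truth attains the minimal loss.
    """
    p = np.asarray(prob_fg, dtype=float)
    y = np.asarray(truth, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    eps = 1e-12  # numerical floor inside the logs only
    ce = float(-(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps)).mean())
    inter = float((p * y).sum())
    soft_dice = (2.0 * inter + DICE_SMOOTH) / (p.sum() + y.sum() + DICE_SMOOTH)
    return ce + (1.0 - soft_dice)


def _loss_and_grad(logits: np.ndarray, truth: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """(ce, dice_loss, dlogits, soft_dice) for a two-channel logit volume."""
    p = nn.softmax(logits)
    p1 = p[..., 1]
    y = truth.astype(np.float32)
    n = y.size
    eps = 1e-12
    ce = float(-(y * np.log(p1 + eps) + (1.0 - y) * np.log(p[..., 0] + eps)).mean())
    inter = float((p1 * y).sum())
    denom = float(p1.sum() + y.sum()) + DICE_SMOOTH
    soft_dice = (2.0 * inter + DICE_SMOOTH) / denom
    # CE gradient directly wrt logits: (softmax - onehot)/n
    onehot = np.stack([1.0 - y, y], axis=-1)
    dlogits = (p - onehot) / n
    if truth.any():
        # the dice term combats class imbalance where aliasing exists; on
        # empty-truth volumes it only races the background probability toward
        # saturation (CE already handles those), so its gradient is skipped
        dD_dp1 = (2.0 * y * denom - (2.0 * inter + DICE_SMOOTH)) / denom**2
        g1 = -dD_dp1  # gradient of the dice-loss term wrt p1
        # dice term: dL/dz_c = p_c * (g_c - sum_k g_k p_k) with g = (0, g1)
        s = g1 * p1
        dlogits[..., 0] += p[..., 0] * (-s)
        dlogits[..., 1] += p1 * (g1 - s)
    return ce, float(1.0 - soft_dice), dlogits, float(soft_dice)


# ---------------------------------------------------------------------------
# training / inference


@dataclass
class TrainingRecord:
    """Per-epoch training history (losses, Dice, wall-clock, rng digests)."""

    ce: list[float] = field(default_factory=list)
    dice_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    seconds: list[float] = field(default_factory=list)
    rng_digests: list[str] = field(default_factory=list)
    n_samples_per_epoch: int = 0
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def _volume_samples(aliased: VelocityField, truth: np.ndarray, crop_xy):
    """Yield (normalized cropped volume, cropped truth) per frame x direction."""
    venc = aliased.venc
    for t in range(aliased.n_frames):
        for d in range(3):
            vol, info = center_crop(aliased.volume(t, d) / venc, crop_xy)
            lab, _ = center_crop(truth[:, :, :, t, d], crop_xy)
            yield vol, lab


def train(
    model: DenseUNet,
    fields: list[VelocityField],
    config: CnnConfig | None = None,
    val_fields: list[VelocityField] | None = None,
    val_fraction: float = 0.5,
) -> tuple[DenseUNet, TrainingRecord]:
    """Train on clean (non-aliased) fields with per-epoch simulated aliasing.

    Every epoch, each training field is wrapped ``wraps_per_dataset_per_epoch``
    times at venc fractions drawn uniformly from ``venc_fraction_range``; every
    (frame, direction) volume of every wrap is one sample.  Optimization is
    Adam at ``learning_rate`` with gradient accumulation over ``batch_size``
    samples.  With a fixed config seed the loss trajectory is reproducible.

    ``val_fields``, if given, are wrapped once at ``val_fraction`` and the
    mask Dice on them is recorded after each epoch.
    """
    if config is None:
        config = model.config
    if not fields:
        raise ValueError("training requires at least one velocity field")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1CE]))
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    record = TrainingRecord()
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        state = repr(rng.bit_generator.state).encode()
        record.rng_digests.append(hashlib.sha256(state).hexdigest()[:16])
        if config.lr_decay == "hold-cosine" and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            if frac <= 0.5:
                opt.lr = config.learning_rate
            else:
                t = (frac - 0.5) / 0.5
                opt.lr = config.learning_rate * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * t)))
        samples = []
        for f in fields:
            for _ in range(config.wraps_per_dataset_per_epoch):
                frac = rng.uniform(*config.venc_fraction_range)
                aliased, truth = wrap_velocity(f, WrapSpec(venc_fraction=frac))
                samples.extend(_volume_samples(aliased, truth, config.crop_xy))
        order = rng.permutation(len(samples))
        ces, dls, sds = [], [], []
        opt.zero_grad()
        in_batch = 0
        for j in order:
            vol, lab = samples[j]
            logits = model.forward(vol, train=True)
            ce, dl, dlogits, sd = _loss_and_grad(logits, lab)
            model.backward(dlogits)
            ces.append(ce)
            dls.append(dl)
            sds.append(sd)
            in_batch += 1
            if in_batch == config.batch_size:
                opt.step()
                opt.zero_grad()
                in_batch = 0
        if in_batch:
            opt.step()
            opt.zero_grad()
        record.ce.append(float(np.mean(ces)))
        record.dice_loss.append(float(np.mean(dls)))
        record.train_dice.append(float(np.mean(sds)))
        record.n_samples_per_epoch = len(samples)
        if val_fields:
            vds = []
            for f in val_fields:
                aliased, truth = wrap_velocity(f, WrapSpec(venc_fraction=val_fraction))
                vds.append(dice(predict(model, aliased), truth))
            record.val_dice.append(float(np.mean(vds)))
        record.seconds.append(time.perf_counter() - t0)
        logger.info(
            "epoch %d/%d: CE %.4f, dice-loss %.4f, train soft-Dice %.3f%s (%.1f s)",
            epoch + 1, config.epochs, record.ce[-1], record.dice_loss[-1],
            record.train_dice[-1],
            f", val Dice {record.val_dice[-1]:.3f}" if val_fields else "",
            record.seconds[-1],
        )
    return model, record


def save_model(path, model: DenseUNet) -> None:
    """Checkpoint weights together with the full config (reproducibility)."""
    import json

    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    cfg = asdict(model.config)
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_model(path) -> DenseUNet:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        for key in ("crop_xy", "kernel", "venc_fraction_range"):
            cfg[key] = tuple(cfg[key])
        model = DenseUNet(CnnConfig(**cfg))
        params = model.params()
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]
    return model


def predict(model: DenseUNet, field: VelocityField) -> np.ndarray:
    """Aliased-voxel mask for a full 4D-flow field.

    Each (frame, direction) volume is normalized by the field's venc, cropped
    exactly as in training, classified, and re-embedded (crop-removed regions
    are background).  Deterministic given the weights.
    """
    crop_xy = model.config.crop_xy
    mask = np.zeros(field.shape, dtype=bool)
    venc = field.venc
    for t in range(field.n_frames):
        for d in range(3):
            vol, info = center_crop(field.volume(t, d) / venc, crop_xy)
            mask[:, :, :, t, d] = uncrop(model.predict_volume(vol), info)
    return mask
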