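"""Two-level nested U-shaped segmentation network with deep supervision.

The architecture is a stack of residual U-blocks (RSU): each encoder/decoder
stage of the outer U is itself a small U-Net whose output is added back to a
stage-input convolution.  The deepest stages swap pooling for dilated
convolutions so the receptive field keeps growing at low resolution.  Every
decoder stage (plus the deepest encoder stage) emits a side probability map;
a 1x1 fusion convolution over the concatenated side logits produces the
fused map that drives inference.

All sizes live in :class:`ModelConfig` so the same code runs the full-size
network or a small CPU-friendly preset.  Segmentation is 2D and slice-wise:
volumes are segmented axial slice by axial slice and restacked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .grids import VesselMask, VolumeGrid

__all__ = [
    "ModelConfig",
    "SegmentationOutput",
    "U2Net",
    "build_model",
    "deep_supervision_loss",
    "predict_mask",
    "predict_slices",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``rsu_depths[i]`` is the internal U depth of stage ``i``'s residual
    U-block (an RSU of depth L pools L-2 times internally).  When
    ``use_dilated_bottom_stages`` is set, the deepest stage(s) replace
    pooling with dilation (two dilated stages when there are >= 5 stages,
    one otherwise).
    """

    n_encoder_stages: int = 6
    base_channels: int = 64
    rsu_depths: tuple[int, ...] = (7, 6, 5, 4, 4, 4)
    use_dilated_bottom_stages: bool = True

    def __post_init__(self) -> None:
        if self.n_encoder_stages < 2:
            raise ValueError("n_encoder_stages must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if len(self.rsu_depths) != self.n_encoder_stages:
            raise ValueError(
                f"rsu_depths must have one entry per stage "
                f"({self.n_encoder_stages}), got {len(self.rsu_depths)}"
            )
        if any(d < 2 for d in self.rsu_depths):
            raise ValueError("every RSU depth must be >= 2")

    @classmethod
    def scaled(cls) -> "ModelConfig":
        """Small preset (4 stages, 8 base channels) that trains on one CPU."""
        return cls(n_encoder_stages=4, base_channels=8, rsu_depths=(4, 3, 2, 2))

    @property
    def n_dilated_stages(self) -> int:
        if not self.use_dilated_bottom_stages:
            return 0
        return 2 if self.n_encoder_stages >= 5 else 1

    @property
    def n_side_outputs(self) -> int:
        return self.n_encoder_stages

    def stage_out_channels(self, i: int) -> int:
        return self.base_channels * 2 ** min(i, 3)

    def stage_mid_channels(self, i: int) -> int:
        return max(self.stage_out_channels(i) // 4, 4)

    def required_divisor(self) -> int:
        """Input spatial sizes must be divisible by this power of two."""
        need = self.n_encoder_stages - 1
        for i, depth in enumerate(self.rsu_depths):
            if i >= self.n_encoder_stages - self.n_dilated_stages:
                continue  # dilated stage: no internal pooling
            need = max(need, i + depth - 2)
        return 2**need

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rsu_depths"] = list(self.rsu_depths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["rsu_depths"] = tuple(d["rsu_depths"])
        return cls(**d)


@dataclass
class SegmentationOutput:
    """Slice-batch network output: fused and per-stage probability maps,
    all at the input spatial size, values strictly in (0, 1)."""

    fused_prob: np.ndarray
    side_probs: list[np.ndarray]


class _ConvBnRelu:
    def __init__(self, cin: int, cout: int, dilation: int, rng: np.random.Generator):
        self.conv = ag.Conv2d(cin, cout, 3, dilation=dilation, rng=rng)
        self.bn = ag.BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()

    def modules(self):
        return [self.conv, self.bn]


class _RSU:
    """Residual U-block of depth L: L-2 internal poolings, dilated bottom."""

    def __init__(self, depth: int, cin: int, mid: int, cout: int, rng):
        self.depth = depth
        self.conv_in = _ConvBnRelu(cin, cout, 1, rng)
        self.enc = [_ConvBnRelu(cout, mid, 1, rng)]
        for _ in range(depth - 2):
            self.enc.append(_ConvBnRelu(mid, mid, 1, rng))
        self.bottom = _ConvBnRelu(mid, mid, 2, rng)
        self.dec = []
        for _ in range(depth - 2):
            self.dec.append(_ConvBnRelu(2 * mid, mid, 1, rng))
        self.dec.append(_ConvBnRelu(2 * mid, cout, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        hx = self.conv_in(x)
        skips = [self.enc[0](hx)]
        h = skips[0]
        for layer in self.enc[1:]:
            h = layer(ag.maxpool2x2(h))
            skips.append(h)
        h = self.bottom(h)
        for k, layer in enumerate(self.dec):
            skip = skips[-(k + 1)]
            h = layer(ag.concat_channels([h, skip]))
            if k < len(self.dec) - 1:
                h = ag.upsample_nearest(h, 2)
        return hx + h

    def parameters(self):
        ps = self.conv_in.parameters()
        for m in self.enc + [self.bottom] + self.dec:
            ps += m.parameters()
        return ps

    def modules(self):
        ms = self.conv_in.modules()
        for m in self.enc + [self.bottom] + self.dec:
            ms += m.modules()
        return ms


class _RSUDilated:
    """Pooling-free residual U-block: dilation doubles with depth."""

    def __init__(self, depth: int, cin: int, mid: int, cout: int, rng):
        self.conv_in = _ConvBnRelu(cin, cout, 1, rng)
        self.enc = [_ConvBnRelu(cout, mid, 1, rng)]
        for k in range(1, depth - 1):
            self.enc.append(_ConvBnRelu(mid, mid, 2**k, rng))
        self.bottom = _ConvBnRelu(mid, mid, 2 ** (depth - 1), rng)
        self.dec = []
        for k in range(depth - 2, 0, -1):
            self.dec.append(_ConvBnRelu(2 * mid, mid, 2**k, rng))
        self.dec.append(_ConvBnRelu(2 * mid, cout, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        hx = self.conv_in(x)
        skips = [self.enc[0](hx)]
        h = skips[0]
        for layer in self.enc[1:]:
            h = layer(h)
            skips.append(h)
        h = self.bottom(h)
        for k, layer in enumerate(self.dec):
            h = layer(ag.concat_channels([h, skips[-(k + 1)]]))
        return hx + h

    parameters = _RSU.parameters
    modules = _RSU.modules


class U2Net:
    """The nested-U segmentation model (single input channel, binary output)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        n = cfg.n_encoder_stages
        first_dilated = n - cfg.n_dilated_stages

        def make_rsu(i: int, cin: int) -> _RSU | _RSUDilated:
            cls = _RSUDilated if i >= first_dilated else _RSU
            return cls(cfg.rsu_depths[i], cin, cfg.stage_mid_channels(i), cfg.stage_out_channels(i), rng)

        self.encoders = []
        cin = 1
        for i in range(n):
            self.encoders.append(make_rsu(i, cin))
            cin = cfg.stage_out_channels(i)
        self.decoders = []
        for i in range(n - 2, -1, -1):
            dec_in = cfg.stage_out_channels(i + 1) + cfg.stage_out_channels(i)
            cls = _RSUDilated if i >= first_dilated else _RSU
            self.decoders.append(
                cls(cfg.rsu_depths[i], dec_in, cfg.stage_mid_channels(i), cfg.stage_out_channels(i), rng)
            )
        # one side head per stage: deepest encoder + each decoder
        self.side_convs = []
        self.side_convs.append(ag.Conv2d(cfg.stage_out_channels(n - 1), 1, 3, rng=rng))
        for i in range(n - 2, -1, -1):
            self.side_convs.append(ag.Conv2d(cfg.stage_out_channels(i), 1, 3, rng=rng))
        self.fuse_conv = ag.Conv2d(n, 1, 1, rng=rng)

    # -- plumbing ----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for block in self.encoders + self.decoders:
            ps += block.parameters()
        for c in self.side_convs:
            ps += c.parameters()
        ps += self.fuse_conv.parameters()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def set_training(self, training: bool) -> None:
        for block in self.encoders + self.decoders:
            for m in block.modules():
                if isinstance(m, ag.BatchNorm2d):
                    m.training = training

    def state_dict(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        for block in self.encoders + self.decoders:
            for m in block.modules():
                if isinstance(m, ag.BatchNorm2d):
                    arrays += [m.running_mean.copy(), m.running_var.copy()]
        return arrays

    def load_state_dict(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            p.data = a.astype(np.float32).copy()
        rest = iter(arrays[len(params) :])
        for block in self.encoders + self.decoders:
            for m in block.modules():
                if isinstance(m, ag.BatchNorm2d):
                    m.running_mean = next(rest).astype(np.float32).copy()
                    m.running_var = next(rest).astype(np.float32).copy()

    def save(self, path: str | Path) -> None:
        arrays = self.state_dict()
        np.savez_compressed(
            str(path),
            __meta__=np.frombuffer(
                json.dumps({"config": self.cfg.to_dict(), "seed": self.seed}).encode(),
                dtype=np.uint8,
            ),
            **{f"arr_{i}": a for i, a in enumerate(arrays)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "U2Net":
        with np.load(str(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        model = cls(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        model.load_state_dict(arrays)
        return model

    # -- forward -----------------------------------------------------------
    def _check_shape(self, h: int, w: int) -> None:
        div = self.cfg.required_divisor()
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} not divisible by {div} "
                f"(required by {self.cfg.n_encoder_stages}-stage config)"
            )

    def forward_tensors(self, x: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Returns (fused_logit, side_logits), each (n, 1, H, W)."""
        n, c, h, w = x.shape
        self._check_shape(h, w)
        t = Tensor(x)
        skips = []
        hcur = t
        for i, enc in enumerate(self.encoders):
            hcur = enc(hcur)
            skips.append(hcur)
            if i < len(self.encoders) - 1:
                hcur = ag.maxpool2x2(hcur)
        side_logits = [self.side_convs[0](skips[-1])]
        dcur = skips[-1]
        for k, dec in enumerate(self.decoders):
            skip = skips[-(k + 2)]
            dcur = dec(ag.concat_channels([ag.upsample_nearest(dcur, 2), skip]))
            side_logits.append(self.side_convs[k + 1](dcur))
        # upsample all side logits to the input size
        nstg = self.cfg.n_encoder_stages
        ups = []
        for j, s in enumerate(side_logits):
            factor = 2 ** (nstg - 1 - j) if j > 0 else 2 ** (nstg - 1)
            ups.append(ag.upsample_nearest(s, factor))
        fused = self.fuse_conv(ag.concat_channels(ups))
        return fused, ups

    def forward(self, x: np.ndarray) -> SegmentationOutput:
        fused, sides = self.forward_tensors(np.asarray(x, dtype=np.float32))
        return SegmentationOutput(
            fused_prob=ag.stable_sigmoid(fused.data),
            side_probs=[ag.stable_sigmoid(s.data) for s in sides],
        )


def build_model(cfg: ModelConfig, seed: int = 0) -> U2Net:
    """Construct a network; the parameter count depends only on ``cfg``."""
    return U2Net(cfg, seed=seed)


def deep_supervision_loss(
    output: SegmentationOutput, target: np.ndarray, eps: float = 1e-7
) -> float:
    """Sum over all maps (sides + fused) of per-pixel-mean binary
    cross-entropy against a binary target, equal weights."""
    t = np.asarray(target)
    uniq = np.unique(t)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"target must be binary, found values {uniq[:5]}")
    t = t.astype(np.float64)
    total = 0.0
    for p in [output.fused_prob, *output.side_probs]:
        pc = np.clip(np.asarray(p, dtype=np.float64), eps, 1 - eps)
        if pc.shape[-2:] != t.shape[-2:]:
            raise ValueError("probability map and target shapes differ")
        total += float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
    return total


def _pad_to_divisor(sl: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = sl.shape
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        sl = np.pad(sl, ((0, ph), (0, pw)), mode="reflect")
    return sl, (h, w)


def predict_slices(model: U2Net, slices: np.ndarray, batch: int = 16) -> np.ndarray:
    """Fused probability maps for a stack of normalized 2D slices (k, H, W)."""
    model.set_training(False)
    div = model.cfg.required_divisor()
    out = []
    padded = [_pad_to_divisor(s, div) for s in slices]
    h0, w0 = padded[0][1]
    stack = np.stack([p[0] for p in padded])[:, None, :, :].astype(np.float32)
    for i in range(0, len(stack), batch):
        fused, _ = model.forward_tensors(stack[i : i + batch])
        prob = ag.stable_sigmoid(fused.data[:, 0])
        out.append(prob)
    prob = np.concatenate(out, axis=0)
    return prob[:, :h0, :w0]


def predict_mask(
    model: U2Net, vol: VolumeGrid, prob_threshold: float = 0.5
) -> VesselMask:
    """Segment a normalized volume axial slice by slice.

    Slices whose in-plane size is not divisible by the config's power of two
    are reflect-padded for inference and cropped back.  A voxel is vessel iff
    its fused probability is strictly greater than ``prob_threshold``.
    """
    if vol.intensity_kind != "normalized":
        raise ValueError("predict_mask expects a window-normalized volume")
    slices = np.moveaxis(np.asarray(vol.data, dtype=np.float32), 2, 0)
    prob = predict_slices(model, slices)
    mask3d = np.moveaxis(prob > prob_threshold, 0, 2)
    return VesselMask(mask3d, vol.spacing_mm, vol.origin_mm)
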