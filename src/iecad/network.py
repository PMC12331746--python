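"""The multi-task video network.

A 3-D DeepLabV3+-style encoder (3D-ResNet50 backbone, spatial-only
downsampling so the 20-frame axis survives every stage, atrous spatial
pyramid head) feeds six decoders:

* view classification from the downsampled low-level features;
* cardiac segmentation from upsampled backbone features concatenated with
  the pre-downsampling low-level features;
* GLS and LVEF curve regression through bidirectional LSTMs over the pooled
  20-step sequence;
* GWE scalar regression from the globally pooled features;
* Gensini-score and CAD heads from a 1,072-channel fusion of backbone,
  task-sparse and low-level features, through temporal self-attention.

Task-sparse features come from low-rank convolution blocks: the 3x3x3 stage
is factorised through a rank-r channel bottleneck, which extracts sparse
complementary features for multi-task fusion at a fraction of the dense
parameter count.

All channel widths scale with ``ModelConfig.width`` (1.0 reproduces the
reference dimensions); regression heads emit scaled units (strain/EF/GWE as
fractions, Gensini per 100 points) which `NetworkOutput` converts back.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    BatchNorm3d, BiLSTM, Conv3d, Linear, Module, MultiheadAttention,
    Sequential, ReLU, Tensor, concat, no_grad, upsample_nearest,
)
from .preprocess import N_FRAMES, VIEWS

__all__ = ["ModelConfig", "FeatureBundle", "NetworkOutput", "IECadNetwork",
           "GENSINI_SCALE", "PERCENT_SCALE"]

GENSINI_SCALE = 100.0   # network predicts Gensini per 100 points
PERCENT_SCALE = 100.0   # network predicts strain/EF/GWE as fractions


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the reference dimensions; ``width`` scales every
    channel count and ``frame_size`` the input raster for reduced-scale runs.
    """

    frame_size: int = 256
    width: float = 1.0
    rank: int = 4
    n_heads: int = 8
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)
    seed: int = 0

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("aspp_rates", "stage_blocks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def ch(self, base: int) -> int:
        """Scaled channel count (multiple of n_heads for attention widths)."""
        return max(1, int(round(base * self.width)))

    def att(self, base: int) -> int:
        c = self.ch(base)
        return max(self.n_heads, (c // self.n_heads) * self.n_heads)


@dataclass
class FeatureBundle:
    """Intermediate features shared by the decoders (N leading axis)."""

    low_level_pre: Tensor    # 48 x 20 x S/4 x S/4, before downsampling
    low_level: Tensor        # 48 x 20 x S/16 x S/16
    deep: Tensor             # 256 x 20 x S/16 x S/16 (pyramid output)
    backbone: Tensor         # 256 x 20 x S/16 x S/16 (conv block output)
    sparse_gls: Tensor       # 256 x 20 x S/16 x S/16
    sparse_lvef: Tensor
    sparse_gwe: Tensor
    sparse_gensini: Tensor


@dataclass
class NetworkOutput:
    """Per-clip head outputs in clinical units."""

    view_logits: np.ndarray      # (3,)
    view_probs: np.ndarray       # (3,), sums to 1
    seg_logits: np.ndarray       # (3, 20, S, S)
    seg_probs: np.ndarray        # (3, 20, S, S), voxel softmax
    gls_curve: np.ndarray        # (20,), %
    lvef_curve: np.ndarray       # (20,), %
    gwe: float                   # %
    gensini: float               # points
    cad_logits: np.ndarray       # (2,)
    cad_probs: np.ndarray        # (2,), sums to 1

    @property
    def view(self) -> str:
        return VIEWS[int(np.argmax(self.view_probs))]

    @property
    def significant(self) -> bool:
        return bool(np.argmax(self.cad_probs) == 1)


def _bn_relu_conv(cfg_rng, n_in, n_out, kernel, stride=1, padding=0,
                  dilation=1):
    return Sequential(
        Conv3d(n_in, n_out, kernel, cfg_rng, stride=stride, padding=padding,
               dilation=dilation, bias=False),
        BatchNorm3d(n_out), ReLU())


class Bottleneck(Module):
    """ResNet50-style bottleneck with 3x3x3 middle conv (spatial stride only)."""

    def __init__(self, rng, n_in, mid, n_out, stride=1, dilation=1):
        super().__init__()
        self.conv1 = _bn_relu_conv(rng, n_in, mid, 1)
        self.conv2 = _bn_relu_conv(rng, mid, mid, 3, stride=(1, stride, stride),
                                   padding=dilation, dilation=dilation)
        self.conv3 = Sequential(
            Conv3d(mid, n_out, 1, rng, bias=False), BatchNorm3d(n_out))
        self.down = None
        if stride != 1 or n_in != n_out:
            self.down = Sequential(
                Conv3d(n_in, n_out, 1, rng, stride=(1, stride, stride),
                       bias=False), BatchNorm3d(n_out))

    def forward(self, x):
        y = self.conv3(self.conv2(self.conv1(x)))
        skip = self.down(x) if self.down is not None else x
        return (y + skip).relu()


class ASPP(Module):
    """Atrous spatial pyramid: 1x1, three dilated 3x3x3, and image pooling."""

    def __init__(self, rng, n_in, n_out, rates):
        super().__init__()
        self.branch1 = _bn_relu_conv(rng, n_in, n_out, 1)
        self.dilated = [
            _bn_relu_conv(rng, n_in, n_out, 3, padding=(1, r, r),
                          dilation=(1, r, r)) for r in rates]
        self.pool_proj = _bn_relu_conv(rng, n_in, n_out, 1)
        self.project = _bn_relu_conv(rng, n_out * (len(rates) + 2), n_out, 1)

    def forward(self, x):
        n, c, t, h, w = x.shape
        feats = [self.branch1(x)] + [d(x) for d in self.dilated]
        pooled = x.mean(axis=(3, 4), keepdims=True)
        pooled = self.pool_proj(pooled)
        feats.append(upsample_nearest(pooled, (1, h, w)))
        return self.project(concat(feats, axis=1))


class LowRankConv3d(Module):
    """Conv3d factorised through a rank-r channel bottleneck.

    Full k x k x k convolution down to r channels, then pointwise r -> out;
    parameter count ~ r (k^3 c_in + c_out) instead of k^3 c_in c_out.
    """

    def __init__(self, rng, n_in, n_out, kernel, rank, padding=0):
        super().__init__()
        self.reduce = Conv3d(n_in, rank, kernel, rng, padding=padding,
                             bias=False)
        self.expand = Conv3d(rank, n_out, 1, rng, bias=False)

    def forward(self, x):
        return self.expand(self.reduce(x))


class LowRankBlock(Module):
    """Two low-rank stages (3x3x3 then 1x1x1), each with BN + ReLU."""

    def __init__(self, rng, n_ch, rank):
        super().__init__()
        self.stage1 = Sequential(
            LowRankConv3d(rng, n_ch, n_ch, 3, rank, padding=1),
            BatchNorm3d(n_ch), ReLU())
        self.stage2 = Sequential(
            LowRankConv3d(rng, n_ch, n_ch, 1, rank),
            BatchNorm3d(n_ch), ReLU())

    def forward(self, x):
        return self.stage2(self.stage1(x))


class Encoder(Module):
    """3D-ResNet50 trunk with DeepLab output stride 16 and a pyramid head."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        ch = cfg.ch
        self.stem = _bn_relu_conv(rng, 1, ch(64), (3, 7, 7),
                                  stride=(1, 2, 2), padding=(1, 3, 3))
        widths = [(ch(64), ch(256)), (ch(128), ch(512)),
                  (ch(256), ch(1024)), (ch(512), ch(2048))]
        strides = (2, 2, 2, 1)       # stage 4 is dilated, not strided
        dilations = (1, 1, 1, 2)
        stages = []
        n_in = ch(64)
        for (mid, out), n_blocks, stride, dil in zip(
                widths, cfg.stage_blocks, strides, dilations):
            blocks = [Bottleneck(rng, n_in, mid, out, stride=stride,
                                 dilation=dil)]
            blocks += [Bottleneck(rng, out, mid, out, dilation=dil)
                       for _ in range(n_blocks - 1)]
            stages.append(Sequential(*blocks))
            n_in = out
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.low_proj = _bn_relu_conv(rng, ch(256), ch(48), 1)
        self.low_down = Sequential(
            _bn_relu_conv(rng, ch(48), ch(48), 3, stride=(1, 2, 2), padding=1),
            _bn_relu_conv(rng, ch(48), ch(48), 3, stride=(1, 2, 2), padding=1))
        # dilation rates scale with the raster so the pyramid's receptive
        # fields stay proportional to the feature map at reduced frame sizes
        rates = tuple(max(1, round(r * cfg.frame_size / 256))
                      for r in cfg.aspp_rates)
        self.aspp = ASPP(rng, ch(2048), ch(256), rates)

    def forward(self, x):
        x = self.stem(x)
        s1 = self.stage1(x)            # S/4
        low_pre = self.low_proj(s1)    # 48 ch at S/4
        low = self.low_down(low_pre)   # 48 ch at S/16
        deep = self.aspp(self.stage4(self.stage3(self.stage2(s1))))
        return low_pre, low, deep


class IECadNetwork(Module):
    """Shared encoder + six task decoders (view / seg / GLS / LVEF / GWE /
    Gensini + CAD)."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.ch
        self.encoder = Encoder(cfg, rng)
        # Conv Block: deep semantic -> backbone features
        self.conv_block = Sequential(
            _bn_relu_conv(rng, ch(256), ch(256), 3, padding=1),
            _bn_relu_conv(rng, ch(256), ch(256), 1))
        self.lowrank_gls = LowRankBlock(rng, ch(256), cfg.rank)
        self.lowrank_lvef = LowRankBlock(rng, ch(256), cfg.rank)
        self.lowrank_gwe = LowRankBlock(rng, ch(256), cfg.rank)
        self.lowrank_gensini = LowRankBlock(rng, ch(256), cfg.rank)
        # view head: pool + FC(48, 3)
        self.view_fc = Linear(ch(48), len(VIEWS), rng)
        # segmentation head over 304 = 256 + 48 channels at S/4
        self.seg_conv = _bn_relu_conv(rng, ch(256) + ch(48), ch(256), 3,
                                      padding=1)
        self.seg_out = Conv3d(ch(256), 3, 1, rng)
        # curve heads: Bi-LSTM(256 -> 2x256) + per-step FC(512, 1)
        self.gls_lstm = BiLSTM(ch(256), ch(256), rng)
        self.gls_fc = Linear(2 * ch(256), 1, rng)
        self.lvef_lstm = BiLSTM(ch(256), ch(256), rng)
        self.lvef_fc = Linear(2 * ch(256), 1, rng)
        self.gwe_fc = Linear(ch(256), 1, rng)
        # fusion heads: conv(1072 -> 512) + temporal attention + MLP
        fused = 4 * ch(256) + ch(48)
        att = cfg.att(512)
        self.gensini_conv = _bn_relu_conv(rng, fused, att, 3, padding=1)
        self.gensini_att = MultiheadAttention(att, cfg.n_heads, rng)
        self.gensini_fc1 = Linear(att, ch(256), rng)
        self.gensini_fc2 = Linear(ch(256), 1, rng)
        self.cad_conv = _bn_relu_conv(rng, fused, att, 3, padding=1)
        self.cad_att = MultiheadAttention(att, cfg.n_heads, rng)
        self.cad_fc1 = Linear(att, ch(256), rng)
        self.cad_fc2 = Linear(ch(256), 2, rng)

    # -- forward pieces -----------------------------------------------------

    def encode(self, x: Tensor) -> FeatureBundle:
        """x: (N, 1, 20, S, S) in [0, 1]."""
        n, c, t, h, w = x.shape
        s = self.config.frame_size
        if (c, t, h, w) != (1, N_FRAMES, s, s):
            raise ValueError(
                f"expected input (N, 1, {N_FRAMES}, {s}, {s}), got {x.shape}")
        low_pre, low, deep = self.encoder(x)
        backbone = self.conv_block(deep)
        return FeatureBundle(
            low_level_pre=low_pre, low_level=low, deep=deep, backbone=backbone,
            sparse_gls=self.lowrank_gls(deep),
            sparse_lvef=self.lowrank_lvef(deep),
            sparse_gwe=self.lowrank_gwe(deep),
            sparse_gensini=self.lowrank_gensini(deep))

    def fuse(self, fb: FeatureBundle) -> Tensor:
        """1,072-channel fusion: (backbone + Gensini-sparse) ++ GLS ++ LVEF
        ++ GWE ++ low-level."""
        return concat([fb.backbone + fb.sparse_gensini, fb.sparse_gls,
                       fb.sparse_lvef, fb.sparse_gwe, fb.low_level], axis=1)

    def decode_all(self, fb: FeatureBundle,
                   tasks: tuple[str, ...] | None = None) -> dict[str, Tensor]:
        """Raw head outputs (scaled units) as graph tensors.

        ``tasks`` restricts computation to the named heads (training phases
        pay only for the heads they optimise); None computes all six.
        """
        active = set(tasks) if tasks is not None else {
            "view", "seg", "gls", "lvef", "gwe", "gensini", "cad"}
        out: dict[str, Tensor] = {}
        if "view" in active:
            out["view_logits"] = self.view_fc(
                fb.low_level.mean(axis=(2, 3, 4)))
        if "seg" in active:
            # upsample backbone S/16 -> S/4, join low-level, conv, -> S
            up = upsample_nearest(fb.backbone, (1, 4, 4))
            seg = self.seg_out(
                self.seg_conv(concat([up, fb.low_level_pre], axis=1)))
            out["seg_logits"] = upsample_nearest(seg, (1, 4, 4))
        for name, lstm, fc, sparse in (
                ("gls", self.gls_lstm, self.gls_fc, fb.sparse_gls),
                ("lvef", self.lvef_lstm, self.lvef_fc, fb.sparse_lvef)):
            if name not in active:
                continue
            feats = (fb.backbone + sparse).mean(axis=(3, 4))  # (N, C, T)
            seq = feats.transpose(0, 2, 1)                    # (N, T, C)
            out[name] = fc(lstm(seq)).reshape(seq.shape[0], N_FRAMES)
        if "gwe" in active:
            out["gwe"] = self.gwe_fc(
                (fb.backbone + fb.sparse_gwe).mean(axis=(2, 3, 4))).reshape(-1)
        if active & {"gensini", "cad"}:
            fused = self.fuse(fb)
            for name, conv, att, fc1, fc2, act in (
                    ("gensini", self.gensini_conv, self.gensini_att,
                     self.gensini_fc1, self.gensini_fc2, "gelu"),
                    ("cad_logits", self.cad_conv, self.cad_att,
                     self.cad_fc1, self.cad_fc2, "relu")):
                if name.replace("_logits", "") not in active:
                    continue
                z = conv(fused).mean(axis=(3, 4)).transpose(0, 2, 1)
                z = att(z).mean(axis=1)                      # (N, D)
                z = fc1(z)
                z = z.gelu() if act == "gelu" else z.relu()
                y = fc2(z)
                out[name] = y.reshape(-1) if name == "gensini" else y
        return out

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        return self.decode_all(self.encode(x))

    # -- inference ----------------------------------------------------------

    def predict(self, block: np.ndarray) -> NetworkOutput:
        """Evaluation-mode forward of one (20, S, S) clip, clinical units."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                x = Tensor(np.asarray(block, dtype=np.float32)[None, None])
                out = self.forward(x)
        finally:
            self.train(was_training)
        view_logits = out["view_logits"].data[0]
        seg_logits = out["seg_logits"].data[0]
        cad_logits = out["cad_logits"].data[0]
        return NetworkOutput(
            view_logits=view_logits, view_probs=_softmax(view_logits),
            seg_logits=seg_logits, seg_probs=_softmax(seg_logits, axis=0),
            gls_curve=out["gls"].data[0] * PERCENT_SCALE,
            lvef_curve=out["lvef"].data[0] * PERCENT_SCALE,
            gwe=float(out["gwe"].data[0]) * PERCENT_SCALE,
            gensini=float(out["gensini"].data[0]) * GENSINI_SCALE,
            cad_logits=cad_logits, cad_probs=_softmax(cad_logits))

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        import json
        state = {k: v for k, v in self.state_dict().items()}
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez_compressed(path, **state)

    @classmethod
    def load(cls, path) -> "IECadNetwork":
        import json
        with np.load(path) as data:
            cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
            for key in ("aspp_rates", "stage_blocks"):
                cfg_raw[key] = tuple(cfg_raw[key])
            net = cls(ModelConfig(**cfg_raw))
            net.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"})
        return net


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)
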