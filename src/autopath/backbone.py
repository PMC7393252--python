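"""Gated 3D residual segmentation network (DeepLab-V3 style).

The encoder is a 3D ResNet whose residual blocks are individually gateable:
a binary action vector decides, per block, whether the residual branch runs
(keep) or only the shortcut branch is evaluated (drop). Convolution strides
along the slice (z) axis are forced to 1 so volumes are never downsampled
along z. An ASPP context module and a small convolutional decoder map encoder
features back to per-voxel class probabilities at input resolution.

Gateable set: exactly the residual blocks. The stem, ASPP and decoder always
execute. Dropping a block skips its residual branch entirely (its batch-norm
statistics are untouched), emitting the shortcut output: the identity for
same-shape blocks, or the strided 1x1x1 projection where the block changes
resolution or width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .nn.losses import softmax

BASIC_VARIANT = "resnet18-style"
BOTTLENECK_VARIANT = "resnet50-style"
TINY_PREFIX = "tiny-"

#: residual blocks per stage, as in the 18- and 50-layer ResNet encoders
STAGE_BLOCKS = {BASIC_VARIANT: (2, 2, 2, 2), BOTTLENECK_VARIANT: (3, 4, 6, 3)}
BOTTLENECK_EXPANSION = 4


@dataclass
class BackboneConfig:
    """Configuration of the gated segmentation backbone.

    ``depth_variant`` is one of ``resnet18-style`` (8 basic blocks),
    ``resnet50-style`` (16 bottleneck blocks) or ``tiny-k`` (k basic blocks,
    for small-scale experiments). Stage widths default to a compact scale
    suitable for CPU work; they are free parameters, the gateable block count
    is what each variant fixes.
    """

    depth_variant: str = BASIC_VARIANT
    in_channels: int = 1
    num_classes: int = 2
    stage_widths: tuple[int, ...] | None = None
    z_stride_policy: bool = True
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    aspp_channels: int = 32
    decoder_channels: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.num_classes != 2:
            raise ValueError("binary segmentation only: num_classes must be 2")
        if self.depth_variant in STAGE_BLOCKS:
            default_widths = (16, 32, 64, 128)
            if self.stage_widths is None:
                self.stage_widths = default_widths
            if len(self.stage_widths) != 4:
                raise ValueError(
                    f"{self.depth_variant} needs 4 stage widths, got {self.stage_widths}"
                )
        elif self.depth_variant.startswith(TINY_PREFIX):
            k = self.tiny_k  # validates
            if self.stage_widths is None:
                self.stage_widths = (16,)
            if len(self.stage_widths) != 1:
                raise ValueError("tiny variants use a single stage width")
            if k < 1:
                raise ValueError("tiny-k needs k >= 1")
        else:
            raise ValueError(f"unknown depth_variant {self.depth_variant!r}")

    @property
    def tiny_k(self) -> int:
        try:
            return int(self.depth_variant[len(TINY_PREFIX):])
        except ValueError as exc:
            raise ValueError(f"unknown depth_variant {self.depth_variant!r}") from exc

    @property
    def n_blocks(self) -> int:
        if self.depth_variant in STAGE_BLOCKS:
            return sum(STAGE_BLOCKS[self.depth_variant])
        return self.tiny_k

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["stage_widths"] = list(self.stage_widths)
        d["aspp_rates"] = list(self.aspp_rates)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "BackboneConfig":
        d = json.loads(s)
        d["stage_widths"] = tuple(d["stage_widths"])
        d["aspp_rates"] = tuple(d["aspp_rates"])
        return cls(**d)


def _stride3(s: int, z_policy: bool) -> tuple[int, int, int]:
    return (1, s, s) if z_policy else (s, s, s)


def _dil3(r: int, z_policy: bool) -> tuple[int, int, int]:
    return (1, r, r) if z_policy else (r, r, r)


class BasicBlock(nn.Module):
    """Two 3x3x3 convs with batch norm; gateable residual branch."""

    def __init__(self, cin, cout, stride, dilation, z_policy, rng):
        super().__init__()
        s = _stride3(stride, z_policy)
        d = _dil3(dilation, z_policy)
        self.conv1 = nn.Conv3d(cin, cout, 3, stride=s, dilation=d, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm3d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(cout, cout, 3, stride=1, dilation=d, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm3d(cout)
        self.has_projection = cin != cout or stride != 1
        if self.has_projection:
            self.proj = nn.Conv3d(cin, cout, 1, stride=s, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm3d(cout)
        self.out_relu = nn.ReLU()
        self._kept = True

    # residual-branch modules, in forward order (used for MACs and zeroing)
    def residual_modules(self):
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]

    def shortcut(self, x):
        if self.has_projection:
            return self.proj_bn.forward(self.proj.forward(x))
        return x

    def residual(self, x):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        return self.bn2.forward(self.conv2.forward(h))

    def forward(self, x, keep: bool = True):
        self._kept = bool(keep)
        s = self.shortcut(x)
        out = s + self.residual(x) if keep else s
        return self.out_relu.forward(out)

    def backward(self, gy):
        g = self.out_relu.backward(gy)
        if self.has_projection:
            gx = self.proj.backward(self.proj_bn.backward(g))
        else:
            gx = g.copy()
        if self._kept:
            gr = self.conv1.backward(
                self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
            )
            gx = gx + gr
        return gx

    def macs(self, in_spatial, keep: bool) -> int:
        total = 0
        if self.has_projection:
            total += self.proj.macs(in_spatial)
        if keep:
            total += self.conv1.macs(in_spatial)
            total += self.conv2.macs(self.conv1.out_shape(in_spatial))
        return total

    def out_spatial(self, in_spatial):
        return self.conv1.out_shape(in_spatial)


class Bottleneck(nn.Module):
    """1x1x1 - 3x3x3 - 1x1x1 bottleneck with expansion 4; gateable."""

    def __init__(self, cin, width, stride, dilation, z_policy, rng):
        super().__init__()
        cout = width * BOTTLENECK_EXPANSION
        s = _stride3(stride, z_policy)
        d = _dil3(dilation, z_policy)
        self.conv1 = nn.Conv3d(cin, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm3d(width)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(width, width, 3, stride=s, dilation=d, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm3d(width)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv3d(width, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm3d(cout)
        self.has_projection = cin != cout or stride != 1
        if self.has_projection:
            self.proj = nn.Conv3d(cin, cout, 1, stride=s, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm3d(cout)
        self.out_relu = nn.ReLU()
        self.cout = cout
        self._kept = True

    def residual_modules(self):
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2,
                self.conv3, self.bn3]

    def shortcut(self, x):
        if self.has_projection:
            return self.proj_bn.forward(self.proj.forward(x))
        return x

    def residual(self, x):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h)))
        return self.bn3.forward(self.conv3.forward(h))

    def forward(self, x, keep: bool = True):
        self._kept = bool(keep)
        s = self.shortcut(x)
        out = s + self.residual(x) if keep else s
        return self.out_relu.forward(out)

    def backward(self, gy):
        g = self.out_relu.backward(gy)
        if self.has_projection:
            gx = self.proj.backward(self.proj_bn.backward(g))
        else:
            gx = g.copy()
        if self._kept:
            gr = self.bn3.backward(g)
            gr = self.conv3.backward(gr)
            gr = self.relu2.backward(gr)
            gr = self.bn2.backward(gr)
            gr = self.conv2.backward(gr)
            gr = self.relu1.backward(gr)
            gr = self.bn1.backward(gr)
            gr = self.conv1.backward(gr)
            gx = gx + gr
        return gx

    def macs(self, in_spatial, keep: bool) -> int:
        total = 0
        if self.has_projection:
            total += self.proj.macs(in_spatial)
        if keep:
            total += self.conv1.macs(in_spatial)
            mid = self.conv2.out_shape(in_spatial)
            total += self.conv2.macs(in_spatial)
            total += self.conv3.macs(mid)
        return total

    def out_spatial(self, in_spatial):
        return self.conv2.out_shape(in_spatial)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: 1x1 conv, dilated 3x3x3 convs, image pooling."""

    def __init__(self, cin, channels, rates, z_policy, rng):
        super().__init__()
        self.branch0 = nn.Sequential(
            nn.Conv3d(cin, channels, 1, bias=False, rng=rng), nn.BatchNorm3d(channels), nn.ReLU()
        )
        self.atrous = [
            nn.Sequential(
                nn.Conv3d(cin, channels, 3, dilation=_dil3(r, z_policy), bias=False, rng=rng),
                nn.BatchNorm3d(channels),
                nn.ReLU(),
            )
            for r in rates
        ]
        self.pool = nn.GlobalAvgPool3d()
        self.pool_fc = nn.Linear(cin, channels, rng=rng)
        self.pool_relu = nn.ReLU()
        n_branches = 2 + len(rates)
        self.project = nn.Sequential(
            nn.Conv3d(n_branches * channels, channels, 1, bias=False, rng=rng),
            nn.BatchNorm3d(channels),
            nn.ReLU(),
        )
        self.channels = channels
        self._cache = None

    def forward(self, x):
        b, c, d, h, w = x.shape
        feats = [self.branch0.forward(x)]
        feats += [br.forward(x) for br in self.atrous]
        pooled = self.pool_relu.forward(self.pool_fc.forward(self.pool.forward(x)))
        pooled_map = np.broadcast_to(
            pooled.reshape(b, self.channels, 1, 1, 1), (b, self.channels, d, h, w)
        ).astype(np.float32)
        feats.append(pooled_map)
        cat = np.concatenate(feats, axis=1)
        self._cache = (x.shape,)
        return self.project.forward(cat)

    def backward(self, gy):
        (x_shape,) = self._cache
        gcat = self.project.backward(gy)
        ch = self.channels
        gx = self.branch0.backward(gcat[:, :ch])
        for i, br in enumerate(self.atrous):
            gx = gx + br.backward(gcat[:, (i + 1) * ch : (i + 2) * ch])
        gpool_map = gcat[:, -ch:]
        gpooled = gpool_map.sum(axis=(2, 3, 4))
        gx = gx + self.pool.backward(self.pool_fc.backward(self.pool_relu.backward(gpooled)))
        self._cache = None
        return gx

    def macs(self, in_spatial) -> int:
        total = self.branch0.modules_list[0].macs(in_spatial)
        for br in self.atrous:
            total += br.modules_list[0].macs(in_spatial)
        total += self.project.modules_list[0].macs(in_spatial)
        return total


class GatedBackbone(nn.Module):
    """Stem -> gateable residual blocks -> ASPP -> convolutional decoder."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        zp = config.z_stride_policy

        blocks: list[nn.Module] = []
        if config.depth_variant in STAGE_BLOCKS:
            widths = config.stage_widths
            stem_ch = widths[0]
            # in-plane output stride 8: stem /2, stage2 /2, stage3 /2,
            # stage4 dilated instead of strided (DeepLab-V3 convention)
            stage_strides = (1, 2, 2, 1)
            stage_dils = (1, 1, 1, 2)
            basic = config.depth_variant == BASIC_VARIANT
            cin = stem_ch
            for stage, n_blk in enumerate(STAGE_BLOCKS[config.depth_variant]):
                for b in range(n_blk):
                    stride = stage_strides[stage] if b == 0 else 1
                    dil = stage_dils[stage]
                    if basic:
                        blk = BasicBlock(cin, widths[stage], stride, dil, zp, rng)
                        cin = widths[stage]
                    else:
                        blk = Bottleneck(cin, widths[stage], stride, dil, zp, rng)
                        cin = blk.cout
                    blocks.append(blk)
            feat_ch = cin
        else:
            k = config.tiny_k
            width = config.stage_widths[0]
            stem_ch = max(width // 2, 4)
            cin = stem_ch
            for b in range(k):
                stride = 2 if b < 2 else 1
                blk = BasicBlock(cin, width, stride, 1, zp, rng)
                cin = width
                blocks.append(blk)
            feat_ch = width

        self.stem_conv = nn.Conv3d(
            config.in_channels, stem_ch, 3, stride=_stride3(2, zp), bias=False, rng=rng
        )
        self.stem_bn = nn.BatchNorm3d(stem_ch)
        self.stem_relu = nn.ReLU()
        self.blocks = blocks
        self.aspp = ASPP(feat_ch, config.aspp_channels, config.aspp_rates, zp, rng)

        # decoder: upsample x2, two 3x3x3 convs, 1x1x1 classifier, upsample to input res
        stride_total = self._encoder_inplane_stride()
        up1 = min(2, stride_total)
        self.up1 = nn.Upsample3d((1, up1, up1))
        dec = config.decoder_channels
        self.dec_conv1 = nn.Conv3d(config.aspp_channels, dec, 3, bias=False, rng=rng)
        self.dec_bn1 = nn.BatchNorm3d(dec)
        self.dec_relu1 = nn.ReLU()
        self.dec_conv2 = nn.Conv3d(dec, dec, 3, bias=False, rng=rng)
        self.dec_bn2 = nn.BatchNorm3d(dec)
        self.dec_relu2 = nn.ReLU()
        self.classifier = nn.Conv3d(dec, config.num_classes, 1, rng=rng)
        up2 = stride_total // up1
        self.up2 = nn.Upsample3d((1, up2, up2)) if up2 > 1 else None
        self._pad_hw = None

    # ------------------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def _encoder_inplane_stride(self) -> int:
        s = 2  # stem
        for blk in self.blocks:
            s *= blk.conv1.stride[1] if isinstance(blk, BasicBlock) else blk.conv2.stride[1]
        return s

    @property
    def inplane_stride(self) -> int:
        return self._encoder_inplane_stride()

    def _check_actions(self, actions) -> np.ndarray:
        if actions is None:
            return np.ones(self.n_blocks, dtype=np.int64)
        a = np.asarray(actions)
        if a.shape != (self.n_blocks,):
            raise ValueError(f"action vector length {a.shape} != N={self.n_blocks}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("actions must be binary")
        return a.astype(np.int64)

    def forward_logits(self, x: np.ndarray, actions=None) -> np.ndarray:
        """Logits (B, num_classes, D, H, W) for a batch (B, C, D, H, W).

        In-plane dims are zero-padded to the next multiple of the network's
        in-plane stride and the output is cropped back.
        """
        a = self._check_actions(actions)
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError(f"expected (B, C, D, H, W), got shape {x.shape}")
        if not np.isfinite(x).all():
            raise ValueError("input volume contains non-finite values")
        stride = self.inplane_stride
        b, c, d, h, w = x.shape
        ph = (-h) % stride
        pw = (-w) % stride
        self._pad_hw = (h, w, ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, 0), (0, ph), (0, pw)))

        h_feat = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x)))
        for blk, keep in zip(self.blocks, a):
            h_feat = blk.forward(h_feat, keep=bool(keep))
        h_feat = self.aspp.forward(h_feat)
        h_feat = self.up1.forward(h_feat)
        h_feat = self.dec_relu1.forward(self.dec_bn1.forward(self.dec_conv1.forward(h_feat)))
        h_feat = self.dec_relu2.forward(self.dec_bn2.forward(self.dec_conv2.forward(h_feat)))
        logits = self.classifier.forward(h_feat)
        if self.up2 is not None:
            logits = self.up2.forward(logits)
        if ph or pw:
            logits = np.ascontiguousarray(logits[:, :, :, :h, :w])
        return logits

    def backward(self, glogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        h, w, ph, pw = self._pad_hw
        if ph or pw:
            glogits = np.pad(glogits, ((0, 0), (0, 0), (0, 0), (0, ph), (0, pw)))
        g = self.up2.backward(glogits) if self.up2 is not None else glogits
        g = self.classifier.backward(g)
        g = self.dec_conv2.backward(self.dec_bn2.backward(self.dec_relu2.backward(g)))
        g = self.dec_conv1.backward(self.dec_bn1.backward(self.dec_relu1.backward(g)))
        g = self.up1.backward(g)
        g = self.aspp.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    def forward_probs(self, x: np.ndarray, actions=None) -> np.ndarray:
        return softmax(self.forward_logits(x, actions), axis=1)

    def count_macs(self, spatial: tuple[int, int, int], actions=None) -> int:
        """Analytic multiply-accumulate count for one input volume."""
        a = self._check_actions(actions)
        stride = self.inplane_stride
        d, h, w = spatial
        h += (-h) % stride
        w += (-w) % stride
        total = self.stem_conv.macs((d, h, w))
        sp = self.stem_conv.out_shape((d, h, w))
        for blk, keep in zip(self.blocks, a):
            total += blk.macs(sp, keep=bool(keep))
            sp = blk.out_spatial(sp)
        total += self.aspp.macs(sp)
        sp = (sp[0], sp[1] * self.up1.factor[1], sp[2] * self.up1.factor[2])
        total += self.dec_conv1.macs(sp)
        total += self.dec_conv2.macs(sp)
        total += self.classifier.macs(sp)
        return int(total)


def build_backbone(config: BackboneConfig) -> GatedBackbone:
    """Construct the gated segmentation network described by ``config``."""
    net = GatedBackbone(config)
    expected = config.n_blocks
    assert net.n_blocks == expected, "block count inconsistent with variant"
    return net


def forward_with_actions(net: GatedBackbone, x: np.ndarray, actions) -> np.ndarray:
    """Per-voxel class probabilities (num_classes, D, H, W) for one volume."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected a (D, H, W) volume, got shape {x.shape}")
    probs = net.forward_probs(x[None, None], actions)
    return probs[0]


def predict_mask(net: GatedBackbone, x: np.ndarray, actions=None) -> np.ndarray:
    """Binary foreground mask via argmax; ties go to background."""
    probs = forward_with_actions(net, x, actions)
    return (probs[1] > probs[0]).astype(np.uint8)


def zero_residual_branch(block, freeze: bool = True) -> None:
    """Make a block's residual branch an exact no-op (outputs zero).

    The final batch norm's scale and shift are zeroed, so the branch output is
    identically zero in both training and eval mode. With ``freeze`` the whole
    branch is excluded from optimization, keeping the no-op property under
    further training.
    """
    final_bn = block.residual_modules()[-1]
    final_bn.gamma.data[...] = 0.0
    final_bn.beta.data[...] = 0.0
    if freeze:
        for mod in block.residual_modules():
            for p in mod.parameters():
                p.trainable = False


def save_backbone(net: GatedBackbone, path) -> None:
    state = net.state_dict()
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.array(net.config.to_json()), **state)


def load_backbone(path) -> GatedBackbone:
    with np.load(path, allow_pickle=False) as archive:
        config = BackboneConfig.from_json(str(archive["__config__"]))
        net = build_backbone(config)
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    net.load_state_dict(state)
    if net.n_blocks != config.n_blocks:
        raise ValueError("checkpoint block count does not match its config")
    return net
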