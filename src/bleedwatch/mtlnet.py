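"""Multi-task U-Net: shared encoder, segmentation decoder, classification head.

The network jointly learns two tasks from one shared contracting path:

* semantic segmentation of surgical instruments (U-Net expansive path with
  skip connections, 1-channel sigmoid output the size of the input), and
* per-frame bleeding event detection (a 2-way softmax head fed by global
  average pooling of the bottleneck feature map).

Training the two branches against a summed loss lets the instrument-
segmentation signal regularise the shared features used for bleeding
recognition. The implementation is pure NumPy (see ``_nn``): explicit
forward/backward wiring, float32 NHWC tensors, He initialisation from a
single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Conv2d, ConvTranspose2x2, Dense, MaxPool2x2

__all__ = ["NetConfig", "MTLPrediction", "MTLUNet", "build_network"]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of 2x down-sampling levels; channel width at
    level ``i`` is ``base_channels * channel_multiplier**i`` and the
    bottleneck sits one multiplier step deeper. The default (64 px, depth 3,
    base 16) is sized for CPU training; the canonical 572-px/depth-4/base-64
    U-Net is expressible but not the default.
    """

    input_size: int = 64
    depth: int = 3
    base_channels: int = 16
    channel_multiplier: int = 2
    in_channels: int = 3
    seg_classes: int = 1
    cls_classes: int = 2
    cls_hidden: int = 64

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")

    def level_channels(self, i: int) -> int:
        return self.base_channels * self.channel_multiplier**i


@dataclass
class MTLPrediction:
    """Per-frame output: instrument probability map + 2-class blood vector."""

    seg_prob: np.ndarray  # H x W in [0, 1]
    cls_prob: np.ndarray  # (p_no_blood, p_blood), sums to 1

    def __post_init__(self) -> None:
        if not np.isclose(self.cls_prob.sum(), 1.0, atol=1e-6):
            raise ValueError("cls_prob must sum to 1")


class MTLUNet:
    """Shared-encoder two-branch network; see module docstring."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0E7]))
        cfg = config

        self.enc_convs: list[tuple[Conv2d, Conv2d]] = []
        self.pools: list[MaxPool2x2] = []
        c_prev = cfg.in_channels
        for i in range(cfg.depth):
            c = cfg.level_channels(i)
            self.enc_convs.append((Conv2d(c_prev, c, 3, rng), Conv2d(c, c, 3, rng)))
            self.pools.append(MaxPool2x2())
            c_prev = c

        c_bot = cfg.level_channels(cfg.depth)
        self.bot_convs = (Conv2d(c_prev, c_bot, 3, rng), Conv2d(c_bot, c_bot, 3, rng))

        # decoder runs deepest level first
        self.dec_ups: list[ConvTranspose2x2] = []
        self.dec_convs: list[tuple[Conv2d, Conv2d]] = []
        c_prev = c_bot
        for i in reversed(range(cfg.depth)):
            c = cfg.level_channels(i)
            self.dec_ups.append(ConvTranspose2x2(c_prev, c, rng))
            self.dec_convs.append((Conv2d(2 * c, c, 3, rng), Conv2d(c, c, 3, rng)))
            c_prev = c

        self.seg_head = Conv2d(cfg.base_channels, cfg.seg_classes, 1, rng)
        self.cls_fc1 = Dense(c_bot, cfg.cls_hidden, rng)
        self.cls_fc2 = Dense(cfg.cls_hidden, cfg.cls_classes, rng)

        self._cache: dict | None = None

    # -- plumbing ----------------------------------------------------------

    def layers(self) -> list:
        out: list = []
        for a, b in self.enc_convs:
            out += [a, b]
        out += list(self.bot_convs)
        for up, (a, b) in zip(self.dec_ups, self.dec_convs):
            out += [up, a, b]
        out += [self.seg_head, self.cls_fc1, self.cls_fc2]
        return out

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False):
        """Batch forward pass.

        ``x``: (N, H, W, 3) float32 in [0, 1]. Returns
        ``(seg_prob (N,H,W), cls_prob (N,2))``; with ``train=True`` the
        activations needed by :meth:`backward` are cached and raw logits are
        stored in the cache.
        """
        cfg = self.config
        if x.ndim != 4 or x.shape[1:] != (cfg.input_size, cfg.input_size, cfg.in_channels):
            raise ValueError(
                f"expected (N, {cfg.input_size}, {cfg.input_size}, {cfg.in_channels}), "
                f"got {x.shape}"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache: dict = {"enc": [], "dec": []}

        a = x
        skips = []
        for (c1, c2), pool in zip(self.enc_convs, self.pools):
            y1 = _nn.relu(c1.forward(a, train))
            y2 = _nn.relu(c2.forward(y1, train))
            skips.append(y2)
            if train:
                cache["enc"].append((y1, y2))
            a = pool.forward(y2, train)

        b1 = _nn.relu(self.bot_convs[0].forward(a, train))
        b2 = _nn.relu(self.bot_convs[1].forward(b1, train))
        if train:
            cache["bot"] = (b1, b2)

        d = b2
        for up, (c1, c2), skip in zip(self.dec_ups, self.dec_convs, reversed(skips)):
            u = up.forward(d, train)
            cat = np.concatenate([u, skip], axis=-1)
            y1 = _nn.relu(c1.forward(cat, train))
            y2 = _nn.relu(c2.forward(y1, train))
            if train:
                cache["dec"].append((y1, y2))
            d = y2

        seg_logits = self.seg_head.forward(d, train)  # (N, H, W, 1)
        gap = b2.mean(axis=(1, 2))  # (N, c_bot)
        h1 = _nn.relu(self.cls_fc1.forward(gap, train))
        cls_logits = self.cls_fc2.forward(h1, train)
        if train:
            cache["h1"] = h1
            cache["bot_hw"] = b2.shape[1:3]
            cache["seg_logits"] = seg_logits
            cache["cls_logits"] = cls_logits
            self._cache = cache

        return _nn.sigmoid(seg_logits[..., 0]), _nn.softmax(cls_logits)

    def backward(self, dseg_logits: np.ndarray, dcls_logits: np.ndarray) -> None:
        """Accumulate parameter gradients from loss gradients w.r.t. logits."""
        cache = self._cache
        if cache is None:
            raise RuntimeError("backward requires a prior forward(train=True)")

        # classification head -> bottleneck (through global average pooling)
        dh1 = self.cls_fc2.backward(dcls_logits)
        dgap = self.cls_fc1.backward(_nn.relu_backward(dh1, cache["h1"]))
        hb, wb = cache["bot_hw"]
        n, c_bot = dgap.shape
        db2_cls = np.broadcast_to(
            dgap[:, None, None, :] / (hb * wb), (n, hb, wb, c_bot)
        )

        # segmentation head -> decoder -> skips + bottleneck
        dd = self.seg_head.backward(dseg_logits)
        dskips: list[np.ndarray] = []
        for up, (c1, c2), (y1, y2) in zip(
            reversed(self.dec_ups), reversed(self.dec_convs), reversed(cache["dec"])
        ):
            dy1 = c2.backward(_nn.relu_backward(dd, y2))
            dcat = c1.backward(_nn.relu_backward(dy1, y1))
            c_skip = dcat.shape[-1] // 2
            dskips.append(dcat[..., c_skip:])
            dd = up.backward(np.ascontiguousarray(dcat[..., :c_skip]))
        # decoder backward ran top level first, so dskips[i] is the gradient
        # for encoder level i's skip output

        db2 = dd + db2_cls
        b1, b2 = cache["bot"]
        db1 = self.bot_convs[1].backward(_nn.relu_backward(db2, b2))
        da = self.bot_convs[0].backward(_nn.relu_backward(db1, b1))

        for (c1, c2), pool, (y1, y2), dskip in zip(
            reversed(self.enc_convs),
            reversed(self.pools),
            reversed(cache["enc"]),
            reversed(dskips),
        ):
            dy2 = pool.backward(da) + dskip
            dy1 = c2.backward(_nn.relu_backward(dy2, y2))
            da = c1.backward(_nn.relu_backward(dy1, y1))

        self._cache = None

    # -- convenience -------------------------------------------------------

    def predict(self, image: np.ndarray) -> MTLPrediction:
        """Inference on a single H x W x 3 frame."""
        seg, cls = self.forward(image[None].astype(np.float32))
        return MTLPrediction(seg_prob=seg[0], cls_prob=cls[0])

    # -- checkpointing -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}_{k}": p
            for i, l in enumerate(self.layers())
            for k, p in l.params.items()
        }

    def save(self, path: str | Path) -> None:
        header = json.dumps(
            {"format_version": _CHECKPOINT_VERSION, "config": asdict(self.config)}
        )
        np.savez(Path(path), __header__=np.array(header), **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "MTLUNet":
        with np.load(Path(path)) as data:
            header = json.loads(str(data["__header__"]))
            if header["format_version"] != _CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {header['format_version']}"
                )
            model = cls(NetConfig(**header["config"]))
            for i, layer in enumerate(model.layers()):
                for k in layer.params:
                    layer.params[k][...] = data[f"layer{i}_{k}"]
        return model


def build_network(config: NetConfig, seed: int = 0) -> MTLUNet:
    """Construct the multi-task U-Net with seeded initialisation."""
    return MTLUNet(config, seed=seed)
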