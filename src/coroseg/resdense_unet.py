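"""ResDense U-Net: five-level encoder–decoder for 2D slice segmentation.

The network is a U-Net whose level blocks can be plain, residual, dense or
residual-dense ("resdense"). Every block stacks two conv(3x3)–ReLU–BN units
(the unit order is configurable). Skip forms:

* plain     — no shortcut,
* residual  — additive identity shortcut (1x1 projection when the channel
              counts differ),
* dense     — the block input is concatenated onto the block output,
* resdense  — two *residual* sub-blocks linked by a dense (concatenative)
              connection: the block input is concatenated with the second
              residual sub-block's output.

In the channel-doubling regime (output = 2 x input channels, the encoder
contract) the concatenated branch carries exactly the block input, so a
resdense block doubles the feature-map depth. Decoder blocks reduce
channels; there the concatenated input branch is projected by a 1x1
convolution to half the output width.

The encoder applies a block then 2x2 max pooling at each level (no pooling
at the bottleneck); the decoder mirrors with parameter-free 2x nearest-
neighbour upsampling and concatenation of the matching encoder feature map,
and a 1x1 convolution + sigmoid head emits per-pixel probabilities.
Input spatial size must be divisible by ``2**(n_levels - 1)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Tuple

import numpy as np

from ._layers import (
    BatchNorm2d,
    Conv2d,
    ConvUnit,
    Layer,
    MaxPool2,
    Sigmoid,
    Upsample2,
)

__all__ = ["NetworkSpec", "build_network", "ResDenseUNet", "save_checkpoint", "load_checkpoint"]

_BLOCK_TYPES = ("plain", "residual", "dense", "resdense")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the segmentation network.

    base_channels is the width after the first encoder block; each deeper
    encoder level doubles it. unit_order selects conv-ReLU-BN (default) or
    the conventional conv-BN-ReLU within each sub-unit.
    """

    n_levels: int = 5
    base_channels: int = 16
    block_type: str = "resdense"
    in_channels: int = 1
    out_channels: int = 1
    unit_order: str = "conv-relu-bn"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.block_type not in _BLOCK_TYPES:
            raise ValueError(f"block_type must be one of {_BLOCK_TYPES}")
        if self.out_channels != 1:
            raise ValueError("the binary head is fixed to one output channel")

    @property
    def divisor(self) -> int:
        return 2 ** (self.n_levels - 1)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        return cls(**json.loads(text))


class _Block(Layer):
    """A two-unit level block with the configured skip form."""

    def __init__(
        self,
        cin: int,
        cout: int,
        block_type: str,
        rng: np.random.Generator,
        order: str,
    ):
        self.cin, self.cout, self.block_type = cin, cout, block_type
        self._modules: List[Layer] = []

        def unit(a: int, b: int, kernel: int = 3) -> ConvUnit:
            u = ConvUnit(a, b, rng, kernel=kernel, order=order)
            self._modules.append(u)
            return u

        if block_type in ("plain", "residual"):
            self.u1 = unit(cin, cout)
            self.u2 = unit(cout, cout)
            self.short = None
            if block_type == "residual" and cin != cout:
                self.short = Conv2d(cin, cout, 1, rng)
                self._modules.append(self.short)
        else:  # dense / resdense: concat(input branch -> h, main branch -> h)
            if cout % 2:
                raise ValueError(
                    f"{block_type} blocks need an even output width, got {cout}"
                )
            h = cout // 2
            self.h = h
            if block_type == "dense":
                self.u1 = unit(cin, h)
                self.u2 = unit(h, h)
                self.r1_short = self.r2_short = None
            else:  # residual sub-blocks linked by the dense concatenation
                self.u1 = unit(cin, h)
                self.u2 = unit(h, h)
                self.r1_short = None
                if cin != h:
                    self.r1_short = Conv2d(cin, h, 1, rng)
                    self._modules.append(self.r1_short)
                self.r2_short = None  # identity: u2 maps h -> h
            self.in_proj = None
            if cin != h:
                self.in_proj = Conv2d(cin, h, 1, rng)
                self._modules.append(self.in_proj)

    def params(self):
        return [p for m in self._modules for p in m.params()]

    def grads(self):
        return [g for m in self._modules for g in m.grads()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        bt = self.block_type
        if bt in ("plain", "residual"):
            out = self.u2.forward(self.u1.forward(x, train), train)
            if bt == "residual":
                out = out + (self.short.forward(x, train) if self.short else x)
            return out
        # dense / resdense
        if bt == "dense":
            main = self.u2.forward(self.u1.forward(x, train), train)
        else:
            y1 = self.u1.forward(x, train)
            y1 = y1 + (self.r1_short.forward(x, train) if self.r1_short else x)
            y2 = self.u2.forward(y1, train)
            main = y2 + y1  # identity shortcut of the second residual sub-block
        branch = self.in_proj.forward(x, train) if self.in_proj else x
        return np.concatenate([branch, main], axis=-1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        bt = self.block_type
        if bt in ("plain", "residual"):
            dx = self.u1.backward(self.u2.backward(gout))
            if bt == "residual":
                dx = dx + (self.short.backward(gout) if self.short else gout)
            return dx
        gbranch = gout[..., : self.h]
        gmain = gout[..., self.h :]
        if bt == "dense":
            dx = self.u1.backward(self.u2.backward(gmain))
        else:
            gy1 = self.u2.backward(gmain) + gmain  # through identity shortcut
            dx = self.u1.backward(gy1)
            dx = dx + (self.r1_short.backward(gy1) if self.r1_short else gy1)
        dx = dx + (self.in_proj.backward(gbranch) if self.in_proj else gbranch)
        return dx


class ResDenseUNet:
    """The assembled encoder–decoder; see module docstring for wiring."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.n_levels
        widths = [spec.base_channels * (2**i) for i in range(L)]
        self.widths = widths

        self.enc_blocks: List[_Block] = []
        self.pools: List[MaxPool2] = []
        cin = spec.in_channels
        for i in range(L):
            self.enc_blocks.append(
                _Block(cin, widths[i], spec.block_type, rng, spec.unit_order)
            )
            cin = widths[i]
            if i < L - 1:
                self.pools.append(MaxPool2())

        self.ups: List[Upsample2] = []
        self.dec_blocks: List[_Block] = []
        for d in range(L - 2, -1, -1):
            self.ups.append(Upsample2())
            self.dec_blocks.append(
                _Block(
                    widths[d] + widths[d + 1],
                    widths[d],
                    spec.block_type,
                    rng,
                    spec.unit_order,
                )
            )
        self.head = Conv2d(widths[0], spec.out_channels, 1, rng)
        self.sigmoid = Sigmoid()
        self._modules: List[Layer] = (
            list(self.enc_blocks) + list(self.dec_blocks) + [self.head]
        )
        # (in_channels, out_channels) recorded per encoder block on the last
        # forward pass; lets callers assert the channel-doubling contract
        self.last_encoder_shapes: List[Tuple[int, int]] = []

    # -- parameters ----------------------------------------------------
    def params(self) -> List[np.ndarray]:
        return [p for m in self._modules for p in m.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for m in self._modules for g in m.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def _bn_layers(self) -> List[BatchNorm2d]:
        out = []
        stack: List = list(self._modules)
        while stack:
            m = stack.pop()
            if isinstance(m, BatchNorm2d):
                out.append(m)
            elif isinstance(m, ConvUnit):
                out.append(m.bn)
            elif isinstance(m, _Block):
                stack.extend(m._modules)
        return out

    # -- execution -----------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError(f"expected NCHW input, got ndim {x.ndim}")
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} channels, got {x.shape[1]}"
            )
        div = self.spec.divisor
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial size {x.shape[2]}x{x.shape[3]} not divisible by "
                f"2^(n_levels-1) = {div}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities in (0, 1), same NCHW shape as the input.

        Internally the network runs channels-last; the conversion happens
        only here at the boundary.
        """
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # NCHW -> NHWC
        self.last_encoder_shapes = []
        skips = []
        for i, block in enumerate(self.enc_blocks):
            cin = x.shape[-1]
            x = block.forward(x, train)
            self.last_encoder_shapes.append((cin, x.shape[-1]))
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=-1)
            block._skip_channels = skip.shape[-1]
            x = block.forward(x, train)
        logits = self.head.forward(x, train)
        prob = self.sigmoid.forward(logits, train)
        return np.ascontiguousarray(prob.transpose(0, 3, 1, 2))  # NHWC -> NCHW

    def backward(self, gout: np.ndarray) -> None:
        """Backprop from d(loss)/d(probabilities); fills all layer grads."""
        g = np.ascontiguousarray(
            np.asarray(gout, dtype=np.float32).transpose(0, 2, 3, 1)
        )
        g = self.sigmoid.backward(g)
        g = self.head.backward(g)
        skip_grads = []
        for up, block in zip(reversed(self.ups), reversed(self.dec_blocks)):
            g = block.backward(g)
            cs = block._skip_channels
            skip_grads.append(g[..., :cs])
            g = up.backward(g[..., cs:])
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                # skip_grads were collected shallow-to-deep (d = 0 .. L-2)
                g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)


def build_network(spec: NetworkSpec, seed: int = 0) -> ResDenseUNet:
    """Instantiate the network from its declarative spec (seeded init)."""
    return ResDenseUNet(spec, seed=seed)


def forward(model: ResDenseUNet, batch: np.ndarray) -> np.ndarray:
    """Deterministic evaluation-mode inference on an NCHW batch."""
    return model.forward(batch, train=False)


def save_checkpoint(model: ResDenseUNet, path: str) -> None:
    """Save weights + BN running stats with the NetworkSpec embedded."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.params())}
    for i, bn in enumerate(model._bn_layers()):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    arrays["spec_json"] = np.frombuffer(
        model.spec.to_json().encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> ResDenseUNet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        spec = NetworkSpec.from_json(bytes(data["spec_json"]).decode("utf-8"))
        model = build_network(spec)
        for i, p in enumerate(model.params()):
            p[...] = data[f"param_{i}"]
        for i, bn in enumerate(model._bn_layers()):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
    return model
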