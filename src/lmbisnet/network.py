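"""LMBiS-Net: a lightweight multipath encoder-decoder with bidirectional
skip connections for retinal vessel segmentation.

Topology (default channel plan, input side divisible by 4):

    stem conv3  ->  E1 (conv-ReLU-BN) -> pool -> E2 -> pool -> E3
                ->  multipath block (two stages of three parallel
                    1x1 / 3x3 / 5x5 conv-ReLU-BN paths, summed)
                ->  bottleneck 1x1 conv-ReLU-BN
                ->  D1: 2x transpose conv, concat E2 skip, conv-ReLU-BN
                ->  reverse skip: D1 features projected (1x1), upsampled,
                    added onto the stored E1 features
                ->  D2: 2x transpose conv, concat refined E1, conv-ReLU-BN
                ->  D3: full-resolution conv-ReLU-BN
                ->  1x1 conv head -> per-pixel softmax over 2 classes

Only two max-pooling layers are used so thin-vessel detail survives the
contracting path; the whole network stays within a 172,000
trainable-parameter budget. Operator order inside every block is
conv -> ReLU -> batch-norm.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .types import ValidationError

__all__ = [
    "PARAMETER_BUDGET",
    "ChannelPlan",
    "MultipathBlockSpec",
    "MultipathBlock",
    "LayerInfo",
    "SkipEdge",
    "NetworkGraph",
    "LMBiSNet",
    "build_network",
    "build_ablation_variant",
    "count_parameters",
    "multipath_block_forward",
    "remap_reverse_skip",
]

PARAMETER_BUDGET = 172_000  # "0.172 million" learnable parameters


@dataclass
class ChannelPlan:
    """Per-stage channel widths. The defaults keep the full network well
    inside the 172 k parameter budget; the budget, not any particular
    width, is the hard constraint."""

    stem_channels: int = 8
    encoder_channels: tuple[int, int, int] = (8, 16, 32)
    multipath_channels: int = 32
    bottleneck_channels: int = 32
    decoder_channels: tuple[int, int, int] = (32, 16, 8)
    num_classes: int = 2

    def __post_init__(self):
        widths = (self.stem_channels, *self.encoder_channels, self.multipath_channels,
                  self.bottleneck_channels, *self.decoder_channels, self.num_classes)
        if any(w <= 0 for w in widths):
            raise ValidationError("all channel widths must be positive")


@dataclass
class MultipathBlockSpec:
    """Three parallel conv-ReLU-BN paths with kernels n = 2k-1 for k=1..3,
    i.e. {1, 3, 5}, summed elementwise; applied in two consecutive stages."""

    in_channels: int
    out_channels: int
    kernel_sizes: tuple[int, ...] = (1, 3, 5)
    stages: int = 2

    def __post_init__(self):
        expected = tuple(2 * k - 1 for k in range(1, len(self.kernel_sizes) + 1))
        if tuple(self.kernel_sizes) != expected:
            raise ValidationError(f"kernel sizes must follow n=2k-1, got {self.kernel_sizes}")


class _ConvReluBN(nn.Module):
    """conv -> ReLU -> batch-norm, the block used throughout the network."""

    def __init__(self, cin, cout, ksize, rng, dtype):
        self.conv = nn.Conv2d(cin, cout, ksize, rng, dtype)
        self.bn = nn.BatchNorm2d(cout, dtype=dtype)
        self._pre = None

    def forward(self, x, training=False):
        z = self.conv.forward(x, training)
        if training:
            self._pre = z
        return self.bn.forward(nn.relu(z), training)

    def backward(self, g):
        g = self.bn.backward(g)
        g = nn.relu_backward(g, self._pre)
        self._pre = None
        return self.conv.backward(g)


class _MultipathStage(nn.Module):
    """One stage: sum over the three parallel conv-ReLU-BN paths."""

    def __init__(self, cin, cout, kernel_sizes, rng, dtype):
        self.paths = [_ConvReluBN(cin, cout, k, rng, dtype) for k in kernel_sizes]

    def forward(self, x, training=False):
        out = self.paths[0].forward(x, training)
        for p in self.paths[1:]:
            out = out + p.forward(x, training)
        return out

    def backward(self, g):
        dx = self.paths[0].backward(g)
        for p in self.paths[1:]:
            dx = dx + p.backward(g)
        return dx


class MultipathBlock(nn.Module):
    """Two consecutive multipath stages (the second consumes the first's sum)."""

    def __init__(self, spec: MultipathBlockSpec, rng, dtype=np.float32):
        self.spec = spec
        self.stage1 = _MultipathStage(spec.in_channels, spec.out_channels,
                                      spec.kernel_sizes, rng, dtype)
        self.stage2 = _MultipathStage(spec.out_channels, spec.out_channels,
                                      spec.kernel_sizes, rng, dtype)

    def forward(self, x, training=False):
        if x.shape[1] != self.spec.in_channels:
            raise ValidationError(
                f"multipath block expects {self.spec.in_channels} channels, got {x.shape[1]}")
        return self.stage2.forward(self.stage1.forward(x, training), training)

    def backward(self, g):
        return self.stage1.backward(self.stage2.backward(g))


def multipath_block_forward(x: np.ndarray, block: MultipathBlock) -> np.ndarray:
    """Inference-mode forward pass of a multipath block."""
    return block.forward(x, training=False)


def _upsample_nn2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_nn2_backward(g: np.ndarray) -> np.ndarray:
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def remap_reverse_skip(decoder_features: np.ndarray, encoder_features: np.ndarray,
                       projection: nn.Conv2d, training: bool = False) -> np.ndarray:
    """Remap decoder features back onto stored encoder features.

    The decoder map passes a 1x1 conv projection, is resized
    (nearest-neighbour) to the encoder stage's spatial shape, and is added
    elementwise. With a zero projection the encoder features come back
    unchanged.
    """
    r = projection.forward(decoder_features, training)
    eh, ew = encoder_features.shape[2:]
    if r.shape[2:] != (eh, ew):
        if (eh, ew) != (2 * r.shape[2], 2 * r.shape[3]):
            raise ValidationError(
                f"reverse skip cannot map {r.shape[2:]} onto {(eh, ew)}")
        r = _upsample_nn2(r)
    if r.shape[1] != encoder_features.shape[1]:
        raise ValidationError("reverse-skip projection width mismatch")
    return encoder_features + r


@dataclass(frozen=True)
class LayerInfo:
    """One trainable layer: enough to recompute its parameter count in
    closed form (k^2*Cin*Cout + Cout for convs, 2*C for batch-norms)."""

    name: str
    kind: str          # conv | tconv | batchnorm | maxpool | softmax | add | concat
    kernel: int = 0
    stride: int = 1
    in_channels: int = 0
    out_channels: int = 0

    @property
    def param_count(self) -> int:
        if self.kind in ("conv", "tconv"):
            return self.kernel ** 2 * self.in_channels * self.out_channels + self.out_channels
        if self.kind == "batchnorm":
            return 2 * self.out_channels
        return 0


@dataclass(frozen=True)
class SkipEdge:
    source: str
    destination: str
    direction: str     # forward | reverse
    merge: str         # concat | add


@dataclass
class NetworkGraph:
    """Ordered layer descriptors plus skip edges, wrapping the runnable model."""

    layers: list[LayerInfo]
    skips: list[SkipEdge]
    model: "LMBiSNet"
    variant: str = "full"

    def parameter_table(self) -> pd.DataFrame:
        rows = [{"layer": l.name, "kind": l.kind, "kernel": l.kernel,
                 "in_channels": l.in_channels, "out_channels": l.out_channels,
                 "params": l.param_count} for l in self.layers]
        return pd.DataFrame(rows)

    def parameter_table_csv(self) -> str:
        buf = _io.StringIO()
        self.parameter_table().to_csv(buf, index=False)
        return buf.getvalue()

    def is_acyclic(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        names = [l.name for l in self.layers]
        g.add_nodes_from(names)
        g.add_edges_from(zip(names, names[1:]))  # execution order
        for s in self.skips:
            g.add_edge(s.source, s.destination)
        return nx.is_directed_acyclic_graph(g)

    def count_maxpool(self) -> int:
        return sum(1 for l in self.layers if l.kind == "maxpool")

    def count_encoder_blocks(self) -> int:
        return sum(1 for l in self.layers if l.name.startswith("enc") and l.kind == "conv")

    def count_decoder_blocks(self) -> int:
        return sum(1 for l in self.layers
                   if l.name.startswith("dec") and l.kind == "conv" and "proj" not in l.name)


class LMBiSNet(nn.Module):
    """The runnable network. ``use_multipath`` / ``use_reverse_skip`` toggle
    the ablation axes; both on is the full model."""

    def __init__(self, plan: ChannelPlan, seed: int = 0, dtype=np.float32,
                 use_multipath: bool = True, use_reverse_skip: bool = True):
        rng = np.random.default_rng(seed)
        self.plan = plan
        self.dtype = dtype
        self.use_multipath = use_multipath
        self.use_reverse_skip = use_reverse_skip
        e1, e2, e3 = plan.encoder_channels
        d1, d2, d3 = plan.decoder_channels

        self.stem = nn.Conv2d(3, plan.stem_channels, 3, rng, dtype)
        self.enc1 = _ConvReluBN(plan.stem_channels, e1, 3, rng, dtype)
        self.pool1 = nn.MaxPool2d()
        self.enc2 = _ConvReluBN(e1, e2, 3, rng, dtype)
        self.pool2 = nn.MaxPool2d()
        self.enc3 = _ConvReluBN(e2, e3, 3, rng, dtype)
        if use_multipath:
            self.multipath = MultipathBlock(
                MultipathBlockSpec(e3, plan.multipath_channels), rng, dtype)
            bneck_in = plan.multipath_channels
        else:
            self.multipath = None
            bneck_in = e3
        self.bottleneck = _ConvReluBN(bneck_in, plan.bottleneck_channels, 1, rng, dtype)
        self.up1 = nn.ConvTranspose2d(plan.bottleneck_channels, d1, rng, dtype)
        self.dec1 = _ConvReluBN(d1 + e2, d1, 3, rng, dtype)
        if use_reverse_skip:
            self.rev_proj = nn.Conv2d(d1, e1, 1, rng, dtype)
        else:
            self.rev_proj = None
        self.up2 = nn.ConvTranspose2d(d1, d2, rng, dtype)
        self.dec2 = _ConvReluBN(d2 + e1, d2, 3, rng, dtype)
        self.dec3 = _ConvReluBN(d2, d3, 3, rng, dtype)
        self.head = nn.Conv2d(d3, plan.num_classes, 1, rng, dtype)
        self._cache = None

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map an (N,3,H,W) image batch to (N,num_classes,H,W) softmax
        probabilities. H and W must be divisible by 4."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValidationError(f"expected (N,3,H,W) input, got {x.shape}")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValidationError("input sides must be divisible by 4")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        s = self.stem.forward(x, training)
        f1 = self.enc1.forward(s, training)               # full res, e1 ch
        p1 = self.pool1.forward(f1, training)
        f2 = self.enc2.forward(p1, training)              # 1/2 res, e2 ch
        p2 = self.pool2.forward(f2, training)
        f3 = self.enc3.forward(p2, training)              # 1/4 res, e3 ch
        m = self.multipath.forward(f3, training) if self.multipath else f3
        b = self.bottleneck.forward(m, training)
        u1 = self.up1.forward(b, training)                # 1/2 res
        c1 = np.concatenate([u1, f2], axis=1)             # forward skip E2->D1
        g1 = self.dec1.forward(c1, training)
        if self.rev_proj is not None:                     # reverse skip D1->E1
            f1r = remap_reverse_skip(g1, f1, self.rev_proj, training)
        else:
            f1r = f1
        u2 = self.up2.forward(g1, training)               # full res
        c2 = np.concatenate([u2, f1r], axis=1)            # forward skip E1->D2
        g2 = self.dec2.forward(c2, training)
        g3 = self.dec3.forward(g2, training)
        logits = self.head.forward(g3, training)
        probs = nn.softmax_channels(logits)
        if training:
            self._cache = {"probs": probs, "split1": u1.shape[1], "split2": u2.shape[1]}
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the softmax probabilities."""
        cache = self._cache
        self._cache = None
        probs = cache["probs"]
        # softmax jacobian: dz_c = p_c * (dp_c - sum_k dp_k p_k)
        dot = (dprobs * probs).sum(axis=1, keepdims=True)
        dlogits = probs * (dprobs - dot)
        g = self.head.backward(dlogits)
        g = self.dec3.backward(g)
        g = self.dec2.backward(g)
        du2, df1r = g[:, :cache["split2"]], g[:, cache["split2"]:]
        dg1 = self.up2.backward(du2)
        df1 = df1r
        if self.rev_proj is not None:
            dr = _upsample_nn2_backward(df1r)
            dg1 = dg1 + self.rev_proj.backward(dr)
        dc1 = self.dec1.backward(dg1)
        du1, df2 = dc1[:, :cache["split1"]], dc1[:, cache["split1"]:]
        db = self.up1.backward(du1)
        dm = self.bottleneck.backward(db)
        df3 = self.multipath.backward(dm) if self.multipath else dm
        dp2 = self.enc3.backward(df3)
        df2 = df2 + self.pool2.backward(dp2)
        dp1 = self.enc2.backward(df2)
        df1 = df1 + self.pool1.backward(dp1)
        ds = self.enc1.backward(df1)
        self.stem.backward(ds)

    # -- weight snapshots -------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}
        state.update(self._bn_state())
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"rm{i}"]
            bn.running_var[...] = state[f"rv{i}"]

    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        out = []

        def walk(mod):
            for v in vars(mod).values():
                if isinstance(v, nn.BatchNorm2d):
                    out.append(v)
                elif isinstance(v, nn.Module):
                    walk(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, nn.Module):
                            if isinstance(item, nn.BatchNorm2d):
                                out.append(item)
                            else:
                                walk(item)
        walk(self)
        return out

    def _bn_state(self):
        st = {}
        for i, bn in enumerate(self._bn_layers()):
            st[f"rm{i}"] = bn.running_mean.copy()
            st[f"rv{i}"] = bn.running_var.copy()
        return st


def _graph_layers(model: LMBiSNet) -> tuple[list[LayerInfo], list[SkipEdge]]:
    plan = model.plan
    e1, e2, e3 = plan.encoder_channels
    d1, d2, d3 = plan.decoder_channels
    L: list[LayerInfo] = []

    def conv(name, cin, cout, k):
        L.append(LayerInfo(name, "conv", kernel=k, in_channels=cin, out_channels=cout))

    def bn(name, c):
        L.append(LayerInfo(name, "batchnorm", out_channels=c))

    conv("stem", 3, plan.stem_channels, 3)
    conv("enc1.conv", plan.stem_channels, e1, 3); bn("enc1.bn", e1)
    L.append(LayerInfo("pool1", "maxpool", kernel=2, stride=2))
    conv("enc2.conv", e1, e2, 3); bn("enc2.bn", e2)
    L.append(LayerInfo("pool2", "maxpool", kernel=2, stride=2))
    conv("enc3.conv", e2, e3, 3); bn("enc3.bn", e3)
    if model.multipath is not None:
        mp = plan.multipath_channels
        for stage, cin in ((1, e3), (2, mp)):
            for k in (1, 3, 5):
                conv(f"multipath.s{stage}.k{k}.conv", cin, mp, k)
                bn(f"multipath.s{stage}.k{k}.bn", mp)
        bneck_in = mp
    else:
        bneck_in = e3
    conv("bottleneck.conv", bneck_in, plan.bottleneck_channels, 1)
    bn("bottleneck.bn", plan.bottleneck_channels)
    L.append(LayerInfo("up1", "tconv", kernel=2, stride=2,
                       in_channels=plan.bottleneck_channels, out_channels=d1))
    conv("dec1.conv", d1 + e2, d1, 3); bn("dec1.bn", d1)
    if model.rev_proj is not None:
        conv("dec1.rev_proj", d1, e1, 1)
        L.append(LayerInfo("enc1.refine", "add"))
    L.append(LayerInfo("up2", "tconv", kernel=2, stride=2, in_channels=d1, out_channels=d2))
    conv("dec2.conv", d2 + e1, d2, 3); bn("dec2.bn", d2)
    conv("dec3.conv", d2, d3, 3); bn("dec3.bn", d3)
    conv("head", d3, plan.num_classes, 1)
    L.append(LayerInfo("softmax", "softmax"))

    skips = [SkipEdge("enc2.bn", "dec1.conv", "forward", "concat"),
             SkipEdge("enc1.bn", "dec2.conv", "forward", "concat")]
    if model.rev_proj is not None:
        skips.append(SkipEdge("dec1.bn", "enc1.refine", "reverse", "add"))
    return L, skips


def count_parameters(graph: NetworkGraph) -> int:
    """Closed-form trainable-parameter total over the layer descriptors."""
    return sum(l.param_count for l in graph.layers)


def build_network(plan: ChannelPlan | None = None, seed: int = 0, dtype=np.float32,
                  use_multipath: bool = True, use_reverse_skip: bool = True,
                  enforce_budget: bool = True, variant: str = "full") -> NetworkGraph:
    """Build the network and its descriptor graph, enforcing the 172 k
    trainable-parameter budget (violations raise with the per-layer table)."""
    plan = plan or ChannelPlan()
    model = LMBiSNet(plan, seed=seed, dtype=dtype, use_multipath=use_multipath,
                     use_reverse_skip=use_reverse_skip)
    layers, skips = _graph_layers(model)
    graph = NetworkGraph(layers=layers, skips=skips, model=model, variant=variant)
    total = count_parameters(graph)
    if total != model.num_parameters():
        raise AssertionError(
            f"parameter accounting mismatch: table {total} vs arrays {model.num_parameters()}")
    if enforce_budget and total > PARAMETER_BUDGET:
        raise ValidationError(
            f"parameter budget exceeded: {total} > {PARAMETER_BUDGET}\n"
            + graph.parameter_table_csv())
    return graph


_UNET_BASELINE_PLAN = ChannelPlan(stem_channels=32, encoder_channels=(32, 64, 128),
                                  multipath_channels=128, bottleneck_channels=128,
                                  decoder_channels=(128, 64, 32))


def build_ablation_variant(name: str, seed: int = 0, dtype=np.float32) -> NetworkGraph:
    """Ablation axes: plain U-Net baseline, the lightweight baseline
    (no multipath block, no reverse skips), +multipath, and the full model."""
    if name == "baseline_unet":
        return build_network(_UNET_BASELINE_PLAN, seed=seed, dtype=dtype,
                             use_multipath=False, use_reverse_skip=False,
                             enforce_budget=False, variant=name)
    if name == "lightweight_baseline":
        return build_network(seed=seed, dtype=dtype, use_multipath=False,
                             use_reverse_skip=False, variant=name)
    if name == "lbl_mfeb":
        return build_network(seed=seed, dtype=dtype, use_multipath=True,
                             use_reverse_skip=False, variant=name)
    if name == "full":
        return build_network(seed=seed, dtype=dtype, variant=name)
    raise ValidationError(f"unknown ablation variant {name!r}")
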