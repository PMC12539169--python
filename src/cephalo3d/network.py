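"""Lightweight 3D U-Net with planewise-attention pseudo-3D (PA-P3D) blocks
and the spatial-separation (SS-P3D) 2D refinement branches.

The pseudo-3D factorization replaces each dense ``n x n x n`` convolution by
an in-plane ``n x n x 1`` convolution followed by a through-plane
``1 x 1 x n`` convolution, cutting per-kernel weights from ``n^3`` to
``n^2 + n`` (27 -> 12 at n = 3).  The planewise attention gate forms three
per-plane descriptors by averaging the feature tensor along each spatial
axis, passes each through a small bottleneck to a sigmoid gate, broadcasts
the gates back and averages them into one multiplicative mask.  The exact
attention design is this package's reconstruction and can be toggled off.

The coarse 3D head maps a 1-channel volume to one same-size heatmap per
landmark.  Each SS-P3D branch is an independent 2D encoder-decoder mapping a
1-channel orthogonal slice to a same-size per-landmark heatmap stack; the
three branches are architecturally identical with independent weights.

Everything runs on the numpy autodiff engine in :mod:`cephalo3d.nn`; forward
passes are deterministic for fixed weights and input.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor

__all__ = [
    "P3DBlockSpec",
    "NetworkSpec",
    "Conv",
    "PAP3DBlock",
    "ConvBlock2D",
    "UNet",
    "build_pa_p3d_block",
    "build_network",
    "build_ss_p3d_branch",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class P3DBlockSpec:
    """One PA-P3D block: factorized kernels (n,n,1)+(1,1,n), optional gate."""

    in_channels: int
    out_channels: int
    kernel: int = 3
    attention: str = "planewise"  # or "none"
    residual: bool = False
    bias: bool = False
    norm: bool = True
    # Factorization order.  The default runs the cheap through-plane (1,1,n)
    # kernel first and lets the expressive in-plane (n,n,1) kernel carry the
    # channel expansion: with mid = min(ci, co) this keeps every block's
    # weight count strictly below the dense n^3 replacement while retaining
    # full in-plane kernels on the widened channels.  The serial
    # in-plane-first order is available via the flag.
    inplane_first: bool = False

    def __post_init__(self):
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.attention not in ("planewise", "none"):
            raise ValueError(f"unknown attention {self.attention!r}")


@dataclass
class NetworkSpec:
    """Topology of the coarse 3D U-Net (and, mutatis mutandis, a 2D branch).

    ``crop`` dims must be divisible by ``2**depth`` on each axis.  The default
    matches the full-resolution crop (128 x 128 x 64, depth 4, base 16); the
    phantom preset is 96 x 96 x 64 and the tiny training preset uses base 8 /
    depth 3 on smaller grids.
    """

    landmarks: int
    depth: int = 4
    base_channels: int = 16
    crop: tuple[int, ...] = (128, 128, 64)
    attention: str = "planewise"
    dense: bool = False  # dense n^3 convolutions instead of the P3D pair
    max_channels: int = 128

    def channels(self, level: int) -> int:
        return min(self.base_channels * (2 ** level), self.max_channels)

    @property
    def head_channels(self) -> int:
        # the 1x1 output head is linear, so its input width bounds the rank of
        # the per-landmark map family; widen the last stage to at least L
        return max(self.base_channels, self.landmarks)

    def validate(self) -> None:
        f = 2 ** self.depth
        bad = [d for d in self.crop if d % f]
        if bad:
            raise ValueError(
                f"crop dims {self.crop} not divisible by 2^depth = {f}")


class Module:
    """Base: a callable with a flat parameter list."""

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out += v.params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out += item.params()
        return out


class Conv(Module):
    """Same-padded convolution with odd kernel, He init (seeded)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 kernel: tuple[int, ...], bias: bool = True, gain: float = 2.0):
        fan_in = cin * int(np.prod(kernel))
        std = float(np.sqrt(gain / fan_in))
        self.weight = Tensor(rng.normal(0.0, std, size=(cout, cin) + tuple(kernel)),
                             requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x.conv(self.weight)
        return out.bias(self.b) if self.b is not None else out


class Norm(Module):
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.instance_norm(self.gamma, self.beta)


class PlanewiseAttention(Module):
    """Average along each axis -> bottleneck -> sigmoid gate -> mean mask."""

    def __init__(self, rng: np.random.Generator, channels: int, nd: int, reduction: int = 4):
        mid = max(channels // reduction, 1)
        k1 = (1,) * (nd - 1)
        self.squeeze = [Conv(rng, channels, mid, k1) for _ in range(nd)]
        self.excite = [Conv(rng, mid, channels, k1) for _ in range(nd)]
        self.nd = nd

    def __call__(self, x: Tensor) -> Tensor:
        gates = []
        for ax in range(self.nd):
            d = x.mean_axis(ax)
            g = self.excite[ax](self.squeeze[ax](d).relu()).sigmoid()
            gates.append(g.expand_axis(ax, x.shape[1 + ax]))
        mask = gates[0]
        for g in gates[1:]:
            mask = mask + g
        return x * mask.scale(1.0 / self.nd)


class PAP3DBlock(Module):
    """conv(n,n,1) -> norm -> relu -> conv(1,1,n) -> norm -> relu, gated.

    With ``spec.dense`` semantics handled by the caller (see
    :func:`build_pa_p3d_block`), ``residual`` adds the input back when channel
    counts match.
    """

    def __init__(self, rng: np.random.Generator, spec: P3DBlockSpec, dense: bool = False):
        n, ci, co = spec.kernel, spec.in_channels, spec.out_channels
        # the first kernel of the pair keeps mid = min(ci, co) channels and
        # the second carries the channel change; in the default through-plane-
        # first order the pair costs n*ci*mid + n^2*mid*co weights, strictly
        # below the dense n^3*ci*co for every channel pairing, and reduces to
        # the n^2 + n identity at 1->1.
        mid = min(ci, co)
        if dense:
            self.convs = [Conv(rng, ci, co, (n, n, n), bias=spec.bias)]
        elif spec.inplane_first:
            self.convs = [Conv(rng, ci, mid, (n, n, 1), bias=spec.bias),
                          Conv(rng, mid, co, (1, 1, n), bias=spec.bias)]
        else:
            self.convs = [Conv(rng, ci, mid, (1, 1, n), bias=spec.bias),
                          Conv(rng, mid, co, (n, n, 1), bias=spec.bias)]
        chans = [co] if dense else [mid, co]
        self.norms = ([Norm(c) for c in chans] if spec.norm
                      else [None] * len(self.convs))
        self.att = (PlanewiseAttention(rng, co, nd=3)
                    if spec.attention == "planewise" else None)
        self.residual = spec.residual and ci == co
        self.spec = spec

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for c in self.convs:
            out += c.params()
        for nrm in self.norms:
            if nrm is not None:
                out += nrm.params()
        if self.att is not None:
            out += self.att.params()
        return out

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, nrm in zip(self.convs, self.norms):
            h = conv(h)
            if nrm is not None:
                h = nrm(h)
            h = h.relu()
        if self.att is not None:
            h = self.att(h)
        if self.residual:
            h = h + x
        return h


class ConvBlock2D(Module):
    """Two 3x3 conv-norm-relu layers (the 2D branch building block)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        self.c1, self.n1 = Conv(rng, cin, cout, (3, 3), bias=False), Norm(cout)
        self.c2, self.n2 = Conv(rng, cout, cout, (3, 3), bias=False), Norm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.n1(self.c1(x)).relu()
        return self.n2(self.c2(h)).relu()


class UNet(Module):
    """Encoder-decoder with skip connections; 3D (P3D blocks) or 2D."""

    def __init__(self, spec: NetworkSpec, nd: int, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.nd = nd
        rng = np.random.default_rng((seed, 0xE7))

        def block(ci, co):
            if nd == 3:
                return PAP3DBlock(rng, P3DBlockSpec(ci, co, attention=spec.attention),
                                  dense=spec.dense)
            return ConvBlock2D(rng, ci, co)

        def dec_out(lvl: int) -> int:
            return spec.head_channels if lvl == 0 else spec.channels(lvl)

        self.enc = [block(1 if lvl == 0 else spec.channels(lvl - 1), spec.channels(lvl))
                    for lvl in range(spec.depth)]
        self.bottom = block(spec.channels(spec.depth - 1), spec.channels(spec.depth))
        self.dec = [block(spec.channels(lvl + 1) + spec.channels(lvl), dec_out(lvl))
                    for lvl in reversed(range(spec.depth))]
        # linear 1x1(x1) output head, small init so initial heatmaps are near 0
        self.head = Conv(rng, spec.head_channels, spec.landmarks, (1,) * nd, gain=0.01)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1:] != tuple(self.spec.crop[: self.nd]):
            raise ValueError(f"input {x.shape[1:]} != spec crop {self.spec.crop}")
        skips = []
        h = x
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
            h = h.avgpool2()
        h = self.bottom(h)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = h.upsample2().concat(skip)
            h = blk(h)
        return self.head(h)

    def forward_numpy(self, vol: np.ndarray) -> np.ndarray:
        """Inference helper: (D,H,W[,..]) float array -> (L, ...) heatmaps."""
        out = self(Tensor(vol[None]))
        return out.data


def build_pa_p3d_block(spec: P3DBlockSpec, seed: int = 0, dense: bool = False) -> PAP3DBlock:
    """Construct a single PA-P3D block (or its dense n^3 counterpart)."""
    rng = np.random.default_rng((seed, 0xB1))
    return PAP3DBlock(rng, spec, dense=dense)


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet:
    """The coarse 3D network: 1-channel volume in, L same-size heatmaps out."""
    if len(spec.crop) != 3:
        raise ValueError("3D network requires a 3-axis crop")
    return UNet(spec, nd=3, seed=seed)


def build_ss_p3d_branch(plane: str, spec: NetworkSpec, seed: int = 0) -> UNet:
    """One 2D refinement branch for ``plane`` in axial/sagittal/coronal.

    The three branches are architecturally identical; independent weights come
    from seeding by plane.
    """
    from .heatmap import plane_axes  # local import to avoid a cycle

    normal, axes = plane_axes(plane)
    crop2d = tuple(spec.crop[a] for a in axes) if len(spec.crop) == 3 else tuple(spec.crop)
    spec2d = NetworkSpec(landmarks=spec.landmarks, depth=spec.depth,
                         base_channels=spec.base_channels, crop=crop2d,
                         attention="none", max_channels=spec.max_channels)
    return UNet(spec2d, nd=2, seed=(seed * 7919 + 13 * normal) % (2 ** 31))


def count_parameters(model) -> int:
    """Exact count of trainable scalars in a module or parameter list."""
    params = model.params() if hasattr(model, "params") else list(model)
    return int(sum(p.data.size for p in params))


def save_checkpoint(model: UNet, path: str | Path, extra: dict | None = None) -> Path:
    """Serialize weights plus the embedded NetworkSpec as a single file."""
    path = Path(path)
    payload = {
        "spec": json.dumps(asdict(model.spec)),
        "nd": model.nd,
        "weights": [p.data for p in model.params()],
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    return path


def load_checkpoint(path: str | Path) -> UNet:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    spec_dict = json.loads(payload["spec"])
    spec_dict["crop"] = tuple(spec_dict["crop"])
    model = UNet(NetworkSpec(**spec_dict), nd=payload["nd"])
    for p, w in zip(model.params(), payload["weights"]):
        assert p.data.shape == w.shape
        p.data = np.asarray(w, dtype=np.float32)
    return model
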