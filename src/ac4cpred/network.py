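"""The hybrid ac4C classifier: selective-kernel convolution, a temporal
convolutional network, and multi-head self-attention, followed by a flatten
and an MLP head with a single sigmoid output.

Stage contracts
---------------
* SKC (split/fuse/select): M parallel convolution branches with distinct odd
  kernel sizes, each ReLU(BatchNorm(conv)); branches are summed, globally
  average-pooled, passed through a two-layer bottleneck to an attention
  vector, and softmax-normalised *across branches per output channel*; the
  output is the attention-weighted sum of the branch maps. Length preserved.
* TCN: residual blocks of two weight-normalised causal dilated convolutions
  (ReLU + dropout after each), dilation doubling per block; a 1x1 projection
  on the skip path when channel counts differ. Output at position t depends
  only on inputs at positions <= t.
* MHSA: positions become rows (n = L, features d = channels); per head,
  A = softmax(Q K^T / sqrt(d_k)) row-wise, head outputs A V are concatenated.
  No positional encoding: position information comes from the convolutions.

Every stage can be disabled independently (the ablation matrix); 1x1
convolution adapters reconcile channel widths where a disabled stage would
break the chain. Flatten order is position-major, channel-minor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .autodiff import Tensor, concat, conv1d, softmax
from .encoding import ENCODERS, encoder_channels
from .layers import BatchNorm1d, Conv1d, Dropout, Embedding, Linear, Module

__all__ = [
    "SKCParams", "TCNParams", "MHSAParams", "ModelConfig",
    "SKCBlock", "TCNBlock", "TCNStack", "MHSABlock", "Ac4cNet",
    "build_model", "predict", "causal_dilated_conv",
    "save_checkpoint", "load_checkpoint", "ablation_matrix",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SKCParams:
    out_channels: int = 64
    branch_kernel_sizes: tuple[int, ...] = (3, 5)
    reduction: int = 4  # bottleneck ratio of the two selection FC layers

    def __post_init__(self):
        if len(self.branch_kernel_sizes) < 1:
            raise ValueError("need at least one branch kernel")
        if any(k % 2 == 0 or k < 1 for k in self.branch_kernel_sizes):
            raise ValueError("branch kernel sizes must be odd and positive")
        if self.reduction < 1:
            raise ValueError("reduction must be >= 1")


@dataclasses.dataclass
class TCNParams:
    kernel_size: int = 3
    num_blocks: int = 3
    channels: tuple[int, ...] | None = None  # per block; default 64 each
    dropout: float = 0.2

    def __post_init__(self):
        if self.channels is None:
            self.channels = tuple([64] * self.num_blocks)
        self.channels = tuple(self.channels)
        if len(self.channels) != self.num_blocks:
            raise ValueError("channels must list one width per block")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def dilations(self) -> tuple[int, ...]:
        """Doubling schedule d_b = 2^b."""
        return tuple(2 ** b for b in range(self.num_blocks))


@dataclasses.dataclass
class MHSAParams:
    model_dim: int = 64
    heads: int = 4

    def __post_init__(self):
        if self.model_dim % self.heads != 0:
            raise ValueError(
                f"heads ({self.heads}) must divide model_dim ({self.model_dim})")

    @property
    def head_dim(self) -> int:
        return self.model_dim // self.heads


@dataclasses.dataclass
class ModelConfig:
    """Full architecture description; serialised into every checkpoint."""

    use_skc: bool = True
    use_tcn: bool = True
    use_mhsa: bool = True
    skc: SKCParams = dataclasses.field(default_factory=SKCParams)
    tcn: TCNParams = dataclasses.field(default_factory=TCNParams)
    mhsa: MHSAParams = dataclasses.field(default_factory=MHSAParams)
    mlp_hidden: tuple[int, ...] = (64,)
    embed_dim: int = 5
    encoder: str = "onehot"
    window_length: int = 201
    seed: int = 0

    def __post_init__(self):
        if not (self.use_skc or self.use_tcn or self.use_mhsa):
            raise ValueError("at least one of the SKC/TCN/MHSA stages must be enabled")
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.window_length < 1:
            raise ValueError("window_length must be positive")
        self.mlp_hidden = tuple(self.mlp_hidden)

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Reduced-width preset for quick experiments and CPU-scale studies."""
        base = dict(
            skc=SKCParams(out_channels=16, branch_kernel_sizes=(3, 5), reduction=4),
            tcn=TCNParams(kernel_size=3, num_blocks=2, channels=(16, 16), dropout=0.1),
            mhsa=MHSAParams(model_dim=16, heads=4),
            mlp_hidden=(32,),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["skc"] = SKCParams(**d["skc"])
        d["tcn"] = TCNParams(**{k: (tuple(v) if k == "channels" and v is not None else v)
                                for k, v in d["tcn"].items()})
        d["mhsa"] = MHSAParams(**d["mhsa"])
        d["mlp_hidden"] = tuple(d["mlp_hidden"])
        d["skc"].branch_kernel_sizes = tuple(d["skc"].branch_kernel_sizes)
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def ablation_matrix() -> list[dict[str, bool]]:
    """The seven usable stage-flag combinations (at least one stage on)."""
    combos = []
    for use_skc in (False, True):
        for use_tcn in (False, True):
            for use_mhsa in (False, True):
                if use_skc or use_tcn or use_mhsa:
                    combos.append(dict(use_skc=use_skc, use_tcn=use_tcn,
                                       use_mhsa=use_mhsa))
    return combos


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

class SKCBlock(Module):
    """Selective kernel convolution: split / fuse / select."""

    def __init__(self, in_channels: int, p: SKCParams, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.m = len(p.branch_kernel_sizes)
        self.out_channels = p.out_channels
        for i, k in enumerate(p.branch_kernel_sizes):
            setattr(self, f"conv{i}", Conv1d(in_channels, p.out_channels, k, rng))
            setattr(self, f"norm{i}", BatchNorm1d(p.out_channels))
        bottleneck = max(p.out_channels // p.reduction, 4)
        self.fc1 = Linear(p.out_channels, bottleneck, rng)
        self.fc2 = Linear(bottleneck, self.m * p.out_channels, rng)
        self.store_attention = False  # set True to keep the last select weights
        self.last_attention: np.ndarray | None = None  # (N, C_out, M), rows sum to 1

    def forward(self, x: Tensor) -> Tensor:
        # split: branch maps U_i = ReLU(Norm(K_i * X))
        branches = [getattr(self, f"norm{i}")(getattr(self, f"conv{i}")(x)).relu()
                    for i in range(self.m)]
        # fuse: U = sum_i U_i ; global descriptor s = GAP(U)
        u = branches[0]
        for b in branches[1:]:
            u = u + b
        s = u.mean(axis=2)  # (N, C_out)
        # select: z through the two FC layers, softmax across branches per channel
        z = self.fc2(self.fc1(s).relu())  # (N, M*C_out), element m + M*c
        n = z.shape[0]
        a = softmax(z.reshape(n, self.out_channels, self.m), axis=-1)
        if self.store_attention:
            self.last_attention = a.data.copy()
        out = branches[0] * a[:, :, 0].reshape(n, self.out_channels, 1)
        for i in range(1, self.m):
            out = out + branches[i] * a[:, :, i].reshape(n, self.out_channels, 1)
        return out

    __call__ = forward


class TCNBlock(Module):
    """One residual block: two weight-normalised causal dilated convolutions."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(in_channels, out_channels, kernel_size, rng,
                            dilation=dilation, padding="causal", weight_norm=True)
        self.conv2 = Conv1d(out_channels, out_channels, kernel_size, rng,
                            dilation=dilation, padding="causal", weight_norm=True)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.skip = (Conv1d(in_channels, out_channels, 1, rng, padding="causal")
                     if in_channels != out_channels else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop1(self.conv1(x).relu())
        h = self.drop2(self.conv2(h).relu())
        s = self.skip(x) if self.skip is not None else x
        return (h + s).relu()

    __call__ = forward


class TCNStack(Module):
    """Residual blocks with dilation doubling per block (d_b = 2^b)."""

    def __init__(self, in_channels: int, p: TCNParams, rng: np.random.Generator):
        super().__init__()
        self.p = p
        c = in_channels
        self.num_blocks = p.num_blocks
        for b, (width, d) in enumerate(zip(p.channels, p.dilations)):
            setattr(self, f"block{b}",
                    TCNBlock(c, width, p.kernel_size, d, p.dropout, rng))
            c = width
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        for b in range(self.num_blocks):
            x = getattr(self, f"block{b}")(x)
        return x

    __call__ = forward

    @staticmethod
    def receptive_field(kernel_size: int, num_blocks: int) -> int:
        """1 + 2(k-1)(2^B - 1): two convolutions per block, doubling dilations."""
        return 1 + 2 * (kernel_size - 1) * (2 ** num_blocks - 1)


class MHSABlock(Module):
    """Multi-head self-attention over positions (no positional encoding)."""

    def __init__(self, p: MHSAParams, rng: np.random.Generator):
        super().__init__()
        self.p = p
        d, dk = p.model_dim, p.head_dim
        for i in range(p.heads):
            setattr(self, f"wq{i}", Linear(d, dk, rng))
            setattr(self, f"wk{i}", Linear(d, dk, rng))
            setattr(self, f"wv{i}", Linear(d, dk, rng))
        self.store_attention = False  # set True to keep the last attention maps
        self.last_attention: list[np.ndarray] = []  # per head, (N, n, n)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, L) with C == model_dim; returns the same shape."""
        xt = x.transpose(0, 2, 1)  # positions as rows: (N, n, d)
        scale = float(1.0 / np.sqrt(self.p.head_dim))  # python float: keeps float32
        heads = []
        self.last_attention = []
        for i in range(self.p.heads):
            q = getattr(self, f"wq{i}")(xt)
            k = getattr(self, f"wk{i}")(xt)
            v = getattr(self, f"wv{i}")(xt)
            a = softmax((q @ k.swapaxes(1, 2)) * scale, axis=-1)
            if self.store_attention:
                self.last_attention.append(a.data.copy())
            heads.append(a @ v)
        out = concat(heads, axis=-1)  # (N, n, d)
        return out.transpose(0, 2, 1)

    __call__ = forward


def causal_dilated_conv(x: Sequence[float], w: Sequence[float], b: float = 0.0,
                        dilation: int = 1) -> np.ndarray:
    """Causal dilated convolution of a plain 1-D sequence.

    y'_t = sum_i w_i * x_{t - d*i} + b, with zero padding for indices before
    the start; d=1 reduces to the standard causal convolution. Output length
    equals input length.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size == 0:
        raise ValueError("empty input sequence")
    if dilation < 1 or w.size < 1:
        raise ValueError("need dilation >= 1 and kernel size >= 1")
    # kernel tap i multiplies x_{t - d*i}: reverse the tap order of conv1d
    xt = Tensor(x.reshape(1, 1, -1))
    wt = Tensor(w[::-1].copy().reshape(1, 1, -1))
    bt = Tensor(np.array([b], dtype=float))
    return conv1d(xt, wt, bt, dilation=dilation, padding="causal").data.reshape(-1)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

class Ac4cNet(Module):
    """SKC -> TCN -> MHSA -> flatten -> MLP -> sigmoid score in (0, 1).

    Disabled stages are skipped; 1x1-convolution adapters lift channel counts
    where the remaining chain requires it. Construction is deterministic
    given ``cfg.seed``.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        c = encoder_channels(cfg.encoder)
        self.embedding = (Embedding(5, cfg.embed_dim, rng)
                          if cfg.encoder == "embed" else None)
        if cfg.encoder == "embed":
            c = cfg.embed_dim

        self.skc = SKCBlock(c, cfg.skc, rng) if cfg.use_skc else None
        if cfg.use_skc:
            c = cfg.skc.out_channels

        self.pre_tcn = None
        if cfg.use_tcn:
            self.tcn = TCNStack(c, cfg.tcn, rng)
            c = self.tcn.out_channels
        else:
            self.tcn = None

        self.pre_mhsa = None
        if cfg.use_mhsa:
            if c != cfg.mhsa.model_dim:
                self.pre_mhsa = Conv1d(c, cfg.mhsa.model_dim, 1, rng)
                c = cfg.mhsa.model_dim
            self.mhsa = MHSABlock(cfg.mhsa, rng)
        else:
            self.mhsa = None

        self.out_channels = c
        flat = c * cfg.window_length
        dims = [flat, *cfg.mlp_hidden, 1]
        for i in range(len(dims) - 1):
            setattr(self, f"mlp{i}", Linear(dims[i], dims[i + 1], rng))
        self.n_mlp = len(dims) - 1

    def forward(self, x) -> Tensor:
        """x: (N, channels, L) float array or Tensor; returns (N,) scores."""
        if self.embedding is not None:
            codes = (x.data if isinstance(x, Tensor) else np.asarray(x))
            codes = codes.reshape(codes.shape[0], -1).astype(int)
            h = self.embedding(codes).transpose(0, 2, 1)  # (N, d, L)
        else:
            h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if self.skc is not None:
            h = self.skc(h)
        if self.tcn is not None:
            h = self.tcn(h)
        if self.mhsa is not None:
            if self.pre_mhsa is not None:
                h = self.pre_mhsa(h)
            h = self.mhsa(h)
        # flatten position-major, channel-minor: (N, L, C) -> (N, L*C)
        n = h.shape[0]
        flat = h.transpose(0, 2, 1).reshape(n, -1)
        for i in range(self.n_mlp):
            flat = getattr(self, f"mlp{i}")(flat)
            if i < self.n_mlp - 1:
                flat = flat.relu()
        return flat.sigmoid().reshape(n)

    __call__ = forward


def build_model(cfg: ModelConfig) -> Ac4cNet:
    """Construct the network; initial parameters are reproducible from cfg.seed."""
    return Ac4cNet(cfg)


def predict(model: Ac4cNet, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Score encoded records in inference mode (dropout off, frozen norms).

    Deterministic and order-preserving; scores are identical whether records
    are scored singly or batched.
    """
    was_training = model.training
    model.eval()
    try:
        out = []
        for lo in range(0, X.shape[0], batch_size):
            out.append(model(X[lo: lo + batch_size]).data)
        return np.concatenate(out) if out else np.empty(0)
    finally:
        model.train(was_training)


def check_encoder(model: Ac4cNet, encoder: str) -> None:
    if encoder != model.cfg.encoder:
        raise ValueError(
            f"model was built for encoder {model.cfg.encoder!r}, got {encoder!r}")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Ac4cNet, path: str | Path) -> None:
    """Single-archive checkpoint: weights + config + encoder + version."""
    meta = {
        "config": model.cfg.to_dict(),
        "config_hash": model.cfg.config_hash(),
        "encoder": model.cfg.encoder,
        "package_version": __version__,
    }
    arrays = {f"arr::{k}": v for k, v in model.state_arrays().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> Ac4cNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = ModelConfig.from_dict(meta["config"])
        if cfg.config_hash() != meta["config_hash"]:
            raise ValueError("checkpoint config hash mismatch; file corrupted?")
        model = build_model(cfg)
        state = {k[len("arr::"):]: z[k] for k in z.files if k.startswith("arr::")}
        model.load_state_arrays(state)
    return model
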