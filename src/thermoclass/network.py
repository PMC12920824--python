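"""Progressive residual feature extractor.

The network maps a preprocessed thermogram patch to an embedding through
two parallel paths of residual blocks,

    H(x) = F(x, W) + x,

where the residual function F is a two-layer map (conv/linear → ReLU →
conv/linear) and the skip connection is the identity, or a learned linear
projection when the block changes width or resolution:

* the *progressive* path: a short stack of blocks whose widths strictly
  increase stage by stage, refining features while retaining the input
  through the skips;
* the *backbone* path: a deeper hierarchical stack of residual stages at
  fixed-per-stage widths (a reduced, configurable stand-in for a deep
  residual backbone).

Two block flavors share the same residual algebra: ``conv`` blocks (3×3
convolutions, strided downsampling, global average pooling before fusion —
the default for image patches, translation-invariant by construction) and
``dense`` blocks (two linear maps on flat vectors).  The two path outputs
are fused (concatenation by default) into the embedding consumed by the
SVM head.  Training minimizes a multi-class hinge surrogate through a
linear scoring head using the package's own Adam optimizer; the scoring
head is discarded afterwards and the margin classifier is refit on frozen
embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optim import AdamState, adam_step


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# --------------------------------------------------------------------------
# dense residual block

@dataclass
class ResidualBlock:
    """Dense residual block: H(x) = W2·relu(W1·x + b1) + b2 + P·x.

    ``P`` is None for an identity skip (requires in_dim == out_dim).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    P: np.ndarray | None = None

    @property
    def in_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def out_dim(self) -> int:
        return self.W2.shape[1]

    @classmethod
    def init(cls, in_dim: int, out_dim: int, hidden: int,
             rng: np.random.Generator) -> "ResidualBlock":
        """He-scaled random initialization; projection added iff widths differ."""
        W1 = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, hidden))
        W2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, out_dim))
        P = None
        if in_dim != out_dim:
            P = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(in_dim, out_dim))
        return cls(W1=W1, b1=np.zeros(hidden), W2=W2, b2=np.zeros(out_dim), P=P)

    def params(self) -> list[np.ndarray]:
        out = [self.W1, self.b1, self.W2, self.b2]
        if self.P is not None:
            out.append(self.P)
        return out


def residual_block_forward(x: np.ndarray, block: ResidualBlock,
                           cache: dict | None = None) -> np.ndarray:
    """H(x) = F(x, W) + x, with the projected skip when widths differ."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != block.in_dim:
        raise ValueError(f"input width {x.shape[1]} != block width {block.in_dim}")
    if block.P is None and block.in_dim != block.out_dim:
        raise ValueError("width change requires a projection")
    z1 = x @ block.W1 + block.b1
    a1 = relu(z1)
    f = a1 @ block.W2 + block.b2
    skip = x if block.P is None else x @ block.P
    if cache is not None:
        cache.update(x=x, z1=z1, a1=a1)
    return f + skip


def _residual_block_backward(dh: np.ndarray, block: ResidualBlock,
                             cache: dict) -> tuple[np.ndarray, list[np.ndarray]]:
    """Gradients of the block output w.r.t. input and parameters."""
    x, z1, a1 = cache["x"], cache["z1"], cache["a1"]
    dW2 = a1.T @ dh
    db2 = dh.sum(axis=0)
    da1 = dh @ block.W2.T
    dz1 = da1 * (z1 > 0)
    dW1 = x.T @ dz1
    db1 = dz1.sum(axis=0)
    dx = dz1 @ block.W1.T
    grads = [dW1, db1, dW2, db2]
    if block.P is None:
        dx = dx + dh
    else:
        grads.append(x.T @ dh)
        dx = dx + dh @ block.P.T
    return dx, grads


# --------------------------------------------------------------------------
# 3x3 convolution primitives (NCHW layout, zero padding 1)

def _conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                   stride: int) -> tuple[np.ndarray, np.ndarray]:
    """3×3 convolution; W has shape (C_in*9, C_out).  Returns (out, cols)."""
    B, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    sw = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    sw = sw[:, :, ::stride, ::stride]
    Ho, Wo = sw.shape[2], sw.shape[3]
    cols = sw.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * 9)
    out = (cols @ W + b).reshape(B, Ho, Wo, -1).transpose(0, 3, 1, 2)
    return out, cols


def _conv3_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                    x_shape: tuple, stride: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) for :func:`_conv3_forward`."""
    B, C, H, Wd = x_shape
    Bo, Co, Ho, Wo = dout.shape
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, Co)
    dW = cols.T @ dflat
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.T).reshape(B, Ho, Wo, C, 3, 3)
    dxp = np.zeros((B, C, H + 2, Wd + 2))
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki: ki + stride * Ho: stride,
                kj: kj + stride * Wo: stride] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _proj_forward(x: np.ndarray, P: np.ndarray, stride: int) -> np.ndarray:
    """1×1 strided projection; P has shape (C_in, C_out)."""
    xs = x[:, :, ::stride, ::stride]
    return np.einsum("bchw,cd->bdhw", xs, P)


def _proj_backward(dout: np.ndarray, x: np.ndarray, P: np.ndarray,
                   stride: int) -> tuple[np.ndarray, np.ndarray]:
    xs = x[:, :, ::stride, ::stride]
    dP = np.einsum("bchw,bdhw->cd", xs, dout)
    dx = np.zeros_like(x)
    dx[:, :, ::stride, ::stride] = np.einsum("bdhw,cd->bchw", dout, P)
    return dx, dP


@dataclass
class ConvResidualBlock:
    """Conv residual block: H(x) = conv3(relu(conv3(x, stride))) + P(x).

    The skip is the identity when stride = 1 and channels match, else a
    strided 1×1 projection.  Weight layout: W1 (C_in·9, C_mid),
    W2 (C_mid·9, C_out), P (C_in, C_out) or None.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    P: np.ndarray | None
    stride: int = 1
    in_channels: int = 1

    @property
    def out_channels(self) -> int:
        return self.W2.shape[1]

    @classmethod
    def init(cls, c_in: int, c_out: int, stride: int,
             rng: np.random.Generator) -> "ConvResidualBlock":
        W1 = rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), size=(c_in * 9, c_out))
        W2 = rng.normal(0.0, np.sqrt(2.0 / (c_out * 9)), size=(c_out * 9, c_out))
        P = None
        if stride != 1 or c_in != c_out:
            P = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in, c_out))
        return cls(W1=W1, b1=np.zeros(c_out), W2=W2, b2=np.zeros(c_out), P=P,
                   stride=stride, in_channels=c_in)

    def params(self) -> list[np.ndarray]:
        out = [self.W1, self.b1, self.W2, self.b2]
        if self.P is not None:
            out.append(self.P)
        return out


def conv_block_forward(x: np.ndarray, block: ConvResidualBlock,
                       cache: dict | None = None) -> np.ndarray:
    if block.P is None and (block.stride != 1 or x.shape[1] != block.out_channels):
        raise ValueError("stride/channel change requires a projection")
    z1, cols1 = _conv3_forward(x, block.W1, block.b1, block.stride)
    a1 = relu(z1)
    f, cols2 = _conv3_forward(a1, block.W2, block.b2, 1)
    skip = x if block.P is None else _proj_forward(x, block.P, block.stride)
    if cache is not None:
        cache.update(x=x, z1=z1, a1=a1, cols1=cols1, cols2=cols2)
    return f + skip


def _conv_block_backward(dh: np.ndarray, block: ConvResidualBlock,
                         cache: dict) -> tuple[np.ndarray, list[np.ndarray]]:
    x, z1, a1 = cache["x"], cache["z1"], cache["a1"]
    da1, dW2, db2 = _conv3_backward(dh, cache["cols2"], block.W2, a1.shape, 1)
    dz1 = da1 * (z1 > 0)
    dx, dW1, db1 = _conv3_backward(dz1, cache["cols1"], block.W1, x.shape, block.stride)
    grads = [dW1, db1, dW2, db2]
    if block.P is None:
        dx = dx + dh
    else:
        dskip, dP = _proj_backward(dh, x, block.P, block.stride)
        grads.append(dP)
        dx = dx + dskip
    return dx, grads


# --------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``kind='conv'`` (default) treats each input row as a flattened
    ``input_hw``×``input_hw`` single-channel patch; widths are channel
    counts, every progressive block and the first block of every backbone
    stage downsample by stride 2, and each path ends in global average
    pooling.  ``kind='dense'`` runs the same residual algebra on flat
    vectors of length ``input_dim``.  Progressive widths must be
    non-decreasing; ``backbone_widths``/``blocks_per_stage`` define the
    hierarchical path (defaults: 4 stages × 2 blocks = 8).
    """

    kind: str = "conv"
    input_hw: int = 32
    input_dim: int = 256
    prn_widths: tuple[int, ...] = (8, 12, 16)
    backbone_widths: tuple[int, ...] = (8, 8, 16, 16)
    blocks_per_stage: int = 2
    fusion: str = "concatenate"  # or "sum"

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "dense"):
            raise ValueError("kind must be 'conv' or 'dense'")
        if any(b > a for a, b in zip(self.prn_widths[1:], self.prn_widths[:-1])):
            raise ValueError("progressive widths must be non-decreasing")
        if self.fusion not in ("concatenate", "sum"):
            raise ValueError("fusion must be 'concatenate' or 'sum'")
        if self.fusion == "sum" and self.prn_widths[-1] != self.backbone_widths[-1]:
            raise ValueError("sum fusion requires equal final widths")


@dataclass
class NetworkModel:
    """Parameters of the two-path residual feature extractor."""

    config: NetworkConfig
    prn_blocks: list
    backbone_blocks: list

    @property
    def embedding_dim(self) -> int:
        # conv paths emit mean+max pooled features (2 per channel)
        per = 2 if self.config.kind == "conv" else 1
        if self.config.fusion == "concatenate":
            return per * (self.config.prn_widths[-1] + self.config.backbone_widths[-1])
        return per * self.config.prn_widths[-1]

    @classmethod
    def init(cls, config: NetworkConfig, seed: int = 0) -> "NetworkModel":
        rng = np.random.default_rng(seed)
        prn: list = []
        backbone: list = []
        if config.kind == "conv":
            c = 1
            for w in config.prn_widths:
                prn.append(ConvResidualBlock.init(c, w, stride=2, rng=rng))
                c = w
            c = 1
            for w in config.backbone_widths:
                for j in range(config.blocks_per_stage):
                    backbone.append(ConvResidualBlock.init(c, w, stride=2 if j == 0 else 1,
                                                           rng=rng))
                    c = w
        else:
            d = config.input_dim
            for w in config.prn_widths:
                prn.append(ResidualBlock.init(d, w, max(w, 4), rng))
                d = w
            d = config.input_dim
            for w in config.backbone_widths:
                for _ in range(config.blocks_per_stage):
                    backbone.append(ResidualBlock.init(d, w, max(w, 4), rng))
                    d = w
        return cls(config=config, prn_blocks=prn, backbone_blocks=backbone)

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for b in self.prn_blocks + self.backbone_blocks:
            out.extend(b.params())
        return out


def _path_forward(x: np.ndarray, blocks: list, conv: bool, caches: list | None) -> np.ndarray:
    h = x
    for blk in blocks:
        c: dict = {}
        h = conv_block_forward(h, blk, c) if conv else residual_block_forward(h, blk, c)
        if caches is not None:
            caches.append(c)
    if conv:
        # global average + global max pooling per channel
        B, C, H, W = h.shape
        flat = h.reshape(B, C, H * W)
        argmax = flat.argmax(axis=2)
        if caches is not None:
            caches.append({"gap_shape": h.shape, "argmax": argmax})
        h = np.concatenate([flat.mean(axis=2), np.take_along_axis(
            flat, argmax[:, :, None], axis=2)[:, :, 0]], axis=1)
    return h


def network_forward(x: np.ndarray, model: NetworkModel,
                    caches: list | None = None) -> np.ndarray:
    """Embedding for a sample (D,) or batch (B, D); rows are independent."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    conv = model.config.kind == "conv"
    if conv:
        hw = model.config.input_hw
        if x.shape[1] != hw * hw:
            raise ValueError(f"input width {x.shape[1]} != {hw}x{hw} patch")
        x = x.reshape(-1, 1, hw, hw)
    elif x.shape[1] != model.config.input_dim:
        raise ValueError(f"input width {x.shape[1]} != configured {model.config.input_dim}")

    prn_caches: list | None = [] if caches is not None else None
    bb_caches: list | None = [] if caches is not None else None
    h_prn = _path_forward(x, model.prn_blocks, conv, prn_caches)
    h_bb = _path_forward(x, model.backbone_blocks, conv, bb_caches)

    if model.config.fusion == "concatenate":
        emb = np.concatenate([h_prn, h_bb], axis=1)
    else:
        emb = h_prn + h_bb
    if not np.all(np.isfinite(emb)):
        raise FloatingPointError("non-finite activations in network forward pass")
    if caches is not None:
        caches.append((prn_caches, bb_caches))
    return emb[0] if single else emb


def _path_backward(d: np.ndarray, blocks: list, conv: bool, caches: list) -> list[list[np.ndarray]]:
    if conv:
        B, C, H, W = caches[-1]["gap_shape"]
        argmax = caches[-1]["argmax"]
        d_mean, d_max = d[:, :C], d[:, C:]
        dh = np.broadcast_to(d_mean[:, :, None] / (H * W), (B, C, H * W)).copy()
        np.put_along_axis(dh, argmax[:, :, None],
                          np.take_along_axis(dh, argmax[:, :, None], axis=2)
                          + d_max[:, :, None], axis=2)
        d = dh.reshape(B, C, H, W)
        caches = caches[:-1]
    grads_rev = []
    for blk, c in zip(reversed(blocks), reversed(caches)):
        if conv:
            d, g = _conv_block_backward(d, blk, c)
        else:
            d, g = _residual_block_backward(d, blk, c)
        grads_rev.append(g)
    return grads_rev


def _network_backward(demb: np.ndarray, model: NetworkModel,
                      caches: tuple) -> list[np.ndarray]:
    """Parameter gradients from an embedding gradient (input grad discarded)."""
    prn_caches, bb_caches = caches
    conv = model.config.kind == "conv"
    w_prn = (2 if conv else 1) * model.config.prn_widths[-1]
    if model.config.fusion == "concatenate":
        d_prn, d_bb = demb[:, :w_prn], demb[:, w_prn:]
    else:
        d_prn = d_bb = demb

    prn_grads = _path_backward(d_prn, model.prn_blocks, conv, prn_caches)
    bb_grads = _path_backward(d_bb, model.backbone_blocks, conv, bb_caches)

    grads: list[np.ndarray] = []
    for g in reversed(prn_grads):
        grads.extend(g)
    for g in reversed(bb_grads):
        grads.extend(g)
    return grads


# --------------------------------------------------------------------------
# training with the multi-class hinge surrogate

def _pack(arrays: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unpack(vec: np.ndarray, templates: list[np.ndarray]) -> list[np.ndarray]:
    out, i = [], 0
    for t in templates:
        out.append(vec[i: i + t.size].reshape(t.shape))
        i += t.size
    return out


def _set_params(model: NetworkModel, arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Install packed arrays into the model; returns the trailing head (W, b)."""
    i = 0
    for blk in model.prn_blocks + model.backbone_blocks:
        blk.W1 = arrays[i]; blk.b1 = arrays[i + 1]
        blk.W2 = arrays[i + 2]; blk.b2 = arrays[i + 3]
        i += 4
        if blk.P is not None:
            blk.P = arrays[i]; i += 1
    return arrays[i], arrays[i + 1]


def multiclass_hinge(scores: np.ndarray, y: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    """Mean one-vs-correct hinge loss and its gradient w.r.t. scores."""
    n = scores.shape[0]
    correct = scores[np.arange(n), y][:, None]
    margins = np.maximum(0.0, 1.0 + scores - correct)
    margins[np.arange(n), y] = 0.0
    loss = margins.sum() / n
    dscores = (margins > 0).astype(np.float64)
    dscores[np.arange(n), y] -= dscores.sum(axis=1)
    return loss, dscores / n


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    lr: float = 0.01
    weight_decay: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class TrainingLog:
    losses: list[float] = field(default_factory=list)


def train_network(X: np.ndarray, y: np.ndarray, n_classes: int,
                  net_config: NetworkConfig | None = None,
                  train_config: TrainConfig = TrainConfig(),
                  seed: int = 0) -> tuple[NetworkModel, TrainingLog]:
    """Fit the feature extractor by full-batch Adam on the hinge surrogate.

    Deterministic for a fixed seed: initialization and every update are
    pure functions of (X, y, configs, seed).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")

    if net_config is None:
        hw = int(round(np.sqrt(X.shape[1])))
        if hw * hw == X.shape[1]:
            net_config = NetworkConfig(kind="conv", input_hw=hw)
        else:
            net_config = NetworkConfig(kind="dense", input_dim=X.shape[1])
    model = NetworkModel.init(net_config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    head_W = rng.normal(0.0, np.sqrt(1.0 / model.embedding_dim),
                        size=(model.embedding_dim, n_classes))
    head_b = np.zeros(n_classes)

    templates = model.params() + [head_W, head_b]
    theta = _pack(templates)
    state = AdamState(shape=theta.shape, lr=train_config.lr,
                      beta1=train_config.beta1, beta2=train_config.beta2,
                      eps=train_config.eps)
    log = TrainingLog()

    for epoch in range(train_config.epochs):
        arrays = _unpack(theta, templates)
        head_W, head_b = _set_params(model, arrays)
        caches: list = []
        emb = network_forward(X, model, caches)
        scores = emb @ head_W + head_b
        loss, dscores = multiclass_hinge(scores, y)
        loss += 0.5 * train_config.weight_decay * float(theta @ theta)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        log.losses.append(loss)

        dW_head = emb.T @ dscores
        db_head = dscores.sum(axis=0)
        demb = dscores @ head_W.T
        net_grads = _network_backward(demb, model, caches[0])
        grad = _pack(net_grads + [dW_head, db_head]) + train_config.weight_decay * theta
        theta, state = adam_step(theta, grad, state)

    arrays = _unpack(theta, templates)
    _set_params(model, arrays)
    return model, log
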