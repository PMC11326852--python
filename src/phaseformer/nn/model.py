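"""Hybrid 3D-CNN / transformer for Patterson-to-density map regression.

The network tokenizes a Patterson map into 3D patches after a small
convolutional stem, runs an encoder-only transformer whose attention is
*one-way conditioned* on partial-structure tokens — Patterson tokens attend
to partial-structure tokens, never the reverse, and the partial tokens are
embedded once and reused unchanged at every layer — and decodes tokens back
to a map through an inverse patch rearrangement, a decoder CNN and a final
tanh, so predictions live in (-1, 1) like the normalized targets.

Per head h at layer l (pre-norm residual blocks around this core):

    Q = Wq X,  K = [Wk X ; Wk' U],  V = [Wv X ; Wv' U]
    A = softmax(Q K^T / sqrt(d_h))          # S x (S + S*J)
    X <- X + Wo concat_h(A V)
    X <- X + Wff2 ReLU(Wff1 LN(X))

All computation is float64 numpy via the package's autodiff engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, conv3d, layer_norm, softmax

__all__ = ["ModelConfig", "ModelParameters", "forward", "embed_patterson",
           "embed_partials", "one_way_attention_layer", "decode", "init_parameters"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are a desk-scale configuration (16^3 grids, 4^3 patches,
    2 layers); every field is overridable. The token width is tied to
    ``heads * d_head`` so the output projection is square.
    """

    grid: tuple[int, int, int] = (16, 16, 16)
    patch: tuple[int, int, int] = (4, 4, 4)
    in_channels: int = 1
    channels: int = 8  # CNN stem output channels (c)
    d_t: int = 64  # token width
    heads: int = 4
    d_head: int = 16
    layers: int = 2
    ff_width: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for n, d in zip(self.grid, self.patch):
            if n % d != 0:
                raise ValueError(
                    f"grid dims {self.grid} not divisible by patch dims {self.patch}")
        if self.d_t != self.heads * self.d_head:
            raise ValueError("d_t must equal heads * d_head")
        if self.seq_len < 1:
            raise ValueError("token sequence must be non-empty")

    @property
    def seq_len(self) -> int:
        """S = N1 N2 N3 / (d1 d2 d3)."""
        return int(np.prod(self.grid) // np.prod(self.patch))

    @property
    def patch_width(self) -> int:
        return int(self.channels * np.prod(self.patch))

    def to_dict(self) -> dict:
        return {
            "grid": list(self.grid), "patch": list(self.patch),
            "in_channels": self.in_channels, "channels": self.channels,
            "d_t": self.d_t, "heads": self.heads, "d_head": self.d_head,
            "layers": self.layers, "ff_width": self.ff_width, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["grid"] = tuple(d["grid"])
        d["patch"] = tuple(d["patch"])
        return cls(**d)


@dataclass
class ModelParameters:
    """Named trainable tensors, consistent with a ModelConfig."""

    config: ModelConfig
    tensors: dict[str, Tensor] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def trainable(self) -> dict[str, Tensor]:
        return self.tensors

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.tensors.items():
            t.data = np.asarray(arrays[k], dtype=np.float64).reshape(t.shape)


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    x = rng.standard_normal(shape)
    return np.clip(x, -2.0, 2.0) * std


def init_parameters(config: ModelConfig, dtype=np.float64) -> ModelParameters:
    """Seeded initialization: truncated-normal projections, zero biases.

    ``dtype`` selects the working precision (float32 for training speed,
    float64 for gradient checks); the random draws are made in float64
    first so both precisions share the same initialization.
    """
    rng = np.random.default_rng(config.seed)
    c, dt, ff = config.channels, config.d_t, config.ff_width
    pw, s = config.patch_width, config.seq_len
    t: dict[str, Tensor] = {}

    def param(name, shape, std=None):
        if std is None:
            std = 1.0 / math.sqrt(shape[-1] if len(shape) > 1 else shape[0])
        t[name] = Tensor(_trunc_normal(rng, shape, std), requires_grad=True)

    def zeros(name, shape):
        t[name] = Tensor(np.zeros(shape), requires_grad=True)

    def ones(name, shape):
        t[name] = Tensor(np.ones(shape), requires_grad=True)

    for stem, cin in (("p", config.in_channels), ("u", 1)):
        param(f"stem_{stem}_w1", (c, cin, 3, 3, 3), std=1.0 / math.sqrt(27 * cin))
        zeros(f"stem_{stem}_b1", (c,))
        param(f"stem_{stem}_w2", (c, c, 3, 3, 3), std=1.0 / math.sqrt(27 * c))
        zeros(f"stem_{stem}_b2", (c,))
        param(f"patch_{stem}_w", (pw, dt))
        zeros(f"patch_{stem}_b", (dt,))
        param(f"pos_{stem}", (s, dt), std=0.02)

    ones("lnu_g", (dt,)); zeros("lnu_b", (dt,))
    for l in range(config.layers):
        ones(f"l{l}_ln1_g", (dt,)); zeros(f"l{l}_ln1_b", (dt,))
        for name in ("q", "k", "v", "ku", "vu", "o"):
            param(f"l{l}_{name}_w", (dt, dt))
        zeros(f"l{l}_o_b", (dt,))
        ones(f"l{l}_ln2_g", (dt,)); zeros(f"l{l}_ln2_b", (dt,))
        param(f"l{l}_ff1_w", (dt, ff)); zeros(f"l{l}_ff1_b", (ff,))
        param(f"l{l}_ff2_w", (ff, dt)); zeros(f"l{l}_ff2_b", (dt,))
    ones("lnf_g", (dt,)); zeros("lnf_b", (dt,))
    # token -> patch decode is a real two-layer MLP: a single linear map
    # would confine all decoded patches to a d_t-dimensional subspace
    param("dec1_w", (dt, pw)); zeros("dec1_b", (pw,))
    param("dec2_w", (pw, pw)); zeros("dec2_b", (pw,))
    param("decconv_w1", (c, c, 3, 3, 3), std=1.0 / math.sqrt(27 * c))
    zeros("decconv_b1", (c,))
    param("decconv_w2", (1, c, 3, 3, 3), std=1.0 / math.sqrt(27 * c))
    zeros("decconv_b2", (1,))
    for tensor in t.values():
        tensor.data = tensor.data.astype(dtype)
    return ModelParameters(config, t)


def _patchify(x: Tensor, config: ModelConfig) -> Tensor:
    """(B, c, N1, N2, N3) -> (B, S, c*d1*d2*d3), raster patch order."""
    b = x.shape[0]
    c = x.shape[1]
    (n1, n2, n3), (d1, d2, d3) = config.grid, config.patch
    x = x.reshape(b, c, n1 // d1, d1, n2 // d2, d2, n3 // d3, d3)
    x = x.transpose(0, 2, 4, 6, 1, 3, 5, 7)
    return x.reshape(b, config.seq_len, c * d1 * d2 * d3)


def _unpatchify(tokens: Tensor, config: ModelConfig) -> Tensor:
    """Inverse of _patchify: (B, S, c*d1*d2*d3) -> (B, c, N1, N2, N3)."""
    b = tokens.shape[0]
    c = config.channels
    (n1, n2, n3), (d1, d2, d3) = config.grid, config.patch
    x = tokens.reshape(b, n1 // d1, n2 // d2, n3 // d3, c, d1, d2, d3)
    x = x.transpose(0, 4, 1, 5, 2, 6, 3, 7)
    return x.reshape(b, c, n1, n2, n3)


def _stem(x: Tensor, params: ModelParameters, which: str) -> Tensor:
    # leaky slope keeps sparse map inputs from killing the conv path
    x = conv3d(x, params[f"stem_{which}_w1"], params[f"stem_{which}_b1"]).leaky_relu()
    return conv3d(x, params[f"stem_{which}_w2"], params[f"stem_{which}_b2"])


def embed_patterson(p: Tensor, params: ModelParameters) -> Tensor:
    """Patterson map (B, Cin, N1, N2, N3) -> token sequence X0 (B, S, d_t)."""
    cfg = params.config
    if tuple(p.shape[2:]) != cfg.grid or p.shape[1] != cfg.in_channels:
        raise ValueError(f"input shape {p.shape} does not match config grid "
                         f"{cfg.grid} / in_channels {cfg.in_channels}")
    x = _stem(p, params, "p")
    tokens = _patchify(x, cfg) @ params["patch_p_w"] + params["patch_p_b"]
    return tokens + params["pos_p"]


def embed_partials(u: Tensor | None, params: ModelParameters) -> Tensor | None:
    """Partial maps (B, J, N1, N2, N3) -> tokens U (B, S*J, d_t); None if J=0.

    Every u_j receives the same partial positional-embedding table, so the
    model is invariant to the order of the partial structures.
    """
    cfg = params.config
    if u is None or u.shape[1] == 0:
        return None
    b, j = u.shape[0], u.shape[1]
    flat = u.reshape(b * j, 1, *cfg.grid)
    x = _stem(flat, params, "u")
    tokens = _patchify(x, cfg) @ params["patch_u_w"] + params["patch_u_b"]
    tokens = tokens + params["pos_u"]  # shared table across j
    tokens = tokens.reshape(b, j * cfg.seq_len, cfg.d_t)
    return layer_norm(tokens, params["lnu_g"], params["lnu_b"])


def _split_heads(x: Tensor, cfg: ModelConfig) -> Tensor:
    b, n = x.shape[0], x.shape[1]
    return x.reshape(b, n, cfg.heads, cfg.d_head).transpose(0, 2, 1, 3)


def one_way_attention_layer(x: Tensor, u: Tensor | None,
                            params: ModelParameters, layer: int) -> Tensor:
    """One pre-norm transformer block with one-way partial conditioning.

    Patterson tokens form the queries; keys/values concatenate projected
    Patterson tokens with projected partial tokens. ``u`` is read, never
    written: the partial sequence passes unchanged to the next layer.
    """
    cfg = params.config
    pre = layer_norm(x, params[f"l{layer}_ln1_g"], params[f"l{layer}_ln1_b"])
    q = _split_heads(pre @ params[f"l{layer}_q_w"], cfg)
    k_self = pre @ params[f"l{layer}_k_w"]
    v_self = pre @ params[f"l{layer}_v_w"]
    if u is not None:
        k = concat([k_self, u @ params[f"l{layer}_ku_w"]], axis=1)
        v = concat([v_self, u @ params[f"l{layer}_vu_w"]], axis=1)
    else:
        k, v = k_self, v_self
    k, v = _split_heads(k, cfg), _split_heads(v, cfg)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(cfg.d_head))
    attn = softmax(scores, axis=-1)
    ctx = attn @ v  # (B, H, S, d_head)
    ctx = ctx.transpose(0, 2, 1, 3).reshape(x.shape[0], cfg.seq_len, cfg.d_t)
    x = x + (ctx @ params[f"l{layer}_o_w"] + params[f"l{layer}_o_b"])
    pre2 = layer_norm(x, params[f"l{layer}_ln2_g"], params[f"l{layer}_ln2_b"])
    ff = (pre2 @ params[f"l{layer}_ff1_w"] + params[f"l{layer}_ff1_b"]).relu()
    ff = ff @ params[f"l{layer}_ff2_w"] + params[f"l{layer}_ff2_b"]
    return x + ff


def attention_weights(x: Tensor, u: Tensor | None, params: ModelParameters,
                      layer: int) -> np.ndarray:
    """Post-softmax attention matrix (B, H, S, S + S*J) for inspection."""
    cfg = params.config
    pre = layer_norm(x, params[f"l{layer}_ln1_g"], params[f"l{layer}_ln1_b"])
    q = _split_heads(pre @ params[f"l{layer}_q_w"], cfg)
    k = pre @ params[f"l{layer}_k_w"]
    if u is not None:
        k = concat([k, u @ params[f"l{layer}_ku_w"]], axis=1)
    k = _split_heads(k, cfg)
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(cfg.d_head))
    return softmax(scores, axis=-1).data


def decode(tokens: Tensor, params: ModelParameters) -> Tensor:
    """Token sequence (B, S, d_t) -> map (B, 1, N1, N2, N3) in (-1, 1)."""
    cfg = params.config
    x = layer_norm(tokens, params["lnf_g"], params["lnf_b"])
    x = (x @ params["dec1_w"] + params["dec1_b"]).leaky_relu()
    x = x @ params["dec2_w"] + params["dec2_b"]
    x = _unpatchify(x, cfg)
    x = conv3d(x, params["decconv_w1"], params["decconv_b1"]).leaky_relu()
    x = conv3d(x, params["decconv_w2"], params["decconv_b2"])
    return x.tanh()


def forward(p: Tensor | np.ndarray, u: Tensor | np.ndarray | None,
            params: ModelParameters) -> Tensor:
    """Full model: embed, L one-way attention layers (same U each layer), decode.

    p: (B, Cin, N1, N2, N3); u: (B, J, N1, N2, N3) or None.
    Returns (B, 1, N1, N2, N3).
    """
    if not isinstance(p, Tensor):
        p = Tensor(p)
    if u is not None and not isinstance(u, Tensor):
        u = Tensor(u)
    x = embed_patterson(p, params)
    u_tokens = embed_partials(u, params)
    for layer in range(params.config.layers):
        x = one_way_attention_layer(x, u_tokens, params, layer)
    return decode(x, params)
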