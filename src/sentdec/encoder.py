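"""Gated transformer sentiment encoder.

Each layer computes a per-token sentiment modulation gate
``gamma_t = sigmoid(W_s x_t + b_s)`` and interpolates between the token's
transformed state and its unmodified state, first around multi-head
attention::

    x~_t = gamma_t * MHAttn(x_t, X, X) + (1 - gamma_t) * x_t

then, reusing the same gate, around the position-wise feed-forward block::

    h~_t = gamma_t * FFN(x~_t) + (1 - gamma_t) * x~_t

A gated attention pooling layer turns the final token states into one
sentence vector ``z = sum_t alpha_t h~_t`` with
``alpha = softmax_t(u' tanh(W_h h~_t + b_h))``, and a softmax head maps z to
class probabilities. The same head applied to individual final-layer token
states yields a token-level polarity score used for lexicon regularization.

All functions operate on batched ``(B, T, d)`` tensors with a 0/1 padding
mask; the single-example wrappers at the bottom mirror that API for tests
and for the explanation module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor, gradient_reversal, no_grad

__all__ = [
    "ModelConfig", "LayerTrace", "PoolingResult", "Prediction",
    "init_params", "encoder_param_names", "discriminator_param_names",
    "embed_sequence", "encode", "encode_batch", "gated_attention_pool",
    "predict_head", "token_polarity_score", "modulation_gate",
    "modulated_attention_sublayer", "modulated_ffn_sublayer",
    "discriminate_domain", "save_checkpoint", "load_checkpoint",
    "build_vocab_index", "MASK_TOKEN",
]

MASK_TOKEN = "<mask>"  # reserved embedding row used by the explanation audit


class ConfigurationError(ValueError):
    pass


class OutOfVocabularyError(KeyError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture dimensions of the encoder.

    embed_dim must be divisible by n_heads. ``layer_norm`` and ``positional``
    exist so tests can reduce the encoder to algebraically checkable limits.
    """

    embed_dim: int = 32
    n_layers: int = 2
    n_heads: int = 2
    ffn_hidden: int = 64
    pool_hidden: int = 16
    n_classes: int = 2
    n_domains: int = 2
    disc_hidden: int = 16
    disc_linear: bool = False
    max_length: int = 64
    dropout_rate: float = 0.0
    layer_norm: bool = True
    positional: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ConfigurationError(
                f"embed_dim={self.embed_dim} not divisible by n_heads={self.n_heads}")
        for name in ("embed_dim", "n_heads", "ffn_hidden", "pool_hidden",
                     "n_classes", "n_domains", "max_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_layers < 0:
            raise ConfigurationError("n_layers must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")


@dataclass
class LayerTrace:
    """Per-layer intermediates kept for the explanation module (numpy)."""

    inputs: list[np.ndarray]       # x^(l), one (B, T, d) per layer
    gates: list[np.ndarray]        # gamma^(l), (B, T)
    post_attention: list[np.ndarray]
    post_ffn: list[np.ndarray]


@dataclass
class PoolingResult:
    attention_weights: np.ndarray  # alpha_t, sums to 1 over real tokens
    sentence_vector: np.ndarray    # z


@dataclass
class Prediction:
    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: int


def build_vocab_index(vocabulary: Sequence[str]) -> dict[str, int]:
    return {tok: i for i, tok in enumerate(vocabulary)}


# ------------------------------------------------------------- parameters

def init_params(config: ModelConfig, n_vocab: int) -> dict[str, Tensor]:
    """Initialize all trainable tensors, keyed by module path.

    The embedding table carries one extra all-zero row (index ``n_vocab``)
    reserved for the mask token used by the fidelity audit.
    """
    rng = np.random.default_rng(config.seed)
    d, k = config.embed_dim, config.pool_hidden

    def w(*shape, scale=None):
        scale = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
        return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape if shape else ()), requires_grad=True)

    emb = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n_vocab + 1, d))
    emb[n_vocab] = 0.0  # mask row
    params: dict[str, Tensor] = {"embedding": Tensor(emb, requires_grad=True)}
    for l in range(config.n_layers):
        p = f"layer{l}."
        for name in ("Wq", "Wk", "Wv", "Wo"):
            params[p + "attn." + name] = w(d, d)
        for name in ("bq", "bk", "bv", "bo"):
            params[p + "attn." + name] = zeros(d)
        params[p + "gate.W"] = w(d)
        params[p + "gate.b"] = zeros()
        params[p + "ffn.W1"] = w(d, config.ffn_hidden)
        params[p + "ffn.b1"] = zeros(config.ffn_hidden)
        params[p + "ffn.W2"] = w(config.ffn_hidden, d)
        params[p + "ffn.b2"] = zeros(d)
        params[p + "ln1.g"] = Tensor(np.ones(d), requires_grad=True)
        params[p + "ln1.b"] = zeros(d)
        params[p + "ln2.g"] = Tensor(np.ones(d), requires_grad=True)
        params[p + "ln2.b"] = zeros(d)
    params["pool.Wh"] = w(k, d)
    params["pool.bh"] = zeros(k)
    params["pool.u"] = w(k)
    params["head.Wo"] = w(config.n_classes, d)
    params["head.bo"] = zeros(config.n_classes)
    if config.disc_linear:
        params["disc.W"] = w(d, config.n_domains)
        params["disc.b"] = zeros(config.n_domains)
    else:
        params["disc.W1"] = w(d, config.disc_hidden)
        params["disc.b1"] = zeros(config.disc_hidden)
        params["disc.W2"] = w(config.disc_hidden, config.n_domains)
        params["disc.b2"] = zeros(config.n_domains)
    return params


def discriminator_param_names(params: Mapping[str, Tensor]) -> list[str]:
    return [k for k in params if k.startswith("disc.")]


def encoder_param_names(params: Mapping[str, Tensor]) -> list[str]:
    return [k for k in params if not k.startswith("disc.")]


# ---------------------------------------------------------------- embedding

def sinusoidal_positions(T: int, d: int) -> np.ndarray:
    """Fixed sinusoidal positional encodings, (T, d)."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def tokens_to_ids(tokens: Sequence[str], vocab_index: Mapping[str, int]) -> np.ndarray:
    ids = []
    for tok in tokens:
        if tok == MASK_TOKEN:
            ids.append(len(vocab_index))
            continue
        if tok not in vocab_index:
            raise OutOfVocabularyError(f"token {tok!r} is not in the vocabulary")
        ids.append(vocab_index[tok])
    return np.asarray(ids, dtype=np.int64)


def embed_batch(ids: np.ndarray, params: Mapping[str, Tensor],
                config: ModelConfig) -> Tensor:
    """(B, T) int ids -> (B, T, d) embeddings plus positional encodings."""
    X = params["embedding"][ids]
    if config.positional:
        X = X + Tensor(sinusoidal_positions(ids.shape[-1], config.embed_dim))
    return X


def embed_sequence(tokens: Sequence[str], vocab_index: Mapping[str, int],
                   params: Mapping[str, Tensor], config: ModelConfig) -> Tensor:
    """Embed one sequence: row t is e(w_t) + pos(t). (T, d)."""
    if len(tokens) > config.max_length:
        raise ConfigurationError(
            f"sequence length {len(tokens)} exceeds max_length={config.max_length}")
    ids = tokens_to_ids(tokens, vocab_index)
    return embed_batch(ids[None, :], params, config).reshape(len(tokens), config.embed_dim)


# ------------------------------------------------------------------- layers

def modulation_gate(x: Tensor, W_s: Tensor, b_s: Tensor) -> Tensor:
    """gamma = sigmoid(W_s x + b_s); strictly inside (0, 1) for finite input."""
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError("non-finite input to modulation gate")
    return ((x * W_s).sum(axis=-1) + b_s).sigmoid()


def _mh_attention(X: Tensor, prefix: str, params: Mapping[str, Tensor],
                  config: ModelConfig, mask: np.ndarray | None) -> Tensor:
    """Standard multi-head scaled dot-product self-attention, (B, T, d)."""
    B, T, d = X.shape
    h = config.n_heads
    dh = d // h

    def split(t: Tensor) -> Tensor:  # (B, T, d) -> (B, h, T, dh)
        return t.reshape(B, T, h, dh).swapaxes(1, 2)

    q = split(X @ params[prefix + "Wq"] + params[prefix + "bq"])
    k = split(X @ params[prefix + "Wk"] + params[prefix + "bk"])
    v = split(X @ params[prefix + "Wv"] + params[prefix + "bv"])
    scores = (q @ k.T) * (1.0 / np.sqrt(dh))
    if mask is not None:
        bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e9)
        scores = scores + Tensor(bias)
    attn = scores.softmax(axis=-1)
    out = (attn @ v).swapaxes(1, 2).reshape(B, T, d)
    return out @ params[prefix + "Wo"] + params[prefix + "bo"]


def modulated_attention_sublayer(X: Tensor, layer: str,
                                 params: Mapping[str, Tensor], config: ModelConfig,
                                 mask: np.ndarray | None = None
                                 ) -> tuple[Tensor, Tensor]:
    """Gate-interpolated attention: returns (x~, gamma)."""
    gamma = modulation_gate(X, params[layer + "gate.W"], params[layer + "gate.b"])
    attn = _mh_attention(X, layer + "attn.", params, config, mask)
    g = gamma.reshape(*gamma.shape, 1)
    return g * attn + (1.0 - g) * X, gamma


def modulated_ffn_sublayer(X: Tensor, gamma: Tensor, layer: str,
                           params: Mapping[str, Tensor]) -> Tensor:
    """Gate-interpolated position-wise feed-forward, sharing the layer's gate."""
    hidden = (X @ params[layer + "ffn.W1"] + params[layer + "ffn.b1"]).relu()
    ffn = hidden @ params[layer + "ffn.W2"] + params[layer + "ffn.b2"]
    g = gamma.reshape(*gamma.shape, 1)
    return g * ffn + (1.0 - g) * X


def _dropout(X: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or rate <= 0.0:
        return X
    keep = (rng.random(X.shape) >= rate) / (1.0 - rate)
    return X * Tensor(keep)


def encode_batch(ids: np.ndarray, params: Mapping[str, Tensor], config: ModelConfig,
                 mask: np.ndarray | None = None, collect_trace: bool = False,
                 dropout_rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, LayerTrace | None]:
    """Run embeddings through all modulated layers; (B, T, d) final states."""
    X = embed_batch(ids, params, config)
    trace = LayerTrace([], [], [], []) if collect_trace else None
    for l in range(config.n_layers):
        layer = f"layer{l}."
        if trace is not None:
            trace.inputs.append(X.data.copy())
        Xt, gamma = modulated_attention_sublayer(X, layer, params, config, mask)
        if config.layer_norm:
            Xt = Xt.layer_norm(params[layer + "ln1.g"], params[layer + "ln1.b"])
        Xt = _dropout(Xt, config.dropout_rate, dropout_rng)
        H = modulated_ffn_sublayer(Xt, gamma, layer, params)
        if config.layer_norm:
            H = H.layer_norm(params[layer + "ln2.g"], params[layer + "ln2.b"])
        H = _dropout(H, config.dropout_rate, dropout_rng)
        if trace is not None:
            trace.gates.append(gamma.data.copy())
            trace.post_attention.append(Xt.data.copy())
            trace.post_ffn.append(H.data.copy())
        X = H
    return X, trace


def forward_from_embeddings(X: Tensor, params: Mapping[str, Tensor],
                            config: ModelConfig, mask: np.ndarray | None = None
                            ) -> tuple[Tensor, Tensor, Tensor]:
    """Run the layer stack, pooling and head from given embedded inputs.

    Returns (final token states H, pooling weights alpha, logits). Used for
    gradient-based attributions, where the embedded input is the leaf.
    """
    for l in range(config.n_layers):
        layer = f"layer{l}."
        Xt, gamma = modulated_attention_sublayer(X, layer, params, config, mask)
        if config.layer_norm:
            Xt = Xt.layer_norm(params[layer + "ln1.g"], params[layer + "ln1.b"])
        H = modulated_ffn_sublayer(Xt, gamma, layer, params)
        if config.layer_norm:
            H = H.layer_norm(params[layer + "ln2.g"], params[layer + "ln2.b"])
        X = H
    alpha, z = gated_attention_pool_batch(X, params, mask=mask)
    logits = z @ params["head.Wo"].T + params["head.bo"]
    return X, alpha, logits


def encode(tokens: Sequence[str], vocab_index: Mapping[str, int],
           params: Mapping[str, Tensor], config: ModelConfig,
           collect_trace: bool = True) -> tuple[LayerTrace | None, Tensor]:
    """Single-sequence encoding; returns (trace, final token states (T, d))."""
    ids = tokens_to_ids(tokens, vocab_index)
    H, trace = encode_batch(ids[None, :], params, config, collect_trace=collect_trace)
    return trace, H.reshape(len(tokens), config.embed_dim)


# ------------------------------------------------------------------ pooling

def gated_attention_pool_batch(H: Tensor, params: Mapping[str, Tensor],
                               mask: np.ndarray | None = None
                               ) -> tuple[Tensor, Tensor]:
    """Returns (alpha (B, T), z (B, d))."""
    scores = (H @ params["pool.Wh"].T + params["pool.bh"]).tanh() @ params["pool.u"]
    if mask is not None:
        scores = scores + Tensor(np.where(mask > 0, 0.0, -1e9))
    alpha = scores.softmax(axis=-1)
    z = (alpha.reshape(*alpha.shape, 1) * H).sum(axis=-2)
    return alpha, z


def gated_attention_pool(H: Tensor, params: Mapping[str, Tensor]) -> PoolingResult:
    with no_grad():
        alpha, z = gated_attention_pool_batch(H.detach().reshape(1, *H.shape), params)
    return PoolingResult(attention_weights=alpha.data[0], sentence_vector=z.data[0])


# --------------------------------------------------------------------- head

def predict_head_batch(z: Tensor, params: Mapping[str, Tensor]) -> Tensor:
    """Logits (B, |Y|)."""
    return z @ params["head.Wo"].T + params["head.bo"]


def predict_head(z: Tensor | np.ndarray, params: Mapping[str, Tensor]) -> Prediction:
    with no_grad():
        logits = predict_head_batch(Tensor(np.atleast_2d(
            z.data if isinstance(z, Tensor) else z)), params)
        probs = logits.softmax(axis=-1)
    logits, probs = logits.data[0], probs.data[0]
    return Prediction(logits=logits, probabilities=probs,
                      predicted_class=int(np.argmax(probs)))


def token_polarity_score_batch(H: Tensor, params: Mapping[str, Tensor]) -> Tensor:
    """tanh(positive logit - negative logit) per token; (B, T)."""
    if params["head.Wo"].shape[0] != 2:
        raise ConfigurationError("token polarity scores require binary sentiment")
    logits = H @ params["head.Wo"].T + params["head.bo"]
    return (logits[..., 1] - logits[..., 0]).tanh()


def token_polarity_score(x_t: Tensor | np.ndarray, params: Mapping[str, Tensor],
                         hard: bool = False) -> float:
    x = Tensor(np.asarray(x_t.data if isinstance(x_t, Tensor) else x_t))
    with no_grad():
        s = token_polarity_score_batch(x.reshape(1, 1, -1), params)
    val = float(s.data[0, 0])
    return float(np.sign(val)) if hard else val


# ------------------------------------------------------------ discriminator

def discriminate_domain(z: Tensor, params: Mapping[str, Tensor],
                        grl_scale: float | None = None) -> Tensor:
    """Domain log-probabilities from z, (B, |D|).

    When ``grl_scale`` is given, a gradient-reversal node is inserted at z:
    forward unchanged, encoder-bound gradient multiplied by ``-grl_scale``.
    """
    if grl_scale is not None:
        z = gradient_reversal(z, grl_scale)
    if "disc.W" in params:  # linear (softmax-probe) discriminator
        return (z @ params["disc.W"] + params["disc.b"]).log_softmax(axis=-1)
    h = (z @ params["disc.W1"] + params["disc.b1"]).relu()
    return (h @ params["disc.W2"] + params["disc.b2"]).log_softmax(axis=-1)


# --------------------------------------------------------------- checkpoint

def save_checkpoint(path, params: Mapping[str, Tensor], config: ModelConfig,
                    n_vocab: int, extra_meta: dict | None = None) -> None:
    """One .npz archive: parameter arrays keyed by path + JSON-encoded config."""
    arrays = {k: v.data for k, v in params.items()}
    meta = json.dumps({"config": asdict(config), "n_vocab": n_vocab,
                       **(extra_meta or {})})
    np.savez(path, __meta__=np.frombuffer(meta.encode("utf-8"), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig, dict]:
    """Load a checkpoint, validating every parameter's shape against the config."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        config = ModelConfig(**meta["config"])
        reference = init_params(config, meta["n_vocab"])
        params: dict[str, Tensor] = {}
        for key, ref in reference.items():
            if key not in data:
                raise ConfigurationError(f"checkpoint is missing parameter {key!r}")
            arr = np.asarray(data[key])
            if arr.shape != ref.data.shape:
                raise ConfigurationError(
                    f"checkpoint parameter {key!r} has shape {arr.shape}, "
                    f"expected {ref.data.shape}")
            params[key] = Tensor(arr, requires_grad=True)
    return params, config, meta
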