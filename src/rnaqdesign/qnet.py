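"""Structure-conditioned action-value network.

Maps a target secondary structure and a partial sequence to per-position
action values (Q-values) over the four nucleotides.  The encoder reads the
dot-bracket token string together with the contact matrix; the decoder is
causal and autoregressive, conditioned on the encoder context and on a
binary paired/unpaired flag for the position being predicted.

Encoder pipeline: learned token embedding -> LSTM positional encoding ->
1-D convolution (local motifs) -> contact-graph message passing -> stack of
multi-head self-attention blocks.

Decoder pipeline: token embedding + paired-flag embedding -> LSTM
positional encoding -> causal 1-D convolution -> stack of (masked
self-attention, cross-attention over the encoder context, feed-forward)
blocks -> linear projection onto the four nucleotide actions.

Everything is written against ``autograd.numpy`` so the same forward code
serves both gradient-based training and plain inference; weights live in a
nested dict of float64 arrays.  Stepwise decoding with key-value caching
reproduces the full-grid forward pass exactly (up to float round-off), which
is the module's central correctness oracle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import autograd.numpy as anp
import numpy as np

#: Encoder (structure) vocabulary: dot plus the four bracket tiers.
STRUCT_VOCAB = ".()[]{}<>"
STRUCT_TOKEN = {ch: i for i, ch in enumerate(STRUCT_VOCAB)}

#: Decoder (sequence) vocabulary; START begins every decoder input, PAD is
#: reserved for batching and never receives an action value.
BASES = "ACGU"
BASE_TOKEN = {b: i for i, b in enumerate(BASES)}
START_TOKEN = 4
PAD_TOKEN = 5
DEC_VOCAB_SIZE = 6
N_ACTIONS = 4


@dataclass(frozen=True)
class QNetworkConfig:
    """Hyperparameters of the action-value network.

    Desk-scale defaults: the training scheme, not layer size, is what this
    package studies, so the network is kept small enough to train on one CPU.
    """

    embed_dim: int = 64
    encoder_layers: int = 2
    decoder_layers: int = 2
    attention_heads: int = 4
    conv_kernel: int = 5
    gcn_layers: int = 1
    ffn_mult: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % self.attention_heads != 0:
            raise ValueError("embed_dim must be divisible by attention_heads")
        if self.conv_kernel % 2 != 1 or self.conv_kernel < 1:
            raise ValueError("conv_kernel must be an odd positive integer")
        for name in ("embed_dim", "encoder_layers", "decoder_layers", "attention_heads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.gcn_layers < 0:
            raise ValueError("gcn_layers must be non-negative")


# ---------------------------------------------------------------------------
# Parameter initialization

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _linear_params(rng: np.random.Generator, d_in: int, d_out: int) -> dict:
    return {"W": _glorot(rng, d_in, d_out), "b": np.zeros(d_out)}


def _ln_params(d: int) -> dict:
    return {"g": np.ones(d), "b": np.zeros(d)}


def _lstm_params(rng: np.random.Generator, d: int) -> dict:
    return {
        "Wx": _glorot(rng, d, 4 * d),
        "Wh": _glorot(rng, d, 4 * d),
        "b": np.zeros(4 * d),
    }


def _attn_params(rng: np.random.Generator, d: int) -> dict:
    return {
        "Wq": _linear_params(rng, d, d),
        "Wk": _linear_params(rng, d, d),
        "Wv": _linear_params(rng, d, d),
        "Wo": _linear_params(rng, d, d),
    }


def _ffn_params(rng: np.random.Generator, d: int, mult: int) -> dict:
    return {"fc1": _linear_params(rng, d, mult * d), "fc2": _linear_params(rng, mult * d, d)}


def init_params(config: QNetworkConfig) -> dict:
    """Seeded parameter store; identical config and seed give identical weights."""
    rng = np.random.default_rng(config.seed)
    d, k = config.embed_dim, config.conv_kernel
    params: dict = {
        "enc": {
            "embed": rng.normal(0.0, 0.02, size=(len(STRUCT_VOCAB), d)),
            "lstm": _lstm_params(rng, d),
            "conv": {"W": rng.normal(0.0, 0.02, size=(k, d, d)), "b": np.zeros(d)},
            "conv_ln": _ln_params(d),
            "gcn": [_linear_params(rng, d, d) for _ in range(config.gcn_layers)],
            "layers": [
                {
                    "attn": _attn_params(rng, d),
                    "attn_ln": _ln_params(d),
                    "ffn": _ffn_params(rng, d, config.ffn_mult),
                    "ffn_ln": _ln_params(d),
                }
                for _ in range(config.encoder_layers)
            ],
            "final_ln": _ln_params(d),
        },
        "dec": {
            "embed": rng.normal(0.0, 0.02, size=(DEC_VOCAB_SIZE, d)),
            "pair_embed": rng.normal(0.0, 0.02, size=(2, d)),
            "lstm": _lstm_params(rng, d),
            "conv": {"W": rng.normal(0.0, 0.02, size=(k, d, d)), "b": np.zeros(d)},
            "conv_ln": _ln_params(d),
            "layers": [
                {
                    "self_attn": _attn_params(rng, d),
                    "self_ln": _ln_params(d),
                    "cross_attn": _attn_params(rng, d),
                    "cross_ln": _ln_params(d),
                    "ffn": _ffn_params(rng, d, config.ffn_mult),
                    "ffn_ln": _ln_params(d),
                }
                for _ in range(config.decoder_layers)
            ],
            "final_ln": _ln_params(d),
            "out": _linear_params(rng, d, N_ACTIONS),
        },
    }
    return params


def parameter_count(params: dict) -> int:
    total = 0
    stack = [params]
    while stack:
        node = stack.pop()
        if isinstance(node, dict):
            stack.extend(node.values())
        elif isinstance(node, list):
            stack.extend(node)
        else:
            total += int(np.size(node))
    return total


# ---------------------------------------------------------------------------
# Forward primitives (autograd-differentiable)

def _layer_norm(x, p, eps: float = 1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps) * p["g"] + p["b"]


def _linear(x, p):
    return anp.matmul(x, p["W"]) + p["b"]


def _softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def _lstm_cell(x_t, h, c, p):
    z = anp.matmul(x_t, p["Wx"]) + anp.matmul(h, p["Wh"]) + p["b"]
    d = z.shape[-1] // 4
    i = _sigmoid(z[..., :d])
    f = _sigmoid(z[..., d : 2 * d])
    g = anp.tanh(z[..., 2 * d : 3 * d])
    o = _sigmoid(z[..., 3 * d :])
    c_new = f * c + i * g
    h_new = o * anp.tanh(c_new)
    return h_new, c_new


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def _lstm(x, p):
    """Unidirectional LSTM over axis 1 of ``x`` with shape (B, T, D)."""
    B, T, D = x.shape[0], x.shape[1], x.shape[2]
    h = anp.zeros((B, D))
    c = anp.zeros((B, D))
    outs = []
    for t in range(T):
        h, c = _lstm_cell(x[:, t, :], h, c, p)
        outs.append(h)
    return anp.stack(outs, axis=1)


def _conv1d(x, p, causal: bool):
    """Kernel-K 1-D convolution over axis 1; 'same' or left-only padding."""
    K = p["W"].shape[0]
    B, T, D = x.shape[0], x.shape[1], x.shape[2]
    if causal:
        pad_left, pad_right = K - 1, 0
    else:
        pad_left = pad_right = (K - 1) // 2
    zeros_l = anp.zeros((B, pad_left, D))
    zeros_r = anp.zeros((B, pad_right, D))
    xp = anp.concatenate([zeros_l, x, zeros_r], axis=1)
    out = p["b"]
    for k in range(K):
        out = out + anp.matmul(xp[:, k : k + T, :], p["W"][k])
    return out


_NEG_INF = -1e9


def _mha(q_in, kv_in, p, n_heads: int, mask=None):
    """Multi-head attention.  ``mask`` is additive, broadcast to (Tq, Tk)."""
    B, Tq, D = q_in.shape[0], q_in.shape[1], q_in.shape[2]
    Tk = kv_in.shape[1]
    hd = D // n_heads

    def split(x, T):
        return anp.transpose(anp.reshape(x, (B, T, n_heads, hd)), (0, 2, 1, 3))

    q = split(_linear(q_in, p["Wq"]), Tq)
    k = split(_linear(kv_in, p["Wk"]), Tk)
    v = split(_linear(kv_in, p["Wv"]), Tk)
    scores = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / anp.sqrt(float(hd))
    if mask is not None:
        scores = scores + mask
    attn = _softmax(scores, axis=-1)
    out = anp.matmul(attn, v)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, Tq, D))
    return _linear(out, p["Wo"])


def _ffn(x, p):
    return _linear(anp.maximum(_linear(x, p["fc1"]), 0.0), p["fc2"])


def causal_mask(T: int) -> np.ndarray:
    """Additive square causal mask: position t may attend to s <= t."""
    m = np.zeros((T, T))
    m[np.triu_indices(T, k=1)] = _NEG_INF
    return m


# ---------------------------------------------------------------------------
# Encoder / decoder forward passes

def encode(params: dict, tokens: np.ndarray, contacts: np.ndarray, n_heads: int):
    """Encoder forward: (B, L) token ids + (B, L, L) contacts -> (B, L, D)."""
    tokens = np.atleast_2d(np.asarray(tokens))
    contacts = np.asarray(contacts, dtype=float)
    if contacts.ndim == 2:
        contacts = contacts[None, :, :]
    if tokens.shape[1] != contacts.shape[1] or contacts.shape[1] != contacts.shape[2]:
        raise ValueError("token length and contact matrix size disagree")
    p = params["enc"]
    h = p["embed"][tokens]
    h = h + _lstm(h, p["lstm"])
    h = _layer_norm(h + _conv1d(h, p["conv"], causal=False), p["conv_ln"])
    if p["gcn"]:
        # symmetric row-normalized propagation with self-loops
        L = contacts.shape[1]
        a_hat = contacts + np.eye(L)
        a_hat = a_hat / a_hat.sum(axis=-1, keepdims=True)
        for gp in p["gcn"]:
            h = h + anp.maximum(_linear(anp.matmul(a_hat, h), gp), 0.0)
    for layer in p["layers"]:
        h = h + _mha(_layer_norm(h, layer["attn_ln"]), _layer_norm(h, layer["attn_ln"]),
                     layer["attn"], n_heads)
        h = h + _ffn(_layer_norm(h, layer["ffn_ln"]), layer["ffn"])
    return _layer_norm(h, p["final_ln"])


def decode_full(
    params: dict,
    prefix_tokens: np.ndarray,
    paired_flags: np.ndarray,
    context,
    n_heads: int,
):
    """Full decoder forward: (B, T) shifted tokens -> (B, T, 4) Q-value grid.

    ``prefix_tokens`` must begin with START; ``paired_flags[t]`` is the
    paired/unpaired flag of the *output* position t (the position whose
    action values row t carries).  Row t depends only on tokens 0..t thanks
    to the causal convolution, the causal self-attention mask, and the
    left-to-right LSTM.
    """
    prefix_tokens = np.atleast_2d(np.asarray(prefix_tokens))
    paired_flags = np.atleast_2d(np.asarray(paired_flags))
    if np.any(prefix_tokens[:, 0] != START_TOKEN):
        raise ValueError("decoder prefix must begin with the START token")
    if paired_flags.shape != prefix_tokens.shape:
        raise ValueError("paired_flags must match prefix shape")
    p = params["dec"]
    T = prefix_tokens.shape[1]
    h = p["embed"][prefix_tokens] + p["pair_embed"][paired_flags]
    h = h + _lstm(h, p["lstm"])
    h = _layer_norm(h + _conv1d(h, p["conv"], causal=True), p["conv_ln"])
    mask = causal_mask(T)
    for layer in p["layers"]:
        hn = _layer_norm(h, layer["self_ln"])
        h = h + _mha(hn, hn, layer["self_attn"], n_heads, mask=mask)
        h = h + _mha(_layer_norm(h, layer["cross_ln"]), context, layer["cross_attn"], n_heads)
        h = h + _ffn(_layer_norm(h, layer["ffn_ln"]), layer["ffn"])
    h = _layer_norm(h, p["final_ln"])
    return _linear(h, p["out"])


# ---------------------------------------------------------------------------
# Incremental (KV-cached) decoding

class DecoderCache:
    """Incremental decoding state for one context.

    Holds the LSTM carry, the causal-convolution input window, per-layer
    self-attention key/value histories, and the cross-attention keys/values
    (computed once from the encoder context).
    """

    def __init__(self, params: dict, context: np.ndarray, n_heads: int) -> None:
        self.params = params
        self.n_heads = n_heads
        self.context = np.asarray(context)
        if self.context.ndim == 2:
            self.context = self.context[None]
        p = params["dec"]
        d = p["embed"].shape[1]
        B = self.context.shape[0]
        self.lstm_h = np.zeros((B, d))
        self.lstm_c = np.zeros((B, d))
        self.conv_window: list[np.ndarray] = []  # last K-1 conv inputs
        self.self_k: list[list[np.ndarray]] = [[] for _ in p["layers"]]
        self.self_v: list[list[np.ndarray]] = [[] for _ in p["layers"]]
        hd = d // n_heads
        self.cross_k = []
        self.cross_v = []
        L = self.context.shape[1]
        for layer in p["layers"]:
            k = _linear(self.context, layer["cross_attn"]["Wk"])
            v = _linear(self.context, layer["cross_attn"]["Wv"])
            self.cross_k.append(np.transpose(k.reshape(B, L, n_heads, hd), (0, 2, 1, 3)))
            self.cross_v.append(np.transpose(v.reshape(B, L, n_heads, hd), (0, 2, 1, 3)))
        self.t = 0

    def copy(self) -> "DecoderCache":
        new = object.__new__(DecoderCache)
        new.params = self.params
        new.n_heads = self.n_heads
        new.context = self.context
        new.lstm_h = self.lstm_h.copy()
        new.lstm_c = self.lstm_c.copy()
        new.conv_window = list(self.conv_window)
        new.self_k = [list(ks) for ks in self.self_k]
        new.self_v = [list(vs) for vs in self.self_v]
        new.cross_k = self.cross_k
        new.cross_v = self.cross_v
        new.t = self.t
        return new


def init_cache(params: dict, context: np.ndarray, n_heads: int) -> DecoderCache:
    return DecoderCache(params, context, n_heads)


def decode_step(cache: DecoderCache, token: int, paired_flag: int):
    """Advance one position; returns the 4-vector of action values.

    ``token`` is the decoder input at this step (START first, then the
    previously chosen base) and ``paired_flag`` the flag of the position
    being predicted.  Stepwise decoding over a full prefix reproduces
    :func:`decode_full` exactly.
    """
    p = cache.params["dec"]
    n_heads = cache.n_heads
    B = cache.context.shape[0]
    d = p["embed"].shape[1]
    hd = d // n_heads
    K = p["conv"]["W"].shape[0]

    x = np.broadcast_to(p["embed"][token] + p["pair_embed"][paired_flag], (B, d))
    cache.lstm_h, cache.lstm_c = _lstm_cell(x, cache.lstm_h, cache.lstm_c, p["lstm"])
    h = x + cache.lstm_h

    # causal convolution over the last K inputs (missing history = zeros)
    cache.conv_window.append(h)
    window = cache.conv_window[-K:]
    conv = p["conv"]["b"]
    for k_idx in range(K):
        src = K - 1 - k_idx  # offset from the newest element
        if src < len(window):
            conv = conv + window[len(window) - 1 - src] @ p["conv"]["W"][k_idx]
    h = _layer_norm(h + conv, p["conv_ln"])

    for li, layer in enumerate(p["layers"]):
        hn = _layer_norm(h, layer["self_ln"])
        q = (_linear(hn, layer["self_attn"]["Wq"])).reshape(B, n_heads, 1, hd)
        k_new = (_linear(hn, layer["self_attn"]["Wk"])).reshape(B, n_heads, 1, hd)
        v_new = (_linear(hn, layer["self_attn"]["Wv"])).reshape(B, n_heads, 1, hd)
        cache.self_k[li].append(k_new)
        cache.self_v[li].append(v_new)
        k_all = np.concatenate(cache.self_k[li], axis=2)
        v_all = np.concatenate(cache.self_v[li], axis=2)
        scores = np.matmul(q, np.transpose(k_all, (0, 1, 3, 2))) / np.sqrt(float(hd))
        attn = _softmax(scores, axis=-1)
        out = np.matmul(attn, v_all).reshape(B, d)
        h = h + _linear(out, layer["self_attn"]["Wo"])

        hc = _layer_norm(h, layer["cross_ln"])
        qc = (_linear(hc, layer["cross_attn"]["Wq"])).reshape(B, n_heads, 1, hd)
        scores = np.matmul(qc, np.transpose(cache.cross_k[li], (0, 1, 3, 2))) / np.sqrt(
            float(hd)
        )
        attn = _softmax(scores, axis=-1)
        out = np.matmul(attn, cache.cross_v[li]).reshape(B, d)
        h = h + _linear(out, layer["cross_attn"]["Wo"])

        h = h + _ffn(_layer_norm(h, layer["ffn_ln"]), layer["ffn"])

    h = _layer_norm(h, p["final_ln"])
    cache.t += 1
    return _linear(h, p["out"])


# ---------------------------------------------------------------------------
# Network facade and checkpoints

CHECKPOINT_VERSION = 1


class QNetwork:
    """Config + parameters with convenience forwards."""

    def __init__(self, config: QNetworkConfig, params: dict | None = None) -> None:
        self.config = config
        self.params = params if params is not None else init_params(config)

    def encode(self, tokens, contacts):
        return encode(self.params, tokens, contacts, self.config.attention_heads)

    def encode_structure(self, structure) -> np.ndarray:
        """Encode a SecondaryStructure directly (single item, no batch dim)."""
        from .structures import contact_matrix, render_dotbracket

        tokens = tokenize_structure(render_dotbracket(structure))
        return self.encode(tokens[None, :], contact_matrix(structure)[None])[0]

    def decode_full(self, prefix_tokens, paired_flags, context):
        return decode_full(
            self.params, prefix_tokens, paired_flags, context, self.config.attention_heads
        )

    def init_cache(self, context) -> DecoderCache:
        return init_cache(self.params, context, self.config.attention_heads)

    def parameter_count(self) -> int:
        return parameter_count(self.params)

    def copy(self) -> "QNetwork":
        return QNetwork(self.config, _tree_copy(self.params))

    def save(self, path: str) -> None:
        flat = dict(_tree_flatten(self.params, "p"))
        np.savez(
            path,
            __config__=json.dumps({"version": CHECKPOINT_VERSION, **asdict(self.config)}),
            **flat,
        )

    @classmethod
    def load(cls, path: str, expected_config: QNetworkConfig | None = None) -> "QNetwork":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__config__"]))
            version = meta.pop("version")
            if version != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {version}")
            config = QNetworkConfig(**meta)
            if expected_config is not None and config != expected_config:
                raise ValueError("checkpoint config does not match the expected config")
            flat = {k: data[k] for k in data.files if k != "__config__"}
        template = init_params(config)
        params = _tree_unflatten(template, flat, "p")
        return cls(config, params)


def tokenize_structure(dotbracket: str) -> np.ndarray:
    try:
        return np.array([STRUCT_TOKEN[ch] for ch in dotbracket], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown structure character {exc.args[0]!r}") from exc


def tokenize_sequence(sequence: str) -> np.ndarray:
    try:
        return np.array([BASE_TOKEN[b] for b in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown base {exc.args[0]!r}") from exc


def _tree_copy(node):
    if isinstance(node, dict):
        return {k: _tree_copy(v) for k, v in node.items()}
    if isinstance(node, list):
        return [_tree_copy(v) for v in node]
    return np.array(node, copy=True)


def _tree_flatten(node, prefix: str):
    if isinstance(node, dict):
        for k, v in node.items():
            yield from _tree_flatten(v, f"{prefix}.{k}")
    elif isinstance(node, list):
        for i, v in enumerate(node):
            yield from _tree_flatten(v, f"{prefix}.{i}")
    else:
        yield prefix, node


def _tree_unflatten(template, flat: dict, prefix: str):
    if isinstance(template, dict):
        return {k: _tree_unflatten(v, flat, f"{prefix}.{k}") for k, v in template.items()}
    if isinstance(template, list):
        return [_tree_unflatten(v, flat, f"{prefix}.{i}") for i, v in enumerate(template)]
    return flat[prefix]
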