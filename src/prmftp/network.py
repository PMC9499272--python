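"""The forward model: embedding -> multi-scale CNN -> BiLSTM -> multi-head
self-attention -> sigmoid classification, plus its functional attention
primitives and an Adam optimizer.

The architecture scores a peptide against M function classes independently
(multi-label).  Tokens 1..20 index the standard amino acids, token 0 pads
short sequences to the fixed length L; the pad embedding is frozen at zero
and no attention mask is applied.  Ablation flags (`use_cnn`, `use_bilstm`,
`use_mhsa`) drop one block each while keeping the rest of the path intact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor, concat, stack

__all__ = [
    "ModelConfig",
    "AttentionParams",
    "PeptideNetwork",
    "Adam",
    "self_attention",
    "multi_head_self_attention",
    "predict_labels",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are full scale; :meth:`small` returns a desk-scale configuration
    for CPU experiments and the test suite.
    """

    n_labels: int
    seq_len: int = 50
    vocab_size: int = 21  # 20 amino acids + pad
    embed_dim: int = 128
    kernel_sizes: tuple[int, ...] = (2, 3, 8)
    filters_per_kernel: int = 64
    pool_size: int = 2
    recurrent_hidden: int = 64
    heads: int = 8
    key_dim: int = 16
    dropout: float = 0.5
    use_cnn: bool = True
    use_bilstm: bool = True
    use_mhsa: bool = True

    def __post_init__(self):
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if any(k > self.seq_len for k in self.kernel_sizes):
            raise ValueError("kernel sizes must not exceed the sequence length")

    @property
    def conv_dim(self) -> int:
        """Feature width after the (optional) multi-scale CNN block."""
        if self.use_cnn:
            return len(self.kernel_sizes) * self.filters_per_kernel
        return self.embed_dim

    @property
    def d_m(self) -> int:
        """Feature width entering attention: twice the BiLSTM hidden size, or
        the CNN/embedding width when the BiLSTM is ablated."""
        if self.use_bilstm:
            return 2 * self.recurrent_hidden
        return self.conv_dim

    @classmethod
    def small(cls, n_labels: int, **overrides) -> "ModelConfig":
        """Desk-scale configuration: same topology, narrow layers."""
        base = dict(
            n_labels=n_labels, embed_dim=20, filters_per_kernel=16,
            recurrent_hidden=24, heads=4, key_dim=12, dropout=0.5,
        )
        base.update(overrides)
        return cls(**base)

    def variant(self, name: str) -> "ModelConfig":
        """Ablation variant dropping one architecture block."""
        flags = {"no_cnn": "use_cnn", "no_bilstm": "use_bilstm", "no_mhsa": "use_mhsa"}
        if name not in flags:
            raise ValueError(f"unknown variant {name!r}; options: {sorted(flags)}")
        return replace(self, **{flags[name]: False})


@dataclass
class AttentionParams:
    """Per-head projection matrices and the output projection.

    w_q, w_k, w_v each hold h matrices of shape (d_m, d_k); w_o maps the
    concatenated heads (h*d_k) back to d_m.
    """

    w_q: list[np.ndarray]
    w_k: list[np.ndarray]
    w_v: list[np.ndarray]
    w_o: np.ndarray

    def __post_init__(self):
        h = len(self.w_q)
        if not (len(self.w_k) == len(self.w_v) == h):
            raise ValueError("head counts of w_q/w_k/w_v disagree")
        dm, dk = self.w_q[0].shape
        for mats in (self.w_q, self.w_k, self.w_v):
            for w in mats:
                if w.shape != (dm, dk):
                    raise ValueError("inconsistent head projection shapes")
        if self.w_o.shape != (h * dk, dm):
            raise ValueError(
                f"w_o must be ({h * dk}, {dm}) to map concatenated heads back to d_m"
            )


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def self_attention(f: np.ndarray, w_q: np.ndarray, w_k: np.ndarray, w_v: np.ndarray) -> np.ndarray:
    """Scaled dot-product self-attention for one head.

    ``softmax(Q K^T / sqrt(d_k)) V`` with Q = F W^Q, K = F W^K, V = F W^V;
    F is L x d_m, the result L x d_k.
    """
    f = np.asarray(f, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValueError("attention input contains non-finite values")
    q, k, v = f @ w_q, f @ w_k, f @ w_v
    dk = w_q.shape[1]
    return _softmax_rows(q @ k.T / np.sqrt(dk)) @ v


def multi_head_self_attention(f: np.ndarray, params: AttentionParams) -> np.ndarray:
    """h attention heads, concatenated and projected back to d_m."""
    heads = [
        self_attention(f, wq, wk, wv)
        for wq, wk, wv in zip(params.w_q, params.w_k, params.w_v)
    ]
    return np.concatenate(heads, axis=1) @ params.w_o


def predict_labels(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize per-class probabilities at the decision threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    probs = np.asarray(probs, dtype=np.float64)
    return (probs >= threshold).astype(np.int64)


# ---------------------------------------------------------------------------
# The trainable network
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class PeptideNetwork:
    """Trainable multi-label peptide classifier.

    Parameters live in ``self.params`` (name -> autodiff Tensor).  The pad
    embedding row is frozen at zero: :meth:`mask_frozen_grads` must run after
    each backward pass (the trainer does this).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}

        emb = rng.normal(0.0, 0.1, size=(config.vocab_size, config.embed_dim))
        emb[0] = 0.0
        p["embed"] = Tensor(emb, requires_grad=True)

        if config.use_cnn:
            for k in config.kernel_sizes:
                p[f"conv{k}_w"] = Tensor(
                    _glorot(rng, (k * config.embed_dim, config.filters_per_kernel)),
                    requires_grad=True,
                )
                p[f"conv{k}_b"] = Tensor(
                    np.zeros(config.filters_per_kernel), requires_grad=True
                )

        if config.use_bilstm:
            h = config.recurrent_hidden
            for d in ("fwd", "bwd"):
                p[f"lstm_{d}_wx"] = Tensor(
                    _glorot(rng, (config.conv_dim, 4 * h)), requires_grad=True
                )
                p[f"lstm_{d}_wh"] = Tensor(_glorot(rng, (h, 4 * h)), requires_grad=True)
                b = np.zeros(4 * h)
                b[h : 2 * h] = 1.0  # forget-gate bias
                p[f"lstm_{d}_b"] = Tensor(b, requires_grad=True)

        if config.use_mhsa:
            dm, dk = config.d_m, config.key_dim
            for i in range(config.heads):
                p[f"att{i}_wq"] = Tensor(_glorot(rng, (dm, dk)), requires_grad=True)
                p[f"att{i}_wk"] = Tensor(_glorot(rng, (dm, dk)), requires_grad=True)
                p[f"att{i}_wv"] = Tensor(_glorot(rng, (dm, dk)), requires_grad=True)
            p["att_wo"] = Tensor(
                _glorot(rng, (config.heads * dk, dm)), requires_grad=True
            )

        p["dense_w"] = Tensor(_glorot(rng, (config.d_m, config.n_labels)), requires_grad=True)
        p["dense_b"] = Tensor(np.zeros(config.n_labels), requires_grad=True)
        self.params = p

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grads(self) -> None:
        for t in self.params.values():
            t.grad = None

    def mask_frozen_grads(self) -> None:
        """Zero the pad-row embedding gradient so the pad stays a zero vector."""
        g = self.params["embed"].grad
        if g is not None:
            g[0] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    # -- forward --------------------------------------------------------------

    def _bilstm(self, x: Tensor) -> Tensor:
        cfg = self.config
        h = cfg.recurrent_hidden
        n, length, din = x.shape
        outs = []
        for d in ("fwd", "bwd"):
            wx, wh, b = (self.params[f"lstm_{d}_{s}"] for s in ("wx", "wh", "b"))
            # project the whole sequence against Wx in one matmul
            xp = (x.reshape(n * length, din) @ wx + b).reshape(n, length, 4 * h)
            hs: list[Tensor | None] = [None] * length
            ht = Tensor(np.zeros((n, h)))
            ct = Tensor(np.zeros((n, h)))
            steps = range(length) if d == "fwd" else range(length - 1, -1, -1)
            for t in steps:
                gates = xp[:, t, :] + ht @ wh
                i_g = gates[:, :h].sigmoid()
                f_g = gates[:, h : 2 * h].sigmoid()
                g_g = gates[:, 2 * h : 3 * h].tanh()
                o_g = gates[:, 3 * h :].sigmoid()
                ct = f_g * ct + i_g * g_g
                ht = o_g * ct.tanh()
                hs[t] = ht
            outs.append(stack(hs, axis=1))
        return concat(outs, axis=2)

    def _mhsa(self, x: Tensor) -> Tensor:
        cfg = self.config
        scale = 1.0 / np.sqrt(cfg.key_dim)
        heads = []
        for i in range(cfg.heads):
            q = x @ self.params[f"att{i}_wq"]
            k = x @ self.params[f"att{i}_wk"]
            v = x @ self.params[f"att{i}_wv"]
            att = ((q @ k.swapaxes(1, 2)) * scale).softmax()
            heads.append(att @ v)
        return concat(heads, axis=2) @ self.params["att_wo"]

    def forward(
        self,
        tokens: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Probabilities (N x M Tensor, entries strictly in (0,1))."""
        cfg = self.config
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim != 2:
            raise ValueError("tokens must be an N x L integer matrix")
        if tokens.min() < 0 or tokens.max() >= cfg.vocab_size:
            raise ValueError(
                f"token out of range 0..{cfg.vocab_size - 1}: "
                f"found {int(tokens.min())}..{int(tokens.max())}"
            )
        x = Tensor.embedding(self.params["embed"], tokens)  # (N, L, E)
        if cfg.use_cnn:
            branches = []
            for k in cfg.kernel_sizes:
                b = x.conv1d_same(self.params[f"conv{k}_w"], self.params[f"conv{k}_b"], k)
                branches.append(b.relu().maxpool1d(cfg.pool_size))
            x = concat(branches, axis=2)  # (N, L', 3*filters)
        if cfg.use_bilstm:
            x = self._bilstm(x)  # (N, L', d_m)
        if cfg.use_mhsa:
            x = self._mhsa(x)  # (N, L', d_m)
        x = x.max(axis=1)  # global max pool over positions -> (N, d_m)
        if training and cfg.dropout > 0:
            if dropout_rng is None:
                raise ValueError("training with dropout needs a dropout_rng")
            keep = dropout_rng.random(x.shape) >= cfg.dropout
            x = x * (keep / (1.0 - cfg.dropout))
        logits = x @ self.params["dense_w"] + self.params["dense_b"]
        return logits.sigmoid()

    def predict_proba(self, tokens: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference without building a gradient tape."""
        flags = [(t, t.requires_grad) for t in self.parameters()]
        for t, _ in flags:
            t.requires_grad = False
        try:
            chunks = [
                self.forward(tokens[i : i + batch_size]).data
                for i in range(0, len(tokens), batch_size)
            ]
        finally:
            for t, was in flags:
                t.requires_grad = was
        return np.concatenate(chunks, axis=0)


class Adam:
    """Adam optimizer over a network's parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in params]
        self.v = [np.zeros_like(t.data) for t in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
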