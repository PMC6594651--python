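"""The drug-target interaction network.

Architecture: a trainable residue embedding feeds parallel 1-D convolutions,
one bank of filters per window size, whose outputs are globally max-pooled
(per filter, over valid sequence positions only) into a position-invariant
protein feature vector of dimension filters x windows. That vector passes
through fully connected layers; the drug's binary Morgan fingerprint passes
through its own fully connected stack; the two latent vectors are
concatenated and mapped through joint dense layers to a sigmoid interaction
probability. Hidden layers use batch-norm then ELU; the embedding layer is
regularised by 1-D spatial dropout (whole channels) instead of batch-norm.

Training minimises binary cross-entropy plus an L2 penalty on dense and
convolution kernels, optimised with Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..encoding import DEFAULT_MPL, DEFAULT_VOCABULARY, EncodedProtein, Vocabulary
from .layers import (
    BatchNorm,
    Dense,
    Dropout,
    ELU,
    Embedding,
    MaskedGlobalMaxPool,
    Param,
    WindowConv1D,
)

PROB_CLIP = 1e-7


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: alpha*(e^x - 1) for x < 0, x otherwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, alpha * np.expm1(x))
    return out.item() if out.ndim == 0 else out


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def bce_loss(probabilities, labels, clip: float = PROB_CLIP) -> float:
    """Mean binary cross-entropy, with probabilities clipped away from {0,1}."""
    p = np.clip(np.asarray(probabilities, dtype=float), clip, 1.0 - clip)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``window_sizes`` are the residue spans of the convolution filter banks;
    each bank holds ``filters_per_window`` filters, so the pooled protein
    feature has dimension ``filters_per_window * len(window_sizes)``.
    ``mask_padding`` restricts global max-pooling to windows lying entirely
    within the true sequence (recommended); disabling it reproduces the
    bare pool-over-everything variant. ``conv_bias`` toggles per-filter bias
    terms (off gives the pure double-sum convolution).
    """

    window_sizes: tuple[int, ...] = (8, 16, 24)
    filters_per_window: int = 128
    embedding_size: int = 20
    mpl: int = DEFAULT_MPL
    protein_dense_sizes: tuple[int, ...] = (128,)
    drug_dense_sizes: tuple[int, ...] = (128,)
    joint_dense_sizes: tuple[int, ...] = (64,)
    fingerprint_bits: int = 2048
    elu_alpha: float = 1.0
    l2_lambda: float = 1e-6
    spatial_dropout_rate: float = 0.1
    dense_dropout_rate: float = 0.1
    learning_rate: float = 0.0001
    batch_size: int = 32
    epochs: int = 10
    mask_padding: bool = True
    conv_bias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_sizes", tuple(sorted(self.window_sizes)))
        object.__setattr__(self, "protein_dense_sizes", tuple(self.protein_dense_sizes))
        object.__setattr__(self, "drug_dense_sizes", tuple(self.drug_dense_sizes))
        object.__setattr__(self, "joint_dense_sizes", tuple(self.joint_dense_sizes))
        if not self.window_sizes:
            raise ValueError("window_sizes must be non-empty")
        sizes = (self.filters_per_window, self.embedding_size, self.mpl,
                 self.fingerprint_bits, self.batch_size,
                 *self.protein_dense_sizes, *self.drug_dense_sizes,
                 *self.joint_dense_sizes, *self.window_sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("all sizes must be positive")
        for r in (self.spatial_dropout_rate, self.dense_dropout_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.mpl < max(self.window_sizes):
            raise ValueError("mpl must be >= the largest window size")

    @property
    def n_pooled_features(self) -> int:
        return self.filters_per_window * len(self.window_sizes)

    def parameter_count(self, vocab_size: int = DEFAULT_VOCABULARY.size) -> int:
        n = vocab_size * self.embedding_size
        for ws in self.window_sizes:
            n += self.embedding_size * ws * self.filters_per_window
            if self.conv_bias:
                n += self.filters_per_window
        def dense_chain(n_in, sizes):
            c = 0
            for s in sizes:
                c += n_in * s + s + 2 * s  # W, b, batch-norm gamma/beta
                n_in = s
            return c, n_in
        c, _ = dense_chain(self.n_pooled_features, self.protein_dense_sizes)
        n += c + 2 * self.n_pooled_features
        c, _ = dense_chain(self.fingerprint_bits, self.drug_dense_sizes)
        n += c
        p_out = (self.protein_dense_sizes or (self.n_pooled_features,))[-1]
        d_out = (self.drug_dense_sizes or (self.fingerprint_bits,))[-1]
        c, last = dense_chain(p_out + d_out, self.joint_dense_sizes)
        n += c + last + 1
        return n


@dataclass
class ForwardTrace:
    """Everything the forward pass exposes for one drug-protein pair."""

    probability: float
    pooled: dict[int, np.ndarray]
    argmax_start: dict[int, np.ndarray]  # 1-based window starts; -1 if no valid window
    protein_latent: np.ndarray
    drug_latent: np.ndarray


@dataclass
class ModelState:
    """Serializable parameter snapshot: config + all trainable arrays +
    batch-norm running statistics + optional classification threshold."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    running: dict[str, np.ndarray]
    vocabulary: Vocabulary = field(default_factory=lambda: DEFAULT_VOCABULARY)
    threshold: float | None = None

    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "tokens": list(self.vocabulary.tokens),
            "threshold": self.threshold,
        }
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        arrays.update({f"running:{k}": v for k, v in self.running.items()})
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k[6:]: data[k] for k in data.files if k.startswith("param:")}
            running = {k[8:]: data[k] for k in data.files if k.startswith("running:")}
        cfg = meta["config"]
        for key in ("window_sizes", "protein_dense_sizes", "drug_dense_sizes",
                    "joint_dense_sizes"):
            cfg[key] = tuple(cfg[key])
        return cls(ModelConfig(**cfg), params, running,
                   Vocabulary(tuple(meta["tokens"])), meta["threshold"])


class _DenseBlock:
    """Dense -> batch-norm -> ELU, the hidden-layer unit used everywhere."""

    def __init__(self, n_in, n_out, alpha, rng, name):
        self.dense = Dense(n_in, n_out, rng, name)
        self.bn = BatchNorm(n_out, f"{name}.bn")
        self.act = ELU(alpha)

    def params(self):
        return self.dense.params() + self.bn.params()

    def forward(self, x, training):
        return self.act.forward(self.bn.forward(self.dense.forward(x), training))

    def backward(self, g):
        return self.dense.backward(self.bn.backward(self.act.backward(g)))


class DTIModel:
    """The convolutional drug-target interaction classifier."""

    def __init__(self, config: ModelConfig, vocabulary: Vocabulary = DEFAULT_VOCABULARY):
        self.config = config
        self.vocabulary = vocabulary
        self.threshold: float | None = None
        rng = np.random.default_rng(config.seed)
        c = config
        self.embedding = Embedding(vocabulary.size, c.embedding_size, rng, "emb")
        self.convs = {
            ws: WindowConv1D(c.embedding_size, ws, c.filters_per_window, rng,
                             f"conv{ws}", bias=c.conv_bias)
            for ws in c.window_sizes
        }
        self.pools = {ws: MaskedGlobalMaxPool() for ws in c.window_sizes}
        self.pool_bn = BatchNorm(c.n_pooled_features, "pool.bn")
        self.pool_act = ELU(c.elu_alpha)
        self.protein_blocks: list[_DenseBlock] = []
        n_in = c.n_pooled_features
        for i, s in enumerate(c.protein_dense_sizes):
            self.protein_blocks.append(_DenseBlock(n_in, s, c.elu_alpha, rng, f"prot{i}"))
            n_in = s
        p_out = n_in
        self.drug_blocks: list[_DenseBlock] = []
        n_in = c.fingerprint_bits
        for i, s in enumerate(c.drug_dense_sizes):
            self.drug_blocks.append(_DenseBlock(n_in, s, c.elu_alpha, rng, f"drug{i}"))
            n_in = s
        d_out = n_in
        self.joint_blocks: list[_DenseBlock] = []
        self.joint_dropouts: list[Dropout] = []
        n_in = p_out + d_out
        for i, s in enumerate(c.joint_dense_sizes):
            self.joint_blocks.append(_DenseBlock(n_in, s, c.elu_alpha, rng, f"joint{i}"))
            self.joint_dropouts.append(Dropout(c.dense_dropout_rate))
            n_in = s
        self.output = Dense(n_in, 1, rng, "out")
        self._p_out = p_out
        self._cache: dict = {}

    # -- parameters --------------------------------------------------------

    def params(self) -> list[Param]:
        out = self.embedding.params()
        for ws in self.config.window_sizes:
            out += self.convs[ws].params()
        out += self.pool_bn.params()
        for blk in self.protein_blocks + self.drug_blocks + self.joint_blocks:
            out += blk.params()
        out += self.output.params()
        return out

    def _batch_norms(self) -> list[BatchNorm]:
        bns = [self.pool_bn]
        bns += [blk.bn for blk in self.protein_blocks + self.drug_blocks + self.joint_blocks]
        return bns

    def l2_penalty(self) -> float:
        lam = self.config.l2_lambda
        if lam == 0:
            return 0.0
        return lam * sum(float(np.sum(p.value ** 2))
                         for p in self.params() if p.weight_decay)

    def penalized_loss(self, probabilities, labels) -> float:
        return bce_loss(probabilities, labels) + self.l2_penalty()

    # -- forward / backward ------------------------------------------------

    def _protein_trunk_conv(self, labels: np.ndarray, lengths: np.ndarray,
                            training: bool, rng: np.random.Generator | None):
        """Embedding (+ spatial dropout) -> conv -> masked pool, per window."""
        c = self.config
        # padding invariance lets us trim the batch to its longest sequence
        l_eff = int(max(lengths.max(), max(c.window_sizes)))
        l_eff = min(l_eff, labels.shape[1])
        labels = labels[:, :l_eff]
        e = self.embedding.forward(labels)
        if training and c.spatial_dropout_rate > 0:
            keep = 1.0 - c.spatial_dropout_rate
            mask = (rng.random((e.shape[0], 1, c.embedding_size)) < keep) / keep
            e = e * mask
        else:
            mask = None
        pooled_parts, argmaxes = [], {}
        for ws in c.window_sizes:
            conv = self.convs[ws].forward(e)
            if c.mask_padding:
                n_valid = np.maximum(lengths - ws + 1, 0)
            else:
                n_valid = np.full(lengths.shape, conv.shape[1])
            pooled, arg = self.pools[ws].forward(conv, n_valid)
            pooled_parts.append(pooled)
            argmaxes[ws] = np.where(arg >= 0, arg + 1, -1)  # 1-based
        self._cache["sdrop_mask"] = mask
        return np.concatenate(pooled_parts, axis=1), argmaxes

    def forward_batch(self, labels: np.ndarray, lengths: np.ndarray,
                      fingerprints: np.ndarray, training: bool = False,
                      rng: np.random.Generator | None = None) -> dict:
        """Run the network on a batch; returns probabilities and trace parts.

        ``labels``: (B, MPL) int; ``lengths``: (B,); ``fingerprints``:
        (B, fingerprint_bits) binary. Caches activations for ``backward_batch``.
        """
        c = self.config
        pooled, argmaxes = self._protein_trunk_conv(labels, lengths, training, rng)
        h = self.pool_act.forward(self.pool_bn.forward(pooled, training))
        for blk in self.protein_blocks:
            h = blk.forward(h, training)
        d = np.asarray(fingerprints, dtype=np.float64)
        for blk in self.drug_blocks:
            d = blk.forward(d, training)
        z = np.concatenate([h, d], axis=1)
        for blk, drop in zip(self.joint_blocks, self.joint_dropouts):
            z = blk.forward(z, training)
            z = drop.forward(z, training, rng)
        logits = self.output.forward(z)[:, 0]
        probs = sigmoid(logits)
        self._cache.update(pooled=pooled, argmaxes=argmaxes,
                           protein_latent=h, drug_latent=d)
        return {
            "probability": probs,
            "logits": logits,
            "pooled": pooled,
            "argmax": argmaxes,
            "protein_latent": h,
            "drug_latent": d,
        }

    def backward_batch(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dlogits (shape (B,))."""
        g = self.output.backward(dlogits[:, None])
        for blk, drop in zip(reversed(self.joint_blocks), reversed(self.joint_dropouts)):
            g = blk.backward(drop.backward(g))
        gh, gd = g[:, :self._p_out], g[:, self._p_out:]
        for blk in reversed(self.drug_blocks):
            gd = blk.backward(gd)
        for blk in reversed(self.protein_blocks):
            gh = blk.backward(gh)
        gp = self.pool_bn.backward(self.pool_act.backward(gh))
        nf = self.config.filters_per_window
        ge = None
        for i, ws in enumerate(self.config.window_sizes):
            gconv = self.pools[ws].backward(gp[:, i * nf:(i + 1) * nf])
            gx = self.convs[ws].backward(gconv)
            ge = gx if ge is None else ge + gx
        mask = self._cache.get("sdrop_mask")
        if mask is not None:
            ge = ge * mask
        self.embedding.backward(ge)

    def add_l2_gradients(self) -> None:
        lam = self.config.l2_lambda
        if lam == 0:
            return
        for p in self.params():
            if p.weight_decay:
                p.grad += 2.0 * lam * p.value

    # -- single-pair / attribution interfaces ------------------------------

    def forward(self, protein: EncodedProtein, fingerprint: np.ndarray) -> ForwardTrace:
        """Inference on one pair, returning the full ForwardTrace."""
        out = self.forward_batch(protein.labels[None, :],
                                 np.array([protein.true_length]),
                                 np.asarray(fingerprint, dtype=float)[None, :],
                                 training=False)
        nf = self.config.filters_per_window
        pooled = {ws: out["pooled"][0, i * nf:(i + 1) * nf].copy()
                  for i, ws in enumerate(self.config.window_sizes)}
        return ForwardTrace(
            probability=float(out["probability"][0]),
            pooled=pooled,
            argmax_start={ws: a[0].copy() for ws, a in out["argmax"].items()},
            protein_latent=out["protein_latent"][0].copy(),
            drug_latent=out["drug_latent"][0].copy(),
        )

    def protein_conv_trace(self, protein: EncodedProtein) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Pooled values and 1-based argmax starts per window size for one
        protein — the drug-independent part of the trace used by attribution."""
        pooled, argmaxes = self._protein_trunk_conv(
            protein.labels[None, :], np.array([protein.true_length]),
            training=False, rng=None)
        nf = self.config.filters_per_window
        return {ws: (pooled[0, i * nf:(i + 1) * nf].copy(), argmaxes[ws][0].copy())
                for i, ws in enumerate(self.config.window_sizes)}

    def predict(self, labels: np.ndarray, lengths: np.ndarray,
                fingerprints: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        """Inference probabilities for many pairs, minibatched."""
        bs = batch_size or self.config.batch_size
        out = []
        for i in range(0, labels.shape[0], bs):
            out.append(self.forward_batch(labels[i:i + bs], lengths[i:i + bs],
                                          fingerprints[i:i + bs], training=False)
                       ["probability"])
        return np.concatenate(out)

    # -- state -------------------------------------------------------------

    def get_state(self) -> ModelState:
        params = {p.name: p.value.copy() for p in self.params()}
        running = {}
        for bn_name, bn in self._named_batch_norms():
            running[f"{bn_name}.mean"] = bn.running_mean.copy()
            running[f"{bn_name}.var"] = bn.running_var.copy()
        return ModelState(self.config, params, running, self.vocabulary, self.threshold)

    def set_state(self, state: ModelState) -> None:
        lookup = {p.name: p for p in self.params()}
        if set(lookup) != set(state.params):
            raise ValueError("parameter names in state do not match the model")
        for name, value in state.params.items():
            lookup[name].value = np.array(value, dtype=np.float64)
            lookup[name].grad = np.zeros_like(lookup[name].value)
        for bn_name, bn in self._named_batch_norms():
            bn.running_mean = np.array(state.running[f"{bn_name}.mean"])
            bn.running_var = np.array(state.running[f"{bn_name}.var"])
        self.threshold = state.threshold

    def _named_batch_norms(self):
        yield "pool.bn", self.pool_bn
        for prefix, blocks in (("prot", self.protein_blocks),
                               ("drug", self.drug_blocks),
                               ("joint", self.joint_blocks)):
            for i, blk in enumerate(blocks):
                yield f"{prefix}{i}.bn", blk.bn

    @classmethod
    def from_state(cls, state: ModelState) -> "DTIModel":
        model = cls(state.config, state.vocabulary)
        model.set_state(state)
        return model
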