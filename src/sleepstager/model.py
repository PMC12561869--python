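"""The multimodal multi-scale attention network for sleep staging.

Architecture, applied independently to every 30 s four-channel epoch
(EEG Fpz-Cz + Pz-Oz as one two-channel modality, EOG, EMG):

1.  Multi-scale feature extraction — per modality, two parallel 1-D
    convolution branches: a small kernel (50 samples, 0.5 s) for transient
    activity such as spindles, and a large kernel (400 samples, 4 s) for slow
    trends such as N3 delta waves.  Each branch is conv → batch norm →
    LeakyReLU → max pool → dropout; the two branch outputs are concatenated
    along the time axis.
2.  Squeeze-and-excitation channel attention per modality — feature channels
    are gated by sigmoid weights derived from their global time average.
3.  The three modality feature maps are concatenated along the feature axis
    and handed to a bidirectional LSTM; a learned attention pooling collapses
    the hidden-state sequence into one context vector.
4.  Dropout + a fully connected softmax layer produce the 5-class posterior
    (W, N1, N2, N3, REM).

Five ablation variants (single-scale convolution, EEG-only input, no SE
gating, no recurrence, no attention pooling) are built from the same
configuration via :func:`build_variant`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import DTYPE, BatchNorm1d, BiLSTM, Conv1d, Linear, Module, _uniform_fan_in

VARIANTS = ("full", "no_msconv", "eeg_only", "no_se", "no_lstm", "no_attn")

#: fixed channel layout of an epoch array (see preprocess.SleepEpochSet)
MODALITY_SLICES = {"eeg": slice(0, 2), "eog": slice(2, 3), "emg": slice(3, 4)}


@dataclass
class ModelConfig:
    """Every architecture hyperparameter, with the published defaults."""

    small_kernel: int = 50
    large_kernel: int = 400
    filters: int = 64
    small_stride: int = 6
    large_stride: int = 50
    small_pool: int = 8
    large_pool: int = 4
    conv_dropout: float = 0.5
    leaky_slope: float = 0.01
    se_reduction: int = 4
    lstm_hidden: int = 128
    attention_width: int = 128
    classifier_dropout: float = 0.5
    n_classes: int = 5
    n_samples: int = 3000
    seed: int = 0

    def __post_init__(self):
        if self.filters % self.se_reduction != 0:
            raise ValueError("se_reduction must divide filters")
        if max(self.small_kernel, self.large_kernel) >= self.n_samples:
            raise ValueError("kernels must be shorter than the epoch")

    def branch_length(self, kernel: int, stride: int, pool: int) -> int:
        conv_len = (self.n_samples - kernel) // stride + 1
        return conv_len // pool

    @property
    def seq_length(self) -> int:
        """Time steps after the dual-branch time-axis concatenation."""
        return (self.branch_length(self.small_kernel, self.small_stride,
                                   self.small_pool)
                + self.branch_length(self.large_kernel, self.large_stride,
                                     self.large_pool))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


# -- functional pieces (also used standalone in tests) ---------------------

def se_layer(x: Tensor, w1: Tensor, w2: Tensor) -> Tensor:
    """Squeeze-and-excitation gating on a (B, F, T) feature map.

    z_c is the global time average per channel, the excitation is
    ``s = sigmoid(W2 relu(W1 z))`` (no biases), and the output is ``X_c s_c``.
    """
    z = x.mean(axis=2)                              # (B, F)
    s = ad.sigmoid(ad.matmul(ad.relu(ad.matmul(z, w1)), w2))
    return x * ad.reshape(s, (s.shape[0], s.shape[1], 1))


def attention_pool(h: Tensor, w_h: Tensor, b_h: Tensor,
                   v: Tensor) -> tuple[Tensor, np.ndarray]:
    """Softmax attention pooling over time of a (B, T, D) sequence.

    Scores are ``v' tanh(W_h h_t + b_h)``; returns the context vector
    (B, D) and the attention weights as a plain array for inspection.
    """
    B, T, D = h.shape
    u = ad.tanh(ad.reshape(ad.matmul(ad.reshape(h, (-1, D)), w_h) + b_h,
                           (B, T, -1)))
    scores = ad.reshape(ad.matmul(ad.reshape(u, (-1, u.shape[2])),
                                  ad.reshape(v, (-1, 1))), (B, T))
    shift = Tensor(scores.data.max(axis=1, keepdims=True))
    e = ad.exp(scores - shift)
    alpha = e * ad.power(e.sum(axis=1, keepdims=True), -1.0)
    c = (h * ad.reshape(alpha, (B, T, 1))).sum(axis=1)
    return c, alpha.data.copy()


def cross_entropy_loss(logits: Tensor, labels: np.ndarray,
                       class_weights: np.ndarray | None = None) -> Tensor:
    """Batch-mean 5-class cross-entropy computed from logits.

    The log-sum-exp form never evaluates ``log`` of a normalized
    probability, so a confident wrong prediction cannot overflow.  With
    ``class_weights`` each sample is scaled by the weight of its true class.
    """
    return ad.softmax_cross_entropy(logits, labels, class_weights)


def inverse_frequency_weights(labels: np.ndarray, n_classes: int = 5,
                              ) -> np.ndarray:
    """w_k = N / (K * N_k); classes absent from ``labels`` get weight 0."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    w = np.zeros(n_classes)
    nz = counts > 0
    w[nz] = counts.sum() / (n_classes * counts[nz])
    return w


# -- modules ---------------------------------------------------------------

class ConvBranch(Module):
    """conv → batch norm → LeakyReLU → max pool → dropout."""

    def __init__(self, in_channels: int, cfg: ModelConfig, kernel: int,
                 stride: int, pool: int, rng: np.random.Generator):
        self.conv = Conv1d(in_channels, cfg.filters, kernel, stride, rng)
        self.bn = BatchNorm1d(cfg.filters)
        self.pool = pool
        self.dropout_p = cfg.conv_dropout
        self.slope = cfg.leaky_slope

    def forward(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        h = ad.leaky_relu(self.bn(self.conv(x)), self.slope)
        h = ad.maxpool1d(h, self.pool)
        return ad.dropout(h, self.dropout_p, rng, self.training)


class SELayer(Module):
    def __init__(self, n_features: int, reduction: int,
                 rng: np.random.Generator):
        hidden = n_features // reduction
        self.w1 = Tensor(_uniform_fan_in(rng, (n_features, hidden),
                                         n_features), requires_grad=True)
        self.w2 = Tensor(_uniform_fan_in(rng, (hidden, n_features), hidden),
                         requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return se_layer(x, self.w1, self.w2)

    __call__ = forward


class ModalityEncoder(Module):
    """Dual-branch multi-scale convolution + optional SE for one modality."""

    def __init__(self, in_channels: int, cfg: ModelConfig,
                 rng: np.random.Generator, multiscale: bool, use_se: bool):
        self.small = ConvBranch(in_channels, cfg, cfg.small_kernel,
                                cfg.small_stride, cfg.small_pool, rng)
        self.large = (ConvBranch(in_channels, cfg, cfg.large_kernel,
                                 cfg.large_stride, cfg.large_pool, rng)
                      if multiscale else None)
        self.se = (SELayer(cfg.filters, cfg.se_reduction, rng)
                   if use_se else None)

    def forward(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        feats = self.small.forward(x, rng)
        if self.large is not None:  # small-scale features first along time
            feats = ad.concat([feats, self.large.forward(x, rng)], axis=2)
        if self.se is not None:
            feats = self.se(feats)
        return feats


class SleepStageNet(Module):
    """Full network or one of its ablation variants (see :data:`VARIANTS`)."""

    def __init__(self, config: ModelConfig | None = None,
                 variant: str = "full"):
        if variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {variant!r}; valid: {', '.join(VARIANTS)}")
        cfg = config or ModelConfig()
        self.config = cfg
        self.variant = variant
        rng = np.random.default_rng(cfg.seed)
        self._rng = np.random.default_rng(cfg.seed + 1)  # dropout stream

        multiscale = variant != "no_msconv"
        use_se = variant != "no_se"
        mods = (["eeg"] if variant == "eeg_only"
                else ["eeg", "eog", "emg"])
        self.modalities = mods
        self.encoders = [
            ModalityEncoder(2 if m == "eeg" else 1, cfg, rng,
                            multiscale, use_se)
            for m in mods
        ]
        feat_dim = cfg.filters * len(mods)

        if variant == "no_lstm":
            self.bilstm = None
            ctx_dim = feat_dim
        else:
            self.bilstm = BiLSTM(feat_dim, cfg.lstm_hidden, rng)
            ctx_dim = 2 * cfg.lstm_hidden

        if variant == "no_attn":
            self.attn_w = self.attn_b = self.attn_v = None
        else:
            A = cfg.attention_width
            self.attn_w = Tensor(_uniform_fan_in(rng, (ctx_dim, A), ctx_dim),
                                 requires_grad=True)
            self.attn_b = Tensor(_uniform_fan_in(rng, (A,), ctx_dim),
                                 requires_grad=True)
            self.attn_v = Tensor(_uniform_fan_in(rng, (A,), A),
                                 requires_grad=True)

        self.classifier = Linear(ctx_dim, cfg.n_classes, rng)
        self.last_attention: np.ndarray | None = None

    # -- forward pieces ----------------------------------------------------
    @property
    def n_input_channels(self) -> int:
        return 2 if self.variant == "eeg_only" else 4

    def mfem(self, x: Tensor) -> Tensor:
        """Multi-scale extraction + SE fusion: (B, C, L) -> (B, T, features)."""
        if x.shape[1] != self.n_input_channels:
            raise ValueError(f"expected {self.n_input_channels} input "
                             f"channels, got {x.shape[1]}")
        per_mod = [enc.forward(x[:, MODALITY_SLICES[m], :], self._rng)
                   for m, enc in zip(self.modalities, self.encoders)]
        fused = per_mod[0] if len(per_mod) == 1 else ad.concat(per_mod, axis=1)
        return ad.transpose(fused, (0, 2, 1))

    def encode(self, x: Tensor) -> Tensor:
        """Context vector: MFEM → (BiLSTM) → attention pool / last step."""
        seq = self.mfem(x)
        if self.bilstm is not None:
            seq = self.bilstm(seq)
        if self.attn_v is None:
            self.last_attention = None
            return seq[:, -1, :]
        c, alpha = attention_pool(seq, self.attn_w, self.attn_b, self.attn_v)
        self.last_attention = alpha
        return c

    def forward(self, x) -> Tensor:
        """Raw class logits for a (B, C, 3000) batch."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=DTYPE))
        c = self.encode(x)
        c = ad.dropout(c, self.config.classifier_dropout, self._rng,
                       self.training)
        return self.classifier(c)

    __call__ = forward

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class posteriors in evaluation mode (deterministic)."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            out.append(ad.softmax(logits.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- persistence -------------------------------------------------------
    def save(self, path):
        meta = json.dumps({"variant": self.variant,
                           "config": self.config.to_dict()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "SleepStageNet":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        model = cls(ModelConfig.from_dict(meta["config"]), meta["variant"])
        model.load_state_dict(state)
        return model


def build_variant(name: str, config: ModelConfig | None = None,
                  ) -> SleepStageNet:
    """Construct the full model or an ablation variant by name."""
    return SleepStageNet(config, name)
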