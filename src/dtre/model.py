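"""Multi-label relation classifier: encoder contract, focal loss, training.

The classifier is a linear head over a sentence embedding: an encoder maps
the marker-tagged (optionally description-augmented) text to a fixed-size
context vector - the analogue of a transformer's [CLS] embedding - and a
fully connected layer produces 13 logits, one per relation type, squashed
element-wise through a sigmoid. Protein sequence descriptors can be fused
by concatenation with the context vector before the head.

Two encoders satisfy the contract out of the box:

* :class:`HashingEncoder` - a seeded feature-hashing bag-of-tokens
  embedding. Deterministic, dependency-free and fast on one CPU; the
  reference encoder for tests and synthetic experiments.
* any transformer adapter exposing ``name``, ``dim`` and
  ``encode_batch`` - the contract is deliberately minimal so pretrained
  biomedical encoders can be plugged in without touching the head,
  the loss or the ensemble machinery.

Training minimizes focal loss (binary cross-entropy selectable) with Adam
on the head weights. A single integer seed drives initialization and
shuffling, so two runs with identical inputs, config and seed produce
bit-identical states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from hashlib import blake2b
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from dtre.instance_gen import RelationInstance, build_model_text
from dtre.relations import N_CLASSES

log = logging.getLogger(__name__)

# sigmoid outputs are clamped away from {0, 1}: epsilon alone does not
# bound log(1 - p + eps) for p -> 1 in finite precision
PROB_CLAMP = 1e-7


@runtime_checkable
class EncoderContract(Protocol):
    """Deterministic text -> fixed-length context embedding."""

    name: str
    dim: int

    def encode(self, text: str) -> np.ndarray: ...

    def encode_batch(self, texts: Sequence[str]) -> np.ndarray: ...


class HashingEncoder:
    """Seeded feature-hashing bag-of-tokens embedding.

    Tokens are lowercased whitespace tokens; each token is hashed with a
    keyed BLAKE2b digest to a bucket index and a sign, counts are
    accumulated and the vector is L2-normalized. Same (text, dim, seed)
    always yields the same vector, across processes and platforms.
    """

    def __init__(self, dim: int = 4096, seed: int = 0):
        if dim <= 0:
            raise ValueError("encoder dim must be positive")
        self.dim = dim
        self.seed = seed
        self.name = f"hashed:{dim}:{seed}"
        self._key = seed.to_bytes(8, "little", signed=False)

    def _bucket(self, token: str) -> tuple[int, float]:
        h = blake2b(token.encode("utf-8"), digest_size=8, key=self._key).digest()
        value = int.from_bytes(h, "little")
        return value % self.dim, 1.0 if (value >> 63) & 1 else -1.0

    def encode(self, text: str) -> np.ndarray:
        if not text.strip():
            raise ValueError("cannot encode empty text")
        vec = np.zeros(self.dim)
        for raw in text.lower().split():
            token = raw.strip(".,;:!?()\"'")  # sentence-final "word." == "word"
            if not token:
                continue
            idx, sign = self._bucket(token)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def encode_batch(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self.encode(t) for t in texts])


def build_encoder(spec: str) -> HashingEncoder:
    """Encoder from a spec string like ``hashed:1024`` or ``hashed:1024:7``."""
    parts = spec.split(":")
    if parts[0] != "hashed":
        raise ValueError(f"unknown encoder family {parts[0]!r}; available: hashed")
    dim = int(parts[1]) if len(parts) > 1 else 4096
    seed = int(parts[2]) if len(parts) > 2 else 0
    return HashingEncoder(dim=dim, seed=seed)


@dataclass(frozen=True)
class FocalLossParams:
    """Focusing parameter gamma and the log-argument epsilon."""

    gamma: float = 0.5
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def focal_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    params: FocalLossParams = FocalLossParams(),
    reduction: str = "sum",
) -> float:
    """Focal loss over all instance-class terms.

    loss = -sum_i [ y_i (1-p_i)^g log(p_i + eps) + (1-y_i) p_i^g log(1-p_i + eps) ]

    where the sum runs over every (instance, class) term. With gamma = 0
    and eps -> 0 this reduces to binary cross-entropy. ``reduction`` is
    ``"sum"`` (the formula as written) or ``"mean"`` (divides by the
    number of terms; useful for optimizer step-size stability).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    g, eps = params.gamma, params.eps
    terms = y * (1 - p) ** g * np.log(p + eps) + (1 - y) * p**g * np.log(1 - p + eps)
    total = -float(terms.sum()) + 0.0  # normalizes -0.0
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / p.size
    raise ValueError(f"unknown reduction {reduction!r}")


def _focal_grad_probs(p: np.ndarray, y: np.ndarray, params: FocalLossParams) -> np.ndarray:
    """d(loss)/d(p), element-wise, for the sum reduction."""
    g, eps = params.gamma, params.eps
    pos = g * (1 - p) ** (g - 1) * np.log(p + eps) - (1 - p) ** g / (p + eps)
    neg = -g * p ** (g - 1) * np.log(1 - p + eps) + p**g / (1 - p + eps)
    if g == 0:  # 0 * x**-1 overflows before it cancels; drop the factor-g terms
        pos = -1.0 / (p + eps) * np.ones_like(p)
        neg = 1.0 / (1 - p + eps) * np.ones_like(p)
    return y * pos + (1 - y) * neg


def bce_loss(probs: np.ndarray, labels: np.ndarray, reduction: str = "sum") -> float:
    """Plain binary cross-entropy (the gamma=0, eps->0 limit of focal loss)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    total = -float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
    return total / p.size if reduction == "mean" else total


def fuse_features(
    cls_vec: np.ndarray,
    feat_vec: np.ndarray | None,
    mode: str = "none",
    projection: np.ndarray | None = None,
) -> np.ndarray:
    """Combine the context embedding with a sequence descriptor vector.

    ``mode="none"`` returns the context vector unchanged; ``mode="concat"``
    appends the (optionally linearly projected) descriptor vector, which
    should be L2-normalized beforehand.
    """
    if mode == "none":
        return cls_vec
    if mode != "concat":
        raise ValueError(f"unknown fusion mode {mode!r}")
    if feat_vec is None:
        raise ValueError("concat fusion requires a feature vector")
    fv = np.asarray(feat_vec, dtype=float)
    if projection is not None:
        if projection.shape[0] != fv.shape[0]:
            raise ValueError(
                f"projection rows {projection.shape[0]} != feature dim {fv.shape[0]}"
            )
        fv = fv @ projection
    return np.concatenate([cls_vec, fv])


@dataclass
class TrainConfig:
    """Head-training hyperparameters; defaults favor small CPU corpora."""

    seed: int = 0
    epochs: int = 150
    learning_rate: float = 0.2
    batch_size: int = 32
    loss: str = "focal"  # "focal" | "bce"
    gamma: float = 0.5
    eps: float = 1e-6
    reduction: str = "mean"
    weight_decay: float = 0.003
    input_dropout: float = 0.0  # inverted dropout on encoder features
    # drop hash buckets active in fewer training instances than this (the
    # hashing analogue of a min-document-frequency cutoff); prevents the
    # head from memorizing one-off tokens such as singleton entity names
    min_feature_count: int = 2
    feature_fusion: str = "none"  # "none" | "concat"
    feature_projection_dim: int | None = None
    max_tokens: int = 512
    use_chem_desc: bool = True
    use_gene_desc: bool = True


@dataclass
class ClassifierState:
    """Trained head weights plus everything needed to rebuild the model."""

    encoder_name: str
    weights: np.ndarray  # (input_dim, 13)
    bias: np.ndarray  # (13,)
    config: TrainConfig
    projection: np.ndarray | None = None
    feature_mask: np.ndarray | None = None  # (encoder dim,) bool

    def to_json(self) -> str:
        payload = {
            "encoder_name": self.encoder_name,
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "projection": None if self.projection is None else self.projection.tolist(),
            "feature_mask": (
                None
                if self.feature_mask is None
                else [int(v) for v in self.feature_mask]
            ),
            "config": asdict(self.config),
            "format_version": 1,
        }
        return json.dumps(payload, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "ClassifierState":
        payload = json.loads(text)
        return cls(
            encoder_name=payload["encoder_name"],
            weights=np.array(payload["weights"]),
            bias=np.array(payload["bias"]),
            projection=(
                None if payload["projection"] is None else np.array(payload["projection"])
            ),
            feature_mask=(
                None
                if payload.get("feature_mask") is None
                else np.array(payload["feature_mask"], dtype=bool)
            ),
            config=TrainConfig(**payload["config"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierState":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _design_matrix(
    instances: Sequence[RelationInstance],
    encoder: EncoderContract,
    config: TrainConfig,
    projection: np.ndarray | None,
    feature_mask: np.ndarray | None = None,
) -> np.ndarray:
    texts = [
        build_model_text(
            inst,
            use_chem_desc=config.use_chem_desc,
            use_gene_desc=config.use_gene_desc,
            max_tokens=config.max_tokens,
        )
        for inst in instances
    ]
    X = encoder.encode_batch(texts)
    if feature_mask is not None:
        X = X * feature_mask
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = np.divide(X, norms, out=X, where=norms > 0)
    if config.feature_fusion == "concat":
        rows = []
        for inst, cls_vec in zip(instances, X):
            if inst.feature_vector is None:
                raise ValueError(
                    f"instance {inst.instance_id} has no feature vector but "
                    "feature_fusion='concat'"
                )
            rows.append(
                fuse_features(cls_vec, inst.feature_vector, "concat", projection)
            )
        X = np.stack(rows)
    return X


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return np.clip(out, PROB_CLAMP, 1.0 - PROB_CLAMP)


def predict_probs(
    state: ClassifierState,
    instances: Sequence[RelationInstance],
    encoder: EncoderContract | None = None,
) -> np.ndarray:
    """Per-class sigmoid probabilities, one row per instance.

    The encoder is rebuilt from ``state.encoder_name`` when not supplied
    (hashed encoders only; adapters must be passed explicitly).
    """
    if encoder is None:
        encoder = build_encoder(state.encoder_name)
    X = _design_matrix(
        instances, encoder, state.config, state.projection, state.feature_mask
    )
    return _sigmoid(X @ state.weights + state.bias)


def train(
    instances: Sequence[RelationInstance],
    encoder: EncoderContract,
    config: TrainConfig,
) -> ClassifierState:
    """Train the linear head with Adam; deterministic given the seed.

    Raises on an empty instance list and on non-finite loss (training can
    diverge for unlucky seed/learning-rate combinations; the failure is
    reported rather than silently producing garbage).
    """
    if not instances:
        raise ValueError("cannot train on an empty instance list")
    if config.loss not in ("focal", "bce"):
        raise ValueError(f"unknown loss {config.loss!r}")
    rng = np.random.default_rng(config.seed)

    projection = None
    if config.feature_fusion == "concat" and config.feature_projection_dim is not None:
        n_feat = len(instances[0].feature_vector)
        projection = rng.normal(0.0, 1.0 / np.sqrt(n_feat), (n_feat, config.feature_projection_dim))

    feature_mask = None
    if config.min_feature_count > 1:
        raw = encoder.encode_batch(
            [
                build_model_text(
                    inst,
                    use_chem_desc=config.use_chem_desc,
                    use_gene_desc=config.use_gene_desc,
                    max_tokens=config.max_tokens,
                )
                for inst in instances
            ]
        )
        support = (raw != 0).sum(axis=0)
        feature_mask = support >= config.min_feature_count
        if not feature_mask.any():
            feature_mask = None  # degenerate corpus: keep all features

    X = _design_matrix(instances, encoder, config, projection, feature_mask)
    Y = np.stack([inst.label for inst in instances]).astype(float)
    n, d = X.shape

    W = rng.normal(0.0, 0.01, (d, N_CLASSES))
    b = np.zeros(N_CLASSES)
    params = FocalLossParams(gamma=config.gamma, eps=config.eps)

    # Adam state
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            Xb, Yb = X[idx], Y[idx]
            if config.input_dropout > 0.0:
                # inverted dropout on encoder features: discourages the head
                # from relying on buckets seen in only one training instance
                keep = 1.0 - config.input_dropout
                mask = rng.random(Xb.shape) < keep
                Xb = Xb * mask / keep
            P = _sigmoid(Xb @ W + b)
            if config.loss == "focal":
                loss = focal_loss(P, Yb, params, reduction=config.reduction)
                dP = _focal_grad_probs(P, Yb, params)
            else:
                loss = bce_loss(P, Yb, reduction=config.reduction)
                dP = -(Yb / P) + (1 - Yb) / (1 - P)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, seed {config.seed}: "
                    f"training failed to converge (try a lower learning rate "
                    f"or a different seed)"
                )
            scale = 1.0 / dP.size if config.reduction == "mean" else 1.0
            dZ = dP * P * (1 - P) * scale
            gW = Xb.T @ dZ
            gb = dZ.sum(axis=0)

            step += 1
            mW = beta1 * mW + (1 - beta1) * gW
            vW = beta2 * vW + (1 - beta2) * gW**2
            mb = beta1 * mb + (1 - beta1) * gb
            vb = beta2 * vb + (1 - beta2) * gb**2
            mW_hat = mW / (1 - beta1**step)
            vW_hat = vW / (1 - beta2**step)
            mb_hat = mb / (1 - beta1**step)
            vb_hat = vb / (1 - beta2**step)
            # decoupled (AdamW-style) weight decay: applied to the update,
            # not folded into the gradient moments
            W = W - config.learning_rate * (
                mW_hat / (np.sqrt(vW_hat) + adam_eps) + config.weight_decay * W
            )
            b = b - config.learning_rate * mb_hat / (np.sqrt(vb_hat) + adam_eps)
            epoch_loss += loss
        log.debug("epoch %d: loss %.6f", epoch, epoch_loss)

    return ClassifierState(
        encoder_name=encoder.name,
        weights=W,
        bias=b,
        config=config,
        projection=projection,
        feature_mask=feature_mask,
    )
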