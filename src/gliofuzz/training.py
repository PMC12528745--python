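"""Two-stage gradient-free training protocol.

Stage 1 tunes the fuzzy filter genes (w, code per filter, or per layer in
tied mode) together with the five ReLU slopes by maximizing the Fisher
trace ratio — trace of between-class scatter over trace of within-class
scatter — of the extracted 128-d features on a small stratified subset
(default 100 cases, 50 hybrid-optimizer iterations).  Stage 2 freezes the
extractor and trains only the classification head on the full training
features: either the FC+softmax head (hybrid optimizer over the 258-d
weight box, minimizing mean cross-entropy) or a linear hinge-loss SVM
refined by deterministic subgradient descent and warm-started from the
optimized FC weight difference vector.

Head training standardizes the features with train-set statistics stored
in the model; raw activations of the cosine-kernel network can span
orders of magnitude, which would saturate any fixed weight box.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .fcnn3d import (
    FEATURE_LENGTH,
    HeadParams,
    NetworkSpec,
    ReLUParams,
    forward_features_batch,
    softmax,
)
from .fuzzy_weights import FilterGene, build_kernel_bank
from .optimizers import OptimizerConfig, OptResult, run_hybrid

__all__ = [
    "TrainConfig",
    "SvmParams",
    "TrainedModel",
    "fisher_fitness",
    "stage1_optimize",
    "stage2_train",
    "svm_decision",
    "train_model",
    "predict",
]

logger = logging.getLogger(__name__)

_SLOPE_BOUNDS = (1e-3, 2.0)
_HEAD_BOX = 2.0  # FC weight/bias box half-width on standardized features


@dataclass(frozen=True)
class TrainConfig:
    stage1_subset_size: int = 100
    stage1_iterations: int = 50
    stage2_iterations: int = 200
    population: int = 16
    head: str = "softmax"  # "softmax" | "svm"
    tie_genes_per_layer: bool = True
    seed: int = 0
    svm_epochs: int = 500
    svm_l2: float = 1e-3

    def __post_init__(self) -> None:
        if self.head not in ("softmax", "svm"):
            raise ValueError("head must be 'softmax' or 'svm'")
        if min(self.stage1_subset_size, self.stage1_iterations,
               self.stage2_iterations, self.population) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SvmParams:
    """Linear decision rule: score = weight . features + bias."""

    weight: np.ndarray  # (128,)
    bias: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=float)
        if w.shape != (FEATURE_LENGTH,):
            raise ValueError(f"weight must have shape ({FEATURE_LENGTH},), got {w.shape}")
        object.__setattr__(self, "weight", w)


@dataclass
class FeatureScaler:
    """Train-set standardization applied before either head."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, features: np.ndarray) -> "FeatureScaler":
        std = features.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=features.mean(axis=0), std=std)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) / self.std


@dataclass
class TrainedModel:
    genes: List[List[FilterGene]]
    relu: ReLUParams
    spec: NetworkSpec
    head_type: str
    head: HeadParams | SvmParams
    scaler: FeatureScaler
    audit: Dict[str, int]

    @property
    def bank(self):
        return build_kernel_bank(self.genes, self.spec)


def fisher_fitness(features: np.ndarray, labels: np.ndarray) -> float:
    """Fisher trace ratio: class separability of a feature matrix.

    trace(between-class scatter) / (trace(within-class scatter) + 1e-9),
    with the between-class scatter weighted by class counts.  Larger is
    more separable; both classes must be present.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("fisher_fitness requires both classes present")
    grand_mean = features.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in classes:
        group = features[labels == c]
        mu = group.mean(axis=0)
        between += len(group) * float(np.sum((mu - grand_mean) ** 2))
        within += float(np.sum((group - mu) ** 2))
    return between / (within + 1e-9)


def _gene_dimension(spec: NetworkSpec, tied: bool) -> int:
    return 2 * (len(spec.channels) if tied else sum(spec.channels))


def _decode_stage1(
    vector: np.ndarray, spec: NetworkSpec, tied: bool
) -> Tuple[List[List[FilterGene]], ReLUParams]:
    n_gene = _gene_dimension(spec, tied)
    gene_vals, slopes = vector[:n_gene], vector[n_gene:]
    genes: List[List[FilterGene]] = []
    cursor = 0
    for out_ch in spec.channels:
        count = 1 if tied else out_ch
        layer = [
            FilterGene(w=gene_vals[cursor + 2 * i], code=gene_vals[cursor + 2 * i + 1])
            for i in range(count)
        ]
        genes.append(layer)
        cursor += 2 * count
    relu = ReLUParams(slopes=tuple(float(np.clip(c, *_SLOPE_BOUNDS)) for c in slopes))
    return genes, relu


def _stratified_subset(
    labels: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(labels)
    size = min(size, n)
    if size == n:
        return np.arange(n)
    idx: List[int] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        take = max(1, int(round(size * len(members) / n)))
        idx.extend(rng.choice(members, size=min(take, len(members)), replace=False))
    return np.array(sorted(idx))


def stage1_optimize(
    volumes: Sequence[np.ndarray],
    labels: np.ndarray,
    spec: NetworkSpec,
    cfg: TrainConfig,
) -> Tuple[List[List[FilterGene]], ReLUParams, OptResult]:
    """Optimize genes + ReLU slopes for feature separability (stage 1)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("stage 1 requires both classes in the training split")
    rng = np.random.default_rng(cfg.seed)
    subset = _stratified_subset(labels, cfg.stage1_subset_size, rng)
    sub_volumes = [volumes[i] for i in subset]
    sub_labels = labels[subset]

    tied = cfg.tie_genes_per_layer
    n_gene = _gene_dimension(spec, tied)
    dim = n_gene + len(spec.channels)
    bounds = np.empty((dim, 2))
    bounds[:n_gene] = (0.0, 1.0)
    bounds[n_gene:] = _SLOPE_BOUNDS

    def objective(vector: np.ndarray) -> float:
        genes, relu = _decode_stage1(vector, spec, tied)
        bank = build_kernel_bank(genes, spec)
        feats = forward_features_batch(sub_volumes, bank, relu)
        return -fisher_fitness(feats, sub_labels)

    opt = OptimizerConfig(
        bounds=bounds,
        population=cfg.population,
        iterations=cfg.stage1_iterations,
        seed=cfg.seed,
    )
    result = run_hybrid(objective, opt)
    genes, relu = _decode_stage1(result.best.position, spec, tied)
    logger.info(
        "stage 1: dim=%d, subset=%d, %d evals, fisher=%.4g",
        dim, len(subset), result.n_evals, -result.best.fitness,
    )
    return genes, relu, result


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def _train_softmax_head(
    features_std: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> HeadParams:
    dim = FEATURE_LENGTH * 2 + 2
    bounds = np.tile((-_HEAD_BOX, _HEAD_BOX), (dim, 1))

    def objective(vector: np.ndarray) -> float:
        w = vector[: 2 * FEATURE_LENGTH].reshape(FEATURE_LENGTH, 2)
        b = vector[2 * FEATURE_LENGTH :]
        return _cross_entropy(softmax(features_std @ w + b), y)

    opt = OptimizerConfig(
        bounds=bounds,
        population=max(cfg.population, 24),
        iterations=cfg.stage2_iterations,
        seed=cfg.seed + 1,
    )
    result = run_hybrid(objective, opt)
    v = result.best.position
    return HeadParams(
        fc_weights=v[: 2 * FEATURE_LENGTH].reshape(FEATURE_LENGTH, 2),
        fc_bias=v[2 * FEATURE_LENGTH :],
    )


def _train_svm_head(
    features_std: np.ndarray, y: np.ndarray, cfg: TrainConfig, fc: HeadParams
) -> SvmParams:
    """Deterministic full-batch subgradient descent on hinge + L2.

    Warm start: the FC weight difference vector (positive minus negative
    column), which already points toward the positive class.
    """
    w = fc.fc_weights[:, 1] - fc.fc_weights[:, 0]
    b = float(fc.fc_bias[1] - fc.fc_bias[0])
    signs = np.where(y == 1, 1.0, -1.0)
    n = len(y)
    for epoch in range(cfg.svm_epochs):
        lr = 1.0 / (1.0 + 0.05 * epoch)
        margins = signs * (features_std @ w + b)
        active = margins < 1.0
        grad_w = cfg.svm_l2 * w - (signs[active, None] * features_std[active]).sum(axis=0) / n
        grad_b = -float(signs[active].sum()) / n
        w -= lr * grad_w
        b -= lr * grad_b
    return SvmParams(weight=w, bias=b)


def stage2_train(
    features: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> Tuple[HeadParams | SvmParams, FeatureScaler]:
    """Train the classification head on frozen-extractor features."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("stage 2 requires both classes present")
    scaler = FeatureScaler.fit(np.asarray(features, dtype=float))
    features_std = scaler.transform(features)
    fc = _train_softmax_head(features_std, labels, cfg)
    if cfg.head == "softmax":
        return fc, scaler
    return _train_svm_head(features_std, labels, cfg, fc), scaler


def svm_decision(features: np.ndarray, svm: SvmParams) -> Tuple[float, str]:
    """Linear decision: score = w.x + b; HGG if score > 0, LGG otherwise.

    Ties (score exactly 0) go to the negative class (LGG).
    """
    features = np.asarray(features, dtype=float)
    if features.shape != svm.weight.shape:
        raise ValueError(
            f"feature length {features.shape} does not match weight "
            f"{svm.weight.shape}"
        )
    score = float(features @ svm.weight + svm.bias)
    return score, ("HGG" if score > 0 else "LGG")


def _hash_params(genes: List[List[FilterGene]], relu: ReLUParams) -> str:
    h = hashlib.sha256()
    for layer in genes:
        for g in layer:
            h.update(np.array([g.w, g.code]).tobytes())
    h.update(np.array(relu.slopes).tobytes())
    return h.hexdigest()


def _audit(genes, relu, head_type: str) -> Dict[str, int]:
    n_genes = sum(len(layer) for layer in genes)
    head_count = FEATURE_LENGTH * 2 + 2 if head_type == "softmax" else FEATURE_LENGTH + 1
    ledger = {
        "gene_scalars": 2 * n_genes,
        "relu_scalars": len(relu.slopes),
        "head_scalars": head_count,
    }
    ledger["total"] = sum(ledger.values())
    return ledger


def train_model(
    cohort, spec: NetworkSpec | None = None, cfg: TrainConfig | None = None
) -> TrainedModel:
    """Full two-stage protocol on a cohort's training split."""
    spec = spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    train_volumes = cohort.volumes("train")
    train_labels = cohort.labels("train")

    genes, relu, _ = stage1_optimize(train_volumes, train_labels, spec, cfg)
    frozen = _hash_params(genes, relu)

    bank = build_kernel_bank(genes, spec)
    features = forward_features_batch(train_volumes, bank, relu)
    head, scaler = stage2_train(features, train_labels, cfg)

    assert _hash_params(genes, relu) == frozen, "stage 2 mutated the extractor"
    audit = _audit(genes, relu, cfg.head)
    logger.info("parameter ledger: %s", audit)
    return TrainedModel(
        genes=genes, relu=relu, spec=spec, head_type=cfg.head,
        head=head, scaler=scaler, audit=audit,
    )


def predict(model: TrainedModel, volumes: Sequence[np.ndarray]):
    """Predicted binary labels (HGG=1) and positive-class scores."""
    bank = model.bank
    features = forward_features_batch(volumes, bank, model.relu)
    features_std = model.scaler.transform(features)
    if model.head_type == "softmax":
        probs = softmax(
            features_std @ model.head.fc_weights + model.head.fc_bias
        )
        scores = probs[:, 1]
        labels = (scores > 0.5).astype(int)
    else:
        scores = features_std @ model.head.weight + model.head.bias
        labels = (scores > 0).astype(int)
    return labels, scores
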