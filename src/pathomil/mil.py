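"""Attention-pooling, instance-level multiple-instance learning classifier.

A whole-slide image is a bag X_n of p patches.  A frozen convolutional
backbone encodes each patch into a feature vector; a trainable head maps
features through an embedding layer (ReLU) to (a) per-patch multiclass
logits z[p, c] and (b) per-class attention scores.  Attention weights
a[c, p] = softmax over patches of the class-c scores (each class row sums
to 1); the slide-level logit for class c is the attention-weighted sum
sum_p a[c, p] * z[p, c], passed through a logistic function to give
multilabel slide probabilities.  Training minimizes the mean per-class
binary cross-entropy against the (weak) slide label with Adam, one bag per
gradient step, slide-level augmentation re-sampled each epoch, and the
backbone frozen throughout.  Gradients are derived in closed form and
implemented directly in NumPy.

Model selection follows validation loss: per fold the epoch checkpoint with
the lowest validation loss is kept, and grid search picks the configuration
with the lowest mean validation loss across folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .backbones import BackboneSpec, make_backbone
from .preprocess import apply_transform, sample_wsi_transform
from .schema import N_CLASSES, as_label

logger = logging.getLogger(__name__)


class MILError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Bag:
    """One slide's ordered patch collection — the MIL unit.

    Either ``tiles`` (p, 224, 224, 3 uint8) or precomputed ``features``
    (p, feature_dim) must be present.  ``label`` is the weak slide-level
    label vector; ``patch_gt`` optional per-patch classes for evaluation.
    """

    slide_id: str
    patient_id: str
    tiles: np.ndarray | None = None
    features: np.ndarray | None = None
    label: np.ndarray | None = None
    coords: list | None = None
    patch_gt: np.ndarray | None = None

    def __post_init__(self):
        if self.tiles is None and self.features is None:
            raise MILError(f"bag {self.slide_id!r} has neither tiles nor features")
        if self.n_patches < 1:
            raise MILError(f"bag {self.slide_id!r} is empty")
        if self.label is not None:
            self.label = as_label(self.label)
            if not self.label.any():
                raise MILError(f"bag {self.slide_id!r} label is not finalized (all-zero)")

    @property
    def n_patches(self) -> int:
        source = self.features if self.features is not None else self.tiles
        return len(source)


@dataclass
class TrainConfig:
    epochs: int = 15
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    embed_dim: int = 128
    decision_threshold: float = 0.5
    augment: bool = True
    shared_attention: bool = False
    seed: int = 0
    #: exhaustive search space used by grid_search when none is passed
    grid: dict = field(
        default_factory=lambda: {
            "learning_rate": [1e-2, 1e-3, 1e-4, 1e-5],
            "weight_decay": [1e-2, 1e-3, 1e-4, 1e-5],
            "embed_dim": [32, 64, 128, 256],
        }
    )

    def __post_init__(self):
        if self.epochs < 1:
            raise MILError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise MILError("learning_rate must be positive, weight_decay non-negative")


@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]

    def fold_of(self, patient_id: str) -> int:
        return self.assignment[patient_id]

    def patients(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]


# ---------------------------------------------------------------------------
# Head parameters and forward/backward


class MILHead:
    """Trainable parameters: embedding, classifier and attention maps."""

    def __init__(
        self,
        feature_dim: int,
        embed_dim: int = 128,
        n_classes: int = N_CLASSES,
        shared_attention: bool = False,
        rng: np.random.Generator | int | None = None,
    ):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.feature_dim = feature_dim
        self.embed_dim = embed_dim
        self.n_classes = n_classes
        self.shared_attention = shared_attention
        n_att = 1 if shared_attention else n_classes
        # input standardization, fitted on training features and frozen
        self.norm_mu = np.zeros(feature_dim)
        self.norm_sigma = np.ones(feature_dim)
        def init(fan_in, shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self.params = {
            "We": init(feature_dim, (feature_dim, embed_dim)),
            "be": np.zeros(embed_dim),
            "Wc": init(embed_dim, (embed_dim, n_classes)),
            "bc": np.zeros(n_classes),
            "Wa": init(embed_dim, (embed_dim, n_att)),
            "ba": np.zeros(n_att),
        }

    def fit_standardizer(self, features: np.ndarray) -> None:
        """Fit per-dimension standardization on (stacked) training features."""
        self.norm_mu = features.mean(axis=0)
        self.norm_sigma = features.std(axis=0) + 1e-8

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.norm_mu) / self.norm_sigma

    def copy(self) -> "MILHead":
        clone = MILHead.__new__(MILHead)
        clone.feature_dim = self.feature_dim
        clone.embed_dim = self.embed_dim
        clone.n_classes = self.n_classes
        clone.shared_attention = self.shared_attention
        clone.norm_mu = self.norm_mu.copy()
        clone.norm_sigma = self.norm_sigma.copy()
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def state_dict(self) -> dict:
        return {
            "feature_dim": self.feature_dim,
            "embed_dim": self.embed_dim,
            "n_classes": self.n_classes,
            "shared_attention": self.shared_attention,
            "norm_mu": self.norm_mu,
            "norm_sigma": self.norm_sigma,
            **{f"param.{k}": v for k, v in self.params.items()},
        }

    @classmethod
    def from_state(cls, state: dict) -> "MILHead":
        head = cls.__new__(cls)
        head.feature_dim = int(state["feature_dim"])
        head.embed_dim = int(state["embed_dim"])
        head.n_classes = int(state["n_classes"])
        head.shared_attention = bool(state["shared_attention"])
        head.norm_mu = np.asarray(state.get("norm_mu", np.zeros(head.feature_dim)))
        head.norm_sigma = np.asarray(state.get("norm_sigma", np.ones(head.feature_dim)))
        head.params = {
            k.split(".", 1)[1]: np.asarray(v)
            for k, v in state.items()
            if k.startswith("param.")
        }
        return head


def _softmax_columns(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=0, keepdims=True)


def embed_bag(bag: Bag, backbone, head: MILHead) -> np.ndarray:
    """Per-patch embeddings (p, embed_dim): backbone features through the
    embedding layer and ReLU.  Order-preserving; the backbone stays frozen."""
    features = bag.features
    if features is None:
        features = backbone.features(bag.tiles)
    features = np.asarray(features, dtype=np.float64)
    if features.shape[1] != head.feature_dim:
        raise MILError(
            f"feature dimension mismatch: head expects {head.feature_dim}, "
            f"got {features.shape[1]}"
        )
    x = head.standardize(features)
    return np.maximum(x @ head.params["We"] + head.params["be"], 0.0)


def patch_predict(embeddings: np.ndarray, head: MILHead) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch multiclass probabilities (softmax over 5 logits) and hard
    labels (argmax; ties break to the lowest class index)."""
    logits = embeddings @ head.params["Wc"] + head.params["bc"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs, probs.argmax(axis=1)


def attention_pool(
    embeddings: np.ndarray, patch_logits: np.ndarray, head: MILHead
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attention weights a[c, p] and multilabel slide probabilities.

    Per class c the attention row is a softmax over patches of that class's
    attention scores (each row sums to 1); the slide logit for c is
    sum_p a[c, p] * z[p, c] and the slide probability its logistic transform.
    Returns (attention (5, p), wsi_probs (5,), wsi_logits (5,)).
    """
    p = embeddings.shape[0]
    if p < 1:
        raise MILError("attention pooling needs at least one patch")
    scores = embeddings @ head.params["Wa"] + head.params["ba"]  # (p, n_att)
    if head.shared_attention:
        scores = np.repeat(scores, head.n_classes, axis=1)
    att = _softmax_columns(scores)  # (p, C), columns sum to 1
    wsi_logits = (att * patch_logits).sum(axis=0)
    wsi_probs = expit(wsi_logits)
    return att.T, wsi_probs, wsi_logits


def predict_wsi(
    bag: Bag, backbone, head: MILHead, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slide-level multilabel prediction.

    A class is set iff its probability exceeds the threshold; when none does,
    the argmax class is set so a diagnosis is always emitted.
    Returns (label vector, per-class probabilities, attention (5, p)).
    """
    embeddings = embed_bag(bag, backbone, head)
    logits = embeddings @ head.params["Wc"] + head.params["bc"]
    att, probs, _ = attention_pool(embeddings, logits, head)
    label = (probs > threshold).astype(np.int8)
    if not label.any():
        label[int(np.argmax(probs))] = 1
    return label, probs, att


# ---------------------------------------------------------------------------
# Loss and gradients


def _forward_loss(features: np.ndarray, y: np.ndarray, head: MILHead):
    P = head.params
    x = head.standardize(features)
    pre = x @ P["We"] + P["be"]
    H = np.maximum(pre, 0.0)
    Z = H @ P["Wc"] + P["bc"]
    S = H @ P["Wa"] + P["ba"]
    S_full = np.repeat(S, head.n_classes, axis=1) if head.shared_attention else S
    A = _softmax_columns(S_full)  # (p, C)
    g = (A * Z).sum(axis=0)
    # numerically stable mean binary cross-entropy from logits
    loss = float(np.mean(np.maximum(g, 0) - g * y + np.log1p(np.exp(-np.abs(g)))))
    cache = (x, pre, H, Z, A, g)
    return loss, cache


def _backward(y: np.ndarray, head: MILHead, cache) -> dict:
    P = head.params
    x, pre, H, Z, A, g = cache
    C = head.n_classes
    dg = (expit(g) - y) / C  # (C,)
    dZ = dg * A  # (p, C)
    dS_full = dg * A * (Z - g)  # (p, C)
    dS = dS_full.sum(axis=1, keepdims=True) if head.shared_attention else dS_full
    dH = dZ @ P["Wc"].T + dS @ P["Wa"].T
    dpre = dH * (pre > 0)
    return {
        "We": x.T @ dpre,
        "be": dpre.sum(axis=0),
        "Wc": H.T @ dZ,
        "bc": dZ.sum(axis=0),
        "Wa": H.T @ dS,
        "ba": dS.sum(axis=0),
    }


class _Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, p in params.items():
            gk = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training


def ensure_features(bags: Sequence[Bag], backbone) -> None:
    """Compute and cache frozen-backbone features for bags that lack them."""
    for bag in bags:
        if bag.features is None:
            bag.features = backbone.features(bag.tiles)


def _check_patient_disjoint(train_bags, val_bags) -> None:
    overlap = {b.patient_id for b in train_bags} & {b.patient_id for b in val_bags}
    if overlap:
        raise MILError(f"patients shared between train and validation: {sorted(overlap)[:5]}")


def _mean_loss(bags: Sequence[Bag], head: MILHead) -> float:
    return float(
        np.mean([_forward_loss(b.features, b.label.astype(float), head)[0] for b in bags])
    )


def train_fold(
    train_bags: Sequence[Bag],
    val_bags: Sequence[Bag],
    backbone,
    config: TrainConfig | None = None,
    seed: int | None = None,
) -> tuple[MILHead, dict]:
    """Train the head on one fold; return the lowest-validation-loss epoch.

    One bag per Adam step, bags shuffled per epoch; slide-level augmentation
    (when tiles are available) re-sampled per bag per epoch; backbone frozen.
    Fully determined by the seed.
    """
    config = config or TrainConfig()
    seed = config.seed if seed is None else seed
    if not train_bags:
        raise MILError("no training bags")
    _check_patient_disjoint(train_bags, val_bags)
    ensure_features(train_bags, backbone)
    ensure_features(val_bags, backbone)
    feature_dim = train_bags[0].features.shape[1]

    ss = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    head = MILHead(
        feature_dim,
        embed_dim=config.embed_dim,
        shared_attention=config.shared_attention,
        rng=init_rng,
    )
    head.fit_standardizer(np.vstack([b.features for b in train_bags]))
    opt = _Adam(head.params, config.learning_rate, config.weight_decay)

    history = {"train_loss": [], "val_loss": []}
    best_state, best_val, best_epoch = head.copy(), np.inf, -1
    epoch_seeds = ss.spawn(config.epochs)
    for epoch in range(config.epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        order = rng.permutation(len(train_bags))
        losses = []
        for i in order:
            bag = train_bags[i]
            features = bag.features
            if config.augment and bag.tiles is not None:
                desc = sample_wsi_transform(rng)
                if any((desc["rotation"], desc["hflip"], desc["vflip"], desc["color"])):
                    features = backbone.features(apply_transform(bag.tiles, desc))
            y = bag.label.astype(float)
            loss, cache = _forward_loss(features, y, head)
            grads = _backward(y, head, cache)
            opt.step(head.params, grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        val_loss = _mean_loss(val_bags, head) if val_bags else history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, head.copy(), epoch
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return best_state, history


def make_folds(patient_ids: Sequence[str], k: int = 10, seed: int = 0) -> FoldPlan:
    """Random patient-level partition into k folds with sizes differing by <=1."""
    unique = sorted(set(patient_ids))
    if k > len(unique):
        raise MILError(f"k={k} exceeds the number of patients ({len(unique)})")
    if k < 1:
        raise MILError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment = {unique[idx]: i % k for i, idx in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment)


def _split_by_fold(bags: Sequence[Bag], plan: FoldPlan, fold: int):
    train = [b for b in bags if plan.fold_of(b.patient_id) != fold]
    val = [b for b in bags if plan.fold_of(b.patient_id) == fold]
    return train, val


def grid_search(
    space,
    bags: Sequence[Bag],
    backbone,
    folds: FoldPlan,
    seed: int = 0,
    base_config: TrainConfig | None = None,
) -> tuple[TrainConfig, list[dict]]:
    """Exhaustive search over hyperparameter candidates by mean validation loss.

    ``space`` is either an iterable of parameter dicts or a dict of lists
    (expanded as a product).  Ties break by (smaller embed_dim, smaller
    learning rate) for parsimony; the result is invariant to enumeration
    order.  Returns the winning config and the full trial log.
    """
    base = base_config or TrainConfig()
    if isinstance(space, dict):
        keys = sorted(space)
        candidates = [dict(zip(keys, vals)) for vals in itertools.product(*(space[k] for k in keys))]
    else:
        candidates = [dict(c) for c in space]
    if not candidates:
        raise MILError("empty hyperparameter space")
    ensure_features(bags, backbone)
    trials = []
    for cand in candidates:
        config = replace(base, **cand)
        fold_losses = []
        for fold in range(folds.k):
            train, val = _split_by_fold(bags, folds, fold)
            _, history = train_fold(train, val, backbone, config, seed=seed + fold)
            fold_losses.append(history["best_val_loss"])
        mean_loss = float(np.mean(fold_losses))
        trials.append({"params": cand, "mean_val_loss": mean_loss, "fold_losses": fold_losses})
        logger.info("grid trial %s -> val loss %.4f", cand, mean_loss)
    best = min(
        trials,
        key=lambda t: (
            t["mean_val_loss"],
            t["params"].get("embed_dim", base.embed_dim),
            t["params"].get("learning_rate", base.learning_rate),
        ),
    )
    return replace(base, **best["params"]), trials


def cross_validate(
    bags: Sequence[Bag],
    backbone,
    config: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Patient-level k-fold cross-validation.

    Each fold's model trains on the other k-1 folds and is validated on the
    held-out fold; metrics are reported as mean +/- sample standard deviation
    across the k models.
    """
    from .metrics import micro_accuracy, weighted_f1

    config = config or TrainConfig()
    plan = make_folds([b.patient_id for b in bags], k=k, seed=seed)
    ensure_features(bags, backbone)
    heads, fold_metrics = [], []
    for fold in range(k):
        train, val = _split_by_fold(bags, plan, fold)
        head, history = train_fold(train, val, backbone, config, seed=seed + fold)
        heads.append(head)
        gt = np.vstack([b.label for b in val])
        pred = np.vstack(
            [predict_wsi(b, backbone, head, config.decision_threshold)[0] for b in val]
        )
        f1, _ = weighted_f1(gt, pred)
        fold_metrics.append(
            {
                "fold": fold,
                "micro_accuracy": micro_accuracy(gt, pred),
                "weighted_f1": f1,
                "best_epoch": history["best_epoch"],
                "val_loss": history["best_val_loss"],
            }
        )
    def agg(key):
        values = [m[key] for m in fold_metrics]
        return {
            "mean": float(np.mean(values)),
            "std": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        }
    return {
        "heads": heads,
        "plan": plan,
        "folds": fold_metrics,
        "micro_accuracy": agg("micro_accuracy"),
        "weighted_f1": agg("weighted_f1"),
    }


# ---------------------------------------------------------------------------
# Estimator facade


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style attention-MIL slide classifier.

    ``X`` is a sequence of :class:`Bag` objects; ``y`` an optional (n, 5)
    multilabel indicator matrix (defaults to the bags' own weak labels).

    Parameters mirror the training configuration: a frozen backbone preset
    ('tiny' or 'paper'), the embedding width, Adam learning rate and weight
    decay, the number of epochs, the multilabel decision threshold, whether
    slide-level augmentation is applied, and whether attention is shared
    across classes.

    Fitted attributes: ``head_`` (trained parameters), ``backbone_``,
    ``history_`` (per-epoch losses), ``feature_dim_``.
    """

    def __init__(
        self,
        backbone: str | BackboneSpec = "tiny",
        embed_dim: int = 128,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-3,
        epochs: int = 15,
        decision_threshold: float = 0.5,
        augment: bool = True,
        shared_attention: bool = False,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.embed_dim = embed_dim
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.decision_threshold = decision_threshold
        self.augment = augment
        self.shared_attention = shared_attention
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            embed_dim=self.embed_dim,
            decision_threshold=self.decision_threshold,
            augment=self.augment,
            shared_attention=self.shared_attention,
            seed=self.random_state,
        )

    def fit(self, X: Sequence[Bag], y=None, X_val: Sequence[Bag] | None = None):
        bags = list(X)
        if y is not None:
            y = np.asarray(y)
            bags = [replace_label(b, y[i]) for i, b in enumerate(bags)]
        self.backbone_ = make_backbone(self.backbone)
        self.head_, self.history_ = train_fold(
            bags, list(X_val or []), self.backbone_, self._train_config(),
            seed=self.random_state,
        )
        self.feature_dim_ = self.head_.feature_dim
        self.classes_ = np.arange(N_CLASSES)
        return self

    def predict(self, X: Sequence[Bag]) -> np.ndarray:
        check_is_fitted(self, "head_")
        return np.vstack(
            [predict_wsi(b, self.backbone_, self.head_, self.decision_threshold)[0] for b in X]
        )

    def predict_proba(self, X: Sequence[Bag]) -> np.ndarray:
        check_is_fitted(self, "head_")
        return np.vstack(
            [predict_wsi(b, self.backbone_, self.head_, self.decision_threshold)[1] for b in X]
        )

    def attention(self, bag: Bag) -> np.ndarray:
        """Per-class, per-patch attention weight matrix (5, p)."""
        check_is_fitted(self, "head_")
        return predict_wsi(bag, self.backbone_, self.head_, self.decision_threshold)[2]

    def patch_labels(self, bag: Bag) -> tuple[np.ndarray, np.ndarray]:
        """Per-patch multiclass probabilities and hard labels."""
        check_is_fitted(self, "head_")
        embeddings = embed_bag(bag, self.backbone_, self.head_)
        return patch_predict(embeddings, self.head_)

    def embed(self, bag: Bag) -> np.ndarray:
        check_is_fitted(self, "head_")
        return embed_bag(bag, self.backbone_, self.head_)


def replace_label(bag: Bag, label) -> Bag:
    return Bag(
        slide_id=bag.slide_id,
        patient_id=bag.patient_id,
        tiles=bag.tiles,
        features=bag.features,
        label=as_label(label),
        coords=bag.coords,
        patch_gt=bag.patch_gt,
    )


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path, head: MILHead, config: TrainConfig, backbone_spec) -> None:
    """Self-describing archive: head weights, config, class order, version."""
    from . import __version__
    from .schema import CLASS_NAMES

    spec = backbone_spec if isinstance(backbone_spec, BackboneSpec) else BackboneSpec(architecture=str(backbone_spec))
    meta = {
        "class_order": ",".join(CLASS_NAMES),
        "version": __version__,
        "backbone_architecture": spec.architecture,
        "backbone_seed": spec.seed,
        "learning_rate": config.learning_rate,
        "weight_decay": config.weight_decay,
        "epochs": config.epochs,
        "embed_dim": config.embed_dim,
        "decision_threshold": config.decision_threshold,
    }
    state = head.state_dict()
    np.savez(path, **state, **{f"meta.{k}": np.asarray(v) for k, v in meta.items()})


def load_checkpoint(path) -> tuple[MILHead, dict]:
    data = dict(np.load(path, allow_pickle=False))
    meta = {k[5:]: data.pop(k).item() for k in list(data) if k.startswith("meta.")}
    return MILHead.from_state(data), meta
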