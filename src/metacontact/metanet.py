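"""Two-stage neural-network contact meta-predictor.

Stage 1 is a one-hidden-layer perceptron (logistic activations throughout)
mapping per-pair feature vectors to an initial contact probability map.
Stage 2 slides an odd window (default 11 x 11) over the stage-1 map and
re-estimates each pair from its neighbourhood plus the global depth and
separation features; this removes isolated spurious responses and fills in
gaps inside genuine contact blocks, because real contacts come in stripes
and patches while noise does not.

Training delegates to scikit-learn's MLPClassifier under a fixed
``train_seed`` (initialization and minibatch shuffling both flow from it);
the fitted weights are extracted into a plain :class:`MLPModel` with a
numpy forward pass, so a saved model reloads bit-exactly from JSON and
inference has no scikit-learn dependency on the hot path.

Class imbalance (contacts are rare) is handled by deterministically
subsampling non-contacts to a 5:1 negative:positive ratio at training time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit
from sklearn.neural_network import MLPClassifier

from .covariation import DEFAULT_MIN_SEPARATION, ScoreMatrix
from .features import (
    FeatureConfig,
    PairFeatures,
    assemble_pair_features,
    depth_feature_vector,
    separation_onehot,
)
from .weighting import WeightedAlignment

NEGATIVE_TO_POSITIVE_RATIO = 5


@dataclass
class MetaNetConfig:
    stage2_window: int = 11
    hidden_units: int = 50
    epochs: int = 300
    learning_rate: float = 1e-3
    train_seed: int = 0
    pad_value: float = -1.0

    def __post_init__(self) -> None:
        if self.stage2_window < 3 or self.stage2_window % 2 != 1:
            raise ValueError("stage2_window must be odd and >= 3")


@dataclass
class MLPModel:
    """A fitted one-hidden-layer logistic MLP, serializable to JSON.

    Inputs are standardized with the per-feature mean and scale recorded
    at training time (features span very different ranges — coupling-score
    norms versus probabilities — and the network is trained without any
    other normalization).
    """

    w1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray
    w2: np.ndarray  # (n_hidden, 1)
    b2: np.ndarray
    train_seed: int
    feature_names: List[str] = field(default_factory=list)
    x_mean: Optional[np.ndarray] = None  # default: no centering
    x_scale: Optional[np.ndarray] = None  # default: unit scale

    def __post_init__(self) -> None:
        if self.x_mean is None:
            self.x_mean = np.zeros(self.w1.shape[0])
        if self.x_scale is None:
            self.x_scale = np.ones(self.w1.shape[0])
        for arr in (self.w1, self.b1, self.w2, self.b2, self.x_mean, self.x_scale):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite model weights")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model input {self.n_inputs}"
            )
        Z = (X - self.x_mean) / self.x_scale
        hidden = expit(Z @ self.w1 + self.b1)
        return expit(hidden @ self.w2 + self.b2).ravel()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    def to_dict(self) -> dict:
        return {
            "format": "metacontact-mlp-1",
            "train_seed": self.train_seed,
            "feature_names": self.feature_names,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPModel":
        if payload.get("format") != "metacontact-mlp-1":
            raise ValueError("not a metacontact MLP model file")
        return cls(
            w1=np.array(payload["w1"], dtype=float),
            b1=np.array(payload["b1"], dtype=float),
            w2=np.array(payload["w2"], dtype=float),
            b2=np.array(payload["b2"], dtype=float),
            train_seed=int(payload["train_seed"]),
            feature_names=list(payload["feature_names"]),
            x_mean=np.array(payload["x_mean"], dtype=float),
            x_scale=np.array(payload["x_scale"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _balance_classes(
    X: np.ndarray, y: np.ndarray, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    keep_neg = min(len(neg), NEGATIVE_TO_POSITIVE_RATIO * len(pos))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    neg_kept = rng.choice(neg, size=keep_neg, replace=False) if keep_neg else neg[:0]
    idx = np.sort(np.concatenate([pos, neg_kept]))
    return X[idx], y[idx]


def _train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    config: MetaNetConfig,
    feature_names: List[str],
) -> MLPModel:
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    Xb, yb = _balance_classes(X, y, config.train_seed)
    mu = Xb.mean(axis=0)
    sd = Xb.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xb = (Xb - mu) / sd
    clf = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="logistic",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=config.train_seed,
        n_iter_no_change=50,
        tol=1e-6,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are expected
        clf.fit(Xb, yb)
    return MLPModel(
        w1=clf.coefs_[0],
        b1=clf.intercepts_[0],
        w2=clf.coefs_[1],
        b2=clf.intercepts_[1],
        train_seed=config.train_seed,
        feature_names=feature_names,
        x_mean=mu,
        x_scale=sd,
    )


def train_stage1(
    features: PairFeatures, labels: np.ndarray, config: MetaNetConfig
) -> MLPModel:
    """Train the stage-1 pair classifier on labelled pair features."""
    y = np.asarray(labels).astype(int)
    if y.shape[0] != features.matrix.shape[0]:
        raise ValueError("one label per pair required")
    return _train_mlp(features.matrix, y, config, features.feature_names)


@dataclass
class ContactProbabilityMap:
    """Symmetric L x L map of contact probabilities; near-diagonal masked."""

    probs: np.ndarray
    min_separation: int = DEFAULT_MIN_SEPARATION
    stage: int = 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        L = self.probs.shape[0]
        if self.probs.shape != (L, L):
            raise ValueError("probability map must be square")
        idx = np.arange(L)
        eligible = np.abs(idx[:, None] - idx[None, :]) >= self.min_separation
        vals = self.probs[eligible]
        if vals.size and (np.any(vals < 0) or np.any(vals > 1) or not np.all(np.isfinite(vals))):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    def ranked_pairs(self) -> List[Tuple[int, int, float]]:
        """Eligible pairs (0-based, i<j) by probability desc, ties lexicographic."""
        out = []
        for i in range(self.L):
            for j in range(i + self.min_separation, self.L):
                out.append((i, j, float(self.probs[i, j])))
        out.sort(key=lambda t: (-t[2], t[0], t[1]))
        return out


def predict_stage1(
    model: MLPModel, features: PairFeatures
) -> ContactProbabilityMap:
    """Apply the stage-1 model and assemble a symmetric probability map."""
    p = model.predict_proba(features.matrix)
    probs = np.zeros((features.L, features.L))
    for (i, j), pij in zip(features.pairs, p):
        probs[i, j] = probs[j, i] = pij
    return ContactProbabilityMap(probs=probs, stage=1)


def extract_stage2_features(
    cmap: ContactProbabilityMap,
    pair: Tuple[int, int],
    depth_features: np.ndarray,
    window: int = 11,
    pad_value: float = -1.0,
    center_rank: Optional[float] = None,
) -> np.ndarray:
    """Window x window patch of stage-1 probabilities centred at (i, j),
    row-major, padded outside the map, plus global (depth, optional
    center-rank) and separation features."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    i, j = pair
    half = window // 2
    L = cmap.L
    patch = np.full((window, window), pad_value)
    r0, r1 = i - half, i + half + 1
    c0, c1 = j - half, j + half + 1
    rr0, rr1 = max(r0, 0), min(r1, L)
    cc0, cc1 = max(c0, 0), min(c1, L)
    patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = cmap.probs[rr0:rr1, cc0:cc1]
    sep = separation_onehot(abs(j - i))
    extras = [] if center_rank is None else [center_rank]
    return np.concatenate([patch.ravel(), extras, depth_features, sep])


def stage2_feature_names(window: int, n_depth: int = 3) -> List[str]:
    names = [f"win_{r}_{c}" for r in range(window) for c in range(window)]
    names += ["center_rank"]
    names += [f"depth_{k}" for k in range(n_depth)]
    names += [f"sep_bin{k}" for k in range(len(separation_onehot(4)))]
    return names


def _center_ranks(
    cmap: ContactProbabilityMap, pairs: Sequence[Tuple[int, int]]
) -> np.ndarray:
    """Within-map quantile rank of each pair's stage-1 probability.

    Scale-free: lets stage 2 preserve the stage-1 ranking when the
    neighbourhood carries no extra information (shallow alignments).
    """
    vals = np.sort([cmap.probs[p] for p in pairs])
    ranks = np.searchsorted(vals, [cmap.probs[p] for p in pairs], side="right")
    return ranks / max(len(vals), 1)


def _stage2_matrix(
    cmap: ContactProbabilityMap,
    pairs: Sequence[Tuple[int, int]],
    depth_features: np.ndarray,
    config: MetaNetConfig,
) -> np.ndarray:
    ranks = _center_ranks(cmap, pairs)
    return np.vstack(
        [
            extract_stage2_features(
                cmap, p, depth_features, config.stage2_window, config.pad_value,
                center_rank=r,
            )
            for p, r in zip(pairs, ranks)
        ]
    )


def train_stage2(
    maps_and_labels: Sequence[Tuple[ContactProbabilityMap, Sequence[Tuple[int, int]], np.ndarray, np.ndarray]],
    config: MetaNetConfig,
) -> MLPModel:
    """Train the stage-2 refiner.

    ``maps_and_labels`` holds, per training family, the stage-1 map, the
    eligible pairs, the per-family depth feature vector and the binary
    labels for those pairs.
    """
    X_parts, y_parts = [], []
    n_depth = 3
    for cmap, pairs, depth, y in maps_and_labels:
        n_depth = len(depth)
        X_parts.append(_stage2_matrix(cmap, pairs, depth, config))
        y_parts.append(np.asarray(y).astype(int))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    return _train_mlp(
        X, y, config, stage2_feature_names(config.stage2_window, n_depth)
    )


def predict_stage2(
    model: MLPModel,
    cmap: ContactProbabilityMap,
    depth_features: np.ndarray,
    config: MetaNetConfig,
) -> ContactProbabilityMap:
    """Refine a stage-1 map into the final stage-2 probability map."""
    pairs = [
        (i, j)
        for i in range(cmap.L)
        for j in range(i + cmap.min_separation, cmap.L)
    ]
    X = _stage2_matrix(cmap, pairs, depth_features, config)
    p = model.predict_proba(X)
    probs = np.zeros((cmap.L, cmap.L))
    for (i, j), pij in zip(pairs, p):
        probs[i, j] = probs[j, i] = pij
    return ContactProbabilityMap(probs=probs, min_separation=cmap.min_separation, stage=2)


def predict_contacts(
    walign: WeightedAlignment,
    scores: Sequence[ScoreMatrix],
    stage1: MLPModel,
    stage2: MLPModel,
    feature_config: Optional[FeatureConfig] = None,
    net_config: Optional[MetaNetConfig] = None,
    aux: Optional[np.ndarray] = None,
) -> ContactProbabilityMap:
    """End-to-end prediction: features -> stage 1 -> stage 2."""
    feature_config = feature_config or FeatureConfig()
    net_config = net_config or MetaNetConfig()
    feats = assemble_pair_features(walign, scores, aux=aux, config=feature_config)
    map1 = predict_stage1(stage1, feats)
    depth = depth_feature_vector(walign)
    return predict_stage2(stage2, map1, depth, net_config)
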