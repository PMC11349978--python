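"""Dual-branch CNN classifier and nearest-pattern OA grader.

The dual CNN runs the fused radiograph through one convolutional branch
(C1: 64 filters 3x3, C2: 128 filters 5x5, each followed by 2x2 max
pooling) and the Morphological Feature Matrix through a second branch
(C3: 32 filters 5x5, C4: 64 filters 7x7, pooled likewise).  Both branch
outputs are globally average-pooled, concatenated, and passed through three
fully connected layers (4096 -> 2048 -> 2) with ReLU and a terminal
softmax, yielding normal-vs-osteoarthritis probabilities.  A
``width_multiplier`` shrinks every filter count and dense width uniformly
for desk-scale experiments.

The backbone is trained by seeded minibatch SGD on cross-entropy; the
final dense layer is then refined by the Gaussian Aquila Optimizer, with
the backprop solution seeded into the population so tuning can never
degrade validation fitness.  Grading of OA-positive images is a separate
nearest-pattern classifier over the six morphological features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .optim import GAOConfig, GaussianAquilaOptimizer, ObjectiveSpec

__all__ = [
    "DCNNSpec",
    "DualCNN",
    "TrainedMatrix",
    "build_dcnn",
    "train_backbone",
    "gao_tune_fcnn",
    "DualCNNClassifier",
    "NearestPatternGrader",
    "fit_grades",
    "assign_grade",
]


@dataclass
class DCNNSpec:
    """Architecture of the dual CNN.

    Defaults give the full-size network (512-pixel input, width 1); tests
    and the synthetic-phantom experiments shrink both.
    """

    input_size: int = 512
    mfm_grid: tuple[int, int] = (32, 32)
    mfm_channels: int = 6
    width_multiplier: float = 1.0
    branch1_filters: tuple[int, int] = (64, 128)
    branch1_kernels: tuple[int, int] = (3, 5)
    branch2_filters: tuple[int, int] = (32, 64)
    branch2_kernels: tuple[int, int] = (5, 7)
    fcnn_sizes: tuple[int, int, int] = (4096, 2048, 2)
    dropout: float = 0.5  # on the hidden dense layers, training time only
    flatten_mode: bool = False  # flatten branch maps instead of global pooling

    def scaled(self, n: int) -> int:
        return max(1, int(round(n * self.width_multiplier)))

    def validate(self) -> None:
        if self.input_size < 4:
            raise ValueError("input_size too small for the two-stage pooling cascade")
        if min(self.mfm_grid) < 4:
            raise ValueError("mfm_grid too small for the two-stage pooling cascade")
        if self.fcnn_sizes[-1] != 2:
            raise ValueError("the final dense layer must have 2 output units")


class DualCNN:
    """The assembled network; see module docstring for the layer plan."""

    def __init__(self, spec: DCNNSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        s = spec.scaled
        f1, f2 = spec.branch1_filters
        k1, k2 = spec.branch1_kernels
        g1, g2 = spec.branch2_filters
        q1, q2 = spec.branch2_kernels
        self.branch1 = [
            nn.Conv2D(1, s(f1), k1, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2D(s(f1), s(f2), k2, rng), nn.ReLU(), nn.MaxPool2x2(),
        ]
        self.branch2 = [
            nn.Conv2D(spec.mfm_channels, s(g1), q1, rng), nn.ReLU(), nn.MaxPool2x2(),
            nn.Conv2D(s(g1), s(g2), q2, rng), nn.ReLU(), nn.MaxPool2x2(),
        ]
        self.gap1 = nn.GlobalAvgPool()
        self.gap2 = nn.GlobalAvgPool()
        if spec.flatten_mode:
            m1 = (spec.input_size // 4) ** 2 * s(f2)
            m2 = (spec.mfm_grid[0] // 4) * (spec.mfm_grid[1] // 4) * s(g2)
        else:
            m1, m2 = s(f2), s(g2)
        concat = m1 + m2
        d1, d2, d3 = (s(spec.fcnn_sizes[0]), s(spec.fcnn_sizes[1]), spec.fcnn_sizes[2])
        drop_rng = np.random.default_rng((seed, 1))
        self.fcnn = [
            nn.Dense(concat, d1, rng), nn.ReLU(), nn.Dropout(spec.dropout, drop_rng),
            nn.Dense(d1, d2, rng), nn.ReLU(), nn.Dropout(spec.dropout, drop_rng),
            nn.Dense(d2, d3, rng),
        ]

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self):
        return self.branch1 + self.branch2 + self.fcnn

    @property
    def final_dense(self) -> nn.Dense:
        return self.fcnn[-1]

    def _branch(self, layers, gap, x, train):
        for layer in layers:
            x = layer.forward(x, train=train)
        if self.spec.flatten_mode:
            self._pre_flat_shape = x.shape
            return x.reshape(x.shape[0], -1)
        return gap.forward(x, train=train)

    def penultimate(self, images: np.ndarray, mfms: np.ndarray, train: bool = False) -> np.ndarray:
        """Activations feeding the final dense layer."""
        x1 = self._branch(self.branch1, self.gap1, self._prep_images(images), train)
        x2 = self._branch(self.branch2, self.gap2, self._prep_mfms(mfms), train)
        h = np.concatenate([x1, x2], axis=1)
        if train:
            self._split = x1.shape[1]
        for layer in self.fcnn[:-1]:
            h = layer.forward(h, train=train)
        return h

    def logits(self, images: np.ndarray, mfms: np.ndarray, train: bool = False) -> np.ndarray:
        return self.final_dense.forward(self.penultimate(images, mfms, train), train=train)

    def predict_proba(self, images: np.ndarray, mfms: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(images, mfms))

    @staticmethod
    def _prep_images(images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=nn.DTYPE)
        if arr.ndim == 3:
            arr = arr[:, None]  # (N, 1, H, W)
        # normalise 8-bit intensities into [0, 1] for stable gradients
        return arr / nn.DTYPE(255.0)

    @staticmethod
    def _prep_mfms(mfms: np.ndarray) -> np.ndarray:
        arr = np.asarray(mfms, dtype=nn.DTYPE)
        # accept channels-last (N, gh, gw, C) and convert to channels-first
        if arr.ndim != 4:
            raise ValueError(f"MFM batch must be 4-D, got shape {arr.shape}")
        if arr.shape[1] != 6 and arr.shape[-1] == 6:
            arr = arr.transpose(0, 3, 1, 2)
        return arr

    def _backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.fcnn):
            grad = layer.backward(grad)
        g1, g2 = grad[:, : self._split], grad[:, self._split :]
        for branch, gap, g in ((self.branch1, self.gap1, g1), (self.branch2, self.gap2, g2)):
            if self.spec.flatten_mode:
                g = g.reshape(self._pre_flat_shape)
            else:
                g = gap.backward(g)
            for layer in reversed(branch):
                g = layer.backward(g)

    # -- serialisation -----------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                out[f"layer{i}_{p}"] = getattr(layer, p).copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                arr = np.asarray(weights[f"layer{i}_{p}"], dtype=nn.DTYPE)
                if arr.shape != getattr(layer, p).shape:
                    raise ValueError(f"shape mismatch for layer{i}_{p}")
                setattr(layer, p, arr.copy())


@dataclass
class TrainedMatrix:
    """Learned parameter set plus training metadata; round-trips bit-exactly."""

    spec: DCNNSpec
    weights: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        meta = {"spec": asdict(self.spec), "metadata": self.metadata}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.weights)

    @classmethod
    def load(cls, path) -> "TrainedMatrix":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        spec_dict = meta["spec"]
        for key in ("mfm_grid", "branch1_filters", "branch1_kernels", "branch2_filters",
                    "branch2_kernels", "fcnn_sizes"):
            spec_dict[key] = tuple(spec_dict[key])
        return cls(DCNNSpec(**spec_dict), weights, meta["metadata"])

    def build_model(self) -> DualCNN:
        model = DualCNN(self.spec, seed=self.metadata.get("seed", 0))
        model.set_weights(self.weights)
        return model


def build_dcnn(spec: DCNNSpec, seed: int = 0) -> DualCNN:
    """Deterministically initialise a dual CNN from its spec."""
    return DualCNN(spec, seed=seed)


def train_backbone(
    model: DualCNN,
    images: np.ndarray,
    mfms: np.ndarray,
    labels: np.ndarray,
    epochs: int = 25,
    batch_size: int = 16,
    lr: float = 0.01,
    momentum: float = 0.9,
    weight_decay: float = 5e-4,
    seed: int = 0,
) -> TrainedMatrix:
    """Minibatch SGD on softmax cross-entropy; returns the TrainedMatrix.

    ``labels`` are integer class indices (0 = normal, 1 = osteoarthritis).
    Zero epochs returns the initial weights unchanged.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2 and epochs > 0:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.layers, lr=lr, momentum=momentum, weight_decay=weight_decay)
    n = len(labels)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.logits(images[idx], mfms[idx], train=True)
            probs = nn.softmax(logits)
            loss = nn.cross_entropy(probs, labels[idx])
            onehot = np.eye(2, dtype=nn.DTYPE)[labels[idx]]
            dlogits = (probs.astype(nn.DTYPE) - onehot) / len(idx)
            model._backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return TrainedMatrix(
        model.spec,
        model.get_weights(),
        metadata={"epochs": epochs, "seed": seed, "lr": lr, "batch_size": batch_size,
                  "weight_decay": weight_decay, "loss_curve": losses},
    )


def _val_fitness(weight_vec, feats, labels, shape):
    w_size = shape[0] * shape[1]
    W = weight_vec[:w_size].reshape(shape).astype(nn.DTYPE)
    b = weight_vec[w_size:].astype(nn.DTYPE)
    logits = feats @ W.T + b
    probs = nn.softmax(logits)
    err = float((probs.argmax(axis=1) != labels).mean())
    ce = nn.cross_entropy(probs, labels)
    # misclassification rate with a small cross-entropy tie-break
    return err + 1e-6 * ce


def gao_tune_fcnn(
    model: DualCNN,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    gao_config: GAOConfig | None = None,
    weight_bound: float = 2.0,
    dim_cap: int = 16384,
) -> TrainedMatrix:
    """Refine the final dense layer with the Gaussian Aquila Optimizer.

    The search runs over the final layer's weights and biases inside
    ``[-w_max, w_max]`` (w_max grown to cover the incumbent), with fitness
    the validation misclassification rate (cross-entropy tie-break).  The
    backprop incumbent seeds one population member, so with elitist
    acceptance the tuned validation fitness can never exceed the
    incumbent's.  ``train_data``/``val_data`` are (images, mfms, labels).
    """
    if gao_config is None:
        gao_config = GAOConfig(max_iterations=40, convergence_window=40)
    layer = model.final_dense
    shape = layer.W.shape
    dim = layer.W.size + layer.b.size
    if dim > dim_cap:
        raise ValueError(
            f"GAO dimension {dim} exceeds cap {dim_cap}; reduce width_multiplier"
        )
    val_feats = model.penultimate(val_data[0], val_data[1])
    val_labels = np.asarray(val_data[2])
    incumbent = np.concatenate([layer.W.ravel(), layer.b]).astype(float)
    w_max = max(weight_bound, 1.1 * float(np.abs(incumbent).max()))
    objective = ObjectiveSpec(
        evaluate=lambda v: _val_fitness(v, val_feats, val_labels, shape),
        dim=dim,
        lower_bound=np.full(dim, -w_max),
        upper_bound=np.full(dim, w_max),
    )
    result = GaussianAquilaOptimizer(gao_config).optimize(objective, seed_positions=[incumbent])
    best = result.best_position
    layer.W = best[: layer.W.size].reshape(shape).astype(nn.DTYPE)
    layer.b = best[layer.W.size :].astype(nn.DTYPE)
    return TrainedMatrix(
        model.spec,
        model.get_weights(),
        metadata={"gao_seed": gao_config.seed, "gao_generations": result.generations_elapsed,
                  "val_fitness": result.best_fitness},
    )


class DualCNNClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style estimator wrapping the dual CNN plus GAO refinement.

    ``X`` is a tuple ``(images, mfms)`` with images of shape (N, H, W) and
    MFMs of shape (N, gh, gw, 6); ``y`` holds binary labels.  Set
    ``gao_iterations=0`` to skip the metaheuristic refinement step.
    """

    def __init__(
        self,
        input_size: int = 64,
        width_multiplier: float = 0.25,
        mfm_grid: tuple[int, int] = (4, 4),
        epochs: int = 25,
        batch_size: int = 16,
        lr: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 5e-4,
        gao_iterations: int = 40,
        validation_fraction: float = 0.2,
        mfm_scaling: str = "dataset",
        seed: int = 0,
    ):
        self.input_size = input_size
        self.width_multiplier = width_multiplier
        self.mfm_grid = mfm_grid
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.gao_iterations = gao_iterations
        self.validation_fraction = validation_fraction
        self.mfm_scaling = mfm_scaling
        self.seed = seed

    def _split_X(self, X):
        images, mfms = X
        return np.asarray(images), np.asarray(mfms)

    def _scale_mfms(self, mfms: np.ndarray) -> np.ndarray:
        if self.mfm_scaling != "dataset":
            return mfms
        occupied = np.any(mfms != 0.0, axis=-1)
        out = mfms.copy()
        out[occupied] = (mfms[occupied] - self.mfm_mean_) / self.mfm_std_
        return out

    def fit(self, X, y):
        images, mfms = self._split_X(X)
        y = np.asarray(y)
        self.classes_, labels = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("DualCNNClassifier is a binary classifier")
        if self.mfm_scaling == "dataset":
            # channel statistics over the occupied tiles of the training set;
            # empty tiles stay at zero
            occupied = np.any(mfms != 0.0, axis=-1)
            occ = mfms[occupied] if occupied.any() else mfms.reshape(-1, mfms.shape[-1])
            self.mfm_mean_ = occ.mean(axis=0)
            std = occ.std(axis=0)
            std[std == 0] = 1.0
            self.mfm_std_ = std
        mfms = self._scale_mfms(mfms)
        spec = DCNNSpec(
            input_size=self.input_size,
            mfm_grid=tuple(self.mfm_grid),
            width_multiplier=self.width_multiplier,
        )
        self.model_ = build_dcnn(spec, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        n = len(labels)
        order = rng.permutation(n)
        n_val = max(2, int(round(self.validation_fraction * n))) if self.gao_iterations else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        self.trained_matrix_ = train_backbone(
            self.model_, images[train_idx], mfms[train_idx], labels[train_idx],
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            momentum=self.momentum, weight_decay=self.weight_decay, seed=self.seed,
        )
        self.loss_curve_ = self.trained_matrix_.metadata["loss_curve"]
        if self.gao_iterations:
            cfg = GAOConfig(
                max_iterations=self.gao_iterations,
                convergence_window=self.gao_iterations,
                seed=self.seed,
            )
            pre = _val_fitness(
                np.concatenate([self.model_.final_dense.W.ravel(), self.model_.final_dense.b]),
                self.model_.penultimate(images[val_idx], mfms[val_idx]),
                labels[val_idx],
                self.model_.final_dense.W.shape,
            )
            self.trained_matrix_ = gao_tune_fcnn(
                self.model_,
                (images[train_idx], mfms[train_idx], labels[train_idx]),
                (images[val_idx], mfms[val_idx], labels[val_idx]),
                gao_config=cfg,
            )
            self.pre_tuning_val_fitness_ = pre
            self.val_fitness_ = self.trained_matrix_.metadata["val_fitness"]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        images, mfms = self._split_X(X)
        return self.model_.predict_proba(images, self._scale_mfms(mfms))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class NearestPatternGrader(ClassifierMixin, BaseEstimator):
    """OA grade (1-4) by nearest trained pattern.

    Fits one centroid and per-channel dispersion per grade over
    standardised morphological feature vectors; assignment minimises the
    dispersion-scaled Euclidean distance, ties going to the lower grade.
    """

    GRADES = (1, 2, 3, 4)

    def fit(self, F, grades):
        F = np.asarray(F, dtype=float)
        grades = np.asarray(grades)
        missing = [g for g in self.GRADES if g not in grades]
        if missing:
            raise ValueError(f"missing samples for grades: {missing}")
        self.mean_ = F.mean(axis=0)
        std = F.std(axis=0)
        std[std == 0] = 1.0
        self.std_ = std
        Z = (F - self.mean_) / self.std_
        pooled = Z.std(axis=0)
        pooled[pooled == 0] = 1.0
        self.centroids_ = np.stack([Z[grades == g].mean(axis=0) for g in self.GRADES])
        disp = np.stack([Z[grades == g].std(axis=0) for g in self.GRADES])
        disp = np.where(disp == 0, pooled, disp)
        self.dispersion_ = disp
        self.classes_ = np.array(self.GRADES)
        return self

    def predict(self, F):
        check_is_fitted(self, "centroids_")
        Z = (np.asarray(F, dtype=float) - self.mean_) / self.std_
        d = np.linalg.norm(
            (Z[:, None, :] - self.centroids_[None]) / self.dispersion_[None], axis=2
        )
        return self.classes_[d.argmin(axis=1)]  # argmin keeps the lowest grade on ties


def fit_grades(features: np.ndarray, grades: np.ndarray) -> NearestPatternGrader:
    """Fit the per-grade trained patterns (centroid + dispersion)."""
    return NearestPatternGrader().fit(features, grades)


def assign_grade(features: np.ndarray, grader: NearestPatternGrader) -> np.ndarray:
    """Assign OA grades to one or more feature vectors."""
    F = np.atleast_2d(np.asarray(features, dtype=float))
    return grader.predict(F)
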