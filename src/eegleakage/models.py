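"""Segment classifiers with a scikit-learn estimator surface.

:class:`CNNSegmentClassifier` is the study's convolutional model — two
time-axis convolutional blocks and a small classification head — trained
with Adam (L2 weight decay), binary cross-entropy, a warm-up/linear-decay
learning-rate schedule, a per-fit validation split, and min-validation-loss
model selection. :class:`LinearSegmentBaseline` is a regularised logistic
regression on flattened segments, used as a cheap model-agnostic
cross-check of partition effects.

Both follow the scikit-learn contract (``fit`` / ``predict`` /
``decision_function``, ``get_params`` / ``set_params``, trailing-underscore
fitted attributes) except that ``X`` is the 3-D segment tensor
``(n, C, L)`` rather than a 2-D feature matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._seeds import spawn_rng
from .nn import Adam, ConvNet, bce_with_logits, lr_at_step
from .preprocess import NEGATIVE, POSITIVE

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "FitResult",
    "build_cnn",
    "train_model",
    "predict",
    "linear_baseline",
    "CNNSegmentClassifier",
    "LinearSegmentBaseline",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the convolutional classifier."""

    conv1_filters: int = 512
    conv1_kernel: int = 65
    conv2_filters: int = 10
    conv2_kernel: int = 33
    pool1: int = 2
    pool2: int = 4
    hidden_units: int = 160
    elu_alpha: float = 1.0
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.1
    padding_mode: str = "same"


@dataclass
class TrainConfig:
    """Optimisation hyperparameters."""

    max_epochs: int = 15
    batch_size: int = 100
    learning_rate: float = 1e-3
    warmup: float = 0.1
    weight_decay: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")


@dataclass
class FitResult:
    """A trained network plus its training history."""

    net: ConvNet
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    selected_epoch: int = 0  # index of the minimum-validation-loss epoch


def build_cnn(
    C: int, L: int, cfg: ModelConfig | None = None, *, seed: int = 0
) -> ConvNet:
    """Construct the untrained network for segments of shape (C, L)."""
    cfg = cfg or ModelConfig()
    rng = spawn_rng(seed, "model")
    return ConvNet(
        C,
        L,
        rng,
        conv1_filters=cfg.conv1_filters,
        conv1_kernel=cfg.conv1_kernel,
        conv2_filters=cfg.conv2_filters,
        conv2_kernel=cfg.conv2_kernel,
        pool1=cfg.pool1,
        pool2=cfg.pool2,
        hidden_units=cfg.hidden_units,
        elu_alpha=cfg.elu_alpha,
        bn_epsilon=cfg.bn_epsilon,
        bn_momentum=cfg.bn_momentum,
        padding_mode=cfg.padding_mode,
    )


def train_model(
    net: ConvNet, X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None
) -> FitResult:
    """Train ``net`` and return the minimum-validation-loss parameters.

    A ``val_fraction`` share of the training segments is held out (from
    the training indices only) for model selection; after every epoch the
    validation loss is evaluated with running batch-norm statistics, and
    the parameters of the best epoch are restored at the end.
    Deterministic under a fixed config seed.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        warnings.warn(
            "training set contains a single class; fit is degenerate",
            stacklevel=2,
        )
    rng = spawn_rng(cfg.seed, "model", 1)

    n_val = max(1, int(round(cfg.val_fraction * len(X))))
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("training set too small for the validation split")
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    params = net.params()
    opt = Adam(
        params,
        lr=cfg.learning_rate,
        beta1=cfg.adam_beta1,
        beta2=cfg.adam_beta2,
        weight_decay=cfg.weight_decay,
    )
    n_batches = int(np.ceil(len(Xtr) / cfg.batch_size))
    total_steps = cfg.max_epochs * n_batches
    result = FitResult(net=net)
    best_val = np.inf
    best_state = net.get_state()
    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            logits = net.forward(Xtr[idx], train=True)
            loss, grad = bce_with_logits(logits, ytr[idx])
            net.backward(grad)
            lr = lr_at_step(step, total_steps, cfg.learning_rate, cfg.warmup)
            opt.step(lr=lr)
            epoch_loss += loss * len(idx)
            step += 1
        val_logits = net.predict_logits(Xval)
        val_loss, _ = bce_with_logits(val_logits, yval)
        result.train_loss.append(epoch_loss / len(Xtr))
        result.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            result.selected_epoch = epoch
    net.set_state(best_state)
    return result


def predict(
    fit: FitResult, X: np.ndarray, *, return_scores: bool = False
):
    """Classify segments: positive iff logit > 0 (ties go negative)."""
    X = np.asarray(X, dtype=np.float32)
    if len(X) == 0:
        empty = np.array([], dtype=np.int64)
        return (empty, np.array([])) if return_scores else empty
    if X.shape[1:] != (fit.net.C, fit.net.L):
        raise ValueError(
            f"segments of shape {X.shape[1:]} do not match the model's "
            f"build-time shape ({fit.net.C}, {fit.net.L})"
        )
    scores = fit.net.predict_logits(X)
    labels = np.where(scores > 0, POSITIVE, NEGATIVE)
    return (labels, scores) if return_scores else labels


class CNNSegmentClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn wrapper around the convolutional segment classifier.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`;
    ``random_state`` seeds initialisation, the validation split and batch
    shuffling (one isolated stream, independent of any data-split seeds).

    Fitted attributes: ``net_``, ``history_`` (per-epoch train/val loss),
    ``best_epoch_``, ``classes_``, ``n_parameters_``.
    """

    def __init__(
        self,
        conv1_filters: int = 512,
        conv1_kernel: int = 65,
        conv2_filters: int = 10,
        conv2_kernel: int = 33,
        pool1: int = 2,
        pool2: int = 4,
        hidden_units: int = 160,
        elu_alpha: float = 1.0,
        bn_epsilon: float = 1e-5,
        bn_momentum: float = 0.1,
        padding_mode: str = "same",
        max_epochs: int = 15,
        batch_size: int = 100,
        learning_rate: float = 1e-3,
        warmup: float = 0.1,
        weight_decay: float = 0.01,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.conv1_filters = conv1_filters
        self.conv1_kernel = conv1_kernel
        self.conv2_filters = conv2_filters
        self.conv2_kernel = conv2_kernel
        self.pool1 = pool1
        self.pool2 = pool2
        self.hidden_units = hidden_units
        self.elu_alpha = elu_alpha
        self.bn_epsilon = bn_epsilon
        self.bn_momentum = bn_momentum
        self.padding_mode = padding_mode
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.warmup = warmup
        self.weight_decay = weight_decay
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            conv1_filters=self.conv1_filters,
            conv1_kernel=self.conv1_kernel,
            conv2_filters=self.conv2_filters,
            conv2_kernel=self.conv2_kernel,
            pool1=self.pool1,
            pool2=self.pool2,
            hidden_units=self.hidden_units,
            elu_alpha=self.elu_alpha,
            bn_epsilon=self.bn_epsilon,
            bn_momentum=self.bn_momentum,
            padding_mode=self.padding_mode,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            warmup=self.warmup,
            weight_decay=self.weight_decay,
            adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_segments, C, L)")
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        net = build_cnn(
            X.shape[1], X.shape[2], self._model_config(),
            seed=self.random_state,
        )
        fit_result = train_model(net, X, y, self._train_config())
        self.net_ = net
        self.fit_result_ = fit_result
        self.history_ = {
            "train_loss": list(fit_result.train_loss),
            "val_loss": list(fit_result.val_loss),
        }
        self.best_epoch_ = fit_result.selected_epoch
        self.n_parameters_ = net.n_parameters()
        return self

    def decision_function(self, X):
        _, scores = predict(self.fit_result_, np.asarray(X), return_scores=True)
        return scores

    def predict(self, X):
        return predict(self.fit_result_, np.asarray(X))

    def predict_proba(self, X):
        z = self.decision_function(X).astype(np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p, p])


class LinearSegmentBaseline(ClassifierMixin, BaseEstimator):
    """L2-regularised logistic regression on flattened segments.

    A deliberately simple reference model: partition effects that appear
    under both this baseline and the convolutional model are attributable
    to the data split, not to the architecture.
    """

    def __init__(self, C_reg: float = 1.0, max_iter: int = 500,
                 random_state: int = 0):
        self.C_reg = C_reg
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        Xf = X.reshape(len(X), -1)
        self.classes_ = np.array([NEGATIVE, POSITIVE])
        self.scaler_ = StandardScaler()
        self.clf_ = LogisticRegression(
            C=self.C_reg, max_iter=self.max_iter,
            random_state=self.random_state,
        )
        if len(np.unique(y)) < 2:
            warnings.warn(
                "training set contains a single class; predicting it "
                "everywhere",
                stacklevel=2,
            )
            self.constant_ = int(np.asarray(y)[0])
            return self
        self.constant_ = None
        self.clf_.fit(self.scaler_.fit_transform(Xf), y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        Xf = X.reshape(len(X), -1)
        if len(Xf) == 0:
            return np.array([], dtype=np.int64)
        if self.constant_ is not None:
            return np.full(len(Xf), self.constant_, dtype=np.int64)
        return self.clf_.predict(self.scaler_.transform(Xf))

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        Xf = X.reshape(len(X), -1)
        if self.constant_ is not None:
            sign = 1.0 if self.constant_ == POSITIVE else -1.0
            return np.full(len(Xf), sign)
        return self.clf_.decision_function(self.scaler_.transform(Xf))


def linear_baseline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    *,
    seed: int = 0,
) -> np.ndarray:
    """Fit the linear baseline and classify the test segments."""
    model = LinearSegmentBaseline(random_state=seed)
    model.fit(X_train, y_train)
    return model.predict(X_test)
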