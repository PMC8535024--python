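"""Lesion classifiers: compact GLCM CNN, Haralick random forest, PI-RADS rule.

The CNN consumes the 26-channel stack of 64x64 directional co-occurrence
matrices: conv(26->32, 3x3, pad 1) + BN + ReLU -> maxpool 2x2 ->
conv(32->64) + BN + ReLU -> maxpool 2x2 -> flatten -> FC 256 -> FC 2 ->
softmax, trained with class-weighted cross-entropy and Adam (lr 1e-5,
betas (0.9, 0.999), 200 epochs, batch size 10), keeping the epoch
checkpoint with the highest validation AUC. The random-forest baseline
(50 trees, gini, nodes expanded until pure, bootstrap) consumes the
104-dimensional Haralick vector. The PI-RADS rule predicts csPCa iff the
radiologist score is >= 4 (a single-operating-point classifier).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from . import nn
from .stats import auc

__all__ = ["CNNConfig", "RFConfig", "GLCMConvNetClassifier", "PIRADSRuleClassifier",
           "build_network", "cnn_forward", "train_cnn", "train_rf", "predict_rf",
           "pirads_cla", "network_parameter_count"]


@dataclass
class CNNConfig:
    """Architecture and optimization settings for the GLCM CNN."""

    conv_channels: tuple = ((26, 32), (32, 64))
    fc_hidden: int = 256
    n_classes: int = 2
    input_size: int = 64            # GLCM side length
    lr: float = 1e-5
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 200
    batch_size: int = 10
    class_weights: str | tuple | None = "balanced"
    seed: int = 0

    def validate(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.conv_channels[0][1] != self.conv_channels[1][0]:
            raise ValueError("conv channel sizes must chain")


@dataclass
class RFConfig:
    """Random-forest settings: 50 gini trees, pure leaves, bootstrap."""

    n_trees: int = 50
    split_criterion: str = "gini"
    max_depth: int | None = None    # expand until leaves are pure
    bootstrap: bool = True
    seed: int = 0

    def validate(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def build_network(config: CNNConfig, rng: np.random.Generator) -> nn.Sequential:
    (c_in, c_mid), (_, c_out) = config.conv_channels
    side = config.input_size // 4   # two 2x2 poolings
    return nn.Sequential(
        nn.Conv2d(c_in, c_mid, rng), nn.BatchNorm2d(c_mid), nn.ReLU(), nn.MaxPool2d(),
        nn.Conv2d(c_mid, c_out, rng), nn.BatchNorm2d(c_out), nn.ReLU(), nn.MaxPool2d(),
        nn.Flatten(),
        nn.Linear(c_out * side * side, config.fc_hidden, rng), nn.ReLU(),
        nn.Linear(config.fc_hidden, config.n_classes, rng),
    )


def network_parameter_count(config: CNNConfig = CNNConfig()) -> int:
    """Trainable parameter count implied by a CNN configuration."""
    return build_network(config, np.random.default_rng(0)).n_parameters()


def _to_channels_last(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4:
        raise ValueError("expected stacks of shape (n, channels, L, L)")
    return np.ascontiguousarray(X.transpose(0, 2, 3, 1))


class GLCMConvNetClassifier(ClassifierMixin, BaseEstimator):
    """Compact CNN over stacked directional GLCMs (scikit-learn estimator).

    Parameters mirror :class:`CNNConfig`; ``fit`` accepts stacks of shape
    ``(n, 26, 64, 64)`` and binary labels, with an optional held-out
    validation set used for best-epoch checkpoint selection (without one,
    the final-epoch weights are kept). ``class_weight='balanced'`` weights
    the loss by inverse class frequency on the training split.
    """

    def __init__(self, fc_hidden: int = 256, lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), epochs: int = 200,
                 batch_size: int = 10, class_weight: str | None = "balanced",
                 input_channels: int = 26, input_size: int = 64,
                 random_state: int = 0):
        self.fc_hidden = fc_hidden
        self.lr = lr
        self.betas = betas
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.input_channels = input_channels
        self.input_size = input_size
        self.random_state = random_state

    def _config(self) -> CNNConfig:
        return CNNConfig(conv_channels=((self.input_channels, 32), (32, 64)),
                         fc_hidden=self.fc_hidden, input_size=self.input_size,
                         lr=self.lr, betas=tuple(self.betas), epochs=self.epochs,
                         batch_size=self.batch_size, seed=self.random_state)

    def _class_weights(self, y: np.ndarray) -> np.ndarray:
        if self.class_weight is None:
            return np.ones(2)
        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=2)
            return y.size / (2.0 * counts)
        return np.asarray(self.class_weight, dtype=np.float64)

    def fit(self, X, y, X_val=None, y_val=None):
        config = self._config()
        config.validate()
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain both classes")
        yi = np.searchsorted(self.classes_, y)
        Xc = _to_channels_last(X)
        if Xc.shape[3] != self.input_channels or Xc.shape[1] != self.input_size:
            raise ValueError(
                f"expected stacks of shape (n, {self.input_channels}, "
                f"{self.input_size}, {self.input_size}), got {tuple(np.shape(X))[1:]}")
        weights = self._class_weights(yi)
        rng = np.random.default_rng(self.random_state)
        net = build_network(config, rng)
        opt = nn.Adam(net, lr=config.lr, betas=config.betas)
        has_val = X_val is not None and y_val is not None
        if has_val:
            Xv = _to_channels_last(X_val)
            yv = np.searchsorted(self.classes_, np.asarray(y_val))
            if np.unique(yv).size < 2:
                # single-class validation set: AUC (and therefore checkpoint
                # selection) is undefined; keep final-epoch weights
                has_val = False
        n = Xc.shape[0]
        history = []
        best_auc, best_state, best_epoch = -np.inf, None, -1
        for epoch in range(config.epochs):
            net.train()
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                idx = perm[start:start + config.batch_size]
                if idx.size < 2:
                    continue    # batch statistics are undefined for one sample
                logits = net.forward(Xc[idx])
                loss, dlogits = nn.weighted_cross_entropy(logits, yi[idx], weights)
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if has_val:
                val_auc = auc(self._scores(net, Xv), yv)
                row["val_auc"] = val_auc
                if val_auc > best_auc:
                    best_auc, best_state, best_epoch = val_auc, net.state_dict(), epoch
            history.append(row)
        if has_val and best_state is not None:
            net.load_state_dict(best_state)
            self.best_epoch_ = best_epoch
            self.best_val_auc_ = best_auc
        else:
            self.best_epoch_ = config.epochs - 1
        net.eval()
        self.network_ = net
        self.history_ = pd.DataFrame(history)
        self.n_parameters_ = net.n_parameters()
        return self

    @staticmethod
    def _scores(net: nn.Sequential, Xc: np.ndarray, batch: int = 64) -> np.ndarray:
        net.eval()
        out = np.empty(Xc.shape[0])
        for start in range(0, Xc.shape[0], batch):
            logits = net.forward(Xc[start:start + batch])
            out[start:start + batch] = nn.softmax(logits.astype(np.float64))[:, 1]
        return out

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        p1 = self._scores(self.network_, _to_channels_last(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def save_weights(self, path) -> None:
        """Persist the fitted network (npz) with a JSON config sidecar."""
        check_is_fitted(self, "network_")
        path = Path(path)
        np.savez(path, **self.network_.state_dict())
        sidecar = {"config": asdict(self._config()),
                   "classes": self.classes_.tolist(),
                   "best_epoch": int(self.best_epoch_)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    def load_weights(self, path) -> "GLCMConvNetClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        self.classes_ = np.asarray(sidecar["classes"])
        self.best_epoch_ = sidecar["best_epoch"]
        net = build_network(self._config(), np.random.default_rng(0))
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as data:
            net.load_state_dict(dict(data))
        net.eval()
        self.network_ = net
        self.history_ = pd.DataFrame()
        self.n_parameters_ = net.n_parameters()
        return self


def cnn_forward(stack, network: nn.Sequential) -> float:
    """P(csPCa) for a single stack under a fitted network (eval mode)."""
    arr = stack.matrices if hasattr(stack, "matrices") else np.asarray(stack)
    Xc = _to_channels_last(arr[None] if arr.ndim == 3 else arr)
    return float(GLCMConvNetClassifier._scores(network, Xc)[0])


def train_cnn(X_train, y_train, X_val, y_val, config: CNNConfig = CNNConfig()
              ) -> tuple[GLCMConvNetClassifier, pd.DataFrame]:
    """Train the GLCM CNN with validation-AUC checkpoint selection."""
    clf = GLCMConvNetClassifier(fc_hidden=config.fc_hidden, lr=config.lr,
                                betas=config.betas, epochs=config.epochs,
                                batch_size=config.batch_size,
                                input_channels=config.conv_channels[0][0],
                                input_size=config.input_size,
                                random_state=config.seed)
    clf.fit(X_train, y_train, X_val, y_val)
    return clf, clf.history_


def train_rf(features, labels, config: RFConfig = RFConfig()) -> RandomForestClassifier:
    """Fit the Haralick-feature random forest."""
    config.validate()
    X = np.asarray(features, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, criterion=config.split_criterion,
        max_depth=config.max_depth, bootstrap=config.bootstrap,
        random_state=config.seed)
    forest.fit(X, np.asarray(labels))
    return forest


def predict_rf(forest: RandomForestClassifier, features) -> np.ndarray:
    """Mean-tree P(csPCa) scores."""
    X = np.asarray(features, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN")
    return forest.predict_proba(X)[:, 1]


class PIRADSRuleClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based baseline: predict csPCa iff PI-RADS >= threshold (default 4).

    A single-operating-point classifier; its score is the binary prediction
    treated as a two-level ranking, the only reading under which an AUC is
    defined for the rule.
    """

    def __init__(self, threshold: int = 4):
        self.threshold = threshold

    @staticmethod
    def _pirads(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if "pirads" not in X.columns:
                raise ValueError("records must carry a 'pirads' column")
            X = X["pirads"].to_numpy()
        arr = np.asarray(X, dtype=np.float64)
        if np.isnan(arr).any():
            raise ValueError("missing PI-RADS score")
        if not np.isin(arr, (3, 4, 5)).all():
            raise ValueError("PI-RADS scores must be in {3, 4, 5}")
        return arr

    def fit(self, X, y=None):
        self._pirads(X)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        return (self._pirads(X) >= self.threshold).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        hard = self.predict(X).astype(np.float64)
        return np.column_stack([1.0 - hard, hard])


def pirads_cla(records) -> np.ndarray:
    """Hard csPCa predictions from the PI-RADS >= 4 rule."""
    return PIRADSRuleClassifier().fit(records).predict(records)
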