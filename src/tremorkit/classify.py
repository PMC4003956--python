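"""MLP diagnosis of tremor class from the 26-parameter feature vectors.

A single-hidden-layer perceptron with hyperbolic-tangent (tansig)
activations in both the hidden and output layers maps a feature vector to
three outputs, one per diagnostic class: class 1 = (1,0,0) essential
tremor, class 2 = (0,1,0) Parkinsonian tremor, class 3 = (0,0,1) healthy.
Inputs are z-scored with statistics fitted on the training rows only.
Training is stochastic back-propagation on the mean squared error: one
pass per epoch over the (seeded, reshuffled) training rows with a fixed
learning rate, for exactly 200 epochs by default.  The number of hidden
neurons is determined experimentally by sweeping 2-10 and repeating each
training 10 times from different seeded initializations.

Three experiment groups select feature columns: PSD only (parameters
1-9), HOS only (parameters 10-26) and all 26 parameters.  Results report
the mean validation error and its decomposition by true pathology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simulate import CLASS_LABELS

__all__ = [
    "FEATURE_GROUPS",
    "Normalizer",
    "MLPModel",
    "ExperimentResult",
    "labels_to_onehot",
    "normalize_fit",
    "normalize_apply",
    "train_mlp",
    "predict",
    "evaluate",
    "run_test_group",
]

#: Feature-column selections per experiment group (0-based, inclusive ranges
#: over the 26 parameters: 1-9, 10-26, 1-26).
FEATURE_GROUPS = {
    "psd_only": np.arange(0, 9),
    "hos_only": np.arange(9, 26),
    "all": np.arange(0, 26),
}

N_CLASSES = 3


def labels_to_onehot(labels: Sequence[str]) -> np.ndarray:
    """Map class labels to the one-hot coding ET=(1,0,0), PD=(0,1,0), healthy=(0,0,1)."""
    idx = np.array([CLASS_LABELS.index(l) for l in labels])
    out = np.zeros((len(idx), N_CLASSES))
    out[np.arange(len(idx)), idx] = 1.0
    return out


@dataclass(frozen=True)
class Normalizer:
    """Per-feature z-score statistics fitted on training data.

    Zero-variance features are mapped with std := 1 so constant columns
    become zeros rather than dividing by zero.
    """

    mean: np.ndarray
    std: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[-1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} features, got {X.shape[-1]}")
        return (X - self.mean) / self.std


def normalize_fit(X: np.ndarray) -> Normalizer:
    """Fit zero-mean/unit-std statistics on the training rows."""
    X = np.asarray(X, float)
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return Normalizer(mean=mean, std=std)


def normalize_apply(norm: Normalizer, X: np.ndarray) -> np.ndarray:
    """Apply training statistics to any row set (training or validation)."""
    return norm.apply(X)


@dataclass
class MLPModel:
    """Weights, biases and input normalization of a trained 2-layer tansig MLP."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    normalizer: Normalizer
    feature_columns: np.ndarray = field(default_factory=lambda: np.arange(26))

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_n(self) -> int:
        return self.W1.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network outputs for already-normalized inputs (rows)."""
        H = np.tanh(X @ self.W1.T + self.b1)
        return np.tanh(H @ self.W2.T + self.b2)

    def to_json(self) -> str:
        return json.dumps({
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "norm_mean": self.normalizer.mean.tolist(),
            "norm_std": self.normalizer.std.tolist(),
            "feature_columns": self.feature_columns.tolist(),
        })

    @staticmethod
    def from_json(text: str) -> "MLPModel":
        d = json.loads(text)
        return MLPModel(
            W1=np.asarray(d["W1"], float), b1=np.asarray(d["b1"], float),
            W2=np.asarray(d["W2"], float), b2=np.asarray(d["b2"], float),
            normalizer=Normalizer(np.asarray(d["norm_mean"], float),
                                  np.asarray(d["norm_std"], float)),
            feature_columns=np.asarray(d["feature_columns"], int),
        )


def train_mlp(train_features: np.ndarray, train_labels: Sequence[str],
              hidden_n: int, epochs: int = 200, seed: int = 0,
              learning_rate: float = 0.01,
              feature_columns: Optional[np.ndarray] = None) -> MLPModel:
    """Back-propagation training of the tansig MLP.

    ``train_features`` are raw (un-normalized) rows; normalization
    statistics are fitted here on the training rows only and stored with
    the model.  Weights start uniform in [-0.5, 0.5] scaled by 1/sqrt(fan
    in); updates are per-sample gradient steps on the squared error with a
    fixed learning rate, with the presentation order reshuffled each
    epoch.  Fully reproducible from ``seed``.
    """
    X = np.asarray(train_features, float)
    if feature_columns is not None:
        feature_columns = np.asarray(feature_columns, int)
        if X.shape[1] != feature_columns.size:
            raise ValueError(
                f"feature matrix has {X.shape[1]} columns but "
                f"{feature_columns.size} feature columns were declared")
    else:
        feature_columns = np.arange(X.shape[1])
    if hidden_n < 1:
        raise ValueError("hidden_n must be positive")
    T = labels_to_onehot(train_labels)
    norm = normalize_fit(X)
    Xn = norm.apply(X)
    n, d = Xn.shape

    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, (hidden_n, d)) / np.sqrt(d)
    b1 = np.zeros(hidden_n)
    W2 = rng.uniform(-0.5, 0.5, (N_CLASSES, hidden_n)) / np.sqrt(hidden_n)
    b2 = np.zeros(N_CLASSES)

    lr = learning_rate
    for _ in range(epochs):
        for i in rng.permutation(n):
            x = Xn[i]
            h = np.tanh(W1 @ x + b1)
            y = np.tanh(W2 @ h + b2)
            # squared-error gradients through both tansig layers
            delta2 = (y - T[i]) * (1.0 - y**2)
            delta1 = (W2.T @ delta2) * (1.0 - h**2)
            W2 -= lr * np.outer(delta2, h)
            b2 -= lr * delta2
            W1 -= lr * np.outer(delta1, x)
            b1 -= lr * delta1
    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2, normalizer=norm,
                    feature_columns=feature_columns)


def predict(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Predicted class labels (argmax of the 3 outputs; ties break toward
    the lower class index, i.e. ET before PD before healthy)."""
    X = np.asarray(features, float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"model expects {model.input_dim} features, got {X.shape[1]}")
    Y = model.forward(normalize_apply(model.normalizer, X))
    idx = np.argmax(Y, axis=1)  # first maximum: lower class index wins ties
    labels = np.array([CLASS_LABELS[i] for i in idx])
    return labels[0] if single else labels


@dataclass
class ExperimentResult:
    """Classification error of one configuration and its pathology breakdown.

    ``per_class_error_share`` gives, for each true class, its share of all
    misclassifications (summing to 1 when any errors exist; all zeros when
    classification is perfect).
    """

    group: str
    hidden_n: int
    repeats: int
    mean_error: float
    per_class_error_share: dict
    errors_per_repeat: Optional[list] = None

    def __post_init__(self):
        if not (0.0 <= self.mean_error <= 1.0):
            raise ValueError("mean_error must be a fraction in [0, 1]")


def evaluate(model: MLPModel, features: np.ndarray,
             labels: Sequence[str]) -> ExperimentResult:
    """Validation error and per-pathology error decomposition of one model."""
    X = np.asarray(features, float)
    labels = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty set")
    pred = predict(model, X)
    wrong = pred != labels
    n_err = int(np.count_nonzero(wrong))
    if n_err:
        shares = {c: float(np.count_nonzero(wrong & (labels == c)) / n_err)
                  for c in CLASS_LABELS}
    else:
        shares = {c: 0.0 for c in CLASS_LABELS}
    return ExperimentResult(group="", hidden_n=model.hidden_n, repeats=1,
                            mean_error=n_err / X.shape[0],
                            per_class_error_share=shares)


def run_test_group(train_features: np.ndarray, train_labels: Sequence[str],
                   val_features: np.ndarray, val_labels: Sequence[str],
                   group: str, hidden_range: Sequence[int] = range(2, 11),
                   repeats: int = 10, epochs: int = 200,
                   seed: int = 0,
                   learning_rate: float = 0.01) -> list:
    """Run one experiment group: sweep hidden-layer sizes with repeats.

    ``group`` selects the feature columns ('psd_only' -> parameters 1-9,
    'hos_only' -> 10-26, 'all' -> 1-26).  For each hidden size,
    ``repeats`` seeded trainings are run and the mean validation error and
    mean per-pathology error shares are reported.
    """
    if group not in FEATURE_GROUPS:
        raise ValueError(
            f"unknown group {group!r}; expected one of {sorted(FEATURE_GROUPS)}")
    cols = FEATURE_GROUPS[group]
    Xtr = np.asarray(train_features, float)[:, cols]
    Xva = np.asarray(val_features, float)[:, cols]
    seeds = np.random.SeedSequence(seed).spawn(len(list(hidden_range)) * repeats)
    results = []
    si = 0
    for hidden_n in hidden_range:
        errs = []
        share_acc = {c: [] for c in CLASS_LABELS}
        for _ in range(repeats):
            s = int(seeds[si].generate_state(1)[0] % (2**31))
            si += 1
            model = train_mlp(Xtr, train_labels, hidden_n, epochs=epochs,
                              seed=s, learning_rate=learning_rate,
                              feature_columns=cols)
            res = evaluate(model, Xva, val_labels)
            errs.append(res.mean_error)
            for c in CLASS_LABELS:
                share_acc[c].append(res.per_class_error_share[c])
        results.append(ExperimentResult(
            group=group, hidden_n=hidden_n, repeats=repeats,
            mean_error=float(np.mean(errs)),
            per_class_error_share={c: float(np.mean(v))
                                   for c, v in share_acc.items()},
            errors_per_repeat=[float(e) for e in errs]))
    return results
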