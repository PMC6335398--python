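"""Feedforward-network compression of the joint SFS into ABC summaries.

A four-layer network (input, two hidden layers, output) is trained on
simulated spectra either to classify the generating demographic model
(softmax head) or to predict the generating parameters (linear head); the
network output is then used as the low-dimensional summary statistic
("SS-DL") in the ABC step.

Training uses SFS-like noise injection: instead of white noise, each
training record is mixed cellwise with a reference spectrum computed from
the half of the observed data reserved for noise,

    sfs' = (1 - alpha) * sfs_sim + alpha * sfs_ref,

with alpha drawn fresh per record per epoch from U[0, alpha_max]
(default alpha_max = 0.2).  Because the real data are generated by a process
that at best partially overlaps the candidate models, this pushes the
network towards summaries that remain informative on observed-data-like
inputs.

Estimators follow scikit-learn conventions (``fit`` / ``predict`` /
``get_params``; fitted attributes end in an underscore) and wrap
scikit-learn multilayer perceptrons as the trainer; the frozen forward pass
is re-implemented here in numpy so that :func:`summarize` is a pure,
deterministic function of the stored weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.neural_network import MLPClassifier, MLPRegressor

from .coalsim import JointSFS

__all__ = [
    "NoiseSpec",
    "TrainingSet",
    "TrainedSummaryNet",
    "SFSClassifier",
    "SFSRegressor",
    "inject_noise",
    "train_classifier_net",
    "train_regressor_net",
    "summarize",
]


def inject_noise(sim_sfs: JointSFS, ref_sfs: JointSFS, alpha: float) -> JointSFS:
    """Cellwise mix ``(1 - alpha) * sim + alpha * ref`` (real-valued cells)."""
    if not sim_sfs.same_layout(ref_sfs):
        raise ValueError("simulated and reference SFS layouts differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    cells = (1.0 - alpha) * sim_sfs.cells.astype(float) + alpha * ref_sfs.cells.astype(float)
    return JointSFS(cells, list(sim_sfs.populations))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise-injection configuration: mixing bound and reference spectrum."""

    alpha_max: float = 0.2
    reference: JointSFS | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_max <= 1.0:
            raise ValueError("alpha_max must lie in [0, 1]")
        if self.alpha_max > 0 and self.reference is None:
            raise ValueError("noise injection needs a reference SFS")


class TrainingSet:
    """Simulated training records sharing one SFS layout.

    ``X`` holds the raw included-cell vectors (one row per simulation);
    ``labels`` the generating model letters (classification) and/or
    ``params`` a (n x p) parameter matrix with ``param_names``
    (regression).
    """

    def __init__(self, populations: Sequence[str], shape: tuple[int, ...],
                 X: np.ndarray, labels: np.ndarray | None = None,
                 params: np.ndarray | None = None,
                 param_names: Sequence[str] | None = None,
                 seeds: Sequence[int] | None = None):
        self.populations = list(populations)
        self.shape = tuple(shape)
        self.X = np.asarray(X, dtype=float)
        self.labels = None if labels is None else np.asarray(labels)
        self.params = None if params is None else np.asarray(params, dtype=float)
        self.param_names = list(param_names) if param_names is not None else None
        self.seeds = list(seeds) if seeds is not None else None
        if self.labels is not None and len(self.labels) != len(self.X):
            raise ValueError("labels length mismatch")
        if self.params is not None and len(self.params) != len(self.X):
            raise ValueError("params length mismatch")

    @classmethod
    def from_records(cls, records: Sequence[tuple], seeds=None) -> "TrainingSet":
        """Build from (label_or_param_mapping, JointSFS) pairs."""
        first = records[0][1]
        X = np.empty((len(records), first.to_vector().size))
        labels, params = [], []
        param_names: list[str] | None = None
        for i, (meta, sfs) in enumerate(records):
            if not sfs.same_layout(first):
                raise ValueError("all SFS must share one axis layout")
            X[i] = sfs.to_vector()
            if isinstance(meta, str):
                labels.append(meta)
            elif isinstance(meta, Mapping):
                if param_names is None:
                    param_names = sorted(meta)
                params.append([meta[k] for k in param_names])
        return cls(first.populations, first.shape, X,
                   labels=np.array(labels) if labels else None,
                   params=np.array(params) if params else None,
                   param_names=param_names, seeds=seeds)


@dataclass
class TrainedSummaryNet:
    """Frozen weights and preprocessing of a trained summary network."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]           # (in, out) per layer transition
    biases: list[np.ndarray]
    activation: str                     # relu | logistic | tanh
    head: str                           # softmax | linear
    proportion_normalize: bool
    input_center: np.ndarray
    input_scale: np.ndarray
    output_names: list[str]             # model labels or parameter names
    target_center: np.ndarray | None = None
    target_scale: np.ndarray | None = None
    populations: list[str] | None = None
    sfs_shape: tuple[int, ...] | None = None

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "logistic":
            return special.expit(z)
        if self.activation == "tanh":
            return np.tanh(z)
        raise ValueError(f"unknown activation {self.activation!r}")

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.proportion_normalize:
            totals = X.sum(axis=1, keepdims=True)
            X = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
        return (X - self.input_center) / self.input_scale

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass on raw included-cell vectors."""
        h = self.preprocess(X)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = self._act(h @ W + b)
        out = h @ self.weights[-1] + self.biases[-1]
        if self.head == "softmax":
            if out.shape[1] == 1:  # binary net: single logistic output unit
                p = special.expit(out[:, 0])
                return np.column_stack([1.0 - p, p])
            return special.softmax(out, axis=1)
        if self.target_center is not None:
            out = out * self.target_scale + self.target_center
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return json.dumps({
            "format": "abcdl-summary-net", "version": 1,
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activation": self.activation, "head": self.head,
            "proportion_normalize": self.proportion_normalize,
            "input_center": arr(self.input_center),
            "input_scale": arr(self.input_scale),
            "output_names": list(self.output_names),
            "target_center": arr(self.target_center),
            "target_scale": arr(self.target_scale),
            "populations": self.populations,
            "sfs_shape": list(self.sfs_shape) if self.sfs_shape else None,
        })

    @classmethod
    def from_json(cls, text: str) -> "TrainedSummaryNet":
        d = json.loads(text)
        if d.get("format") != "abcdl-summary-net":
            raise ValueError("not a summary-net file")
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)
        return cls(tuple(d["layer_sizes"]),
                   [np.asarray(w) for w in d["weights"]],
                   [np.asarray(b) for b in d["biases"]],
                   d["activation"], d["head"], d["proportion_normalize"],
                   arr(d["input_center"]), arr(d["input_scale"]),
                   list(d["output_names"]), arr(d["target_center"]),
                   arr(d["target_scale"]), d.get("populations"),
                   tuple(d["sfs_shape"]) if d.get("sfs_shape") else None)


def _default_hidden(d_in: int) -> tuple[int, int]:
    """Geometric compression of the SFS: input/3 and input/9 (at least 2)."""
    return (max(2, -(-d_in // 3)), max(2, -(-d_in // 9)))


class _SummaryNetBase(BaseEstimator):
    def __init__(self, hidden_layer_sizes=None, activation="relu",
                 alpha_max=0.2, reference=None, max_epochs=200, patience=15,
                 learning_rate_init=1e-3, batch_size=32,
                 validation_fraction=0.15, proportion_normalize=True,
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.alpha_max = alpha_max
        self.reference = reference
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate_init = learning_rate_init
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.proportion_normalize = proportion_normalize
        self.random_state = random_state

    # -- shared plumbing ---------------------------------------------------
    def _ref_vector(self, d: int) -> np.ndarray | None:
        if self.reference is None:
            return None
        ref = self.reference
        if isinstance(ref, JointSFS):
            ref = ref.to_vector()
        ref = np.asarray(ref, dtype=float)
        if ref.size != d:
            raise ValueError("reference SFS layout mismatch")
        return ref

    def _normalize_fit(self, X: np.ndarray) -> np.ndarray:
        if self.proportion_normalize:
            totals = X.sum(axis=1, keepdims=True)
            X = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
        self.input_center_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        self.input_scale_ = scale
        return (X - self.input_center_) / self.input_scale_

    def _noisy(self, X_raw: np.ndarray, ref: np.ndarray | None,
               rng: np.random.Generator) -> np.ndarray:
        """Fresh per-record mixing with the reference (raw-count scale)."""
        if ref is None or self.alpha_max == 0:
            alphas = np.zeros((len(X_raw), 1))
        else:
            alphas = rng.uniform(0.0, self.alpha_max, size=(len(X_raw), 1))
        return (1.0 - alphas) * X_raw + alphas * (ref if ref is not None else 0.0)

    def _apply_norm(self, X: np.ndarray) -> np.ndarray:
        if self.proportion_normalize:
            totals = X.sum(axis=1, keepdims=True)
            X = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
        return (X - self.input_center_) / self.input_scale_

    def _epoch(self, mlp, X_raw, y, ref, rng, classes=None) -> None:
        """One training epoch: fresh noise per record, shuffled minibatches."""
        import warnings

        Xn = self._apply_norm(self._noisy(X_raw, ref, rng))
        order = rng.permutation(len(Xn))
        bs = min(self.batch_size, len(Xn))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for start in range(0, len(Xn), bs):
                sel = order[start:start + bs]
                if classes is not None:
                    mlp.partial_fit(Xn[sel], y[sel], classes=classes)
                else:
                    mlp.partial_fit(Xn[sel], y[sel])

    def _freeze(self, mlp, head: str, output_names: list[str],
                target_center=None, target_scale=None,
                populations=None, sfs_shape=None) -> TrainedSummaryNet:
        sizes = (mlp.coefs_[0].shape[0],
                 *[w.shape[1] for w in mlp.coefs_])
        return TrainedSummaryNet(
            layer_sizes=sizes,
            weights=[w.copy() for w in mlp.coefs_],
            biases=[b.copy() for b in mlp.intercepts_],
            activation=self.activation, head=head,
            proportion_normalize=self.proportion_normalize,
            input_center=self.input_center_.copy(),
            input_scale=self.input_scale_.copy(),
            output_names=output_names,
            target_center=target_center, target_scale=target_scale,
            populations=populations, sfs_shape=sfs_shape)


class SFSClassifier(_SummaryNetBase, ClassifierMixin):
    """Model-class summary network: softmax scores over model labels.

    ``fit(X, y)`` takes raw included-cell SFS vectors and model labels;
    ``predict_proba`` is the SS-DL summary.  Two hidden layers default to
    input/3 and input/9 units.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set contains a single model label; "
                             "need at least two classes")
        rng = np.random.default_rng(self.random_state)
        ref = self._ref_vector(X.shape[1])
        n_val = max(1, int(round(self.validation_fraction * len(X))))
        perm = rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(np.unique(y[tr_idx])) < len(classes):
            raise ValueError("a class is missing from the training split; "
                             "provide more records per model")
        hidden = self.hidden_layer_sizes or _default_hidden(X.shape[1])
        if len(hidden) != 2:
            raise ValueError("four-layer network: exactly two hidden layers")
        self._normalize_fit(X)  # stats from the full clean training set
        mlp = MLPClassifier(hidden_layer_sizes=tuple(hidden),
                            activation=self.activation, solver="adam",
                            learning_rate_init=self.learning_rate_init,
                            random_state=int(self.random_state))
        X_val = self._apply_norm(X[val_idx])
        y_val = y[val_idx]
        best_loss, best_state, since_best = np.inf, None, 0
        self.loss_curve_ = []
        for _epoch in range(self.max_epochs):
            self._epoch(mlp, X[tr_idx], y[tr_idx], ref, rng, classes=classes)
            proba = np.clip(mlp.predict_proba(X_val), 1e-12, 1.0)
            onehot = (y_val[:, None] == mlp.classes_[None, :]).astype(float)
            val_loss = float(-(onehot * np.log(proba)).sum(axis=1).mean())
            self.loss_curve_.append((float(mlp.loss_), val_loss))
            if not np.isfinite(mlp.loss_):
                raise FloatingPointError("non-finite training loss")
            if val_loss < best_loss - 1e-6:
                best_loss, since_best = val_loss, 0
                best_state = ([w.copy() for w in mlp.coefs_],
                              [b.copy() for b in mlp.intercepts_])
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_state is not None:
            mlp.coefs_, mlp.intercepts_ = best_state
        self.classes_ = mlp.classes_
        self.net_ = self._freeze(mlp, "softmax", [str(c) for c in mlp.classes_])
        self.validation_loss_ = best_loss
        return self

    def predict_proba(self, X):
        return self.net_.forward(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class SFSRegressor(_SummaryNetBase, RegressorMixin):
    """Parameter summary network: one linear output head per parameter.

    Targets are z-scored internally against the training draws; predictions
    are returned in original units.  ``heldout_correlation_`` reports the
    per-parameter Pearson correlation on the internal held-out split.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        t_sd = y.std(axis=0)
        if np.any(t_sd < 1e-15):
            raise ValueError("constant (zero-variance) target parameter; "
                             "fixed-prior parameters cannot be regressed")
        self.target_center_ = y.mean(axis=0)
        self.target_scale_ = t_sd
        yz = (y - self.target_center_) / self.target_scale_
        rng = np.random.default_rng(self.random_state)
        ref = self._ref_vector(X.shape[1])
        n_val = max(1, int(round(self.validation_fraction * len(X))))
        perm = rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        hidden = self.hidden_layer_sizes or _default_hidden(X.shape[1])
        if len(hidden) != 2:
            raise ValueError("four-layer network: exactly two hidden layers")
        self._normalize_fit(X)
        mlp = MLPRegressor(hidden_layer_sizes=tuple(hidden),
                           activation=self.activation, solver="adam",
                           learning_rate_init=self.learning_rate_init,
                           random_state=int(self.random_state))
        X_val = self._apply_norm(X[val_idx])
        best_loss, best_state, since_best = np.inf, None, 0
        self.loss_curve_ = []
        for _epoch in range(self.max_epochs):
            self._epoch(mlp, X[tr_idx], yz[tr_idx], ref, rng)
            pred = mlp.predict(X_val)
            if pred.ndim == 1:
                pred = pred[:, None]
            val_loss = float(((pred - yz[val_idx]) ** 2).mean())
            self.loss_curve_.append((float(mlp.loss_), val_loss))
            if not np.isfinite(mlp.loss_):
                raise FloatingPointError("non-finite training loss")
            if val_loss < best_loss - 1e-8:
                best_loss, since_best = val_loss, 0
                best_state = ([w.copy() for w in mlp.coefs_],
                              [b.copy() for b in mlp.intercepts_])
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_state is not None:
            mlp.coefs_, mlp.intercepts_ = best_state
        names = [f"param_{i}" for i in range(y.shape[1])]
        self.net_ = self._freeze(mlp, "linear", names,
                                 target_center=self.target_center_.copy(),
                                 target_scale=self.target_scale_.copy())
        pred_val = self.net_.forward(X[val_idx])
        corr = np.empty(y.shape[1])
        for j in range(y.shape[1]):
            corr[j] = np.corrcoef(pred_val[:, j], y[val_idx, j])[0, 1]
        self.heldout_correlation_ = corr
        return self

    def predict(self, X):
        out = self.net_.forward(np.asarray(X, dtype=float))
        return out[:, 0] if out.shape[1] == 1 else out


# ---------------------------------------------------------------------------
# functional wrappers over the estimators
# ---------------------------------------------------------------------------

def _noise_kwargs(noise: NoiseSpec | None) -> dict:
    if noise is None:
        return {"alpha_max": 0.0, "reference": None}
    return {"alpha_max": noise.alpha_max, "reference": noise.reference}


def train_classifier_net(train: TrainingSet, noise: NoiseSpec | None = None,
                         hyper: Mapping | None = None,
                         rng_seed: int = 0) -> TrainedSummaryNet:
    """Train the model-classification summary network on a training set."""
    if train.labels is None:
        raise ValueError("training set has no model labels")
    clf = SFSClassifier(random_state=rng_seed, **_noise_kwargs(noise),
                        **dict(hyper or {}))
    clf.fit(train.X, train.labels)
    net = clf.net_
    net.populations = list(train.populations)
    net.sfs_shape = tuple(train.shape)
    return net


def train_regressor_net(train: TrainingSet, noise: NoiseSpec | None = None,
                        target: str | Sequence[str] | None = None,
                        hyper: Mapping | None = None,
                        rng_seed: int = 0) -> TrainedSummaryNet:
    """Train the parameter-prediction summary network; ``target`` selects
    parameter name(s) (default: all)."""
    if train.params is None:
        raise ValueError("training set has no parameter draws")
    names = train.param_names or [f"param_{i}" for i in range(train.params.shape[1])]
    if target is None:
        targets = names
    else:
        targets = [target] if isinstance(target, str) else list(target)
    idx = [names.index(t) for t in targets]
    reg = SFSRegressor(random_state=rng_seed, **_noise_kwargs(noise),
                       **dict(hyper or {}))
    reg.fit(train.X, train.params[:, idx])
    net = reg.net_
    net.output_names = targets
    net.populations = list(train.populations)
    net.sfs_shape = tuple(train.shape)
    return net


def summarize(net: TrainedSummaryNet, sfs: JointSFS | np.ndarray) -> np.ndarray:
    """SS-DL: forward pass of the frozen network on one spectrum."""
    if isinstance(sfs, JointSFS):
        if net.populations is not None and (list(sfs.populations) != net.populations
                                            or tuple(sfs.shape) != net.sfs_shape):
            raise ValueError("SFS layout does not match the training layout")
        x = sfs.to_vector()
    else:
        x = np.asarray(sfs, dtype=float)
    if x.ndim == 1 and x.size != net.layer_sizes[0]:
        raise ValueError("input size does not match the network")
    return net.forward(x)[0] if x.ndim == 1 else net.forward(x)
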